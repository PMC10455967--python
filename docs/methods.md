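# Methods

## Scope

`petrokin` quantifies the stepwise hydrogen/deuterium exchange of a small
molecule — specifically the petrosamine molecular cation, C21H17BrN3O2 (+1),
whose two equivalent methylene protons α to a ketone exchange in deuterated
solvent — from rapid-sampling centroided ESI-TOF spectra. The chain is:
exact-mass and isotope-pattern computation, extraction of d0/d1/d2 channel
intensities, natural-abundance correction, and nonlinear fitting of the
sequential first-order kinetic model. Ancillary modules quantify
solvatochromic band shifts, bound a pKa from a flat spectrophotometric
titration, and convert NMR detection limits into tautomer-equilibrium
bounds. A synthetic-data generator reproduces the statistical structure of
the experiment so the whole pipeline can be validated end to end.

## Mass computation

Isotope masses and abundances are pinned in `petrokin/data/isotopes.csv`
(AME2020 masses, CIAAW 2021 representative abundances); all m/z arithmetic
derives from this single table for reproducibility at the 0.1 mDa level.
Monoisotopic m/z of a charged species is the sum of lightest-isotope
masses, with n hydrogen masses swapped for deuterium, **minus z electron
masses**, divided by |z|. The electron-mass convention is deliberate: for
the petrosamine cation the uncorrected sum is 422.0504 Da while the
corrected value is 422.0499 — the value a calibrated instrument reports for
a cation — and the same convention reproduces the d1 (423.0561) and d2
(424.0624) species to four decimals.

Isotope patterns are full multinomial convolutions over the pinned
abundances, computed per element by binary-exponentiation convolution with
terms below 1e-14 pruned, then convolved across elements. Deuterated
positions contribute a fixed ²H mass; the remaining hydrogens keep their
natural ¹H/²H distribution. Fine structure is centroided the way a TOF
instrument merges unresolved peaks: adjacent peaks closer than
m/z / RP (RP = resolving power, m/Δm FWHM, default 20,000) are greedily
merged left to right into abundance-weighted centroids. After optional
floor pruning the pattern is renormalized to sum to 1.

## Why natural-abundance correction matters here

For a brominated analyte the measurement channels overlap satellite
structure of lighter isotopologues at TOF resolution:

- the ¹³C₁ satellite of d0 lies ~3 mDa below the d1 monoisotopic peak
  (unresolved at RP 20,000, where the peak width at m/z 423 is ~21 mDa);
- the ⁸¹Br satellite of d0 lies ~15 mDa below the d2 peak — also
  unresolved, and nearly as intense as the monoisotopic peak
  (⁸¹Br/⁷⁹Br ≈ 0.973).

Observed channel intensities are therefore `r = M f`, with `f` the true
molar fractions and `M` the lower-triangular matrix whose column j is the
isotope pattern of the j-deuterated species binned into the channels
(a centroid is booked to channel n when it lies within the resolution
width of the channel center; abundance outside every channel is a
per-column loss factor). Correction solves the triangular system, clips
negative components (noise), renormalizes, and flags the result when the
clipped mass exceeds 2% of the total; a non-negative least-squares solve
is available as an alternative to clipping.

**Window consistency.** Extraction and matrix binning must share one
window. The instrument model merges a satellite and a neighboring channel
peak into a single composite centroid whose position moves with
composition; an extraction window much narrower than the resolution width
(e.g. 10 ppm ≈ ±4 mDa) can miss that centroid entirely and break the
correction. `extract_raw_intensities` keeps a conventional 10 ppm default
for isolated-peak work, but the pipeline entry point
(`correct_time_course`) defaults the window to the resolution width
(1e6/RP ppm), matching the matrix. With that choice the noiseless chain
reproduces the generator's fractions to better than 1e-6 (tested to
1e-14 in practice).

## Kinetic model and fitting

The sequential scheme d0 →(k1) d1 →(k2) d2 has the closed form

    f_d0(t) = e^{-k1 t}
    f_d1(t) = k1/(k2-k1) (e^{-k1 t} - e^{-k2 t})
    f_d2(t) = 1 - f_d0 - f_d1

with the limit f_d1 = k1 t e^{-k1 t} used when |k1-k2| < 1e-9·max(k1,k2)
to avoid catastrophic cancellation. The closed form is verified against a
Runge-Kutta integration of the rate equations to < 1e-8 over
t ∈ [0, 300] s and rates in [1e-3, 1] s⁻¹. For two equivalent sites with
no primary kinetic isotope effect the macroscopic rates obey the
statistical factor k1/k2 = 2 (two ways to make the first exchange, one for
the second); `ratio_test` propagates the parameter covariance to the ratio
(delta method) and reports whether ratio ± 1.96σ contains 2.

Fitting follows the Model/Results convention: `SequentialExchange` pools
all replicates and all three fraction trajectories; `fit()` minimizes the
residuals with `scipy.optimize.least_squares` (TRF, bounds default
(1e-6, 10) s⁻¹). Initialization: k1 from a log-linear regression of f_d0
against t, k2 = k1/2 (the statistical-factor prior). k1 ≥ k2 is preferred
at initialization only — f_d2 is symmetric under k1 ↔ k2 but f_d0 and
f_d1 are not, so the joint fit is identifiable; if the optimizer settles
on k2 > k1 the results flag `label_swapped` rather than silently
reordering. Estimates pinned at the bounds (e.g. from a series with no
exchange) set `at_bounds` and a summary warning instead of returning a
silent k ≈ 0.

**Error model.** Corrected fractions are neither homoscedastic nor
independent within a scan: multiplicative (electrospray-type) intensity
noise propagates through the correction solve and the renormalization,
inflating some components and correlating all three (they sum to 1). An
unweighted fit still gives essentially unbiased point estimates, but its
Jacobian covariance misallocates uncertainty between k1 and k2 (observed
coverage of a nominal 95% interval for k2 was ~79% in a 200-repeat study).
When the correction matrix is supplied, `fit()` therefore whitens each
scan's residual with the first-order propagated covariance of the
corrected fractions under proportional channel noise,

    Cov(x) ∝ C Cᵀ,   C = (I − f 1ᵀ) M⁻¹ diag(M f),

which has rank 2 (the sum constraint); residuals are projected onto that
subspace and scaled, leaving one overall scale (the channel CV) estimated
from the whitened residual variance. A first unweighted pass supplies the
f used in the whitener; a second, whitened pass yields the estimates and
t-based Wald intervals. This restores near-nominal calibration
(95.5%/94% coverage for k1/k2; the delta-method ratio σ matches the
Monte-Carlo scatter of the ratio within 10%). Without a matrix the fit
falls back to plain unweighted least squares. A replicate-resampling
percentile bootstrap (seeded, default 1000 draws) is available as an
alternative interval method, though with triplicate data its resampling
base is small.

A consequence worth stating plainly: under the generator's default
conditions (3% noise, 7 timepoints × 3 replicates) the pipeline resolves
the rate ratio to ~0.3% relative uncertainty, so a fit to data generated
at k1/k2 = 0.1311/0.0755 = 1.736 correctly *excludes* the statistical
factor 2.0. The consistency flag answers a question about uncertainty:
it is true only when the data are noisy enough (σ_ratio ≳ 0.13 at this
ratio) that the factor of 2 cannot be distinguished.

## Synthetic data

`simulate_time_course` emulates the reference experiment: dissolution at
t = 0, scans at 0, 15, …, 90 s, triplicate runs, RP 20,000, the analyte's
full natural isotope structure per d-species, cross-species centroid
merging at the instrument resolution, and independent multiplicative
log-normal noise per centroid (CV default 0.03, mean-one
parameterization). All randomness flows from one seed through
`numpy.random.SeedSequence` per-replicate substreams, so replicate r2 is
byte-identical whether 2 or 3 replicates are generated. An optional
`dead_time_s` shifts the kinetic clock to emulate the unknown delay
between dissolution and the first scan — the main unmodeled nuisance of
the real experiment; it defaults to 0 (model time).

What the generator does **not** emulate: ionization physics and ion
suppression, drift of the external methanol reference channel (external
normalization is retained only as a diagnostic; fractions are
scale-invariant), profile-mode peak shapes, mass-calibration error, and
back-exchange. Passing tests therefore demonstrate correctness of the
computational chain under the stated noise model, not robustness to every
instrumental artifact.

Problem sizes used in the shipped tests and acceptance computations:
63 pooled observations (3 replicates × 7 timepoints × 3 fractions) per
fit; 200 Monte-Carlo repeats for the bias/coverage study; enumeration
oracles limited to ≤ 11-atom formulas.

## Acid-base and solvatochromism

`hh_fraction_deprotonated` is the logistic form of the
Henderson-Hasselbalch relation. A titration series whose maximum pairwise
relative spectral change — max over wavelengths of |A_i − A_j| / max(A) —
stays below a threshold (default 0.05, operationalizing "unchanged")
yields an exclusion verdict: the pKa lies outside the sampled window,
with a ±1 pH margin reflecting the detectability width of a two-state
transition. Otherwise the pH of steepest change (parabolic interpolation
over adjacent-pair gradients) is returned as a crude locator, accurate to
~0.2 units on grids of ≤ 0.5 pH steps. `tautomer_ratio_upper_bound` maps
an integration detection limit f to Keq ≤ f/(1−f).

Band shifts over the packaged DMSO-water series are reported as a
magnitude plus an explicit direction label (hypsochromic = blue shift
with increasing water fraction, bathochromic = red, "none" below 1 nm),
because raw signed deltas are ambiguous about which endpoint is the
reference. Wavelength-energy conversion uses hc = 1239.841984 eV·nm.
The packaged table carries its printed normalization note (ε scaled to
the literature value 4700 M⁻¹cm⁻¹ at λ_max2 in pure water).

## Known limitations

- Single charge states only; no adducts beyond the bare cation convention.
- Two exchangeable sites (d0/d1/d2); no multi-site generalization.
- No back-exchange; the model assumes an irreversible d0→d1→d2 cascade,
  valid in a large excess of deuterated solvent.
- The channel-noise error model assumes a common CV across peaks and
  scans; strongly time-varying spray stability would call for per-scan
  scales.
- The pKa locator assumes a single two-state transition in the window.
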