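"""Isotopologue quantification from centroided spectra.

Converts timestamped centroided peak lists into natural-abundance-corrected
d0/d1/d2 molar fractions.  The correction matters because for a brominated
analyte the satellites of lighter isotopologues land, unresolved at TOF
resolving power, inside the measurement channels of heavier ones: the 13C1
satellite of d0 sits ~3 mDa from the d1 monoisotopic peak, and the 81Br
satellite of d0 sits ~15 mDa from the d2 peak.  Observed channel
intensities are therefore a triangular convolution of the true fractions,
undone here by a linear solve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import nnls

from .formula import ElementCounts, isotope_pattern, monoisotopic_mz

__all__ = [
    "CentroidSpectrum",
    "IsotopologueTimeSeries",
    "RawIntensities",
    "CorrectedFractions",
    "extract_raw_intensities",
    "build_correction_matrix",
    "correct_fractions",
    "normalize_to_reference",
    "correct_time_course",
    "read_peaks_csv",
    "read_peaks_json",
    "fractions_to_frame",
    "write_fractions_csv",
    "read_fractions_csv",
]

#: Fraction of clipped negative mass above which a correction is flagged.
CLIP_FLAG_THRESHOLD = 0.02


@dataclass(frozen=True)
class CentroidSpectrum:
    """One centroided scan: (m/z, intensity) peaks at a given reaction time."""

    time_s: float
    peaks: tuple[tuple[float, float], ...]
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError("time_s must be >= 0")
        mz = self.mz
        if np.any(np.diff(mz) < 0):
            raise ValueError("peaks must be sorted by m/z")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum()) if self.peaks else 0.0


@dataclass(frozen=True)
class IsotopologueTimeSeries:
    """Corrected isotopologue fractions over time for one replicate."""

    replicate_id: str
    times_s: np.ndarray
    fractions: np.ndarray  # shape (n_times, max_d + 1), rows sum to 1
    raw_intensities: np.ndarray  # same shape, pre-correction channel sums
    quality_flags: tuple[str, ...] = ()
    reference_intensity: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing within a replicate")
        f = np.asarray(self.fractions, float)
        good = ~np.all(f == 0, axis=1)  # all-zero rows mark no-signal scans
        if np.any(np.abs(f[good].sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("fraction rows must sum to 1")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "raw_intensities", np.asarray(self.raw_intensities, float))


@dataclass(frozen=True)
class RawIntensities:
    """Channel intensity vector for one scan, with a no-signal flag."""

    intensities: np.ndarray
    no_signal: bool


@dataclass(frozen=True)
class CorrectedFractions:
    fractions: np.ndarray
    clipped_mass: float
    flagged: bool


def extract_raw_intensities(
    spectrum: CentroidSpectrum,
    ec: ElementCounts,
    max_d: int = 2,
    tol_ppm: float = 10.0,
) -> RawIntensities:
    """Sum peak intensities within ``tol_ppm`` of each d0..d_max channel.

    Channel centers are the monoisotopic m/z of the 0..max_d deuterated
    species.  An entirely empty window set yields a flagged no-signal
    result rather than an exception, so a dropped scan does not abort a
    time course.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if max_d > ec.counts.get("H", 0):
        raise ValueError("max_d exceeds the hydrogen count of the formula")
    mz = spectrum.mz
    inten = spectrum.intensity
    out = np.zeros(max_d + 1)
    for n in range(max_d + 1):
        center = monoisotopic_mz(ec.with_deuterium(n))
        half = tol_ppm * 1e-6 * center
        sel = np.abs(mz - center) < half
        out[n] = inten[sel].sum()
    return RawIntensities(out, no_signal=bool(out.sum() == 0))


def build_correction_matrix(
    ec: ElementCounts,
    max_d: int = 2,
    resolving_power: float = 20000.0,
) -> np.ndarray:
    """Natural-abundance correction matrix for the d0..d_max channels.

    Column ``j`` is the isotope pattern of the j-deuterated species binned
    into the measurement channels: a pattern centroid is assigned to
    channel ``n`` when it lies within the resolution width
    ``m/z / resolving_power`` of the channel center.  Pattern abundance
    falling outside every channel is the per-column loss factor
    ``1 - column_sum``.  The matrix is lower-triangular (a j-deuterated
    species has no peaks lighter than its own monoisotopic mass), which is
    what makes the correction a stable forward substitution.
    """
    if resolving_power <= 0:
        raise ValueError("resolving_power must be > 0")
    centers = np.array([monoisotopic_mz(ec.with_deuterium(n)) for n in range(max_d + 1)])
    widths = centers / resolving_power
    if max_d >= 1:
        spacing = np.diff(centers)
        if np.all(widths[:-1] >= spacing):
            raise ValueError(
                "channels indistinguishable: resolution width exceeds the "
                "deuterium channel spacing everywhere"
            )
    M = np.zeros((max_d + 1, max_d + 1))
    for j in range(max_d + 1):
        pat = isotope_pattern(
            ec.with_deuterium(j), resolving_power=resolving_power, abundance_floor=0.0
        )
        for mz, ab in pat.peaks:
            dist = np.abs(mz - centers)
            n = int(np.argmin(dist))
            if dist[n] < widths[n]:
                M[n, j] += ab
    return M


def correct_fractions(
    raw: np.ndarray, M: np.ndarray, method: str = "solve"
) -> CorrectedFractions:
    """Undo isotope-satellite cross-talk: solve ``M x = raw`` for fractions.

    Negative components of the solution (noise pushed below zero) are
    clipped and the result renormalized to a probability vector; the
    clipped mass is reported and the result flagged when it exceeds
    :data:`CLIP_FLAG_THRESHOLD` of the total.  ``method="nnls"`` solves the
    non-negatively constrained least-squares problem instead of clipping.
    """
    raw = np.asarray(raw, float)
    M = np.asarray(M, float)
    if np.any(np.diag(M) <= 0):
        raise np.linalg.LinAlgError("correction matrix is singular (zero diagonal)")
    if raw.sum() == 0:
        return CorrectedFractions(np.zeros_like(raw), 0.0, True)
    if method == "nnls":
        x, _ = nnls(M, raw)
        clipped = 0.0
    elif method == "solve":
        x = solve_triangular(M, raw, lower=True)
        neg = x < 0
        clipped = float(-x[neg].sum())
        x = np.where(neg, 0.0, x)
    else:
        raise ValueError(f"unknown method {method!r}")
    total = x.sum()
    if total == 0:
        return CorrectedFractions(np.zeros_like(raw), clipped, True)
    frac_clipped = clipped / (total + clipped)
    return CorrectedFractions(x / total, clipped, frac_clipped > CLIP_FLAG_THRESHOLD)


def normalize_to_reference(
    series: IsotopologueTimeSeries, reference_intensity: float
) -> IsotopologueTimeSeries:
    """Scale raw intensities by an external reference ion intensity.

    Mirrors the bench practice of normalizing the analyte [M]+ signal to
    that of an undeuterated reference solution at the same concentration;
    it controls for ionization drift and leaves fractions untouched
    (fractions are scale-invariant).
    """
    if reference_intensity <= 0:
        raise ValueError("reference_intensity must be > 0")
    return replace(
        series,
        raw_intensities=series.raw_intensities / reference_intensity,
        reference_intensity=reference_intensity,
    )


def correct_time_course(
    spectra: Iterable[CentroidSpectrum],
    ec: ElementCounts,
    max_d: int = 2,
    resolving_power: float = 20000.0,
    tol_ppm: float | None = None,
    correction: bool = True,
) -> list[IsotopologueTimeSeries]:
    """Run extract -> correct over a whole time course, per replicate.

    ``tol_ppm=None`` matches the extraction window to the resolution width
    used by the correction matrix (``1e6 / resolving_power`` ppm), so that
    every satellite the matrix books into a channel is also collected by
    the extractor — the two steps must share one window for the correction
    to be exact.  Pass an explicit ``tol_ppm`` to override.
    """
    if tol_ppm is None:
        tol_ppm = 1e6 / resolving_power
    M = build_correction_matrix(ec, max_d, resolving_power) if correction else np.eye(max_d + 1)
    by_rep: dict[str, list[CentroidSpectrum]] = {}
    for s in spectra:
        by_rep.setdefault(s.replicate_id, []).append(s)
    out = []
    for rep, scans in by_rep.items():
        scans.sort(key=lambda s: s.time_s)
        times, fracs, raws, flags = [], [], [], []
        for s in scans:
            r = extract_raw_intensities(s, ec, max_d, tol_ppm)
            if r.no_signal:
                times.append(s.time_s)
                fracs.append(np.zeros(max_d + 1))
                raws.append(r.intensities)
                flags.append("no_signal")
                continue
            c = correct_fractions(r.intensities, M)
            times.append(s.time_s)
            fracs.append(c.fractions)
            raws.append(r.intensities)
            flags.append("clipped" if c.flagged else "ok")
        out.append(
            IsotopologueTimeSeries(
                replicate_id=rep,
                times_s=np.array(times),
                fractions=np.array(fracs),
                raw_intensities=np.array(raws),
                quality_flags=tuple(flags),
            )
        )
    return out


# ---------------------------------------------------------------------------
# plain-text IO


def read_peaks_csv(path) -> list[CentroidSpectrum]:
    """Read the peak-list dialect ``replicate_id,time_s,mz,intensity``."""
    df = pd.read_csv(path, comment="#")
    required = {"replicate_id", "time_s", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak-list CSV missing columns: {sorted(missing)}")
    spectra = []
    for (rep, t), grp in df.groupby(["replicate_id", "time_s"], sort=True):
        grp = grp.sort_values("mz")
        spectra.append(
            CentroidSpectrum(
                time_s=float(t),
                peaks=tuple(zip(grp["mz"].astype(float), grp["intensity"].astype(float))),
                replicate_id=str(rep),
            )
        )
    return spectra


def read_peaks_json(path) -> list[CentroidSpectrum]:
    """Read a JSON array of ``{replicate_id, time_s, peaks: [[mz, i], ...]}``."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return [
        CentroidSpectrum(
            time_s=float(obj["time_s"]),
            peaks=tuple((float(m), float(i)) for m, i in sorted(obj["peaks"])),
            replicate_id=str(obj.get("replicate_id", "r1")),
        )
        for obj in data
    ]


def spectra_to_frame(spectra: Sequence[CentroidSpectrum]) -> pd.DataFrame:
    rows = [
        (s.replicate_id, s.time_s, mz, i)
        for s in spectra
        for mz, i in s.peaks
    ]
    return pd.DataFrame(rows, columns=["replicate_id", "time_s", "mz", "intensity"])


def fractions_to_frame(series: Sequence[IsotopologueTimeSeries]) -> pd.DataFrame:
    """Tidy frame ``replicate_id,time_s,f_d0..f_dN,quality_flag``."""
    rows = []
    for s in series:
        flags = s.quality_flags or ("ok",) * len(s.times_s)
        for t, f, flag in zip(s.times_s, s.fractions, flags):
            rows.append({"replicate_id": s.replicate_id, "time_s": t, "quality_flag": flag}
                        | {f"f_d{n}": v for n, v in enumerate(f)})
    df = pd.DataFrame(rows)
    cols = ["replicate_id", "time_s"] + [c for c in df.columns if c.startswith("f_d")] + ["quality_flag"]
    return df[cols]


def write_fractions_csv(series: Sequence[IsotopologueTimeSeries], path) -> None:
    fractions_to_frame(series).to_csv(path, index=False)


def read_fractions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns or not any(c.startswith("f_d") for c in df.columns):
        raise ValueError("fractions CSV must have time_s and f_d* columns")
    return df
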