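"""Henderson-Hasselbalch utilities and detection-limit bounds.

A chromophore whose UV-vis spectrum is flat across a pH window cannot have
its pKa inside that window: a two-state acid/base transition is detectable
spectrophotometrically within about +/- 1 pH unit of the pKa.  This module
operationalizes that argument (pKa exclusion from a flat titration series,
or a crude pKa locator when the series does change), and converts an NMR
integration detection limit for an undetected minor tautomer into an upper
bound on the tautomerization equilibrium constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TitrationSeries",
    "PkaBoundResult",
    "hh_fraction_deprotonated",
    "pka_bound_from_flat_titration",
    "tautomer_ratio_upper_bound",
]


@dataclass(frozen=True)
class TitrationSeries:
    """Absorbance vectors (fixed wavelength grid) measured at several pH."""

    ph: np.ndarray
    spectra: np.ndarray  # shape (n_ph, n_wavelengths)
    wavelengths_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, float)
        spectra = np.asarray(self.spectra, float)
        if len(np.unique(ph)) != len(ph):
            raise ValueError("pH values must be distinct")
        if spectra.ndim != 2 or spectra.shape[0] != len(ph):
            raise ValueError("spectra must be (n_ph, n_wavelengths)")
        if np.any(spectra < 0):
            raise ValueError("absorbances must be >= 0")
        order = np.argsort(ph)
        object.__setattr__(self, "ph", ph[order])
        object.__setattr__(self, "spectra", spectra[order])


@dataclass(frozen=True)
class PkaBoundResult:
    """Outcome of a flat-titration analysis.

    ``kind == "exclusion"``: the spectrum never changed, so the pKa lies
    outside the sampled window ``excluded_window``; ``pka_below`` /
    ``pka_above`` widen that window by the one-unit detectability margin.
    ``kind == "estimate"``: the series does change and ``pka_estimate``
    locates the steepest spectral change.
    """

    kind: str
    max_relative_change: float
    excluded_window: tuple[float, float] | None = None
    pka_below: float | None = None
    pka_above: float | None = None
    pka_estimate: float | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.kind == "exclusion":
            lo, hi = self.excluded_window
            return (
                f"spectra unchanged (max relative change "
                f"{self.max_relative_change:.3f}): pKa outside [{lo:g}, {hi:g}] "
                f"(pKa < {self.pka_below:g} or pKa > {self.pka_above:g})"
            )
        return f"spectral transition located: pKa ~ {self.pka_estimate:.2f}"


def hh_fraction_deprotonated(ph, pka):
    """Deprotonated fraction [A-]/([HA]+[A-]) from pH = pKa + log10([A-]/[HA]).

    Vectorized over either argument; returns values in (0, 1) with
    f = 1/2 exactly at pH = pKa.
    """
    x = np.asarray(ph, float) - np.asarray(pka, float)
    # logistic form in base 10; stable for extreme pH
    out = 1.0 / (1.0 + 10.0 ** (-x))
    return out if out.ndim else float(out)


def _pair_change(a: np.ndarray, b: np.ndarray, scale: float) -> float:
    return float(np.max(np.abs(a - b)) / scale)


def pka_bound_from_flat_titration(
    series: TitrationSeries, change_threshold: float = 0.05
) -> PkaBoundResult:
    """Bound or locate a pKa from a pH series of spectra.

    The spectral-change metric between two pH points is
    ``max_wavelength |A_i - A_j| / max(A)`` over the whole series.  If no
    pair exceeds ``change_threshold`` the verdict is exclusion: the pKa
    lies outside the sampled pH window (with a one-unit margin reflecting
    the detectability width of a two-state transition).  Otherwise the pH
    of steepest change, refined by parabolic interpolation over adjacent
    pair gradients, is returned as a crude pKa estimate.
    """
    if not 0.0 < change_threshold < 1.0:
        raise ValueError("change_threshold must be in (0, 1)")
    ph, spectra = series.ph, series.spectra
    if len(ph) < 3:
        raise ValueError("need at least 3 pH points")
    scale = float(spectra.max())
    if scale == 0:
        raise ValueError("all-zero spectra")

    n = len(ph)
    max_change = max(
        _pair_change(spectra[i], spectra[j], scale)
        for i in range(n)
        for j in range(i + 1, n)
    )
    if max_change < change_threshold:
        return PkaBoundResult(
            kind="exclusion",
            max_relative_change=max_change,
            excluded_window=(float(ph[0]), float(ph[-1])),
            pka_below=float(ph[0]) - 1.0,
            pka_above=float(ph[-1]) + 1.0,
        )

    # gradient of spectral change between successive pH points
    grads = np.array(
        [_pair_change(spectra[i], spectra[i + 1], scale) / (ph[i + 1] - ph[i]) for i in range(n - 1)]
    )
    mids = 0.5 * (ph[:-1] + ph[1:])
    i = int(np.argmax(grads))
    est = mids[i]
    if 0 < i < len(grads) - 1:
        # parabolic vertex through the three top gradient points
        x0, x1, x2 = mids[i - 1 : i + 2]
        y0, y1, y2 = grads[i - 1 : i + 2]
        denom = (x0 - x1) * (y1 - y2) - (x1 - x2) * (y0 - y1)
        if denom != 0:
            num = (x0**2 - x1**2) * (y1 - y2) - (x1**2 - x2**2) * (y0 - y1)
            est = 0.5 * num / denom
    return PkaBoundResult(kind="estimate", max_relative_change=max_change, pka_estimate=float(est))


def tautomer_ratio_upper_bound(detection_limit_fraction: float) -> float:
    """Upper bound on Keq for an NMR-undetected minor tautomer.

    If the minor species would have been detected above a molar fraction
    ``f`` of the total, its absence bounds the equilibrium constant by
    ``Keq <= f / (1 - f)``.
    """
    f = float(detection_limit_fraction)
    if not 0.0 < f < 0.5:
        raise ValueError("detection_limit_fraction must be in (0, 0.5)")
    return f / (1.0 - f)
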