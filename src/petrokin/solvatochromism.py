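"""Solvatochromic band-shift quantification.

Merocyanine-like chromophores shift their absorption maxima with solvent
polarity: stabilization of a zwitterionic ground state in water raises the
transition energy of the long-wavelength band (hypsochromic/blue shift),
while band intensities can collapse as the dominant resonance form changes.
This module quantifies such trends over a solvent-composition series — the
packaged reference series is petrosamine in DMSO-H2O mixtures — and
converts wavelengths to transition energies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd

__all__ = [
    "SolvatochromicSeries",
    "BandShift",
    "EpsilonTrend",
    "load_reference_series",
    "band_shift",
    "epsilon_trend",
    "nm_to_ev",
    "ev_to_nm",
    "HC_EV_NM",
]

#: hc in eV.nm (CODATA): E[eV] = HC_EV_NM / lambda[nm].
HC_EV_NM = 1239.841984

#: Shifts smaller than this are classified as "none".
_SHIFT_FLOOR_NM = 1.0


@dataclass(frozen=True)
class SolvatochromicSeries:
    """lambda_max / epsilon records for two bands over a solvent series."""

    records: pd.DataFrame  # columns water_pct, lmax1_nm, eps1, lmax2_nm, eps2

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        required = {"water_pct", "lmax1_nm", "eps1", "lmax2_nm", "eps2"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"series missing columns: {sorted(missing)}")
        w = df["water_pct"].to_numpy(float)
        if np.any((w < 0) | (w > 100)):
            raise ValueError("water_pct must lie in [0, 100]")
        if np.any(np.diff(w) <= 0):
            raise ValueError("water_pct must be strictly increasing")
        if np.any(df[["lmax1_nm", "lmax2_nm"]].to_numpy(float) <= 0):
            raise ValueError("wavelengths must be > 0")
        if np.any(df[["eps1", "eps2"]].to_numpy(float) <= 0):
            raise ValueError("molar absorptivities must be > 0")
        object.__setattr__(self, "records", df)

    def lmax(self, band: int) -> np.ndarray:
        return self.records[_band_col(band, "lmax")].to_numpy(float)

    def eps(self, band: int) -> np.ndarray:
        return self.records[_band_col(band, "eps")].to_numpy(float)

    def reversed(self) -> "SolvatochromicSeries":
        """Series traversed from high to low water content (for symmetry checks)."""
        df = self.records.iloc[::-1].reset_index(drop=True).copy()
        df["water_pct"] = 100.0 - df["water_pct"].to_numpy(float)
        return SolvatochromicSeries(df)


@dataclass(frozen=True)
class BandShift:
    """Signed and magnitude-form band shift along increasing water content."""

    delta_lambda_nm: float  # magnitude, nm
    signed_delta_nm: float  # lambda(first) - lambda(last)
    classification: str  # hypsochromic | bathochromic | none


@dataclass(frozen=True)
class EpsilonTrend:
    verdict: str  # strictly decreasing | strictly increasing | mixed | flat
    endpoint_ratio: float  # eps(first) / eps(last)


def _band_col(band: int, stem: str) -> str:
    if band not in (1, 2):
        raise ValueError("band must be 1 or 2")
    return f"{stem}{band}" if stem == "eps" else f"{stem}{band}_nm"


def load_reference_series() -> SolvatochromicSeries:
    """Packaged petrosamine DMSO-H2O series (band maxima in nm, eps in M^-1 cm^-1)."""
    path = files("petrokin.data").joinpath("uvvis_dmso_water.csv")
    with path.open("r", encoding="utf-8") as fh:
        return SolvatochromicSeries(pd.read_csv(fh, comment="#"))


def band_shift(series: SolvatochromicSeries, band: int) -> BandShift:
    """Band shift between the series endpoints, signed along rising water content.

    ``signed_delta_nm = lambda_max(first) - lambda_max(last)``; the shift is
    hypsochromic (blue) when lambda_max decreases with water fraction,
    bathochromic (red) when it increases, "none" below 1 nm.  The
    magnitude/direction split avoids the sign ambiguity of raw deltas.
    """
    lam = series.lmax(band)
    if len(lam) < 2:
        raise ValueError("need at least 2 records for a shift")
    signed = float(lam[0] - lam[-1])
    if abs(signed) < _SHIFT_FLOOR_NM:
        cls = "none"
    elif signed > 0:
        cls = "hypsochromic"  # wavelength falls as water increases
    else:
        cls = "bathochromic"
    return BandShift(abs(signed), signed, cls)


def epsilon_trend(series: SolvatochromicSeries, band: int) -> EpsilonTrend:
    """Monotonicity verdict for epsilon along the series, plus endpoint ratio.

    The verdict is a sign-consistency check of successive differences
    (no external rank test): strictly decreasing / increasing when all
    differences share one sign, "flat" for all ties, "mixed" otherwise.
    """
    eps = series.eps(band)
    if len(eps) < 3:
        raise ValueError("need at least 3 records for a trend")
    d = np.diff(eps)
    if np.all(d == 0):
        verdict = "flat"
    elif np.all(d < 0):
        verdict = "strictly decreasing"
    elif np.all(d > 0):
        verdict = "strictly increasing"
    else:
        verdict = "mixed"
    return EpsilonTrend(verdict, float(eps[0] / eps[-1]))


def nm_to_ev(lambda_nm):
    """Photon energy in eV for a wavelength in nm (E = hc / lambda)."""
    lam = np.asarray(lambda_nm, float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be > 0")
    out = HC_EV_NM / lam
    return out if out.ndim else float(out)


def ev_to_nm(energy_ev):
    """Wavelength in nm for a photon energy in eV."""
    e = np.asarray(energy_ev, float)
    if np.any(e <= 0):
        raise ValueError("energy must be > 0")
    out = HC_EV_NM / e
    return out if out.ndim else float(out)
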