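"""Molecular formulas, monoisotopic m/z and natural-abundance isotope patterns.

This module supplies the mass arithmetic behind the rest of the package:
parsing a Hill-notation formula, computing the monoisotopic m/z of a
(possibly deuterated) charged species with the electron-mass correction,
and building the full natural-abundance isotope pattern by multinomial
convolution of the pinned per-element isotope distributions, with
fine-structure peaks merged at a finite resolving power the way a
centroiding TOF instrument would.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .elements import (
    DEUTERIUM_MASS_SHIFT,
    ELECTRON_MASS,
    isotope_table,
    isotopes_of,
    lightest_isotope_mass,
)

__all__ = [
    "ElementCounts",
    "IsotopePattern",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mz",
    "isotope_pattern",
]

# Abundance below which fine-structure terms are dropped during convolution.
# Far below any floor a caller can meaningfully request.
_CONV_PRUNE = 1e-14

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formulas."""


@dataclass(frozen=True, eq=False)
class ElementCounts:
    """A parsed molecular formula with charge and explicit deuteration.

    Parameters
    ----------
    counts
        Mapping element symbol -> atom count (all counts >= 1).
    charge
        Net charge in elementary units; the electron-mass correction is
        applied when computing m/z.
    n_labile_replaced
        Number of H atoms replaced by D (0 <= n <= counts["H"]).  These
        positions are treated as pure deuterium; the remaining H keep
        their natural 1H/2H distribution.
    """

    counts: Mapping[str, int]
    charge: int = 0
    n_labile_replaced: int = 0

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        if not counts:
            raise FormulaError("empty formula")
        for el, n in counts.items():
            if not isinstance(n, (int, np.integer)) or n <= 0:
                raise FormulaError(f"count for {el!r} must be a positive integer, got {n!r}")
        if self.n_labile_replaced < 0:
            raise FormulaError("n_labile_replaced must be >= 0")
        if self.n_labile_replaced > counts.get("H", 0):
            raise FormulaError(
                f"cannot replace {self.n_labile_replaced} H by D: formula has "
                f"{counts.get('H', 0)} hydrogens"
            )
        object.__setattr__(self, "counts", counts)

    # counts is a dict, so hashing/equality go through a canonical key
    def _key(self) -> tuple:
        return (tuple(sorted(self.counts.items())), self.charge, self.n_labile_replaced)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementCounts):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        formula = "".join(f"{el}{n if n > 1 else ''}" for el, n in sorted(self.counts.items()))
        return (
            f"ElementCounts({formula!r}, charge={self.charge:+d}, "
            f"n_labile_replaced={self.n_labile_replaced})"
        )

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def with_deuterium(self, n: int) -> "ElementCounts":
        """Copy of this species with *n* hydrogens replaced by deuterium."""
        return ElementCounts(self.counts, charge=self.charge, n_labile_replaced=n)

    def with_charge(self, charge: int) -> "ElementCounts":
        return ElementCounts(self.counts, charge=charge, n_labile_replaced=self.n_labile_replaced)


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided natural-abundance isotope pattern of one species.

    ``peaks`` is an ordered tuple of ``(m/z, relative_abundance)`` with
    abundances summing to 1; ``resolving_power`` (m/dm FWHM) records the
    merging resolution used to aggregate fine structure.
    """

    peaks: tuple[tuple[float, float], ...]
    resolving_power: float = field(default=float("inf"))

    def __post_init__(self) -> None:
        mzs = self.mz
        if np.any(np.diff(mzs) <= 0):
            raise ValueError("pattern m/z values must be strictly increasing")
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be non-negative")
        if abs(float(self.abundance.sum()) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def abundance(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


def parse_formula(formula: str) -> ElementCounts:
    """Parse a Hill-notation molecular formula such as ``"C21H17BrN3O2"``.

    Only element symbols present in the pinned isotope table are accepted;
    counts are plain positive integers (an omitted count means 1).
    Repeated symbols accumulate.  No isotope-bracket syntax is supported.

    Examples
    --------
    >>> parse_formula("C21H17BrN3O2").counts
    {'C': 21, 'H': 17, 'Br': 1, 'N': 3, 'O': 2}
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("formula must be a non-empty string")
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    known = isotope_table()
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula at {formula[pos:]!r}")
        symbol, digits = m.groups()
        if symbol not in known:
            raise FormulaError(f"unknown element symbol {symbol!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {symbol!r} in {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return ElementCounts(counts)


def monoisotopic_mz(ec: ElementCounts) -> float:
    """Monoisotopic m/z (or neutral mass) of a species.

    Sums the lightest-isotope mass of every atom, swaps
    ``n_labile_replaced`` hydrogen masses for deuterium, subtracts
    ``charge`` electron masses and divides by |charge|.  For ``charge == 0``
    the neutral monoisotopic mass is returned.
    """
    mass = sum(n * lightest_isotope_mass(el) for el, n in ec.counts.items())
    mass += ec.n_labile_replaced * DEUTERIUM_MASS_SHIFT
    mass -= ec.charge * ELECTRON_MASS
    if ec.charge == 0:
        return mass
    return mass / abs(ec.charge)


# ---------------------------------------------------------------------------
# isotope pattern machinery


def _combine(dist_a: dict[float, float], dist_b: Iterable[tuple[float, float]]) -> dict[float, float]:
    """Convolve two fine-structure distributions, pruning tiny terms."""
    out: dict[float, float] = {}
    for ma, pa in dist_a.items():
        for mb, pb in dist_b:
            p = pa * pb
            if p < _CONV_PRUNE:
                continue
            m = round(ma + mb, 9)  # aggregate numerically identical masses
            out[m] = out.get(m, 0.0) + p
    return out


def _element_distribution(element: str, n: int) -> dict[float, float]:
    """Fine-structure mass distribution of *n* atoms of one element."""
    single = isotopes_of(element)
    dist = {0.0: 1.0}
    # binary exponentiation keeps the term count low for large n
    base: dict[float, float] = {m: p for m, p in single}
    while n:
        if n & 1:
            dist = _combine(dist, base.items())
        n >>= 1
        if n:
            base = _combine(base, base.items())
    return dist


def merge_centroids(
    mz: np.ndarray, weight: np.ndarray, resolving_power: float
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy left-to-right merge of peaks closer than the resolution width.

    Adjacent peaks separated by less than ``m/z / resolving_power`` are
    coalesced; the merged position is the abundance-weighted mean, the way
    a centroiding algorithm reports unresolved fine structure.
    """
    order = np.argsort(mz)
    mz, weight = np.asarray(mz, float)[order], np.asarray(weight, float)[order]
    out_mz: list[float] = []
    out_w: list[float] = []
    for m, w in zip(mz, weight):
        if out_mz and (m - mz_last) < m / resolving_power:  # noqa: F821
            tot = out_w[-1] + w
            out_mz[-1] = (out_mz[-1] * out_w[-1] + m * w) / tot
            out_w[-1] = tot
        else:
            out_mz.append(float(m))
            out_w.append(float(w))
        mz_last = m
    return np.array(out_mz), np.array(out_w)


def isotope_pattern(
    ec: ElementCounts,
    resolving_power: float = float("inf"),
    abundance_floor: float = 0.0,
) -> IsotopePattern:
    """Natural-abundance isotope pattern of a species, centroided.

    The full multinomial convolution over the pinned isotope abundances is
    computed (deuterated positions contribute a fixed 2H mass), peaks whose
    separation falls below ``m/z / resolving_power`` are merged into
    abundance-weighted centroids, peaks below ``abundance_floor`` are
    pruned, and the remainder is renormalized to sum 1.
    """
    if resolving_power <= 0:
        raise ValueError("resolving_power must be > 0")
    if not 0.0 <= abundance_floor < 1.0:
        raise ValueError("abundance_floor must be in [0, 1)")

    dist = {0.0: 1.0}
    for el, n in ec.counts.items():
        if el == "H":
            n = n - ec.n_labile_replaced
            if n == 0:
                continue
        dist = _combine(dist, _element_distribution(el, n).items())

    offset = ec.n_labile_replaced * (
        isotopes_of("H")[1][0]
    )  # fixed D atoms: exact 2H masses
    base = offset - ec.charge * ELECTRON_MASS
    scale = 1.0 / abs(ec.charge) if ec.charge else 1.0

    mz = (np.array(list(dist.keys())) + base) * scale
    ab = np.array(list(dist.values()))
    mz, ab = merge_centroids(mz, ab, resolving_power)

    keep = ab >= abundance_floor if abundance_floor > 0 else slice(None)
    mz, ab = mz[keep], ab[keep]
    if mz.size == 0:
        raise ValueError("abundance_floor pruned every peak")
    ab = ab / ab.sum()
    return IsotopePattern(tuple(zip(mz.tolist(), ab.tolist())), resolving_power)
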