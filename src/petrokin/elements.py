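"""Pinned isotope masses and abundances.

The table shipped under ``petrokin/data/isotopes.csv`` pins every mass and
natural abundance used anywhere in the package (AME2020 atomic masses,
CIAAW 2021 representative abundances).  Pinning, rather than deferring to a
third-party mass library, keeps computed m/z values reproducible to the
sub-0.1 mDa level across environments.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib.resources import files

__all__ = [
    "ELECTRON_MASS",
    "ISOTOPE_TABLE_VERSION",
    "isotope_table",
    "lightest_isotope_mass",
    "isotopes_of",
]

#: CODATA 2018 electron mass in unified atomic mass units.
ELECTRON_MASS = 0.000548579909065

#: Provenance tag for the packaged isotope table.
ISOTOPE_TABLE_VERSION = "AME2020 masses / CIAAW 2021 abundances"

# Mass difference of one deuterium substitution, m(2H) - m(1H), in Da.
DEUTERIUM_MASS_SHIFT = 2.01410177785 - 1.00782503207


@lru_cache(maxsize=1)
def isotope_table() -> dict[str, tuple[tuple[float, float], ...]]:
    """Load the pinned isotope table.

    Returns a mapping ``element -> ((mass_Da, abundance), ...)`` with
    isotopes sorted by increasing mass.  Abundances for each element sum
    to 1 as shipped.
    """
    path = files("petrokin.data").joinpath("isotopes.csv")
    table: dict[str, list[tuple[float, float]]] = {}
    with path.open("r", encoding="utf-8") as fh:
        rows = (row for row in fh if not row.startswith("#"))
        for rec in csv.DictReader(rows):
            table.setdefault(rec["element"], []).append(
                (float(rec["mass_Da"]), float(rec["abundance"]))
            )
    return {el: tuple(sorted(iso)) for el, iso in table.items()}


def isotopes_of(element: str) -> tuple[tuple[float, float], ...]:
    """Isotopes ``(mass_Da, abundance)`` of *element*, lightest first."""
    try:
        return isotope_table()[element]
    except KeyError:
        raise KeyError(f"element {element!r} is not in the pinned isotope table") from None


def lightest_isotope_mass(element: str) -> float:
    """Mass of the lightest stable isotope of *element* in Da."""
    return isotopes_of(element)[0][0]
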