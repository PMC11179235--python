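"""Periodic-table information: IUPAC groups, periods, and radii.

Group and period are derived arithmetically from the atomic number (the
layout of the standard 18-column table is fixed, so no lookup table is
needed). Shannon effective ionic radii for common oxidation states are
bundled as a plain-text data file; the covalent radius (via gemmi) is the
documented fallback when no ionic entry applies.

Convention for the f-block: La (Z=57) and Ac (Z=89) occupy group 3;
Z 58-71 and 90-103 are groupless f-block elements, for which group-based
element substitution is disallowed.
"""

from __future__ import annotations

import importlib.resources
import warnings
from functools import lru_cache

import gemmi

from .errors import CIFParseError, RadiusLookupError

# first atomic number of each period
_PERIOD_START = {1: 1, 2: 3, 3: 11, 4: 19, 5: 37, 6: 55, 7: 87}
_MAX_Z = 118


def atomic_number(symbol: str) -> int:
    """Atomic number for an element symbol; raises on unknown symbols."""
    el = gemmi.Element(symbol)
    if el.atomic_number == 0 or el.name != symbol:
        raise CIFParseError(f"unknown element symbol: {symbol!r}")
    return el.atomic_number


def period(symbol: str) -> int:
    z = atomic_number(symbol)
    for p in range(7, 0, -1):
        if z >= _PERIOD_START[p]:
            return p
    raise CIFParseError(f"no period for Z={z}")


def group(symbol: str) -> int | None:
    """IUPAC group 1-18, or None for groupless f-block elements."""
    z = atomic_number(symbol)
    p = period(symbol)
    pos = z - _PERIOD_START[p] + 1
    if p == 1:
        return 1 if pos == 1 else 18
    if p in (2, 3):
        return pos if pos <= 2 else pos + 10
    if p in (4, 5):
        return pos
    # periods 6-7: La/Ac are group 3, Ce-Lu / Th-Lr are f-block
    if pos <= 3:
        return pos
    if pos <= 17:
        return None
    return pos - 14


def atomic_weight(symbol: str) -> float:
    atomic_number(symbol)  # validates
    return gemmi.Element(symbol).weight


def covalent_radius(symbol: str) -> float:
    """Covalent radius in Angstrom (fallback when no ionic radius applies)."""
    atomic_number(symbol)
    r = gemmi.Element(symbol).covalent_r
    if r <= 0:
        raise RadiusLookupError(f"no covalent radius for {symbol}")
    return float(r)


@lru_cache(maxsize=1)
def _shannon_table() -> dict[tuple[str, int], float]:
    table: dict[tuple[str, int], float] = {}
    text = (
        importlib.resources.files("nanocarve.data")
        .joinpath("shannon_radii.txt")
        .read_text()
    )
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        sym, q, r = line.split()
        table[(sym, int(q))] = float(r)
    return table


def shannon_radius(symbol: str, charge: int) -> float:
    """Shannon ionic radius (Å) for an element at a formal oxidation state."""
    try:
        return _shannon_table()[(symbol, int(charge))]
    except KeyError:
        raise RadiusLookupError(
            f"no Shannon radius tabulated for {symbol}{charge:+d}"
        ) from None


def ionic_radius(symbol: str, charge: float | None = None) -> float:
    """Best available radius: Shannon at the given oxidation state, else
    covalent fallback (a warning is emitted since the coordination-cutoff
    rule is stated in terms of ionic radii)."""
    if charge is not None and int(round(charge)) != 0:
        try:
            return shannon_radius(symbol, int(round(charge)))
        except RadiusLookupError:
            pass
    warnings.warn(
        f"no ionic radius for {symbol} (charge={charge}); "
        "falling back to covalent radius",
        stacklevel=2,
    )
    return covalent_radius(symbol)
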