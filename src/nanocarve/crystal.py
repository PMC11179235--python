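"""Unit-cell construction: CIF parsing, symmetry expansion, substitution.

The supported CIF dialect is the minimal COD-style subset needed to carve
nanoparticles: cell lengths/angles, a symmetry-operator loop (``x,y,z``
notation), fractional atom sites with optional oxidation-state suffixes on
the type symbol (``Zr4+``) and optional occupancies. Occupancies must be 1:
carving a disordered cell is not defined. Anything else in the file is
ignored.

Element substitution follows the same-group / adjacent-period rule: an
element may only be replaced by another element of the same IUPAC group
whose period differs by at most one. Same-group elements bond alike and
adjacent-period elements are close in size, so the substituted structure
remains chemically plausible and free of atom overlap.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from gemmi import cif as gcif

from . import ptable
from .errors import CIFParseError, SubstitutionError, UnsupportedFeatureError

__all__ = [
    "Site",
    "UnitCell",
    "parse_cif",
    "write_cif_p1",
    "substitution_candidates",
    "substitute_element",
]

#: fractional-coordinate tolerance for deduplicating symmetry-equivalent sites
DEDUP_TOL = 1e-3
#: tolerance on Σ(charge × occupancy) over the expanded cell
NEUTRALITY_TOL = 1e-6

_TYPE_SYMBOL_RE = re.compile(r"^([A-Z][a-z]?)(?:(\d+)?([+-]))?$")


@dataclass(frozen=True)
class Site:
    """One atomic site: element, fractional coordinates, charge, occupancy."""

    element: str
    frac: tuple[float, float, float]
    charge: float | None = None
    occupancy: float = 1.0


@dataclass
class UnitCell:
    """A symmetry-expanded crystallographic unit cell.

    ``lattice_vectors`` follow the standard crystallographic Cartesian
    convention: **a** along x, **b** in the xy-plane. ``sites`` hold the
    full orbit of the asymmetric unit under ``symmetry_ops``, wrapped into
    [0, 1) and deduplicated.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    sites: list[Site]
    symmetry_ops: list[str] = field(default_factory=lambda: ["x,y,z"])

    @property
    def lattice_vectors(self) -> np.ndarray:
        """3x3 row matrix of lattice vectors in Å."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        va = np.array([self.a, 0.0, 0.0])
        vb = np.array([self.b * math.cos(ga), self.b * math.sin(ga), 0.0])
        cx = math.cos(be)
        cy = (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
        cz = math.sqrt(max(1.0 - cx * cx - cy * cy, 0.0))
        vc = self.c * np.array([cx, cy, cz])
        return np.array([va, vb, vc])

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.lattice_vectors)))

    @property
    def formula_unit(self) -> dict[str, int]:
        """Smallest integer element ratio of the cell contents."""
        counts: dict[str, int] = {}
        for s in self.sites:
            counts[s.element] = counts.get(s.element, 0) + 1
        g = math.gcd(*counts.values()) if counts else 1
        return {el: n // g for el, n in sorted(counts.items())}

    @property
    def formula_unit_charge(self) -> float:
        """Net charge of one formula unit (0 for neutral formulas)."""
        counts: dict[str, int] = {}
        qsum: dict[str, float] = {}
        for s in self.sites:
            counts[s.element] = counts.get(s.element, 0) + 1
            qsum[s.element] = qsum.get(s.element, 0.0) + (s.charge or 0.0)
        fu = self.formula_unit
        total = 0.0
        for el, nu in fu.items():
            total += nu * qsum[el] / counts[el]
        return total

    def charges_by_element(self) -> dict[str, float]:
        """Formal charge per element (errors if sites of one element differ)."""
        out: dict[str, float] = {}
        for s in self.sites:
            q = s.charge or 0.0
            if s.element in out and abs(out[s.element] - q) > 1e-9:
                raise CIFParseError(
                    f"inconsistent charges for element {s.element}"
                )
            out[s.element] = q
        return out


def _parse_type_symbol(token: str) -> tuple[str, float | None]:
    """Split ``Zr4+``/``O2-``/``Ti`` into (element, formal charge or None)."""
    m = _TYPE_SYMBOL_RE.match(token)
    if not m:
        raise CIFParseError(f"cannot parse atom type symbol {token!r}")
    el, digits, sign = m.group(1), m.group(2), m.group(3)
    ptable.atomic_number(el)  # validates the symbol
    if sign is None:
        return el, None
    mag = int(digits) if digits else 1
    return el, float(mag if sign == "+" else -mag)


def _wrap_frac(x: np.ndarray, tol: float = DEDUP_TOL) -> np.ndarray:
    """Wrap fractional coordinates into [0, 1), snapping 1-tol..1 to 0."""
    w = x - np.floor(x)
    w[w > 1.0 - tol] = 0.0
    return w


def _expand_sites(
    sites: list[Site], ops: list[str], tol: float = DEDUP_TOL
) -> list[Site]:
    """Unique orbit of the asymmetric unit under the symmetry operators."""
    parsed = []
    for op in ops:
        try:
            parsed.append(gemmi.Op(op.replace(" ", "")))
        except Exception as exc:  # gemmi raises RuntimeError on bad triplets
            raise CIFParseError(f"invalid symmetry operator {op!r}") from exc
    expanded: list[Site] = []
    for site in sites:
        for op in parsed:
            frac = _wrap_frac(np.asarray(op.apply_to_xyz(list(site.frac))), tol)
            dup = False
            for other in expanded:
                if other.element != site.element:
                    continue
                d = frac - np.asarray(other.frac)
                d -= np.round(d)  # periodic image
                if np.max(np.abs(d)) < tol:
                    dup = True
                    break
            if not dup:
                expanded.append(replace(site, frac=tuple(frac)))
    return expanded


def _require(block: gcif.Block, tag: str) -> str:
    val = block.find_value(tag)
    if val is None:
        raise CIFParseError(f"CIF is missing required tag {tag}")
    return val


def parse_cif(
    text: str, charge_map: dict[str, float] | None = None
) -> UnitCell:
    """Parse a CIF document into a symmetry-expanded :class:`UnitCell`.

    Formal charges are taken from type-symbol suffixes when present, else
    from ``charge_map``, else left at zero (pure pair-potential use). If any
    charges are present, the expanded cell must be charge-neutral.

    Raises
    ------
    CIFParseError
        Missing cell parameters, unknown element symbols, or (when charges
        are given) a non-neutral cell.
    UnsupportedFeatureError
        Partial occupancy.
    """
    try:
        doc = gcif.read_string(text)
        block = doc.sole_block()
    except Exception as exc:
        raise CIFParseError(f"unreadable CIF document: {exc}") from exc

    def flt(tag: str) -> float:
        return gcif.as_number(_require(block, tag))

    a, b, c = flt("_cell_length_a"), flt("_cell_length_b"), flt("_cell_length_c")
    alpha = flt("_cell_angle_alpha")
    beta = flt("_cell_angle_beta")
    gamma = flt("_cell_angle_gamma")

    ops: list[str] = []
    for tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
        col = block.find_loop(tag)
        ops = [gcif.as_string(v) for v in col]
        if ops:
            break
    if not ops:
        ops = ["x,y,z"]  # no operator loop: treat as P1

    table = block.find(
        "_atom_site_",
        ["type_symbol", "fract_x", "fract_y", "fract_z", "?occupancy"],
    )
    if len(table) == 0:
        raise CIFParseError("CIF has no atom-site loop")
    asym: list[Site] = []
    for row in table:
        el, q = _parse_type_symbol(gcif.as_string(row[0]))
        frac = tuple(gcif.as_number(row[i]) for i in (1, 2, 3))
        occ = 1.0
        if table.has_column(4) and row[4] is not None:
            occ = gcif.as_number(row[4])
        if abs(occ - 1.0) > 1e-3:
            raise UnsupportedFeatureError(
                f"partial occupancy {occ} on {el}: disordered cells are not "
                "supported (carving them is undefined)"
            )
        if q is None and charge_map is not None:
            q = charge_map.get(el)
        asym.append(Site(el, frac, q, 1.0))

    if any(s.charge is not None for s in asym):
        asym = [replace(s, charge=s.charge or 0.0) for s in asym]

    sites = _expand_sites(asym, ops)
    cell = UnitCell(a, b, c, alpha, beta, gamma, sites, list(ops))

    if any(s.charge is not None for s in sites):
        net = sum((s.charge or 0.0) * s.occupancy for s in sites)
        if abs(net) > max(NEUTRALITY_TOL, 1e-9 * len(sites)):
            raise CIFParseError(
                f"expanded cell is not charge neutral (net {net:+g} e)"
            )
    return cell


def write_cif_p1(cell: UnitCell, data_name: str = "nanocarve") -> str:
    """Serialize an expanded cell as a P1 CIF (identity operator only)."""
    lines = [
        f"data_{data_name}",
        f"_cell_length_a {cell.a:.6f}",
        f"_cell_length_b {cell.b:.6f}",
        f"_cell_length_c {cell.c:.6f}",
        f"_cell_angle_alpha {cell.alpha:.6f}",
        f"_cell_angle_beta {cell.beta:.6f}",
        f"_cell_angle_gamma {cell.gamma:.6f}",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
        "'x,y,z'",
        "loop_",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    for s in cell.sites:
        sym = s.element
        if s.charge is not None and abs(s.charge) > 1e-9:
            q = int(round(s.charge))
            sym = f"{s.element}{abs(q)}{'+' if q > 0 else '-'}"
        lines.append(
            f"{sym} {s.frac[0]:.9f} {s.frac[1]:.9f} {s.frac[2]:.9f} "
            f"{s.occupancy:.4f}"
        )
    return "\n".join(lines) + "\n"


def substitution_candidates(element: str) -> set[str]:
    """Elements allowed to replace ``element``: same IUPAC group, period
    within ±1, excluding the element itself.

    Raises
    ------
    SubstitutionError
        For groupless f-block elements, where the rule is undefined.
    """
    g = ptable.group(element)
    if g is None:
        raise SubstitutionError(
            f"{element} is an f-block element without an IUPAC group; "
            "group-based substitution is undefined"
        )
    p = ptable.period(element)
    out: set[str] = set()
    for z in range(1, ptable._MAX_Z + 1):
        sym = gemmi.Element(z).name
        if sym == element:
            continue
        if ptable.group(sym) == g and abs(ptable.period(sym) - p) <= 1:
            out.add(sym)
    return out


def substitute_element(cell: UnitCell, old: str, new: str) -> UnitCell:
    """Relabel every ``old`` site as ``new``; geometry and charges unchanged.

    ``new`` must be an allowed candidate (same group, adjacent period).
    """
    if all(s.element != old for s in cell.sites):
        raise SubstitutionError(f"element {old} does not occur in the cell")
    if new not in substitution_candidates(old):
        raise SubstitutionError(
            f"{old} -> {new} violates the same-group/adjacent-period rule"
        )
    new_sites = [
        replace(s, element=new) if s.element == old else s for s in cell.sites
    ]
    return UnitCell(
        cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma,
        new_sites, list(cell.symmetry_ops),
    )
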