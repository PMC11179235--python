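"""Programmatic crystal-structure fixtures.

Small canonical cells emitted as P1 CIF text so the whole pipeline is
exercisable without downloading anything from a crystallography database:

* ``rutile_MO2`` — tetragonal rutile-type MO₂ (2 metal + 4 oxygen sites;
  the TiO₂-rutile defaults match the published cell, and a Ti→Zr
  substitution gives the rutile-like zirconia structure).
* ``rocksalt``  — cubic AB rock salt, 4 + 4 sites (NaCl defaults).
* ``fcc``       — cubic close-packed single species, 4 sites (Al default).
"""

from __future__ import annotations

from .crystal import UnitCell, parse_cif, write_cif_p1

__all__ = ["generate_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("rutile_MO2", "rocksalt", "fcc")


def _rutile_cif(
    metal: str, a: float, c: float, u: float, qm: int, qo: int
) -> str:
    if not (0.0 < u < 0.5):
        raise ValueError("rutile internal coordinate u must be in (0, 0.5)")
    mo = f"{metal}{qm}+" if qm else metal
    ox = f"O{-qo}-" if qo else "O"
    sites = [
        (mo, 0.0, 0.0, 0.0),
        (mo, 0.5, 0.5, 0.5),
        (ox, u, u, 0.0),
        (ox, 1 - u, 1 - u, 0.0),
        (ox, 0.5 + u, 0.5 - u, 0.5),
        (ox, 0.5 - u, 0.5 + u, 0.5),
    ]
    return _p1_cif("rutile_MO2", a, a, c, sites)


def _rocksalt_cif(
    cation: str, anion: str, a: float, qc: int, qa: int
) -> str:
    cs = f"{cation}{qc}+" if qc else cation
    an = f"{anion}{-qa}-" if qa else anion
    sites = [
        (cs, 0.0, 0.0, 0.0), (cs, 0.5, 0.5, 0.0),
        (cs, 0.5, 0.0, 0.5), (cs, 0.0, 0.5, 0.5),
        (an, 0.5, 0.0, 0.0), (an, 0.0, 0.5, 0.0),
        (an, 0.0, 0.0, 0.5), (an, 0.5, 0.5, 0.5),
    ]
    return _p1_cif("rocksalt", a, a, a, sites)


def _fcc_cif(element: str, a: float) -> str:
    sites = [
        (element, 0.0, 0.0, 0.0), (element, 0.5, 0.5, 0.0),
        (element, 0.5, 0.0, 0.5), (element, 0.0, 0.5, 0.5),
    ]
    return _p1_cif("fcc", a, a, a, sites)


def _p1_cif(name, a, b, c, sites) -> str:
    if min(a, b, c) <= 0:
        raise ValueError("cell lengths must be positive")
    lines = [
        f"data_{name}",
        f"_cell_length_a {a:.6f}",
        f"_cell_length_b {b:.6f}",
        f"_cell_length_c {c:.6f}",
        "_cell_angle_alpha 90.0",
        "_cell_angle_beta 90.0",
        "_cell_angle_gamma 90.0",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
        "'x,y,z'",
        "loop_",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for sym, x, y, z in sites:
        lines.append(f"{sym} {x:.9f} {y:.9f} {z:.9f}")
    return "\n".join(lines) + "\n"


def generate_fixture(name: str, **params) -> tuple[str, UnitCell]:
    """Return (CIF text, parsed UnitCell) for a named fixture.

    rutile_MO2: metal="Ti", a=4.593, c=2.959, u=0.305, charges (4+, 2−).
    rocksalt:   cation="Na", anion="Cl", a=5.64, charges (1+, 1−).
    fcc:        element="Al", a=4.05, no charges.

    Pass ``charged=False`` to emit the cell without formal charges (for
    pure pair-potential work).
    """
    charged = params.pop("charged", True)
    if name == "rutile_MO2":
        text = _rutile_cif(
            params.pop("metal", "Ti"),
            params.pop("a", 4.593),
            params.pop("c", 2.959),
            params.pop("u", 0.305),
            params.pop("qm", 4) if charged else 0,
            params.pop("qo", -2) if charged else 0,
        )
    elif name == "rocksalt":
        text = _rocksalt_cif(
            params.pop("cation", "Na"),
            params.pop("anion", "Cl"),
            params.pop("a", 5.64),
            params.pop("qc", 1) if charged else 0,
            params.pop("qa", -1) if charged else 0,
        )
    elif name == "fcc":
        text = _fcc_cif(params.pop("element", "Al"), params.pop("a", 4.05))
    else:
        raise ValueError(
            f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
        )
    if params:
        raise ValueError(f"unused fixture parameters: {sorted(params)}")
    cell = parse_cif(text)
    # round-trip through the canonical writer so fixture CIFs and
    # exported cells share one format
    return write_cif_p1(cell, name), cell
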