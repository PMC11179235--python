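"""Structure and report writers/readers.

All writers are deterministic byte-for-byte for a fixed input: stable atom
ordering, fixed decimal formatting. XYZ files carry the construction
provenance on the comment line as ``key=value`` pairs so a downstream
stage (or a re-run) can verify what it is consuming; when any formal
charge is nonzero a fifth column with the charge is appended so
charge-dependent potentials survive a round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import ptable
from .builder import ParticleStructure
from .descriptors import DescriptorSet
from .errors import CIFParseError, EmptyParticleError

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_lammps_data",
    "write_descriptor_csv",
    "write_descriptor_json",
]

#: provenance keys serialized onto the XYZ comment line
_PROV_KEYS = ("stage", "minimized", "potential", "energy")


def _comment_line(structure: ParticleStructure) -> str:
    parts = []
    for key in _PROV_KEYS:
        if key in structure.provenance:
            parts.append(f"{key}={structure.provenance[key]}")
    spec = structure.provenance.get("spec")
    if spec is not None:
        parts.append(
            f"axes_nm={spec.dx:g}x{spec.dy:g}x{spec.dz:g}"
        )
        rv = spec.rotation_vector
        parts.append(
            f"rotation={rv[0]:g},{rv[1]:g},{rv[2]:g}@{spec.rotation_angle:g}deg"
        )
    return " ".join(parts) if parts else "nanocarve structure"


def write_xyz(structure: ParticleStructure, path) -> None:
    """Write a standard XYZ file (Å, 6 decimals).

    Extra per-atom columns (formal charge ``q``, per-atom energy ``e``)
    are appended when present and declared as ``fields=...`` on the
    comment line, so the relaxed energies survive the stage boundary.
    """
    if len(structure) == 0:
        raise EmptyParticleError("refusing to write an empty structure")
    with_q = structure.charges is not None and np.any(structure.charges != 0)
    with_e = structure.energies is not None
    fields = (["q"] if with_q else []) + (["e"] if with_e else [])
    comment = _comment_line(structure)
    if fields:
        comment += f" fields={','.join(fields)}"
    lines = [str(len(structure)), comment]
    for i in range(len(structure)):
        x, y, z = structure.positions[i]
        row = f"{structure.elements[i]} {x:.6f} {y:.6f} {z:.6f}"
        if with_q:
            row += f" {structure.charges[i]:.4f}"
        if with_e:
            row += f" {structure.energies[i]:.8f}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> ParticleStructure:
    """Read an XYZ file written by :func:`write_xyz` (or any standard XYZ)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise CIFParseError(f"empty XYZ file: {path}")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise CIFParseError(f"bad XYZ header in {path}") from None
    if len(lines) < n + 2:
        raise CIFParseError(f"XYZ file {path} truncated: expected {n} atoms")
    prov = {}
    for token in lines[1].split():
        if "=" in token:
            k, v = token.split("=", 1)
            if v in ("True", "False"):
                prov[k] = v == "True"
            else:
                prov[k] = v
    fields = str(prov.pop("fields", "q")).split(",")
    els, pos, charges, energies = [], [], [], []
    for line in lines[2 : 2 + n]:
        f = line.split()
        if len(f) < 4:
            raise CIFParseError(f"bad XYZ atom line: {line!r}")
        ptable.atomic_number(f[0])
        els.append(f[0])
        pos.append([float(f[1]), float(f[2]), float(f[3])])
        extras = dict(zip(fields, f[4:]))
        charges.append(float(extras.get("q", 0.0)))
        energies.append(float(extras["e"]) if "e" in extras else np.nan)
    q = np.array(charges)
    e = np.array(energies)
    return ParticleStructure(
        np.array(els, dtype=object),
        np.array(pos),
        q if np.any(q != 0) else None,
        e if not np.any(np.isnan(e)) else None,
        provenance=prov,
    )


def write_lammps_data(structure: ParticleStructure, path) -> None:
    """Write a LAMMPS data file, atom_style charge (id type q x y z).

    Type ids follow sorted element symbols; masses come from the standard
    atomic-weight table; the box is the axis-aligned bounding box padded
    by 10 Å of vacuum on every side (isolated cluster). This file is the
    bridge to external engines — e.g. a LAMMPS run with a many-body
    force field reproduces the construction exactly.
    """
    if len(structure) == 0:
        raise EmptyParticleError("refusing to write an empty structure")
    els = structure.elements.astype(str)
    species = sorted(set(els.tolist()))
    type_of = {s: i + 1 for i, s in enumerate(species)}
    lo = structure.positions.min(axis=0) - 10.0
    hi = structure.positions.max(axis=0) + 10.0
    q = structure.charges if structure.charges is not None else np.zeros(
        len(structure)
    )
    out = [
        f"LAMMPS data file: {_comment_line(structure)}",
        "",
        f"{len(structure)} atoms",
        f"{len(species)} atom types",
        "",
        f"{lo[0]:.6f} {hi[0]:.6f} xlo xhi",
        f"{lo[1]:.6f} {hi[1]:.6f} ylo yhi",
        f"{lo[2]:.6f} {hi[2]:.6f} zlo zhi",
        "",
        "Masses",
        "",
    ]
    for s in species:
        out.append(f"{type_of[s]} {ptable.atomic_weight(s):.4f}  # {s}")
    out += ["", "Atoms  # charge", ""]
    for i in range(len(structure)):
        x, y, z = structure.positions[i]
        out.append(
            f"{i + 1} {type_of[els[i]]} {q[i]:.4f} {x:.6f} {y:.6f} {z:.6f}"
        )
    Path(path).write_text("\n".join(out) + "\n")


def write_descriptor_csv(report: DescriptorSet, path) -> None:
    """One CSV row per region plus the derived ratio/difference block."""
    d = report.as_dict()
    fields = [
        "n_atoms", "dx", "dy", "dz", "surface_area", "volume",
        "avg_energy", "avg_coordination", "avg_cnp", "hex_first",
        "hex_second",
    ]

    def fmt(v):
        return "" if v is None else f"{v:.10g}"

    lines = ["region," + ",".join(fields)]
    for region in ("whole", "core", "surface"):
        lines.append(
            region + "," + ",".join(fmt(d[region][f]) for f in fields)
        )
    lines.append("")
    lines.append("derived,descriptor,core_over_surface,core_minus_surface")
    for name in d["core_over_surface"]:
        lines.append(
            f"derived,{name},{fmt(d['core_over_surface'][name])},"
            f"{fmt(d['core_minus_surface'][name])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_descriptor_json(report: DescriptorSet, path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2) + "\n")
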