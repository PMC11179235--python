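"""Stability-driven exploration of particle shapes and growth pathways.

Three searches, all scored by the stability metric (average potential
energy per atom after relaxation; lower = more stable):

* fixed-volume shape scan — enumerate ellipsoid axis triples sharing one
  volume, build + relax each, rank by energy;
* rotation scan — fixed axes, sweep the lattice rotation angle;
* growth pathway — greedy walk through shape space from a small seed
  particle, at each step taking the move whose relaxed particle has the
  lowest energy per atom, emulating atom deposition during crystal growth.

Everything is deterministic: no random numbers, fixed tie-breaks
(run id for scans, lexicographically smallest axes for pathway moves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .builder import (
    MAX_ATOMS_DEFAULT,
    EllipsoidSpec,
    ParticleStructure,
    build_ellipsoidal_np,
)
from .crystal import UnitCell
from .energetics import (
    MinimizationSettings,
    PotentialModel,
    minimize,
)
from .errors import NanocarveError

__all__ = [
    "ShapeCandidate",
    "GrowthPath",
    "enumerate_fixed_volume",
    "rank_shapes",
    "rotation_scan",
    "growth_pathway",
]


@dataclass
class ShapeCandidate:
    """One shape in a scan: its spec, relaxed energy and bookkeeping."""

    run_id: int
    spec: EllipsoidSpec
    built: bool = False
    minimized: bool = False
    n_atoms: int = 0
    energy_per_atom: float | None = None
    termination: str | None = None
    error: str | None = None
    structure: ParticleStructure | None = None


@dataclass
class GrowthPath:
    """Greedy lowest-energy growth route through ellipsoid shape space."""

    nodes: list[dict] = field(default_factory=list)
    candidates_per_step: list[list[dict]] = field(default_factory=list)
    move_rule: str = ""
    termination: str = ""

    def as_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "candidates_per_step": self.candidates_per_step,
            "move_rule": self.move_rule,
            "termination": self.termination,
        }


def enumerate_fixed_volume(
    volume_nm3: float, axis_pairs: list[tuple[float, float]]
) -> list[tuple[float, float, float]]:
    """Axis triples (Dx, Dy, Dz) in nm sharing one ellipsoid volume.

    Dz = 6V/(π·Dx·Dy) closes each pair; the exact (unrounded) triples are
    returned — round only for reporting.
    """
    if volume_nm3 <= 0:
        raise ValueError("volume must be positive")
    out = []
    for dx, dy in axis_pairs:
        if dx <= 0 or dy <= 0:
            raise ValueError("axis lengths must be positive")
        out.append((dx, dy, 6.0 * volume_nm3 / (math.pi * dx * dy)))
    return out


def _build_and_score(
    cell: UnitCell,
    spec: EllipsoidSpec,
    potential: PotentialModel,
    settings: MinimizationSettings,
    max_atoms: int,
    cand: ShapeCandidate,
    keep_structure: bool,
) -> ShapeCandidate:
    try:
        particle = build_ellipsoidal_np(cell, spec, max_atoms)
        cand.built = True
        cand.n_atoms = len(particle)
        res = minimize(particle, potential, settings)
        cand.minimized = True
        cand.energy_per_atom = res.energy_per_atom
        cand.termination = res.termination
        if keep_structure:
            cand.structure = res.structure
    except NanocarveError as exc:
        cand.error = f"{type(exc).__name__}: {exc}"
    return cand


def rank_shapes(
    cell: UnitCell,
    candidates: list[tuple[float, float, float]],
    potential: PotentialModel,
    settings: MinimizationSettings = MinimizationSettings(),
    rotation_vector=(0.0, 0.0, 1.0),
    rotation_angle: float = 0.0,
    max_atoms: int = MAX_ATOMS_DEFAULT,
    keep_structures: bool = False,
) -> list[ShapeCandidate]:
    """Build, relax and rank shape candidates (most stable first).

    Failed candidates are recorded (``error`` set) and sort last. Ties in
    energy break on run id, so the ordering is deterministic.
    """
    scored = []
    for rid, (dx, dy, dz) in enumerate(candidates, start=1):
        spec = EllipsoidSpec(dx, dy, dz, tuple(rotation_vector), rotation_angle)
        cand = ShapeCandidate(run_id=rid, spec=spec)
        scored.append(
            _build_and_score(
                cell, spec, potential, settings, max_atoms, cand,
                keep_structures,
            )
        )
    return sorted(
        scored,
        key=lambda c: (
            c.energy_per_atom is None,
            c.energy_per_atom if c.energy_per_atom is not None else 0.0,
            c.run_id,
        ),
    )


def rotation_scan(
    cell: UnitCell,
    axes_nm: tuple[float, float, float],
    rotation_vector,
    angles_deg: list[float],
    potential: PotentialModel,
    settings: MinimizationSettings = MinimizationSettings(),
    max_atoms: int = MAX_ATOMS_DEFAULT,
) -> list[ShapeCandidate]:
    """Relaxed energy per atom versus lattice rotation angle (input order)."""
    out = []
    for rid, angle in enumerate(angles_deg, start=1):
        spec = EllipsoidSpec(*axes_nm, tuple(rotation_vector), angle)
        cand = ShapeCandidate(run_id=rid, spec=spec)
        out.append(
            _build_and_score(
                cell, spec, potential, settings, max_atoms, cand, False
            )
        )
    return out


def growth_pathway(
    cell: UnitCell,
    start_axes_nm: tuple[float, float, float],
    moves: list[tuple[float, float, float]],
    target_max_axis_nm: float,
    potential: PotentialModel,
    settings: MinimizationSettings = MinimizationSettings(),
    rotation_vector=(0.0, 0.0, 1.0),
    rotation_angle: float = 0.0,
    max_atoms: int = MAX_ATOMS_DEFAULT,
) -> GrowthPath:
    """Greedy lowest-energy crystal-growth route.

    From the seed axes, repeatedly apply every move (a per-axis increment
    triple, nm), relax each resulting particle, and advance to the
    candidate with the lowest average potential energy per atom (ties:
    lexicographically smallest axes). Stops when the largest axis reaches
    ``target_max_axis_nm``, or with a truncation diagnostic if every
    candidate at some step fails.
    """
    if not moves:
        raise ValueError("need at least one growth move")
    if target_max_axis_nm <= max(start_axes_nm):
        raise ValueError("target must exceed the largest starting axis")

    path = GrowthPath(
        move_rule=f"per-axis increments {sorted(moves)} (nm)",
    )

    def score_axes(axes, rid):
        spec = EllipsoidSpec(*axes, tuple(rotation_vector), rotation_angle)
        cand = ShapeCandidate(run_id=rid, spec=spec)
        return _build_and_score(
            cell, spec, potential, settings, max_atoms, cand, False
        )

    def node_dict(axes, cand):
        return {
            "axes_nm": [round(a, 6) for a in axes],
            "energy_per_atom": cand.energy_per_atom,
            "n_atoms": cand.n_atoms,
            "error": cand.error,
        }

    current = tuple(float(a) for a in start_axes_nm)
    seed = score_axes(current, 0)
    path.nodes.append(node_dict(current, seed))

    while max(current) < target_max_axis_nm:
        candidates = []
        for rid, mv in enumerate(sorted(moves), start=1):
            axes = tuple(round(c + m, 9) for c, m in zip(current, mv))
            if min(axes) <= 0:
                continue
            candidates.append((axes, score_axes(axes, rid)))
        path.candidates_per_step.append(
            [node_dict(a, c) for a, c in candidates]
        )
        viable = [(a, c) for a, c in candidates if c.energy_per_atom is not None]
        if not viable:
            path.termination = "truncated: all candidates failed"
            return path
        # argmin energy; ties -> lexicographically smallest axes
        best_axes, best = min(
            viable, key=lambda ac: (ac[1].energy_per_atom, ac[0])
        )
        current = best_axes
        path.nodes.append(node_dict(current, best))
    path.termination = f"target max axis {target_max_axis_nm} nm reached"
    return path
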