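"""Geometric and atomistic descriptors of carved nanoparticles.

Geometric descriptors describe the particle envelope: the extents Dx, Dy,
Dz (largest interatomic separation per Cartesian direction), the Knud
Thomsen closed-form approximation of the ellipsoid surface area (exponent
p = 1.6075, worst-case relative error 1.061 %) and the exact ellipsoid
volume (4/3)π·Rx·Ry·Rz.

Atomistic descriptors are averages of per-atom quantities: potential
energy, coordination number (neighbours within a radius-derived cutoff),
the Tsuzuki common-neighbour parameter (CNP; zero inside a perfect FCC
crystal) and the hexatic bond-orientational order parameter ψ6 evaluated
in the laboratory xy-plane.

Every descriptor is reported for the whole particle and separately for its
core and surface, where "surface" is the shell of uniform 4 Å thickness
just inside the bounding ellipsoid; ratios and differences of core vs
surface values form the derived reactivity descriptors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from . import ptable
from .builder import ParticleStructure, ellipsoid_s
from .energetics import PotentialModel, total_energy
from .errors import EmptyParticleError, StageOrderError

__all__ = [
    "DescriptorSettings",
    "DescriptorSet",
    "axis_diameters",
    "thomsen_surface_area",
    "exact_ellipsoid_surface_area",
    "ellipsoid_volume",
    "classify_core_surface",
    "coordination_cutoff",
    "neighbour_lists",
    "avg_coordination",
    "cnp",
    "hexatic",
    "descriptor_report",
]

THOMSEN_P = 1.6075
#: documented worst-case relative error of the Thomsen formula (percent)
THOMSEN_MAX_ERROR_PCT = 1.061


@dataclass(frozen=True)
class DescriptorSettings:
    """Knobs of the descriptor panel.

    ``surface_thickness``: uniform shell thickness (Å) separating surface
    from core atoms — 4 Å for every material so core/surface descriptors
    are comparable across chemistries. Cutoff rule: 2.4·r for a single
    species, 1.2·(r_a + r_b) per pair for two species, a flat 5 Å when
    more than two species are present.
    """

    surface_thickness: float = 4.0
    thomsen_p: float = THOMSEN_P
    single_species_factor: float = 2.4
    two_species_factor: float = 1.2
    multi_species_cutoff: float = 5.0

    def __post_init__(self):
        if self.surface_thickness <= 0:
            raise ValueError("surface thickness must be positive")
        if self.thomsen_p <= 1:
            raise ValueError("Thomsen exponent must exceed 1")


def axis_diameters(structure: ParticleStructure) -> tuple[float, float, float]:
    """Largest interatomic separation along x, y and z (Å).

    Equals max−min of each coordinate, which is the maximum |Δc| over all
    atom pairs.
    """
    if len(structure) == 0:
        raise EmptyParticleError("axis diameters of an empty structure")
    ext = structure.positions.max(axis=0) - structure.positions.min(axis=0)
    return tuple(float(v) for v in ext)


def thomsen_surface_area(
    rx: float, ry: float, rz: float, p: float = THOMSEN_P
) -> float:
    """Approximate ellipsoid surface area (Thomsen formula).

    S ≈ 4π·[((RxRy)^p + (RxRz)^p + (RyRz)^p)/3]^(1/p). Exact for spheres;
    relative error at most 1.061 % for any aspect ratio.
    """
    if min(rx, ry, rz) <= 0:
        raise ValueError("semilengths must be positive")
    m = ((rx * ry) ** p + (rx * rz) ** p + (ry * rz) ** p) / 3.0
    return 4.0 * math.pi * m ** (1.0 / p)


def exact_ellipsoid_surface_area(rx: float, ry: float, rz: float) -> float:
    """Ellipsoid surface area by adaptive quadrature of the surface
    integral (numerical reference for the Thomsen approximation).

    Parametrization x = Rx cos u sin v, y = Ry sin u sin v, z = Rz cos v;
    the area element is sin v·√(Ry²Rz²cos²u sin²v + Rx²Rz²sin²u sin²v
    + Rx²Ry²cos²v). Integrated over one octant and multiplied by 8.
    """
    if min(rx, ry, rz) <= 0:
        raise ValueError("semilengths must be positive")

    def dA(v, u):
        sv, cv = math.sin(v), math.cos(v)
        su, cu = math.sin(u), math.cos(u)
        return sv * math.sqrt(
            (ry * rz * cu * sv) ** 2
            + (rx * rz * su * sv) ** 2
            + (rx * ry * cv) ** 2
        )

    area, _ = integrate.dblquad(
        dA, 0.0, math.pi / 2.0, 0.0, math.pi / 2.0,
        epsabs=1e-10, epsrel=1e-10,
    )
    return 8.0 * area


def ellipsoid_volume(rx: float, ry: float, rz: float) -> float:
    """Ellipsoid volume V = (4/3)π·Rx·Ry·Rz."""
    if min(rx, ry, rz) <= 0:
        raise ValueError("semilengths must be positive")
    return 4.0 / 3.0 * math.pi * rx * ry * rz


def classify_core_surface(
    structure: ParticleStructure,
    semilengths,
    settings: DescriptorSettings = DescriptorSettings(),
) -> np.ndarray:
    """Boolean mask: True = core atom, False = surface atom.

    Core atoms lie inside the ellipsoid shrunk by the uniform surface
    thickness t on every semilength (full lengths reduced by 2t). If any
    semilength is ≤ t the shrunk ellipsoid is empty and all atoms are
    surface.
    """
    if len(structure) == 0:
        raise EmptyParticleError("cannot classify an empty structure")
    semi = np.asarray(semilengths, dtype=float)
    t = settings.surface_thickness
    if np.min(semi) <= t:
        return np.zeros(len(structure), dtype=bool)
    inner = semi - t
    s = ellipsoid_s(structure.positions, structure.centroid, inner)
    return s <= 1.0 + 1e-9


def coordination_cutoff(
    species: set[str],
    charges: dict[str, float] | None = None,
    settings: DescriptorSettings = DescriptorSettings(),
) -> dict[frozenset, float]:
    """Neighbour cutoff per species pair (Å), from the radius-based rule.

    One species: 2.4·r. Two species: a single cutoff 1.2·(r_a + r_b) —
    the sum of the two species' radii — applied to every pair; this keeps
    like-species shells (e.g. the 12 anion–anion contacts in rock salt)
    out of the neighbour count, so an interior rock-salt atom has
    coordination 6. More than two species: flat 5 Å. Radii are Shannon
    ionic radii at the formal oxidation state, with covalent fallback.
    """
    species = sorted(species)
    charges = charges or {}
    out: dict[frozenset, float] = {}
    if len(species) == 1:
        el = species[0]
        r = ptable.ionic_radius(el, charges.get(el))
        out[frozenset((el, el))] = settings.single_species_factor * r
    elif len(species) == 2:
        radii = {el: ptable.ionic_radius(el, charges.get(el)) for el in species}
        cut = settings.two_species_factor * sum(radii.values())
        for i, a in enumerate(species):
            for b in species[i:]:
                out[frozenset((a, b))] = cut
    else:
        for i, a in enumerate(species):
            for b in species[i:]:
                out[frozenset((a, b))] = settings.multi_species_cutoff
    return out


def _charges_by_element(structure: ParticleStructure) -> dict[str, float]:
    if structure.charges is None:
        return {}
    out: dict[str, float] = {}
    for el, q in zip(structure.elements.astype(str), structure.charges):
        out.setdefault(el, float(q))
    return out


def neighbour_lists(
    structure: ParticleStructure,
    cutoffs: dict[frozenset, float] | float,
) -> list[np.ndarray]:
    """Index arrays of neighbours per atom (distance strictly below the
    cutoff of the species pair). ``cutoffs`` may be a single float."""
    n = len(structure)
    els = structure.elements.astype(str)
    pos = structure.positions
    if np.isscalar(cutoffs):
        cmat = None
        cmax = float(cutoffs)
    else:
        species = sorted(set(els.tolist()))
        ti = {s: i for i, s in enumerate(species)}
        cmat = np.zeros((len(species), len(species)))
        for i, a in enumerate(species):
            for j, b in enumerate(species):
                cmat[i, j] = cutoffs[frozenset((a, b))]
        cmax = float(cmat.max())
        types = np.array([ti[e] for e in els])
    nbrs: list[np.ndarray] = []
    for i in range(n):
        d = np.linalg.norm(pos - pos[i], axis=1)
        cut = cmax if cmat is None else cmat[types[i], types]
        m = (d < cut) & (np.arange(n) != i)
        nbrs.append(np.flatnonzero(m))
    return nbrs


def avg_coordination(
    structure: ParticleStructure,
    settings: DescriptorSettings = DescriptorSettings(),
    cutoffs: dict[frozenset, float] | float | None = None,
) -> tuple[np.ndarray, float]:
    """Per-atom neighbour counts and their average."""
    if cutoffs is None:
        cutoffs = coordination_cutoff(
            set(structure.elements.astype(str).tolist()),
            _charges_by_element(structure),
            settings,
        )
    nbrs = neighbour_lists(structure, cutoffs)
    counts = np.array([len(x) for x in nbrs], dtype=float)
    return counts, float(counts.mean())


def cnp(
    structure: ParticleStructure,
    cutoffs: dict[frozenset, float] | float,
) -> tuple[np.ndarray, float]:
    """Common-neighbour parameter Q per atom (Ų) and its average.

    Q_i = (1/n_i)·Σ_{j ∈ nbr(i)} ‖ Σ_{k ∈ common(i,j)} (r_ik + r_jk) ‖²,
    with common(i,j) the atoms neighbouring both i and j. Q distinguishes
    perfect-lattice atoms (Q = 0 in FCC) from defect or surface atoms.
    Atoms with no neighbours get Q = 0; empty common sums contribute 0.
    """
    nbrs = neighbour_lists(structure, cutoffs)
    pos = structure.positions
    nbr_sets = [set(x.tolist()) for x in nbrs]
    q = np.zeros(len(structure))
    for i, ni in enumerate(nbrs):
        if len(ni) == 0:
            continue
        acc = 0.0
        for j in ni:
            common = ni[np.fromiter(
                (k in nbr_sets[j] for k in ni), dtype=bool, count=len(ni)
            )]
            if len(common):
                vec = (pos[common] - pos[i]).sum(axis=0) + (
                    pos[common] - pos[j]
                ).sum(axis=0)
                acc += float(vec @ vec)
        q[i] = acc / len(ni)
    return q, float(q.mean()) if len(q) else 0.0


def hexatic(
    structure: ParticleStructure,
    cutoffs: dict[frozenset, float] | float,
) -> tuple[np.ndarray, float, float]:
    """ψ6 bond-orientational order parameter per atom, plus the averages
    of its real ("first hex parameter") and imaginary ("second hex
    parameter") parts.

    q_k = (1/N)·Σ_j exp(i·6θ_kj) where θ_kj is the angle between the bond
    vector's xy-projection and the laboratory x-axis. Atoms without
    neighbours contribute 0; bonds with an xy-projection shorter than
    1e-9 Å (near-vertical) are skipped.
    """
    nbrs = neighbour_lists(structure, cutoffs)
    pos = structure.positions
    q = np.zeros(len(structure), dtype=complex)
    for k, nk in enumerate(nbrs):
        if len(nk) == 0:
            continue
        d = pos[nk] - pos[k]
        proj = np.hypot(d[:, 0], d[:, 1])
        keep = proj >= 1e-9
        if not keep.any():
            continue
        theta = np.arctan2(d[keep, 1], d[keep, 0])
        q[k] = np.exp(1j * 6.0 * theta).sum() / len(nk)
    if len(q) == 0:
        return q, 0.0, 0.0
    return q, float(q.real.mean()), float(q.imag.mean())


@dataclass
class RegionDescriptors:
    """Descriptor values for one region (whole, core or surface)."""

    n_atoms: int
    dx: float | None = None
    dy: float | None = None
    dz: float | None = None
    surface_area: float | None = None
    volume: float | None = None
    avg_energy: float | None = None
    avg_coordination: float | None = None
    avg_cnp: float | None = None
    hex_first: float | None = None
    hex_second: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


#: atomistic descriptors that get core/surface ratio+difference derivatives
ATOMISTIC_FIELDS = (
    "avg_energy",
    "avg_coordination",
    "avg_cnp",
    "hex_first",
    "hex_second",
)


@dataclass
class DescriptorSet:
    """Full descriptor panel: per-region values plus core-vs-surface
    ratios and differences of every atomistic descriptor."""

    whole: RegionDescriptors
    core: RegionDescriptors
    surface: RegionDescriptors
    ratios: dict[str, float | None] = field(default_factory=dict)
    differences: dict[str, float | None] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "whole": self.whole.as_dict(),
            "core": self.core.as_dict(),
            "surface": self.surface.as_dict(),
            "core_over_surface": dict(self.ratios),
            "core_minus_surface": dict(self.differences),
        }


def _region(
    structure, mask, per_energy, counts, qcnp, qhex, settings
) -> RegionDescriptors:
    n = int(mask.sum())
    if n == 0:
        return RegionDescriptors(n_atoms=0)
    sub = structure.select(mask)
    dx, dy, dz = axis_diameters(sub)
    semi = np.array([dx, dy, dz]) / 2.0
    rd = RegionDescriptors(
        n_atoms=n, dx=dx, dy=dy, dz=dz,
        avg_energy=(
            float(per_energy[mask].mean()) if per_energy is not None else None
        ),
        avg_coordination=float(counts[mask].mean()),
        avg_cnp=float(qcnp[mask].mean()),
        hex_first=float(qhex[mask].real.mean()),
        hex_second=float(qhex[mask].imag.mean()),
    )
    if np.min(semi) > 0:
        rd.surface_area = thomsen_surface_area(*semi, p=settings.thomsen_p)
        rd.volume = ellipsoid_volume(*semi)
    return rd


def descriptor_report(
    structure: ParticleStructure,
    potential: PotentialModel | None = None,
    settings: DescriptorSettings = DescriptorSettings(),
    semilengths=None,
    require_minimized: bool = True,
) -> DescriptorSet:
    """Compute the full descriptor panel for a particle.

    The structure is expected to be energy-minimized first (the geometric
    construction is not an equilibrium configuration, so atomistic
    descriptors on it would be misleading); pass
    ``require_minimized=False`` to override. Core/surface classification
    uses the effective semilengths Dc/2 of the (possibly relaxed) structure
    by default — atoms move during relaxation, so the user ellipsoid may no
    longer bound them — or an explicit ``semilengths`` triple (Å).
    """
    if len(structure) == 0:
        raise EmptyParticleError("descriptor report of an empty structure")
    if require_minimized and not structure.provenance.get("minimized", False):
        raise StageOrderError(
            "descriptors requested on a never-minimized structure; run the "
            "minimization stage first or pass require_minimized=False"
        )

    per_energy = structure.energies
    if per_energy is None and potential is not None:
        _, per_energy = total_energy(structure, potential)

    cutoffs = coordination_cutoff(
        set(structure.elements.astype(str).tolist()),
        _charges_by_element(structure),
        settings,
    )
    counts, _ = avg_coordination(structure, settings, cutoffs)
    qcnp, _ = cnp(structure, cutoffs)
    qhex, _, _ = hexatic(structure, cutoffs)

    if semilengths is None:
        semilengths = np.array(axis_diameters(structure)) / 2.0
    core_mask = classify_core_surface(structure, semilengths, settings)

    whole = _region(
        structure, np.ones(len(structure), bool), per_energy,
        counts, qcnp, qhex, settings,
    )
    core = _region(structure, core_mask, per_energy, counts, qcnp, qhex, settings)
    surface = _region(
        structure, ~core_mask, per_energy, counts, qcnp, qhex, settings
    )

    ratios: dict[str, float | None] = {}
    diffs: dict[str, float | None] = {}
    for name in ATOMISTIC_FIELDS:
        cv = getattr(core, name)
        sv = getattr(surface, name)
        if cv is None or sv is None:
            ratios[name] = None
            diffs[name] = None
        else:
            ratios[name] = cv / sv if sv != 0 else None
            diffs[name] = cv - sv
    return DescriptorSet(whole, core, surface, ratios, diffs)
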