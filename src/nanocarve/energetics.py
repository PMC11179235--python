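"""Energy evaluation and conjugate-gradient relaxation of finite clusters.

Two pluggable pair potentials are built in — Lennard-Jones and
Buckingham — optionally combined with an unscreened Coulomb term over the
formal charges (direct O(N²) sum; the particles are isolated clusters in
vacuum, so no Ewald/Wolf treatment is needed or wanted). The total energy
is partitioned onto atoms: each pair term contributes half to each partner,
so the per-atom energies sum exactly to the total. This per-atom energy is
the basis of the stability metric (average potential energy per atom) and
of the core/surface energy descriptors.

The minimizer is Polak–Ribière conjugate gradient with Armijo backtracking
and the four ordered stopping criteria used by standard minimization
engines: relative energy change, global force 2-norm, iteration budget,
evaluation budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builder import ParticleStructure
from .errors import ParameterizationError, UnstableConfigurationError

__all__ = [
    "PairStyle",
    "PotentialModel",
    "lennard_jones",
    "buckingham_coulomb",
    "MinimizationSettings",
    "MinimizationResult",
    "total_energy",
    "forces",
    "minimize",
]

#: Coulomb constant e²/(4πε0) in eV·Å
COULOMB_K = 14.399645


@dataclass(frozen=True)
class PairStyle:
    """Parameters for one species pair.

    Lennard-Jones: V(r) = 4ε[(σ/r)¹² − (σ/r)⁶], params (ε eV, σ Å).
    Buckingham:    V(r) = A·exp(−r/ρ) − C/r⁶, params (A eV, ρ Å, C eV·Å⁶).
    """

    style: str  # "lj" | "buckingham"
    params: tuple[float, ...]
    cutoff: float

    def __post_init__(self):
        if self.style not in ("lj", "buckingham"):
            raise ValueError(f"unknown pair style {self.style!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.style == "lj" and (self.params[0] < 0 or self.params[1] <= 0):
            raise ValueError("LJ requires eps >= 0, sigma > 0")
        if self.style == "buckingham" and self.params[1] <= 0:
            raise ValueError("Buckingham requires rho > 0")


@dataclass
class PotentialModel:
    """Pair-potential table keyed by unordered species pair, plus an
    optional full Coulomb sum over formal charges."""

    pairs: dict[frozenset, PairStyle] = field(default_factory=dict)
    use_coulomb: bool = False

    def set_pair(self, a: str, b: str, style: PairStyle) -> None:
        self.pairs[frozenset((a, b))] = style

    def get_pair(self, a: str, b: str) -> PairStyle:
        try:
            return self.pairs[frozenset((a, b))]
        except KeyError:
            raise ParameterizationError(
                f"no pair parameters for species pair ({a}, {b})"
            ) from None


def lennard_jones(
    species, eps: float = 1.0, sigma: float = 1.0, cutoff: float | None = None
) -> PotentialModel:
    """Uniform LJ model over all (unordered) pairs of ``species``."""
    if cutoff is None:
        cutoff = 2.5 * sigma
    pot = PotentialModel()
    species = list(species)
    for i, a in enumerate(species):
        for b in species[i:]:
            pot.set_pair(a, b, PairStyle("lj", (eps, sigma), cutoff))
    return pot


def buckingham_coulomb(
    params: dict[tuple[str, str], tuple[float, float, float]],
    cutoff: float = 10.0,
    use_coulomb: bool = True,
) -> PotentialModel:
    """Buckingham model from an {(a, b): (A, rho, C)} table + Coulomb."""
    pot = PotentialModel(use_coulomb=use_coulomb)
    for (a, b), (A, rho, C) in params.items():
        pot.set_pair(a, b, PairStyle("buckingham", (A, rho, C), cutoff))
    return pot


def _pair_tables(structure: ParticleStructure, potential: PotentialModel):
    """Resolve species to integer types and per-type-pair parameter arrays."""
    els = structure.elements.astype(str)
    species = sorted(set(els.tolist()))
    type_of = {s: i for i, s in enumerate(species)}
    types = np.array([type_of[e] for e in els])
    ns = len(species)
    style = np.empty((ns, ns), dtype=object)
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            style[i, j] = potential.get_pair(a, b)
    return types, style, species


def _pair_energy_dvdr(ps: PairStyle, r: np.ndarray):
    """(V(r), dV/dr) for one pair style on an array of distances."""
    if ps.style == "lj":
        eps, sig = ps.params
        sr6 = (sig / r) ** 6
        v = 4.0 * eps * (sr6 * sr6 - sr6)
        dv = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    else:
        A, rho, C = ps.params
        ex = A * np.exp(-r / rho)
        v = ex - C / r**6
        dv = -ex / rho + 6.0 * C / r**7
    return v, dv


def _evaluate(
    structure: ParticleStructure,
    potential: PotentialModel,
    positions: np.ndarray | None = None,
    want_forces: bool = True,
):
    """Energy, per-atom energies and (optionally) forces at given positions.

    Pair terms use the tabulated cutoffs; the Coulomb term is summed over
    all pairs with no cutoff (finite cluster).
    """
    pos = structure.positions if positions is None else positions
    n = len(structure)
    per_atom = np.zeros(n)
    frc = np.zeros((n, 3)) if want_forces else None
    if n < 2:
        return 0.0, per_atom, frc

    types, style, _ = _pair_tables(structure, potential)
    iu, ju = np.triu_indices(n, k=1)
    dr = pos[iu] - pos[ju]
    r = np.linalg.norm(dr, axis=1)
    if np.any(r < 1e-12):
        raise UnstableConfigurationError("coincident atoms (r = 0)")

    pair_e = np.zeros(len(r))
    pair_dv = np.zeros(len(r))
    ti, tj = types[iu], types[ju]
    for a in range(style.shape[0]):
        for b in range(a, style.shape[0]):
            ps = style[a, b]
            sel = ((ti == a) & (tj == b)) | ((ti == b) & (tj == a))
            sel &= r <= ps.cutoff
            if sel.any():
                v, dv = _pair_energy_dvdr(ps, r[sel])
                pair_e[sel] += v
                pair_dv[sel] += dv

    if potential.use_coulomb and structure.charges is not None:
        qq = structure.charges[iu] * structure.charges[ju]
        pair_e += COULOMB_K * qq / r
        pair_dv += -COULOMB_K * qq / r**2

    # half of each pair term to each partner: per-atom sums reproduce E
    np.add.at(per_atom, iu, 0.5 * pair_e)
    np.add.at(per_atom, ju, 0.5 * pair_e)
    total = float(per_atom.sum())

    if want_forces:
        # F_i = -dV/dr * r_hat contributions, Newton's third law on j
        f_pair = (-pair_dv / r)[:, None] * dr
        np.add.at(frc, iu, f_pair)
        np.add.at(frc, ju, -f_pair)
    return total, per_atom, frc


def total_energy(
    structure: ParticleStructure, potential: PotentialModel
) -> tuple[float, np.ndarray]:
    """Total potential energy (eV) and its per-atom partition.

    The total is computed *as* the sum of the per-atom energies (same
    summation order), so the partition identity Σᵢ Eᵢ = E holds exactly.
    """
    e, per_atom, _ = _evaluate(structure, potential, want_forces=False)
    return e, per_atom


def forces(
    structure: ParticleStructure, potential: PotentialModel
) -> np.ndarray:
    """Analytic forces −∇E, shape (N, 3), eV/Å. Net force sums to ~0."""
    _, _, f = _evaluate(structure, potential, want_forces=True)
    return f


def load_potential_file(path, use_coulomb: bool = False) -> PotentialModel:
    """Load a pair-potential table from a plain-text file.

    One line per species pair::

        # element1 element2 style params... cutoff
        Al Al lj 0.392 2.620 6.55
        Zr O  buckingham 1453.8 0.35 0.0 10.0

    ``lj`` takes (eps eV, sigma Å, cutoff Å); ``buckingham`` takes
    (A eV, rho Å, C eV·Å⁶, cutoff Å). Lines starting with ``#`` and blank
    lines are ignored.
    """
    from pathlib import Path

    pot = PotentialModel(use_coulomb=use_coulomb)
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        f = line.split()
        if len(f) < 4:
            raise ParameterizationError(f"bad potential line: {raw!r}")
        a, b, style, *nums = f
        try:
            vals = [float(x) for x in nums]
        except ValueError:
            raise ParameterizationError(
                f"non-numeric potential parameters: {raw!r}"
            ) from None
        if style == "lj" and len(vals) == 3:
            pot.set_pair(a, b, PairStyle("lj", (vals[0], vals[1]), vals[2]))
        elif style == "buckingham" and len(vals) == 4:
            pot.set_pair(
                a, b, PairStyle("buckingham", tuple(vals[:3]), vals[3])
            )
        else:
            raise ParameterizationError(
                f"unknown style or wrong parameter count: {raw!r}"
            )
    if not pot.pairs:
        raise ParameterizationError(f"no pair parameters found in {path}")
    return pot


@dataclass(frozen=True)
class MinimizationSettings:
    """Stopping criteria for the conjugate-gradient relaxation.

    ``etol`` is the *relative* energy change between iterations
    (|ΔE| / max(|E|, 1e-12)); ``ftol`` the 2-norm of the global 3N force
    vector in eV/Å. Defaults follow common minimization practice for
    nanoparticle relaxation.
    """

    etol: float = 1e-4
    ftol: float = 1e-6
    max_iterations: int = 1000
    max_evaluations: int = 100_000

    def __post_init__(self):
        if min(self.etol, self.ftol) < 0:
            raise ValueError("tolerances must be nonnegative")
        if self.max_iterations < 0 or self.max_evaluations < 0:
            raise ValueError("budgets must be nonnegative")


@dataclass
class MinimizationResult:
    structure: ParticleStructure
    energy: float
    energy_per_atom: float
    initial_energy: float
    iterations: int
    evaluations: int
    termination: str  # "etol" | "ftol" | "maxiter" | "maxeval"


# Armijo line-search constants
_ARMIJO_C = 1e-4
_SHRINK = 0.5
_STEP0 = 0.1  # Å: initial maximum per-atom displacement
_MAX_BACKTRACK = 60


def minimize(
    structure: ParticleStructure,
    potential: PotentialModel,
    settings: MinimizationSettings = MinimizationSettings(),
) -> MinimizationResult:
    """Relax a cluster with Polak–Ribière CG + Armijo backtracking.

    Stopping criteria are tested in order each iteration: relative energy
    change ≤ etol, force 2-norm ≤ ftol, iteration budget, evaluation
    budget. The energy sequence is monotone non-increasing by construction
    (the line search only accepts decreases).

    Raises
    ------
    UnstableConfigurationError
        Non-finite energy at the start (overlapping atoms); try a
        different potential or starting geometry.
    """
    n = len(structure)
    pos = structure.positions.copy()
    evals = 0

    def eval_at(x):
        nonlocal evals
        evals += 1
        return _evaluate(structure, potential, positions=x)

    e, per_atom, f = eval_at(pos)
    if not np.isfinite(e):
        raise UnstableConfigurationError(
            "non-finite energy at start of minimization (overlapping "
            "atoms?); select another force-field or adjust the structure"
        )
    e0 = e
    g = -f.reshape(-1)  # gradient of E
    d = -g
    it = 0
    reason = None
    e_prev = None
    restart_every = max(3 * 3 * n, 1)

    while True:
        # ordered stopping criteria
        if e_prev is not None:
            if abs(e - e_prev) / max(abs(e), 1e-12) <= settings.etol:
                reason = "etol"
                break
        if np.linalg.norm(g) <= settings.ftol:
            reason = "ftol"
            break
        if it >= settings.max_iterations:
            reason = "maxiter"
            break
        if evals >= settings.max_evaluations:
            reason = "maxeval"
            break

        if np.dot(g, d) >= 0:  # not a descent direction: steepest restart
            d = -g
        dmax = np.max(np.linalg.norm(d.reshape(-1, 3), axis=1))
        alpha = _STEP0 / dmax if dmax > 0 else 0.0
        gd = np.dot(g, d)
        accepted = False
        budget_cut = False
        for _ in range(_MAX_BACKTRACK):
            if evals >= settings.max_evaluations:
                budget_cut = True
                break
            x_new = pos + alpha * d.reshape(-1, 3)
            e_new, per_new, f_new = eval_at(x_new)
            if np.isfinite(e_new) and e_new <= e + _ARMIJO_C * alpha * gd:
                accepted = True
                break
            alpha *= _SHRINK
        # a line search cut short by the evaluation budget is not a
        # converged energy change: skip the etol test so maxeval reports
        e_prev = None if (budget_cut and not accepted) else e
        it += 1
        if accepted:
            g_new = -f_new.reshape(-1)
            beta = max(0.0, np.dot(g_new, g_new - g) / max(np.dot(g, g), 1e-300))
            if it % restart_every == 0:
                beta = 0.0
            d = -g_new + beta * d
            pos, e, per_atom, g = x_new, e_new, per_new, g_new
        # if not accepted: e unchanged -> etol (or a budget) fires next pass

    out = structure.select(np.ones(n, dtype=bool), stage="minimized")
    out.positions = pos
    out.energies = per_atom
    out.provenance["minimized"] = True
    out.provenance["termination"] = reason
    return MinimizationResult(
        structure=out,
        energy=e,
        energy_per_atom=e / n if n else 0.0,
        initial_energy=e0,
        iterations=it,
        evaluations=evals,
        termination=reason,
    )
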