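# Methods

This note records the models, conventions and numerical choices behind
`nanocarve`, in the order the pipeline runs them.

## Unit-cell reconstruction

CIF input is restricted to a minimal, well-defined dialect: cell lengths
and angles, a symmetry-operator loop in `x,y,z` triplet notation
(`_symmetry_equiv_pos_as_xyz` or `_space_group_symop_operation_xyz`),
fractional atom sites with type symbols (oxidation-state suffixes such as
`Zr4+` are parsed into formal charges) and optional occupancies. The
asymmetric unit is expanded into the full orbit under the listed
operators, wrapped into [0,1) and deduplicated at 1e-3 fractional
tolerance (periodic minimum image). Files without an operator loop are
treated as P1. Space-group *names* are never interpreted: operators must
be listed. Partial occupancy is a hard error, not a warning — carving a
finite particle out of a disordered average structure has no defined
meaning, and silently rounding occupancies would fabricate a crystal the
file does not describe. If any formal charges are present the expanded
cell must be exactly neutral; charge bookkeeping is what later guarantees
neutral particles.

Element substitution is allowed only within the same IUPAC group with a
period difference of at most one: same group preserves bonding character,
adjacent period keeps atomic size close enough that the substituted
structure is not sterically absurd. Group and period are computed
arithmetically from the atomic number; La and Ac are assigned group 3 and
Z 58–71 / 90–103 are treated as groupless f-block, for which the rule is
undefined and substitution is refused.

## Geometric construction

All user-facing lengths are nm, converted ×10 to Å internally; all
coordinates are Cartesian Å.

The supercell replication count per lattice direction is
`ceil(D / w_i) + 1`, where `D` is the largest ellipsoid axis and `w_i`
the perpendicular width of the cell along direction i (cell volume
divided by the area of the opposite face; equal to the edge length for
orthogonal cells). The +1 guarantees the carving sphere fits regardless
of where lattice planes fall. A configurable atom-count guard (default
2,000,000) fails fast instead of exhausting memory.

The carving sphere is centered on the geometric center of the supercell
box — not snapped to an atom — because that choice is reproducible and
unbiased. The lattice (not the ellipsoid) is then rotated about the
user's axis through the structure centroid (Rodrigues formula,
right-hand rule); the ellipsoid itself is always axis-aligned with the
laboratory frame. Carving predicates use closed surfaces (`≤ 1`) with a
1e-9 tolerance against floating-point flicker.

Stoichiometry neutralization removes, per element, the minimal number of
atoms `count_e − ν_e·n_fu` (with `n_fu = min_e floor(count_e/ν_e)`),
choosing atoms with the largest normalized ellipsoidal coordinate
`s(r) = √((x/Rx)² + (y/Ry)² + (z/Rz)²)` — i.e. nearest the surface from
inside. `s` is a monotone, cheap and unambiguous proxy for the Euclidean
distance to the ellipsoid surface, which has no closed form. Ties break
lexicographically on (x, y, z); there is no randomness anywhere in the
builder, so identical inputs give bit-identical particles.

## Energetics

Built-in potentials are Lennard-Jones and Buckingham pair terms with
per-pair cutoffs, plus an optional Coulomb term over formal charges
summed over *all* pairs with no cutoff: the particles are finite clusters
in vacuum, so the direct O(N²) sum is exact and no Ewald/Wolf screening
is appropriate. The Coulomb constant is k = 14.399645 eV·Å/e². Many-body
variable-charge force fields (e.g. COMB3) are deliberately not
implemented; the LAMMPS data export (`atom_style charge`, bounding box
padded by 10 Å of vacuum) hands the exact atom set to engines that have
them.

Each pair term is split half-and-half between its two atoms, and the
total energy is computed *as the sum of the per-atom energies in the same
order*, so the partition identity Σᵢ Eᵢ = E holds exactly, not just to
rounding. (Three- and four-body terms would be split 1/3 and 1/4 per atom
under the same convention; the built-in potentials are pair-only.)
Forces are analytic; translation invariance (ΣF = 0) and agreement with
central finite differences to 1e-5 relative are enforced by tests.

The minimizer is Polak–Ribière conjugate gradient with Armijo
backtracking (c₁ = 1e-4, shrink 0.5, initial step scaled so the largest
atom displacement is 0.1 Å, steepest-descent restart on non-descent
directions or every 9N iterations). Four stopping criteria are tested in
order each iteration:

1. `|E_k − E_{k−1}| / max(|E_k|, 1e-12) ≤ etol` (default 1e-4) — the
   energy tolerance is *relative*, matching common minimization-engine
   semantics;
2. `‖F‖₂ ≤ ftol` (default 1e-6 eV/Å) — the 2-norm of the global 3N force
   vector;
3. iteration budget (default 1000);
4. energy/force evaluation budget (default 1e5).

The published tolerance values are quoted without units; the relative-
energy / global-force-norm reading is the documented choice here. The
accepted-step rule makes the energy sequence monotone non-increasing. A
line search cut short by the evaluation budget does not count as a
converged energy change (the budget criterion reports instead). A
non-finite starting energy (overlapping atoms) raises immediately with
advice to pick another force field or geometry.

## Descriptors

Surface atoms are those outside the ellipsoid shrunk by a uniform
t = 4 Å on every semilength; the same thickness for every material keeps
core/surface descriptors comparable across chemistries. If any
semilength is ≤ t, the whole particle is surface. By default the
classification uses effective semilengths `D_c/2` from the *relaxed*
structure's axis extents — relaxation moves atoms, so the user's ellipsoid
may no longer bound them — but an explicit semilength triple can be
passed to use the construction ellipsoid instead. Atomistic descriptors
are computed once per atom on the whole particle (neighbour lists do not
stop at the region boundary) and then averaged per region; consequently
the whole-particle average is exactly the count-weighted mean of the core
and surface averages.

Neighbour cutoffs follow the radius rule: 2.4·r for a single species;
for exactly two species a *single* cutoff 1.2·(r_a + r_b) applied to
every pair — this keeps like-species second shells (e.g. the twelve
anion–anion contacts in rock salt at a/√2) out of the neighbour count,
so an interior rock-salt atom has coordination 6; a flat 5 Å when more
than two species are present. Radii are Shannon effective ionic radii at
the site's formal oxidation state (bundled plain-text table, octahedral
coordination), with the covalent radius as a logged fallback when no
ionic entry applies. The neighbour predicate is strictly `distance <
cutoff`.

The common-neighbour parameter is the Tsuzuki form: for atom i,
`Q_i = (1/n_i) Σ_j ‖Σ_{k∈common(i,j)} (r_ik + r_jk)‖²` over neighbours j
and the atoms k neighbouring both i and j. Atoms without neighbours get
Q = 0 and empty common sums contribute 0. The hexatic parameter projects
each bond onto the laboratory xy-plane (`θ = atan2(Δy, Δx)`), skips
bonds whose projection is shorter than 1e-9 Å, and averages
`exp(i·6θ)` over the atom's neighbour count; the mean real and imaginary
parts are reported separately. Both Dx/Dy/Dz and ψ6 are deliberately
frame-dependent (they measure anisotropy in the laboratory frame where
the ellipsoid lives) and are therefore not rotation-invariant; all other
descriptors are invariant under rigid motions.

The Thomsen surface formula with p = 1.6075 is exact for spheres (the
exponent cancels) and within 1.061 % of the true area otherwise. The
package verifies this against an independent adaptive quadrature
(`scipy.integrate.dblquad`, epsrel 1e-10) of the surface integral in
spherical parametrization over one octant; the sweep covers aspect
ratios from 1:1:1 to 1:1:100 and 1:100:100 on a logarithmic grid, where
the observed worst case is ≈ 1.059 %.

## Exploration

All three searches score a candidate by its average potential energy per
atom after relaxation — lower is more stable. The fixed-volume scan
closes each (Dx, Dy) pair with Dz = 6V/(π·Dx·Dy) and carves with the
unrounded triple (values are rounded to 2 decimals only for reporting;
note that recomputing the volume from rounded axes can disagree with the
design volume in the last decimal, e.g. 2.50/1.95/1.64 nm semilengths
give 33.49 nm³ against a 33.51 nm³ design constraint). The growth search
is greedy — at each node every allowed per-axis increment is built,
relaxed and scored, and the walk advances to the argmin (ties:
lexicographically smallest axes) until the largest axis reaches the
target. Greedy is the intended model of gradual atom deposition, not an
attempt at global optimization; an exhaustive route enumeration exists
only in the test suite at toy scale. Failed candidates (memory guard,
empty carve) are recorded per run and sort last; they never abort a scan.

## Synthetic fixtures and what they show

The bundled generators produce ideal rutile-type MO₂ (tetragonal, 2 metal
+ 4 oxygen sites, defaults matching the published TiO₂ cell a = 4.593 Å,
c = 2.959 Å, u = 0.305, charges 4+/2−), rock salt (NaCl defaults,
a = 5.64 Å) and FCC (Al, a = 4.05 Å) cells as P1 CIF text. They emulate
COD-style input files exactly in format, but they are *ideal* crystals:
no thermal disorder, no vacancies, no surface reconstruction, no
experimental uncertainty in coordinates. Tests passing on them validate
the construction geometry, the bookkeeping and the descriptor
mathematics — they do not validate any force field against real zirconia
energetics, which requires the exported LAMMPS route.

Desk-scale test problems are kept small deliberately: LJ scan fixtures
use ~1–2 nm particles (hundreds of atoms, seconds per relaxation), and
the fixed-volume stability comparison runs two ~2,000-atom candidates.
The surface-to-volume trend those tests check (elongation destabilizes at
fixed volume) is scale-free, so nothing is lost by testing it small.

## Known limitations

- Only ellipsoids: no polyhedral (Wulff-type) shapes, rods or
  core–shell particles.
- Pair potentials only; no charge equilibration, no molecular dynamics,
  no periodic boundary conditions. Energies from the built-in potentials
  order shapes sensibly but are not quantitative for oxides — export to
  LAMMPS for many-body force fields.
- CIF support is the minimal dialect above; space-group symbol inference
  and disordered structures are out of scope.
- Shannon radii are bundled only for common oxidation states; exotic
  ions fall back to covalent radii with a warning.
- The conjugate-gradient minimizer finds local minima; surmounting
  barriers toward a global minimum would need annealing dynamics, which
  is explicitly out of scope.
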