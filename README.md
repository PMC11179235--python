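# nanocarve

Digital construction and stability analysis of ellipsoidal nanoparticles,
for materials and nanosafety researchers who want to screen particle
shapes, sizes and hypothetical chemistries *in silico* before anyone tries
to synthesize them.

Starting from any crystal structure in CIF form, `nanocarve`:

1. **reconstructs the unit cell** — symmetry expansion of the asymmetric
   unit, with optional element substitution restricted to the same IUPAC
   group and adjacent periods (similar bonding, similar size, so the
   hypothetical structure stays plausible);
2. **carves a charge-neutral, stoichiometric ellipsoidal nanoparticle** —
   replicate the cell into a supercell, cut a sphere with diameter equal
   to the longest ellipsoid axis, rotate the lattice about a user axis,
   cut the laboratory-frame ellipsoid, and finally remove surplus atoms
   nearest the surface so element counts are an exact multiple of the
   formula unit;
3. **relaxes the cluster** with a Polak–Ribière conjugate-gradient
   minimizer over pluggable pair potentials (Lennard-Jones, Buckingham,
   optional full Coulomb sum over formal charges — the particle is an
   isolated cluster in vacuum, so no lattice sums are involved), stopping
   on relative energy change, force norm, or iteration/evaluation budgets;
4. **computes a descriptor panel** for the whole particle and separately
   for its core and its 4 Å surface shell, plus core-vs-surface ratios and
   differences;
5. **explores shape space** — fixed-volume shape ranking, lattice-rotation
   scans, and a greedy lowest-energy crystal-growth pathway — using the
   average potential energy per atom as the stability metric.

## Descriptors

Geometric: the per-axis extents `Dx, Dy, Dz` (largest interatomic
separation per Cartesian direction), the ellipsoid volume
`V = (4/3)π RxRyRz`, and the Knud Thomsen approximation of the ellipsoid
surface area

    S ≈ 4π [((RxRy)^p + (RxRz)^p + (RyRz)^p)/3]^(1/p),   p = 1.6075,

which is exact for spheres and within 1.061 % of the true area for any
aspect ratio (the package ships an adaptive-quadrature exact integrator
used to verify this bound).

Atomistic: average potential energy per atom (each pair term split half
per partner, so per-atom energies sum exactly to the total), coordination
number (neighbours strictly inside a cutoff derived from Shannon ionic
radii: 2.4·r for one species, 1.2·(r_a+r_b) for two, 5 Å beyond that),
the Tsuzuki common-neighbour parameter

    Q_i = (1/n_i) Σ_j ‖ Σ_{k ∈ common(i,j)} (r_ik + r_jk) ‖²

(zero inside a perfect FCC crystal, positive at defects and surfaces),
and the hexatic order parameter ψ6 = ⟨exp(i·6θ)⟩ over bond angles in the
laboratory xy-plane.

## Worked example

Build a rutile-like zirconia nanoparticle from the bundled rutile TiO₂
cell by Ti→Zr substitution, relax it with a rigid-ion Buckingham +
Coulomb model, and compute its descriptors:

```
$ nanocarve fixture rutile_MO2 -o tio2.cif
wrote tio2.cif (6 sites, formula {'O': 2, 'Ti': 1})

$ nanocarve build tio2.cif --substitute Ti:Zr --axes 2,2,2 -o zro2_geo.xyz
wrote zro2_geo.xyz: 393 atoms, composition {'O': 262, 'Zr': 131}, net charge +0.0000 e

$ cat > zro2.pot <<'EOF'
Zr O  buckingham 985.869 0.3760 0.0   10.0
O  O  buckingham 22764.0 0.1490 27.89 10.0
Zr Zr buckingham 0.0     1.0    0.0   10.0
EOF
$ nanocarve minimize zro2_geo.xyz --potential buckingham --param-file zro2.pot \
      --coulomb --max-iterations 200 -o zro2_min.xyz --lammps-data zro2.lmp
E = -14100.493590 eV (-35.879119 eV/atom), 21 iterations, 22 evaluations, stopped on etol

$ nanocarve descriptors zro2_min.xyz -o zro2_desc
wrote zro2_desc.csv and zro2_desc.json (core 51 / surface 342 atoms)
```

The 2 nm particle holds 131 ZrO₂ formula units (393 atoms, exactly 2 O
per Zr, net charge zero — the neutralization stage guarantees both). The
relaxation stopped when the relative energy change fell below the default
1e-4. In the descriptor CSV the core (51 atoms deeper than 4 Å below the
surface) shows higher average coordination than the 342-atom surface
shell (4.35 vs 3.77), and the derived block reports the core/surface
ratios and differences used as reactivity descriptors. The exported
`zro2.lmp` (LAMMPS `atom_style charge`) can feed the same exact atom set
to an external LAMMPS run with a many-body force field such as COMB3.

Shape exploration works the same way from the shell, e.g.

```
$ nanocarve scan-shapes tio2.cif -o scan.csv --volume 33.51 \
      --pairs "4,4;3,4;2,2.5" ...
```

ranks the fixed-volume candidates (Dz is closed from the volume
constraint: 4.00/4.00 → 4.00, 3.00/4.00 → 5.33, 2.00/2.50 → 12.80 nm) by
relaxed energy per atom, and `nanocarve grow` walks the greedy
lowest-energy growth pathway.

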