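# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `denrefine`.  It is the package's own account of its
science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## The restraint network

A deformable elastic network is a set of N harmonic distance restraints
between randomly chosen atom pairs,

    E_DEN(x) = w_DEN Σ_ij (d_ij(x) − d⁰_ij)²,

with the per-restraint spring constant absorbed into the single weight
w_DEN (the only strength knob exposed).  Pair eligibility is evaluated on
the **reference model**: distance within [d_lo, d_hi] = [3, 15] Å, sequence
separation within [0, 10] residues for same-chain pairs, and no inter-chain
pairs unless enabled.  Setting `seq_sep_hi=None` together with
`allow_inter_chain=True` reproduces the very-low-resolution multi-chain
mode in which restraints also tie chains to each other.  Selection is a
uniform sample without replacement, implemented as a seeded shuffle of the
deterministically enumerated eligible list, so repeats with different seeds
draw genuinely different networks.  `n_restraints="auto"` (the default)
selects one restraint per restrainable atom; the appropriate density is not
a settled quantity, so it is config-exposed.  Initial equilibria d⁰ are
taken from the **starting model** — the refinement begins at the minimum of
E_DEN, avoiding large initial forces — while d_ref comes from the
reference; when the two models coincide (the common case) d⁰ = d_ref
initially.

After each temperature decrement of slow cooling the equilibria deform:

    d⁰ ← d⁰ + κ[γ(d(t) − d⁰) + (1−γ)(d_ref − d⁰)],  κ = 0.1 default.

Analytic consequences used as test oracles: at frozen coordinates the
update has fixed point d⁰* = γ·d + (1−γ)·d_ref and converges to it
geometrically with factor (1−κ) per update; the update is affine in γ; at
γ=1 the reference distances cancel out of the formula entirely, and at the
fixed point both E_DEN and its forces vanish, so restrained and
unrestrained targets share their local minima.

## The stereochemical term

E_MM is a deliberately minimal stand-in for a full geometric force field:
harmonic bonds (k = 1000 kcal mol⁻¹ Å⁻²) and angles (k = 100 kcal mol⁻¹
rad⁻²) with equilibrium values taken from the build-time (assumed ideal)
geometry, plus a purely repulsive quartic contact term
k_rep(r_c − d)⁴ (k_rep = 100 kcal mol⁻¹ Å⁻⁴) switching on below
r_c = 0.9 × (vdW_i + vdW_j).  Bonds are inferred from element-pair distance
cutoffs (1.3 × summed covalent radii, capped at 2.0 Å) within and between
consecutive residues of one chain; angles are enumerated from the bond
graph.  Nonbonded exclusions are the bonded 1-2 and 1-3 pairs **plus any
pair already inside its contact radius in the build geometry** (helical
i,i+4 hydrogen-bond partners and some 1-4 pairs): those contacts are part
of the reference structure, not clashes, and excluding them makes the build
geometry an exact zero of E_MM.  There are no dihedral, electrostatic or
attractive nonbonded terms; at the scales treated here chirality and
planarity are maintained by the angle terms and the restraint network.  The
package's claims concern restraint behaviour, not force-field fidelity.

## The diffraction term

Space group P1, one model per cell, no bulk solvent, no anisotropic
scaling.  Structure factors are computed by direct summation

    F(h) = Σ_a occ_a f_a(s) e^(−B_a s²/4) e^(2πi h·x_frac,a),  s = 1/d(h),

with one-Gaussian-plus-constant form factors f(s) = a·e^(−b s²) + c fitted
per element to standard scattering tables (worst-case fit error ≤ 0.14 e).
Since the synthetic observations use the same table, form-factor accuracy
cancels from every comparison.  The hot loop evaluates the phase factors by
per-dimension recursion over integer Miller indices (3·N_atoms trig calls
per evaluation), exact to ~1e-14 relative against the direct expression.

The refinement target is amplitude least squares over **working**
reflections only,

    E_X-ray = w_X-ray Σ_work (F_obs − k·|F_calc|)²,

with k the closed-form least-squares scale over the work set.  Because k is
at its optimum, its coordinate dependence contributes nothing to the
gradient (envelope theorem), so the analytic forces are exact; test-set
reflections contribute to neither energy nor forces, which the suite
verifies by scrambling the test amplitudes.  R_work/R_free use the
conventional Σ|F_obs − k|F_calc|| / ΣF_obs with k fitted on work data.
Friedel-unique indices are chosen by "first nonzero of (h,k,l) positive";
the reflection file header records the cell, resolution limit and this
hemisphere rule.  Maximum-likelihood targets, experimental-phase targets
and twinning are out of scope.

The test-set fraction defaults to 0.10 — a customary choice; nothing in the
method fixes it — and is config-exposed.

## Dynamics and protocol

Annealing is **Cartesian** velocity-Verlet with per-level velocity
rescaling, not torsion-angle dynamics; this is the main deliberate
deviation from classic implementations of the method, and it is why
refinement configurations default to a 1 fs timestep.  The schedule object
itself keeps the classic constants — 3000 K → 0 K, 50 K decrements, six
steps per level, 4 fs — under which the ladder has 60 levels and 1.44 ps of
simulated time; those constants are verified as arithmetic, while actual
refinements run the same ladder at 1 fs (0.36 ps).  Units are Å, fs, amu,
kcal/mol; with these, velocity variance k_B·T·c/m (c = 4.184e-4 Å² fs⁻²
per kcal mol⁻¹ amu⁻¹) gives Maxwell–Boltzmann draws whose kinetic
temperature the suite checks at 500 atoms.  The deformation update is
applied exactly once per level, **after** the level's dynamics steps (the
alternative order is a config flag; nothing in the method's description
fixes it).

A refinement is n_macrocycles (default 8) rounds of: automatic X-ray
weighting → one annealing pass → 200-step adaptive steepest-descent
positional minimization → optional B-factor refinement.  w_X-ray is set by
gradient-norm matching (RMS per-atom X-ray force = RMS per-atom E_MM force
at the current model, recomputed each macrocycle; fallback 1.0 at a zero
stereochemical gradient).  The first macrocycle uses γ=0 — the network
relaxes the model toward the reference before local structure is allowed
to deform — and the last two optionally run with w_DEN=0 as a convergence
probe; the RMSD between the models before and after the released
macrocycles is reported as `drift_rmsd`.  The restraint pair list is
selected once per refinement and never changes; only d⁰ evolves.  Grouped
B-factor refinement (two values per residue: main chain {N, CA, C, O} and
side chain) is bounded to [1, 500] Å² and solved by L-BFGS-B with analytic
gradients through the Debye–Waller factor; it is the default at toy
resolutions because individual B factors over-parameterize.

Segmented rigid-body pre-refinement optimizes a rotation vector and
translation per segment (default one per chain) against the work-set
residual.  P1 amplitudes are invariant under a uniform translation of the
whole model, so the common translation is projected out of the search
space, and the synthetic displacement generator likewise removes the net
shift it applies — the common mode is unrecoverable from amplitude data as
a matter of mathematics.  With that convention, recovery of 5°/2 Å
per-chain displacements from 7.4 Å data is exact to numerical precision.

## Grid search and model selection

The default grid is γ ∈ {0, 0.2, 0.4, 0.6, 0.8, 1.0} ×
w_DEN ∈ {3, 10, 30, 100, 300} with 5 repeats (5–20 recommended); a
line-search constructor varies γ at fixed w_DEN = 100.  Every cell×repeat
is an independent refinement whose seed derives from
`SeedSequence(base_seed, spawn_key=(γ-index, w-index, repeat))` — stable
across platforms, embarrassingly parallel, reduced below 2³¹.  Each repeat
re-selects restraints and re-draws velocities.  Selection: records with
R_free within 2/√N_test of the minimum are statistically
indistinguishable; among them the lowest geometry score wins.  The
geometry score is RMS bond-length deviation (Å) + 0.1 × RMS angle deviation
(degrees) — a proxy for Ramachandran/rotamer-based quality, which is out of
scope for poly-alanine toys.

## Synthetic data: what it does and does not emulate

Toy structures are poly-alanine only (5 heavy atoms per residue, ≤ ~600
atoms): enough to expose distance windows, sequence separation, chain
identity, helical contacts and register shifts, while keeping a full grid
search on one CPU in minutes.  Boxes are padded by ≥10 Å so reflection
counts stay in the hundreds-to-thousands.  Perturbed starts use random
φ/ψ kicks propagated down-chain (or a low-frequency Cartesian displacement
field), with the amplitude bisected until the no-superposition RMSD is
within 10% of target, then bonded geometry is restored by E_MM
minimization.  Observations are |F_calc(truth)|·(1+ε), ε ~ N(0,
noise_frac), clipped at zero.

The benchmark scenarios fix the study conditions: `lowres_helix` (20
residues, start perturbed to 2.5 Å, d_min 3.5 Å, 2% noise), `verylow_bundle`
(3 × 12 residues, per-chain 5°/2 Å rigid displacement plus torsion noise to
4 Å total, d_min 7.4 Å, inter-chain restraints with no sequence limit) and
`register_shift` (one-residue register error over a 6-residue window, ideal
reference).  The benchmark experiment (`benchmark.py`) uses a reduced grid
γ ∈ {0, 0.4, 1} × w_DEN ∈ {10, 100}, 3 repeats, two macrocycles per trial
(γ=0 relaxation, then the grid γ; restraints kept on throughout, which is
the appropriate regime at low resolution), 150 minimization steps, no
B-factor refinement (the truth B field is uniform), and 3 unrestrained
controls — sizes chosen once for a single CPU.

What passing these tests shows: with data this clean and models this small,
deformable restraints measurably beat unrestrained annealing in model error
*and* the improvement is visible through R_free, i.e. cross-validation
ranks (γ, w_DEN) cells consistently with their true accuracy.  What it does
not show: behaviour with real measurement error models, bulk solvent,
side-chain rotamers, large multi-domain rearrangements, or data pathologies
(twinning, anisotropy) — none of which are modelled here.

## Numerical choices and degenerate inputs

* Forces are analytic everywhere and verified against central finite
  differences at 1e-4–1e-5 relative tolerance; the angle gradient guards
  sin θ ≥ 1e-6, the repulsion guards coincident atoms, and |F| is floored
  at 1e-30 in the chain rule.
* Coincident restrained atoms raise a singular-geometry error rather than
  returning an infinite force.
* The equilibrium-distance update validates γ ∈ [0,1], κ ∈ (0,1].
* A refinement is bitwise reproducible given its config seed; all
  sub-seeds (selection, per-macrocycle velocities, noise, free flags)
  derive from it through `SeedSequence.spawn`.
* Empty eligible-pair sets, empty test sets, all-zero amplitudes, zero-ATOM
  PDB files and out-of-range fractions raise typed errors with messages
  naming the cause (and the line number, for PDB parse failures).

## Known limitations

Cartesian rather than torsion-angle dynamics (broader effective search,
needs the stiff-bond timestep); amplitude least squares rather than maximum
likelihood; P1 only, single overall scale, no solvent model; poly-alanine
fixtures without rotamers; the geometry score is a bond/angle proxy, not a
Ramachandran statistic; no TLS, occupancy or multi-reference refinement.
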