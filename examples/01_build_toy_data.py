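"""Build a toy refinement problem: an ideal helix, a perturbed starting
model, and synthetic diffraction amplitudes.

The truth is a 20-residue poly-alanine α-helix in a padded P1 box.  The
starting model is the truth perturbed by random φ/ψ kicks to ~2 Å RMSD, and
the "observations" are |F_calc(truth)| with 2% multiplicative noise plus
free-set flags.  Run: python examples/01_build_toy_data.py
"""

import numpy as np

from denrefine import (
    calc_structure_factors,
    compare,
    make_helix,
    make_observations,
    perturb_structure,
    r_factors,
    write_pdb,
    write_reflections,
)

truth = make_helix(20)
print(f"truth: {len(truth)} atoms, cell "
      f"{tuple(round(x, 1) for x in truth.unit_cell.lengths)} Å")

start = perturb_structure(truth, target_rmsd=2.0, seed=1, mode="torsion")
print(f"start model RMSD to truth: {compare(start, truth).rmsd_all:.2f} Å "
      "(crystal frame, no superposition)")

obs = make_observations(truth, d_min=3.5, noise_frac=0.02, seed=1)
print(f"reflections to 3.5 Å: {len(obs)}  (test set: {obs.n_test})")

r_work, r_free = r_factors(obs, calc_structure_factors(start, obs))
print(f"starting R_work/R_free: {r_work:.3f}/{r_free:.3f} "
      "— the gap a refinement has to close")

write_pdb(truth, "truth.pdb")
write_pdb(start, "start.pdb")
write_reflections(obs, "observed.hkl")
print("wrote truth.pdb, start.pdb, observed.hkl")
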