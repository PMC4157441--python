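"""Segmented rigid-body pre-refinement at very low resolution.

Each chain of a three-helix bundle is rotated 5° and translated 2 Å; the
refiner treats chains as 6-DOF rigid bodies against 7.4 Å amplitude data and
recovers the poses.  Run: python examples/05_rigid_body.py  (≈5 s)
"""

from denrefine import compare, make_bundle, make_observations, rigid_body_refine
from denrefine.synthetic import displace_chains_rigidly

truth = make_bundle(3, 12, spacing=10.0)
obs = make_observations(truth, d_min=7.4, noise_frac=0.0, seed=5)
print(f"bundle: {len(truth)} atoms, {len(obs)} reflections to 7.4 Å")

displaced = displace_chains_rigidly(truth, rot_deg=5.0, trans=2.0, seed=5)
print(f"after per-chain 5°/2 Å displacement: "
      f"RMSD {compare(displaced, truth).rmsd_all:.2f} Å")

recovered = rigid_body_refine(displaced, obs)
print(f"after segmented rigid-body refinement: "
      f"RMSD {compare(recovered, truth).rmsd_all:.4f} Å")
print("Low-resolution amplitudes fix chain poses almost exactly; the "
      "remaining (internal) errors are what restrained annealing is for.")
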