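"""Model-quality metrics: RMSD to a known truth and geometry quality.

RMSD is computed in the crystal frame by default (no superposition), the
convention under which refinement deviations are meaningful; an optional
least-squares superposition (quaternion/Kabsch) removes rigid motion first.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .den import check_correspondence
from .forcefield import build_topology, geometry_score
from .structures import Structure


@dataclass
class ComparisonReport:
    rmsd_all: float            # Å
    rmsd_ca: float             # Å
    fraction_within_2A: float
    geometry_score: float
    superposed: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def superpose_coords(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares superposition of mobile onto target (rotation via the
    quaternion-based Kabsch solver)."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.apply(mobile - mc) + tc


def compare(model: Structure, truth: Structure, superpose: bool = False) -> ComparisonReport:
    """Per-atom deviation statistics of ``model`` against ``truth``."""
    check_correspondence(model, truth)
    xyz_m = model.coords
    xyz_t = truth.coords
    if superpose:
        xyz_m = superpose_coords(xyz_m, xyz_t)
    dev = np.linalg.norm(xyz_m - xyz_t, axis=1)
    is_ca = np.array([a.name == "CA" for a in model.atoms])
    rmsd_all = float(np.sqrt(np.mean(dev**2)))
    rmsd_ca = float(np.sqrt(np.mean(dev[is_ca] ** 2))) if is_ca.any() else rmsd_all
    topo = build_topology(truth)
    return ComparisonReport(
        rmsd_all=rmsd_all,
        rmsd_ca=rmsd_ca,
        fraction_within_2A=float(np.mean(dev < 2.0)),
        geometry_score=geometry_score(model.coords, topo),
        superposed=superpose,
    )
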