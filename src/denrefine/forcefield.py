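"""Simplified stereochemical force field E_MM.

Harmonic bonds and angles with equilibria taken from the build-time (assumed
ideal) geometry, plus a purely repulsive quartic contact term.  This is a
deliberately minimal stand-in for a full geometric force field: the package's
claims concern restraint behaviour during refinement, not force-field
fidelity.  No dihedral, electrostatic or attractive nonbonded terms; at the
small scales treated here chirality and planarity are maintained implicitly
by the angle terms and the restraint network.

Units: kcal·mol⁻¹, Å, radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import element_data
from .structures import Structure

DEFAULT_BOND_K = 1000.0    # kcal mol⁻¹ Å⁻²
DEFAULT_ANGLE_K = 100.0    # kcal mol⁻¹ rad⁻²
DEFAULT_REPULSION_K = 100.0  # kcal mol⁻¹ Å⁻⁴
CONTACT_FACTOR = 0.9       # repulsion onset at 0.9 × (vdW_i + vdW_j)
MAX_BOND_LENGTH = 2.0      # Å, build-time sanity limit


class TopologyError(ValueError):
    pass


@dataclass
class Topology:
    """Bond/angle lists with equilibrium values and the nonbonded setup."""

    bonds: np.ndarray          # (nb, 2) int
    bond_r0: np.ndarray        # (nb,)
    bond_k: np.ndarray         # (nb,)
    angles: np.ndarray         # (na, 3) int, vertex atom in the middle
    angle_theta0: np.ndarray   # (na,) rad
    angle_k: np.ndarray        # (na,)
    contact_radius: np.ndarray  # (n, n) pairwise repulsion onset, Å
    excluded: np.ndarray       # (n, n) bool, pairs exempt from repulsion
    repulsion_k: float = DEFAULT_REPULSION_K
    warnings: list = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return self.excluded.shape[0]


def default_bond_cutoff(el_i: str, el_j: str) -> float:
    """Element-pair bond detection cutoff: 1.3 × sum of covalent radii,
    capped at the build-time sanity limit."""
    r = 1.3 * (element_data(el_i).r_covalent + element_data(el_j).r_covalent)
    return min(r, MAX_BOND_LENGTH)


def build_topology(
    structure: Structure,
    bond_cutoffs=None,
    bond_k: float = DEFAULT_BOND_K,
    angle_k: float = DEFAULT_ANGLE_K,
    repulsion_k: float = DEFAULT_REPULSION_K,
) -> Topology:
    """Infer bonds by element-pair distance cutoffs (within a residue and
    between consecutive residues of one chain), enumerate angles from the
    bond graph, and set all equilibrium values from the structure's own
    geometry.  Inter-chain bonds are never created.

    ``bond_cutoffs`` may be a dict {(el_i, el_j): Å} overriding the default
    covalent-radius rule (symmetrized automatically).
    """
    xyz = structure.coords
    n = len(structure)
    elements = structure.elements
    resi = np.array([a.residue_index for a in structure.atoms])
    chain = np.array([a.chain_id for a in structure.atoms])

    def cutoff(ei: str, ej: str) -> float:
        if bond_cutoffs:
            key = (ei, ej) if (ei, ej) in bond_cutoffs else (ej, ei)
            if key in bond_cutoffs:
                return bond_cutoffs[key]
        return default_bond_cutoff(ei, ej)

    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            if chain[i] != chain[j]:
                continue  # inter-chain bond inference rejected
            if abs(resi[i] - resi[j]) > 1:
                continue
            if d[i, j] <= cutoff(elements[i], elements[j]):
                bonds.append((i, j))
    bonds = np.array(bonds, dtype=int).reshape(-1, 2)

    warnings = []
    degree = np.zeros(n, dtype=int)
    for i, j in bonds:
        degree[i] += 1
        degree[j] += 1
    for i in np.flatnonzero(degree == 0):
        warnings.append(f"atom {i} ({structure.atoms[i].name}) has zero bonds")

    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    angles = []
    for j in range(n):
        nb = sorted(neighbors[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    angles = np.array(angles, dtype=int).reshape(-1, 3)

    bond_r0 = d[bonds[:, 0], bonds[:, 1]] if len(bonds) else np.zeros(0)

    def angle_value(pos, trip):
        u = pos[trip[:, 0]] - pos[trip[:, 1]]
        v = pos[trip[:, 2]] - pos[trip[:, 1]]
        cu = np.linalg.norm(u, axis=1)
        cv = np.linalg.norm(v, axis=1)
        cosang = np.clip(np.sum(u * v, axis=1) / (cu * cv), -1.0, 1.0)
        return np.arccos(cosang)

    theta0 = angle_value(xyz, angles) if len(angles) else np.zeros(0)

    vdw = np.array([element_data(e).r_vdw for e in elements])
    contact = CONTACT_FACTOR * (vdw[:, None] + vdw[None, :])

    excluded = np.eye(n, dtype=bool)
    for i, j in bonds:
        excluded[i, j] = excluded[j, i] = True
    for i, j, k in angles:
        excluded[i, k] = excluded[k, i] = True
    # pairs already inside the repulsion onset in the (ideal) build geometry
    # are part of the reference structure, not clashes: exclude them so the
    # build geometry sits exactly at E_MM = 0
    native_contact = d < contact
    excluded |= native_contact

    return Topology(
        bonds=bonds,
        bond_r0=bond_r0,
        bond_k=np.full(len(bonds), bond_k),
        angles=angles,
        angle_theta0=theta0,
        angle_k=np.full(len(angles), angle_k),
        contact_radius=contact,
        excluded=excluded,
        repulsion_k=repulsion_k,
        warnings=warnings,
    )


def geom_energy_forces(
    positions: np.ndarray, topology: Topology
) -> tuple[float, np.ndarray]:
    """E_MM and its negative gradient.

    E = Σ k_b (r − r0)² + Σ k_θ (θ − θ0)² + k_rep Σ' (r_c − d)⁴ for
    non-excluded pairs with d < r_c.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    energy = 0.0
    forces = np.zeros_like(pos)

    if len(topology.bonds):
        i, j = topology.bonds[:, 0], topology.bonds[:, 1]
        dvec = pos[i] - pos[j]
        r = np.linalg.norm(dvec, axis=1)
        delta = r - topology.bond_r0
        energy += float(np.sum(topology.bond_k * delta**2))
        g = (2.0 * topology.bond_k * delta / r)[:, None] * dvec
        np.add.at(forces, i, -g)
        np.add.at(forces, j, g)

    if len(topology.angles):
        ai, aj, ak = (topology.angles[:, c] for c in range(3))
        u = pos[ai] - pos[aj]
        v = pos[ak] - pos[aj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cosang = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        theta = np.arccos(cosang)
        sin = np.sqrt(np.maximum(1.0 - cosang**2, 1e-12))
        delta = theta - topology.angle_theta0
        energy += float(np.sum(topology.angle_k * delta**2))
        dEdtheta = 2.0 * topology.angle_k * delta
        # dθ/dr_i = −(v̂ − cosθ·û)/(|u| sinθ); symmetric for r_k
        gi = (-dEdtheta / (nu * sin))[:, None] * (vh - cosang[:, None] * uh)
        gk = (-dEdtheta / (nv * sin))[:, None] * (uh - cosang[:, None] * vh)
        np.add.at(forces, ai, -gi)
        np.add.at(forces, ak, -gk)
        np.add.at(forces, aj, gi + gk)

    # repulsion over non-excluded close pairs
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    with np.errstate(invalid="ignore"):
        close = (dist < topology.contact_radius) & ~topology.excluded
    iu = np.triu(close, k=1)
    ii, jj = np.nonzero(iu)
    if len(ii):
        dd = np.maximum(dist[ii, jj], 1e-8)  # coincident atoms: finite force
        gap = topology.contact_radius[ii, jj] - dd
        energy += topology.repulsion_k * float(np.sum(gap**4))
        g = (-4.0 * topology.repulsion_k * gap**3 / dd)[:, None] * diff[ii, jj]
        np.add.at(forces, ii, -g)
        np.add.at(forces, jj, g)

    return energy, forces


def geometry_score(positions: np.ndarray, topology: Topology) -> float:
    """Composite geometry quality: RMS bond-length deviation (Å) plus
    0.1 × RMS angle deviation (degrees).  Lower is better."""
    pos = np.asarray(positions, dtype=float)
    rms_bond = 0.0
    if len(topology.bonds):
        i, j = topology.bonds[:, 0], topology.bonds[:, 1]
        r = np.linalg.norm(pos[i] - pos[j], axis=1)
        rms_bond = float(np.sqrt(np.mean((r - topology.bond_r0) ** 2)))
    rms_angle = 0.0
    if len(topology.angles):
        u = pos[topology.angles[:, 0]] - pos[topology.angles[:, 1]]
        v = pos[topology.angles[:, 2]] - pos[topology.angles[:, 1]]
        cosang = np.clip(
            np.sum(u * v, axis=1)
            / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)),
            -1.0,
            1.0,
        )
        dtheta = np.degrees(np.arccos(cosang) - topology.angle_theta0)
        rms_angle = float(np.sqrt(np.mean(dtheta**2)))
    return rms_bond + 0.1 * rms_angle
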