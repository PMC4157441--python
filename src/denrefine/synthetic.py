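"""Synthetic fixtures and benchmark scenarios.

Everything needed to exercise restrained refinement without external data:
ideal poly-alanine helices (5 heavy atoms per residue), multi-chain helix
bundles, controlled perturbations calibrated to a target RMSD, and synthetic
observed amplitudes computed from a "true" structure at a stated resolution
limit.  Poly-alanine keeps atom counts at desk scale while exposing all the
mechanics a restraint network interacts with: local geometry, helical
H-bond-range contacts, sequence separation and chain identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .den import SelectionConfig
from .forcefield import build_topology, geom_energy_forces
from .structures import Atom, Structure, UnitCell, center_in_cell, default_box
from .xray import ReflectionSet, assign_test_set, calc_structure_factors

# ideal backbone geometry (Å, degrees)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.521}
_ANGLE = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2, "CA-C-O": 120.8,
          "N-CA-CB": 110.4}
# dihedral(C, N, CA, CB) is internal to the residue; −122.55° gives the
# L-configuration (chiral volume at CA ≈ +2.5 Å³)
_CB_TORSION = -122.55
HELIX_PHI = -57.0
HELIX_PSI = -47.0
OMEGA = 180.0
DEFAULT_B = 20.0
BOX_PADDING = 10.0  # Å minimum margin


class CalibrationError(RuntimeError):
    """Perturbation amplitude calibration failed to reach the target RMSD."""


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors (natural extension reference
    frame): |cd| = bond, angle(b,c,d), dihedral(a,b,c,d)."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            bond * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_polyala(n_residues: int, phi: float = HELIX_PHI, psi: float = HELIX_PSI):
    """Heavy-atom poly-alanine backbone coordinates, atoms ordered
    N, CA, C, O, CB per residue.  Returns (coords, names) arrays."""
    coords: list[np.ndarray] = []
    names: list[str] = []

    # seed residue 0 backbone in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbone = [(n0, ca0, c0)]
    for i in range(1, n_residues):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = _nerf(n_prev, ca_prev, c_prev, _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        ca_i = _nerf(ca_prev, c_prev, n_i, _BOND["N-CA"], _ANGLE["C-N-CA"], OMEGA)
        c_i = _nerf(c_prev, n_i, ca_i, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        backbone.append((n_i, ca_i, c_i))

    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        o_i = _nerf(n_i, ca_i, c_i, _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0)
        cb_i = _nerf(c_i, n_i, ca_i, _BOND["CA-CB"], _ANGLE["N-CA-CB"], _CB_TORSION)
        for name, pos in (("N", n_i), ("CA", ca_i), ("C", c_i), ("O", o_i), ("CB", cb_i)):
            coords.append(pos)
            names.append(name)
    return np.array(coords), names


def _assemble(coords: np.ndarray, names: list[str], chain_id: str,
              serial0: int = 1, b: float = DEFAULT_B) -> list[Atom]:
    atoms = []
    for k, (pos, name) in enumerate(zip(coords, names)):
        atoms.append(
            Atom(
                serial=serial0 + k,
                name=name,
                element=name[0],
                residue_index=k // 5,
                residue_name="ALA",
                chain_id=chain_id,
                position=pos,
                b_factor=b,
                occupancy=1.0,
                auth_resseq=k // 5 + 1,
            )
        )
    return atoms


def _align_principal_to_z(coords: np.ndarray) -> np.ndarray:
    """Proper rotation taking the principal extent onto the z axis (keeps the
    padded box snug)."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    rot = np.array([vt[1], np.cross(vt[0], vt[1]), vt[0]])  # rows: new x, y, z
    if np.linalg.det(rot) < 0:
        rot[1] = -rot[1]
    return centered @ rot.T


def make_helix(n_residues: int, chain_id: str = "A") -> Structure:
    """Ideal poly-alanine α-helix (φ=−57°, ψ=−47°), heavy atoms only, axis
    along z, centered in a padded orthogonal P1 box, uniform B = 20 Å²."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    coords, names = _build_polyala(n_residues)
    coords = _align_principal_to_z(coords)
    atoms = _assemble(coords, names, chain_id)
    structure = Structure(atoms, default_box(coords, BOX_PADDING))
    center_in_cell(structure)
    return structure


def make_bundle(n_chains: int, n_residues: int, spacing: float = 10.0) -> Structure:
    """Parallel copies of an ideal helix on a circle with the given
    nearest-neighbour spacing; distinct chain identifiers."""
    if n_chains < 2:
        raise ValueError("need at least 2 chains")
    if spacing < 4.0:
        raise ValueError("spacing below 4 Å would clash the helices")
    coords, names = _build_polyala(n_residues)
    # helix axis: principal direction; positions offset perpendicular to it
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    perp1 = vt[1]
    perp2 = np.cross(axis, perp1)
    radius = spacing / (2.0 * math.sin(math.pi / n_chains))
    atoms: list[Atom] = []
    for c in range(n_chains):
        ang = 2.0 * math.pi * c / n_chains
        offset = radius * (math.cos(ang) * perp1 + math.sin(ang) * perp2)
        atoms.extend(
            _assemble(centered + offset, names, chr(ord("A") + c),
                      serial0=len(atoms) + 1)
        )
    all_xyz = _align_principal_to_z(np.array([a.position for a in atoms]))
    for atom, pos in zip(atoms, all_xyz):
        atom.position = pos
    structure = Structure(atoms, default_box(all_xyz, BOX_PADDING))
    center_in_cell(structure)
    return structure


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def _rotate_about_axis(points: np.ndarray, origin: np.ndarray,
                       axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    rel = points - origin
    cosa, sina = math.cos(angle), math.sin(angle)
    return (
        origin
        + rel * cosa
        + np.cross(axis, rel) * sina
        + np.outer(rel @ axis, axis) * (1.0 - cosa)
    )


def _apply_torsion_kicks(structure: Structure, kicks: np.ndarray) -> np.ndarray:
    """Rotate φ/ψ of each residue by the given angles (radians), propagating
    each rotation down-chain.  kicks has shape (n_residues_total, 2)."""
    xyz = structure.coords.copy()
    chains = structure.chain_atom_indices()
    row = 0
    for cid, idx in chains.items():
        n_res = len(idx) // 5
        base = idx[0]
        for r in range(n_res):
            off = base + 5 * r
            n_i, ca_i, c_i = xyz[off], xyz[off + 1], xyz[off + 2]
            dphi, dpsi = kicks[row]
            row += 1
            # φ: about N–CA, moves C, O, CB of this residue and all downstream
            moving = np.concatenate([[off + 2, off + 3, off + 4],
                                     np.arange(off + 5, base + 5 * n_res)])
            xyz[moving] = _rotate_about_axis(xyz[moving], n_i, ca_i - n_i, dphi)
            # ψ: about CA–C, moves O and downstream residues
            c_i = xyz[off + 2]
            moving = np.concatenate([[off + 3],
                                     np.arange(off + 5, base + 5 * n_res)])
            xyz[moving] = _rotate_about_axis(xyz[moving], xyz[off + 1],
                                             c_i - xyz[off + 1], dpsi)
    return xyz


def reidealize(structure: Structure, reference: Structure | None = None,
               max_iter: int = 300) -> Structure:
    """Restore ideal bonded geometry by minimizing E_MM (topology and
    equilibria from ``reference``, default the ideal builder geometry)."""
    topo = build_topology(reference if reference is not None else structure)

    def objective(x):
        e, f = geom_energy_forces(x.reshape(-1, 3), topo)
        return e, -f.ravel()

    res = minimize(objective, structure.coords.ravel(), jac=True,
                   method="L-BFGS-B", options={"maxiter": max_iter})
    return structure.with_coords(res.x.reshape(-1, 3))


def rmsd_plain(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def perturb_structure(
    structure: Structure,
    target_rmsd: float,
    seed: int = 0,
    mode: str = "torsion",
    rmsd_tol: float = 0.10,
) -> Structure:
    """Perturb a structure to a prescribed coordinate RMSD (no superposition).

    torsion mode draws random φ/ψ kicks propagated down-chain;
    cartesian_smooth applies a low-frequency correlated displacement field.
    The kick amplitude is bisected until the RMSD after re-idealization
    (E_MM minimization against the input geometry) is within ``rmsd_tol`` of
    the target.  Deterministic by seed.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be non-negative")
    if mode not in ("torsion", "cartesian_smooth"):
        raise ValueError("mode must be torsion or cartesian_smooth")
    if target_rmsd == 0.0:
        return structure.copy()

    rng = np.random.default_rng(seed)
    xyz0 = structure.coords

    if mode == "torsion":
        n_res_total = sum(len(idx) // 5 for idx in structure.chain_atom_indices().values())
        unit = rng.standard_normal((n_res_total, 2))

        def displaced(scale: float) -> Structure:
            kicked = _apply_torsion_kicks(structure, scale * unit)
            return reidealize(structure.with_coords(kicked), structure)
    else:
        # a handful of long-wavelength sinusoidal modes across the extent
        span = xyz0.max(axis=0) - xyz0.min(axis=0) + 1e-9
        n_modes = 6
        dirs = rng.standard_normal((n_modes, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        waves = rng.integers(1, 3, size=(n_modes, 3)) * np.pi / span
        phases = rng.uniform(0, 2 * np.pi, n_modes)
        amps = rng.uniform(0.5, 1.0, n_modes)

        def displaced(scale: float) -> Structure:
            disp = np.zeros_like(xyz0)
            for m in range(n_modes):
                phase = xyz0 @ waves[m] + phases[m]
                disp += scale * amps[m] * np.outer(np.sin(phase), dirs[m])
            return reidealize(structure.with_coords(xyz0 + disp), structure)

    def achieved(scale: float) -> tuple[float, Structure]:
        out = displaced(scale)
        return rmsd_plain(out.coords, xyz0), out

    # bracket, then bisect the amplitude
    lo, hi = 0.0, 0.2
    r_hi, out_hi = achieved(hi)
    doubles = 0
    while r_hi < target_rmsd:
        lo, hi = hi, hi * 2.0
        r_hi, out_hi = achieved(hi)
        doubles += 1
        if doubles > 12:
            raise CalibrationError(
                f"target RMSD {target_rmsd} Å unreachable (best {r_hi:.2f} Å)"
            )
    best = out_hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        r_mid, out_mid = achieved(mid)
        if abs(r_mid - target_rmsd) <= rmsd_tol * target_rmsd:
            return out_mid
        if r_mid < target_rmsd:
            lo = mid
        else:
            hi, best = mid, out_mid
    raise CalibrationError(f"bisection failed to reach {target_rmsd} Å")


def displace_chains_rigidly(
    structure: Structure,
    rot_deg: float = 5.0,
    trans: float = 2.0,
    seed: int = 0,
) -> Structure:
    """Apply an independent rigid rotation (about the chain centroid, random
    axis) and translation (random direction, each of magnitude ``trans``) to
    every chain.  The net translation is removed so the overall centre stays
    fixed: diffraction amplitudes in P1 are invariant under a uniform
    translation, so a common-mode shift would be unrecoverable by design."""
    rng = np.random.default_rng(seed)
    xyz = structure.coords.copy()
    chains = structure.chain_atom_indices()
    shifts = []
    for cid, idx in chains.items():
        axis = rng.standard_normal(3)
        tdir = rng.standard_normal(3)
        tdir /= np.linalg.norm(tdir)
        center = xyz[idx].mean(axis=0)
        xyz[idx] = _rotate_about_axis(xyz[idx], center, axis, math.radians(rot_deg))
        shifts.append(trans * tdir)
    shifts = np.array(shifts)
    weights = np.array([len(idx) for idx in chains.values()], dtype=float)
    shifts -= (weights[:, None] * shifts).sum(axis=0) / weights.sum()
    for (cid, idx), shift in zip(chains.items(), shifts):
        xyz[idx] += shift
    return structure.with_coords(xyz)


def shift_register(structure: Structure, window_start: int, window_len: int = 6) -> Structure:
    """Introduce a register-shift error: residues in the window take the
    coordinates of their +1 neighbour (sequence threaded one step off along
    the same backbone path), then bonded geometry is re-idealized."""
    xyz = structure.coords.copy()
    for r in range(window_start, window_start + window_len):
        src = (r + 1) * 5
        dst = r * 5
        xyz[dst : dst + 5] = structure.coords[src : src + 5]
    return reidealize(structure.with_coords(xyz), structure)


# ---------------------------------------------------------------------------
# Synthetic observations and benchmark scenarios
# ---------------------------------------------------------------------------

def make_observations(
    truth: Structure,
    d_min: float,
    noise_frac: float = 0.0,
    test_fraction: float = 0.10,
    seed: int = 0,
) -> ReflectionSet:
    """Observed amplitudes |F_calc(truth)|·(1+ε), ε ~ N(0, noise_frac),
    clipped at zero, with seeded free-set flags."""
    if noise_frac < 0:
        raise ValueError("noise_frac must be non-negative")
    from .xray import generate_hkl

    ss = np.random.SeedSequence(seed)
    s_noise, s_free = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2)]
    refl = generate_hkl(truth.unit_cell, d_min)
    f_true = np.abs(calc_structure_factors(truth, refl))
    rng = np.random.default_rng(s_noise)
    eps = rng.normal(0.0, noise_frac, len(refl)) if noise_frac > 0 else np.zeros(len(refl))
    refl.f_obs = np.clip(f_true * (1.0 + eps), 0.0, None)
    refl.sigma = noise_frac * f_true
    return assign_test_set(refl, test_fraction, s_free)


@dataclass
class ScenarioSpec:
    name: str
    truth: Structure
    start: Structure
    reference: Structure
    refl: ReflectionSet
    selection: SelectionConfig
    provenance: dict = field(default_factory=dict)


_PRESETS = ("lowres_helix", "verylow_bundle", "register_shift")


def make_benchmark_scenario(preset: str, seed: int = 0) -> ScenarioSpec:
    """Reproducible end-to-end scenarios.

    lowres_helix — 20-residue helix, start perturbed to 2.5 Å, data to 3.5 Å.
    verylow_bundle — 3×12-residue bundle; chains rigidly displaced (5°, 2 Å)
        then torsion-perturbed to a total of 4 Å; data to 7.4 Å; inter-chain
        restraints enabled with no sequence-separation limit.
    register_shift — 20-residue helix with a one-residue register error over
        a 6-residue window; the reference model is the ideal helix.
    """
    ss = np.random.SeedSequence(seed)
    s_perturb, s_obs, s_rigid = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]

    if preset == "lowres_helix":
        truth = make_helix(20)
        start = perturb_structure(truth, 2.5, seed=s_perturb, mode="torsion")
        refl = make_observations(truth, d_min=3.5, noise_frac=0.02, seed=s_obs)
        selection = SelectionConfig()
        prov = {"target_start_rmsd": 2.5, "d_min": 3.5, "noise_frac": 0.02}
        reference = start.copy()
    elif preset == "verylow_bundle":
        truth = make_bundle(3, 12, spacing=10.0)
        displaced = displace_chains_rigidly(truth, 5.0, 2.0, seed=s_rigid)
        # torsion noise on top of the rigid displacement, sized so the total
        # deviation from the truth is 4 Å
        r_rigid = rmsd_plain(displaced.coords, truth.coords)
        torsion_target = math.sqrt(max(4.0**2 - r_rigid**2, 1.0))
        start = perturb_structure(displaced, torsion_target, seed=s_perturb,
                                  mode="torsion", rmsd_tol=0.15)
        refl = make_observations(truth, d_min=7.4, noise_frac=0.02, seed=s_obs)
        selection = SelectionConfig(allow_inter_chain=True, seq_sep_hi=None)
        prov = {"rigid_rot_deg": 5.0, "rigid_trans": 2.0, "target_rmsd": 4.0,
                "d_min": 7.4, "noise_frac": 0.02}
        reference = start.copy()
    elif preset == "register_shift":
        truth = make_helix(20)
        start = shift_register(truth, window_start=7, window_len=6)
        refl = make_observations(truth, d_min=3.5, noise_frac=0.02, seed=s_obs)
        selection = SelectionConfig()
        prov = {"window_start": 7, "window_len": 6, "d_min": 3.5, "noise_frac": 0.02}
        reference = truth.copy()  # an ideal model is available as reference
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {_PRESETS}")

    prov.update({"preset": preset, "seed": int(seed)})
    return ScenarioSpec(
        name=preset, truth=truth, start=start, reference=reference,
        refl=refl, selection=selection, provenance=prov,
    )
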