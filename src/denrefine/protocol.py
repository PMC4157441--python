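"""Refinement protocol orchestration.

A refinement is a chain of macrocycles, each consisting of automatic X-ray
weighting, one slow-cooling annealing pass with DEN restraints, a short
positional minimization, and optional grouped/individual B-factor
refinement.  The default protocol uses nondeformable (γ=0) restraints in the
first macrocycle and can switch the restraints off (w_DEN=0) in the last two
macrocycles to probe whether the model has converged to a stable minimum of
the target; the drift (RMSD between the model before and after the released
macrocycles) is reported.

Segmented rigid-body refinement is available as a pre-refinement step for
very low resolution problems: the model is split into segments (one per
chain by default) that move as 6-DOF rigid bodies against the work-set
amplitude residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .den import DENNetwork, SelectionConfig, check_correspondence, den_energy_forces, select_restraints
from .dynamics import AnnealingSchedule, DynamicsState, assign_velocities, run_slow_cooling
from .forcefield import Topology, build_topology, geom_energy_forces, geometry_score
from .structures import Structure
from .xray import (
    ReflectionSet,
    StructureFactorEngine,
    ls_scale,
    r_factors,
    xray_energy_bgrad,
    xray_energy_forces,
)


@dataclass
class RefinementConfig:
    gamma: float = 0.0
    w_den: float = 100.0
    w_xray: float | str = "auto"
    kappa: float = 0.1
    n_macrocycles: int = 8
    first_cycle_gamma_zero: bool = True
    release_last_two: bool = True
    schedule: AnnealingSchedule = field(
        default_factory=lambda: AnnealingSchedule(timestep=1.0)
    )
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    bfactor_mode: str = "grouped"   # none | grouped | individual
    seed: int = 0
    min_steps: int = 200            # post-annealing gradient-descent steps
    update_before_dynamics: bool = False
    atom_mask: np.ndarray | None = None  # partial reference model support

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if self.w_den < 0:
            raise ValueError("w_den must be non-negative")
        if self.n_macrocycles < 1:
            raise ValueError("need at least one macrocycle")
        if self.release_last_two and self.n_macrocycles < 3:
            raise ValueError("release_last_two requires n_macrocycles >= 3")
        if self.bfactor_mode not in ("none", "grouped", "individual"):
            raise ValueError("bfactor_mode must be none|grouped|individual")


@dataclass
class MacrocycleRecord:
    index: int
    gamma: float
    w_den: float
    w_xray: float
    r_work: float
    r_free: float
    geometry_score: float
    e_den_final: float


@dataclass
class RefinementResult:
    model: Structure
    r_work: float
    r_free: float
    geometry_score: float
    trace: list[MacrocycleRecord]
    seed: int
    network: DENNetwork
    drift_rmsd: float | None = None  # model drift across released macrocycles


def auto_weight_xray(
    structure: Structure,
    refl: ReflectionSet,
    topology: Topology,
    engine: StructureFactorEngine | None = None,
) -> float:
    """w_X-ray by gradient-norm matching: make the RMS per-atom X-ray force
    equal to the RMS per-atom stereochemical force at the current model."""
    _, f_mm = geom_energy_forces(structure.coords, topology)
    rms_mm = float(np.sqrt(np.mean(f_mm**2)))
    if rms_mm == 0.0:
        return 1.0
    _, f_x, _ = xray_energy_forces(structure, refl, 1.0, engine=engine)
    rms_x = float(np.sqrt(np.mean(f_x**2)))
    if rms_x == 0.0:
        return 1.0
    return rms_mm / rms_x


def minimize_positions(
    positions: np.ndarray,
    force_fn: Callable[[np.ndarray], tuple[float, np.ndarray]],
    n_steps: int = 200,
    step0: float = 1e-4,
) -> np.ndarray:
    """Adaptive-step steepest descent on the composite target."""
    pos = np.asarray(positions, dtype=float).copy()
    energy, forces = force_fn(pos)
    alpha = step0
    for _ in range(n_steps):
        trial = pos + alpha * forces
        e_trial, f_trial = force_fn(trial)
        if e_trial < energy:
            pos, energy, forces = trial, e_trial, f_trial
            alpha *= 1.2
        else:
            alpha *= 0.5
            if alpha < 1e-12:
                break
    return pos


# ---------------------------------------------------------------------------
# Segmented rigid-body refinement
# ---------------------------------------------------------------------------

def _apply_rigid(coords: np.ndarray, segments, params: np.ndarray) -> np.ndarray:
    out = coords.copy()
    for s, seg in enumerate(segments):
        rotvec = params[6 * s : 6 * s + 3]
        trans = params[6 * s + 3 : 6 * s + 6]
        sub = coords[seg]
        center = sub.mean(axis=0)
        out[seg] = Rotation.from_rotvec(rotvec).apply(sub - center) + center + trans
    return out


def rigid_body_refine(
    structure: Structure,
    refl: ReflectionSet,
    segments: Sequence[np.ndarray] | None = None,
    max_iter: int = 200,
) -> Structure:
    """Jointly optimize a rotation+translation per segment (quaternion-backed
    rotation vectors, 6 DOF each) against the work-set amplitude residual.
    Segment-internal geometry is preserved exactly.  On non-convergence the
    best pose found is returned with a warning attached to the result."""
    if segments is None:
        segments = list(structure.chain_atom_indices().values())
    segments = [np.asarray(s, dtype=int) for s in segments]
    if not segments:
        raise ValueError("need at least one segment")
    counts = np.zeros(len(structure), dtype=int)
    for seg in segments:
        counts[seg] += 1
    if np.any(counts != 1):
        raise ValueError("every atom must belong to exactly one segment")

    engine = StructureFactorEngine(structure, refl)
    coords0 = structure.coords
    work = refl.work_mask
    f_obs = refl.f_obs[work]
    nseg = len(segments)
    weights = np.array([len(s) for s in segments], dtype=float)
    weights /= weights.sum()

    def project(params):
        # amplitudes in P1 are blind to a common translation; remove it so
        # the optimizer cannot drift the origin
        p = params.reshape(nseg, 6).copy()
        p[:, 3:] -= (weights[:, None] * p[:, 3:]).sum(axis=0)
        return p.ravel()

    def objective(params):
        amp = np.abs(engine.f_calc(_apply_rigid(coords0, segments, project(params))))[work]
        k = ls_scale(f_obs, amp)
        return float(np.sum((f_obs - k * amp) ** 2))

    x0 = np.zeros(6 * nseg)
    res = minimize(
        objective, x0, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-12, "eps": 1e-6},
    )
    best = project(res.x) if res.fun <= objective(x0) else x0
    out = structure.with_coords(_apply_rigid(coords0, segments, best))
    if not res.success:
        out.rigid_body_warning = str(res.message)  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# B-factor refinement
# ---------------------------------------------------------------------------

_MAIN_CHAIN = {"N", "CA", "C", "O"}
B_MIN, B_MAX = 1.0, 500.0


def _bfactor_groups(structure: Structure, mode: str) -> list[np.ndarray]:
    if mode == "individual":
        return [np.array([i]) for i in range(len(structure))]
    groups: dict[tuple, list[int]] = {}
    for i, atom in enumerate(structure.atoms):
        part = "main" if atom.name in _MAIN_CHAIN else "side"
        groups.setdefault((atom.chain_id, atom.residue_index, part), []).append(i)
    return [np.array(v) for v in groups.values()]


def bfactor_refine(
    structure: Structure,
    refl: ReflectionSet,
    mode: str = "grouped",
    engine: StructureFactorEngine | None = None,
    max_iter: int = 100,
) -> Structure:
    """Refine isotropic B factors against the work-set residual with bound
    constraints B ∈ [1, 500] Å².  Grouped mode assigns one value per residue
    main-chain group ({N, CA, C, O}) and one per side-chain group.
    Coordinates are untouched."""
    if mode not in ("grouped", "individual"):
        raise ValueError("mode must be grouped or individual")
    if engine is None:
        engine = StructureFactorEngine(structure, refl)
    groups = _bfactor_groups(structure, mode)
    pos = structure.coords
    b0 = structure.b_factors
    x0 = np.array([float(np.mean(b0[g])) for g in groups])

    def expand(x):
        b = np.empty(len(structure))
        for g, val in zip(groups, x):
            b[g] = val
        return b

    def objective(x):
        e, gb = xray_energy_bgrad(engine, refl, pos, expand(x), 1.0)
        return e, np.array([float(np.sum(gb[g])) for g in groups])

    res = minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        bounds=[(B_MIN, B_MAX)] * len(groups), options={"maxiter": max_iter},
    )
    out = structure.copy()
    out.set_b_factors(expand(res.x if res.fun <= objective(x0)[0] else x0))
    return out


# ---------------------------------------------------------------------------
# The macrocycle loop
# ---------------------------------------------------------------------------

def make_target(
    topology: Topology,
    engine: StructureFactorEngine,
    refl: ReflectionSet,
    structure: Structure,
    w_xray: float,
    w_den: float,
):
    """Composite evaluator: E_target = E_MM + w_xray·E_X-ray + E_DEN."""

    def energies(positions, network):
        e_mm, f_mm = geom_energy_forces(positions, topology)
        e_x, f_x, _ = xray_energy_forces(
            structure, refl, w_xray, engine=engine, positions=positions
        )
        e_den, f_den = den_energy_forces(positions, network, w_den)
        return e_mm + e_x + e_den, f_mm + f_x + f_den, {
            "e_mm": e_mm, "e_xray": e_x, "e_den": e_den,
        }

    return energies


def run_den_refinement(
    start: Structure,
    reference: Structure,
    refl: ReflectionSet,
    config: RefinementConfig,
) -> RefinementResult:
    """DEN-restrained simulated-annealing refinement.

    The restraint pair list is selected once (eligibility on the reference
    model, initial equilibria from the starting model) and never changes;
    only the equilibrium distances deform.  Fully deterministic given
    ``config.seed``.
    """
    check_correspondence(start, reference)
    topology = build_topology(start)
    engine = StructureFactorEngine(start, refl)

    ss = np.random.SeedSequence(config.seed)
    seed_selection, *seed_mc = [
        int(s.generate_state(1)[0] % 2**31)
        for s in ss.spawn(1 + config.n_macrocycles)
    ]
    network = select_restraints(
        start, reference, config.selection, seed_selection, atom_mask=config.atom_mask
    )
    n_restraints = len(network)

    model = start.copy()
    masses = start.masses
    trace: list[MacrocycleRecord] = []
    snapshots: list[np.ndarray] = []

    for mc in range(config.n_macrocycles):
        gamma = 0.0 if (mc == 0 and config.first_cycle_gamma_zero) else config.gamma
        released = config.release_last_two and mc >= config.n_macrocycles - 2
        w_den = 0.0 if released else config.w_den

        if config.w_xray == "auto":
            w_xray = auto_weight_xray(model, refl, topology, engine=engine)
        else:
            w_xray = float(config.w_xray)

        energies = make_target(topology, engine, refl, model, w_xray, w_den)
        state = DynamicsState(model.coords, np.zeros_like(model.coords), masses)
        state = assign_velocities(state, config.schedule.t_start, seed_mc[mc])
        state, network, _ = run_slow_cooling(
            state, config.schedule, network, energies,
            gamma=gamma, kappa=config.kappa,
            update_before_dynamics=config.update_before_dynamics,
        )
        assert len(network) == n_restraints  # pair list is immutable

        def force_fn(pos, _energies=energies, _net=network):
            e, f, _ = _energies(pos, _net)
            return e, f

        pos = minimize_positions(state.positions, force_fn, config.min_steps)
        model.set_coords(pos)

        if config.bfactor_mode != "none":
            model = bfactor_refine(model, refl, config.bfactor_mode, engine=engine)
            engine.set_b_factors(model.b_factors)

        f_calc = engine.f_calc(model.coords)
        r_work, r_free = r_factors(refl, f_calc)
        e_den_final, _ = den_energy_forces(model.coords, network, w_den)
        trace.append(
            MacrocycleRecord(
                index=mc, gamma=gamma, w_den=w_den, w_xray=w_xray,
                r_work=r_work, r_free=r_free,
                geometry_score=geometry_score(model.coords, topology),
                e_den_final=e_den_final,
            )
        )
        snapshots.append(model.coords)

    drift = None
    if config.release_last_two and len(snapshots) >= 3:
        d = snapshots[-1] - snapshots[-3]
        drift = float(np.sqrt(np.mean(np.sum(d**2, axis=1))))

    last = trace[-1]
    return RefinementResult(
        model=model,
        r_work=last.r_work,
        r_free=last.r_free,
        geometry_score=last.geometry_score,
        trace=trace,
        seed=config.seed,
        network=network,
        drift_rmsd=drift,
    )
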