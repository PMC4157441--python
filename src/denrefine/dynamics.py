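"""Slow-cooling simulated-annealing molecular dynamics.

Cartesian velocity-Verlet integration with per-level velocity rescaling to
the target temperature.  The temperature ladder descends from t_start in
dt_temp decrements down to (but excluding) t_end; at each level
steps_per_level integration steps are run and then the DEN equilibrium
distances are deformed exactly once.  The default ladder (3000 K → 0 K in
50 K decrements, six 4 fs steps per level) comprises 60 levels and 1.44 ps
of simulated time.

Note the integrator is Cartesian, not torsion-angle: bond and angle terms
are explicit stiff springs, so refinement configurations default to a 1 fs
timestep while the schedule object itself retains the classic constants.

Units: Å, fs, amu, kcal·mol⁻¹, K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .den import DENNetwork, update_equilibrium

KB = 0.0019872041          # kcal mol⁻¹ K⁻¹
ACCEL = 4.184e-4           # (kcal mol⁻¹ Å⁻¹ / amu) → Å fs⁻²
KE_UNIT = 1.0 / (2.0 * ACCEL)  # ½ m v² in kcal/mol given amu, Å/fs


class InstabilityError(RuntimeError):
    def __init__(self, level: int, temperature: float):
        super().__init__(
            f"non-finite energy during annealing at level {level} (T={temperature} K)"
        )
        self.level = level


@dataclass(frozen=True)
class AnnealingSchedule:
    t_start: float = 3000.0   # K
    t_end: float = 0.0        # K
    dt_temp: float = 50.0     # K per decrement
    steps_per_level: int = 6
    timestep: float = 4.0     # fs

    def __post_init__(self):
        if not (self.t_start > self.t_end >= 0):
            raise ValueError("require t_start > t_end >= 0")
        if self.dt_temp <= 0:
            raise ValueError("dt_temp must be positive")

    @property
    def temperatures(self) -> np.ndarray:
        """Ladder T = t_start, t_start − dt_temp, …, down to but excluding t_end."""
        return np.arange(self.t_start, self.t_end, -self.dt_temp)

    @property
    def n_levels(self) -> int:
        return len(self.temperatures)

    @property
    def total_time_fs(self) -> float:
        return self.n_levels * self.steps_per_level * self.timestep


@dataclass
class DynamicsState:
    positions: np.ndarray   # (n, 3) Å
    velocities: np.ndarray  # (n, 3) Å/fs
    masses: np.ndarray      # (n,) amu
    rng_seed: int = 0

    def copy(self) -> "DynamicsState":
        return DynamicsState(
            self.positions.copy(), self.velocities.copy(), self.masses.copy(),
            self.rng_seed,
        )

    @property
    def kinetic_energy(self) -> float:
        return KE_UNIT * float(np.sum(self.masses[:, None] * self.velocities**2))

    @property
    def temperature(self) -> float:
        dof = max(3 * len(self.masses) - 3, 1)
        return 2.0 * self.kinetic_energy / (dof * KB)


def assign_velocities(state: DynamicsState, temperature: float, seed: int) -> DynamicsState:
    """Maxwell–Boltzmann velocities at the given temperature with the
    center-of-mass momentum removed; deterministic by seed."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    out = state.copy()
    out.rng_seed = int(seed)
    if temperature == 0.0:
        out.velocities = np.zeros_like(state.positions)
        return out
    rng = np.random.default_rng(seed)
    std = np.sqrt(KB * temperature * ACCEL / state.masses)
    v = rng.standard_normal(state.positions.shape) * std[:, None]
    # remove net momentum
    p = np.sum(state.masses[:, None] * v, axis=0)
    v -= p[None, :] / np.sum(state.masses)
    out.velocities = v
    return out


def _rescale_to(state: DynamicsState, temperature: float) -> None:
    current = state.temperature
    if temperature == 0.0:
        state.velocities[:] = 0.0
    elif current > 0:
        state.velocities *= np.sqrt(temperature / current)


def integrate_nve(
    state: DynamicsState,
    force_fn: Callable[[np.ndarray], tuple[float, np.ndarray]],
    n_steps: int,
    dt: float,
) -> tuple[DynamicsState, float, np.ndarray]:
    """Velocity-Verlet for n_steps; returns (state, last energy, last forces)."""
    pos = state.positions
    vel = state.velocities
    inv_m = (ACCEL / state.masses)[:, None]
    energy, forces = force_fn(pos)
    for _ in range(n_steps):
        vel = vel + 0.5 * dt * forces * inv_m
        pos = pos + dt * vel
        energy, forces = force_fn(pos)
        vel = vel + 0.5 * dt * forces * inv_m
    out = state.copy()
    out.positions = pos
    out.velocities = vel
    return out, energy, forces


@dataclass
class LevelRecord:
    level: int
    temperature: float
    e_total: float
    e_den: float
    e_xray: float
    e_mm: float
    temperature_inst: float


def run_slow_cooling(
    state: DynamicsState,
    schedule: AnnealingSchedule,
    network: DENNetwork,
    energies: Callable[[np.ndarray, DENNetwork], tuple[float, np.ndarray, dict]],
    gamma: float,
    kappa: float = 0.1,
    update_before_dynamics: bool = False,
) -> tuple[DynamicsState, DENNetwork, list[LevelRecord]]:
    """One slow-cooling annealing pass with per-level DEN deformation.

    ``energies(positions, network)`` must return (total energy, total forces,
    component dict with keys e_den/e_xray/e_mm).  At each level the velocities
    are rescaled to the level temperature, steps_per_level velocity-Verlet
    steps are integrated, and the DEN equilibria are updated exactly once
    (after the level's dynamics by default; the alternative order is
    config-flippable).
    """
    state = state.copy()
    network = network.copy()
    trace: list[LevelRecord] = []
    for lvl, T in enumerate(schedule.temperatures):
        if update_before_dynamics:
            network = update_equilibrium(network, state.positions, gamma, kappa)
        _rescale_to(state, T)
        net = network  # bind for the closure below

        def force_fn(pos):
            e, f, _ = energies(pos, net)
            return e, f

        state, e_tot, _ = integrate_nve(state, force_fn, schedule.steps_per_level, schedule.timestep)
        if not update_before_dynamics:
            network = update_equilibrium(network, state.positions, gamma, kappa)
        e_tot, _, comps = energies(state.positions, network)
        if not np.isfinite(e_tot):
            raise InstabilityError(lvl, float(T))
        trace.append(
            LevelRecord(
                level=lvl,
                temperature=float(T),
                e_total=e_tot,
                e_den=comps.get("e_den", 0.0),
                e_xray=comps.get("e_xray", 0.0),
                e_mm=comps.get("e_mm", 0.0),
                temperature_inst=state.temperature,
            )
        )
    return state, network, trace


def trace_to_csv(trace: list[LevelRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "level": r.level,
                "T": r.temperature,
                "E_total": r.e_total,
                "E_den": r.e_den,
                "E_xray": r.e_xray,
                "E_mm": r.e_mm,
            }
            for r in trace
        ]
    ).to_csv(path, index=False)
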