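"""Reciprocal-space target: reflections, structure factors, R factors.

Space group is fixed to P1 with a single model per cell; no bulk solvent or
anisotropic scaling — a single overall linear scale k relates |F_calc| to
F_obs, fitted by least squares over the *working* reflections only.  The
amplitude least-squares target is

    E_X-ray = w_X-ray · Σ_work ( F_obs − k·|F_calc| )²

Test-set reflections never contribute to the energy or the forces; they are
reserved for R_free cross-validation.  Structure factors are computed by
direct summation,

    F(h) = Σ_atoms occ · f_elem(s) · exp(−B s²/4) · exp(2πi h·x_frac)

with s = 1/d(h) and the one-Gaussian-plus-constant form factors of
:mod:`denrefine.elements`.  The Friedel-unique hemisphere is chosen by the
rule "first nonzero index of (h, k, l) is positive".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .elements import element_data
from .structures import Structure, UnitCell


class ReflectionError(ValueError):
    pass


@dataclass
class ReflectionSet:
    cell: UnitCell
    hkl: np.ndarray                  # (N, 3) int, Friedel-unique, no (0,0,0)
    d_min: float
    f_obs: np.ndarray | None = None  # (N,) non-negative amplitudes
    sigma: np.ndarray | None = None
    is_test: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def n_test(self) -> int:
        return 0 if self.is_test is None else int(np.sum(self.is_test))

    @property
    def work_mask(self) -> np.ndarray:
        if self.is_test is None:
            return np.ones(len(self), dtype=bool)
        return ~self.is_test

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            replace(self.cell),
            self.hkl.copy(),
            self.d_min,
            None if self.f_obs is None else self.f_obs.copy(),
            None if self.sigma is None else self.sigma.copy(),
            None if self.is_test is None else self.is_test.copy(),
        )


def generate_hkl(cell: UnitCell, d_min: float) -> ReflectionSet:
    """All Friedel-unique P1 Miller indices with d(hkl) ≥ d_min.

    The unique hemisphere keeps (h,k,l) whose first nonzero component is
    positive; (0,0,0) is excluded.
    """
    if d_min <= 0:
        raise ReflectionError("d_min must be positive")
    # conservative per-index bounds, then exact resolution filter
    hmax = int(np.ceil(cell.a / d_min)) + 1
    kmax = int(np.ceil(cell.b / d_min)) + 1
    lmax = int(np.ceil(cell.c / d_min)) + 1
    h = np.arange(-hmax, hmax + 1)
    k = np.arange(-kmax, kmax + 1)
    l = np.arange(-lmax, lmax + 1)
    grid = np.stack(np.meshgrid(h, k, l, indexing="ij"), axis=-1).reshape(-1, 3)
    # hemisphere rule: first nonzero of (h, k, l) positive
    hh, kk, ll = grid[:, 0], grid[:, 1], grid[:, 2]
    hemi = (hh > 0) | ((hh == 0) & (kk > 0)) | ((hh == 0) & (kk == 0) & (ll > 0))
    grid = grid[hemi]
    inv_d2 = cell.inv_d2(grid)
    grid = grid[inv_d2 <= 1.0 / d_min**2 + 1e-12]
    if len(grid) == 0:
        raise ReflectionError(f"no reflections at d_min={d_min} for this cell")
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0]))
    return ReflectionSet(cell, grid[order].astype(int), float(d_min))


def assign_test_set(refl: ReflectionSet, fraction: float = 0.10, seed: int = 0) -> ReflectionSet:
    """Uniformly random free-set flags, deterministic by seed; ensures at
    least one test and one work reflection."""
    if not (0.0 < fraction < 0.5):
        raise ValueError("test fraction must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    flags = rng.random(len(refl)) < fraction
    if not flags.any():
        flags[rng.integers(len(refl))] = True
    if flags.all():
        flags[rng.integers(len(refl))] = False
    out = refl.copy()
    out.is_test = flags
    return out


class StructureFactorEngine:
    """Direct-summation structure factors with cached per-reflection terms.

    The per-atom scattering prefactor occ·f_elem(s)·exp(−B s²/4) is cached and
    only recomputed when B factors change; the phase matrix is recomputed at
    every coordinate set.
    """

    def __init__(self, structure: Structure, refl: ReflectionSet):
        self.cell = refl.cell
        self.hkl = refl.hkl
        self.s2 = refl.cell.inv_d2(refl.hkl)            # (N_r,)
        self._frac = refl.cell.frac_matrix()
        # phase(h, x) = 2π h·(F x) = (2π Fᵀ h)·x
        self.q = 2.0 * np.pi * (self.hkl @ self._frac)  # (N_r, 3)
        # per-dimension phase-factor recursion setup: the phase separates as
        # 2π(h·u) with u fractional, so exp(i·phase) is a product of three
        # per-index tables exp(2πi m u_d) built by recursion with only
        # 3·N_atoms trig calls
        self._hmax = np.abs(self.hkl).max(axis=0)
        self._hidx = tuple(self.hkl[:, d] + self._hmax[d] for d in range(3))
        self.occ = np.array([a.occupancy for a in structure.atoms])
        self.elements = list(structure.elements)
        self._f_elem = np.column_stack(
            [
                element_data(e).ff_a * np.exp(-element_data(e).ff_b * self.s2)
                + element_data(e).ff_c
                for e in self.elements
            ]
        )                                               # (N_r, N_atoms)
        self._b = None
        self._pref = None
        self.set_b_factors(structure.b_factors)

    def set_b_factors(self, b: np.ndarray) -> None:
        b = np.asarray(b, dtype=float)
        if self._b is not None and np.array_equal(b, self._b):
            return
        self._b = b.copy()
        debye = np.exp(-0.25 * np.outer(self.s2, b))
        self._pref = self._f_elem * debye * self.occ[None, :]

    def contributions(self, positions: np.ndarray) -> np.ndarray:
        """Per-atom complex contributions C_ra; F = C.sum(axis=1)."""
        u = np.asarray(positions, dtype=float) @ self._frac.T  # fractional (N_a, 3)
        out = self._pref.astype(complex)
        for d in range(3):
            hmax = int(self._hmax[d])
            base = np.exp(2j * np.pi * u[:, d])         # (N_a,)
            table = np.empty((2 * hmax + 1, len(u)), dtype=complex)
            table[hmax] = 1.0
            for m in range(1, hmax + 1):
                table[hmax + m] = table[hmax + m - 1] * base
                table[hmax - m] = np.conj(table[hmax + m])
            out *= table[self._hidx[d]]
        return out

    def f_calc(self, positions: np.ndarray) -> np.ndarray:
        return self.contributions(positions).sum(axis=1)


def calc_structure_factors(structure: Structure, refl: ReflectionSet) -> np.ndarray:
    """Complex structure factors of the model for every reflection."""
    return StructureFactorEngine(structure, refl).f_calc(structure.coords)


def ls_scale(f_obs: np.ndarray, f_calc_amp: np.ndarray) -> float:
    """Closed-form least-squares scale k minimizing Σ(F_obs − k|F_calc|)²."""
    denom = float(np.sum(f_calc_amp**2))
    if denom == 0.0:
        raise ZeroDivisionError("all calculated amplitudes vanish")
    return float(np.sum(f_obs * f_calc_amp)) / denom


def xray_energy_forces(
    structure: Structure,
    refl: ReflectionSet,
    w_xray: float = 1.0,
    use_work_only: bool = True,
    engine: StructureFactorEngine | None = None,
    positions: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float]:
    """Amplitude least-squares energy, analytic forces, and the fitted scale.

    The scale k is fitted over work reflections; because k is at its
    least-squares optimum its coordinate dependence does not contribute to
    the gradient.  Test reflections contribute to neither energy nor forces.
    """
    if refl.f_obs is None:
        raise ReflectionError("reflection set carries no observed amplitudes")
    if float(np.max(refl.f_obs)) == 0.0:
        raise ReflectionError("all-zero observed amplitudes cannot be scaled")
    if engine is None:
        engine = StructureFactorEngine(structure, refl)
    pos = structure.coords if positions is None else np.asarray(positions, dtype=float)

    C = engine.contributions(pos)
    F = C.sum(axis=1)
    amp = np.abs(F)
    mask = refl.work_mask if use_work_only else np.ones(len(refl), dtype=bool)
    k = ls_scale(refl.f_obs[mask], amp[mask])
    resid = refl.f_obs[mask] - k * amp[mask]
    energy = w_xray * float(np.sum(resid**2))

    # dE/d|F_r| = −2 w k resid (work only); d|F|/dx_a = −Im(conj(F)·C_ra)/|F| · q_r
    dEdA = np.zeros(len(refl))
    dEdA[mask] = -2.0 * w_xray * k * resid
    safe_amp = np.maximum(amp, 1e-30)
    W = (dEdA / safe_amp)[:, None] * np.imag(np.conj(F)[:, None] * C)
    forces = W.T @ engine.q  # grad_a = −Σ_r W_ra q_r, force = −grad
    return energy, forces, k


def r_factors(
    refl: ReflectionSet, f_calc: np.ndarray
) -> tuple[float, float]:
    """R = Σ|F_obs − k|F_calc|| / ΣF_obs over work and test subsets, with the
    scale k fitted on work reflections only."""
    if refl.f_obs is None:
        raise ReflectionError("reflection set carries no observed amplitudes")
    if refl.is_test is None or refl.n_test == 0:
        raise ReflectionError("R_free undefined: empty test set")
    work = refl.work_mask
    if not work.any():
        raise ReflectionError("empty work set")
    amp = np.abs(np.asarray(f_calc))
    k = ls_scale(refl.f_obs[work], amp[work])

    def _r(mask):
        return float(
            np.sum(np.abs(refl.f_obs[mask] - k * amp[mask])) / np.sum(refl.f_obs[mask])
        )

    return _r(work), _r(~work)


def xray_energy_bgrad(
    engine: StructureFactorEngine,
    refl: ReflectionSet,
    positions: np.ndarray,
    b: np.ndarray,
    w_xray: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Work-set amplitude residual and its analytic gradient w.r.t. per-atom
    B factors (chain rule through the Debye–Waller damping)."""
    engine.set_b_factors(b)
    C = engine.contributions(positions)
    F = C.sum(axis=1)
    amp = np.abs(F)
    mask = refl.work_mask
    k = ls_scale(refl.f_obs[mask], amp[mask])
    resid = refl.f_obs[mask] - k * amp[mask]
    energy = w_xray * float(np.sum(resid**2))
    dEdA = np.zeros(len(refl))
    dEdA[mask] = -2.0 * w_xray * k * resid
    safe_amp = np.maximum(amp, 1e-30)
    # d|F_r|/dB_a = Re(conj(F̂_r)·C_ra)·(−s²_r/4)
    W = (dEdA / safe_amp)[:, None] * np.real(np.conj(F)[:, None] * C)
    grad = -(W * (0.25 * engine.s2)[:, None]).sum(axis=0)
    return energy, grad


# ---------------------------------------------------------------------------
# Reflection file: whitespace-separated H K L FOBS SIGMA FREE with a
# '#'-comment header carrying the cell, d_min and hemisphere rule.
# ---------------------------------------------------------------------------

def write_reflections(refl: ReflectionSet, path, provenance: dict | None = None) -> None:
    cell = refl.cell
    with open(path, "w") as fh:
        fh.write(
            "# cell %.17g %.17g %.17g %.17g %.17g %.17g\n"
            % (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
        )
        fh.write("# d_min %.17g\n" % refl.d_min)
        fh.write("# hemisphere first-nonzero-of-(h,k,l)-positive\n")
        if provenance:
            for key, val in provenance.items():
                fh.write(f"# {key} {val}\n")
        fh.write("# columns H K L FOBS SIGMA FREE\n")
        f_obs = refl.f_obs if refl.f_obs is not None else np.zeros(len(refl))
        sigma = refl.sigma if refl.sigma is not None else np.zeros(len(refl))
        test = refl.is_test if refl.is_test is not None else np.zeros(len(refl), bool)
        for (h, k, l), fo, sg, fl in zip(refl.hkl, f_obs, sigma, test):
            fh.write(f"{h} {k} {l} {fo:.17g} {sg:.17g} {int(fl)}\n")


def read_reflections(path) -> ReflectionSet:
    cell = None
    d_min = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "cell":
                    cell = UnitCell(*(float(x) for x in parts[1:7]))
                elif parts and parts[0] == "d_min":
                    d_min = float(parts[1])
                continue
            rows.append(line.split())
    if cell is None or d_min is None or not rows:
        raise ReflectionError(f"{path}: missing header or data")
    arr = np.array(rows)
    return ReflectionSet(
        cell,
        arr[:, :3].astype(int),
        d_min,
        f_obs=arr[:, 3].astype(float),
        sigma=arr[:, 4].astype(float),
        is_test=arr[:, 5].astype(int).astype(bool),
    )
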