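"""(γ, w_DEN) grid search with repeats and R_free-based model selection.

Every grid cell is refined ``repeats`` times with independent seeds — each
repeat re-selects the restraint pairs and re-draws the initial velocities.
The winning model is the one with the lowest R_free, except that R_free
differences smaller than twice the estimated standard deviation 1/√N_test
are not considered significant: all records within that band compete on
geometry (lower geometry score wins).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocol import RefinementConfig, RefinementResult, run_den_refinement
from .structures import Structure
from .validate import compare
from .xray import ReflectionSet


@dataclass(frozen=True)
class GridSpec:
    gammas: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    w_dens: tuple = (3.0, 10.0, 30.0, 100.0, 300.0)
    repeats: int = 5          # recommended range 5–20
    base_seed: int = 0

    def __post_init__(self):
        if any(not (0.0 <= g <= 1.0) for g in self.gammas):
            raise ValueError("gammas must lie in [0, 1]")
        if any(w <= 0 for w in self.w_dens):
            raise ValueError("w_dens must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @classmethod
    def line_search(cls, w_den: float = 100.0, gammas=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                    repeats: int = 5, base_seed: int = 0) -> "GridSpec":
        """Line-search mode: vary γ at a fixed w_DEN."""
        return cls(gammas=tuple(gammas), w_dens=(w_den,), repeats=repeats,
                   base_seed=base_seed)


def cell_seed(base_seed: int, gamma_idx: int, w_idx: int, repeat: int) -> int:
    """Deterministic per-record seed: numpy SeedSequence with the grid
    coordinates as the spawn key, reduced below 2³¹ (the documented stable
    hash)."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(gamma_idx, w_idx, repeat))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class GridRecord:
    gamma: float
    w_den: float
    repeat: int
    seed: int
    r_work: float = np.nan
    r_free: float = np.nan
    geometry_score: float = np.nan
    rmsd_to_truth: float | None = None
    error: str | None = None
    result: RefinementResult | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class GridSearchResult:
    records: list[GridRecord]
    n_test: int
    grid: GridSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gamma": r.gamma, "w_den": r.w_den, "repeat": r.repeat,
                    "seed": r.seed, "r_work": r.r_work, "r_free": r.r_free,
                    "geometry_score": r.geometry_score,
                    "rmsd_to_truth": r.rmsd_to_truth, "error": r.error,
                }
                for r in self.records
            ]
        )

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.to_frame().to_dict(orient="records"):
                fh.write(json.dumps(row, default=str) + "\n")


def run_grid(
    start: Structure,
    reference: Structure,
    refl: ReflectionSet,
    base_config: RefinementConfig,
    grid: GridSpec,
    truth: Structure | None = None,
    keep_models: bool = False,
) -> GridSearchResult:
    """Independent trial refinements for every (γ, w_DEN) cell × repeat.

    Records are independent of execution order (embarrassingly parallel
    contract); a failing cell is recorded, not fatal.
    """
    records = []
    for gi, gamma in enumerate(grid.gammas):
        for wi, w_den in enumerate(grid.w_dens):
            for rep in range(grid.repeats):
                seed = cell_seed(grid.base_seed, gi, wi, rep)
                rec = GridRecord(gamma=gamma, w_den=w_den, repeat=rep, seed=seed)
                try:
                    config = replace(base_config, gamma=gamma, w_den=w_den, seed=seed)
                    result = run_den_refinement(start, reference, refl, config)
                    rec.r_work = result.r_work
                    rec.r_free = result.r_free
                    rec.geometry_score = result.geometry_score
                    if truth is not None:
                        rec.rmsd_to_truth = compare(
                            result.model, truth, superpose=False
                        ).rmsd_all
                    if keep_models:
                        rec.result = result
                except Exception as exc:  # recorded, not fatal
                    rec.error = f"{type(exc).__name__}: {exc}"
                records.append(rec)
    return GridSearchResult(records=records, n_test=refl.n_test, grid=grid)


@dataclass
class SelectionReport:
    selected: GridRecord
    candidates: list[GridRecord]
    threshold: float            # 2/√N_test
    min_r_free: float


def select_best(result: GridSearchResult) -> SelectionReport:
    """Pick the best record: lowest R_free, with records inside the
    2/√N_test significance band competing on geometry."""
    ok = [r for r in result.records if r.ok]
    if not ok:
        raise RuntimeError("no successful grid records to select from")
    if result.n_test < 1:
        raise RuntimeError("selection requires a non-empty test set")
    threshold = 2.0 / np.sqrt(result.n_test)
    min_r_free = min(r.r_free for r in ok)
    candidates = [r for r in ok if r.r_free <= min_r_free + threshold]
    selected = min(candidates, key=lambda r: (r.geometry_score, r.r_free))
    return SelectionReport(
        selected=selected, candidates=candidates,
        threshold=float(threshold), min_r_free=float(min_r_free),
    )


def export_contours(result: GridSearchResult, path) -> pd.DataFrame:
    """Per-cell mean/min R_free (and mean RMSD-to-truth when known) as CSV,
    suitable for contour plotting."""
    frame = result.to_frame()
    ok = frame[frame["error"].isna()]
    rows = []
    for (gamma, w_den), sub in ok.groupby(["gamma", "w_den"], sort=True):
        rows.append(
            {
                "gamma": gamma,
                "w_den": w_den,
                "mean_r_free": sub["r_free"].mean(),
                "min_r_free": sub["r_free"].min(),
                "mean_rmsd_to_truth": sub["rmsd_to_truth"].mean()
                if sub["rmsd_to_truth"].notna().any()
                else np.nan,
                "n_repeats_used": len(sub),
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(path, index=False)
    return out
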