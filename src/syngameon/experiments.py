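"""Full-factorial parameter sweeps and their summaries.

A sweep runs every combination of (diversity, plc, selfing success,
hybridization success, fecundity) for a fixed number of replicates, each
with a seed derived deterministically from the base seed and the
combination, so the sweep is embarrassingly parallel, resumable, and its
result is independent of execution order.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .dynamics import Trajectory, run_simulation
from .model_core import (
    DEFAULT_ABUNDANCES,
    FECUNDITY_GRID,
    PLC_GRID,
    SUCCESS_GRID,
    MatingParams,
)

__all__ = [
    "SweepGrid",
    "run_sweep",
    "response_surface",
    "recruitment_series",
    "derive_seed",
]

logger = logging.getLogger(__name__)

_KEY_COLS = ["diversity", "plc", "self_success", "hybrid_success", "fecundity", "replicate"]


@dataclass(frozen=True)
class SweepGrid:
    """Grid of parameter values to sweep, defaulting to the canonical grids."""

    diversities: tuple[int, ...] = (3, 5, 10)
    plc_values: tuple[float, ...] = PLC_GRID
    self_values: tuple[float, ...] = SUCCESS_GRID
    hybrid_values: tuple[float, ...] = SUCCESS_GRID
    fecundity_values: tuple[int, ...] = FECUNDITY_GRID
    n_replicates: int = 3
    n_events: int = 500
    mortality_rate: float = 0.015
    abundances: dict[int, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ABUNDANCES)
    )

    @property
    def n_runs(self) -> int:
        return (
            len(self.diversities)
            * len(self.plc_values)
            * len(self.self_values)
            * len(self.hybrid_values)
            * len(self.fecundity_values)
            * self.n_replicates
        )

    def combinations(self) -> Iterator[tuple[int, float, float, float, int, int]]:
        for div in self.diversities:
            for plc in self.plc_values:
                for s in self.self_values:
                    for h in self.hybrid_values:
                        for F in self.fecundity_values:
                            for rep in range(self.n_replicates):
                                yield (div, plc, s, h, F, rep)

    def params_for(self, div: int, plc: float, s: float, h: float, F: int) -> MatingParams:
        return MatingParams(
            n_species=div,
            initial_abundances=self.abundances[div],
            plc=plc,
            self_success=s,
            hybrid_success=h,
            fecundity=F,
            mortality_rate=self.mortality_rate,
            n_events=self.n_events,
            n_replicates=self.n_replicates,
        )


def derive_seed(
    base_seed: int, div: int, plc: float, s: float, h: float, F: int, rep: int
) -> int:
    """Stable per-run seed from the base seed and the parameter combination."""
    key = f"{base_seed}|{div}|{plc:.10g}|{s:.10g}|{h:.10g}|{F}|{rep}"
    digest = hashlib.blake2b(key.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _run_one(grid: SweepGrid, combo: tuple, base_seed: int) -> dict:
    div, plc, s, h, F, rep = combo
    seed = derive_seed(base_seed, div, plc, s, h, F, rep)
    traj = run_simulation(grid.params_for(div, plc, s, h, F), seed)
    return {
        "diversity": div,
        "plc": plc,
        "self_success": s,
        "hybrid_success": h,
        "fecundity": F,
        "replicate": rep,
        "seed": seed,
        "final_richness": traj.final_richness,
    }


def run_sweep(
    grid: SweepGrid,
    base_seed: int,
    out_csv: str | Path | None = None,
    jobs: int = 1,
) -> pd.DataFrame:
    """Run every grid combination ``n_replicates`` times.

    One row per run: parameter combination, replicate, derived seed and
    final species richness.  If ``out_csv`` exists, rows already present
    are skipped (resume) and the merged table is written back.
    """
    done = pd.DataFrame(columns=_KEY_COLS + ["seed", "final_richness"])
    out_path = Path(out_csv) if out_csv is not None else None
    if out_path is not None and out_path.exists():
        done = pd.read_csv(out_path)
        logger.info("resuming sweep: %d rows already complete", len(done))

    done_keys = set(map(tuple, done[_KEY_COLS].itertuples(index=False, name=None)))
    todo = [c for c in grid.combinations() if c not in done_keys]

    if jobs > 1 and todo:
        from concurrent.futures import ProcessPoolExecutor

        with ProcessPoolExecutor(max_workers=jobs) as pool:
            rows = list(pool.map(_run_one, [grid] * len(todo), todo, [base_seed] * len(todo)))
    else:
        rows = [_run_one(grid, c, base_seed) for c in todo]

    new = pd.DataFrame(rows, columns=_KEY_COLS + ["seed", "final_richness"])
    result = new if done.empty else pd.concat([done, new], ignore_index=True)
    result = result.sort_values(_KEY_COLS).reset_index(drop=True)
    if out_path is not None:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        result.to_csv(out_path, index=False)
    return result


def response_surface(
    result: pd.DataFrame,
    facets: Sequence[str] = ("diversity", "fecundity", "plc"),
) -> pd.DataFrame:
    """Mean final richness over replicates per (facet..., selfing, hybridization) cell.

    Tidy output: one row per cell with the replicate mean, matching the
    response-surface summaries the sweep is designed to produce.  Raises
    if any requested cell has no completed runs.
    """
    group_cols = list(facets) + ["self_success", "hybrid_success"]
    n_reps = result.groupby(group_cols, sort=True)["final_richness"].count()
    full_grid = pd.MultiIndex.from_product(
        [sorted(result[c].unique()) for c in group_cols], names=group_cols
    )
    absent = full_grid.difference(n_reps.index)
    short = n_reps[n_reps < n_reps.max()]
    if len(absent) or len(short):
        first = absent[0] if len(absent) else short.index[0]
        raise ValueError(
            f"incomplete sweep: {len(absent)} cells missing entirely and "
            f"{len(short)} under-replicated (first: {first})"
        )
    surface = (
        result.groupby(group_cols, sort=True)["final_richness"]
        .mean()
        .reset_index()
        .rename(columns={"final_richness": "mean_final_richness"})
    )
    return surface


def recruitment_series(trajectory: Trajectory) -> pd.DataFrame:
    """Per-event proportions of recruits by origin, plus richness fraction.

    Proportions sum to 1 whenever recruits exist (NaN otherwise).  The
    richness fraction is current richness over initial diversity — the
    decaying gray line alongside the recruitment composition curves.
    """
    rows = []
    s0 = trajectory.params.n_species
    for e in trajectory.events:
        counts = e.recruit_counts_by_origin
        total = sum(counts.values())
        rows.append(
            {
                "event": e.event_index,
                "n_recruits": total,
                "prop_outcross": counts["outcross"] / total if total else np.nan,
                "prop_self": counts["self"] / total if total else np.nan,
                "prop_hybrid": counts["hybrid"] / total if total else np.nan,
                "richness_fraction": e.richness / s0,
            }
        )
    return pd.DataFrame(rows)
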