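"""Grid-search least-squares estimation of segregation parameters.

The observed male GS-class frequency vector of a clone is compared with
the model prediction at every (tb, cb) combination on a regular grid
spanning [-0.95, 0.95] in both parameters; the pair with the lowest
root-mean-squared error between predicted and observed class
frequencies is the estimate.  The whole error surface is retained so
callers can inspect ridges and near-ties.

For a clone with a single ISE the cosegregation bias has no effect on
the class frequencies (there is no pair of elements), so ``cb`` is
reported as undefined (NaN) and the search runs over tb alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segmodel import ClassDistribution, SegParams, class_distribution

__all__ = ["FitResult", "rmse", "grid_fit", "fit_many", "parameter_grid"]

GRID_LIMIT = 0.95
DEFAULT_GRID_STEP = 0.05


@dataclass(frozen=True)
class FitResult:
    """Best-fitting (tb, cb) with the full RMSE surface.

    ``surface`` is a DataFrame with columns ``tb``, ``cb``, ``rmse``
    containing every grid point evaluated.  For single-ISE clones
    ``best_cb`` is NaN and the surface varies over tb only.
    """

    best_tb: float
    best_cb: float
    best_rmse: float
    surface: pd.DataFrame
    grid_step: float
    n_ise: int


def rmse(predicted: ClassDistribution, observed: ClassDistribution) -> float:
    """Root-mean-squared error between two class-frequency vectors."""
    if predicted.n_ise != observed.n_ise:
        raise ValueError(
            f"class counts differ: {predicted.n_ise + 1} vs {observed.n_ise + 1}"
        )
    d = predicted.freqs - observed.freqs
    return float(np.sqrt(np.mean(d * d)))


def parameter_grid(grid_step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Grid values -0.95, -0.95+step, ..., 0.95 for one parameter."""
    if grid_step <= 0 or grid_step > 2 * GRID_LIMIT:
        raise ValueError(f"invalid grid step {grid_step}")
    n = int(round(2 * GRID_LIMIT / grid_step))
    vals = np.round(-GRID_LIMIT + grid_step * np.arange(n + 1), 12)
    return vals[vals <= GRID_LIMIT + 1e-12]


def grid_fit(
    observed: ClassDistribution,
    grid_step: float = DEFAULT_GRID_STEP,
) -> FitResult:
    """Exhaustive least-squares search over the (tb, cb) grid.

    Ties in RMSE (within 1e-12) are broken toward the most parsimonious
    deviation from unbiased segregation, i.e. smallest |tb| + |cb|,
    then lexicographically by (tb, cb).  When the observation was itself
    generated by the model at a grid point the generating pair is
    recovered with RMSE 0.
    """
    if observed.n_ise < 1:
        raise ValueError("fitting requires at least one ISE (two GS classes)")
    tb_vals = parameter_grid(grid_step)
    cb_identifiable = observed.n_ise >= 2
    cb_vals = parameter_grid(grid_step) if cb_identifiable else np.array([np.nan])

    rows = []
    for tb in tb_vals:
        for cb in cb_vals:
            params = SegParams(tb=float(tb), cb=0.0 if np.isnan(cb) else float(cb))
            pred = class_distribution(observed.n_ise, params)
            rows.append((float(tb), float(cb), rmse(pred, observed)))
    surface = pd.DataFrame(rows, columns=["tb", "cb", "rmse"])

    err = surface["rmse"].to_numpy()
    best_err = err.min()
    tie = surface[err <= best_err + 1e-12].copy()
    tie["_pars"] = tie["tb"].abs() + tie["cb"].abs().fillna(0.0)
    tie = tie.sort_values(["_pars", "tb", "cb"], kind="mergesort")
    best = tie.iloc[0]
    return FitResult(
        best_tb=float(best["tb"]),
        best_cb=float(best["cb"]),
        best_rmse=float(best["rmse"]),
        surface=surface,
        grid_step=grid_step,
        n_ise=observed.n_ise,
    )


def fit_many(
    observations: Iterable[tuple[str, ClassDistribution]],
    grid_step: float = DEFAULT_GRID_STEP,
) -> pd.DataFrame:
    """Fit each clone independently; one summary row per clone.

    Returns a DataFrame with columns ``clone_id``, ``n_ise``,
    ``best_tb``, ``best_cb``, ``best_rmse`` — the shape needed for an
    inbred-vs-outbred parameter scatter.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("need at least one observation")
    ids = [cid for cid, _ in observations]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate clone ids: {dupes}")
    rows = []
    for clone_id, obs in observations:
        fit = grid_fit(obs, grid_step=grid_step)
        rows.append(
            {
                "clone_id": clone_id,
                "n_ise": obs.n_ise,
                "best_tb": fit.best_tb,
                "best_cb": fit.best_cb,
                "best_rmse": fit.best_rmse,
            }
        )
    return pd.DataFrame(rows)
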