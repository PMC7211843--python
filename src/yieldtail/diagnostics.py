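"""Threshold-choice diagnostics: shape and endpoint trajectories over k.

The number of top order statistics ``k`` trades variance (small k) against
bias (large k, the fit leaks into the bulk).  The practical device is to
plot the ML shape estimate as a function of k and pick a value inside the
"stability region" where the curve has flattened.  This module computes the
trajectory, a rolling-range stability heuristic, and the two-panel plot.

The heuristic is an aid to a decision the analyst ultimately makes visually;
it reports the full diagnostic series so it can be overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .gpd import FitError, fit_ml, select_exceedances
from .inference import endpoint_ci, endpoint_estimate, shape_ci

__all__ = ["ShapeTrajectory", "StabilityResult", "shape_trajectory",
           "stability_region", "plot_trajectory"]

TRAJECTORY_COLUMNS = ["k", "t_k", "gamma", "ci_lo", "ci_hi",
                      "endpoint", "endpoint_lo", "endpoint_hi"]


@dataclass(frozen=True)
class ShapeTrajectory:
    """Per-k ML estimates: one row per k in [k_min, k_max].

    ``endpoint`` (and its interval) is absent — NaN — where the shape
    estimate is non-negative, matching the endpoint formula's domain.
    """

    table: pd.DataFrame
    k_min: int
    k_max: int
    level: float
    n: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class StabilityResult:
    """Outcome of the rolling-range stability rule.

    ``recommended_k`` is the largest k whose trailing-window range of shape
    estimates is within ``tol``; None (with ``stable`` False) when no window
    qualifies — a prompt for manual inspection, not an error.
    """

    recommended_k: Optional[int]
    stable: bool
    window: int
    tol: float
    diagnostics: pd.DataFrame
    message: str


def shape_trajectory(values, k_min: int = 15, k_max: int = 400,
                     level: float = 0.95) -> ShapeTrajectory:
    """ML shape (and endpoint) estimates for every k in [k_min, k_max].

    k_max is clipped to n - 1.  Rows where the fit fails are recorded as NaN
    so the k grid stays contiguous.
    """
    if hasattr(values, "columns"):
        values = values["max_yield"]
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if k_min >= k_max:
        raise ValueError(f"k_min={k_min} must be smaller than k_max={k_max}")
    if k_min < 2:
        raise ValueError(f"k_min must be at least 2, got {k_min}")
    k_hi = min(k_max, n - 1)
    if k_hi < k_min:
        raise ValueError(f"sample of size {n} too small for k_min={k_min}")

    rows = []
    for k in range(k_min, k_hi + 1):
        rec = {c: np.nan for c in TRAJECTORY_COLUMNS}
        rec["k"] = k
        try:
            with warnings.catch_warnings():
                # non-regular fits are expected at bulk-contaminated k values
                warnings.simplefilter("ignore", UserWarning)
                exc = select_exceedances(x, k)
                fit = fit_ml(exc)
        except (ValueError, FitError):
            rows.append(rec)
            continue
        g = fit.params.gamma
        rec["t_k"] = exc.threshold
        rec["gamma"] = g
        if g > -0.5:
            rec["ci_lo"], rec["ci_hi"] = shape_ci(fit, level)
        if g < 0:
            rec["endpoint"] = endpoint_estimate(fit)
            if g > -0.5:
                est = endpoint_ci(fit, level)
                rec["endpoint_lo"], rec["endpoint_hi"] = est.ci_lower, est.ci_upper
        rows.append(rec)

    table = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    table["k"] = table["k"].astype(int)
    return ShapeTrajectory(table=table, k_min=k_min, k_max=k_hi, level=level, n=n)


def stability_region(traj: ShapeTrajectory, window: int = 50,
                     tol: float = 0.05) -> StabilityResult:
    """Largest k whose trailing window of shape estimates spans <= tol.

    The trailing range at row i is max - min of gamma over the previous
    ``window`` rows (inclusive); NaN fits disqualify a window.
    """
    if window < 2:
        raise ValueError(f"window must be at least 2, got {window}")
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    t = traj.table
    if len(t) < window:
        raise ValueError(f"trajectory has {len(t)} rows, fewer than window={window}")

    g = t["gamma"]
    rng = g.rolling(window).max() - g.rolling(window).min()
    diagnostics = pd.DataFrame({"k": t["k"], "rolling_range": rng})
    ok = rng.le(tol).to_numpy()
    if ok.any():
        k_rec = int(t["k"].to_numpy()[np.flatnonzero(ok)[-1]])
        return StabilityResult(
            recommended_k=k_rec, stable=True, window=window, tol=tol,
            diagnostics=diagnostics,
            message=f"shape estimates stable (range <= {tol}) in the window ending at k={k_rec}",
        )
    return StabilityResult(
        recommended_k=None, stable=False, window=window, tol=tol,
        diagnostics=diagnostics,
        message=(f"no window of {window} consecutive k values keeps the shape "
                 f"range within {tol}; inspect the trajectory manually"),
    )


def plot_trajectory(traj: ShapeTrajectory, path) -> None:
    """Two-panel plot: shape estimate and endpoint estimate against k,
    each with its confidence band.  Written straight to ``path``."""
    from matplotlib.figure import Figure

    t = traj.table
    fig = Figure(figsize=(7, 7))
    ax1, ax2 = fig.subplots(2, 1, sharex=True)

    ax1.plot(t["k"], t["gamma"], color="black", lw=1)
    ax1.fill_between(t["k"], t["ci_lo"], t["ci_hi"], color="0.8")
    ax1.axhline(0.0, color="red", lw=0.6, ls="--")
    ax1.set_ylabel(r"shape estimate $\hat\gamma_k$")

    ax2.plot(t["k"], t["endpoint"], color="black", lw=1)
    ax2.fill_between(t["k"], t["endpoint_lo"], t["endpoint_hi"], color="0.8")
    ax2.set_ylabel(r"endpoint estimate $\hat x^*_k$ (t/ha)")
    ax2.set_xlabel("effective sample size $k$")

    fig.tight_layout()
    fig.savefig(path, dpi=150)
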