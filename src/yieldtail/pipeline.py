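"""End-to-end analysis runner and panel/report IO.

``run_analysis`` reproduces the shape of a full tail study on a farm
panel: deflate costs, deduplicate to per-farm maxima, optionally stratify
by region or by input spending, fit the GPD tail of each stratum at an
explicit or automatically chosen k, and report — per analysis block — n,
k, the threshold, the shape and scale estimates with confidence intervals,
and the endpoint estimate with its truncated interval, plus
likelihood-ratio tests between strata.

Reports carry full-precision numbers alongside display-rounded strings
(2 decimals, half away from zero); rounding never feeds back into any
computation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .diagnostics import shape_trajectory, stability_region
from .gpd import FitError, GPDFit, fit_ml, select_exceedances
from .inference import (endpoint_ci, endpoint_estimate, lr_test_strata,
                        scale_ci, shape_ci)
from .prep import (SAMPLE_COLUMNS, dedup_farm_max, deflate_costs,
                   ensure_macro_regions, stratify_by_region,
                   stratify_by_spend)
from .simulate import PANEL_COLUMNS, SyntheticConfig, generate_panel

__all__ = [
    "AnalysisConfig",
    "run_analysis",
    "write_report",
    "read_panel",
    "write_panel",
    "read_sample",
    "write_sample",
    "read_price_index",
    "round_display",
    "format_display",
]


# ---------------------------------------------------------------------------
# Display rounding (half away from zero, as tables are usually typeset)
# ---------------------------------------------------------------------------

def _quantize(x: float, decimals: int) -> Decimal:
    q = Decimal(1).scaleb(-decimals)
    return Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)


def round_display(x: float, decimals: int = 2) -> float:
    """Round half away from zero (display only; never re-enters computation)."""
    return float(_quantize(x, decimals))


def format_display(x: Optional[float], decimals: int = 2) -> str:
    if x is None:
        return "--"
    return str(_quantize(x, decimals))


# ---------------------------------------------------------------------------
# Panel / sample IO
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, expected, path) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise ValueError(
            f"{path}: bad header; missing columns {missing}, unexpected {extra}")


def read_panel(path) -> pd.DataFrame:
    """Read and validate a farm-year panel CSV.

    Errors name the offending file rows (1-based, counting the header as
    row 1): non-numeric or negative yields, non-integer years, duplicated
    (farm_id, year) pairs.
    """
    df = pd.read_csv(path, dtype={"farm_id": str, "region": str},
                     float_precision="round_trip")
    _check_columns(df, PANEL_COLUMNS, path)
    rows = df.index + 2  # file line numbers

    for col in ("yield", "fert_cost", "cp_cost"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = rows[vals.isna() | ~np.isfinite(vals)].tolist()
        if bad:
            raise ValueError(f"{path}: non-numeric {col} in row(s) {bad}")
        df[col] = vals.astype(float)
    years = pd.to_numeric(df["year"], errors="coerce")
    bad = rows[years.isna() | (years != years.round())].tolist()
    if bad:
        raise ValueError(f"{path}: non-integer year in row(s) {bad}")
    df["year"] = years.astype(int)

    bad = rows[df["yield"] < 0].tolist()
    if bad:
        raise ValueError(f"{path}: negative yield in row(s) {bad}")
    dup = df.duplicated(["farm_id", "year"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["farm_id", "year"]].drop_duplicates()
        shown = [f"({r.farm_id}, {r.year})" for r in pairs.itertuples()][:10]
        raise ValueError(
            f"{path}: duplicated (farm_id, year) pair(s) {', '.join(shown)} "
            f"in row(s) {rows[dup].tolist()}")
    return df[PANEL_COLUMNS]


def write_panel(panel: pd.DataFrame, path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def read_sample(path) -> pd.DataFrame:
    """Read a deduplicated farm-max sample CSV."""
    df = pd.read_csv(path, dtype={"farm_id": str, "region": str},
                     float_precision="round_trip")
    _check_columns(df, SAMPLE_COLUMNS, path)
    for col in ("max_yield", "total_input_cost"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    return df[SAMPLE_COLUMNS]


def write_sample(sample: pd.DataFrame, path) -> None:
    sample[SAMPLE_COLUMNS].to_csv(path, index=False)


def read_price_index(path) -> dict:
    """Read a two-column year,index CSV into a mapping."""
    df = pd.read_csv(path)
    _check_columns(df, ["year", "index"], path)
    return {int(r.year): float(r.index) for r in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Configuration of a full tail analysis.

    ``panel`` may be a CSV path, an in-memory panel frame, or a
    :class:`SyntheticConfig` (the panel is then generated, with ``seed``
    overriding the generator seed when given).  ``k`` is a single effective
    sample size, a mapping from block name to k, or ``"auto"`` to let the
    stability heuristic choose per stratum.
    """

    panel: Union[str, Path, pd.DataFrame, SyntheticConfig]
    k: Union[int, str, Mapping[str, int]] = "auto"
    level: float = 0.95
    stratify: str = "none"  # none | region | spend | all
    spend_groups: int = 3
    price_index: Optional[Mapping[int, float]] = None
    base_year: Optional[int] = None
    seed: Optional[int] = None
    display_decimals: int = 2
    k_min: int = 15
    k_max: int = 400
    stability_window: int = 50
    stability_tol: float = 0.05

    def __post_init__(self):
        if not 0 < self.level < 1:
            raise ValueError(f"level must lie in (0, 1), got {self.level}")
        if self.stratify not in ("none", "region", "spend", "all"):
            raise ValueError(
                f"stratify must be none/region/spend/all, got {self.stratify!r}")
        if isinstance(self.k, str) and self.k != "auto":
            raise ValueError(f"k must be an integer, a mapping, or 'auto', got {self.k!r}")


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def _resolve_panel(config: AnalysisConfig, log: list) -> pd.DataFrame:
    src = config.panel
    if isinstance(src, SyntheticConfig):
        if config.seed is not None:
            src = dataclasses.replace(src, seed=int(config.seed))
        log.append(f"generated synthetic panel (seed={src.seed})")
        return generate_panel(src)
    if isinstance(src, pd.DataFrame):
        return src.copy()
    log.append(f"read panel from {src}")
    return read_panel(src)


def _resolve_k(name: str, n: int, yields, config: AnalysisConfig, log: list) -> int:
    if isinstance(config.k, (int, np.integer)):
        k = int(config.k)
        if not 1 <= k <= n - 1:
            raise ValueError(f"analysis {name!r}: k={k} invalid for n={n}")
        log.append(f"{name}: explicit k={k}")
        return k
    if isinstance(config.k, Mapping):
        if name not in config.k:
            raise ValueError(f"analysis {name!r}: no k given in the k mapping")
        k = int(config.k[name])
        if not 1 <= k <= n - 1:
            raise ValueError(f"analysis {name!r}: k={k} invalid for n={n}")
        log.append(f"{name}: explicit k={k}")
        return k
    # auto
    k_hi = min(config.k_max, n - 1)
    k_lo = config.k_min
    if k_hi <= k_lo:
        k = max(2, k_hi)
        log.append(f"{name}: sample too small for a trajectory; k={k}")
        return k
    traj = shape_trajectory(yields, k_min=k_lo, k_max=k_hi, level=config.level)
    window = min(config.stability_window, max(2, len(traj.table) // 2))
    res = stability_region(traj, window=window, tol=config.stability_tol)
    if res.stable:
        log.append(f"{name}: auto k={res.recommended_k} ({res.message})")
        return int(res.recommended_k)
    rr = res.diagnostics.dropna()
    k = int(rr.loc[rr["rolling_range"].idxmin(), "k"])
    log.append(f"{name}: {res.message}; falling back to the flattest window, k={k}")
    return k


def _display_block(block: dict, nd: int) -> dict:
    def pair(val, ci):
        if val is None:
            return "--"
        s = format_display(val, nd)
        if ci is None:
            return s
        return f"{s} ({format_display(ci[0], nd)}, {format_display(ci[1], nd)})"

    return {
        "n": str(block["n"]),
        "k": str(block["k"]),
        "threshold": format_display(block["threshold"], nd),
        "gamma": pair(block["gamma"], block["gamma_ci"]),
        "sigma": pair(block["sigma"], block["sigma_ci"]),
        "endpoint": pair(block["endpoint"], block["endpoint_ci"]),
    }


def _analysis_block(name: str, yields: np.ndarray, k: int, level: float,
                    nd: int, log: list):
    exc = select_exceedances(yields, k)
    fit = fit_ml(exc)
    g, s = fit.params.gamma, fit.params.sigma
    block = {
        "name": name,
        "n": int(exc.n),
        "k": int(exc.k),
        "threshold": float(exc.threshold),
        "t0": float(exc.t0),
        "gamma": float(g),
        "sigma": float(s),
        "loglik": float(fit.loglik),
        "converged": bool(fit.converged),
        "gamma_ci": None,
        "sigma_ci": None,
        "endpoint": None,
        "endpoint_ci": None,
        "endpoint_ci_unconstrained_lower": None,
        "truncated": None,
        "notes": [],
    }
    log.append(f"{name}: fit k={exc.k}, t_k={exc.threshold:.4f}, "
               f"gamma={g:.4f}, sigma={s:.4f}, converged={fit.converged}")
    if g > -0.5:
        block["gamma_ci"] = [float(v) for v in shape_ci(fit, level)]
        block["sigma_ci"] = [float(v) for v in scale_ci(fit, level)]
    else:
        block["notes"].append(
            "shape estimate <= -1/2: Wald intervals unavailable")
    if g < 0:
        block["endpoint"] = float(endpoint_estimate(fit))
        if g > -0.5:
            est = endpoint_ci(fit, level)
            block["endpoint_ci"] = [float(est.ci_lower), float(est.ci_upper)]
            block["endpoint_ci_unconstrained_lower"] = float(est.ci_lower_unconstrained)
            block["truncated"] = bool(est.truncated)
            if est.truncated:
                log.append(f"{name}: endpoint CI lower bound truncated at the "
                           f"sample maximum t0={est.t0:.4f}")
    else:
        block["notes"].append("non-negative shape estimate: no finite endpoint")
    block["display"] = _display_block(block, nd)
    return block, fit


def _lr_entry(fits, labels, log, family):
    try:
        cmp_ = lr_test_strata(fits, labels)
    except (FitError, ValueError) as err:
        log.append(f"LR test ({family}) failed: {err}")
        return {"error": str(err)}
    log.append(f"LR test ({family}): stat={cmp_.lr_stat:.4f}, df={cmp_.df}, "
               f"p={cmp_.p_value:.4g}")
    return {
        "strata": list(cmp_.labels),
        "lr_stat": cmp_.lr_stat,
        "df": cmp_.df,
        "p_value": cmp_.p_value,
        "pooled_gamma": cmp_.pooled.params.gamma,
        "pooled_sigma": cmp_.pooled.params.sigma,
    }


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the configured analysis end to end and return the report dict.

    Deterministic given the configuration (and seed, for synthetic input).
    """
    log: list = []
    panel = _resolve_panel(config, log)
    if config.price_index is not None:
        if config.base_year is None:
            raise ValueError("base_year required when a price index is given")
        panel = deflate_costs(panel, config.price_index, config.base_year)
        log.append(f"costs deflated to base year {config.base_year}")
    panel = ensure_macro_regions(panel)
    sample = dedup_farm_max(panel)
    log.append(f"deduplicated to {len(sample)} unique farms "
               f"(from {len(panel)} farm-years)")

    nd = config.display_decimals
    blocks = []
    lr_tests = {}
    spend_cuts = None

    def run_block(name, frame):
        yields = frame["max_yield"].to_numpy()
        k = _resolve_k(name, len(frame), yields, config, log)
        return _analysis_block(name, yields, k, config.level, nd, log)

    if config.stratify in ("none", "all"):
        block, _ = run_block("yield", sample)
        blocks.append(block)

    if config.stratify in ("region", "all"):
        fits, labels = [], []
        for region, frame in stratify_by_region(sample).items():
            block, fit = run_block(f"region:{region}", frame)
            blocks.append(block)
            fits.append(fit)
            labels.append(region)
        if len(fits) >= 2:
            lr_tests["region"] = _lr_entry(fits, labels, log, "region")

    if config.stratify in ("spend", "all"):
        groups, spend_cuts = stratify_by_spend(sample, config.spend_groups)
        if config.spend_groups == 3:
            names = ["low", "medium", "high"]
        else:
            names = [f"spend_q{j + 1}" for j in range(config.spend_groups)]
        fits, labels = [], []
        for label, frame in zip(names, groups):
            block, fit = run_block(f"spend:{label}", frame)
            blocks.append(block)
            fits.append(fit)
            labels.append(label)
        log.append("spend cut points: " +
                   ", ".join(format_display(c, nd) for c in spend_cuts))
        lr_tests["spend"] = _lr_entry(fits, labels, log, "spend")

    return {
        "n_farms": int(len(sample)),
        "level": config.level,
        "stratify": config.stratify,
        "display_decimals": nd,
        "seed": config.seed,
        "spend_cut_points": spend_cuts,
        "analyses": blocks,
        "lr_tests": lr_tests,
        "log": log,
    }


def report_table(report: dict) -> pd.DataFrame:
    """Flatten the report's analysis blocks into a summary table."""
    rows = []
    for b in report["analyses"]:
        rows.append({
            "name": b["name"],
            "n": b["n"],
            "k": b["k"],
            "t": b["threshold"],
            "gamma": b["gamma"],
            "gamma_lo": None if b["gamma_ci"] is None else b["gamma_ci"][0],
            "gamma_hi": None if b["gamma_ci"] is None else b["gamma_ci"][1],
            "sigma": b["sigma"],
            "sigma_lo": None if b["sigma_ci"] is None else b["sigma_ci"][0],
            "sigma_hi": None if b["sigma_ci"] is None else b["sigma_ci"][1],
            "endpoint": b["endpoint"],
            "endpoint_lo": None if b["endpoint_ci"] is None else b["endpoint_ci"][0],
            "endpoint_hi": None if b["endpoint_ci"] is None else b["endpoint_ci"][1],
            "truncated": b["truncated"],
        })
    return pd.DataFrame(rows)


def write_report(report: dict, outdir) -> None:
    """Write report.json and table.csv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    report_table(report).to_csv(outdir / "table.csv", index=False)
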