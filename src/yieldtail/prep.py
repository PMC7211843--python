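"""Survey preparation: deflation, per-farm maxima, regions, spend strata.

Turns a raw farm-year panel (columns farm_id, year, yield, region,
fert_cost, cp_cost) into the analysis sample: one record per farm carrying
its maximum yield over the years it participated, the macro-region, and the
deflated input spending of the retained year.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MACRO_REGIONS",
    "SAMPLE_COLUMNS",
    "assign_macro_region",
    "ensure_macro_regions",
    "deflate_costs",
    "dedup_farm_max",
    "stratify_by_spend",
    "stratify_by_region",
]

SAMPLE_COLUMNS = ["farm_id", "max_yield", "region", "total_input_cost"]

# NUTS1 regions grouped into the three macro-regions used for stratified
# tail analyses (Scotland and Northern Ireland are outside the survey).
MACRO_REGIONS: Dict[str, List[str]] = {
    "east": ["East Midlands", "East of England", "London", "South East England"],
    "north": ["North East England", "North West England", "Yorkshire & Humberside"],
    "west": ["West Midlands", "South West England", "Wales"],
}


def _normalize(label: str) -> str:
    s = " ".join(str(label).split()).lower()
    return s.replace(" and ", " & ")


_NUTS1_TO_MACRO = {
    _normalize(name): macro
    for macro, names in MACRO_REGIONS.items()
    for name in names
}


def assign_macro_region(nuts1_label: str) -> str:
    """Map a NUTS1 region name to its macro-region (east/north/west).

    Matching is case- and whitespace-insensitive and accepts "and" for "&".
    """
    key = _normalize(nuts1_label)
    if key in _NUTS1_TO_MACRO:
        return _NUTS1_TO_MACRO[key]
    accepted = sorted(n for names in MACRO_REGIONS.values() for n in names)
    raise ValueError(
        f"unknown NUTS1 region {nuts1_label!r}; accepted names: {accepted}")


def ensure_macro_regions(panel: pd.DataFrame) -> pd.DataFrame:
    """Return a panel whose region column holds macro-region labels.

    Labels already in {east, north, west} pass through; anything else is
    mapped as a NUTS1 name.
    """
    labels = set(panel["region"].unique())
    if labels <= set(MACRO_REGIONS):
        return panel
    out = panel.copy()
    out["region"] = out["region"].map(assign_macro_region)
    return out


def deflate_costs(panel: pd.DataFrame, index: Mapping[int, float],
                  base_year: int) -> pd.DataFrame:
    """Express fert_cost and cp_cost in base-year money.

    Each cost is multiplied by ``index[base_year] / index[year]``; yields
    are untouched.  Applying this to already-deflated data changes values
    again — deflate the original records exactly once.
    """
    index = {int(y): float(v) for y, v in index.items()}
    if base_year not in index:
        raise ValueError(f"base year {base_year} missing from the price index")
    if any(v <= 0 for v in index.values()):
        raise ValueError("price index values must be positive")
    years = pd.unique(panel["year"])
    missing = sorted(int(y) for y in years if int(y) not in index)
    if missing:
        raise ValueError(f"price index missing year(s): {missing}")

    factor = panel["year"].map(lambda y: index[base_year] / index[int(y)])
    out = panel.copy()
    out["fert_cost"] = out["fert_cost"] * factor
    out["cp_cost"] = out["cp_cost"] * factor
    return out


def dedup_farm_max(panel: pd.DataFrame) -> pd.DataFrame:
    """One record per farm: its maximum yield and that year's covariates.

    If two years tie on the maximum, the earliest year's covariates are
    retained (deterministic and independent of input row order).  Spending
    is the retained year's fert_cost + cp_cost.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    ordered = panel.sort_values(
        ["farm_id", "yield", "year"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    top = ordered.drop_duplicates("farm_id", keep="first")
    sample = pd.DataFrame({
        "farm_id": top["farm_id"].to_numpy(),
        "max_yield": top["yield"].to_numpy(),
        "region": top["region"].to_numpy(),
        "total_input_cost": (top["fert_cost"] + top["cp_cost"]).to_numpy(),
    })
    return sample.reset_index(drop=True)


def stratify_by_spend(sample: pd.DataFrame, n_groups: int = 3
                      ) -> Tuple[List[pd.DataFrame], List[float]]:
    """Equal-size groups ordered by total input spending, plus cut points.

    Farms are stably sorted by (total_input_cost, farm_id) — so ties at a
    boundary resolve reproducibly — and split into groups whose sizes differ
    by at most one, with the larger groups at the low-spend end.  The
    returned cut points are the smallest spend of each group after the
    first (descriptive, not defining, when there are boundary ties).
    """
    if n_groups < 2:
        raise ValueError(f"n_groups must be at least 2, got {n_groups}")
    n = len(sample)
    if n < n_groups:
        raise ValueError(f"cannot split {n} farms into {n_groups} groups")
    ordered = sample.sort_values(["total_input_cost", "farm_id"],
                                 kind="mergesort").reset_index(drop=True)
    base, rem = divmod(n, n_groups)
    sizes = [base + 1] * rem + [base] * (n_groups - rem)
    bounds = np.cumsum([0] + sizes)
    groups = [ordered.iloc[bounds[j]:bounds[j + 1]].reset_index(drop=True)
              for j in range(n_groups)]
    cuts = [float(groups[j]["total_input_cost"].iloc[0])
            for j in range(1, n_groups)]
    return groups, cuts


def stratify_by_region(sample: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Partition the farm-max sample by its region labels."""
    return {
        str(region): df.reset_index(drop=True)
        for region, df in sample.groupby("region", sort=True)
    }
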