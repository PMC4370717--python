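"""Input-cost intensity indicator (IC/ha) and its spatial aggregation.

Agricultural intensity is measured per Small Agricultural Region (SAR) as
Input Cost per hectare: the sum of seven input-cost categories
(fertilizers, feedstuff, pesticides, seeds, fuel, veterinary products,
irrigation water) over all eligible farms, divided by their total
utilised agricultural area, then averaged over three accounting years to
damp price and stock fluctuations.  Only five production types enter the
indicator — industrial crops, cereals, bovine dairy, bovine meat, and
mixed crop/bovine — and a SAR is retained only when those five types
cover strictly more than two-thirds of its agricultural area.

The spatial aggregation index of a SAR is its IC/ha minus the mean IC/ha
of its contiguous neighbours:

    AI_i = X_i − (Σ_j w_ij X_j) / (Σ_j w_ij)

with w the binary contiguity matrix.  A small |AI| means the SAR sits in
a neighbourhood of similar intensity — intensity is spatially
*aggregated* there.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "COST_CATEGORIES",
    "ELIGIBLE_PRODUCTION_TYPES",
    "compute_ic_per_ha",
    "sar_eligibility",
    "aggregation_index",
    "classify_aggregated",
]

logger = logging.getLogger(__name__)

#: The seven input-cost categories summed into IC.
COST_CATEGORIES: tuple[str, ...] = (
    "fertilizers",
    "feedstuff",
    "pesticides",
    "seeds",
    "fuel",
    "veterinary",
    "irrigation_water",
)

#: Production types entering the IC/ha computation.
ELIGIBLE_PRODUCTION_TYPES: frozenset[str] = frozenset(
    {"industrial_crops", "cereals", "bovine_dairy", "bovine_meat", "mixed"}
)


def compute_ic_per_ha(
    records: pd.DataFrame,
    years=(2004, 2005, 2006),
    *,
    ratio_of_sums: bool = True,
) -> pd.Series:
    """Per-SAR IC/ha averaged over the given accounting years.

    ``records`` has one row per farm × year with columns ``farm_id,
    sar_id, production_type, year, utilised_area`` and one column per
    cost category.  Farms of ineligible production types are dropped
    before any computation.

    Within each SAR and year the default is the ratio of sums — total
    input cost of all eligible farms over their total area — which
    weights farms by area; ``ratio_of_sums=False`` averages per-farm
    IC/ha ratios instead.  Yearly SAR values are then averaged over
    ``years``.  SARs with no eligible area in any requested year are
    excluded (logged).

    Returns a Series of €/ha indexed by ``sar_id``.
    """
    needed = {"farm_id", "sar_id", "production_type", "year", "utilised_area", *COST_CATEGORIES}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"farm table missing columns {sorted(missing)}")
    if (records["utilised_area"] <= 0).any():
        raise ValueError("utilised_area must be > 0")
    costs = records[list(COST_CATEGORIES)]
    if (costs < 0).to_numpy().any():
        raise ValueError("input costs must be non-negative")

    eligible = records[
        records["production_type"].isin(ELIGIBLE_PRODUCTION_TYPES)
        & records["year"].isin(list(years))
    ].copy()
    eligible["ic"] = eligible[list(COST_CATEGORIES)].sum(axis=1)

    if ratio_of_sums:
        per_year = eligible.groupby(["sar_id", "year"]).apply(
            lambda g: g["ic"].sum() / g["utilised_area"].sum(), include_groups=False
        )
    else:
        eligible["farm_ratio"] = eligible["ic"] / eligible["utilised_area"]
        per_year = eligible.groupby(["sar_id", "year"])["farm_ratio"].mean()

    result = per_year.groupby(level="sar_id").mean().rename("ic_per_ha")
    dropped = set(records["sar_id"].unique()) - set(result.index)
    if dropped:
        logger.info("%d SAR(s) excluded from IC/ha (no eligible farm area): %s",
                    len(dropped), sorted(dropped)[:5])
    return result


def sar_eligibility(five_type_area: pd.Series, total_agri_area: pd.Series) -> pd.Index:
    """SARs where the five production types cover > 2/3 of agricultural area.

    The inequality is strict: a SAR exactly at two-thirds is excluded
    (a tiny relative tolerance keeps the exact boundary stable under
    floating-point representation of 2/3).
    """
    missing = five_type_area.index.difference(total_agri_area.index)
    if len(missing):
        raise ValueError(f"total agricultural area missing for SARs {sorted(missing)[:5]}")
    total = total_agri_area.reindex(five_type_area.index)
    share = five_type_area / total
    return five_type_area.index[share > (2.0 / 3.0) * (1.0 + 1e-9)]


def aggregation_index(intensities: pd.Series, w: np.ndarray, unit_ids=None) -> pd.Series:
    """Aggregation index AI_i = X_i − mean IC/ha of contiguous neighbours.

    Parameters
    ----------
    intensities
        Per-SAR IC/ha, indexed by SAR id (or positional when a plain
        array is given).
    w
        Symmetric binary contiguity matrix aligned with ``unit_ids``
        (defaults to the order of ``intensities``).
    unit_ids
        Row/column labels of ``w``.

    SARs without any neighbour get ``nan`` (AI undefined, flagged in the
    log).
    """
    x = pd.Series(intensities)
    if unit_ids is None:
        unit_ids = list(x.index)
    w = np.asarray(w, dtype=float)
    if w.shape != (len(unit_ids), len(unit_ids)):
        raise ValueError("connectivity matrix shape does not match unit list")
    xv = x.reindex(unit_ids).to_numpy()
    if np.isnan(xv).any():
        raise ValueError("intensity missing for some units in the connectivity matrix")
    row_sums = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        neighbour_mean = (w @ xv) / row_sums
    ai = xv - neighbour_mean
    isolated = row_sums == 0
    if isolated.any():
        logger.info("%d isolated SAR(s): AI undefined", int(isolated.sum()))
        ai[isolated] = np.nan
    return pd.Series(ai, index=unit_ids, name="ai")


def classify_aggregated(ai: pd.Series, *, rule: str = "abs_mean") -> pd.Series:
    """Binary aggregated/non-aggregated classification of SARs.

    A SAR is *aggregated* when its intensity resembles its neighbours'.
    Rules (strict inequality at the boundary in all cases):

    ``abs_mean`` (default)
        |AI_i| < mean(|AI|) over scored SARs.
    ``signed_mean``
        AI_i < mean(AI) — a literal reading of "lower than the average",
        kept selectable because the two readings differ.
    ``abs_median``
        |AI_i| < median(|AI|).

    SARs with undefined AI get a missing flag (``pd.NA``).
    """
    ai = pd.Series(ai, dtype=float)
    scored = ai.dropna()
    if scored.empty:
        raise ValueError("no SAR has a defined aggregation index")
    if rule == "abs_mean":
        flags = scored.abs() < scored.abs().mean()
    elif rule == "signed_mean":
        flags = scored < scored.mean()
    elif rule == "abs_median":
        flags = scored.abs() < scored.abs().median()
    else:
        raise ValueError(f"unknown classification rule {rule!r}")
    out = pd.Series(pd.NA, index=ai.index, dtype="boolean", name="aggregated")
    out.loc[scored.index] = flags
    return out
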