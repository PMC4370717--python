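"""Land-use, climate and altitude covariates for the site-level models.

Site-level land use comes in as pre-tabulated CORINE land cover (CLC)
category areas; this module turns them into proportions, a Shannon
diversity of cover types, and joins SAR-level climate (mean temperature,
annual precipitation, averaged over the survey years) and the
arable/grassland ratio onto the bird sample sites.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "CLC_CATEGORIES",
    "clc_proportions",
    "shannon_diversity",
    "arable_grassland_ratio",
    "assemble_covariates",
]

logger = logging.getLogger(__name__)

#: The 15 CORINE land cover categories used as site covariates.
CLC_CATEGORIES: tuple[str, ...] = (
    "non_irrigated_arable",
    "vineyards",
    "fruit_trees",
    "pastures",
    "complex_cultivation",
    "agriculture_natural_vegetation",
    "broad_leaved_forest",
    "coniferous_forest",
    "mixed_forest",
    "natural_grasslands",
    "moors_heathland",
    "transitional_woodland_shrub",
    "artificial_surfaces",
    "wetlands",
    "water_bodies",
)


def clc_proportions(areas: pd.DataFrame, site_area: float | pd.Series = 4.0) -> pd.DataFrame:
    """Per-site CLC category proportions from category areas.

    ``areas`` has columns ``site_id, category, area_km2``; ``site_area``
    is the total site area in km² (scalar, default the 2 × 2 km square,
    or a per-site Series).  Absent categories get proportion 0.
    """
    needed = {"site_id", "category", "area_km2"}
    if not needed <= set(areas.columns):
        raise ValueError(f"area table needs columns {sorted(needed)}")
    if (areas["area_km2"] < 0).any():
        raise ValueError("category areas must be non-negative")
    wide = (
        areas.pivot_table(index="site_id", columns="category", values="area_km2",
                          aggfunc="sum", fill_value=0.0)
        .reindex(columns=list(CLC_CATEGORIES), fill_value=0.0)
    )
    total = site_area if np.isscalar(site_area) else pd.Series(site_area).reindex(wide.index)
    props = wide.div(total, axis=0) if not np.isscalar(site_area) else wide / float(site_area)
    over = props.sum(axis=1) > 1.0 + 1e-9
    if over.any():
        raise ValueError(f"category areas exceed site area for sites {list(props.index[over])[:5]}")
    return props


def shannon_diversity(proportions, base: float | None = None) -> float:
    """Shannon index H = −Σ p log p over the categories present.

    Proportions are renormalised over the present (positive) categories;
    natural log by default, ``base`` selects another.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("Shannon diversity undefined: no positive proportion")
    p = p / p.sum()
    h = -float(np.sum(p * np.log(p)))
    return h / np.log(base) if base is not None else h


def arable_grassland_ratio(arable_area: float, grassland_area: float) -> float:
    """Arable area over arable + grassland area; ``nan`` when both are zero."""
    if arable_area < 0 or grassland_area < 0:
        raise ValueError("areas must be non-negative")
    total = arable_area + grassland_area
    if total == 0:
        logger.info("arable/grassland ratio undefined (no arable or grassland area)")
        return float("nan")
    return arable_area / total


def assemble_covariates(
    clc_areas: pd.DataFrame,
    altitude: pd.DataFrame,
    climate: pd.DataFrame,
    site_sar: pd.DataFrame,
    sar_landuse: pd.DataFrame | None = None,
    *,
    climate_years=(2006, 2007, 2008),
    standardise_precipitation: bool = False,
    site_area: float = 4.0,
) -> pd.DataFrame:
    """Join site- and SAR-level covariates into one modelling table.

    Parameters
    ----------
    clc_areas
        ``site_id, category, area_km2``.
    altitude
        ``site_id, altitude_m``.
    climate
        ``sar_id, year, temp_c, precip_mm``; averaged over
        ``climate_years`` on ingestion.
    site_sar
        ``site_id, sar_id`` mapping; a site without a mapping raises.
    sar_landuse
        Optional ``sar_id, arable_km2, grassland_km2`` for the SAR-level
        arable/grassland ratio.
    standardise_precipitation
        Divide precipitation by 1000 (metres of rain) so its coefficient
        magnitude is comparable to the other terms; raw mm by default.

    Returns one row per site with CLC proportions, ``shannon``,
    ``altitude_m``, ``mean_temperature``, ``annual_precipitation``,
    ``arable_grassland_ratio`` and ``sar_id``; sites missing climate are
    flagged via NaN and a log message.
    """
    props = clc_proportions(clc_areas, site_area)
    out = props.copy()
    out["shannon"] = [shannon_diversity(row) if row.sum() > 0 else np.nan
                      for row in props.to_numpy()]

    alt = altitude.set_index("site_id")["altitude_m"]
    out = out.join(alt, how="left")

    mapping = site_sar.set_index("site_id")["sar_id"]
    unmapped = out.index.difference(mapping.index)
    if len(unmapped):
        raise ValueError(f"sites without SAR mapping: {list(unmapped)[:5]}")
    out["sar_id"] = mapping.reindex(out.index)

    clim = (
        climate[climate["year"].isin(list(climate_years))]
        .groupby("sar_id")[["temp_c", "precip_mm"]]
        .mean()
        .rename(columns={"temp_c": "mean_temperature", "precip_mm": "annual_precipitation"})
    )
    if standardise_precipitation:
        clim["annual_precipitation"] = clim["annual_precipitation"] / 1000.0
    out = out.join(clim, on="sar_id")
    missing_climate = out["mean_temperature"].isna()
    if missing_climate.any():
        logger.warning("%d site(s) lack climate for their SAR; flagged NaN",
                       int(missing_climate.sum()))

    if sar_landuse is not None:
        lu = sar_landuse.set_index("sar_id")
        ratio = pd.Series(
            [arable_grassland_ratio(a, g) for a, g in zip(lu["arable_km2"], lu["grassland_km2"])],
            index=lu.index, name="arable_grassland_ratio",
        )
        out = out.join(ratio, on="sar_id")

    return out.sort_index()
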