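"""Breeding-bird-survey count aggregation and community descriptors.

The survey design is the French Breeding Bird Survey (FBBS) one: 2 × 2 km
squares holding ten point counts, each visited twice per spring; the
observer records every contact.  The aggregation chain implemented here is

1. keep only squares with at least five farmland point counts and select
   exactly five of them (at random, seeded, when there are more);
2. per point × species × year, take the maximum of the two visit counts;
3. sum the five point maxima into a yearly square-level relative abundance;
4. average across the surveyed years;
5. summarise each square's community with four descriptors: species
   richness and the abundance-weighted community means CSI, CTI and CSIg
   of the species-level indices SSI, STI and SSIg.

Input tables are plain :class:`pandas.DataFrame` objects with columns
``site_id, point_id, visit, year, species_id, count, habitat_class``
(and optionally ``subhabitat``), one row per point-count contact
aggregate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .species_traits import HABITAT_CLASSES, load_species_table

__all__ = [
    "filter_and_select_points",
    "visit_max",
    "site_year_abundance",
    "multi_year_mean",
    "species_richness",
    "community_index",
    "compute_descriptors",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ("site_id", "point_id", "visit", "year", "species_id", "count", "habitat_class")

N_SELECTED_POINTS = 5


def _validate_records(records: pd.DataFrame) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"point-count table missing columns {missing}")
    if (records["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    bad = set(records["habitat_class"]) - set(HABITAT_CLASSES)
    if bad:
        raise ValueError(f"unknown habitat classes {sorted(bad)}")


def filter_and_select_points(records: pd.DataFrame, seed: int) -> dict[str, list]:
    """Select exactly five farmland points per site; exclude short sites.

    A point's farmland status is taken from its recorded habitat class in
    its first surveyed year.  Sites offering fewer than five farmland
    points are excluded (a normal, logged outcome); sites offering more
    have five drawn uniformly at random with the given seed, once per
    site so the same points serve every year.

    Returns a mapping ``site_id -> sorted list of 5 point_ids`` covering
    only the retained sites.
    """
    _validate_records(records)
    rng = np.random.default_rng(seed)
    selection: dict[str, list] = {}
    # first-year habitat classification governs the farmland status of a point
    first_year = records.sort_values("year").drop_duplicates(["site_id", "point_id"])
    for site_id, grp in first_year.groupby("site_id", sort=True):
        farmland_points = sorted(grp.loc[grp["habitat_class"] == "farmland", "point_id"].unique())
        if len(farmland_points) < N_SELECTED_POINTS:
            logger.info(
                "site %s excluded: %d farmland point(s) < %d",
                site_id, len(farmland_points), N_SELECTED_POINTS,
            )
            continue
        if len(farmland_points) == N_SELECTED_POINTS:
            selection[site_id] = farmland_points
        else:
            chosen = rng.choice(farmland_points, size=N_SELECTED_POINTS, replace=False)
            selection[site_id] = sorted(chosen.tolist())
    return selection


def visit_max(counts: pd.DataFrame) -> pd.DataFrame:
    """Per point × species × year, the maximum count over the two visits.

    A missing visit is treated as a count of 0 (logged), so a species
    seen on one visit only keeps its single count.
    """
    _validate_records(counts)
    n_visits = counts.groupby(["site_id", "point_id", "year"])["visit"].nunique()
    incomplete = int((n_visits < 2).sum())
    if incomplete:
        logger.info("%d point-year(s) have a single recorded visit; missing visit counted as 0", incomplete)
    keys = ["site_id", "point_id", "year", "species_id"]
    out = counts.groupby(keys, as_index=False)["count"].max()
    return out


def site_year_abundance(point_maxima: pd.DataFrame, selection: dict[str, list]) -> pd.DataFrame:
    """Sum per-point visit maxima over each site's five selected points.

    Parameters
    ----------
    point_maxima
        Output of :func:`visit_max`.
    selection
        Output of :func:`filter_and_select_points`.

    Returns a frame with columns ``site_id, year, species_id, abundance``.
    """
    rows = point_maxima[point_maxima["site_id"].isin(selection)]
    keep = pd.Series(
        [p in selection[s] for s, p in zip(rows["site_id"], rows["point_id"])],
        index=rows.index, dtype=bool,
    )
    rows = rows[keep]
    out = (
        rows.groupby(["site_id", "year", "species_id"], as_index=False)["count"]
        .sum()
        .rename(columns={"count": "abundance"})
    )
    return out


def multi_year_mean(yearly: pd.DataFrame) -> pd.DataFrame:
    """Average yearly abundances over the years each site was surveyed.

    The mean runs over surveyed years only, not over a fixed window, so
    squares surveyed once do not contribute diluted values.  Species
    unrecorded in a surveyed year count as 0 for that year.
    """
    out_rows = []
    for site_id, grp in yearly.groupby("site_id", sort=True):
        years = sorted(grp["year"].unique())
        wide = (
            grp.pivot_table(index="species_id", columns="year", values="abundance", fill_value=0.0)
            .reindex(columns=years, fill_value=0.0)
        )
        mean_ab = wide.mean(axis=1)
        for species_id, ab in mean_ab.items():
            out_rows.append((site_id, species_id, float(ab), len(years)))
    return pd.DataFrame(out_rows, columns=["site_id", "species_id", "abundance", "n_years"])


def species_richness(abundances) -> int:
    """Number of community species with strictly positive mean abundance."""
    a = np.asarray(abundances, dtype=float)
    return int((a > 0).sum())


def community_index(abundances, trait_values) -> float:
    """Abundance-weighted community mean of a species trait.

    Computes Σ_i (N_i / N_tot) · t_i over the community species.  With the
    SSI, STI and SSIg trait columns this yields the CSI, CTI and CSIg
    community descriptors respectively.

    Returns ``nan`` when the total abundance is zero (descriptor
    undefined; callers flag the site).
    """
    n = np.asarray(abundances, dtype=float)
    t = np.asarray(trait_values, dtype=float)
    if n.shape != t.shape:
        raise ValueError("abundances and trait values must align")
    if np.any(n < 0):
        raise ValueError("abundances must be non-negative")
    total = n.sum()
    if total == 0:
        return float("nan")
    return float((n / total) @ t)


def compute_descriptors(
    records: pd.DataFrame,
    seed: int,
    traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full survey chain: point selection → visit maxima → sums → means → descriptors.

    Parameters
    ----------
    records
        Raw point-count table.
    seed
        Seed for the random five-point selection.
    traits
        Species trait table indexed by ``species_id`` with columns
        ``ssi, sti, ssig``; defaults to the packaged 22-species table.
        Records of species outside the community are ignored with a
        warning.

    Returns
    -------
    pandas.DataFrame
        One row per retained site: ``site_id, richness, csi, cti, csig,
        n_years, undefined`` (``undefined`` is True when the site held no
        community birds and the weighted indices are NaN).
    """
    if traits is None:
        traits = load_species_table(as_frame=True)
    known = records["species_id"].isin(traits.index)
    if not known.all():
        extras = sorted(set(records.loc[~known, "species_id"]))
        logger.warning("ignoring %d non-community species: %s", len(extras), extras[:5])
        records = records[known]

    selection = filter_and_select_points(records, seed)
    maxima = visit_max(records)
    yearly = site_year_abundance(maxima, selection)
    site_ab = multi_year_mean(yearly)

    rows = []
    for site_id in sorted(selection):
        grp = site_ab[site_ab["site_id"] == site_id]
        ab = grp.set_index("species_id")["abundance"].reindex(traits.index, fill_value=0.0)
        n_years = int(grp["n_years"].iloc[0]) if len(grp) else 0
        if n_years == 0:
            logger.info("site %s excluded: no surveyed year", site_id)
            continue
        csi = community_index(ab.values, traits["ssi"].values)
        cti = community_index(ab.values, traits["sti"].values)
        csig = community_index(ab.values, traits["ssig"].values)
        rows.append(
            dict(
                site_id=site_id,
                richness=species_richness(ab.values),
                csi=csi, cti=cti, csig=csig,
                n_years=n_years,
                undefined=bool(np.isnan(csi)),
            )
        )
    return pd.DataFrame(rows)
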