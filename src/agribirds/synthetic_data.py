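"""Synthetic survey, farm-accounting and covariate data.

The generator produces the full input bundle the analysis pipeline
consumes, with the statistical structure the method assumes, so every
stage is testable without the (undeposited) national datasets:

* a rectangular lattice of Small Agricultural Regions (SARs) carrying a
  spatially autocorrelated intensity field (white noise smoothed by
  iterated neighbour averaging, rescaled to a target mean and sd), with
  rook-contiguity edges and centroids;
* farm accounting records whose ratio-of-sums IC/ha reproduces the SAR
  intensity field exactly, category costs Dirichlet-split over the seven
  input categories;
* point-count records for a 22-species farmland bird community on 2 × 2
  km squares of ten points and two spring visits: each species' expected
  site abundance is ``exp(a_s + f_s(X) + g_s·(X̄_nb − μ))`` where ``X``
  is the local SAR intensity, ``X̄_nb`` the mean intensity of contiguous
  neighbour SARs (the same kernel as the aggregation index, so an
  interaction with aggregation can be planted directly), ``f_s`` a
  convex-declining (scaled negative exponential) response for intensity
  "loser" species, a saturating concave-increasing one for "winners", or
  flat; counts are per-point Poisson abundances binomially thinned by
  the per-visit detection probability;
* site covariates (CORINE category areas with the arable share
  correlated to intensity, Shannon-ready), SAR climate and site
  altitude tables.

Defaults mirror the scale of the national study the pipeline targets:
152 SARs (8 × 19 lattice), 332 sites, an intensity field with mean
405.1 €/ha, and the packaged 22-species trait table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import spatial
from .intensity import COST_CATEGORIES, aggregation_index, classify_aggregated
from .species_traits import HABITAT_CLASSES, load_species_table

__all__ = [
    "ScenarioConfig",
    "Landscape",
    "default_species_response",
    "generate_landscape",
    "generate_counts",
    "generate_covariates",
    "generate_interaction_response",
    "generate_scenario",
]

RESPONSE_SHAPES = ("convex_decline", "concave_increase", "flat")


@dataclass
class ScenarioConfig:
    """All knobs of one synthetic scenario; the seed is mandatory.

    The intensity response of species s is
    ``f_s(x) = effect·exp(−x/response_scale)`` (convex decline, losers),
    ``effect·(1 − exp(−x/response_scale))`` (concave increase, winners)
    or 0 (flat); ``response_scale`` of 250 €/ha places the attenuation
    of the effect around the field mean, as in the national gradient.
    """

    seed: int
    rows: int = 8
    cols: int = 19
    intensity_mean: float = 405.1     # €/ha
    intensity_sd: float = 150.0       # €/ha
    smoothing: float = 0.8            # in [0,1]; 0 = white noise
    n_sites: int = 332
    n_farms_per_sar: int = 3
    p_ineligible_farm: float = 0.1    # chance a SAR also holds an excluded-type farm
    farmland_share: float = 0.8       # chance a point count sits in farmland
    detection_prob: float = 0.9       # per-visit detection probability
    years: tuple[int, ...] = (2006, 2007, 2008)
    accounting_years: tuple[int, ...] = (2004, 2005, 2006)
    response_scale: float = 250.0     # €/ha, attenuation scale of f_s
    baseline_log_abundance: float = 0.0
    baseline_log_sd: float = 1.2      # between-species spread of baselines
    loser_effect: float = 1.5
    winner_effect: float = 1.0
    neighbour_effect: float = -1.5e-3  # per €/ha, grassland specialists
    landuse_intensity_corr: float = 0.6
    species_response: pd.DataFrame | None = None  # overrides the trait-derived default

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("lattice dimensions must be positive")
        if not 0.0 <= self.smoothing <= 1.0:
            raise ValueError("smoothing must lie in [0, 1]")
        if not 0.0 < self.detection_prob <= 1.0:
            raise ValueError("detection probability must lie in (0, 1]")
        if not 0.0 <= self.farmland_share <= 1.0:
            raise ValueError("farmland share must lie in [0, 1]")


def default_species_response(cfg: ScenarioConfig) -> pd.DataFrame:
    """Trait-derived response parameters for the packaged community.

    Grassland specialists (SSIg ≥ 2) are intensity losers with a convex
    declining response and carry the neighbourhood-intensity effect;
    arable-leaning species (SSIg < 2) are winners with a saturating
    increasing response.  This reproduces the winner/loser structure the
    community shows along the national intensity gradient.  Baseline
    log-abundances are heterogeneous across species (Gaussian spread
    ``baseline_log_sd``, drawn from the scenario seed), so the community
    holds common and rare species and site richness varies realistically
    instead of saturating at 22.
    """
    traits = load_species_table(as_frame=True)
    rng = np.random.default_rng(cfg.seed + 3)
    baselines = rng.normal(cfg.baseline_log_abundance, cfg.baseline_log_sd,
                           size=len(traits))
    rows = []
    for (sp, tr), a_s in zip(traits.iterrows(), baselines):
        loser = tr["ssig"] >= 2.0
        rows.append(dict(
            species_id=sp,
            baseline=a_s,
            shape="convex_decline" if loser else "concave_increase",
            effect=cfg.loser_effect if loser else cfg.winner_effect,
            neighbour_effect=cfg.neighbour_effect if loser else 0.0,
        ))
    return pd.DataFrame(rows).set_index("species_id")


@dataclass
class Landscape:
    """One realised SAR lattice with intensity, farms, and site placement."""

    sar_ids: list[str]
    edges: list[tuple[str, str]]
    centroids: pd.DataFrame           # sar_id, x_km, y_km
    intensity: pd.Series              # true IC/ha per SAR
    w: np.ndarray                     # contiguity matrix aligned with sar_ids
    farms: pd.DataFrame               # FarmRecord rows
    site_sar: pd.Series               # site_id -> sar_id
    neighbour_mean: pd.Series         # mean intensity of contiguous neighbours

    @property
    def aggregation(self) -> pd.DataFrame:
        """Per-SAR AI and aggregated flag computed from the true field."""
        ai = aggregation_index(self.intensity, self.w, self.sar_ids)
        return pd.DataFrame({"ai": ai, "aggregated": classify_aggregated(ai)})


def _smooth_field(noise: np.ndarray, w: np.ndarray, smoothing: float) -> np.ndarray:
    """Iterated neighbour averaging: x ← (x + neighbour mean) / 2, k times."""
    k = int(round(10 * smoothing))
    x = noise.copy()
    deg = w.sum(axis=1)
    deg[deg == 0] = 1.0
    for _ in range(k):
        x = 0.5 * (x + (w @ x) / deg)
    return x


def generate_landscape(cfg: ScenarioConfig) -> Landscape:
    """SAR lattice, intensity field, contiguity, farm records and site placement."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.rows * cfg.cols
    sar_ids = [f"SAR{idx:03d}" for idx in range(n)]
    int_edges = spatial.lattice_edges(cfg.rows, cfg.cols)
    edges = [(sar_ids[a], sar_ids[b]) for a, b in int_edges]
    w = spatial.build_contiguity(edges, sar_ids)
    # centroids on a 15 km grid: SARs are small regions a few hundred km² each
    xs = np.tile(np.arange(cfg.cols), cfg.rows) * 15.0
    ys = np.repeat(np.arange(cfg.rows), cfg.cols) * 15.0
    centroids = pd.DataFrame({"sar_id": sar_ids, "x_km": xs, "y_km": ys})

    field_ = _smooth_field(rng.standard_normal(n), w, cfg.smoothing)
    field_ = (field_ - field_.mean()) / field_.std()
    intensity = pd.Series(cfg.intensity_mean + cfg.intensity_sd * field_,
                          index=sar_ids, name="ic_per_ha").clip(lower=10.0)

    farms = _generate_farms(cfg, intensity, rng)
    site_sar = _place_sites(cfg, sar_ids, rng)

    deg = w.sum(axis=1)
    nb_mean = pd.Series((w @ intensity.to_numpy()) / np.where(deg > 0, deg, 1.0),
                        index=sar_ids, name="neighbour_mean")
    return Landscape(sar_ids, edges, centroids, intensity, w, farms, site_sar, nb_mean)


def _generate_farms(cfg: ScenarioConfig, intensity: pd.Series,
                    rng: np.random.Generator) -> pd.DataFrame:
    eligible_types = ["industrial_crops", "cereals", "bovine_dairy", "bovine_meat", "mixed"]
    excluded_types = ["vegetables", "granivore_livestock", "wine", "orchards"]
    rows = []
    for sar_id, x in intensity.items():
        for year in cfg.accounting_years:
            areas = rng.uniform(50.0, 150.0, size=cfg.n_farms_per_sar)
            total_cost = x * areas.sum()          # ratio of sums recovers x exactly
            farm_costs = total_cost * areas / areas.sum()
            for f, (area, cost) in enumerate(zip(areas, farm_costs)):
                shares = rng.dirichlet(np.ones(len(COST_CATEGORIES)))
                row = dict(
                    farm_id=f"{sar_id}-F{f}", sar_id=sar_id,
                    production_type=rng.choice(eligible_types),
                    year=year, utilised_area=area,
                )
                row.update({c: cost * s for c, s in zip(COST_CATEGORIES, shares)})
                rows.append(row)
            if rng.random() < cfg.p_ineligible_farm:
                area = rng.uniform(5.0, 30.0)
                cost = rng.uniform(2000.0, 30000.0)
                shares = rng.dirichlet(np.ones(len(COST_CATEGORIES)))
                row = dict(
                    farm_id=f"{sar_id}-X", sar_id=sar_id,
                    production_type=rng.choice(excluded_types),
                    year=year, utilised_area=area,
                )
                row.update({c: cost * s for c, s in zip(COST_CATEGORIES, shares)})
                rows.append(row)
    return pd.DataFrame(rows)


def _place_sites(cfg: ScenarioConfig, sar_ids: list[str],
                 rng: np.random.Generator) -> pd.Series:
    """Every SAR gets at least one site when counts allow; the rest spread uniformly."""
    n_sar = len(sar_ids)
    assignment: list[str] = []
    if cfg.n_sites >= n_sar:
        assignment.extend(sar_ids)
        extra = cfg.n_sites - n_sar
        assignment.extend(rng.choice(sar_ids, size=extra, replace=True))
    else:
        assignment.extend(rng.choice(sar_ids, size=cfg.n_sites, replace=False))
    rng.shuffle(assignment)  # site ids uncorrelated with SAR order
    return pd.Series(assignment, index=[f"S{i:04d}" for i in range(cfg.n_sites)],
                     name="sar_id")


def _response(shape: str, effect: float, x: np.ndarray, scale: float) -> np.ndarray:
    if shape == "convex_decline":
        return effect * np.exp(-x / scale)
    if shape == "concave_increase":
        return effect * (1.0 - np.exp(-x / scale))
    if shape == "flat":
        return np.zeros_like(x)
    raise ValueError(f"unknown response shape {shape!r}; choose from {RESPONSE_SHAPES}")


def generate_counts(cfg: ScenarioConfig, landscape: Landscape) -> pd.DataFrame:
    """Point-count records for every site, point, visit, year and species.

    Each site holds ten points; a point is farmland with probability
    ``farmland_share`` (other habitat classes uniform otherwise), fixed
    across years.  Per farmland-or-not point, species and year, a latent
    abundance N ~ Poisson(λ_s/5) is drawn (five points are summed
    downstream, so the expected site abundance is λ_s) and each of the
    two visits records a Binomial(N, detection_prob) count.  Zero counts
    are omitted from the table, as in real contact records.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    resp = cfg.species_response if cfg.species_response is not None \
        else default_species_response(cfg)
    bad = set(resp["shape"]) - set(RESPONSE_SHAPES)
    if bad:
        raise ValueError(f"unknown response shape(s) {sorted(bad)}")

    x = landscape.intensity[landscape.site_sar].to_numpy()          # per site
    xnb = landscape.neighbour_mean[landscape.site_sar].to_numpy()
    site_ids = landscape.site_sar.index.to_numpy()
    n_sites = len(site_ids)

    # log expected site abundance per species: a + f(x) + g·(neighbour mean − field mean)
    lam = {}
    for sp, pr in resp.iterrows():
        eta = (pr["baseline"]
               + _response(pr["shape"], pr["effect"], x, cfg.response_scale)
               + pr["neighbour_effect"] * (xnb - cfg.intensity_mean))
        lam[sp] = np.exp(eta)

    other_classes = [h for h in HABITAT_CLASSES if h != "farmland"]
    records = []
    for i, site in enumerate(site_ids):
        is_farm = rng.random(10) < cfg.farmland_share
        habitats = np.where(is_farm, "farmland", rng.choice(other_classes, size=10))
        for sp, lam_s in lam.items():
            rate = lam_s[i] / 5.0
            for year in cfg.years:
                n_true = rng.poisson(rate, size=10)
                for visit in (1, 2):
                    if cfg.detection_prob < 1.0:
                        seen = rng.binomial(n_true, cfg.detection_prob)
                    else:
                        seen = n_true
                    for pt in np.nonzero(seen)[0]:
                        records.append((site, int(pt) + 1, visit, year, sp,
                                        int(seen[pt]), habitats[pt]))
    return pd.DataFrame(
        records,
        columns=["site_id", "point_id", "visit", "year", "species_id", "count",
                 "habitat_class"],
    )


def generate_covariates(cfg: ScenarioConfig, landscape: Landscape):
    """Site CLC areas, SAR climate, site altitude and SAR land-use tables.

    The site arable share is a noisy monotone function of SAR intensity
    with target correlation ``landuse_intensity_corr``; pastures take
    most of the remaining farmland area, and small Dirichlet slivers of
    semi-natural categories fill the rest.  Climate and altitude are
    independent of intensity.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    r = cfg.landuse_intensity_corr
    if not -1.0 <= r <= 1.0:
        raise ValueError("landuse_intensity_corr must lie in [-1, 1]")

    x = landscape.intensity
    z_int = (x - x.mean()) / x.std()
    site_ids = landscape.site_sar.index

    z_site = (r * z_int[landscape.site_sar].to_numpy()
              + np.sqrt(max(0.0, 1 - r * r)) * rng.standard_normal(len(site_ids)))
    arable_share = 1.0 / (1.0 + np.exp(-z_site))      # in (0,1)

    clc_rows = []
    area_total = 4.0                                   # km², the 2 × 2 km square
    minor = ["complex_cultivation", "agriculture_natural_vegetation",
             "broad_leaved_forest", "natural_grasslands", "moors_heathland",
             "artificial_surfaces"]
    for site, a_share in zip(site_ids, arable_share):
        farm_area = area_total * rng.uniform(0.6, 0.95)
        arable = farm_area * a_share
        pasture = farm_area - arable
        # part of the non-farm area stays outside the 15 tabulated categories
        # (roads, minor covers), so proportions do not sum exactly to 1
        rest = (area_total - farm_area) * rng.uniform(0.5, 0.9)
        slivers = rng.dirichlet(np.ones(len(minor))) * rest
        clc_rows.append((site, "non_irrigated_arable", arable))
        clc_rows.append((site, "pastures", pasture))
        for cat, a in zip(minor, slivers):
            if a > 1e-6:
                clc_rows.append((site, cat, a))
    clc = pd.DataFrame(clc_rows, columns=["site_id", "category", "area_km2"])

    climate_rows = []
    base_temp = rng.normal(11.0, 1.5, size=len(landscape.sar_ids))
    base_prec = rng.normal(800.0, 120.0, size=len(landscape.sar_ids))
    for (sar, t0, p0) in zip(landscape.sar_ids, base_temp, base_prec):
        for year in cfg.years:
            climate_rows.append((sar, year,
                                 t0 + rng.normal(0.0, 0.3),
                                 max(200.0, p0 + rng.normal(0.0, 50.0))))
    climate = pd.DataFrame(climate_rows, columns=["sar_id", "year", "temp_c", "precip_mm"])

    altitude = pd.DataFrame({
        "site_id": site_ids,
        "altitude_m": np.maximum(0.0, rng.normal(300.0, 150.0, size=len(site_ids))),
    })

    sar_arable = area_total * 25 * (1.0 / (1.0 + np.exp(-(r * z_int.to_numpy()))))
    sar_landuse = pd.DataFrame({
        "sar_id": landscape.sar_ids,
        "arable_km2": sar_arable,
        "grassland_km2": area_total * 25 - sar_arable,
    })
    site_sar = landscape.site_sar.rename_axis("site_id").reset_index()
    return dict(clc_areas=clc, climate=climate, altitude=altitude,
                sar_landuse=sar_landuse, site_sar=site_sar)


def generate_interaction_response(
    landscape: Landscape,
    *,
    intercept: float = 1.779,
    slope: float = -1.165e-3,
    intercept_diff: float = -0.297,
    slope_diff: float = 7.602e-4,
    noise_sd: float = 0.25,
    seed: int = 0,
    response_name: str = "csig",
) -> pd.DataFrame:
    """Site-level response with a planted intensity × aggregation interaction.

    Builds ``y = b0 + b1·X + d0·A + d1·X·A + ε`` per site, where X is the
    site's SAR intensity, A the binary aggregated flag derived from the
    landscape's true field, and ε Gaussian noise.  The defaults plant
    coefficients of the magnitude the national grassland-specialisation
    model exhibits, so recovery tests run at realistic signal-to-noise.

    Returns columns ``site_id, sar_id, ic_per_ha, aggregated,
    <response_name>``; the planted truth travels in ``df.attrs["truth"]``.
    """
    rng = np.random.default_rng(seed)
    agg = landscape.aggregation
    sar = landscape.site_sar
    x = landscape.intensity[sar].to_numpy()
    a = agg["aggregated"].reindex(sar).to_numpy(dtype=float)
    if np.isnan(a).any():
        # isolated SARs have no defined AI; treat their sites as non-aggregated
        a = np.nan_to_num(a)
    y = intercept + slope * x + intercept_diff * a + slope_diff * x * a \
        + rng.normal(0.0, noise_sd, size=len(x))
    out = pd.DataFrame({
        "site_id": sar.index, "sar_id": sar.to_numpy(),
        "ic_per_ha": x, "aggregated": a, response_name: y,
    })
    out.attrs["truth"] = dict(intercept=intercept, slope=slope,
                              intercept_diff=intercept_diff, slope_diff=slope_diff,
                              noise_sd=noise_sd)
    return out


def generate_scenario(cfg: ScenarioConfig, out_dir: str | Path | None = None):
    """Full input bundle: landscape, farm, count and covariate tables.

    With ``out_dir`` set, writes every table as tab-separated text plus a
    ``truth.json`` of the generating parameters, and returns the paths;
    otherwise returns the in-memory objects.
    """
    landscape = generate_landscape(cfg)
    counts = generate_counts(cfg, landscape)
    cov = generate_covariates(cfg, landscape)
    bundle = dict(
        landscape=landscape, counts=counts, **cov,
        edges=pd.DataFrame(landscape.edges, columns=["unit_a", "unit_b"]),
        centroids=landscape.centroids,
        farms=landscape.farms,
    )
    if out_dir is None:
        return bundle
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = dict(
        counts=counts, farms=landscape.farms, edges=bundle["edges"],
        centroids=landscape.centroids, clc_areas=cov["clc_areas"],
        climate=cov["climate"], altitude=cov["altitude"],
        sar_landuse=cov["sar_landuse"], site_sar=cov["site_sar"],
    )
    paths = {}
    for name, tbl in tables.items():
        p = out / f"{name}.tsv"
        tbl.to_csv(p, sep="\t", index=False)
        paths[name] = p
    truth = {k: v for k, v in asdict(cfg).items() if not isinstance(v, pd.DataFrame)}
    truth["true_intensity"] = landscape.intensity.round(6).to_dict()
    (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
    paths["truth"] = out / "truth.json"
    return paths
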