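"""End-to-end analysis pipeline: intensity → spatial → survey → covariates → models.

:func:`run_analysis` operates on in-memory tables (as produced by the
synthetic generator or loaded from disk) and returns every intermediate
and final product; :func:`run_pipeline` is the file-based wrapper used
by the command line, adding validation, output files and a
reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariates import assemble_covariates
from .intensity import (
    ELIGIBLE_PRODUCTION_TYPES,
    aggregation_index,
    classify_aggregated,
    compute_ic_per_ha,
    sar_eligibility,
)
from .models import (
    ModelSpec,
    backward_stepwise,
    fit_interaction_model,
    loo_cv_error,
    residual_diagnostics,
)
from .spatial import build_contiguity
from .survey import compute_descriptors
from .validation import validate_tables

__all__ = ["PipelineConfig", "PipelineError", "run_analysis", "run_pipeline"]

logger = logging.getLogger(__name__)

DESCRIPTORS = ("richness", "csi", "cti", "csig")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """File-based pipeline configuration; flags override the config file."""

    inputs: dict[str, str]            # table kind -> path (see validation.TABLE_SCHEMAS)
    out_dir: str = "agribirds_out"
    seed: int = 0
    spline_df: int = 2
    n_perm: int = 999
    aggregation_rule: str = "abs_mean"
    accounting_years: tuple[int, ...] = (2004, 2005, 2006)
    climate_years: tuple[int, ...] = (2006, 2007, 2008)
    responses: tuple[str, ...] = DESCRIPTORS
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _candidate_terms(data: pd.DataFrame, exclude=()) -> list[str]:
    """Covariate columns usable as linear terms: numeric, complete, non-constant."""
    out = []
    for c in data.columns:
        if c in exclude or not pd.api.types.is_numeric_dtype(data[c]):
            continue
        col = data[c]
        if col.isna().any() or col.nunique() < 2:
            continue
        out.append(c)
    return out


def run_analysis(
    tables: dict[str, pd.DataFrame],
    *,
    seed: int = 0,
    spline_df: int = 2,
    n_perm: int = 999,
    aggregation_rule: str = "abs_mean",
    accounting_years=(2004, 2005, 2006),
    climate_years=(2006, 2007, 2008),
    responses=DESCRIPTORS,
) -> dict:
    """Run every analysis stage on in-memory input tables.

    ``tables`` must hold ``counts, farms, edges, clc_areas, climate,
    altitude, site_sar`` and optionally ``sar_landuse`` (frames with the
    documented columns).  Returns a dict with the SAR intensity table,
    site descriptors, the assembled modelling frame, and per-descriptor
    stepwise fits, interaction fits, LOO-CV errors and residual
    diagnostics.
    """
    # --- intensity stage -------------------------------------------------
    try:
        farms = tables["farms"]
        ic = compute_ic_per_ha(farms, years=accounting_years)
        area_by_type = farms.drop_duplicates(["farm_id", "year"]).groupby("sar_id").apply(
            lambda g: pd.Series({
                "five_type": g.loc[g["production_type"].isin(ELIGIBLE_PRODUCTION_TYPES),
                                   "utilised_area"].sum(),
                "total": g["utilised_area"].sum(),
            }),
            include_groups=False,
        )
        eligible = sar_eligibility(area_by_type["five_type"], area_by_type["total"])
        ic = ic.loc[ic.index.intersection(eligible)]
    except Exception as err:                                   # noqa: BLE001
        raise PipelineError("intensity", err) from err

    # --- spatial stage ---------------------------------------------------
    try:
        edges_tbl = tables["edges"]
        units = sorted(set(edges_tbl["unit_a"]) | set(edges_tbl["unit_b"]) | set(ic.index))
        w = build_contiguity(list(edges_tbl.itertuples(index=False, name=None)), units)
        ai_all = aggregation_index(
            ic.reindex(units), w, units
        ) if ic.reindex(units).notna().all() else None
        if ai_all is None:
            keep = [u for u in units if u in ic.index]
            idx = [units.index(u) for u in keep]
            w_scored = w[np.ix_(idx, idx)]
            ai_all = aggregation_index(ic[keep], w_scored, keep)
            units, w = keep, w_scored
        aggregated = classify_aggregated(ai_all, rule=aggregation_rule)
        sar_table = pd.DataFrame({"ic_per_ha": ic.reindex(units),
                                  "ai": ai_all, "aggregated": aggregated})
        sar_table.index.name = "sar_id"
    except Exception as err:                                   # noqa: BLE001
        raise PipelineError("spatial", err) from err

    # --- survey stage ----------------------------------------------------
    try:
        descriptors = compute_descriptors(tables["counts"], seed=seed)
    except Exception as err:                                   # noqa: BLE001
        raise PipelineError("survey", err) from err

    # --- covariates stage ------------------------------------------------
    try:
        cov = assemble_covariates(
            tables["clc_areas"], tables["altitude"], tables["climate"],
            tables["site_sar"], tables.get("sar_landuse"),
            climate_years=climate_years,
        )
    except Exception as err:                                   # noqa: BLE001
        raise PipelineError("covariates", err) from err

    # --- modelling stage -------------------------------------------------
    try:
        data = descriptors.set_index("site_id").join(cov, how="inner")
        data = data.join(sar_table[["ic_per_ha", "ai"]], on="sar_id")
        data["aggregated"] = sar_table["aggregated"].reindex(
            data["sar_id"]).to_numpy(dtype=float)
        data = data.dropna(subset=["ic_per_ha"])
        site_sar_map = data["sar_id"]

        exclude = set(DESCRIPTORS) | {"sar_id", "n_years", "undefined", "ai", "aggregated",
                                      "ic_per_ha"}
        linear = tuple(_candidate_terms(data, exclude=exclude))
        fits, interactions, cv_errors, diagnostics = {}, {}, {}, {}
        for resp in responses:
            model_data = data.dropna(subset=[resp])
            spec = ModelSpec(
                response=resp,
                smooth_terms=(("ic_per_ha", spline_df),),
                linear_terms=linear,
                always_keep=frozenset({"s(ic_per_ha)"}),
            )
            fit = backward_stepwise(spec, model_data)
            fits[resp] = fit
            cv_errors[resp] = loo_cv_error(spec, model_data, terms=list(fit.terms))
            diagnostics[resp] = residual_diagnostics(
                fit, site_sar_map.reindex(model_data.index), w, units,
                n_perm=n_perm, seed=seed,
            )
            int_data = model_data.dropna(subset=["aggregated"])
            int_spec = ModelSpec(
                response=resp,
                linear_terms=linear,
                interaction_terms=(("ic_per_ha", "aggregated"),),
                always_keep=frozenset({"ic_per_ha:aggregated"}),
            )
            interactions[resp] = backward_stepwise(int_spec, int_data)
    except PipelineError:
        raise
    except Exception as err:                                   # noqa: BLE001
        raise PipelineError("models", err) from err

    return dict(
        sar_table=sar_table, descriptors=descriptors, covariates=cov, data=data,
        fits=fits, interactions=interactions, cv_errors=cv_errors,
        diagnostics=diagnostics, w=w, units=units,
    )


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Validate inputs, run the analysis, and write the output bundle.

    Output files: ``sar_intensity.tsv``, ``descriptors.tsv``,
    ``fit_<response>.tsv`` and ``interaction_<response>.tsv`` (term,
    estimate, SE, statistic, p; AIC and CV error in the header comment),
    ``diagnostics.tsv``, ``selection_log.txt`` and ``manifest.json``
    (config, hash, seed, package versions).  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    logging.basicConfig(level=cfg.log_level)
    missing = [k for k, p in cfg.inputs.items() if not Path(p).exists()]
    if missing:
        raise PipelineError("inputs", FileNotFoundError(
            f"missing input table(s): {missing}"))
    report = validate_tables(cfg.inputs)
    if not report.ok:
        raise PipelineError("validation", ValueError(str(report)))

    tables = {k: pd.read_csv(p, sep="\t") for k, p in cfg.inputs.items()}
    result = run_analysis(
        tables, seed=cfg.seed, spline_df=cfg.spline_df, n_perm=cfg.n_perm,
        aggregation_rule=cfg.aggregation_rule, accounting_years=cfg.accounting_years,
        climate_years=cfg.climate_years, responses=cfg.responses,
    )

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    chash = cfg.config_hash()

    def _write(name: str, frame: pd.DataFrame, extra: str = "") -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# config_hash={chash}{extra}\n")
            frame.to_csv(fh, sep="\t", index=False)
        written[name] = path

    _write("sar_intensity.tsv", result["sar_table"].reset_index())
    _write("descriptors.tsv", result["descriptors"])
    log_lines = []
    for resp in cfg.responses:
        fit = result["fits"][resp]
        extra = f" aic={fit.aic:.3f} cv_error_pct={result['cv_errors'][resp]:.3f}"
        _write(f"fit_{resp}.tsv", fit.summary_frame(), extra)
        ifit = result["interactions"][resp]
        _write(f"interaction_{resp}.tsv", ifit.summary_frame(), f" aic={ifit.aic:.3f}")
        log_lines.append(f"[{resp}] " + "; ".join(fit.selection_path))
        log_lines.append(f"[{resp} interaction] " + "; ".join(ifit.selection_path))
    diag_rows = [
        dict(response=r, **{k: getattr(d, k) for k in
                            ("shapiro_w", "shapiro_p", "breusch_pagan_lm",
                             "breusch_pagan_p", "moran_i", "moran_p", "n_sar")})
        for r, d in result["diagnostics"].items()
    ]
    _write("diagnostics.tsv", pd.DataFrame(diag_rows))
    (out / "selection_log.txt").write_text("\n".join(log_lines) + "\n")
    written["selection_log.txt"] = out / "selection_log.txt"

    manifest = dict(config=asdict(cfg), config_hash=chash,
                    versions=dict(agribirds=__version__,
                                  numpy=np.__version__, pandas=pd.__version__))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    written["manifest.json"] = out / "manifest.json"
    return written
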