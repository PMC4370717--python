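"""Regression models for the bird-community / intensity analysis.

Two model families are fitted to the site-level descriptor table:

* a Gaussian additive model in which the intensity indicator enters as
  an unpenalised natural-cubic regression spline with a fixed, small
  number of degrees of freedom (default 2), alongside linear land-use,
  climate and altitude terms::

      descriptor ~ s(IC/ha, df=2) + altitude + land use + climate

  Fixing the spline df removes smoothing-parameter estimation entirely,
  so the model is an ordinary least-squares fit on an augmented design
  matrix — a deliberate simplification that keeps every downstream
  quantity (AIC, F-tests, leave-one-out residuals) exact.

* a Gaussian linear model with an intensity × aggregation interaction::

      descriptor ~ IC/ha * aggregated + other covariates

  where ``aggregated`` is the binary SAR classification (0 =
  non-aggregated baseline, 1 = aggregated); the interaction coefficients
  are the differences in intercept and slope between the two groups.

Model selection is backward stepwise on AIC over whole term blocks
(a spline's columns, or an interaction with its hierarchy, are dropped
together); focal terms can be protected from dropping.  Predictive
ability is summarised by the leave-one-out cross-validation error as a
percentage of the mean observed value, and residuals are screened for
non-normality, heteroscedasticity and spatial autocorrelation between
adjacent agricultural regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .spatial import morans_i_permutation_test

__all__ = [
    "ModelSpec",
    "FitResult",
    "DiagnosticReport",
    "spline_basis",
    "build_design",
    "fit_model",
    "backward_stepwise",
    "loo_cv_error",
    "fit_interaction_model",
    "residual_diagnostics",
]

logger = logging.getLogger(__name__)


def spline_basis(x, df: int) -> np.ndarray:
    """Unpenalised natural-cubic regression spline basis with ``df`` columns.

    The construction is the classical truncated-power natural spline:
    ``df + 1`` knots ξ₁ < … < ξ_K at evenly spaced quantiles of ``x``
    (boundary knots at the extremes), basis functions N₁(x) = x and
    N_{k+1}(x) = d_k(x) − d_{K−1}(x) with
    ``d_k(x) = [(x−ξ_k)₊³ − (x−ξ_K)₊³] / (ξ_K − ξ_k)``, giving exactly
    ``df`` columns, linear beyond the boundary knots.  Columns are
    centred so the basis carries no intercept.  ``df=1`` degenerates to
    a single centred linear column, collapsing the smooth term onto an
    ordinary linear one.  Because the knots are quantiles, the spanned
    function space is affine-equivariant: rescaling ``x`` changes the
    columns but not the fitted values of any downstream regression.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if np.unique(x).size < df + 2:
        raise ValueError(f"need at least {df + 2} distinct x values for df={df}")
    if df == 1:
        basis = x[:, None].astype(float)
    else:
        knots = np.quantile(np.unique(x), np.linspace(0.0, 1.0, df + 1))
        xi_k_last = knots[-1]

        def d(k: int) -> np.ndarray:
            num = np.clip(x - knots[k], 0.0, None) ** 3 \
                - np.clip(x - xi_k_last, 0.0, None) ** 3
            return num / (xi_k_last - knots[k])

        d_last = d(df - 1)                      # d_{K-1}, K = df + 1
        cols = [x] + [d(k) - d_last for k in range(df - 1)]
        basis = np.column_stack(cols)
    if basis.shape[1] != df:
        raise RuntimeError(f"basis has {basis.shape[1]} columns, expected {df}")
    return basis - basis.mean(axis=0)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one candidate model.

    ``smooth_terms`` are (variable, df) pairs; ``interaction_terms`` are
    (variable, binary factor) pairs whose main effects are added
    automatically (hierarchy).  ``always_keep`` terms survive stepwise
    selection; interaction hierarchy is enforced on top of it.
    """

    response: str
    smooth_terms: tuple[tuple[str, int], ...] = ()
    linear_terms: tuple[str, ...] = ()
    interaction_terms: tuple[tuple[str, str], ...] = ()
    always_keep: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for var, df in self.smooth_terms:
            if int(df) != df or df < 1:
                raise ValueError(f"smooth df must be a positive integer, got {df} for {var}")

    def term_names(self) -> list[str]:
        names = [f"s({v})" for v, _ in self.smooth_terms]
        names += list(self.linear_terms)
        for var, fac in self.interaction_terms:
            for t in (var, fac, f"{var}:{fac}"):
                if t not in names:
                    names.append(t)
        return names


@dataclass
class FitResult:
    """One fitted Gaussian model: estimates, per-term tests, AIC, residuals."""

    spec: ModelSpec
    terms: tuple[str, ...]                    # term blocks present, in design order
    params: pd.Series                         # per-column estimates (incl. intercept)
    bse: pd.Series                            # per-column standard errors
    term_tests: pd.DataFrame                  # term, statistic ('t'|'F'), value, p
    aic: float
    fittedvalues: np.ndarray
    resid: np.ndarray
    nobs: int
    design: pd.DataFrame = field(repr=False)  # full design matrix incl. intercept
    y: np.ndarray = field(repr=False)
    blocks: dict[str, list[str]] = field(repr=False)  # term -> design columns
    selection_path: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        """Tabular report: term, estimate, SE, statistic, p (spline blocks report F)."""
        rows = []
        for _, r in self.term_tests.iterrows():
            cols = self.blocks.get(r["term"], [r["term"]])
            est = self.params[cols[0]] if len(cols) == 1 else np.nan
            se = self.bse[cols[0]] if len(cols) == 1 else np.nan
            rows.append((r["term"], est, se, r["statistic"], r["value"], r["p"]))
        return pd.DataFrame(rows, columns=["term", "estimate", "se", "statistic", "value", "p"])


def build_design(spec: ModelSpec, data: pd.DataFrame, terms=None):
    """Design matrix (with intercept) and term → column map for ``spec``.

    ``terms`` restricts to a subset of the spec's term blocks (used by
    stepwise selection); smooth bases are always rebuilt from the rows
    of ``data`` actually supplied.
    """
    wanted = list(terms) if terms is not None else spec.term_names()
    cols: dict[str, np.ndarray] = {}
    blocks: dict[str, list[str]] = {}
    smooth_df = dict(spec.smooth_terms)
    for term in wanted:
        if term.startswith("s(") and term.endswith(")"):
            var = term[2:-1]
            basis = spline_basis(data[var].to_numpy(), smooth_df[var])
            names = [f"{term}[{k}]" for k in range(basis.shape[1])]
            for nm, col in zip(names, basis.T):
                cols[nm] = col
            blocks[term] = names
        elif ":" in term:
            a, b = term.split(":", 1)
            cols[term] = data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float)
            blocks[term] = [term]
        else:
            cols[term] = data[term].to_numpy(dtype=float)
            blocks[term] = [term]
    X = pd.DataFrame(cols, index=data.index)
    X.insert(0, "Intercept", 1.0)
    return X, blocks


def _fit(spec: ModelSpec, data: pd.DataFrame, terms=None) -> FitResult:
    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values; supply complete cases")
    X, blocks = build_design(spec, data, terms)
    if np.isnan(X.to_numpy()).any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"design contains missing values in {bad}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design ({rank} < {X.shape[1]}); "
                         f"check collinearity among {list(X.columns)}")
    res = sm.OLS(y, X).fit()
    tests = []
    for term, colnames in blocks.items():
        if len(colnames) == 1:
            c = colnames[0]
            tests.append((term, "t", float(res.tvalues[c]), float(res.pvalues[c])))
        else:
            # F-test of the whole basis block against the model without it
            R = np.zeros((len(colnames), X.shape[1]))
            for k, c in enumerate(colnames):
                R[k, X.columns.get_loc(c)] = 1.0
            ft = res.f_test(R)
            tests.append((term, "F", float(ft.fvalue), float(ft.pvalue)))
    return FitResult(
        spec=spec,
        terms=tuple(blocks),
        params=res.params,
        bse=res.bse,
        term_tests=pd.DataFrame(tests, columns=["term", "statistic", "value", "p"]),
        aic=float(res.aic),
        fittedvalues=np.asarray(res.fittedvalues),
        resid=np.asarray(res.resid),
        nobs=int(res.nobs),
        design=X,
        y=y,
        blocks=blocks,
    )


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit the Gaussian identity-link model described by ``spec``.

    Smooth terms are tested with an F-test of their whole basis block;
    single-column terms with t-tests.  ``fittedvalues + resid`` equals
    the observed response exactly.
    """
    return _fit(spec, data)


def _droppable(terms: list[str], spec: ModelSpec) -> list[str]:
    """Terms eligible for removal: not protected, not a main effect of a present interaction."""
    protected = set(spec.always_keep)
    for t in terms:
        if ":" in t:
            a, b = t.split(":", 1)
            protected.update((a, b))
    return [t for t in terms if t not in protected]


def backward_stepwise(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Backward stepwise selection on AIC over whole term blocks.

    Starting from the maximal model, repeatedly drops the single term
    whose removal lowers AIC the most, until no removal lowers it.
    Spline and interaction blocks leave as a unit; terms in
    ``spec.always_keep`` and main effects of a retained interaction are
    never dropped.  The drop sequence is recorded on
    ``FitResult.selection_path``.
    """
    terms = spec.term_names()
    current = _fit(spec, data, terms)
    path = [f"start AIC={current.aic:.3f} terms={terms}"]
    while True:
        best: FitResult | None = None
        best_term = None
        for t in _droppable(terms, spec):
            reduced = [u for u in terms if u != t]
            cand = _fit(spec, data, reduced)
            if best is None or cand.aic < best.aic:
                best, best_term = cand, t
        if best is None or best.aic >= current.aic:
            break
        terms = [u for u in terms if u != best_term]
        current = best
        path.append(f"drop {best_term} -> AIC={current.aic:.3f}")
    current.selection_path = path
    logger.info("stepwise selection: %s", "; ".join(path))
    return current


def loo_cv_error(spec: ModelSpec, data: pd.DataFrame, *, method: str = "mean_ratio",
                 terms=None) -> float:
    """Leave-one-out cross-validation error, in percent.

    Each observation is predicted from a refit on the remaining n−1
    rows (design matrix held fixed, so for these linear-in-parameters
    models the LOO residual equals e_i/(1−h_ii)).

    ``method='mean_ratio'`` (default): mean |ŷ₍₋ᵢ₎ − yᵢ| divided by the
    mean observed value, × 100.  ``method='per_obs'``: mean of the
    per-observation percentage errors |ŷ₍₋ᵢ₎ − yᵢ|/|yᵢ| × 100.
    """
    y = data[spec.response].to_numpy(dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 observations for LOO-CV")
    X, _ = build_design(spec, data, terms)
    Xv = X.to_numpy()
    n = len(y)
    loo_pred = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        beta, *_ = np.linalg.lstsq(Xv[mask], y[mask], rcond=None)
        loo_pred[i] = Xv[i] @ beta
        mask[i] = True
    abs_err = np.abs(loo_pred - y)
    if method == "mean_ratio":
        ybar = y.mean()
        if ybar == 0:
            raise ValueError("mean observed value is zero; percentage error undefined")
        return float(abs_err.mean() / abs(ybar) * 100.0)
    if method == "per_obs":
        if np.any(y == 0):
            raise ValueError("zero observed values; per-observation percentage undefined")
        return float(np.mean(abs_err / np.abs(y)) * 100.0)
    raise ValueError(f"unknown method {method!r}")


def fit_interaction_model(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit a linear model with an intensity × aggregation interaction.

    ``spec.interaction_terms`` must name at least one (variable, factor)
    pair; the factor must be binary with both levels present.  The
    factor's main-effect coefficient is the intercept difference and the
    product term's the slope difference for the factor-1 group relative
    to the factor-0 baseline.
    """
    if not spec.interaction_terms:
        raise ValueError("spec has no interaction term")
    for _, fac in spec.interaction_terms:
        levels = np.unique(data[fac].to_numpy(dtype=float))
        if not np.array_equal(levels, [0.0, 1.0]):
            raise ValueError(f"factor {fac!r} must take both values 0 and 1, got {levels}")
    return _fit(spec, data)


@dataclass
class DiagnosticReport:
    """Residual screening: normality, homoscedasticity, spatial autocorrelation."""

    shapiro_w: float
    shapiro_p: float
    breusch_pagan_lm: float
    breusch_pagan_p: float
    moran_i: float
    moran_p: float
    n_sar: int
    alpha: float = 0.05

    @property
    def flags(self) -> dict[str, bool]:
        """True where the corresponding assumption is rejected at ``alpha``."""
        return {
            "non_normal": self.shapiro_p < self.alpha,
            "heteroscedastic": self.breusch_pagan_p < self.alpha,
            "spatially_autocorrelated": self.moran_p < self.alpha,
        }


def residual_diagnostics(
    fit: FitResult,
    site_sar: pd.Series,
    w: np.ndarray,
    sar_ids,
    *,
    n_perm: int = 999,
    seed: int | None = None,
) -> DiagnosticReport:
    """Residual checks for a fitted model.

    Shapiro–Wilk tests residual normality and Breusch–Pagan (residuals
    against the model's own design) tests homoscedasticity; both are
    report-only.  Spatial autocorrelation between adjacent agricultural
    regions is assessed by averaging site residuals within each SAR and
    running the Moran's I permutation test on the SAR means under the
    contiguity matrix ``w`` (aligned with ``sar_ids``); SARs without
    sites are excluded along with their matrix rows.
    """
    from statsmodels.stats.diagnostic import het_breuschpagan

    resid = fit.resid
    degenerate = np.allclose(resid, resid[0])
    if degenerate:
        logger.warning("residuals are (numerically) constant; diagnostics undefined")
        sw = type("SW", (), {"statistic": np.nan, "pvalue": np.nan})
        bp_lm = bp_p = np.nan
    else:
        sw = stats.shapiro(resid)
        bp_lm, bp_p, _, _ = het_breuschpagan(resid, fit.design.to_numpy())

    sar_resid = pd.Series(resid, index=fit.design.index).groupby(
        site_sar.reindex(fit.design.index)
    ).mean()
    sar_ids = list(sar_ids)
    present = [i for i, s in enumerate(sar_ids) if s in sar_resid.index]
    if len(present) < 2 or degenerate:
        i_obs, p = np.nan, np.nan
    else:
        w_sub = np.asarray(w, dtype=float)[np.ix_(present, present)]
        values = sar_resid.reindex([sar_ids[i] for i in present]).to_numpy()
        i_obs, p = morans_i_permutation_test(values, w_sub, n_perm=n_perm, seed=seed)
    return DiagnosticReport(
        shapiro_w=float(sw.statistic), shapiro_p=float(sw.pvalue),
        breusch_pagan_lm=float(bp_lm), breusch_pagan_p=float(bp_p),
        moran_i=float(i_obs), moran_p=float(p), n_sar=len(present),
    )
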