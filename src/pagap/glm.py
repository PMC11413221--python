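"""GLMs of per-PA threat composition and species richness.

Two model families over the per-PA covariate table:

* a binomial (logit) GLM for the proportion of a PA's species that are
  threatened, by default weighted by richness — the outcome is the pair
  (threatened count, non-threatened count), which gives a coherent binomial
  likelihood; an unweighted mode regressing the raw proportion is available;
* a negative-binomial (log link, NB2) GLM for species richness with the
  dispersion parameter theta estimated jointly by maximum likelihood.

Model selection is by AIC over a candidate suite including the null
(intercept-only) model, with McFadden's pseudo-R^2
(1 - logLik(model)/logLik(null)) reported per fit.  AIC counts theta as an
estimated parameter for the negative-binomial family.

Fitting is delegated to statsmodels; this module owns the design-matrix
construction (dummy coding with the most frequent category as reference,
products for two-way interactions), the marginality rules, and the
degenerate-input contracts.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

NUMERIC_TERMS = ("abs_latitude_deg", "ln_area", "year")
CATEGORY_TERM = "category"
ALL_TERMS = NUMERIC_TERMS + (CATEGORY_TERM,)

#: Management-category labels excluded from model fitting.
EXCLUDED_CATEGORIES = frozenset({"Not Applicable", "Not Assigned", "Not Reported"})

#: Interactions retained in the canonical candidate suite.
SUITE_INTERACTIONS = (("abs_latitude_deg", "ln_area"), ("ln_area", "year"))


class GLMConvergenceError(RuntimeError):
    """Fit failed to converge (separation, divergence, degenerate data)."""


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: response, main effects, two-way interactions.

    Marginality is enforced: an interaction may appear only when both of its
    main effects do.
    """

    response: str  # "prop_threatened" or "richness"
    terms: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.response not in {"prop_threatened", "richness"}:
            raise ValueError(f"unknown response {self.response!r}")
        for t in self.terms:
            if t not in ALL_TERMS:
                raise ValueError(f"unknown term {t!r}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms")
        for a, b in self.interactions:
            if a not in self.terms or b not in self.terms:
                raise ValueError(
                    f"interaction {a}:{b} violates marginality "
                    f"(both main effects must be present)"
                )

    @property
    def family(self) -> str:
        return "binomial" if self.response == "prop_threatened" else "negative-binomial"

    @property
    def is_null(self) -> bool:
        return not self.terms and not self.interactions

    def label(self) -> str:
        rhs = list(self.terms) + [f"{a}:{b}" for a, b in self.interactions]
        return f"{self.response} ~ " + (" + ".join(rhs) if rhs else "1")


@dataclass
class GLMFit:
    """A fitted GLM: coefficients, fit statistics, dispersion."""

    spec: ModelSpec
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    log_likelihood: float
    aic: float
    mcfadden_r2: float
    dispersion_theta: float | None = None
    n_obs: int = 0
    k_params: int = 0
    warnings_: list[str] = field(default_factory=list)


def prepare_model_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Rows eligible for model fitting.

    Drops PAs with zero richness (proportion undefined), PAs whose
    management category is in :data:`EXCLUDED_CATEGORIES`, and rows with
    missing covariates.
    """
    df = table.copy()
    df = df[df["richness"] > 0]
    df = df[~df["category"].isin(EXCLUDED_CATEGORIES)]
    needed = ["richness", "n_threatened", "abs_latitude_deg", "ln_area", "year",
              "category"]
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    return df.reset_index(drop=True)


def _dummy_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code ``category`` with the most frequent level as reference."""
    counts = frame[CATEGORY_TERM].value_counts()
    reference = counts.index[0]
    levels = [lvl for lvl in counts.index if lvl != reference]
    out = pd.DataFrame(index=frame.index)
    for lvl in levels:
        out[f"category[{lvl}]"] = (frame[CATEGORY_TERM] == lvl).astype(float)
    return out


def build_design(frame: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix for a model spec: intercept, mains, interaction products."""
    cols: dict[str, pd.Series | np.ndarray] = {
        "Intercept": np.ones(len(frame))
    }
    blocks: dict[str, pd.DataFrame] = {}
    for t in spec.terms:
        if t == CATEGORY_TERM:
            blocks[t] = _dummy_columns(frame)
            for c in blocks[t]:
                cols[c] = blocks[t][c]
        else:
            cols[t] = frame[t].astype(float)
    for a, b in spec.interactions:
        a_cols = blocks[a] if a == CATEGORY_TERM else frame[[a]].astype(float)
        b_cols = blocks[b] if b == CATEGORY_TERM else frame[[b]].astype(float)
        for ca in a_cols:
            for cb in b_cols:
                name = f"{ca if ca != a else a}:{cb if cb != b else b}"
                cols[name] = np.asarray(a_cols[ca]) * np.asarray(b_cols[cb])
    return pd.DataFrame(cols, index=frame.index)


def _as_fit(spec, params, bse, llf, llnull, aic, n, k, theta=None, warns=()):
    r2 = 1.0 - llf / llnull if llnull != 0 else 0.0
    if -1e-8 < r2 < 0.0:
        r2 = 0.0
    return GLMFit(
        spec=spec,
        coefficients={k_: float(v) for k_, v in params.items()},
        std_errors={k_: float(v) for k_, v in bse.items()},
        log_likelihood=float(llf),
        aic=float(aic),
        mcfadden_r2=float(r2),
        dispersion_theta=theta,
        n_obs=int(n),
        k_params=int(k),
        warnings_=list(warns),
    )


def fit_binomial_glm(
    table: pd.DataFrame, spec: ModelSpec, weighted: bool = True
) -> GLMFit:
    """Fit the logit-link binomial GLM of proportion threatened.

    ``weighted=True`` (default) models (n_threatened, richness - n_threatened)
    as binomial counts; ``weighted=False`` regresses the bare proportion.
    Raises :class:`GLMConvergenceError` on separation or non-convergence.
    """
    if spec.family != "binomial":
        raise ValueError("spec is not a binomial model")
    frame = prepare_model_frame(table)
    if frame.empty:
        raise GLMConvergenceError("no eligible rows after filtering")
    exog = build_design(frame, spec)
    if weighted:
        endog = np.column_stack(
            [frame["n_threatened"], frame["richness"] - frame["n_threatened"]]
        ).astype(float)
    else:
        endog = frame["prop_threatened"].to_numpy(dtype=float)

    def _fit(x):
        model = sm.GLM(endog, x, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(maxiter=200)

    try:
        res = _fit(exog)
    except PerfectSeparationError as exc:
        raise GLMConvergenceError(f"perfect separation: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise GLMConvergenceError(
            f"non-finite coefficients after {res.fit_history['iteration']} "
            "IRLS iterations"
        )
    null_res = _fit(pd.DataFrame({"Intercept": np.ones(len(frame))},
                                 index=frame.index))
    return _as_fit(
        spec,
        dict(zip(exog.columns, res.params)),
        dict(zip(exog.columns, res.bse)),
        res.llf,
        null_res.llf,
        res.aic,
        len(frame),
        exog.shape[1],
    )


def _fit_negbin_mle(endog: np.ndarray, exog: pd.DataFrame):
    """NB2 MLE with Poisson-warm-started parameters."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        poisson = sm.GLM(endog, exog, family=sm.families.Poisson()).fit(maxiter=100)
        start = np.append(poisson.params, 0.1)
        model = NegativeBinomial(endog, exog, loglike_method="nb2")
        res = model.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
        if not np.all(np.isfinite(res.params)):
            res = model.fit(start_params=start, method="nm", maxiter=5000, disp=0)
    return res


def fit_negbin_glm(table: pd.DataFrame, spec: ModelSpec) -> GLMFit:
    """Fit the log-link negative-binomial GLM of species richness.

    Coefficients and the dispersion theta (= 1/alpha in NB2 notation) are
    estimated jointly; AIC counts theta as a parameter.  Equidispersed data
    drive theta toward infinity: the fit is returned with a warning recorded
    and theta reported as the (large) estimate.  Zero-variance counts raise
    :class:`GLMConvergenceError`.
    """
    if spec.family != "negative-binomial":
        raise ValueError("spec is not a negative-binomial model")
    frame = prepare_model_frame(table)
    if frame.empty:
        raise GLMConvergenceError("no eligible rows after filtering")
    endog = frame["richness"].to_numpy(dtype=float)
    if np.ptp(endog) == 0.0:
        raise GLMConvergenceError("zero-variance counts: dispersion unidentifiable")
    exog = build_design(frame, spec)

    res = _fit_negbin_mle(endog, exog)
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(params)):
        raise GLMConvergenceError(
            f"negative-binomial MLE did not converge for {spec.label()!r}"
        )
    alpha = float(params[-1])
    warns = []
    if alpha < 1e-6:
        alpha = max(alpha, 1e-12)
        warns.append(
            "dispersion alpha ~ 0 (equidispersion): theta estimate diverges; "
            "counts are consistent with a Poisson model"
        )
        logger.warning("%s: %s", spec.label(), warns[-1])
    theta = 1.0 / alpha

    null_res = _fit_negbin_mle(
        endog, pd.DataFrame({"Intercept": np.ones(len(frame))}, index=frame.index)
    )
    k = exog.shape[1] + 1  # + theta
    aic = 2.0 * k - 2.0 * float(res.llf)
    names = list(exog.columns)
    return _as_fit(
        spec,
        dict(zip(names, params[:-1])),
        dict(zip(names, bse[:-1])),
        res.llf,
        null_res.llf,
        aic,
        len(frame),
        k,
        theta=theta,
        warns=warns,
    )


def fit_model(table: pd.DataFrame, spec: ModelSpec, **kwargs) -> GLMFit:
    """Dispatch to the family-appropriate fitter."""
    if spec.family == "binomial":
        return fit_binomial_glm(table, spec, **kwargs)
    return fit_negbin_glm(table, spec)


def candidate_suite(response: str) -> list[ModelSpec]:
    """The canonical candidate suite for AIC selection.

    Every marginality-respecting subset of the four covariates, optionally
    augmented with the latitude x ln(area) and ln(area) x year interactions
    when their main effects are present; the null model is included.
    """
    specs = []
    for r in range(len(ALL_TERMS) + 1):
        for terms in itertools.combinations(ALL_TERMS, r):
            allowed = [
                i for i in SUITE_INTERACTIONS if i[0] in terms and i[1] in terms
            ]
            for k in range(len(allowed) + 1):
                for inter in itertools.combinations(allowed, k):
                    specs.append(
                        ModelSpec(response=response, terms=terms,
                                  interactions=inter)
                    )
    return specs


def select_model(
    table: pd.DataFrame, candidate_specs: list[ModelSpec], **fit_kwargs
) -> tuple[GLMFit, pd.DataFrame]:
    """Fit every candidate; return the minimum-AIC fit and the full ranking.

    The candidate list must contain the null model.  Candidates that fail to
    fit are recorded in the ranking with their error and excluded from the
    minimum.  The ranking table has one row per candidate with k, logLik,
    AIC, delta-AIC (vs the best) and McFadden pseudo-R^2.
    """
    if not any(s.is_null for s in candidate_specs):
        raise ValueError("candidate suite must include the null model")
    rows = []
    fits: dict[int, GLMFit] = {}
    for i, spec in enumerate(candidate_specs):
        try:
            fit = fit_model(table, spec, **fit_kwargs)
        except (GLMConvergenceError, np.linalg.LinAlgError) as exc:
            rows.append(
                {"model": spec.label(), "k": np.nan, "log_likelihood": np.nan,
                 "aic": np.nan, "mcfadden_r2": np.nan, "status": f"failed: {exc}"}
            )
            continue
        fits[i] = fit
        rows.append(
            {"model": spec.label(), "k": fit.k_params,
             "log_likelihood": fit.log_likelihood, "aic": fit.aic,
             "mcfadden_r2": fit.mcfadden_r2, "status": "ok"}
        )
    if not fits:
        raise GLMConvergenceError("every candidate model failed to fit")
    best_idx = min(fits, key=lambda i: fits[i].aic)
    ranking = pd.DataFrame(rows)
    ranking["delta_aic"] = ranking["aic"] - fits[best_idx].aic
    ranking = ranking.sort_values(
        "aic", na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return fits[best_idx], ranking


def percent_change(beta: float) -> float:
    """Back-transform a log/logit-scale coefficient to a percent change.

    ``100 * (e^beta - 1)``: the percent change in the response per unit of
    the covariate under a log link.
    """
    return float(100.0 * np.expm1(beta))


# -- simulation utilities for calibration and validation ---------------------


def simulate_binomial_table(
    n_pas: int,
    intercept: float,
    ln_area_slope: float,
    rng: np.random.Generator,
    mean_richness: float = 30.0,
) -> pd.DataFrame:
    """Simulate a PA table with threat proportions driven by ln(area).

    Threat probability per species is logistic(intercept + slope * ln_area);
    richness is 1 + Poisson(mean_richness - 1).  Covariates not in the model
    are filled with nulls of convenience (year, single category).
    """
    ln_area = rng.normal(2.0, 1.0, n_pas)
    richness = 1 + rng.poisson(mean_richness - 1.0, n_pas)
    p = 1.0 / (1.0 + np.exp(-(intercept + ln_area_slope * ln_area)))
    n_threat = rng.binomial(richness, p)
    return pd.DataFrame(
        {
            "pa_id": [f"sim_{i}" for i in range(n_pas)],
            "richness": richness,
            "n_threatened": n_threat,
            "prop_threatened": n_threat / richness,
            "abs_latitude_deg": rng.uniform(0.0, 60.0, n_pas),
            "ln_area": ln_area,
            "year": rng.integers(1900, 2021, n_pas),
            "category": "II",
            "size_class": "0-10",
        }
    )


def simulate_negbin_table(
    n_pas: int,
    intercept: float,
    lat_slope: float,
    theta: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate a PA table with NB2 richness declining with |latitude|.

    mean = exp(intercept + lat_slope * |lat|); counts are gamma-Poisson with
    shape theta, so Var = mean + mean^2 / theta.  ``theta = inf`` gives
    Poisson counts.
    """
    lat = rng.uniform(0.0, 60.0, n_pas)
    mu = np.exp(intercept + lat_slope * lat)
    if np.isinf(theta):
        richness = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=theta, scale=mu / theta)
        richness = rng.poisson(lam)
    richness = np.maximum(richness, 0)
    n_threat = rng.binomial(richness, 0.3)
    return pd.DataFrame(
        {
            "pa_id": [f"sim_{i}" for i in range(n_pas)],
            "richness": richness,
            "n_threatened": n_threat,
            "prop_threatened": np.where(richness > 0, n_threat / np.maximum(richness, 1), np.nan),
            "abs_latitude_deg": lat,
            "ln_area": rng.normal(2.0, 1.0, n_pas),
            "year": rng.integers(1900, 2021, n_pas),
            "category": "II",
            "size_class": "0-10",
        }
    )
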