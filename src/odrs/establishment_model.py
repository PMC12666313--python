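"""Predicting organoid establishment success from clinical covariates.

A logistic model relates culture success to patient and logistics factors
(age, sex, primary-tumor location and differentiation, timing of metastases,
LDH elevation, prior treatment, mutation status, biopsy period, hospital
type).  Model selection is backward stepwise on AIC; multicollinearity is
screened with variance inflation factors (VIF > 5 flags a problem); apparent
discrimination is summarized by the in-sample AUROC and calibration by
decile-binned predicted-vs-observed frequencies.

Biopsy date enters as a piecewise-constant period factor: culture protocols
evolve over a study, so the day scale is cut at user-supplied knots
(defaults: terciles of the observed days).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .concordance_stats import empirical_roc
from .errors import DomainError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: infinite-VIF sentinel for perfectly collinear columns
VIF_INF = float("inf")

CATEGORICAL_LEVELS = {
    "sex": ("female", "male"),
    "location": ("rectum", "left", "right"),
    "differentiation": ("good", "poor", "unknown"),
    "time_to_metastases": ("metachronous", "synchronous"),
    "prior_treatment": ("none", "adjuvant", "palliative"),
    "mutation": ("WT", "KRAS", "BRAF"),
    "hospital": ("nonacademic", "academic"),
}

COHORT_COLUMNS = (
    "subject_id",
    "success",
    "age",
    "sex",
    "location",
    "differentiation",
    "time_to_metastases",
    "ldh_elevated",
    "prior_treatment",
    "mutation",
    "biopsy_day",
    "hospital",
)

#: formula fragments per candidate term, reference levels fixed for
#: reproducibility (first level of CATEGORICAL_LEVELS)
CANDIDATE_TERMS = {
    "age": "age",
    "sex": "C(sex, Treatment('female'))",
    "location": "C(location, Treatment('rectum'))",
    "differentiation": "C(differentiation, Treatment('good'))",
    "time_to_metastases": "C(time_to_metastases, Treatment('metachronous'))",
    "ldh_elevated": "ldh_elevated",
    "prior_treatment": "C(prior_treatment, Treatment('none'))",
    "mutation": "C(mutation, Treatment('WT'))",
    "biopsy_period": "C(biopsy_period, Treatment('P1'))",
    "hospital": "C(hospital, Treatment('nonacademic'))",
}


@dataclass
class LogisticFit:
    params: pd.Series
    loglik: float
    aic: float
    n: int
    separation_flag: bool
    result: object  # statsmodels results, for prediction


@dataclass
class EstablishmentFit:
    selected_terms: tuple[str, ...]
    fit: LogisticFit
    aic: float
    vif: dict[str, float]
    auroc: float
    auroc_ci: tuple[float, float]
    calibration: pd.DataFrame
    prob_summary: dict[str, float]


def load_cohort_table(path_or_buffer) -> pd.DataFrame:
    df = pd.read_csv(path_or_buffer, sep="\t")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"cohort table missing column(s) {sorted(missing)}")
    for col, levels in CATEGORICAL_LEVELS.items():
        bad = set(df[col].dropna().unique()) - set(levels)
        if bad:
            raise ValidationError(f"column {col} has unknown level(s) {sorted(bad)}")
    if (df["biopsy_day"].dropna() < 0).any():
        raise ValidationError("biopsy_day must be non-negative")
    return df


def biopsy_periods(days: Sequence[float], knots: Sequence[float] | None = None) -> pd.Series:
    """Cut biopsy days into period labels P1..Pk at the given knots.

    With no knots supplied, terciles of the observed distribution are used.
    """
    days = pd.Series(days, dtype=float)
    if knots is None:
        knots = days.quantile([1 / 3, 2 / 3]).to_numpy()
    knots = sorted(float(k) for k in knots)
    edges = [-np.inf, *knots, np.inf]
    labels = [f"P{i + 1}" for i in range(len(edges) - 1)]
    return pd.cut(days, bins=edges, labels=labels, right=False).astype(str)


def prepare_cohort(df: pd.DataFrame, knots: Sequence[float] | None = None) -> pd.DataFrame:
    """Complete-case cohort with the derived biopsy_period factor."""
    out = df.dropna(subset=[c for c in COHORT_COLUMNS if c != "subject_id"]).copy()
    if out.empty:
        raise DomainError("no complete cases in cohort")
    out["biopsy_period"] = biopsy_periods(out["biopsy_day"], knots).to_numpy()
    out["success"] = out["success"].astype(int)
    return out


def fit_logistic(design: pd.DataFrame, outcomes: Sequence[int]) -> LogisticFit:
    """Maximum-likelihood logistic regression on an explicit design matrix.

    `design` must already contain an intercept column if one is wanted.
    Flags (but does not fail on) quasi-complete separation, detected by
    fitted probabilities collapsing to 0/1.
    """
    y = np.asarray(outcomes, dtype=float)
    if len(np.unique(y)) < 2:
        raise DomainError("outcome has a single class; logistic fit undefined")
    if len(y) <= design.shape[1]:
        raise DomainError("need more observations than model terms")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    fitted = res.predict(design)
    separation = bool(np.any((fitted > 1 - 1e-8) | (fitted < 1e-8)))
    if separation:
        logger.warning("possible separation: fitted probabilities at 0/1, "
                       "coefficients may diverge")
    return LogisticFit(
        params=res.params,
        loglik=float(res.llf),
        aic=float(res.aic),
        n=int(len(y)),
        separation_flag=separation,
        result=res,
    )


def _fit_terms(data: pd.DataFrame, terms: Sequence[str]) -> object:
    rhs = " + ".join(CANDIDATE_TERMS[t] for t in terms) if terms else "1"
    model = smf.glm(f"success ~ {rhs}", data=data, family=sm.families.Binomial())
    return model.fit(maxiter=200)


def backward_aic(
    data: pd.DataFrame, candidate_terms: Sequence[str] | None = None
) -> tuple[tuple[str, ...], object]:
    """Backward stepwise selection by AIC over named candidate terms.

    Repeatedly drops the single term whose removal most reduces the AIC,
    stopping when every removal would increase it.  Deterministic: ties are
    broken by candidate order.  Returns (selected terms, fitted result).
    """
    terms = list(candidate_terms if candidate_terms is not None else CANDIDATE_TERMS)
    unknown = set(terms) - set(CANDIDATE_TERMS)
    if unknown:
        raise DomainError(f"unknown candidate term(s) {sorted(unknown)}")
    current = _fit_terms(data, terms)
    while terms:
        best_drop, best_fit, best_aic = None, None, current.aic
        for t in terms:
            reduced = [u for u in terms if u != t]
            fit = _fit_terms(data, reduced)
            if fit.aic < best_aic - 1e-12:
                best_drop, best_fit, best_aic = t, fit, fit.aic
        if best_drop is None:
            break
        terms.remove(best_drop)
        current = best_fit
    return tuple(terms), current


def vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per predictor column.

    VIF_j = 1 / (1 - R^2_j) from regressing column j on the remaining
    predictors (with intercept).  Perfect collinearity yields the infinity
    sentinel.  Intercept columns are ignored.
    """
    cols = [c for c in design.columns if design[c].nunique() > 1]
    if len(cols) < 2:
        raise DomainError("need at least two non-constant predictor columns")
    out: dict[str, float] = {}
    for c in cols:
        others = sm.add_constant(design[[o for o in cols if o != c]], has_constant="add")
        r2 = float(sm.OLS(design[c].astype(float), others.astype(float)).fit().rsquared)
        out[c] = VIF_INF if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def model_performance(result, data: pd.DataFrame, n_bins: int = 10) -> dict:
    """In-sample AUROC, decile calibration, and predicted-probability summary."""
    prob = np.asarray(result.predict(data), dtype=float)
    y = data["success"].to_numpy(dtype=int)
    # empirical_roc treats LOWER scores as responder-like; probabilities are
    # oriented the other way, so negate
    roc = empirical_roc(-prob, y)
    order = np.argsort(prob, kind="mergesort")
    bins = np.array_split(order, n_bins)
    calibration = pd.DataFrame(
        [
            {
                "bin": i + 1,
                "n": len(idx),
                "mean_predicted": float(prob[idx].mean()),
                "observed_rate": float(y[idx].mean()),
            }
            for i, idx in enumerate(bins)
            if len(idx)
        ]
    )
    q25, q50, q75 = np.percentile(prob, [25, 50, 75])
    return {
        "auroc": roc["auroc"],
        "auroc_ci": roc["auroc_ci"],
        "calibration": calibration,
        "prob_summary": {
            "min": float(prob.min()),
            "q25": float(q25),
            "median": float(q50),
            "q75": float(q75),
            "max": float(prob.max()),
        },
    }


def fit_establishment_model(
    df: pd.DataFrame,
    knots: Sequence[float] | None = None,
    candidate_terms: Sequence[str] | None = None,
) -> EstablishmentFit:
    """Full establishment analysis: complete cases, backward-AIC selection,
    VIF screen on the selected design, discrimination and calibration."""
    data = prepare_cohort(df, knots)
    selected, result = backward_aic(data, candidate_terms)
    design = pd.DataFrame(
        result.model.exog, columns=result.model.exog_names, index=data.index
    )
    predictors = design.drop(columns=["Intercept"], errors="ignore")
    vifs = vif(predictors) if predictors.shape[1] >= 2 else {}
    high = {k: v for k, v in vifs.items() if v > 5}
    if high:
        logger.warning("VIF > 5 for %s; multicollinearity suspected", sorted(high))
    perf = model_performance(result, data)
    fit = LogisticFit(
        params=result.params,
        loglik=float(result.llf),
        aic=float(result.aic),
        n=int(result.nobs),
        separation_flag=False,
        result=result,
    )
    return EstablishmentFit(
        selected_terms=selected,
        fit=fit,
        aic=float(result.aic),
        vif=vifs,
        auroc=perf["auroc"],
        auroc_ci=perf["auroc_ci"],
        calibration=perf["calibration"],
        prob_summary=perf["prob_summary"],
    )
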