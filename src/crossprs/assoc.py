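"""Per-cohort regression models.

Covariate-adjusted logistic models for binary cancer outcomes (effects are
log odds ratios, two-sided Wald p from the normal quantile) and ordinary
least squares for quantitative secondary traits (two-sided t test p).
Single-variant scans fit one log-additive logistic model per
(variant, outcome) pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: |log OR| beyond which a logistic fit is treated as separated
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what, and with which adjustment set."""

    outcome: str
    exposure: str
    covariates: tuple[str, ...] = ()
    family: str = "logistic"  # logistic | linear

    def __post_init__(self):
        if self.family not in ("logistic", "linear"):
            raise ValueError(f"family must be 'logistic' or 'linear', got {self.family!r}")


@dataclass
class AssocEstimate:
    """One fitted exposure effect in one cohort."""

    cohort: str
    outcome: str
    exposure: str
    beta: float
    se: float
    p_value: float
    n: int
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    converged: bool = True
    family: str = "logistic"
    duplicate: bool = False
    origin: Optional[str] = None  # PRS of origin for variant-scan rows

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def wald_p(beta: float, se: float) -> float:
    """Two-sided Wald p-value, p = 2 * Phi(-|beta/se|)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def _design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    cols = [spec.exposure, *spec.covariates]
    missing = [c for c in cols + [spec.outcome] if c not in data.columns]
    if missing:
        raise KeyError(f"model columns absent from data: {missing}")
    sub = data[[spec.outcome, *cols]].dropna()
    y = sub[spec.outcome].astype(float)
    X = sub[list(cols)]
    # categorical covariates (genotyping batch/array) enter as indicators
    cat_cols = [c for c in X.columns if not pd.api.types.is_numeric_dtype(X[c])]
    if cat_cols:
        X = pd.get_dummies(X, columns=cat_cols, drop_first=True, dtype=float)
    X = X.astype(float)
    # constant covariates (e.g. sex within a sex-restricted analysis) carry
    # no information and would make the design singular
    constant = [c for c in X.columns if c != spec.exposure and np.ptp(X[c].to_numpy()) == 0]
    if constant:
        X = X.drop(columns=constant)
    X = sm.add_constant(X, has_constant="add")
    return X, y


def fit_logistic(spec: ModelSpec, data: pd.DataFrame, cohort: str = "") -> AssocEstimate:
    """Maximum-likelihood logistic fit; effect is the exposure coefficient.

    Non-convergence and (quasi-)separation yield converged=False so the
    estimate can be excluded from meta-analysis. A constant exposure is an
    error.
    """
    X, y = _design(data, spec)
    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(f"need at least one case and one control for {spec.outcome}")
    if np.ptp(X[spec.exposure].to_numpy()) == 0:
        raise ValueError(f"constant exposure {spec.exposure!r}")
    converged = True
    beta = se = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = float(res.params[spec.exposure])
        se = float(res.bse[spec.exposure])
        converged = bool(res.mle_retvals.get("converged", False))
        if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > SEPARATION_BOUND:
            converged = False
    except Exception as exc:  # perfect separation, singular designs
        logger.warning("logistic fit failed for %s ~ %s: %s", spec.outcome, spec.exposure, exc)
        converged = False
    p = wald_p(beta, se) if converged else np.nan
    return AssocEstimate(
        cohort=cohort,
        outcome=spec.outcome,
        exposure=spec.exposure,
        beta=beta,
        se=se,
        p_value=p,
        n=len(y),
        n_cases=n_cases,
        n_controls=n_controls,
        converged=converged,
        family="logistic",
    )


def fit_linear(spec: ModelSpec, data: pd.DataFrame, cohort: str = "") -> AssocEstimate:
    """OLS slope for the exposure term; two-sided t-test p-value."""
    X, y = _design(data, spec)
    if np.ptp(X[spec.exposure].to_numpy()) == 0:
        raise ValueError(f"constant exposure {spec.exposure!r}")
    res = sm.OLS(y, X).fit()
    beta = float(res.params[spec.exposure])
    se = float(res.bse[spec.exposure])
    df_resid = res.df_resid
    if se > 0 and df_resid > 0:
        p = float(2.0 * stats.t.sf(abs(beta / se), df_resid))
        converged = True
    else:
        p = np.nan
        converged = False
    return AssocEstimate(
        cohort=cohort,
        outcome=spec.outcome,
        exposure=spec.exposure,
        beta=beta,
        se=se,
        p_value=p,
        n=len(y),
        converged=converged,
        family="linear",
    )


def variant_scan(
    prs_defs: Sequence,
    dosages: pd.DataFrame,
    assignments: dict,
    covariate_data: pd.DataFrame,
    covariates: Sequence[str],
    cohort: str = "",
) -> list[AssocEstimate]:
    """One log-additive logistic fit per (PRS variant, cancer outcome).

    ``assignments`` maps outcome site code -> object with ``case_ids`` and
    ``control_ids``. A variant contributing to several score definitions is
    fitted once per origin; repeats beyond the first origin are flagged as
    duplicates for counting.
    """
    estimates: list[AssocEstimate] = []
    fitted: dict[tuple[str, str], AssocEstimate] = {}
    seen_variants: set[str] = set()
    for prs in prs_defs:
        origin_dup = {v: (v in seen_variants) for v in prs.variant_ids}
        seen_variants.update(prs.variant_ids)
        for w in prs.weights:
            for outcome, assign in assignments.items():
                key = (w.variant_id, outcome)
                if key in fitted:
                    est = fitted[key]
                    est = AssocEstimate(**{**est.__dict__})
                else:
                    ids = list(assign.case_ids) + list(assign.control_ids)
                    ids = [i for i in ids if i in dosages.index]
                    data = covariate_data.loc[ids].copy()
                    data[w.variant_id] = dosages.loc[ids, w.variant_id]
                    data[outcome] = [1.0] * len(assign.case_ids) + [0.0] * (
                        len(ids) - len(assign.case_ids)
                    )
                    spec = ModelSpec(
                        outcome=outcome,
                        exposure=w.variant_id,
                        covariates=tuple(covariates),
                        family="logistic",
                    )
                    try:
                        est = fit_logistic(spec, data, cohort=cohort)
                    except ValueError as exc:
                        logger.warning("variant scan fit skipped (%s, %s): %s",
                                       w.variant_id, outcome, exc)
                        continue
                    fitted[key] = est
                    est = AssocEstimate(**{**est.__dict__})
                est.origin = prs.cancer
                est.duplicate = origin_dup[w.variant_id]
                estimates.append(est)
    return estimates


def estimates_to_frame(estimates: Sequence[AssocEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "cohort": e.cohort,
                "outcome": e.outcome,
                "exposure": e.exposure,
                "origin": e.origin or "",
                "family": e.family,
                "n": e.n,
                "n_cases": e.n_cases if e.n_cases is not None else "",
                "n_controls": e.n_controls if e.n_controls is not None else "",
                "beta": e.beta,
                "se": e.se,
                "p": e.p_value,
                "or": np.exp(e.beta) if np.isfinite(e.beta) else "",
                "converged": e.converged,
                "duplicate": e.duplicate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cohort", "outcome", "exposure", "origin", "family", "n", "n_cases",
            "n_controls", "beta", "se", "p", "or", "converged", "duplicate",
        ],
    )
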