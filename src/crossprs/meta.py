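"""Fixed-effects inverse-variance meta-analysis and multiplicity control.

Pooling uses weights w_k = 1/se_k^2; heterogeneity is quantified by
Cochran's Q (chi-square with k-1 df) and I^2 = max(0, (Q - (k-1)) / Q),
reported as undefined (None) for a single study. Multiplicity control is
Bonferroni (alpha/m) and Benjamini-Hochberg step-up q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .assoc import AssocEstimate, wald_p

logger = logging.getLogger(__name__)


@dataclass
class MetaEstimate:
    outcome: str
    exposure: str
    k: int
    beta: float
    se: float
    p_value: float
    cochran_q: float
    p_q: Optional[float]          # chi-square on k-1 df; None for k=1
    i2: Optional[float]           # None (undefined) for k=1
    weights: tuple[float, ...]
    cohorts: tuple[str, ...] = ()
    origin: Optional[str] = None
    duplicate: bool = False

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def fixed_effects_meta(estimates: Sequence[AssocEstimate]) -> MetaEstimate:
    """Pool per-cohort estimates of one (outcome, exposure) pair.

    Non-converged members are skipped with a warning; a single remaining
    study passes through unchanged with Q=0 and undefined I^2.
    """
    usable = [e for e in estimates if e.converged]
    skipped = len(estimates) - len(usable)
    if skipped:
        logger.warning("fixed_effects_meta: skipped %d non-converged estimate(s)", skipped)
    if not usable:
        raise ValueError("no converged estimates to meta-analyze")
    outcomes = {e.outcome for e in usable}
    exposures = {e.exposure for e in usable}
    if len(outcomes) > 1 or len(exposures) > 1:
        raise ValueError(
            f"estimates mix outcomes/exposures: {sorted(outcomes)} / {sorted(exposures)}"
        )
    betas = np.array([e.beta for e in usable], dtype=float)
    ses = np.array([e.se for e in usable], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    k = len(usable)
    if k == 1:
        # exact passthrough (single-cohort outcomes)
        beta_meta, se_meta, q = float(betas[0]), float(ses[0]), 0.0
    else:
        beta_meta = float(np.sum(w * betas) / np.sum(w))
        se_meta = float(np.sum(w) ** -0.5)
        q = float(np.sum(w * (betas - beta_meta) ** 2))
    if k >= 2:
        p_q = float(stats.chi2.sf(q, k - 1))
        i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    else:
        p_q = None
        i2 = None
    return MetaEstimate(
        outcome=usable[0].outcome,
        exposure=usable[0].exposure,
        k=k,
        beta=beta_meta,
        se=se_meta,
        p_value=wald_p(beta_meta, se_meta),
        cochran_q=q,
        p_q=p_q,
        i2=i2,
        weights=tuple(float(x) for x in w),
        cohorts=tuple(e.cohort for e in usable),
        origin=usable[0].origin,
        duplicate=any(e.duplicate for e in usable),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """alpha / m; callers declare significance for p strictly below it."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotone enforcement."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # running minimum from the largest p downward
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
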