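"""Hazard-ratio meta-analysis: fixed and DerSimonian-Laird random effects,
heterogeneity statistics, subgroup pooling, leave-one-out sensitivity, and
Egger's regression test of funnel-plot asymmetry.

Pooling is inverse-variance on the log-HR scale.  Cochran's Q and I^2 are
always reported from the fixed-effect weights; the random-effects model adds
the DL between-study variance tau^2 = max(0, (Q - df) / (S1 - S2/S1)) to
every study variance before re-weighting.  Confidence intervals use normal
quantiles (no Knapp-Hartung adjustment).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Z95, StudyEffect, effect_to_hr_ci

__all__ = [
    "MetaResult",
    "EggerResult",
    "pool_effects",
    "leave_one_out",
    "egger_test",
    "funnel_coordinates",
    "i_squared",
]


@dataclass(frozen=True)
class MetaResult:
    method: str  # {fixed, random-DL}
    k: int
    pooled_log_hr: float
    pooled_se: float
    q: float
    df: int
    i2: float  # percent in [0, 100]
    tau2: float

    @property
    def hr(self) -> float:
        return math.exp(self.pooled_log_hr)

    @property
    def ci95(self) -> tuple[float, float]:
        _, lo, hi = effect_to_hr_ci(self.pooled_log_hr, self.pooled_se)
        return lo, hi

    @property
    def z(self) -> float:
        return self.pooled_log_hr / self.pooled_se

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    t: float
    df: int
    p: float


def i_squared(q: float, df: int) -> float:
    """I^2 heterogeneity percentage: max(0, (Q - df) / Q) * 100."""
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def _filter(
    studies: Sequence[StudyEffect], subgroup: str | None
) -> list[StudyEffect]:
    if subgroup is None:
        return list(studies)
    return [s for s in studies if s.subgroup == subgroup]


def pool_effects(
    studies: Sequence[StudyEffect],
    method: str = "random-DL",
    subgroup: str | None = None,
) -> MetaResult:
    """Inverse-variance pooled log hazard ratio.

    method 'fixed': weights 1/se_i^2.  method 'random-DL': DerSimonian-Laird
    tau^2 added to each study variance before re-weighting.  Q, df, and I^2
    always come from the fixed-effect weights.
    """
    if method not in ("fixed", "random-DL"):
        raise ValueError(f"unknown method {method!r}")
    kept = _filter(studies, subgroup)
    if not kept:
        raise ValueError("no studies to pool" + (f" in subgroup {subgroup!r}" if subgroup else ""))
    y = np.array([s.log_hr for s in kept])
    w = np.array([1.0 / s.se**2 for s in kept])
    k = len(kept)
    mu_fixed = float((w * y).sum() / w.sum())
    q = float((w * (y - mu_fixed) ** 2).sum())
    df = k - 1
    i2 = i_squared(q, df)
    if method == "fixed" or k == 1:
        tau2 = 0.0
        w_star = w
    else:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (1.0 / w + tau2)
    pooled = float((w_star * y).sum() / w_star.sum())
    se = float(math.sqrt(1.0 / w_star.sum()))
    return MetaResult(method, k, pooled, se, q, df, i2, tau2)


def leave_one_out(
    studies: Sequence[StudyEffect], method: str = "random-DL"
) -> pd.DataFrame:
    """Re-pool with each study omitted in turn; one row per omitted study."""
    studies = list(studies)
    if len(studies) < 2:
        raise ValueError("leave-one-out needs at least 2 studies")
    rows = []
    for omit in studies:
        rest = [s for s in studies if s is not omit]
        res = pool_effects(rest, method=method)
        lo, hi = res.ci95
        rows.append(
            {
                "omitted": omit.study_id,
                "k": res.k,
                "pooled_log_hr": res.pooled_log_hr,
                "pooled_se": res.pooled_se,
                "hr": res.hr,
                "ci_lower": lo,
                "ci_upper": hi,
                "tau2": res.tau2,
                "i2": res.i2,
            }
        )
    return pd.DataFrame(rows).set_index("omitted")


def egger_test(studies: Sequence[StudyEffect]) -> EggerResult:
    """Egger's regression: standardized effect (y/se) on precision (1/se).

    A nonzero intercept indicates funnel-plot asymmetry.  OLS with
    intercept tested against t at k - 2 df; requires k >= 3 and non-constant
    standard errors.
    """
    studies = list(studies)
    k = len(studies)
    if k < 3:
        raise ValueError("Egger's test requires at least 3 studies")
    se = np.array([s.se for s in studies])
    if np.allclose(se, se[0]):
        raise ValueError("all standard errors equal; precision regressor degenerate")
    x = 1.0 / se
    y = np.array([s.log_hr for s in studies]) / se
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    slope = ((x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    df = k - 2
    sigma2 = (resid**2).sum() / df
    intercept_se = math.sqrt(sigma2 * (1.0 / k + xbar**2 / sxx))
    t = intercept / intercept_se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return EggerResult(float(intercept), float(intercept_se), float(t), df, p)


def funnel_coordinates(studies: Sequence[StudyEffect]) -> pd.DataFrame:
    """(log_hr, se) pairs for funnel plotting, one row per study."""
    return pd.DataFrame(
        {
            "study_id": [s.study_id for s in studies],
            "log_hr": [s.log_hr for s in studies],
            "se": [s.se for s in studies],
        }
    ).set_index("study_id")
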