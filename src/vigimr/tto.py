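"""Time-to-onset extraction, Weibull maximum-likelihood fits, hazard typing.

Onset time is event date minus therapy start date in whole days. The fitted
shape parameter classifies the hazard: a shape confidently below 1 means the
event rate falls with time on drug (early failure), confidently above 1 means
it rises (wear-out failure), and a confidence interval covering 1 means a
constant rate (random failure).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FitError

logger = logging.getLogger(__name__)

EARLY = "early"
RANDOM = "random"
WEAR_OUT = "wear_out"


def compute_tto(reports: pd.DataFrame, drug: str, pts: Sequence[str] | None = None) -> np.ndarray:
    """Days from therapy start to event for one drug (optionally limited to
    a set of preferred terms). Rows with missing dates are skipped; negative
    intervals are excluded and counted in a log message."""
    sub = reports.loc[reports["drug_name"] == drug]
    if pts is not None:
        sub = sub.loc[sub["pt_name"].isin(list(pts))]
    event = pd.to_datetime(sub["event_date"], errors="coerce")
    start = pd.to_datetime(sub["start_date"], errors="coerce")
    delta = (event - start).dt.days
    valid = delta.notna()
    negative = valid & (delta < 0)
    n_neg = int(negative.sum())
    if n_neg:
        logger.info("%s: excluded %d reports with event before therapy start", drug, n_neg)
    return delta.loc[valid & ~negative].to_numpy(dtype=float)


@dataclass(frozen=True)
class WeibullFit:
    """Two-parameter Weibull fit of one drug's onset-time distribution."""

    drug: str
    n_used: int
    median_days: float
    iqr_low: float
    iqr_high: float
    alpha_scale: float
    alpha_ci_low: float
    alpha_ci_high: float
    beta_shape: float
    beta_ci_low: float
    beta_ci_high: float
    failure_type: str
    zero_shifted: bool


def classify_failure(beta: float, ci_low: float, ci_high: float) -> str:
    """Hazard type from the shape parameter's confidence bounds only."""
    if not ci_low <= beta <= ci_high:
        raise ValueError("shape estimate must lie inside its confidence interval")
    if ci_high < 1.0:
        return EARLY
    if ci_low > 1.0:
        return WEAR_OUT
    return RANDOM


def _weibull_nll(log_params: np.ndarray, x: np.ndarray) -> float:
    log_alpha, log_beta = log_params
    alpha, beta = math.exp(log_alpha), math.exp(log_beta)
    z = x / alpha
    return -(
        x.size * (math.log(beta) - beta * math.log(alpha))
        + (beta - 1.0) * np.log(x).sum()
        - np.power(z, beta).sum()
    )


def _hessian(f, x0: np.ndarray, args, step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian; adequate at a smooth interior optimum."""
    k = x0.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = step
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej, *args)
                - f(x0 + ei - ej, *args)
                - f(x0 - ei + ej, *args)
                + f(x0 - ei - ej, *args)
            ) / (4.0 * step * step)
    return H


def fit_weibull(
    tto_values,
    level: float = 0.95,
    min_n: int = 10,
    drug: str = "",
) -> WeibullFit:
    """Maximum-likelihood Weibull fit with Wald intervals on the log scale.

    Zero-day onsets are shifted by +0.5 day (the distribution's support is
    positive) and the shift is flagged. The reported median and interquartile
    range are empirical quantiles of the raw values, not fit-implied ones.
    """
    x = np.asarray(tto_values, dtype=float)
    if x.size < min_n:
        raise FitError(f"{x.size} onset times < required minimum {min_n}")
    if np.any(x < 0):
        raise FitError("negative onset times must be excluded before fitting")
    median, q1, q3 = (float(np.percentile(x, q)) for q in (50, 25, 75))
    zero_shifted = bool(np.any(x == 0))
    xs = np.where(x == 0, 0.5, x)

    beta0, _, alpha0 = sps.weibull_min.fit(xs, floc=0)
    if not (np.isfinite(alpha0) and np.isfinite(beta0) and alpha0 > 0 and beta0 > 0):
        raise FitError(f"Weibull MLE failed to converge (alpha={alpha0}, beta={beta0})")
    theta = np.array([math.log(alpha0), math.log(beta0)])

    H = _hessian(_weibull_nll, theta, (xs,))
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate data
        raise FitError(f"observed information singular: {exc}") from exc
    se_log = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(se_log)):
        raise FitError("non-finite standard errors from the observed information matrix")
    z = sps.norm.ppf(1 - (1 - level) / 2)
    alpha_ci = (math.exp(theta[0] - z * se_log[0]), math.exp(theta[0] + z * se_log[0]))
    beta_ci = (math.exp(theta[1] - z * se_log[1]), math.exp(theta[1] + z * se_log[1]))

    return WeibullFit(
        drug=drug,
        n_used=int(x.size),
        median_days=median,
        iqr_low=q1,
        iqr_high=q3,
        alpha_scale=float(alpha0),
        alpha_ci_low=alpha_ci[0],
        alpha_ci_high=alpha_ci[1],
        beta_shape=float(beta0),
        beta_ci_low=beta_ci[0],
        beta_ci_high=beta_ci[1],
        failure_type=classify_failure(beta0, beta_ci[0], beta_ci[1]),
        zero_shifted=zero_shifted,
    )


def fit_drug_tto(
    reports: pd.DataFrame,
    drug: str,
    pts: Sequence[str] | None = None,
    level: float = 0.95,
    min_n: int = 10,
) -> WeibullFit:
    """Convenience: extract onset times for a drug and fit in one step."""
    return fit_weibull(compute_tto(reports, drug, pts), level=level, min_n=min_n, drug=drug)


def tto_summary_table(fits: Sequence[WeibullFit]) -> pd.DataFrame:
    """Summary rows: drug, median (IQR), scale and shape with CIs, hazard type."""
    return pd.DataFrame(
        [
            {
                "drug": f.drug,
                "n": f.n_used,
                "median_days": f.median_days,
                "iqr_low": f.iqr_low,
                "iqr_high": f.iqr_high,
                "alpha": f.alpha_scale,
                "alpha_ci_low": f.alpha_ci_low,
                "alpha_ci_high": f.alpha_ci_high,
                "beta": f.beta_shape,
                "beta_ci_low": f.beta_ci_low,
                "beta_ci_high": f.beta_ci_high,
                "failure_type": f.failure_type,
                "zero_shifted": f.zero_shifted,
            }
            for f in fits
        ]
    )
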