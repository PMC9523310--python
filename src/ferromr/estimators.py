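"""MR estimators: Wald ratio, fixed-effect IVW, MR-Egger, weighted median.

Notation: for instrument j, ``beta_x[j]`` / ``se_x[j]`` are the variant's
effect on the exposure and its SE, ``beta_y[j]`` / ``se_y[j]`` the effect on
the outcome. The per-variant causal estimate (Wald ratio) is
``theta_j = beta_y[j] / beta_x[j]``; the pooled estimators combine these
under different assumptions about pleiotropy:

- fixed-effect IVW assumes every instrument is valid and weights the ratios
  by inverse variance;
- MR-Egger regresses beta_y on beta_x with a free intercept; the intercept
  estimates the average direct (pleiotropic) effect, and a non-null intercept
  indicates the IVW estimate is biased;
- the weighted median is the 50% weighted quantile of the ratios and remains
  consistent while valid instruments carry more than half the weight.

Point estimates are on the exposure's SD scale: SD of outcome per SD of
exposure for continuous outcomes, log-odds per SD for binary outcomes
(exponentiate via :func:`to_odds_ratio`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .summary_io import HarmonizedInstrument

#: 95% CI multiplier, Phi^{-1}(0.975) to six decimals.
Z_975 = 1.959964


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are not met."""


@dataclass
class MREstimate:
    """A causal-effect estimate with normal-theory inference.

    ``theta`` is SD/SD for continuous outcomes and log-odds/SD for binary
    outcomes; ``ci_low``/``ci_high`` are theta -/+ 1.959964 * se and
    ``pvalue`` the two-sided normal tail probability of ``z = theta/se``.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    pvalue: float
    n_snps: int

    @classmethod
    def from_theta_se(cls, method: str, theta: float, se: float, n_snps: int) -> "MREstimate":
        if not se > 0:
            raise EstimationError(f"{method}: standard error must be > 0, got {se}")
        z = theta / se
        return cls(
            method=method,
            theta=theta,
            se=se,
            ci_low=theta - Z_975 * se,
            ci_high=theta + Z_975 * se,
            z=z,
            pvalue=pvalue_two_sided(z),
            n_snps=n_snps,
        )


def pvalue_two_sided(z: float) -> float:
    """Two-sided normal tail probability, 2 * Phi(-|z|)."""
    return float(2.0 * stats.norm.sf(abs(z)))


def to_odds_ratio(est: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate to (OR, CI low, CI high)."""
    return float(np.exp(est.theta)), float(np.exp(est.ci_low)), float(np.exp(est.ci_high))


# ---------------------------------------------------------------------------
# Per-instrument ratio
# ---------------------------------------------------------------------------


def wald_ratio(
    h: HarmonizedInstrument, se_order: Literal["first", "second"] = "first"
) -> MREstimate:
    """Per-variant causal estimate: ratio of outcome to exposure effect.

    The SE comes from the delta method. First order ignores the exposure's
    sampling error (se_y / |beta_x|); second order propagates it:
    sqrt(se_y^2/beta_x^2 + beta_y^2 se_x^2 / beta_x^4). For strong
    instruments (F >> 10) the two are nearly identical.
    """
    bx, by = h.beta_exposure, h.beta_outcome
    if bx == 0:
        raise EstimationError(f"wald_ratio: {h.rsid} has zero exposure effect")
    theta = by / bx
    if se_order == "first":
        se = h.se_outcome / abs(bx)
    elif se_order == "second":
        se = np.sqrt(h.se_outcome**2 / bx**2 + by**2 * h.se_exposure**2 / bx**4)
    else:
        raise EstimationError(f"unknown se_order {se_order!r}")
    return MREstimate.from_theta_se("wald_ratio", theta, float(se), 1)


# ---------------------------------------------------------------------------
# Pooled estimators
# ---------------------------------------------------------------------------


def ivw_fixed(per_snp: Sequence[MREstimate]) -> MREstimate:
    """Fixed-effect inverse-variance-weighted pooling of per-SNP ratios.

    Weights w_j = se_j^-2; theta = sum(w theta) / sum(w); se = sum(w)^-1/2.
    With a single instrument this reduces exactly to that Wald ratio.
    """
    if not per_snp:
        raise EstimationError("ivw_fixed: no per-SNP estimates")
    if len(per_snp) == 1:  # degenerate pooling is exactly the single ratio
        only = per_snp[0]
        return MREstimate.from_theta_se("ivw_fixed", only.theta, only.se, 1)
    theta_j = np.array([e.theta for e in per_snp])
    w = np.array([e.se for e in per_snp]) ** -2.0
    theta = float(np.sum(w * theta_j) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return MREstimate.from_theta_se("ivw_fixed", theta, se, len(per_snp))


def heterogeneity_q(
    per_snp: Sequence[MREstimate], pooled: MREstimate
) -> tuple[float, int, float]:
    """Cochran's Q for between-instrument heterogeneity around the pooled value."""
    if len(per_snp) < 2:
        raise EstimationError("heterogeneity_q: need at least 2 per-SNP estimates")
    theta_j = np.array([e.theta for e in per_snp])
    w = np.array([e.se for e in per_snp]) ** -2.0
    q = float(np.sum(w * (theta_j - pooled.theta) ** 2))
    df = len(per_snp) - 1
    return q, df, float(stats.chi2.sf(q, df))


def _oriented_arrays(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack effects as arrays, orienting each instrument so beta_x > 0."""
    bx = np.array([h.beta_exposure for h in instruments], dtype=float)
    by = np.array([h.beta_outcome for h in instruments], dtype=float)
    sx = np.array([h.se_exposure for h in instruments], dtype=float)
    sy = np.array([h.se_outcome for h in instruments], dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign, sx, sy


def mr_egger(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: returns (slope estimate, intercept estimate).

    Weighted least squares of beta_y on beta_x with a free intercept, weights
    se_y^-2, after orienting every instrument to a positive exposure effect
    (the fit is not invariant to allele coding, so a convention is needed).
    SEs use multiplicative residual inflation with the variance scale floored
    at 1 — overdispersion widens the intervals, underdispersion never narrows
    them. The intercept's z-test is the directional-pleiotropy test.
    """
    n = len(instruments)
    if n < 3:
        raise EstimationError(f"mr_egger: needs >= 3 instruments, got {n}")
    bx, by, _, sy = _oriented_arrays(instruments)
    if np.ptp(bx) == 0:
        raise EstimationError("mr_egger: all exposure effects equal after orientation")
    w = sy**-2.0

    # weighted normal equations for [intercept, slope]
    X = np.column_stack([np.ones(n), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    phi = max(float(np.sum(w * resid**2) / (n - 2)), 1.0)
    cov = phi * np.linalg.inv(xtwx)

    slope = MREstimate.from_theta_se(
        "mr_egger_slope", float(coef[1]), float(np.sqrt(cov[1, 1])), n
    )
    intercept = MREstimate.from_theta_se(
        "mr_egger_intercept", float(coef[0]), float(np.sqrt(cov[0, 0])), n
    )
    return slope, intercept


def _weighted_median_point(theta_j: np.ndarray, w: np.ndarray) -> float:
    """Interpolated 50% weighted quantile of the per-SNP ratios."""
    order = np.argsort(theta_j)
    t = theta_j[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - 0.5 * wn
    return float(np.interp(0.5, s, t))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median MR estimate with a parametric-bootstrap SE.

    Per-SNP ratios are weighted by inverse variance of the first-order ratio
    SE, w_j = (se_y / |beta_x|)^-2, and the estimate is the linear
    interpolation of the sorted ratios against cumulative standardized
    weights at 0.5. The estimate is consistent when under half the total
    weight comes from pleiotropic instruments. The SE is the standard
    deviation of the estimate over ``n_boot`` draws resampling each
    beta_x ~ N(beta_x, se_x) and beta_y ~ N(beta_y, se_y).
    """
    n = len(instruments)
    if n < 3:
        raise EstimationError(f"weighted_median: needs >= 3 instruments, got {n}")
    bx, by, sx, sy = _oriented_arrays(instruments)
    theta_j = by / bx
    w = (sy / np.abs(bx)) ** -2.0
    theta = _weighted_median_point(theta_j, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, n))
    by_b = rng.normal(by, sy, size=(n_boot, n))
    theta_b = by_b / bx_b
    w_b = (sy / np.abs(bx_b)) ** -2.0
    # vectorized weighted-median across replicates
    order = np.argsort(theta_b, axis=1)
    t_sorted = np.take_along_axis(theta_b, order, axis=1)
    w_sorted = np.take_along_axis(w_b, order, axis=1)
    w_sorted = w_sorted / np.sum(w_sorted, axis=1, keepdims=True)
    s = np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted
    boot = np.array(
        [np.interp(0.5, s[i], t_sorted[i]) for i in range(n_boot)]
    )
    se = float(np.std(boot, ddof=1))
    return MREstimate.from_theta_se("weighted_median", theta, se, n)
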