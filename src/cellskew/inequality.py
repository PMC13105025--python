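"""Inequality statistics for per-cell activity.

The central descriptive statistic is the share of total activity held by the
most active 20% of cells: 0.2 under perfect equality, approaching 1 when a
few cells dominate community metabolism. It is a point on the (complement of
the) Lorenz curve, so fractional cell counts are handled exactly by linear
interpolation of the cumulative-share curve. For a lognormal activity
distribution with log-sd sigma the share has the closed form

    S(f) = Phi(sigma - Phi^{-1}(1 - f)),

independent of the log-mean, which makes sigma the natural single-parameter
summary of metabolic inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import ActivitySample


@dataclass
class InequalitySummary:
    """Top-share, Lorenz knots and lognormal sigma for one sample."""

    sample_id: str
    top_share: float
    sigma: float
    top_fraction: float = 0.2
    lognormal_best: bool = True
    lorenz: list[tuple[float, float]] = field(default_factory=list)


def _check_positive(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value vector")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("activity values must be finite and strictly positive")
    return values


def lorenz_points(values) -> np.ndarray:
    """Lorenz curve knots for a positive value vector.

    Returns an ``(n + 1, 2)`` array of ``(p, L(p))`` pairs from ``(0, 0)`` to
    ``(1, 1)``: the cumulative share of total activity held by the
    least-active fraction ``p`` of cells. ``L`` is convex and ``L(p) <= p``.
    """
    values = _check_positive(values)
    v = np.sort(values)
    n = v.size
    p = np.arange(n + 1) / n
    shares = np.concatenate([[0.0], np.cumsum(v)]) / v.sum()
    shares[-1] = 1.0  # guard the (1, 1) endpoint against cumsum round-off
    return np.column_stack([p, shares])


def top_share(values, fraction: float = 0.2) -> float:
    """Share of total activity held by the most active ``fraction`` of cells.

    Fractional cell counts (``fraction * n`` not an integer) are resolved by
    linear interpolation on the Lorenz curve, which is exact for the
    cumulative-share construction and independent of tie order.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    pts = lorenz_points(values)
    lower = np.interp(1.0 - fraction, pts[:, 0], pts[:, 1])
    return float(1.0 - lower)


def gini(values) -> float:
    """Gini coefficient (area-based, on the empirical Lorenz curve)."""
    pts = lorenz_points(values)
    area = np.trapezoid(pts[:, 1], pts[:, 0])
    return float(1.0 - 2.0 * area)


def lognormal_top_share(sigma: float, fraction: float = 0.2) -> float:
    """Closed-form top-``fraction`` activity share of a lognormal population.

    ``Phi(sigma - Phi^{-1}(1 - fraction))``; equals ``fraction`` at
    ``sigma = 0`` and tends to 1 as ``sigma`` grows. Does not depend on the
    log-mean (top shares are scale-invariant).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    return float(stats.norm.cdf(sigma - stats.norm.ppf(1.0 - fraction)))


def sigma_from_median_mean(median: float, mean: float) -> tuple[float, float]:
    """Lognormal ``(mu_log, sigma)`` implied by a printed median and mean.

    Under lognormality the median is ``exp(mu_log)`` and the mean is
    ``exp(mu_log + sigma^2 / 2)``, so ``mu_log = ln(median)`` and
    ``sigma = sqrt(2 ln(mean / median))``; the pair is unique.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if mean < median:
        raise ValueError(
            f"mean ({mean}) < median ({median}) is inconsistent with a lognormal"
        )
    mu_log = float(np.log(median))
    sigma = float(np.sqrt(2.0 * np.log(mean / median)))
    return mu_log, sigma


def summarize_inequality(
    sample: ActivitySample,
    fraction: float = 0.2,
    sigma: float | None = None,
    lognormal_best: bool = True,
) -> InequalitySummary:
    """Per-sample inequality summary from raw (gated) values.

    ``sigma`` defaults to the lognormal maximum-likelihood fit of the sample
    (the sd of log values). Sigma is always the *lognormal* log-sd even when
    another family fits best; ``lognormal_best=False`` flags that case.
    """
    if sigma is None:
        sigma = float(np.std(np.log(_check_positive(sample.values)), ddof=0))
    pts = lorenz_points(sample.values)
    return InequalitySummary(
        sample_id=sample.sample_id,
        top_share=top_share(sample.values, fraction),
        sigma=sigma,
        top_fraction=fraction,
        lognormal_best=lognormal_best,
        lorenz=[(float(p), float(s)) for p, s in pts],
    )
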