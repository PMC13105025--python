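"""Goodness-of-fit metrics and model selection across candidate families.

Fits are compared with information criteria (AIC/BIC, with two fits treated
as distinguishable only when they differ by more than 2), the
Kolmogorov-Smirnov distance between the empirical and fitted CDFs (used as a
plain descriptive distance, without a correction for estimated parameters),
and a quantile-quantile r-squared: agreement between sorted observations and
model quantiles at plotting positions (i - 0.5)/n. A pooled bootstrap of the
Q-Q r-squared summarises each family's fit across many samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ActivitySample
from .dist_models import FitResult, fit_mle, model_cdf, model_quantile, _require_family


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """(AIC, BIC) in nats: ``2k - 2 lnL`` and ``k ln n - 2 lnL``."""
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 and k >= 1")
    return 2.0 * k - 2.0 * loglik, k * np.log(n) - 2.0 * loglik


def _values(sample) -> np.ndarray:
    x = sample.values if isinstance(sample, ActivitySample) else np.asarray(sample, float)
    if x.size == 0:
        raise ValueError("empty sample")
    return x


def ks_statistic(sample, family, params) -> float:
    """Kolmogorov-Smirnov distance between the ECDF and the fitted CDF.

    ``D = max_i max(i/n - F(x_(i)), F(x_(i)) - (i-1)/n)`` over the sorted
    sample; 0 means complete agreement, 1 disjoint support.
    """
    x = np.sort(_values(sample))
    n = x.size
    f = np.clip(model_cdf(family, params, x), 0.0, 1.0)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - f)
    d_minus = np.max(f - (i - 1) / n)
    return float(max(d_plus, d_minus, 0.0))


def r2_qq(sample, family, params) -> float:
    """Q-Q r-squared: sorted observations against model quantiles.

    With sorted values ``x_(i)`` and model quantiles ``q_i`` at plotting
    positions ``(i - 0.5)/n``, returns ``1 - SS_res / SS_tot``; 1 for a
    perfect fit, and possibly negative when the model is worse than the
    sample mean.
    """
    x = np.sort(_values(sample))
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values for a Q-Q r-squared")
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero observed variance")
    q = model_quantile(family, params, (np.arange(1, n + 1) - 0.5) / n)
    return float(1.0 - np.sum((x - q) ** 2) / ss_tot)


def qq_points(sample, family, params, m: int | None = None, seed: int | None = None):
    """(theoretical, observed) quantile pairs, optionally subsampled to ``m`` cells."""
    x = _values(sample)
    if m is None or m >= x.size:
        sub = x
    else:
        rng = np.random.default_rng(seed)
        sub = rng.choice(x, size=m, replace=False)
    sub = np.sort(sub)
    n = sub.size
    q = model_quantile(family, params, (np.arange(1, n + 1) - 0.5) / n)
    return np.column_stack([q, sub])


@dataclass
class ComparisonTable:
    """Model selection for one sample: best family and its ΔIC tie set."""

    sample_id: str
    fits: dict[str, FitResult]
    best_family: str
    tie_set: list[str]
    criterion: str = "aic"

    def to_rows(self) -> list[dict]:
        rows = []
        for fam, fit in self.fits.items():
            row = fit.to_row()
            row["sample_id"] = self.sample_id
            row["best_flag"] = fam == self.best_family
            row["tie_flag"] = fam in self.tie_set
            rows.append(row)
        return rows


def select_best(fits: list[FitResult], criterion: str = "aic", delta: float = 2.0) -> ComparisonTable:
    """Pick the criterion-minimising converged fit, with its |ΔIC| <= delta ties.

    Non-converged fits are excluded from selection (their likelihoods are not
    trustworthy); at least one converged fit is required.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to select among")
    score = {f.family: getattr(f, criterion) for f in ok}
    best = min(ok, key=lambda f: getattr(f, criterion))
    ties = [f.family for f in ok if score[f.family] - getattr(best, criterion) <= delta]
    return ComparisonTable(
        sample_id=best.sample_id,
        fits={f.family: f for f in fits},
        best_family=best.family,
        tie_set=ties,
        criterion=criterion,
    )


def compare_families(
    sample: ActivitySample,
    families=("uniform", "bimodal", "gaussian_trunc", "gamma", "lognormal", "pareto"),
    criterion: str = "aic",
    delta: float = 2.0,
) -> ComparisonTable:
    """Fit every family to one sample and select the best by ΔIC."""
    fits = [fit_mle(sample, fam) for fam in families]
    table = select_best(fits, criterion=criterion, delta=delta)
    table.sample_id = sample.sample_id
    return table


def comparison_frame(tables: list[ComparisonTable]) -> pd.DataFrame:
    """Stack ComparisonTables into a tidy results DataFrame."""
    rows = [row for t in tables for row in t.to_rows()]
    cols = [
        "sample_id", "family", "n", "converged", "loglik", "aic", "bic",
        "ks_d", "r2_qq", "best_flag", "tie_flag",
    ]
    df = pd.DataFrame(rows)
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]


def bootstrap_r2m(
    samples: list[ActivitySample],
    family,
    n_sub: int = 5000,
    reps: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pooled bootstrap of the Q-Q r-squared for one family.

    Pools all cells across samples; each repetition subsamples ``n_sub``
    cells without replacement, refits the family, and computes
    :func:`r2_qq`. Returns the mean and sd over repetitions.
    """
    fam = _require_family(family)
    pool = np.concatenate([_values(s) for s in samples])
    if pool.size < n_sub:
        raise ValueError(f"pooled cell count {pool.size} < subsample size {n_sub}")
    rng = np.random.default_rng(seed)
    r2s = np.empty(reps)
    for r in range(reps):
        sub = rng.choice(pool, size=n_sub, replace=False)
        fit = fit_mle(sub, fam, compute_gof=False)
        r2s[r] = r2_qq(sub, fam, fit.params) if fit.converged else np.nan
    return float(np.nanmean(r2s)), float(np.nanstd(r2s, ddof=1)) if reps > 1 else 0.0


def anova_oneway(groups: list) -> tuple[float, int, int, float]:
    """One-way ANOVA: ``(F, df1, df2, p)`` with F = MSB/MSW.

    Used to compare per-sample goodness-of-fit metrics across model families
    within a growth condition.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    N = sum(g.size for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df1, df2 = k - 1, N - k
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, df1, df2, 1.0
        raise ValueError("zero within-group variance")
    f = (ssb / df1) / (ssw / df2)
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


def pairwise_welch_holm(groups: dict) -> pd.DataFrame:
    """Pairwise Welch t-tests with Holm-adjusted p-values.

    Post hoc companion to :func:`anova_oneway`; robust to unequal group
    variances.
    """
    names = list(groups)
    rows = []
    for a, b in combinations(names, 2):
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    order = np.argsort(df["p"].to_numpy())
    m = len(df)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * df["p"].iloc[idx])
        adj[idx] = min(1.0, running)
    df["p_holm"] = adj
    return df
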