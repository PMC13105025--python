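"""Candidate activity distributions and maximum-likelihood fitting.

Six families are fit to per-cell activity data: uniform, bimodal (two-component
truncated-Gaussian mixture), truncated Gaussian, gamma, lognormal, and Pareto.
Each encodes a different generating mechanism — equal contribution, on/off
regulation, additive noise about a mean, sums of exponential waiting times,
multiplicative noise, and reinforcing feedbacks, respectively. Activity is
non-negative, so the Gaussian is truncated at zero.

Fitting is by maximum likelihood: closed forms where they exist (uniform,
lognormal, Pareto) and bounded L-BFGS-B from moment-based starting values
otherwise. All log-likelihoods are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import log_ndtr, ndtr, ndtri

from .core_io import ActivitySample

#: distance kept from open interval endpoints when clamping optimizer bounds
_EPS = 1e-10


@dataclass(frozen=True)
class ModelFamily:
    """A candidate distribution family: parameter names and box bounds."""

    name: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]

    @property
    def k(self) -> int:
        """Number of free parameters (as counted in AIC/BIC)."""
        return len(self.param_names)


_INF = np.inf

FAMILIES: dict[str, ModelFamily] = {
    f.name: f
    for f in (
        ModelFamily("uniform", ("a", "b"), ((-_INF, _INF), (-_INF, _INF))),
        ModelFamily(
            "bimodal",
            ("w", "mu1", "sigma1", "mu2", "sigma2"),
            ((0.0, 1.0), (-_INF, _INF), (0.0, _INF), (-_INF, _INF), (0.0, _INF)),
        ),
        ModelFamily("gaussian_trunc", ("mu", "sigma"), ((-_INF, _INF), (0.0, _INF))),
        ModelFamily("gamma", ("shape", "rate"), ((0.0, _INF), (0.0, _INF))),
        ModelFamily("lognormal", ("mu_log", "sigma"), ((-_INF, _INF), (0.0, _INF))),
        ModelFamily("pareto", ("alpha", "xm"), ((0.0, _INF), (0.0, _INF))),
    )
}


@dataclass
class FitResult:
    """One (sample, family) maximum-likelihood fit with goodness-of-fit metrics.

    For the lognormal, ``params[1]`` is sigma, the log-scale standard
    deviation used throughout as the metabolic-inequality (skew) parameter.
    """

    family: str
    params: np.ndarray
    loglik: float
    n: int
    converged: bool
    message: str = ""
    aic: float = np.nan
    bic: float = np.nan
    ks_d: float = np.nan
    r2_qq: float = np.nan
    sample_id: str = ""

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(FAMILIES[self.family].param_names, np.asarray(self.params, float)))

    def to_row(self) -> dict:
        """Flat mapping for CSV/JSON serialisation."""
        row = {
            "sample_id": self.sample_id,
            "family": self.family,
            "n": self.n,
            "converged": self.converged,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "ks_d": self.ks_d,
            "r2_qq": self.r2_qq,
        }
        row.update(self.param_dict)
        return row


def _require_family(family) -> ModelFamily:
    name = family.name if isinstance(family, ModelFamily) else str(family)
    if name not in FAMILIES:
        raise ValueError(f"unknown family {name!r}; expected one of {sorted(FAMILIES)}")
    return FAMILIES[name]


def _check_params(fam: ModelFamily, params) -> np.ndarray:
    params = np.asarray(params, dtype=float)
    if params.shape != (fam.k,):
        raise ValueError(f"{fam.name} expects {fam.k} parameters {fam.param_names}")
    for name, val, (lo, hi) in zip(fam.param_names, params, fam.bounds):
        if not (lo <= val <= hi) or not np.isfinite(val):
            raise ValueError(f"{fam.name} parameter {name}={val} outside [{lo}, {hi}]")
        if val == lo and lo in (0.0,) and name != "w":
            raise ValueError(f"{fam.name} parameter {name} must be > {lo}")
    if fam.name == "uniform" and params[0] >= params[1]:
        raise ValueError("uniform requires a < b")
    if fam.name == "bimodal" and params[1] > params[3]:
        raise ValueError("bimodal requires mu1 <= mu2")
    return params


def _trunc(mu: float, sigma: float):
    """Normal(mu, sigma) truncated to [0, inf)."""
    return stats.truncnorm(a=-mu / sigma, b=np.inf, loc=mu, scale=sigma)


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _tn_logpdf(x, mu: float, sigma: float) -> np.ndarray:
    """log pdf of N(mu, sigma) truncated to [0, inf); -inf below 0.

    Direct scipy.special form: log phi((x-mu)/s) - log s - log Phi(mu/s);
    avoids the frozen-distribution overhead inside optimizer loops.
    """
    x = np.asarray(x, float)
    z = (x - mu) / sigma
    out = -0.5 * z * z - _LOG_SQRT_2PI - np.log(sigma) - log_ndtr(mu / sigma)
    return np.where(x < 0.0, -np.inf, out)


def _tn_cdf(x, mu: float, sigma: float) -> np.ndarray:
    x = np.asarray(x, float)
    lo = ndtr(-mu / sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (ndtr((x - mu) / sigma) - lo) / (1.0 - lo)
    # mu << 0: all truncated mass is squeezed against 0, so the cdf is 1
    c = np.where(lo < 1.0, c, 1.0)
    return np.clip(np.where(x < 0.0, 0.0, c), 0.0, 1.0)


def _tn_ppf(p, mu: float, sigma: float) -> np.ndarray:
    p = np.asarray(p, float)
    lo = ndtr(-mu / sigma)
    return mu + sigma * ndtri(lo + p * (1.0 - lo))


def _frozen(name: str, params: np.ndarray):
    """Frozen scipy distribution for the single-component families."""
    if name == "uniform":
        a, b = params
        return stats.uniform(loc=a, scale=b - a)
    if name == "gaussian_trunc":
        return _trunc(*params)
    if name == "gamma":
        shape, rate = params
        return stats.gamma(shape, scale=1.0 / rate)
    if name == "lognormal":
        mu_log, sigma = params
        return stats.lognorm(s=sigma, scale=np.exp(mu_log))
    if name == "pareto":
        alpha, xm = params
        return stats.pareto(b=alpha, scale=xm)
    raise AssertionError(name)


def model_logpdf(family, params, x) -> np.ndarray:
    """Log-density (nats) of the named family at positive values ``x``.

    Returns ``-inf`` outside the family's support (e.g. below the Pareto
    minimum ``xm`` or outside the uniform interval).
    """
    fam = _require_family(family)
    params = _check_params(fam, params)
    x = np.asarray(x, dtype=float)
    if fam.name == "bimodal":
        w, mu1, s1, mu2, s2 = params
        with np.errstate(divide="ignore"):
            lp1 = np.log(w) + _tn_logpdf(x, mu1, s1) if w > 0 else np.full_like(x, -np.inf)
            lp2 = (
                np.log1p(-w) + _tn_logpdf(x, mu2, s2)
                if w < 1
                else np.full_like(x, -np.inf)
            )
        return np.logaddexp(lp1, lp2)
    if fam.name == "gaussian_trunc":
        return _tn_logpdf(x, *params)
    return _frozen(fam.name, params).logpdf(x)


def model_cdf(family, params, x) -> np.ndarray:
    """CDF of the named family at ``x`` (nondecreasing, 0/1 at support ends)."""
    fam = _require_family(family)
    params = _check_params(fam, params)
    x = np.asarray(x, dtype=float)
    if fam.name == "bimodal":
        w, mu1, s1, mu2, s2 = params
        return w * _tn_cdf(x, mu1, s1) + (1.0 - w) * _tn_cdf(x, mu2, s2)
    if fam.name == "gaussian_trunc":
        return _tn_cdf(x, *params)
    return _frozen(fam.name, params).cdf(x)


def model_quantile(family, params, p) -> np.ndarray:
    """Generalised inverse of the CDF at probabilities ``p`` in (0, 1)."""
    fam = _require_family(family)
    params = _check_params(fam, params)
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("quantile probabilities must lie strictly inside (0, 1)")
    if fam.name == "bimodal":
        w, mu1, s1, mu2, s2 = params
        q1, q2 = _tn_ppf(p, mu1, s1), _tn_ppf(p, mu2, s2)
        # mixture quantile is bracketed by the extreme component quantiles
        lo, hi = np.minimum(q1, q2), np.maximum(q1, q2)
        return _invert_monotone(lambda x: model_cdf(fam, params, x), p, lo, hi)
    if fam.name == "gaussian_trunc":
        return _tn_ppf(p, *params)
    return _frozen(fam.name, params).ppf(p)


def _invert_monotone(cdf, p, lo, hi, iters: int = 100) -> np.ndarray:
    """Vectorised bisection for a monotone CDF; ~1e-30 relative bracket."""
    lo = np.asarray(lo, float).copy()
    hi = np.asarray(hi, float).copy()
    if np.any(hi < lo):  # pragma: no cover - defensive
        raise ValueError("invalid bracket")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = cdf(mid) < p
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# fitting


def _moment_starts(name: str, x: np.ndarray) -> np.ndarray:
    mean, var = float(np.mean(x)), float(np.var(x))
    sd = max(np.sqrt(var), _EPS)
    if name == "gaussian_trunc":
        return np.array([mean, sd])
    if name == "gamma":
        return np.array([mean**2 / max(var, _EPS), mean / max(var, _EPS)])
    if name == "bimodal":
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        s1 = max(float(np.std(lo)), 1e-3 * sd)
        s2 = max(float(np.std(hi)), 1e-3 * sd)
        return np.array([0.5, float(np.mean(lo)), s1, float(np.mean(hi)), s2])
    raise AssertionError(name)


def _clamped_bounds(fam: ModelFamily, x: np.ndarray) -> list[tuple[float, float]]:
    """Finite-ish optimizer box, clamped ``_EPS`` inside open endpoints."""
    scale = float(np.max(x))
    out = []
    for name, (lo, hi) in zip(fam.param_names, fam.bounds):
        lo = lo + _EPS if lo == 0.0 else lo
        if name == "w":
            lo, hi = _EPS, 1.0 - _EPS
        out.append((lo, hi))
    del scale
    return out


def _closed_form_fit(name: str, x: np.ndarray, n: int):
    """(params, loglik, converged, message) for families with exact MLEs."""
    if name == "uniform":
        a, b = float(np.min(x)), float(np.max(x))
        if b - a <= 1e-12 * max(abs(a), abs(b)):
            return np.array([a, b]), np.nan, False, "degenerate: all values identical"
        return np.array([a, b]), -n * np.log(b - a), True, ""
    if name == "lognormal":
        logs = np.log(x)
        mu, sigma = float(np.mean(logs)), float(np.std(logs, ddof=0))
        if sigma <= 1e-12:
            return np.array([mu, sigma]), np.nan, False, "degenerate: all values identical"
        ll = float(np.sum(stats.norm.logpdf(logs, mu, sigma) - logs))
        return np.array([mu, sigma]), ll, True, ""
    if name == "pareto":
        xm = float(np.min(x))
        s = float(np.sum(np.log(x / xm)))
        if s <= 1e-12 * n:
            return np.array([np.nan, xm]), np.nan, False, "degenerate: all values identical"
        alpha = n / s
        ll = n * np.log(alpha) + n * alpha * np.log(xm) - (alpha + 1) * float(
            np.sum(np.log(x))
        )
        return np.array([alpha, xm]), ll, True, ""
    raise AssertionError(name)


def fit_mle(
    sample: ActivitySample | np.ndarray,
    family,
    starts=None,
    compute_gof: bool = True,
) -> FitResult:
    """Bounded maximum-likelihood fit of one family to one sample.

    Uniform, lognormal and Pareto use their closed-form MLEs (for the Pareto,
    ``xm`` is profiled out as the sample minimum and alpha follows in closed
    form; both count as estimated parameters). The remaining families are
    optimised with L-BFGS-B from moment-based starting values (or ``starts``).
    Optimizer failure yields ``converged=False`` with a message, never an
    exception. AIC/BIC and, when ``compute_gof``, the K-S distance and Q-Q
    r-squared are filled in.
    """
    if isinstance(sample, ActivitySample):
        x, sid = sample.values, sample.sample_id
    else:
        x, sid = np.asarray(sample, dtype=float), ""
    fam = _require_family(family)
    if x.size == 0:
        raise ValueError("cannot fit an empty sample")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("fitting requires finite, strictly positive values (gate first)")
    n = int(x.size)
    if n <= fam.k:
        raise ValueError(f"need n > k = {fam.k} values to fit {fam.name}, got n = {n}")

    if fam.name in ("uniform", "lognormal", "pareto"):
        # exact MLEs; user-supplied starts are irrelevant for these
        params, loglik, converged, message = _closed_form_fit(fam.name, x, n)
    else:
        theta0 = np.asarray(starts, float) if starts is not None else _moment_starts(fam.name, x)
        bounds = _clamped_bounds(fam, x)
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])

        def nll(theta: np.ndarray) -> float:
            if fam.name == "bimodal" and theta[1] > theta[3]:
                theta = np.array([1.0 - theta[0], theta[3], theta[4], theta[1], theta[2]])
            with np.errstate(all="ignore"):
                lp = model_logpdf(fam, theta, x)
            if not np.all(np.isfinite(lp)):
                return 1e300
            return -float(np.sum(lp))

        try:
            res = optimize.minimize(
                nll,
                theta0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"gtol": 1e-8, "maxiter": 500},
            )
            params = np.asarray(res.x, float)
            if fam.name == "bimodal" and params[1] > params[3]:
                # relabel components so mu1 <= mu2 (likelihood is symmetric)
                params = np.array(
                    [1.0 - params[0], params[3], params[4], params[1], params[2]]
                )
            loglik = -float(res.fun)
            converged = bool(res.success) and np.isfinite(loglik)
            message = str(res.message)
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            params = theta0
            loglik, converged, message = np.nan, False, f"optimizer error: {exc}"

    fit = FitResult(
        family=fam.name,
        params=params,
        loglik=loglik,
        n=n,
        converged=converged,
        message=message,
        sample_id=sid,
    )
    if converged:
        fit.aic = 2.0 * fam.k - 2.0 * loglik
        fit.bic = fam.k * np.log(n) - 2.0 * loglik
        if compute_gof and n >= 3:
            from . import model_compare  # late import: model_compare uses this module

            fit.ks_d = model_compare.ks_statistic(x, fam, params)
            try:
                fit.r2_qq = model_compare.r2_qq(x, fam, params)
            except ValueError:
                pass
    return fit


def standard_errors(fit: FitResult, values) -> dict[str, float]:
    """Approximate standard errors of the fitted parameters.

    Regular parameters get observed-information SEs (inverse numerical
    Hessian of the negative log-likelihood; analytic forms for the lognormal
    and Pareto alpha). The non-regular extreme-value estimators — the uniform
    endpoints and the Pareto ``xm`` — have non-Gaussian error laws, so their
    entries are ``nan``; use their exact error distributions instead.
    """
    x = values.values if isinstance(values, ActivitySample) else np.asarray(values, float)
    fam = FAMILIES[fit.family]
    n = fit.n
    if fam.name == "uniform":
        return {"a": np.nan, "b": np.nan}
    if fam.name == "lognormal":
        sigma = fit.params[1]
        return {"mu_log": sigma / np.sqrt(n), "sigma": sigma / np.sqrt(2.0 * n)}
    if fam.name == "pareto":
        return {"alpha": fit.params[0] / np.sqrt(n), "xm": np.nan}

    from statsmodels.tools.numdiff import approx_hess

    def nll(theta):
        with np.errstate(all="ignore"):
            lp = model_logpdf(fam, theta, x)
        return -float(np.sum(lp)) if np.all(np.isfinite(lp)) else 1e300

    hess = approx_hess(np.asarray(fit.params, float), nll)
    try:
        cov = np.linalg.inv(hess)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(fam.k, np.nan)
    return dict(zip(fam.param_names, ses))
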