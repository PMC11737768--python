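"""Fitting the HLEIRD to lifetime data: five estimators and shared plumbing.

Methods
-------
MLE    maximize the log-likelihood
LSE    minimize sum_i [F(x_(i)) - i/(n+1)]^2
WLSE   minimize sum_i w_i [F(x_(i)) - i/(n+1)]^2,  w_i = (n+1)^2 (n+2) / (i (n-i+1))
CVME   minimize 1/(12n) + sum_i [F(x_(i)) - (2i-1)/(2n)]^2
MPS    maximize the mean log cdf-spacing H = (n+1)^{-1} sum log D_i,
       D_i = F(x_(i)) - F(x_(i-1)), with F(x_(0)) = 0 and F(x_(n+1)) = 1

The identifiability ridge
-------------------------
The law depends on (alpha, lam) only through theta = alpha*lam, so every
objective above is a function of (theta, sigma) alone and the three-parameter
problem is not identifiable.  Optimization is therefore carried out over
(log theta, log sigma) — a coarse grid (log theta in [-3, 5], sigma matched to
the sample median through the closed-form median) followed by Nelder-Mead
refinement from the best grid points and, for the MLE, an analytic-gradient
polish.  The reported (alpha, lam) split of theta follows the start point
(default alpha = 1).  A "free" three-parameter mode (``free_shapes=True``,
start required) reproduces the conventional unconstrained optimization used in
published tables; the split it reports is start-dependent by construction.

Wald intervals use the observed information of the identifiable (theta, sigma)
pair; a 3x3 pseudo-inverse version on (sigma, alpha, lam) is also reported for
table comparison, loudly flagged because the ridge makes that matrix singular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

from . import distribution as dist
from .data import LifetimeSample
from .params import HleirdParams

__all__ = [
    "FitResult",
    "HalfLogisticEIRModel",
    "neg_log_likelihood",
    "score",
    "score_and_information",
    "cdf_param_derivatives",
    "ecdf_positions",
    "lse_criterion",
    "wlse_criterion",
    "cvm_criterion",
    "mps_mean_log_spacing",
    "fit_mle",
    "fit_lse",
    "fit_wlse",
    "fit_cvm",
    "fit_mps",
    "METHODS",
]

METHODS = ("mle", "lse", "wlse", "cvme", "mps")

_GRID_LOG_THETA = np.linspace(-3.0, 5.0, 17)


def _as_sample(sample) -> LifetimeSample:
    return sample if isinstance(sample, LifetimeSample) else LifetimeSample(np.asarray(sample))


# ---------------------------------------------------------------------------
# objectives on the identifiable pair
# ---------------------------------------------------------------------------


def _loglik_ts(theta: float, sigma: float, x: np.ndarray) -> float:
    """Log-likelihood as a function of the identifiable pair (theta, sigma)."""
    if not (theta > 0 and sigma > 0):
        return -np.inf
    n = x.size
    with np.errstate(over="ignore"):
        z = (sigma / x) ** 2
    lb = np.log(-np.expm1(-z))
    val = (
        n * (math.log(4.0 * theta) + 2.0 * math.log(sigma))
        - 3.0 * np.sum(np.log(x))
        - np.sum(z)
        + (theta - 1.0) * np.sum(lb)
        - 2.0 * np.sum(np.log1p(np.exp(theta * lb)))
    )
    return float(val) if np.isfinite(val) else -np.inf


def _cdf_ts(xs: np.ndarray, theta: float, sigma: float) -> np.ndarray:
    lu = theta * np.log(-np.expm1(-((sigma / xs) ** 2)))
    return -np.expm1(lu) / (1.0 + np.exp(lu))


def ecdf_positions(n: int):
    """Order index i, plotting positions i/(n+1) and (2i-1)/(2n), and WLS weights.

    Returns a DataFrame with columns ``i``, ``lse_position``, ``cvm_position``,
    ``wls_weight`` (the weight (n+1)^2 (n+2) / (i (n-i+1))).
    """
    i = np.arange(1, n + 1)
    return pd.DataFrame(
        {
            "i": i,
            "lse_position": i / (n + 1.0),
            "cvm_position": (2.0 * i - 1.0) / (2.0 * n),
            "wls_weight": (n + 1.0) ** 2 * (n + 2.0) / (i * (n - i + 1.0)),
        }
    )


def _lse_ts(theta, sigma, xs):
    n = xs.size
    i = np.arange(1, n + 1)
    F = _cdf_ts(xs, theta, sigma)
    return float(np.sum((F - i / (n + 1.0)) ** 2))


def _wlse_ts(theta, sigma, xs):
    n = xs.size
    i = np.arange(1, n + 1)
    w = (n + 1.0) ** 2 * (n + 2.0) / (i * (n - i + 1.0))
    F = _cdf_ts(xs, theta, sigma)
    return float(np.sum(w * (F - i / (n + 1.0)) ** 2))


def _cvm_ts(theta, sigma, xs):
    n = xs.size
    i = np.arange(1, n + 1)
    F = _cdf_ts(xs, theta, sigma)
    return float(1.0 / (12.0 * n) + np.sum((F - (2.0 * i - 1.0) / (2.0 * n)) ** 2))


def _mps_ts(theta, sigma, xs):
    """Mean log spacing with the Cheng–Amin tie correction.

    Exact ties make a spacing identically zero; the corresponding log D_i is
    replaced by the log-density at the tied point, the standard remedy that
    keeps H finite (both embedded fiber datasets contain ties).
    """
    n = xs.size
    p = HleirdParams.from_theta(theta, sigma)
    F = _cdf_ts(xs, theta, sigma)
    spac = np.empty(n + 1)
    spac[0] = F[0]
    spac[1:n] = np.diff(F)
    lu = theta * np.log(-np.expm1(-((sigma / xs[-1]) ** 2)))
    spac[n] = 2.0 * np.exp(lu) / (1.0 + np.exp(lu))  # survival at the maximum
    logd = np.empty(n + 1)
    tied = np.zeros(n + 1, dtype=bool)
    tied[1:n] = xs[1:] == xs[:-1]
    with np.errstate(divide="ignore"):
        logd[~tied] = np.log(np.maximum(spac[~tied], 1e-300))
    if tied.any():
        logd[tied] = dist.logpdf(xs[np.flatnonzero(tied)], p)
    return float(np.mean(logd))


def mps_spacings(p: HleirdParams, sample) -> np.ndarray:
    """The n+1 cdf spacings D_i (telescoping to 1) at the given parameters."""
    xs = _as_sample(sample).sorted_values
    F = np.asarray(dist.cdf(xs, p))
    return np.diff(np.concatenate(([0.0], F, [1.0])))


_OBJECTIVES = {
    # name -> (function(theta, sigma, xs), sign: +1 minimize the value as-is / -1 maximize)
    "mle": (lambda t, s, xs: -_loglik_ts(t, s, xs), -1),
    "lse": (_lse_ts, +1),
    "wlse": (_wlse_ts, +1),
    "cvme": (_cvm_ts, +1),
    "mps": (lambda t, s, xs: -_mps_ts(t, s, xs), -1),
}


# ---------------------------------------------------------------------------
# likelihood derivatives
# ---------------------------------------------------------------------------


def neg_log_likelihood(p: HleirdParams, sample) -> float:
    """Negative log-likelihood -l(p); +inf at infeasible points instead of raising."""
    x = _as_sample(sample).values
    ll = _loglik_ts(p.theta, p.sigma, x)
    return -ll


def score(p: HleirdParams, sample) -> np.ndarray:
    """Analytic score (d l / d sigma, d l / d alpha, d l / d lam).

    The (alpha, lam) components are proportional through theta (the ridge), so
    alpha * score_alpha == lam * score_lam identically.
    """
    x = _as_sample(sample).values
    n = x.size
    sigma, alpha, lam = p.sigma, p.alpha, p.lam
    theta = p.theta
    z = (sigma / x) ** 2
    lb = np.log(-np.expm1(-z))
    w = expit(theta * lb)  # u/(1+u)
    t1 = np.sum(lb)
    t2 = np.sum(lb * w)
    g = np.exp(-z) / (x**2 * (-np.expm1(-z)))  # (1-b)/(x^2 b)
    d_sigma = (
        2.0 * n / sigma
        - 2.0 * sigma * np.sum(1.0 / x**2)
        + 2.0 * sigma * (theta - 1.0) * np.sum(g)
        - 4.0 * sigma * theta * np.sum(g * w)
    )
    d_alpha = n / alpha + lam * t1 - 2.0 * lam * t2
    d_lam = n / lam + alpha * t1 - 2.0 * alpha * t2
    return np.array([d_sigma, d_alpha, d_lam])


def score_and_information(p: HleirdParams, sample):
    """Score vector and observed information matrix on (sigma, alpha, lam).

    The information is the negative Hessian of the log-likelihood, obtained by
    central differences of the analytic score and symmetrized.  Along the ridge
    direction (0, alpha, -lam) the log-likelihood is flat, so this matrix is
    singular by construction; standard errors must use a pseudo-inverse or the
    identifiable (theta, sigma) reparameterization (see :func:`fit_mle`).
    """
    x = _as_sample(sample)
    s = score(p, x)
    vals = np.array([p.sigma, p.alpha, p.lam])
    H = np.zeros((3, 3))
    for j in range(3):
        h = 1e-5 * max(abs(vals[j]), 1e-3)
        up, dn = vals.copy(), vals.copy()
        up[j] += h
        dn[j] -= h
        su = score(HleirdParams(*up), x)
        sd = score(HleirdParams(*dn), x)
        H[:, j] = (su - sd) / (2.0 * h)
    H = 0.5 * (H + H.T)
    return s, -H


def cdf_param_derivatives(x, p: HleirdParams) -> np.ndarray:
    """Partial derivatives of the cdf in (sigma, alpha, lam) at x.

    With b = 1 - e^{-(sigma/x)^2} and u = b^theta,
        dF/dsigma = -4 sigma theta u (1-b) / (x^2 b (1+u)^2)   (< 0),
        dF/dalpha = -2 lam  log(b) u / (1+u)^2                 (> 0),
        dF/dlam   = -2 alpha log(b) u / (1+u)^2                (> 0);
    alpha * dF/dalpha == lam * dF/dlam exactly (theta is the only shape).
    """
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(arr <= 0):
        raise ValueError("x must be positive")
    sigma, alpha, lam = p.sigma, p.alpha, p.lam
    theta = p.theta
    z = (sigma / arr) ** 2
    b = -np.expm1(-z)
    lb = np.log(b)
    u = np.exp(theta * lb)
    denom = (1.0 + u) ** 2
    d_sigma = -4.0 * sigma * theta * u * np.exp(-z) / (arr**2 * b * denom)
    d_alpha = -2.0 * lam * lb * u / denom
    d_lam = -2.0 * alpha * lb * u / denom
    out = np.stack([d_sigma, d_alpha, d_lam])
    return out[:, 0] if np.asarray(x).shape == () else out


# convenience wrappers for the public criterion surface --------------------


def lse_criterion(p: HleirdParams, sample) -> float:
    """Ordinary least-squares criterion at the given parameters."""
    return _lse_ts(p.theta, p.sigma, _as_sample(sample).sorted_values)


def wlse_criterion(p: HleirdParams, sample) -> float:
    return _wlse_ts(p.theta, p.sigma, _as_sample(sample).sorted_values)


def cvm_criterion(p: HleirdParams, sample) -> float:
    return _cvm_ts(p.theta, p.sigma, _as_sample(sample).sorted_values)


def mps_mean_log_spacing(p: HleirdParams, sample) -> float:
    return _mps_ts(p.theta, p.sigma, _as_sample(sample).sorted_values)


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates and diagnostics from one fitting method.

    ``objective_at_optimum`` holds the log-likelihood for MLE, the minimized
    criterion for LSE/WLSE/CVME and the mean log-spacing for MPS.  Standard
    errors are reported only for the MLE: ``std_errors_identifiable`` on the
    well-posed (theta, sigma) pair, and ``std_errors`` on (sigma, alpha, lam)
    from the pseudo-inverse of the (singular) 3x3 observed information —
    ``ridge_degenerate`` flags that those are split-dependent.
    """

    method: str
    params: HleirdParams
    objective_at_optimum: float
    converged: bool
    n_evaluations: int
    sample: LifetimeSample = field(repr=False)
    level: float = 0.95
    std_errors: dict | None = None
    std_errors_identifiable: dict | None = None
    confidence_intervals: dict | None = None
    ridge_degenerate: bool = False

    @property
    def theta(self) -> float:
        return self.params.theta

    @property
    def sigma(self) -> float:
        return self.params.sigma

    @property
    def llf(self) -> float:
        """Log-likelihood at the estimates (computed for any method)."""
        return -neg_log_likelihood(self.params, self.sample)

    @property
    def k_params(self) -> int:
        return 3

    def information_criteria(self):
        """AIC/CAIC/BIC/HQIC at the fitted parameters (natural logs, q = 3)."""
        from .gof import information_criteria

        return information_criteria(self.llf, self.k_params, self.sample.n)

    @property
    def aic(self) -> float:
        return self.information_criteria().aic

    def fitted_cdf(self):
        """The fitted cdf as a callable x -> F(x)."""
        p = self.params
        return lambda x: dist.cdf(x, p)

    def gof(self, **kwargs):
        """Goodness-of-fit report (K-S, Anderson-Darling, Cramer-von Mises)."""
        from .gof import gof_report

        return gof_report(self.sample, self.fitted_cdf(), **kwargs)

    def summary(self) -> str:
        lines = [
            "Half-logistic exponentiated inverse Rayleigh fit",
            f"  sample: {self.sample.provenance} (n = {self.sample.n})",
            f"  method: {self.method.upper()}   converged: {self.converged}"
            f"   evaluations: {self.n_evaluations}",
            f"  objective at optimum: {self.objective_at_optimum:.6f}",
            f"  theta (= alpha*lam): {self.theta:.6f}   sigma: {self.sigma:.6f}",
            f"  split: alpha = {self.params.alpha:.6f}, lam = {self.params.lam:.6f}"
            + ("  [ridge: split is start-dependent]" if self.ridge_degenerate else ""),
        ]
        if self.std_errors_identifiable:
            se = self.std_errors_identifiable
            z = norm.ppf(0.5 + self.level / 2.0)
            lines.append(
                f"  SE(theta) = {se['theta']:.4f}, SE(sigma) = {se['sigma']:.4f}"
                f"   ({100 * self.level:.0f}% Wald z = {z:.3f})"
            )
        if self.confidence_intervals:
            for name, (lo, hi) in self.confidence_intervals.items():
                lines.append(f"  {100 * self.level:.0f}% CI {name}: [{lo:.4f}, {hi:.4f}]")
        if self.method == "mle":
            ic = self.information_criteria()
            lines.append(
                f"  loglik = {self.llf:.4f}  AIC = {ic.aic:.3f}  BIC = {ic.bic:.3f}"
                f"  HQIC = {ic.hqic:.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "sigma": self.sigma,
            "alpha": self.params.alpha,
            "lam": self.params.lam,
            "theta": self.theta,
            "objective_at_optimum": self.objective_at_optimum,
            "loglik": self.llf,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "ridge_degenerate": self.ridge_degenerate,
        }
        if self.std_errors:
            out["std_errors"] = self.std_errors
        if self.std_errors_identifiable:
            out["std_errors_identifiable"] = self.std_errors_identifiable
        if self.confidence_intervals:
            out["confidence_intervals"] = {
                k: list(v) for k, v in self.confidence_intervals.items()
            }
        if self.method == "mle":
            ic = self.information_criteria()
            out.update(AIC=ic.aic, CAIC=ic.caic, BIC=ic.bic, HQIC=ic.hqic)
        return out


# ---------------------------------------------------------------------------
# optimizer harness
# ---------------------------------------------------------------------------


def _sigma_from_median(theta: float, sample_median: float) -> float:
    """Match sigma so the model median equals the sample median, given theta."""
    return sample_median * math.sqrt(-math.log(-math.expm1(math.log(1.0 / 3.0) / theta)))


def _optimize_ts(method: str, xs: np.ndarray, start: tuple[float, float] | None, restarts: int = 5):
    """Minimize the method's criterion over eta = (log theta, log sigma)."""
    obj_ts, _ = _OBJECTIVES[method]
    evals = [0]

    def obj(eta):
        evals[0] += 1
        t, s = math.exp(eta[0]), math.exp(eta[1])
        return obj_ts(t, s, xs)

    med = float(np.median(xs))
    if start is not None:
        starts = [np.array([math.log(start[0]), math.log(start[1])])]
    else:
        grid = [
            np.array([lt, math.log(_sigma_from_median(math.exp(lt), med))])
            for lt in _GRID_LOG_THETA
        ]
        grid.sort(key=obj)
        starts = grid[:restarts]
    best = None
    for eta0 in starts:
        res = optimize.minimize(
            obj, eta0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if method == "mle":  # gradient polish on the identifiable pair
        def grad(eta):
            t, s = math.exp(eta[0]), math.exp(eta[1])
            p = HleirdParams.from_theta(t, s)
            g = score(p, LifetimeSample(xs))
            # chain rule: d(-l)/dlog theta = -theta*dl/dlam (alpha=1 split), d/dlog sigma = -sigma*dl/dsigma
            return np.array([-t * g[2], -s * g[0]])

        res = optimize.minimize(obj, best.x, jac=grad, method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 200})
        if np.isfinite(res.fun) and res.fun <= best.fun:
            best = res
    theta, sigma = math.exp(best.x[0]), math.exp(best.x[1])
    return theta, sigma, best.fun, bool(best.success or best.fun < np.inf), evals[0]


def _optimize_free(method: str, xs: np.ndarray, start: HleirdParams):
    """Unconstrained three-parameter optimization from an explicit start.

    The objective is ridge-flat in the (alpha, lam) split, so the optimum this
    returns depends on the start by construction; the MLE route uses L-BFGS-B
    with the analytic score, the others Nelder-Mead.
    """
    obj_ts, _ = _OBJECTIVES[method]
    evals = [0]
    sample = LifetimeSample(xs)

    def obj(v):
        evals[0] += 1
        s, a, l = v
        if s <= 0 or a <= 0 or l <= 0:
            return np.inf
        return obj_ts(a * l, s, xs)

    x0 = np.array([start.sigma, start.alpha, start.lam])
    if method == "mle":
        def grad(v):
            return -score(HleirdParams(*v), sample)

        res = optimize.minimize(
            obj, x0, jac=grad, method="L-BFGS-B",
            bounds=[(1e-8, None)] * 3, options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
    else:
        res = optimize.minimize(
            obj, x0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 4000},
        )
    s, a, l = res.x
    return HleirdParams(sigma=s, alpha=a, lam=l), res.fun, bool(res.success), evals[0]


def _mle_uncertainty(result: FitResult) -> None:
    """Attach Wald standard errors and confidence intervals to an MLE result."""
    xs = result.sample.values
    theta, sigma = result.theta, result.sigma

    # observed information on the identifiable pair, central differences of -l
    def nll(v):
        return -_loglik_ts(v[0], v[1], xs)

    v0 = np.array([theta, sigma])
    H = np.zeros((2, 2))
    h = 1e-4 * np.maximum(np.abs(v0), 1e-3)
    for i in range(2):
        for j in range(2):
            vpp = v0.copy(); vpp[i] += h[i]; vpp[j] += h[j]
            vpm = v0.copy(); vpm[i] += h[i]; vpm[j] -= h[j]
            vmp = v0.copy(); vmp[i] -= h[i]; vmp[j] += h[j]
            vmm = v0.copy(); vmm[i] -= h[i]; vmm[j] -= h[j]
            H[i, j] = (nll(vpp) - nll(vpm) - nll(vmp) + nll(vmm)) / (4 * h[i] * h[j])
    H = 0.5 * (H + H.T)
    try:
        cov2 = np.linalg.inv(H)
        se_theta, se_sigma = (math.sqrt(max(c, 0.0)) for c in np.diag(cov2))
    except np.linalg.LinAlgError:
        se_theta = se_sigma = float("nan")
    result.std_errors_identifiable = {"theta": se_theta, "sigma": se_sigma}

    # 3x3 pseudo-inverse SEs at the reported split (ridge-singular, flagged)
    _, info3 = score_and_information(result.params, result.sample)
    cov3 = np.linalg.pinv(info3)
    d = np.sqrt(np.clip(np.diag(cov3), 0.0, None))
    result.std_errors = {"sigma": float(d[0]), "alpha": float(d[1]), "lam": float(d[2])}
    result.ridge_degenerate = True

    z = norm.ppf(0.5 + result.level / 2.0)
    result.confidence_intervals = {
        "theta": (theta - z * se_theta, theta + z * se_theta),
        "sigma": (sigma - z * se_sigma, sigma + z * se_sigma),
    }


def _fit(method: str, sample, start: HleirdParams | None, level: float,
         free_shapes: bool) -> FitResult:
    sample = _as_sample(sample)
    if sample.n < 3:
        raise ValueError("fitting requires at least 3 observations")
    xs = sample.sorted_values
    obj_ts, sign = _OBJECTIVES[method]
    if free_shapes:
        if start is None:
            raise ValueError("free_shapes=True requires an explicit start")
        params, fun, ok, evals = _optimize_free(method, xs, start)
    else:
        st = (start.theta, start.sigma) if start is not None else None
        theta, sigma, fun, ok, evals = _optimize_ts(method, xs, st)
        alpha = start.alpha if start is not None else 1.0
        params = HleirdParams.from_theta(theta, sigma).with_split(alpha)
    objective = -fun if sign < 0 else fun  # report l / H on their natural sign
    result = FitResult(
        method=method, params=params, objective_at_optimum=float(objective),
        converged=ok, n_evaluations=evals, sample=sample, level=level,
        ridge_degenerate=free_shapes,
    )
    if method == "mle":
        _mle_uncertainty(result)
    return result


def fit_mle(sample, start: HleirdParams | None = None, level: float = 0.95,
            free_shapes: bool = False) -> FitResult:
    """Maximum-likelihood fit; Wald intervals at the given confidence level."""
    return _fit("mle", sample, start, level, free_shapes)


def fit_lse(sample, start: HleirdParams | None = None, free_shapes: bool = False) -> FitResult:
    """Ordinary least-squares fit on the order-statistic cdf positions i/(n+1)."""
    return _fit("lse", sample, start, 0.95, free_shapes)


def fit_wlse(sample, start: HleirdParams | None = None, free_shapes: bool = False) -> FitResult:
    """Weighted least-squares fit with weights (n+1)^2 (n+2) / (i (n-i+1))."""
    return _fit("wlse", sample, start, 0.95, free_shapes)


def fit_cvm(sample, start: HleirdParams | None = None, free_shapes: bool = False) -> FitResult:
    """Minimum Cramer-von Mises distance fit."""
    return _fit("cvme", sample, start, 0.95, free_shapes)


def fit_mps(sample, start: HleirdParams | None = None, free_shapes: bool = False) -> FitResult:
    """Maximum product of spacings fit (Cheng–Amin tie correction)."""
    return _fit("mps", sample, start, 0.95, free_shapes)


_FITTERS = {"mle": fit_mle, "lse": fit_lse, "wlse": fit_wlse, "cvme": fit_cvm, "mps": fit_mps}


class HalfLogisticEIRModel:
    """HLEIRD model bound to a lifetime sample, statsmodels-style.

    Examples
    --------
    >>> from hleird import load_builtin, HalfLogisticEIRModel
    >>> res = HalfLogisticEIRModel(load_builtin("carbon_fiber_20mm")).fit()
    >>> print(res.summary())        # doctest: +SKIP
    """

    def __init__(self, data, name: str | None = None):
        self.sample = _as_sample(data)
        if name is not None:
            object.__setattr__(self.sample, "provenance", name)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, column: str) -> "HalfLogisticEIRModel":
        return cls(df[column].to_numpy(dtype=float), name=column)

    def nloglike(self, params: HleirdParams) -> float:
        return neg_log_likelihood(params, self.sample)

    def score(self, params: HleirdParams) -> np.ndarray:
        return score(params, self.sample)

    def information(self, params: HleirdParams) -> np.ndarray:
        return score_and_information(params, self.sample)[1]

    def fit(self, method: str = "mle", start: HleirdParams | None = None,
            level: float = 0.95, free_shapes: bool = False) -> FitResult:
        method = method.lower()
        if method not in _FITTERS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        if method == "mle":
            return fit_mle(self.sample, start=start, level=level, free_shapes=free_shapes)
        return _FITTERS[method](self.sample, start=start, free_shapes=free_shapes)

    def fit_all(self, **kwargs) -> dict[str, FitResult]:
        """Fit every method; returns a dict method -> FitResult."""
        return {m: self.fit(m, **kwargs) for m in METHODS}
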