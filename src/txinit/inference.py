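"""Censoring-aware likelihoods and maximum-likelihood fitting.

Observed intervals are known only up to the sampling grid (bounds
(lb, ub]) or are right-censored at the end of the observation window
(bounds (lb, inf)).  The log-likelihood of a record is therefore
log[F(ub) - F(lb)] or log[1 - F(lb)] under the model's interval cdf, and
fitting maximizes the summed censored log-likelihood over log-rate
coordinates with multi-start local optimization.  Uncertainty comes from
the observed information (numerical Hessian) and the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from .models import (
    InitiationModel,
    MomentsSummary,
    _eig_factors_perturbed,
    build_phase_type,
    survival,
)
from .simulate import IntervalRecord

LOG_RATE_LO = np.log(1e-7)
LOG_RATE_HI = np.log(10.0)

# finite stand-in for -inf log-likelihoods: keeps line searches backtracking
# instead of aborting on non-finite objective values
BIG_PENALTY = 1e12


@dataclass(frozen=True)
class ModelStructure:
    """Descriptor of a candidate scheme: step count and switching flag."""

    n_steps: int
    switching: bool

    def __post_init__(self) -> None:
        if not 1 <= self.n_steps <= 3:
            raise ValueError("n_steps must be in {1, 2, 3}")

    @property
    def n_params(self) -> int:
        return self.n_steps + (2 if self.switching else 0)

    @property
    def param_names(self) -> tuple[str, ...]:
        names = tuple(f"k{j}" for j in range(1, self.n_steps + 1))
        if self.switching:
            names = ("k_on", "k_off") + names
        return names

    def build(self, log_rates: Sequence[float]) -> InitiationModel:
        r = np.exp(np.asarray(log_rates, dtype=float))
        if self.switching:
            return InitiationModel(tuple(r[2:]), k_on=r[0], k_off=r[1])
        return InitiationModel(tuple(r))

    def __str__(self) -> str:  # e.g. "on/off+2step"
        return ("on/off+" if self.switching else "") + f"{self.n_steps}step"


@dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate model.

    ``estimates`` are in log-rate coordinates, ordered as
    ``structure.param_names`` (or named by ``param_names`` for joint
    temperature fits); ``covariance`` is the inverse observed information.
    """

    model_spec: str
    estimates: np.ndarray
    loglik: float
    covariance: np.ndarray
    n_exact: int
    n_censored: int
    converged: bool
    n_starts_used: int
    param_names: tuple[str, ...] = ()
    structure: ModelStructure | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.estimates)

    @property
    def rates(self) -> np.ndarray:
        return np.exp(self.estimates)

    @property
    def model(self) -> InitiationModel:
        if self.structure is None:
            raise ValueError("fit has no kinetic structure attached")
        return self.structure.build(self.estimates)

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.covariance), 0.0))


# ---------------------------------------------------------------------------
# record handling

def as_bounds(records) -> tuple[np.ndarray, np.ndarray]:
    """Extract (lb, ub) arrays from records (list of IntervalRecord or frame)."""
    if isinstance(records, pd.DataFrame):
        lb = records["lb_s"].to_numpy(dtype=float)
        ub = records["ub_s"].to_numpy(dtype=float)
    else:
        lb = np.array([r.lb_s for r in records], dtype=float)
        ub = np.array([r.ub_s for r in records], dtype=float)
    if lb.size and (np.any(lb < 0) or np.any(lb >= ub)):
        raise ValueError("records must satisfy 0 <= lb < ub")
    return lb, ub


@dataclass(frozen=True)
class GroupedData:
    """Records compressed to unique bound pairs with multiplicities."""

    bounded_lb: np.ndarray
    bounded_ub: np.ndarray
    bounded_n: np.ndarray
    censored_lb: np.ndarray
    censored_n: np.ndarray

    @property
    def n_exact(self) -> int:
        return int(self.bounded_n.sum())

    @property
    def n_censored(self) -> int:
        return int(self.censored_n.sum())

    @classmethod
    def from_records(cls, records) -> "GroupedData":
        lb, ub = as_bounds(records)
        cens = np.isinf(ub)
        blb, bub = np.round(lb[~cens], 9), np.round(ub[~cens], 9)
        pairs, counts = np.unique(np.column_stack([blb, bub]), axis=0, return_counts=True) \
            if blb.size else (np.empty((0, 2)), np.empty(0, dtype=int))
        clb, ccounts = np.unique(np.round(lb[cens], 9), return_counts=True)
        return cls(pairs[:, 0], pairs[:, 1], counts, clb, ccounts)


def _grouped_loglik(
    surv: Callable[[np.ndarray], np.ndarray],
    g: GroupedData,
    integ_cdf: Callable[[np.ndarray], np.ndarray] | None = None,
) -> float:
    """Censored log-likelihood given survival (and optionally H = int F).

    With ``integ_cdf`` supplied, bounded records use the detection-phase-
    averaged probability [H(ub + d) - 2 H(ub) + H(lb)]/d (d = ub - lb);
    otherwise the plain interval probability F(ub) - F(lb).  Right-censored
    records always contribute log S(lb).
    """
    total = 0.0
    if g.bounded_lb.size:
        if integ_cdf is not None:
            d = g.bounded_ub - g.bounded_lb
            H = integ_cdf(np.concatenate([g.bounded_ub + d, g.bounded_ub, g.bounded_lb]))
            k = g.bounded_ub.size
            p = (H[:k] - 2.0 * H[k:2 * k] + H[2 * k:]) / d
            # records with lb = 0 pool the zero gap (productions detected in
            # the same frame are indistinguishable from adjacent frames)
            zero = g.bounded_lb == 0
            if np.any(zero):
                p = p + np.where(zero, integ_cdf(d) / d, 0.0)
        else:
            p = surv(g.bounded_lb) - surv(g.bounded_ub)
        if np.any(p <= 0):
            return -math.inf
        total += float(g.bounded_n @ np.log(p))
    if g.censored_lb.size:
        if integ_cdf is not None and g.bounded_lb.size:
            # phase-averaged survival over one sampling interval
            d0 = float(np.min(g.bounded_ub - g.bounded_lb))
            Hc = integ_cdf(np.concatenate([g.censored_lb + d0, g.censored_lb]))
            kc = g.censored_lb.size
            s = 1.0 - (Hc[:kc] - Hc[kc:]) / d0
        else:
            s = surv(g.censored_lb)
        if np.any(s <= 0):
            return -math.inf
        total += float(g.censored_n @ np.log(s))
    return total


def _phase_loglik_spectral(fac, g: GroupedData) -> float:
    """Fast phase-averaged log-likelihood from spectral factors of the
    sub-generator (single H evaluation for all required times)."""
    c, lam = fac
    nb, nc = g.bounded_lb.size, g.censored_lb.size
    if not nb:
        # plain survival when no bounded record defines the grid width
        s = np.real(np.exp(np.outer(g.censored_lb, lam)) @ c)
        if np.any(s <= 0):
            return -math.inf
        return float(g.censored_n @ np.log(s))
    d = g.bounded_ub - g.bounded_lb
    d0 = float(np.min(d))
    times = np.concatenate([
        g.bounded_ub + d, g.bounded_ub, g.bounded_lb, d,
        g.censored_lb + d0, g.censored_lb,
    ])
    H = times - np.real((np.expm1(np.outer(times, lam)) / lam) @ c)
    H = np.maximum(H, 0.0)
    total = 0.0
    if nb:
        p = (H[:nb] - 2.0 * H[nb:2 * nb] + H[2 * nb:3 * nb]) / d
        zero = g.bounded_lb == 0
        if np.any(zero):
            p = p + np.where(zero, H[3 * nb:4 * nb] / d, 0.0)
        if np.any(p <= 0):
            return -math.inf
        total += float(g.bounded_n @ np.log(p))
    if nc:
        s = 1.0 - (H[4 * nb:4 * nb + nc] - H[4 * nb + nc:]) / d0
        if np.any(s <= 0):
            return -math.inf
        total += float(g.censored_n @ np.log(s))
    return total


def _gamma_integrated_cdf(a: float, scale: float, t: np.ndarray) -> np.ndarray:
    """H(t) = int_0^t F for a gamma(a, scale): t F_a(t) - a*scale*F_{a+1}(t)."""
    t = np.maximum(np.asarray(t, dtype=float), 0.0)
    return t * stats.gamma.cdf(t, a, scale=scale) \
        - a * scale * stats.gamma.cdf(t, a + 1.0, scale=scale)


def censored_loglik(model, records, dialect: str = "phase") -> float:
    """Censored log-likelihood of records under a model.

    ``model`` is an :class:`InitiationModel`, a frozen scipy gamma, or any
    object with a vectorized ``sf`` method.  ``dialect`` selects how bounded
    (grid-censored) records enter:

    * ``"phase"`` (default): the probability of the observed detection gap,
      averaged over the uniform phase of the sampling grid relative to the
      previous production.  Consistent for data produced by the grid
      observation operator.
    * ``"interval"``: the plain interval probability F(ub) - F(lb), which
      treats the stored bounds as exact truncation limits of the interval.

    Zero-probability records yield -inf rather than an exception.
    """
    if dialect not in ("phase", "interval"):
        raise ValueError(f"unknown likelihood dialect {dialect!r}")
    g = records if isinstance(records, GroupedData) else GroupedData.from_records(records)
    if isinstance(model, InitiationModel):
        pt = build_phase_type(model)
        if dialect == "phase":
            return _phase_loglik_spectral(_eig_factors_perturbed(pt), g)
        surv = lambda t: np.atleast_1d(survival(pt, t))  # noqa: E731
        return _grouped_loglik(surv, g, None)
    if dialect == "phase" and getattr(getattr(model, "dist", None), "name", "") == "gamma":
        a = model.args[0] if model.args else model.kwds["a"]
        scale = model.kwds.get("scale", 1.0)
        return _grouped_loglik(model.sf, g, lambda t: _gamma_integrated_cdf(a, scale, t))
    return _grouped_loglik(model.sf, g)


# ---------------------------------------------------------------------------
# optimization

def _numerical_hessian(f: Callable[[np.ndarray], float], x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with adaptive step."""
    p = len(x)
    h = 1e-4 * np.maximum(1.0, np.abs(x))
    H = np.zeros((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _covariance_from_hessian(H: np.ndarray) -> tuple[np.ndarray, bool]:
    """Inverse observed information; pseudo-inverse when near-singular."""
    try:
        cov = np.linalg.inv(H)
        ok = np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0)
    except np.linalg.LinAlgError:
        ok = False
    if not ok:
        cov = np.linalg.pinv(H)
    # symmetrize against round-off
    return (cov + cov.T) / 2.0, ok


def _start_points(
    structure: ModelStructure, g: GroupedData, n_starts: int, rng: np.random.Generator
) -> np.ndarray:
    """Moment-informed starts plus a seeded Latin-hypercube over the bounds.

    The informed starts stagger the sequential rates geometrically: an
    exactly symmetric start is a saddle point of the likelihood (the
    interval law is invariant under permutation of the sequential rates),
    so gradient methods started there never leave the symmetric manifold.
    """
    lb, ub = g.bounded_lb, g.bounded_ub
    if g.n_exact:
        crude_mean = float(np.average((lb + ub) / 2.0, weights=g.bounded_n))
    else:
        crude_mean = float(np.average(g.censored_lb, weights=g.censored_n)) or 600.0
    crude_mean = max(crude_mean, 1.0)
    m = structure.n_steps
    level = np.log(m / crude_mean)
    starts: list[np.ndarray] = []
    for sigma in (0.0, 1.2, 2.4):
        seq = level + sigma * (np.arange(m) - (m - 1) / 2.0)
        if structure.switching:
            sw = np.array([np.log(1.0 / crude_mean), np.log(1.0 / crude_mean)])
            x0 = np.concatenate([sw, seq])
        else:
            x0 = seq
        starts.append(np.clip(x0, LOG_RATE_LO + 1e-6, LOG_RATE_HI - 1e-6))
        if m == 1 and sigma > 0:
            break  # staggering is a no-op for single-step schemes
    if n_starts > len(starts):
        sampler = qmc.LatinHypercube(d=structure.n_params, seed=rng)
        u = sampler.random(n_starts - len(starts))
        # concentrate random starts around plausible interval time scales
        lo = max(LOG_RATE_LO, np.log(0.001 / crude_mean))
        hi = min(LOG_RATE_HI, np.log(1000.0 / crude_mean))
        starts.extend(lo + u * (hi - lo))
    return np.array(starts)


def _maximize(
    negloglik: Callable[[np.ndarray], float],
    starts: np.ndarray,
    tol: float = 1e-9,
) -> tuple[np.ndarray, float, bool]:
    best_x, best_f, ok = None, math.inf, False
    bounds = [(LOG_RATE_LO, LOG_RATE_HI)] * starts.shape[1]
    for x0 in starts:
        try:
            res = optimize.minimize(
                negloglik, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": tol, "maxiter": 500},
            )
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f, ok = res.x, res.fun, ok or res.success
    if best_x is None:
        best_x = starts[0]
        best_f = negloglik(best_x)
        ok = False
    if not ok and np.isfinite(best_f):
        # line searches on noisy finite-difference gradients occasionally
        # abort; a simplex polish from the best point settles the optimum
        res = optimize.minimize(negloglik, best_x, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if np.isfinite(res.fun) and res.fun <= best_f:
            best_x, best_f = res.x, float(res.fun)
        ok = bool(res.success)
    return best_x, best_f, ok


def fit_model(
    records,
    structure: ModelStructure,
    n_starts: int = 20,
    seed: int | None = None,
    tol: float = 1e-9,
    dialect: str = "phase",
    extra_starts: Sequence[np.ndarray] = (),
) -> FitResult:
    """Censored ML fit of one candidate initiation scheme.

    Optimizes in log-rate space (bounds [1e-7, 10] 1/s) from ``n_starts``
    seeded starting points (plus any ``extra_starts``, e.g. warm starts
    from a simpler nested scheme); the covariance is the inverse observed
    information at the optimum.
    """
    g = records if isinstance(records, GroupedData) else GroupedData.from_records(records)
    if g.n_exact + g.n_censored < 1:
        raise ValueError("at least one record is required")
    rng = np.random.default_rng(seed)

    def negloglik(theta: np.ndarray) -> float:
        try:
            model = structure.build(theta)
        except ValueError:
            return BIG_PENALTY
        ll = censored_loglik(model, g, dialect)
        return BIG_PENALTY if ll == -math.inf else -ll

    starts = _start_points(structure, g, n_starts, rng)
    if len(extra_starts):
        extra = np.clip(np.asarray(extra_starts, dtype=float),
                        LOG_RATE_LO + 1e-6, LOG_RATE_HI - 1e-6)
        starts = np.vstack([starts, extra])
    xhat, fmin, converged = _maximize(negloglik, starts, tol)
    H = _numerical_hessian(negloglik, xhat)
    cov, pd_ok = _covariance_from_hessian(H)
    return FitResult(
        model_spec=str(structure),
        estimates=xhat,
        loglik=-fmin,
        covariance=cov,
        n_exact=g.n_exact,
        n_censored=g.n_censored,
        converged=bool(converged),
        n_starts_used=len(starts),
        param_names=structure.param_names,
        structure=structure,
        extra={"information_pd": pd_ok},
    )


def _gamma_grouped_loglik(a: float, scale: float, g: GroupedData, dialect: str) -> float:
    """Censored gamma log-likelihood via regularized incomplete gammas."""
    from scipy import special

    total = 0.0
    if g.bounded_lb.size:
        if dialect == "phase":
            d = g.bounded_ub - g.bounded_lb
            ts = np.concatenate([g.bounded_ub + d, g.bounded_ub, g.bounded_lb, d])
            H = ts * special.gammainc(a, ts / scale) \
                - a * scale * special.gammainc(a + 1.0, ts / scale)
            k = g.bounded_ub.size
            p = (H[:k] - 2.0 * H[k:2 * k] + H[2 * k:3 * k]) / d
            zero = g.bounded_lb == 0
            if np.any(zero):
                p = p + np.where(zero, H[3 * k:] / d, 0.0)
        else:
            p = special.gammaincc(a, g.bounded_lb / scale) \
                - special.gammaincc(a, g.bounded_ub / scale)
        if np.any(p <= 0):
            return -math.inf
        total += float(g.bounded_n @ np.log(p))
    if g.censored_lb.size:
        s = special.gammaincc(a, g.censored_lb / scale)
        if np.any(s <= 0):
            return -math.inf
        total += float(g.censored_n @ np.log(s))
    return total


def fit_censored_gamma(
    records, n_starts: int = 4, seed: int | None = None, dialect: str = "phase"
) -> tuple[FitResult, MomentsSummary]:
    """Descriptive censored-gamma fit (free mean and sd).

    Uses the same interval/right-censoring likelihood as the kinetic models;
    returns the fit plus the moments (mean, sd, cv, median-to-mean) of the
    fitted gamma.  A gamma is assumed because moments cannot be estimated
    from censored data without a model.
    """
    g = records if isinstance(records, GroupedData) else GroupedData.from_records(records)
    if g.n_exact == 0:
        raise ValueError("all records are right-censored; gamma moments not identifiable")
    rng = np.random.default_rng(seed)
    crude = float(np.average((g.bounded_lb + g.bounded_ub) / 2.0, weights=g.bounded_n))
    crude = max(crude, 1.0)

    def negloglik(theta: np.ndarray) -> float:
        a, scale = np.exp(theta)
        ll = _gamma_grouped_loglik(a, scale, g, dialect)
        return BIG_PENALTY if ll == -math.inf else -ll

    bounds = [(np.log(1e-2), np.log(1e3)), (np.log(1e-2), np.log(1e8))]
    starts = [np.array([0.0, np.log(crude)])]
    for _ in range(n_starts - 1):
        starts.append(np.array([rng.uniform(-2, 2), np.log(crude) + rng.uniform(-2, 2)]))
    best_x, best_f, ok = None, math.inf, False
    for x0 in starts:
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-11, "maxiter": 500})
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f, ok = res.x, res.fun, ok or res.success
    if best_x is None or not np.isfinite(best_f):
        raise ValueError("gamma fit failed to evaluate")
    if not ok:
        res = optimize.minimize(negloglik, best_x, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 1000})
        if np.isfinite(res.fun) and res.fun <= best_f:
            best_x, best_f, ok = res.x, float(res.fun), bool(res.success)
    H = _numerical_hessian(negloglik, best_x)
    cov, _ = _covariance_from_hessian(H)
    fit = FitResult(
        model_spec="gamma",
        estimates=best_x,
        loglik=-best_f,
        covariance=cov,
        n_exact=g.n_exact,
        n_censored=g.n_censored,
        converged=bool(ok),
        n_starts_used=len(starts),
        param_names=("shape", "scale"),
    )
    a, scale = np.exp(best_x)
    mean = a * scale
    sd = math.sqrt(a) * scale
    median = float(stats.gamma.ppf(0.5, a, scale=scale))
    moments = MomentsSummary(mean=mean, sd=sd, cv=sd / mean, cv_sq=(sd / mean) ** 2,
                             median_to_mean=median / mean)
    return fit, moments


def delta_method_interval(
    fit: FitResult, transform: Callable[[np.ndarray], float]
) -> dict[str, float | tuple[float, float]]:
    """Propagate the fit covariance through a differentiable transform.

    Returns {estimate, sd, ci95} with ci95 = estimate +/- 1.96 sd.
    """
    if not fit.converged:
        raise ValueError("delta method requires a converged fit")
    x = fit.estimates
    est = float(transform(x))
    h = 1e-6 * np.maximum(1.0, np.abs(x))
    grad = np.array([
        (transform(x + _e(i, h, len(x))) - transform(x - _e(i, h, len(x)))) / (2 * h[i])
        for i in range(len(x))
    ])
    var = float(grad @ fit.covariance @ grad)
    sd = math.sqrt(max(var, 0.0))
    return {"estimate": est, "sd": sd, "ci95": (est - 1.96 * sd, est + 1.96 * sd)}


def normal_ci95(estimate: float, sd: float) -> tuple[float, float]:
    """Delta-method style 95% CI from a point estimate and its sd."""
    return (estimate - 1.96 * sd, estimate + 1.96 * sd)


def _e(i: int, h: np.ndarray, p: int) -> np.ndarray:
    v = np.zeros(p)
    v[i] = h[i]
    return v
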