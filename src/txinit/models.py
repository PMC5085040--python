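"""Stochastic model of multi-step transcription initiation.

The promoter is described by an on/off (telegraph) switch in series with a
short chain of 1-3 sequential, effectively irreversible steps::

    P_off <-- k_off / k_on --> P_on --k1--> I1 --k2--> I2 --k3--> production

The time between consecutive RNA productions (the observable) is the
absorption time of the corresponding finite continuous-time Markov chain,
i.e. a phase-type distribution.  This module builds that representation and
provides densities, cumulative probabilities, moments, burst statistics and
the analytic noise bounds of the model.

All rates are in 1/s; all durations in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq


class InvalidModelError(ValueError):
    """Raised when a kinetic scheme violates its invariants."""


@dataclass(frozen=True)
class InitiationModel:
    """Kinetic parameters of the initiation scheme.

    Parameters
    ----------
    seq_rates
        Rates of the 1-3 sequential steps (1/s).  The first entry is ``k1``,
        the effective forward rate for an active gene; then ``k2``, ``k3``.
    k_on, k_off
        Telegraph switching rates (1/s); both ``None`` for a purely
        sequential scheme.
    """

    seq_rates: tuple[float, ...]
    k_on: float | None = None
    k_off: float | None = None

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.seq_rates)
        object.__setattr__(self, "seq_rates", rates)
        if not 1 <= len(rates) <= 3:
            raise InvalidModelError("seq_rates must contain 1-3 rates")
        if (self.k_on is None) != (self.k_off is None):
            raise InvalidModelError("k_on and k_off must be given together")
        for r in rates + ((self.k_on, self.k_off) if self.has_switching else ()):
            if not (np.isfinite(r) and r > 0):
                raise InvalidModelError(f"rates must be positive and finite, got {r}")

    @property
    def has_switching(self) -> bool:
        return self.k_on is not None

    @property
    def n_steps(self) -> int:
        return len(self.seq_rates)

    def canonical(self) -> "InitiationModel":
        """Return the model with sequential rates sorted fastest-first.

        The interval distribution is invariant under permutation of the
        sequential rates, so the sorted order is the reportable one.
        """
        return InitiationModel(
            tuple(sorted(self.seq_rates, reverse=True)), self.k_on, self.k_off
        )


@dataclass(frozen=True)
class PhaseTypeRepresentation:
    """Absorbing-chain form of the interval distribution.

    ``sub_generator`` collects the transition rates among transient states;
    absorption (RNA production) occurs with the exit-rate vector
    ``-sub_generator @ 1``.
    """

    initial_distribution: np.ndarray
    sub_generator: np.ndarray
    state_labels: tuple[str, ...] = field(default=())

    @property
    def exit_rates(self) -> np.ndarray:
        return -self.sub_generator @ np.ones(self.sub_generator.shape[0])


@dataclass(frozen=True)
class MomentsSummary:
    mean: float
    sd: float
    cv: float
    cv_sq: float
    median_to_mean: float


def build_phase_type(model: InitiationModel) -> PhaseTypeRepresentation:
    """Build the phase-type representation of the interval distribution.

    State order: ``on@step1``, (``off@step1`` if switching), ``step2``, ...
    A production restarts the chain in ``on@step1``, so the initial
    distribution puts all mass there.
    """
    m = model.n_steps
    k1 = model.seq_rates[0]
    if model.has_switching:
        n = m + 1
        labels = ["on@step1", "off@step1"] + [f"step{j}" for j in range(2, m + 1)]
        T = np.zeros((n, n))
        T[0, 0] = -(model.k_off + k1)
        T[0, 1] = model.k_off
        if m > 1:
            T[0, 2] = k1
        T[1, 0] = model.k_on
        T[1, 1] = -model.k_on
        for j in range(2, m + 1):
            i = j  # state index of step j
            T[i, i] = -model.seq_rates[j - 1]
            if j < m:
                T[i, i + 1] = model.seq_rates[j - 1]
    else:
        n = m
        labels = ["on@step1"] + [f"step{j}" for j in range(2, m + 1)]
        T = np.diag([-r for r in model.seq_rates])
        for j in range(m - 1):
            T[j, j + 1] = model.seq_rates[j]
    alpha = np.zeros(n)
    alpha[0] = 1.0
    return PhaseTypeRepresentation(alpha, T, tuple(labels))


def _eig_factors(pt: PhaseTypeRepresentation):
    """Spectral factors c_i, lam_i with S(t) = Re(sum c_i exp(lam_i t)).

    Returns None when the eigenvector matrix is ill-conditioned (e.g.
    Erlang-like schemes with equal rates give a defective generator), in
    which case callers fall back to dense matrix exponentials.
    """
    T = pt.sub_generator
    lam, V = np.linalg.eig(T)
    try:
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    if not np.isfinite(cond) or cond > 1e8:
        return None
    ones = np.ones(T.shape[0])
    c = (pt.initial_distribution @ V) * np.linalg.solve(V, ones)
    return c, lam


def _eig_factors_perturbed(pt: PhaseTypeRepresentation):
    """Spectral factors with a tiny diagonal perturbation when defective.

    Degenerate eigensystems (e.g. Erlang schemes with equal rates) are
    split by a relative 1e-9 diagonal shift; the induced error in S(t) is
    far below optimization tolerances.  Exact evaluation paths (density,
    cdf, moments) use the dense matrix-exponential fallback instead.
    """
    fac = _eig_factors(pt)
    if fac is not None:
        return fac
    T = pt.sub_generator
    n = T.shape[0]
    scale = float(np.abs(np.diag(T)).max())
    pert = T + np.diag(scale * 1e-9 * np.arange(1, n + 1))
    lam, V = np.linalg.eig(pert)
    c = (pt.initial_distribution @ V) * np.linalg.solve(V, np.ones(n))
    return c, lam


def survival(pt: PhaseTypeRepresentation, t) -> np.ndarray | float:
    """S(t) = P(interval > t) = alpha @ expm(T t) @ 1, vectorized in t."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    fac = _eig_factors(pt)
    if fac is not None:
        c, lam = fac
        S = np.real(np.exp(np.outer(t_arr, lam)) @ c)
    else:
        ones = np.ones(pt.sub_generator.shape[0])
        S = np.array(
            [pt.initial_distribution @ expm(pt.sub_generator * ti) @ ones for ti in t_arr]
        )
    S = np.clip(S, 0.0, 1.0)
    return S if np.ndim(t) else float(S[0])


def interval_density(pt: PhaseTypeRepresentation, t) -> np.ndarray | float:
    """Probability density f(t) = alpha @ expm(T t) @ t0 of the interval."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    t0 = pt.exit_rates
    fac = _eig_factors(pt)
    if fac is not None:
        T = pt.sub_generator
        lam, V = np.linalg.eig(T)
        c = (pt.initial_distribution @ V) * np.linalg.solve(V, t0)
        f = np.real(np.exp(np.outer(t_arr, lam)) @ c)
    else:
        f = np.array(
            [pt.initial_distribution @ expm(pt.sub_generator * ti) @ t0 for ti in t_arr]
        )
    f = np.maximum(f, 0.0)
    return f if np.ndim(t) else float(f[0])


def interval_cdf(pt: PhaseTypeRepresentation, t) -> np.ndarray | float:
    """Cumulative probability F(t) = 1 - S(t)."""
    return 1.0 - survival(pt, t)


def integrated_cdf(pt: PhaseTypeRepresentation, t) -> np.ndarray | float:
    """H(t) = integral of F over [0, t] (0 for t <= 0).

    Used by the detection-phase-averaged likelihood: the probability that
    the detection gap equals g is the second difference
    [H(g + d) - 2 H(g) + H(g - d)]/d on the sampling grid d.
    """
    t_arr = np.maximum(np.atleast_1d(np.asarray(t, dtype=float)), 0.0)
    fac = _eig_factors(pt)
    if fac is not None:
        c, lam = fac
        IS = np.real((np.expm1(np.outer(t_arr, lam)) / lam) @ c)
    else:
        T = pt.sub_generator
        n = T.shape[0]
        ones = np.ones(n)
        negT_inv_one = np.linalg.solve(-T, ones)
        IS = np.array(
            [pt.initial_distribution @ (negT_inv_one - expm(T * ti) @ negT_inv_one)
             for ti in t_arr]
        )
    H = t_arr - IS
    H = np.maximum(H, 0.0)
    return H if np.ndim(t) else float(H[0])


def mean_interval(model: InitiationModel) -> float:
    """Closed-form mean interval: (1 + k_on^-1/k_off^-1)/k1 + 1/k2 + 1/k3."""
    inv = sum(1.0 / r for r in model.seq_rates[1:])
    k1 = model.seq_rates[0]
    if model.has_switching:
        return (1.0 + model.k_off / model.k_on) / k1 + inv
    return 1.0 / k1 + inv


def _matrix_moments(pt: PhaseTypeRepresentation) -> tuple[float, float]:
    """First two raw moments from E[W] = a(-T)^-1 1, E[W^2] = 2 a(-T)^-2 1."""
    negT = -pt.sub_generator
    ones = np.ones(negT.shape[0])
    m1_vec = np.linalg.solve(negT, ones)
    m2_vec = np.linalg.solve(negT, m1_vec)
    a = pt.initial_distribution
    return float(a @ m1_vec), float(2.0 * a @ m2_vec)


def interval_moments(model: InitiationModel) -> MomentsSummary:
    """Mean, sd, cv and median-to-mean ratio of the interval distribution.

    The mean uses the closed form; the variance comes from the phase-type
    matrix moments.  The median is found by root-finding on the cdf.
    """
    pt = build_phase_type(model)
    mean = mean_interval(model)
    _, m2 = _matrix_moments(pt)
    var = max(m2 - mean**2, 0.0)
    sd = np.sqrt(var)
    cv = sd / mean
    median = brentq(lambda t: interval_cdf(pt, t) - 0.5, 0.0, 1e4 * mean, xtol=1e-12 * mean)
    return MomentsSummary(mean=mean, sd=sd, cv=cv, cv_sq=cv**2, median_to_mean=median / mean)


def precommit_cv_sq(k_on: float, k_off: float, k1: float) -> float:
    """Squared coefficient of variation of the pre-commit stage.

    Closed form for the telegraph switch in series with the k1 step:
    cv^2 = 1 + 2 k1 k_off / (k_on + k_off)^2.
    """
    return 1.0 + 2.0 * k1 * k_off / (k_on + k_off) ** 2


def precommit_cv_sq_range(model: InitiationModel, vary: str) -> tuple[float, float]:
    """Attainable cv^2 of the pre-commit stage when one switch rate varies.

    Varying only ``k_on`` gives [1, 1 + 2 k1/k_off] (cv grows monotonically
    with k_on^-1); varying only ``k_off`` gives [1, 1 + k1/(2 k_on)], the
    maximum attained at k_off = k_on.
    """
    if not model.has_switching:
        raise InvalidModelError("pre-commit cv^2 range requires a switching model")
    k1 = model.seq_rates[0]
    if vary == "k_on":
        return (1.0, 1.0 + 2.0 * k1 / model.k_off)
    if vary == "k_off":
        return (1.0, 1.0 + k1 / (2.0 * model.k_on))
    raise ValueError(f"vary must be 'k_on' or 'k_off', got {vary!r}")


def cv_sq_lower_bound(r: float, n: int) -> float:
    """Lower bound of interval cv^2 for a post-commit stage of n equal steps.

    ``r`` is the post-commit share of the mean interval.  The bound is
    (r - 1)^2 + r^2/n, minimized at r* = n/(n+1) with value 1/(n+1) (the
    pre-commit stage then exponential-like and all steps of equal duration).
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be a positive integer")
    return (r - 1.0) ** 2 + r**2 / n


def burst_statistics(model: InitiationModel) -> dict[str, float]:
    """Duty cycle, mean burst size and mean burst interval of the switch.

    duty_cycle = k_on/(k_on + k_off); mean_burst_size = k1/k_off (mean
    initiations per on-period); mean_burst_interval = 1/k_on (mean
    off-period).
    """
    if not model.has_switching:
        raise InvalidModelError("burst statistics require a switching model")
    k1 = model.seq_rates[0]
    return {
        "duty_cycle": model.k_on / (model.k_on + model.k_off),
        "mean_burst_size": k1 / model.k_off,
        "mean_burst_interval": 1.0 / model.k_on,
    }
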