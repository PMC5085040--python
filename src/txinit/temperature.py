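"""Polynomial temperature laws and joint fits across temperatures.

Each kinetic parameter's *inverse* rate may be constant, linear or
quadratic in temperature: k_x(T)^-1 = A T^2 + B T + C with T in deg C.  The
polynomial is deliberately phenomenological (no Arrhenius-type mechanism is
imposed); a quadratic suffices to capture independence, linear trends and
nonlinear/bitonic trends at the few temperatures sampled.

Joint fits tie the per-temperature censored likelihoods together through
the law.  Two constrained variants are provided: a shared-shape model in
which the closed-complex inverse rate follows one function of temperature
up to a per-induction-scheme scale, and an RNA-polymerase-constrained model
in which k1(T) is proportional to the measured relative RpoC abundance.

Internally the laws are optimized through the inverse-rate values at anchor
temperatures (the extremes and midpoint of the fitted range) rather than
raw polynomial coefficients, which conditions the problem and keeps
positivity natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .inference import (
    BIG_PENALTY,
    LOG_RATE_HI,
    LOG_RATE_LO,
    FitResult,
    GroupedData,
    ModelStructure,
    _maximize,
    _numerical_hessian,
    _covariance_from_hessian,
    censored_loglik,
)
from .models import InitiationModel
from .selection import ModelComparison, rank_fits


class InvalidLawError(ValueError):
    """Raised when a temperature law yields a non-positive inverse rate."""


@dataclass(frozen=True)
class TemperatureLaw:
    """Per-parameter polynomial inverse-rate laws.

    ``entries`` maps a parameter name (k_on, k_off, k1, k2, k3) to
    ``(order, (A, B, C))`` with k_x(T)^-1 = A T^2 + B T + C.
    """

    entries: Mapping[str, tuple[int, tuple[float, float, float]]]
    valid_range: tuple[float, float] = (20.0, 45.0)

    def inverse_rate(self, parameter: str, T: float) -> float:
        order, (A, B, C) = self.entries[parameter]
        inv = A * T * T + B * T + C
        if inv <= 0:
            raise InvalidLawError(
                f"{parameter}: inverse rate {inv:g} s is non-positive at T={T} C"
            )
        return inv

    def rate(self, parameter: str, T: float) -> float:
        return 1.0 / self.inverse_rate(parameter, T)

    def model_at(self, T: float) -> InitiationModel:
        seq = [self.rate(k, T) for k in ("k1", "k2", "k3") if k in self.entries]
        if "k_on" in self.entries:
            return InitiationModel(tuple(seq), k_on=self.rate("k_on", T),
                                   k_off=self.rate("k_off", T))
        return InitiationModel(tuple(seq))

    def to_frame(self) -> pd.DataFrame:
        """Serialize as one row per parameter with columns order, A, B, C."""
        rows = [
            {"parameter": p, "order": o, "A": A, "B": B, "C": C}
            for p, (o, (A, B, C)) in self.entries.items()
        ]
        return pd.DataFrame(rows)


def eval_rate(law: TemperatureLaw, parameter: str, T: float) -> float:
    """Rate 1/(A T^2 + B T + C); raises InvalidLawError if the polynomial <= 0."""
    return law.rate(parameter, T)


@dataclass(frozen=True)
class RNAPProfile:
    """Relative RNA-polymerase (RpoC) abundance vs temperature.

    Values are relative to the reference temperature (R = 1 there).
    Interpolation between measured temperatures is piecewise-linear;
    extrapolation outside the measured hull is refused.
    """

    temperatures: tuple[float, ...]
    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.temperatures) != len(self.abundances) or len(self.temperatures) < 1:
            raise ValueError("profile needs matching temperature/abundance lists")
        if any(a <= 0 for a in self.abundances):
            raise ValueError("relative abundances must be positive")
        if not math.isclose(max(self.abundances), 1.0, rel_tol=1e-9):
            raise ValueError("profile must contain a reference temperature with R = 1")

    def abundance(self, T: float) -> float:
        ts = np.asarray(self.temperatures)
        order = np.argsort(ts)
        lo, hi = ts[order[0]], ts[order[-1]]
        if not (lo - 1e-9 <= T <= hi + 1e-9):
            raise ValueError(f"T={T} C outside measured profile hull [{lo}, {hi}]")
        return float(np.interp(T, ts[order], np.asarray(self.abundances)[order]))


# ---------------------------------------------------------------------------
# anchor reparameterization

def _anchor_temps(T_range: tuple[float, float]) -> tuple[float, float, float]:
    lo, hi = T_range
    return (lo, (lo + hi) / 2.0, hi)


def _poly_from_anchors(order: int, anchors: Sequence[float], values: Sequence[float]
                       ) -> tuple[float, float, float]:
    """Polynomial coefficients (A, B, C) through the anchor values."""
    if order == 0:
        return (0.0, 0.0, float(values[0]))
    if order == 1:
        ts, vs = (anchors[0], anchors[2]), values
        B = (vs[1] - vs[0]) / (ts[1] - ts[0])
        return (0.0, float(B), float(vs[0] - B * ts[0]))
    coef = np.polyfit(anchors, values, 2)
    return (float(coef[0]), float(coef[1]), float(coef[2]))


def _poly_positive_on(coefs: tuple[float, float, float], T_range: tuple[float, float]) -> bool:
    A, B, C = coefs
    lo, hi = T_range
    vals = [A * t * t + B * t + C for t in (lo, hi)]
    if A != 0:
        vertex = -B / (2 * A)
        if lo < vertex < hi:
            vals.append(A * vertex * vertex + B * vertex + C)
    return min(vals) > 0


@dataclass
class _JointSpec:
    """Maps an optimization vector to a TemperatureLaw.

    Free entries are log-rates at the anchor temperatures (order + 1 of
    them per parameter); fixed entries are callables T -> rate.
    """

    structure: ModelStructure
    order_spec: Mapping[str, int]
    T_range: tuple[float, float]
    fixed: Mapping[str, Callable[[float], float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.anchors = _anchor_temps(self.T_range)
        self.slices: dict[str, slice] = {}
        pos = 0
        for p in self.structure.param_names:
            if p in self.fixed:
                continue
            k = self.order_spec.get(p, 0) + 1
            self.slices[p] = slice(pos, pos + k)
            pos += k
        self.n_params = pos

    def law(self, theta: np.ndarray) -> TemperatureLaw:
        entries = {}
        for p, sl in self.slices.items():
            order = self.order_spec.get(p, 0)
            inv_vals = np.exp(-np.asarray(theta[sl]))  # anchor inverse rates
            if order == 1:
                vals = (inv_vals[0], inv_vals[1])
            elif order == 0:
                vals = (inv_vals[0],)
            else:
                vals = tuple(inv_vals)
            coefs = _poly_from_anchors(order, self.anchors, vals)
            if order == 2 and not _poly_positive_on(coefs, self.T_range):
                raise InvalidLawError(f"{p}: fitted quadratic non-positive in range")
            entries[p] = (order, coefs)
        return TemperatureLaw(entries, self.T_range)

    def rates_at(self, theta: np.ndarray, T: float) -> dict[str, float]:
        rates = {}
        for p in self.structure.param_names:
            if p in self.fixed:
                rates[p] = self.fixed[p](T)
            else:
                order = self.order_spec.get(p, 0)
                sl = self.slices[p]
                inv_vals = np.exp(-np.asarray(theta[sl]))
                coefs = _poly_from_anchors(order, self.anchors, tuple(inv_vals))
                A, B, C = coefs
                inv = A * T * T + B * T + C
                if inv <= 0:
                    raise InvalidLawError(f"{p}: non-positive inverse rate at {T} C")
                if order == 2 and not _poly_positive_on(coefs, self.T_range):
                    raise InvalidLawError(f"{p}: quadratic non-positive in range")
                rates[p] = 1.0 / inv
        return rates

    def model_at(self, theta: np.ndarray, T: float) -> InitiationModel:
        r = self.rates_at(theta, T)
        seq = tuple(r[f"k{j}"] for j in range(1, self.structure.n_steps + 1))
        if self.structure.switching:
            return InitiationModel(seq, k_on=r["k_on"], k_off=r["k_off"])
        return InitiationModel(seq)


def _group_by_temperature(records_by_T) -> dict[float, GroupedData]:
    out = {}
    for T, recs in records_by_T.items():
        out[float(T)] = recs if isinstance(recs, GroupedData) else GroupedData.from_records(recs)
    return out


def _informed_level(groups: Mapping[float, GroupedData], n_steps: int) -> float:
    means = []
    for g in groups.values():
        if g.n_exact:
            means.append(float(np.average((g.bounded_lb + g.bounded_ub) / 2.0,
                                          weights=g.bounded_n)))
    crude = max(np.mean(means) if means else 600.0, 1.0)
    return float(np.log(n_steps / crude))


def _joint_starts(spec: _JointSpec, groups, n_starts: int, rng: np.random.Generator
                  ) -> np.ndarray:
    level = _informed_level(groups, spec.structure.n_steps)
    informed = np.full(spec.n_params, level)
    for p, sl in spec.slices.items():
        if p in ("k_on", "k_off"):
            informed[sl] = level - np.log(spec.structure.n_steps)
    starts = [np.clip(informed, LOG_RATE_LO + 1e-6, LOG_RATE_HI - 1e-6)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=spec.n_params, seed=rng)
        u = sampler.random(n_starts - 1)
        lo = np.maximum(LOG_RATE_LO, level - 5.0)
        hi = np.minimum(LOG_RATE_HI, level + 5.0)
        starts.extend(lo + u * (hi - lo))
    return np.array(starts)


def _fit_joint(spec: _JointSpec, groups: Mapping[float, GroupedData],
               n_starts: int, seed: int | None, model_spec: str,
               extra_builder=None) -> FitResult:
    rng = np.random.default_rng(seed)

    def negloglik(theta: np.ndarray) -> float:
        total = 0.0
        try:
            for T, g in groups.items():
                total += censored_loglik(spec.model_at(theta, T), g)
        except (InvalidLawError, ValueError):
            return BIG_PENALTY
        return BIG_PENALTY if total == -math.inf else -total

    starts = _joint_starts(spec, groups, n_starts, rng)
    xhat, fmin, converged = _maximize(negloglik, starts)
    H = _numerical_hessian(negloglik, xhat)
    cov, _ = _covariance_from_hessian(H)
    n_exact = sum(g.n_exact for g in groups.values())
    n_cens = sum(g.n_censored for g in groups.values())
    names = tuple(
        f"{p}@{a:g}C" for p, sl in spec.slices.items()
        for a in spec.anchors[: sl.stop - sl.start]
    )
    extra = {"spec": spec}
    if extra_builder is not None:
        extra.update(extra_builder(xhat))
    else:
        try:
            extra["law"] = spec.law(xhat)
        except InvalidLawError:
            pass
    return FitResult(
        model_spec=model_spec,
        estimates=xhat,
        loglik=-fmin,
        covariance=cov,
        n_exact=n_exact,
        n_censored=n_cens,
        converged=bool(converged),
        n_starts_used=len(starts),
        param_names=names,
        extra=extra,
    )


def fit_joint_temperature(
    records_by_T: Mapping[float, object],
    structure: ModelStructure,
    order_spec: Mapping[str, int],
    n_starts: int = 20,
    seed: int | None = None,
) -> FitResult:
    """Joint censored ML across temperatures with polynomial-law ties.

    ``order_spec`` gives the polynomial order (0 constant, 1 linear,
    2 quadratic) of each parameter's inverse rate; omitted parameters are
    constant.  The likelihood is the sum of per-temperature censored
    log-likelihoods with parameters tied through the law.
    """
    groups = _group_by_temperature(records_by_T)
    temps = sorted(groups)
    if any(o > 0 for o in order_spec.values()) and len(temps) < 2:
        raise ValueError("non-constant law orders need >= 2 distinct temperatures")
    T_range = (temps[0], temps[-1]) if len(temps) > 1 else (temps[0] - 1, temps[0] + 1)
    spec = _JointSpec(structure, dict(order_spec), T_range)
    name = "+".join(f"{p}:{order_spec.get(p, 0)}" for p in structure.param_names)
    return _fit_joint(spec, groups, n_starts, seed, f"{structure}[{name}]")


def default_order_lattice(structure: ModelStructure, full: bool = False
                          ) -> list[dict[str, int]]:
    """Order-spec lattice: all-constant plus one non-constant parameter at a
    time (orders 1 and 2); ``full=True`` enumerates all 3^p combinations."""
    params = structure.param_names
    if full:
        lattice = []
        grids = np.indices((3,) * len(params)).reshape(len(params), -1).T
        for combo in grids:
            lattice.append({p: int(o) for p, o in zip(params, combo)})
        return lattice
    lattice = [{p: 0 for p in params}]
    for p in params:
        for order in (1, 2):
            spec = {q: 0 for q in params}
            spec[p] = order
            lattice.append(spec)
    return lattice


def select_temperature_model(
    records_by_T: Mapping[float, object],
    structure: ModelStructure,
    lattice: Sequence[Mapping[str, int]] | None = None,
    n_starts: int = 10,
    seed: int | None = None,
) -> ModelComparison:
    """Rank temperature-dependence structures by censored-weighted BIC."""
    if lattice is None:
        lattice = default_order_lattice(structure)
    if not lattice:
        raise ValueError("order lattice must not be empty")
    rng = np.random.default_rng(seed)
    fits = [
        fit_joint_temperature(records_by_T, structure, spec, n_starts=n_starts,
                              seed=int(rng.integers(2**31)))
        for spec in lattice
    ]
    return rank_fits(fits)


def fit_shared_shape(
    records_by_scheme: Mapping[str, Mapping[float, object]],
    structure: ModelStructure,
    n_starts: int = 10,
    seed: int | None = None,
    reference_scheme: str | None = None,
    shape_param: str = "k1",
) -> FitResult:
    """Joint fit with k1^-1(T, s) = c_s * g(T): one shape, per-scheme scales.

    ``g`` is a quadratic through the anchor temperatures; the reference
    scheme's scale is fixed to 1 for identifiability; all other kinetic
    parameters are per-scheme constants.
    """
    schemes = list(records_by_scheme)
    if len(schemes) < 2:
        raise ValueError("shared-shape fit needs >= 2 induction schemes")
    if reference_scheme is None:
        reference_scheme = schemes[0]
    groups = {s: _group_by_temperature(records_by_scheme[s]) for s in schemes}
    temps = sorted({T for g in groups.values() for T in g})
    T_range = (temps[0], temps[-1])
    anchors = _anchor_temps(T_range)
    others = [p for p in structure.param_names if p != shape_param]

    # layout: [3 shape anchors (log-rate)] + [log c_s, s != ref] + [others x scheme]
    n_shape = 3
    scale_idx = {s: n_shape + i for i, s in enumerate(s for s in schemes if s != reference_scheme)}
    other_idx = {}
    pos = n_shape + len(scale_idx)
    for s in schemes:
        for p in others:
            other_idx[(s, p)] = pos
            pos += 1
    n_par = pos
    rng = np.random.default_rng(seed)

    def model_at(theta, s, T):
        inv_anchor = np.exp(-theta[:n_shape])
        coefs = _poly_from_anchors(2, anchors, tuple(inv_anchor))
        if not _poly_positive_on(coefs, T_range):
            raise InvalidLawError("shared shape non-positive in range")
        A, B, C = coefs
        gT = A * T * T + B * T + C
        scale = 1.0 if s == reference_scheme else float(np.exp(theta[scale_idx[s]]))
        inv_k1 = scale * gT
        if inv_k1 <= 0:
            raise InvalidLawError("non-positive k1 inverse rate")
        rates = {shape_param: 1.0 / inv_k1}
        for p in others:
            rates[p] = float(np.exp(theta[other_idx[(s, p)]]))
        seq = tuple(rates[f"k{j}"] for j in range(1, structure.n_steps + 1))
        if structure.switching:
            return InitiationModel(seq, k_on=rates["k_on"], k_off=rates["k_off"])
        return InitiationModel(seq)

    def negloglik(theta):
        total = 0.0
        try:
            for s in schemes:
                for T, g in groups[s].items():
                    total += censored_loglik(model_at(theta, s, T), g)
        except (InvalidLawError, ValueError):
            return BIG_PENALTY
        return BIG_PENALTY if total == -math.inf else -total

    all_groups = {f"{s}@{T}": g for s in schemes for T, g in groups[s].items()}
    level = _informed_level({i: g for i, g in enumerate(all_groups.values())},
                            structure.n_steps)
    informed = np.full(n_par, level)
    for i in scale_idx.values():
        informed[i] = 0.0
    for (s, p), i in other_idx.items():
        if p in ("k_on", "k_off"):
            informed[i] = level - np.log(structure.n_steps)
    starts = [np.clip(informed, LOG_RATE_LO + 1e-6, LOG_RATE_HI - 1e-6)]
    # warm start from independent per-scheme quadratic fits: anchor the
    # shape on the reference scheme and seed each scale with the mean
    # anchor ratio
    try:
        per = {
            s: fit_joint_temperature(
                records_by_scheme[s], structure,
                {shape_param: 2}, n_starts=max(3, n_starts // 2),
                seed=int(rng.integers(2**31)))
            for s in schemes
        }
        anchors_of = {
            s: np.array([per[s].extra["law"].inverse_rate(shape_param, a) for a in anchors])
            for s in schemes
        }
        warm = np.array(informed)
        ref_inv = anchors_of[reference_scheme]
        warm[:n_shape] = -np.log(ref_inv)
        for s, i in scale_idx.items():
            warm[i] = float(np.log(np.mean(anchors_of[s] / ref_inv)))
        for (s, p), i in other_idx.items():
            spec_s = per[s].extra["spec"]
            warm[i] = per[s].estimates[spec_s.slices[p]][0]
        starts.append(np.clip(warm, LOG_RATE_LO + 1e-6, LOG_RATE_HI - 1e-6))
    except (ValueError, KeyError, InvalidLawError):
        pass
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=n_par, seed=rng)
        u = sampler.random(n_starts - 1)
        starts.extend((level - 4.0) + u * 8.0)
    xhat, fmin, converged = _maximize(negloglik, np.array(starts))
    H = _numerical_hessian(negloglik, xhat)
    cov, _ = _covariance_from_hessian(H)
    n_exact = sum(g.n_exact for g in all_groups.values())
    n_cens = sum(g.n_censored for g in all_groups.values())
    scales = {reference_scheme: 1.0}
    scales.update({s: float(np.exp(xhat[i])) for s, i in scale_idx.items()})
    names = tuple(f"g@{a:g}C" for a in anchors) \
        + tuple(f"scale[{s}]" for s in scale_idx) \
        + tuple(f"{p}[{s}]" for (s, p) in other_idx)
    return FitResult(
        model_spec=f"shared-shape[{structure}]",
        estimates=xhat,
        loglik=-fmin,
        covariance=cov,
        n_exact=n_exact,
        n_censored=n_cens,
        converged=bool(converged),
        n_starts_used=len(starts),
        param_names=names,
        extra={"scales": scales, "anchors": anchors, "reference": reference_scheme},
    )


def fit_rnap_constrained(
    records_by_T: Mapping[float, object],
    profile: RNAPProfile,
    structure: ModelStructure,
    n_starts: int = 10,
    seed: int | None = None,
) -> FitResult:
    """Joint fit with k1(T) = k1_tilde * R(T) and other parameters constant.

    Tests whether the temperature dependence of the closed-complex formation
    is explained solely by the RNA-polymerase abundance R(T).
    """
    groups = _group_by_temperature(records_by_T)
    for T in groups:
        profile.abundance(T)  # validates the hull
    others = [p for p in structure.param_names if p != "k1"]
    rng = np.random.default_rng(seed)

    def model_at(theta, T):
        k1 = float(np.exp(theta[0])) * profile.abundance(T)
        rates = {"k1": k1}
        for i, p in enumerate(others):
            rates[p] = float(np.exp(theta[1 + i]))
        seq = tuple(rates[f"k{j}"] for j in range(1, structure.n_steps + 1))
        if structure.switching:
            return InitiationModel(seq, k_on=rates["k_on"], k_off=rates["k_off"])
        return InitiationModel(seq)

    def negloglik(theta):
        total = 0.0
        try:
            for T, g in groups.items():
                total += censored_loglik(model_at(theta, T), g)
        except ValueError:
            return BIG_PENALTY
        return BIG_PENALTY if total == -math.inf else -total

    level = _informed_level(groups, structure.n_steps)
    informed = np.full(1 + len(others), level)
    for i, p in enumerate(others):
        if p in ("k_on", "k_off"):
            informed[1 + i] = level - np.log(structure.n_steps)
    starts = [np.clip(informed, LOG_RATE_LO + 1e-6, LOG_RATE_HI - 1e-6)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(informed), seed=rng)
        u = sampler.random(n_starts - 1)
        starts.extend((level - 4.0) + u * 8.0)
    xhat, fmin, converged = _maximize(negloglik, np.array(starts))
    H = _numerical_hessian(negloglik, xhat)
    cov, _ = _covariance_from_hessian(H)
    return FitResult(
        model_spec=f"rnap-constrained[{structure}]",
        estimates=xhat,
        loglik=-fmin,
        covariance=cov,
        n_exact=sum(g.n_exact for g in groups.values()),
        n_censored=sum(g.n_censored for g in groups.values()),
        converged=bool(converged),
        n_starts_used=len(starts),
        param_names=("k1_tilde",) + tuple(others),
        extra={"profile": profile},
    )
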