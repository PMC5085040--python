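"""Pre-/post-commit split of the mean transcription interval.

Transcription initiation divides into an RNA-polymerase-dependent stage
(closed-complex formation, before full commitment) and RNA-polymerase-
independent post-commit steps (open-complex formation, promoter escape).
Two independent routes to the split are provided:

* a Lineweaver-Burk (double-reciprocal) regression of relative
  transcription activity against relative RNA-polymerase abundance, whose
  intercept/slope partition the mean interval at the reference condition;
* enumeration of pre/post assignments of fitted step durations when the
  step order is unidentifiable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class ActivityMeasurement:
    """One qPCR/western-blot point: relative activity at relative RNAP level."""

    condition: str
    relative_rnap: float
    relative_activity: float
    replicate: str | None = None

    def __post_init__(self) -> None:
        if self.relative_rnap <= 0 or self.relative_activity <= 0:
            raise ValueError("relative RNAP and activity must be positive")


def lineweaver_burk_split(measurements: Sequence[ActivityMeasurement]) -> dict:
    """Post-commit share of the mean interval from a double-reciprocal fit.

    Ordinary least squares of y = 1/activity on x = 1/RNAP gives
    y = a + b x; the intercept a is the RNAP-independent (post-commit) part
    of the mean interval and a + b its total at the reference condition
    (x = 1), so post_fraction = a/(a + b), in percent.  The sd propagates
    the regression covariance through the ratio (delta method);
    ci95 = estimate +/- 1.96 sd.
    """
    if len(measurements) < 2:
        raise ValueError("need at least two measurements")
    x = np.array([1.0 / m.relative_rnap for m in measurements])
    y = np.array([1.0 / m.relative_activity for m in measurements])
    if np.ptp(x) == 0:
        raise ValueError("all RNAP levels equal: singular design")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    a, b = res.params
    cov = np.asarray(res.cov_params())
    total = a + b
    frac = a / total
    # delta method on f(a, b) = a/(a+b)
    grad = np.array([b / total**2, -a / total**2])
    var = float(grad @ cov @ grad)
    sd = math.sqrt(max(var, 0.0))
    if a < 0:
        warnings.warn("negative intercept: post-commit fraction extrapolated "
                      "outside the model", stacklevel=2)
    est, sd_pct = 100.0 * frac, 100.0 * sd
    return {
        "post_fraction": est,
        "sd": sd_pct,
        "ci95": (est - 1.96 * sd_pct, est + 1.96 * sd_pct),
        "intercept": float(a),
        "slope": float(b),
    }


def postcommit_assignments(step_durations: Sequence[float]) -> tuple[float, ...]:
    """Possible post-commit shares when the step order is unknown.

    For a 3-step scheme exactly one step is pre-commit; each choice of the
    pre-commit step leaves the other two as post-commit, giving a
    post-commit share of the summed durations (percent).  Duplicate step
    durations collapse to a single value.
    """
    if len(step_durations) != 3:
        raise ValueError("exactly three step durations are required")
    durations = [float(d) for d in step_durations]
    if any(d <= 0 for d in durations):
        raise ValueError("step durations must be positive")
    total = sum(durations)
    shares = sorted({round(100.0 * (total - d) / total, 9) for d in durations})
    return tuple(shares)


def reconcile_split(model_split, lb_split: dict) -> dict:
    """Check model-derived split(s) against the regression's 95% CI.

    ``model_split`` is a single post-commit percentage or an iterable of
    candidate assignments; the CI is treated as a closed interval.
    Returns the compatibility verdict and the compatible assignment(s).
    """
    lo, hi = lb_split["ci95"]
    values = np.atleast_1d(np.asarray(model_split, dtype=float))
    compatible = tuple(float(v) for v in values if lo <= v <= hi)
    return {
        "compatible": len(compatible) > 0,
        "compatible_assignments": compatible,
        "ci95": (lo, hi),
        "n_candidates": len(values),
    }


def read_activity(path) -> list[ActivityMeasurement]:
    """Read a (condition, relative_rnap, relative_activity[, replicate]) CSV."""
    df = pd.read_csv(path)
    required = {"condition", "relative_rnap", "relative_activity"}
    if not required.issubset(df.columns):
        raise ValueError(f"activity table must have columns {sorted(required)}")
    return [
        ActivityMeasurement(
            str(r.condition), float(r.relative_rnap), float(r.relative_activity),
            str(getattr(r, "replicate", "")) or None,
        )
        for r in df.itertuples(index=False)
    ]
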