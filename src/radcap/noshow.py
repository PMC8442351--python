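"""Synthetic per-slot outpatient show probabilities.

The studied department predicted each outpatient's no-show risk with a
penalized logistic regression on individual characteristics and schedule
attributes; that patient-level dataset is private.  This module emulates
the *output* of such a model: for each scheduled slot it draws a
covariate vector (generic stand-ins for lead time, period of day and a
patient score), applies the inverse-logit of a linear predictor, and
returns one show probability per slot.  The intercept can be calibrated
by bisection so the population mean show probability hits a target.

The generated probabilities are synthetic: they reproduce the *shape* of
patient-level heterogeneity, not any real patient's risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "NoShowModelSpec",
    "generate_show_probabilities",
    "calibrate_intercept",
    "DEFAULT_SPEC",
]

_CLIP = 1e-6  # keep probabilities strictly inside (0, 1)


@dataclass(frozen=True)
class NoShowModelSpec:
    """Linear-logistic generator of per-slot show probabilities.

    ``coefficients[j]`` multiplies a standard-normal covariate scaled by
    ``covariate_scales[j]``; the show probability of a slot is
    ``expit(intercept + sum_j coef_j * x_j)``.
    """

    intercept: float = 1.5
    coefficients: tuple[float, ...] = (0.8, -0.5, 0.3)
    covariate_scales: tuple[float, ...] = (1.0, 1.0, 1.0)
    target_mean: float | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.covariate_scales):
            raise ValueError("coefficients and covariate_scales must have equal length")
        if self.target_mean is not None and not 0.0 < self.target_mean < 1.0:
            raise ValueError("target_mean must lie strictly in (0, 1)")


DEFAULT_SPEC = NoShowModelSpec()


def _draw_probabilities(
    spec: NoShowModelSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    x = rng.standard_normal((n, len(spec.coefficients))) * np.asarray(
        spec.covariate_scales
    )
    eta = spec.intercept + x @ np.asarray(spec.coefficients)
    return np.clip(expit(eta), _CLIP, 1.0 - _CLIP)


def generate_show_probabilities(
    spec: NoShowModelSpec,
    schedule: Sequence[int],
    rng: np.random.Generator | int = 0,
) -> list[list[float]]:
    """One show probability per scheduled OP slot, shaped like ``schedule``.

    If ``spec.target_mean`` is set, the intercept is first calibrated (see
    :func:`calibrate_intercept`) with a generator split off from ``rng``.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if spec.target_mean is not None:
        spec = calibrate_intercept(
            spec, spec.target_mean, np.random.default_rng(int(rng.integers(2**31)))
        )
    flat = _draw_probabilities(spec, int(sum(schedule)), rng)
    out, pos = [], 0
    for ag in schedule:
        out.append([float(p) for p in flat[pos: pos + ag]])
        pos += ag
    return out


def calibrate_intercept(
    spec: NoShowModelSpec,
    target_mean: float,
    rng: np.random.Generator | int = 0,
    n_mc: int = 100_000,
    tol: float = 0.005,
) -> NoShowModelSpec:
    """Bisect the intercept until the Monte-Carlo mean show probability
    is within ``tol`` of ``target_mean``.

    The mean of ``expit(intercept + eta)`` over a fixed covariate sample
    is strictly increasing in the intercept, so bisection on a wide
    bracket always converges.
    """
    if not 0.0 < target_mean < 1.0:
        raise ValueError("target_mean must lie strictly in (0, 1)")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    x = rng.standard_normal((n_mc, len(spec.coefficients))) * np.asarray(
        spec.covariate_scales
    )
    eta = x @ np.asarray(spec.coefficients)

    def mean_at(b0: float) -> float:
        return float(np.mean(expit(b0 + eta)))

    lo, hi = -30.0, 30.0
    if not mean_at(lo) <= target_mean <= mean_at(hi):
        raise ValueError("target mean not bracketed by intercept range [-30, 30]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        m = mean_at(mid)
        if abs(m - target_mean) <= tol:
            return replace(spec, intercept=mid, target_mean=None)
        if m < target_mean:
            lo = mid
        else:
            hi = mid
    return replace(spec, intercept=0.5 * (lo + hi), target_mean=None)
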