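"""Closed-form survival and hazard functions of the two-process vitality model.

Mortality is partitioned into an *intrinsic* process — death when an
individual's vitality, a dimensionless survival capacity starting at 1 and
declining as a Wiener process with drift ``-r`` and diffusion ``s``, first
reaches zero — and an *extrinsic* process — death when an acute environmental
challenge (Poisson arrivals at rate ``lam``, magnitudes exponential with mean
``beta``) exceeds remaining vitality.  In the closed-form approximation the
extrinsic process sees the deterministic mean vitality ``v(x) = 1 - r*x``,
which makes the two components independent and total survival their product:

    l(x)   = l_i(x) * l_e(x)
    l_i(x) = Phi((1 - r x)/(s sqrt(x))) - exp(2 r / s^2) Phi(-(1 + r x)/(s sqrt(x)))
    l_e(x) = exp(-(lam beta / r) e^{-1/beta} (e^{r x / beta} - 1))

``l_i`` is the first-passage-time (inverse-Gaussian) survival function;
``l_e`` integrates the Strehler–Mildvan-type challenge hazard
``mu_e(x) = lam e^{-(1 - r x)/beta}``, which is log-linear in age with slope
``r/beta`` (the Gompertz slope of the model).

Ages ``x`` are measured on the *model clock*: years since the age at which
vitality is normalized to 1 (the cohort entry/truncation age).  Use
:func:`conditional_survival` to condition a from-birth clock on survival to a
truncation age instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import log_ndtr, ndtr

__all__ = [
    "ModelParams",
    "intrinsic_survival",
    "extrinsic_survival",
    "total_survival",
    "intrinsic_density",
    "intrinsic_hazard",
    "extrinsic_hazard",
    "total_hazard",
    "conditional_survival",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class ModelParams:
    """The four parameters governing one cohort's mortality.

    Parameters
    ----------
    r : float
        Mean rate of vitality loss [1/year].  ``1/r`` is the age (model
        clock) at which mean vitality reaches zero.
    s : float
        Variability (diffusion coefficient) of the vitality path
        [year^(-1/2)].  Controls the spread of intrinsic ages at death.
    lam : float
        Frequency of extrinsic environmental challenges [1/year].
    beta : float
        Mean magnitude of extrinsic challenges, exponentially distributed,
        as a fraction of initial vitality [dimensionless].
    """

    r: float
    s: float
    lam: float
    beta: float

    def __post_init__(self) -> None:
        vals = (self.r, self.s, self.lam, self.beta)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"parameters must be finite, got {self}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.s <= 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.s, self.lam, self.beta], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ModelParams":
        r, s, lam, beta = (float(v) for v in np.asarray(arr, dtype=float))
        return cls(r=r, s=s, lam=lam, beta=beta)

    names = ("r", "s", "lam", "beta")


def _check_age(x: ArrayLike) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise ValueError("age x must be finite and >= 0")
    return x


def intrinsic_survival(params: ModelParams, x: ArrayLike) -> ArrayLike:
    """Probability that the stochastic vitality path stays above zero to age x.

    The survival function of the inverse-Gaussian first-passage time of a
    Wiener process started at 1 with drift ``-r`` and diffusion ``s``.  The
    ``exp(2r/s^2)`` reflection factor is combined with the normal log-CDF in
    log space: for realistic human parameters ``2r/s^2`` is of order 10^2,
    far beyond the direct range of ``exp``.
    """
    x = _check_age(x)
    xs = np.atleast_1d(x)
    out = np.ones_like(xs)
    pos = xs > 0
    if np.any(pos):
        xp = xs[pos]
        denom = params.s * np.sqrt(xp)
        term1 = ndtr((1.0 - params.r * xp) / denom)
        log_term2 = 2.0 * params.r / params.s**2 + log_ndtr(-(1.0 + params.r * xp) / denom)
        term2 = np.exp(log_term2)
        out[pos] = np.clip(term1 - term2, 0.0, 1.0)
    out = out.reshape(np.shape(x))
    return float(out) if out.ndim == 0 else out


def extrinsic_survival(params: ModelParams, x: ArrayLike) -> ArrayLike:
    """Probability of escaping all extrinsic challenges to age x.

    Closed form of ``exp(-∫_0^x lam e^{-(1 - r t)/beta} dt)``: Poisson
    challenges at rate ``lam`` with Exp(mean ``beta``) magnitudes against the
    deterministic vitality ``1 - r t``.  Evaluated as written for all x,
    including beyond ``1/r`` where the linear-vitality approximation has run
    out; the expression stays finite and non-increasing there.
    """
    x = _check_age(x)
    if params.lam == 0.0:
        out = np.ones_like(np.asarray(x, dtype=float))
        return float(out) if out.ndim == 0 else out
    with np.errstate(over="ignore"):  # overflow -> inf hazard -> survival 0
        cum_hazard = (
            (params.lam * params.beta / params.r)
            * np.exp(-1.0 / params.beta)
            * np.expm1(params.r * np.asarray(x, dtype=float) / params.beta)
        )
        out = np.exp(-cum_hazard)
    return float(out) if out.ndim == 0 else out


def total_survival(params: ModelParams, x: ArrayLike) -> ArrayLike:
    """Total survival: the product of the intrinsic and extrinsic curves."""
    return intrinsic_survival(params, x) * extrinsic_survival(params, x)


def intrinsic_density(params: ModelParams, x: ArrayLike) -> ArrayLike:
    """Inverse-Gaussian density of the intrinsic (first-passage) age at death.

    f(x) = 1/(s sqrt(2 pi x^3)) * exp(-(1 - r x)^2 / (2 s^2 x)), x > 0.
    """
    x = _check_age(x)
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(xs == 0):
        raise ValueError("intrinsic density requires x > 0")
    out = (
        1.0
        / (params.s * np.sqrt(2.0 * np.pi * xs**3))
        * np.exp(-((1.0 - params.r * xs) ** 2) / (2.0 * params.s**2 * xs))
    )
    out = out.reshape(np.shape(x))
    return float(out) if out.ndim == 0 else out


def intrinsic_hazard(params: ModelParams, x: ArrayLike) -> ArrayLike:
    """Intrinsic mortality rate f_IG(x) / l_i(x) [1/year], x > 0."""
    x = _check_age(x)
    if np.any(np.atleast_1d(x) <= 0):
        raise ValueError("hazard requires x > 0")
    surv = intrinsic_survival(params, x)
    return intrinsic_density(params, x) / np.maximum(surv, np.finfo(float).tiny)


def extrinsic_hazard(params: ModelParams, x: ArrayLike) -> ArrayLike:
    """Extrinsic mortality rate lam * e^{-(1 - r x)/beta} [1/year].

    Log-linear in age with slope r/beta — the Strehler–Mildvan reading of a
    Gompertz hazard.
    """
    x = _check_age(x)
    out = params.lam * np.exp(-(1.0 - params.r * np.asarray(x, dtype=float)) / params.beta)
    return float(out) if np.ndim(out) == 0 else out


def total_hazard(params: ModelParams, x: ArrayLike) -> ArrayLike:
    """Sum of intrinsic and extrinsic hazards, x > 0."""
    return intrinsic_hazard(params, x) + extrinsic_hazard(params, x)


def conditional_survival(params: ModelParams, x0: float, x: ArrayLike) -> ArrayLike:
    """Survival to age x conditional on survival to age x0 (both on the same clock).

    ``total_survival(x) / total_survival(x0)``; equals 1 at ``x = x0``.  This
    supports the chronological-age convention in which vitality is normalized
    at birth and the data are truncated at a later entry age.
    """
    if x0 < 0:
        raise ValueError("truncation age x0 must be >= 0")
    x = _check_age(x)
    if np.any(np.atleast_1d(x) < x0):
        raise ValueError("x must be >= truncation age x0")
    denom = total_survival(params, x0)
    if denom <= 0:
        raise ValueError(f"survival to truncation age {x0} is zero; cannot condition")
    return total_survival(params, x) / denom
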