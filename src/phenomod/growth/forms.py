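"""Functional forms of the mechanistic growth models and their linearizations.

Each saturating or exponential family is reduced to a straight line
``y* = intercept + slope * x*`` by a response/predictor transform, so the
parameters can be estimated by ordinary least squares.  Transforms have a
restricted domain (log of a non-positive number, response at or above the
asymptote); observations outside the domain are masked out, never silently
altered.

Parameterizations:

===============  =============================  ======================================
model            curve                          linearization
===============  =============================  ======================================
linear           y = a + b t                    identity
exponential      y = a e^{b t}                  ln y  = ln a + b t
monomolecular    y = K (1 - a e^{-r t})         ln(1 - y/K) = ln a - r t
logistic         y = K / (1 + e^{-r (t - t0)})  ln(K/y - 1) = r t0 - r t
gompertz         y = K e^{-a e^{-r t}}          ln(ln(K/y)) = ln a - r t
weibull          y = K (1 - e^{-(t/lam)^k})     ln(-ln(1 - y/K)) = k ln t - k ln lam
===============  =============================  ======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

CONTROL_MODELS = (
    "linear",
    "exponential",
    "monomolecular",
    "logistic",
    "gompertz",
    "weibull",
)

STRESS_MODELS = ("bell_gauss", "bell_loggauss", "bell_sqrtgauss", "quadratic")

ALL_MODELS = CONTROL_MODELS + STRESS_MODELS + ("recovery_linear",)


@dataclass(frozen=True)
class GrowthModelSpec:
    """One registered growth-model family.

    Attributes
    ----------
    model_id : str
        Identifier, one of :data:`ALL_MODELS`.
    requires_asymptote : bool
        Whether the linearization needs an asymptote ``K`` above every
        observed value.
    linearization : str
        Human-readable description of the transform pair.
    """

    model_id: str
    requires_asymptote: bool
    linearization: str
    transform: Callable = field(repr=False, compare=False, default=None)
    from_line: Callable = field(repr=False, compare=False, default=None)
    predict: Callable = field(repr=False, compare=False, default=None)


def _finite(*arrays):
    mask = np.ones(arrays[0].shape, dtype=bool)
    for a in arrays:
        mask &= np.isfinite(a)
    return mask


# ---------------------------------------------------------------- transforms
# each transform: (t, y, K) -> (x_star, y_star, valid_mask)

def _t_linear(t, y, K):
    return t, y, _finite(t, y)


def _t_exponential(t, y, K):
    valid = _finite(t, y) & (y > 0)
    ystar = np.full_like(y, np.nan, dtype=float)
    ystar[valid] = np.log(y[valid])
    return t, ystar, valid


def _t_monomolecular(t, y, K):
    valid = _finite(t, y) & (y < K)
    ystar = np.full_like(y, np.nan, dtype=float)
    ystar[valid] = np.log(1.0 - y[valid] / K)
    return t, ystar, valid


def _t_logistic(t, y, K):
    valid = _finite(t, y) & (y > 0) & (y < K)
    ystar = np.full_like(y, np.nan, dtype=float)
    ystar[valid] = np.log(K / y[valid] - 1.0)
    return t, ystar, valid


def _t_gompertz(t, y, K):
    valid = _finite(t, y) & (y > 0) & (y < K)
    ystar = np.full_like(y, np.nan, dtype=float)
    ystar[valid] = np.log(np.log(K / y[valid]))
    return t, ystar, valid


def _t_weibull(t, y, K):
    valid = _finite(t, y) & (y > 0) & (y < K) & (t > 0)
    xstar = np.full_like(t, np.nan, dtype=float)
    ystar = np.full_like(y, np.nan, dtype=float)
    xstar[valid] = np.log(t[valid])
    ystar[valid] = np.log(-np.log(1.0 - y[valid] / K))
    return xstar, ystar, valid


# ----------------------------------------------------- line -> model params

def _p_linear(intercept, slope, K):
    return {"a": intercept, "b": slope}


def _p_exponential(intercept, slope, K):
    return {"a": float(np.exp(intercept)), "b": slope}


def _p_monomolecular(intercept, slope, K):
    return {"K": K, "a": float(np.exp(intercept)), "r": -slope}


def _p_logistic(intercept, slope, K):
    r = -slope
    t0 = intercept / r if r != 0 else np.nan
    return {"K": K, "r": r, "t0": float(t0)}


def _p_gompertz(intercept, slope, K):
    return {"K": K, "a": float(np.exp(intercept)), "r": -slope}


def _p_weibull(intercept, slope, K):
    k = slope
    lam = float(np.exp(-intercept / k)) if k != 0 else np.nan
    return {"K": K, "k": k, "lam": lam}


# ------------------------------------------------------------------ predict

def _f_linear(t, p):
    return p["a"] + p["b"] * t


def _f_exponential(t, p):
    return p["a"] * np.exp(p["b"] * t)


def _f_monomolecular(t, p):
    return p["K"] * (1.0 - p["a"] * np.exp(-p["r"] * t))


def _f_logistic(t, p):
    return p["K"] / (1.0 + np.exp(-p["r"] * (t - p["t0"])))


def _f_gompertz(t, p):
    return p["K"] * np.exp(-p["a"] * np.exp(-p["r"] * t))


def _f_weibull(t, p):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = p["K"] * (1.0 - np.exp(-((t[pos] / p["lam"]) ** p["k"])))
    return out


MODEL_SPECS: dict[str, GrowthModelSpec] = {
    "linear": GrowthModelSpec(
        "linear", False, "identity (y on t)", _t_linear, _p_linear, _f_linear
    ),
    "exponential": GrowthModelSpec(
        "exponential", False, "ln y on t", _t_exponential, _p_exponential, _f_exponential
    ),
    "monomolecular": GrowthModelSpec(
        "monomolecular", True, "ln(1 - y/K) on t",
        _t_monomolecular, _p_monomolecular, _f_monomolecular,
    ),
    "logistic": GrowthModelSpec(
        "logistic", True, "ln(K/y - 1) on t", _t_logistic, _p_logistic, _f_logistic
    ),
    "gompertz": GrowthModelSpec(
        "gompertz", True, "ln(ln(K/y)) on t", _t_gompertz, _p_gompertz, _f_gompertz
    ),
    "weibull": GrowthModelSpec(
        "weibull", True, "ln(-ln(1 - y/K)) on ln t", _t_weibull, _p_weibull, _f_weibull
    ),
}


def get_model_spec(model_id: str) -> GrowthModelSpec:
    try:
        return MODEL_SPECS[model_id]
    except KeyError:
        from ..exceptions import UnknownModelError

        raise UnknownModelError(
            f"unknown growth model {model_id!r}; known: {sorted(MODEL_SPECS)}"
        ) from None
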