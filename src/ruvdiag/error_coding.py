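"""Registry of residual-error coding variants.

Each coding plays two distinct roles, kept deliberately separate:

* ``variance_fn`` — the residual variance that enters the likelihood
  (determined by the observation equation, i.e. the EPS/SIGMA structure);
* ``w_fn`` — the user-chosen diagnostic scale W that divides the
  individual residual to form IWRES = IRES / W.

For *normalized* codings W**2 equals the likelihood variance identically,
so IWRES behaves as a standardized residual.  Non-normalized codings
(W = 1, W = IPRED) share the same likelihood as their normalized
counterparts but compress IWRES by the constant sqrt(sigma1).  The
SD-style combined coding models W (and hence the residual SD) as a linear
function of IPRED, a non-nested approximation of the variance-style
combined model.

Parameter styles:

* ``sigma`` — variance-scale parameters (entries of SIGMA);
* ``theta`` — SD/CV-scale fixed effects with the noise variance fixed to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np

__all__ = [
    "ConfigurationError",
    "ErrorParams",
    "ErrorCoding",
    "registry",
    "get_coding",
    "w_value",
    "variance_value",
    "CODING_IDS",
]

CODING_IDS = (
    "ADD.1", "ADD.2", "ADD.3",
    "PROP.1", "PROP.2", "PROP.3",
    "COMB_VAR1", "COMB_VAR3", "COMB_SD",
)


class ConfigurationError(ValueError):
    """Unknown coding or inactive parameter slot accessed."""


@dataclass(frozen=True)
class ErrorParams:
    """Residual-error parameter slots; only the coding's slots are active.

    sigma1/sigma2 are variance-scale (SIGMA) entries, theta4/theta5 are
    SD/CV-scale (THETA) entries.
    """

    sigma1: Optional[float] = None
    sigma2: Optional[float] = None
    theta4: Optional[float] = None
    theta5: Optional[float] = None

    def require(self, *names: str) -> Tuple[float, ...]:
        values = []
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ConfigurationError(f"parameter slot {name!r} is not set")
            if value <= 0:
                raise ConfigurationError(f"parameter {name!r} must be > 0, got {value!r}")
            values.append(float(value))
        return tuple(values)


# ---------------------------------------------------------------------------
# variance / W / d(variance)/d(ipred) primitives.  Codings that share an
# observation equation share the *same function object* (ADD.1/ADD.2 and
# PROP.1/PROP.2), which is what makes their likelihoods identical by
# construction.
# ---------------------------------------------------------------------------

def _var_add_sigma(ipred, p: ErrorParams):
    (s1,) = p.require("sigma1")
    return np.broadcast_to(np.asarray(s1, float), np.shape(ipred)).copy() \
        if np.ndim(ipred) else s1


def _dvar_zero(ipred, p: ErrorParams):
    return np.zeros_like(np.asarray(ipred, float)) if np.ndim(ipred) else 0.0


def _w_add_sigma(ipred, p: ErrorParams):
    (s1,) = p.require("sigma1")
    w = np.sqrt(s1)
    return np.broadcast_to(np.asarray(w, float), np.shape(ipred)).copy() \
        if np.ndim(ipred) else float(w)


def _w_one(ipred, p: ErrorParams):
    return np.ones_like(np.asarray(ipred, float)) if np.ndim(ipred) else 1.0


def _var_add_theta(ipred, p: ErrorParams):
    (t4,) = p.require("theta4")
    v = t4 * t4
    return np.broadcast_to(np.asarray(v, float), np.shape(ipred)).copy() \
        if np.ndim(ipred) else v


def _w_add_theta(ipred, p: ErrorParams):
    (t4,) = p.require("theta4")
    return np.broadcast_to(np.asarray(t4, float), np.shape(ipred)).copy() \
        if np.ndim(ipred) else t4


def _var_prop_sigma(ipred, p: ErrorParams):
    (s1,) = p.require("sigma1")
    return np.square(ipred) * s1


def _dvar_prop_sigma(ipred, p: ErrorParams):
    (s1,) = p.require("sigma1")
    return 2.0 * s1 * np.asarray(ipred, float)


def _w_prop_sigma(ipred, p: ErrorParams):
    (s1,) = p.require("sigma1")
    return np.asarray(ipred, float) * np.sqrt(s1)


def _w_ipred(ipred, p: ErrorParams):
    return np.asarray(ipred, float) if np.ndim(ipred) else float(ipred)


def _var_prop_theta(ipred, p: ErrorParams):
    (t4,) = p.require("theta4")
    return np.square(ipred) * t4 * t4


def _dvar_prop_theta(ipred, p: ErrorParams):
    (t4,) = p.require("theta4")
    return 2.0 * t4 * t4 * np.asarray(ipred, float)


def _w_prop_theta(ipred, p: ErrorParams):
    (t4,) = p.require("theta4")
    return np.asarray(ipred, float) * t4


def _var_comb_sigma(ipred, p: ErrorParams):
    s1, s2 = p.require("sigma1", "sigma2")
    return np.square(ipred) * s1 + s2


def _dvar_comb_sigma(ipred, p: ErrorParams):
    s1, _ = p.require("sigma1", "sigma2")
    return 2.0 * s1 * np.asarray(ipred, float)


def _w_comb_sigma(ipred, p: ErrorParams):
    return np.sqrt(_var_comb_sigma(ipred, p))


def _var_comb_theta(ipred, p: ErrorParams):
    t4, t5 = p.require("theta4", "theta5")
    return np.square(ipred) * t4 * t4 + t5 * t5


def _dvar_comb_theta(ipred, p: ErrorParams):
    t4, _ = p.require("theta4", "theta5")
    return 2.0 * t4 * t4 * np.asarray(ipred, float)


def _w_comb_theta(ipred, p: ErrorParams):
    return np.sqrt(_var_comb_theta(ipred, p))


def _w_comb_sd(ipred, p: ErrorParams):
    t4, t5 = p.require("theta4", "theta5")
    return t4 * np.asarray(ipred, float) + t5


def _var_comb_sd(ipred, p: ErrorParams):
    return np.square(_w_comb_sd(ipred, p))


def _dvar_comb_sd(ipred, p: ErrorParams):
    t4, _ = p.require("theta4", "theta5")
    return 2.0 * t4 * _w_comb_sd(ipred, p)


@dataclass(frozen=True)
class ErrorCoding:
    """One coding variant: likelihood variance, diagnostic W, parameter style."""

    id: str
    param_style: str                     # "sigma" | "theta"
    n_eps: int                           # EPS terms in the observation equation
    fixed_sigma: bool                    # True for the "SIGMA 1 FIX" codings
    param_names: Tuple[str, ...]         # active ErrorParams slots, in order
    variance_fn: Callable = field(repr=False)
    w_fn: Callable = field(repr=False)
    dvariance_dipred: Callable = field(repr=False)
    normalized: bool = True              # W**2 == variance identically

    def variance(self, ipred, params: ErrorParams):
        return self.variance_fn(ipred, params)

    def w(self, ipred, params: ErrorParams):
        return self.w_fn(ipred, params)


_REGISTRY = {
    "ADD.1": ErrorCoding("ADD.1", "sigma", 1, False, ("sigma1",),
                         _var_add_sigma, _w_add_sigma, _dvar_zero),
    "ADD.2": ErrorCoding("ADD.2", "sigma", 1, False, ("sigma1",),
                         _var_add_sigma, _w_one, _dvar_zero, normalized=False),
    "ADD.3": ErrorCoding("ADD.3", "theta", 1, True, ("theta4",),
                         _var_add_theta, _w_add_theta, _dvar_zero),
    "PROP.1": ErrorCoding("PROP.1", "sigma", 1, False, ("sigma1",),
                          _var_prop_sigma, _w_prop_sigma, _dvar_prop_sigma),
    "PROP.2": ErrorCoding("PROP.2", "sigma", 1, False, ("sigma1",),
                          _var_prop_sigma, _w_ipred, _dvar_prop_sigma,
                          normalized=False),
    "PROP.3": ErrorCoding("PROP.3", "theta", 1, True, ("theta4",),
                          _var_prop_theta, _w_prop_theta, _dvar_prop_theta),
    "COMB_VAR1": ErrorCoding("COMB_VAR1", "sigma", 2, False, ("sigma1", "sigma2"),
                             _var_comb_sigma, _w_comb_sigma, _dvar_comb_sigma),
    "COMB_VAR3": ErrorCoding("COMB_VAR3", "theta", 1, True, ("theta4", "theta5"),
                             _var_comb_theta, _w_comb_theta, _dvar_comb_theta),
    "COMB_SD": ErrorCoding("COMB_SD", "theta", 1, True, ("theta4", "theta5"),
                           _var_comb_sd, _w_comb_sd, _dvar_comb_sd),
}


def registry() -> dict:
    """The nine coding variants, keyed by id."""
    return dict(_REGISTRY)


def get_coding(coding_id: str) -> ErrorCoding:
    try:
        return _REGISTRY[coding_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown coding {coding_id!r}; choose from {', '.join(CODING_IDS)}"
        ) from None


def w_value(coding: ErrorCoding, ipred, params: ErrorParams):
    """Diagnostic scale W (mg/L) at the given individual prediction."""
    return coding.w_fn(ipred, params)


def variance_value(coding: ErrorCoding, ipred, params: ErrorParams):
    """Residual variance ((mg/L)^2) entering the likelihood."""
    return coding.variance_fn(ipred, params)
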