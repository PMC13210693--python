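"""One-compartment first-order oral absorption model.

Closed-form concentration profile and analytic sensitivities with respect
to the log-normal random effects on clearance and volume.  These are the
building blocks for the conditional (FOCE) linearization: the marginal
covariance of a subject's observations is ``J @ Omega @ J.T + diag(v)``
where ``J`` is the eta-Jacobian computed here.

Parameterization is the standard oral one: apparent clearance CL/F (L/h),
apparent volume V/F (L) and absorption rate constant KA (1/h), with
elimination rate ke = CL/V.  Only single-dose profiles are supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InvalidParameterError",
    "StructuralParams",
    "IndividualParams",
    "concentration",
    "eta_jacobian",
    "tmax",
]

#: relative |ka - ke| threshold below which the flip-flop limit expansion
#: is used instead of the (cancelling) two-exponential form
FLIP_FLOP_RTOL = 1e-8


class InvalidParameterError(ValueError):
    """A structural or individual PK parameter is not strictly positive."""


@dataclass(frozen=True)
class StructuralParams:
    """Typical-value (population) structural parameters.

    Attributes
    ----------
    tvcl : float
        Typical apparent clearance CL/F, L/h.
    tvv : float
        Typical apparent volume of distribution V/F, L.
    ka : float
        First-order absorption rate constant, 1/h.
    """

    tvcl: float
    tvv: float
    ka: float

    def __post_init__(self) -> None:
        for name in ("tvcl", "tvv", "ka"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"{name} must be strictly positive, got {value!r}"
                )

    def individual(self, eta_cl: float = 0.0, eta_v: float = 0.0) -> "IndividualParams":
        """Individual parameters under log-normal random effects."""
        return IndividualParams(
            cl=self.tvcl * float(np.exp(eta_cl)),
            v=self.tvv * float(np.exp(eta_v)),
            ka=self.ka,
        )


@dataclass(frozen=True)
class IndividualParams:
    """Subject-level parameters: cl = TVCL*exp(eta_CL), v = TVV*exp(eta_V)."""

    cl: float
    v: float
    ka: float

    def __post_init__(self) -> None:
        for name in ("cl", "v", "ka"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"{name} must be strictly positive, got {value!r}"
                )


def _conc(dose, t, cl, v, ka):
    """Vectorized closed form; arguments broadcast together."""
    ke = cl / v
    diff = ka - ke
    near = np.abs(diff) < FLIP_FLOP_RTOL * ka
    safe = np.where(near, 1.0, diff)
    general = dose * ka / (v * safe) * (np.exp(-ke * t) - np.exp(-ka * t))
    limit = dose * ka * t * np.exp(-ka * t) / v
    return np.where(near, limit, general)


def _conc_and_jac(dose, t, cl, v, ka):
    """Concentration and its partials w.r.t. (eta_CL, eta_V).

    Uses the chain rule through ke = cl/v with cl = TVCL*exp(eta_CL),
    v = TVV*exp(eta_V), so d ke/d eta_CL = ke and d ke/d eta_V = -ke.
    The volume enters f only through the 1/v prefactor and ke, giving the
    identity df/d eta_V = -f - df/d eta_CL.
    """
    ke = cl / v
    diff = ka - ke
    near = np.abs(diff) < FLIP_FLOP_RTOL * ka
    safe = np.where(near, 1.0, diff)
    e_ke = np.exp(-ke * t)
    e_ka = np.exp(-ka * t)
    f = np.where(near, dose * ka * t * e_ka / v,
                 dose * ka / (v * safe) * (e_ke - e_ka))
    # d f / d ke (ka held fixed); near ka=ke the general form cancels
    # catastrophically, so use the series limit -dose*ka*t^2*exp(-ka t)/(2v).
    dfdke_general = dose * ka / v * (-t * e_ke / safe + (e_ke - e_ka) / safe**2)
    dfdke_limit = -dose * ka * t**2 * e_ka / (2.0 * v)
    dfdke = np.where(near, dfdke_limit, dfdke_general)
    d_cl = ke * dfdke
    d_v = -f - d_cl
    return f, d_cl, d_v


def concentration(dose: float, t, p: IndividualParams):
    """Plasma concentration (mg/L) at time(s) ``t`` hours after ``dose`` mg.

    C(t) = dose*ka / (v*(ka-ke)) * (exp(-ke t) - exp(-ka t)), ke = cl/v,
    replaced by the limit dose*ka*t*exp(-ka t)/v when ka ~= ke.

    ``t`` may be a scalar or an array; a scalar input returns a scalar.
    """
    if dose <= 0:
        raise InvalidParameterError(f"dose must be positive, got {dose!r}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = _conc(dose, t_arr, p.cl, p.v, p.ka)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def tmax(p: IndividualParams) -> float:
    """Time of the concentration peak, ln(ka/ke)/(ka - ke) hours."""
    ke = p.cl / p.v
    if abs(p.ka - ke) < FLIP_FLOP_RTOL * p.ka:
        return 1.0 / p.ka
    return float(np.log(p.ka / ke) / (p.ka - ke))


def predict_eta(dose, times, p0: StructuralParams, etas):
    """Concentrations for a batch of random-effect vectors.

    Parameters
    ----------
    dose : float or (m,) array
        Dose per subject (mg).
    times : (n,) array
        Sampling times (h), shared across subjects.
    etas : (m, 2) array
        Columns are (eta_CL, eta_V).

    Returns
    -------
    (m, n) array of concentrations.
    """
    etas = np.atleast_2d(np.asarray(etas, dtype=float))
    times = np.asarray(times, dtype=float)
    cl = p0.tvcl * np.exp(etas[:, 0])[:, None]
    v = p0.tvv * np.exp(etas[:, 1])[:, None]
    dose_col = np.asarray(dose, dtype=float).reshape(-1, 1) if np.ndim(dose) else dose
    return _conc(dose_col, times[None, :], cl, v, p0.ka)


def predict_and_jac_eta(dose, times, p0: StructuralParams, etas):
    """Batched concentrations and eta-Jacobians.

    Returns ``(f, J)`` with ``f`` of shape (m, n) and ``J`` of shape
    (m, n, 2); ``J[..., 0]`` is df/d eta_CL and ``J[..., 1]`` df/d eta_V.
    """
    etas = np.atleast_2d(np.asarray(etas, dtype=float))
    times = np.asarray(times, dtype=float)
    cl = p0.tvcl * np.exp(etas[:, 0])[:, None]
    v = p0.tvv * np.exp(etas[:, 1])[:, None]
    dose_col = np.asarray(dose, dtype=float).reshape(-1, 1) if np.ndim(dose) else dose
    f, d_cl, d_v = _conc_and_jac(dose_col, times[None, :], cl, v, p0.ka)
    return f, np.stack([d_cl, d_v], axis=-1)


def eta_jacobian(dose, times, p0: StructuralParams, eta):
    """Analytic sensitivities of the concentration to (eta_CL, eta_V).

    Returns an (n_times, 2) matrix evaluated at the supplied eta.  Rows at
    t = 0 are exactly zero since C(0) = 0 for every eta.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    _, jac = predict_and_jac_eta(dose, times, p0, np.asarray(eta, float)[None, :])
    return jac[0]
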