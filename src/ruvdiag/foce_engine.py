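"""First-order conditional estimation with interaction (FOCE-I).

The estimator alternates two levels:

* **inner problem** — per-subject MAP (empirical Bayes) estimation of the
  random effects eta, minimizing
  ``sum_j [log v_j(eta) + (y_j - f_j(eta))^2 / v_j(eta)] + eta' Omega^-1 eta``
  with the residual variance evaluated at the conditional prediction
  (the "interaction" part).  All subjects are advanced simultaneously by
  a damped Newton iteration with an expected-information Hessian.

* **outer problem** — minimization of the linearized marginal -2
  log-likelihood (objective function value, OFV) over the structural
  parameters, the between-subject variances and the residual-error
  parameters, all log-transformed to enforce positivity.  Per subject,
  with J the eta-Jacobian at the MAP eta,

  ``OFV_i = log|V_i| + r_i' V_i^-1 r_i``,
  ``V_i = J Omega J' + diag(v_j)``, ``r_i = y_i - f_i(eta) + J eta``.

The additive constant n*log(2*pi) is excluded from the OFV and reported
separately, so only OFV differences are meaningful.

The engine handles balanced designs: all subjects share one sampling
grid (each may have its own dose).  The structural model is pluggable —
any object with batched ``predict``/``jacobian`` methods works, which is
how the closed-form linear mixed model oracle used in the tests plugs in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, Optional

import numpy as np
from scipy import optimize

from . import pk_model
from .error_coding import ErrorCoding, ErrorParams, get_coding
from .synthetic_data import Dataset, SimulationProtocol

__all__ = [
    "NumericalError",
    "PopulationParams",
    "FitResult",
    "SubjectData",
    "PKEtaModel",
    "map_objective",
    "estimate_etas",
    "foce_ofv",
    "fit",
    "standard_errors",
    "default_init",
    "design_arrays",
]

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))

#: inner (MAP) gradient tolerance — small enough that the OFV is smooth
#: to ~1e-12 for the outer finite-difference machinery
INNER_GTOL = 1e-9
INNER_MAX_ITER = 200

_OMEGA_ZERO_TOL = 1e-12


class NumericalError(RuntimeError):
    """Non-positive residual variance or indefinite marginal covariance."""


@dataclass(frozen=True)
class PopulationParams:
    """One point in the population-parameter space.

    ``ka`` inside ``structural`` is fixed, never estimated.
    """

    structural: pk_model.StructuralParams
    omega2_cl: float
    omega2_v: float
    error_params: ErrorParams

    def omega(self) -> np.ndarray:
        return np.diag([self.omega2_cl, self.omega2_v])


@dataclass(frozen=True)
class SubjectData:
    """Observations of a single subject on a common sampling grid."""

    y: np.ndarray
    dose: float
    times: np.ndarray


@dataclass
class FitResult:
    """Converged (or flagged) population fit."""

    params: PopulationParams
    ofv: float
    etas: np.ndarray                 # (n_subjects, 2) empirical Bayes estimates
    coding_id: str
    converged: bool
    n_iter: int
    n_ofv_evals: int
    grad_norm: float
    se: Optional[Dict[str, float]] = None
    ofv_constant: float = 0.0        # excluded n*log(2*pi) term
    subject_ids: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# structural-model adapters
# ---------------------------------------------------------------------------

class PKEtaModel:
    """Batched one-compartment oral model as a function of eta."""

    n_eta = 2

    def __init__(self, dose, times, structural: pk_model.StructuralParams):
        self.dose = dose
        self.times = np.asarray(times, dtype=float)
        self.structural = structural

    def predict(self, etas: np.ndarray) -> np.ndarray:
        return pk_model.predict_eta(self.dose, self.times, self.structural, etas)

    def predict_and_jac(self, etas: np.ndarray):
        return pk_model.predict_and_jac_eta(self.dose, self.times,
                                            self.structural, etas)


def design_arrays(dataset: Dataset):
    """Extract the balanced-design arrays (y, dose, times, ids).

    Raises ``ValueError`` if subjects do not share one sampling grid.
    """
    obs = dataset.observations.sort_values(["ID", "TIME"], kind="stable")
    ids = obs["ID"].unique()
    times = np.sort(obs["TIME"].unique())
    pivot = obs.pivot_table(index="ID", columns="TIME", values="DV")
    if pivot.isna().any().any() or pivot.shape != (ids.size, times.size):
        raise ValueError("dataset is not balanced: subjects must share one "
                         "sampling grid")
    y = pivot.loc[ids, times].to_numpy(dtype=float)
    doses = dataset.records[dataset.records["EVID"] == 1].groupby("ID")["AMT"].sum()
    dose = doses.reindex(ids).to_numpy(dtype=float)
    if np.allclose(dose, dose[0]):
        dose = float(dose[0])
    return y, dose, times, ids


# ---------------------------------------------------------------------------
# inner problem: vectorized MAP estimation of eta
# ---------------------------------------------------------------------------

def _map_value(y, f, v, etas, omega_inv):
    """Per-subject MAP objective (without log|Omega|)."""
    r = y - f
    data_term = np.sum(np.log(v) + r * r / v, axis=-1)
    prior = np.einsum("mi,ij,mj->m", etas, omega_inv, etas)
    return data_term + prior


def _map_etas_batched(y, model, omega, variance_fn, dvariance_fn,
                      eta0=None, gtol=INNER_GTOL, max_iter=INNER_MAX_ITER):
    """Damped Newton MAP estimation for all subjects at once.

    Returns (etas, max_grad_norm).  The Hessian approximation is the
    expected information sum_j (2/v + (v'/v)^2) J_j J_j' + 2 Omega^-1,
    which is symmetric positive definite, combined with backtracking
    line search on the exact objective.
    """
    m = y.shape[0]
    k = omega.shape[0]
    omega_inv = np.linalg.inv(omega)
    etas = np.zeros((m, k)) if eta0 is None else np.array(eta0, dtype=float)

    f, jac = model.predict_and_jac(etas)
    v = np.maximum(variance_fn(f), 0.0)
    if np.any(v <= 0):
        raise NumericalError("non-positive residual variance in inner problem")
    obj = _map_value(y, f, v, etas, omega_inv)
    # subjects whose line search hit the numerical floor of the objective
    stalled = np.zeros(m, dtype=bool)

    for _ in range(max_iter):
        r = y - f
        dv = dvariance_fn(f)
        coef = dv * (1.0 / v - r * r / (v * v)) - 2.0 * r / v
        grad = np.einsum("mn,mnk->mk", coef, jac) + 2.0 * etas @ omega_inv
        gnorm = np.linalg.norm(grad, axis=1)
        active = (gnorm >= gtol) & ~stalled
        if not np.any(active):
            break
        weight = 2.0 / v + (dv / v) ** 2
        hess = np.einsum("mn,mnk,mnl->mkl", weight, jac, jac) + 2.0 * omega_inv
        try:
            step = -np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            hess = hess + 1e-8 * np.eye(k)
            step = -np.linalg.solve(hess, grad[..., None])[..., 0]

        descent = np.einsum("mk,mk->m", grad, step)
        # slack absorbs objective round-off so progress at machine
        # precision is not rejected forever
        slack = 1e-12 * (1.0 + np.abs(obj))
        alpha = np.ones(m)
        remaining = active.copy()
        new_etas = etas.copy()
        for _bt in range(30):
            trial = etas + alpha[:, None] * step
            f_t, _ = model.predict_and_jac(trial)
            v_t = variance_fn(f_t)
            obj_t = np.where(np.all(v_t > 0, axis=-1),
                             _map_value(y, f_t, np.maximum(v_t, 1e-300),
                                        trial, omega_inv),
                             np.inf)
            ok = obj_t <= obj + 1e-4 * alpha * descent + slack
            accept = remaining & ok
            new_etas[accept] = trial[accept]
            remaining = remaining & ~ok
            if not np.any(remaining):
                break
            alpha[remaining] *= 0.5
        stalled |= remaining  # cannot improve further at this precision
        etas = new_etas
        f, jac = model.predict_and_jac(etas)
        v = variance_fn(f)
        if np.any(v <= 0):
            raise NumericalError("non-positive residual variance in inner problem")
        obj = _map_value(y, f, v, etas, omega_inv)
    else:
        logger.debug("inner MAP iteration limit reached (max grad %.2e)",
                     float(np.max(gnorm)))
    r = y - f
    dv = dvariance_fn(f)
    coef = dv * (1.0 / v - r * r / (v * v)) - 2.0 * r / v
    grad = np.einsum("mn,mnk->mk", coef, jac) + 2.0 * etas @ omega_inv
    return etas, float(np.max(np.linalg.norm(grad, axis=1)))


def _coding_fns(coding: ErrorCoding, params: ErrorParams):
    return (lambda g: coding.variance_fn(g, params),
            lambda g: coding.dvariance_dipred(g, params))


def map_objective(subject: SubjectData, eta, pop: PopulationParams,
                  coding: ErrorCoding) -> float:
    """MAP objective for one subject at a given eta (includes log|Omega|)."""
    omega = pop.omega()
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        raise NumericalError("Omega must be positive definite")
    model = PKEtaModel(subject.dose, subject.times, pop.structural)
    etas = np.asarray(eta, dtype=float)[None, :]
    f = model.predict(etas)
    v = coding.variance_fn(f, pop.error_params)
    if np.any(v <= 0):
        raise NumericalError("non-positive residual variance")
    value = _map_value(subject.y[None, :], f, v, etas, np.linalg.inv(omega))
    return float(value[0] + logdet)


def estimate_etas(dataset: Dataset, pop: PopulationParams,
                  coding: ErrorCoding) -> np.ndarray:
    """Empirical Bayes (MAP) eta for every subject, cold-started at zero."""
    y, dose, times, _ = design_arrays(dataset)
    model = PKEtaModel(dose, times, pop.structural)
    omega = pop.omega()
    if np.all(np.diag(omega) < _OMEGA_ZERO_TOL):
        return np.zeros((y.shape[0], 2))
    variance_fn, dvariance_fn = _coding_fns(coding, pop.error_params)
    etas, _ = _map_etas_batched(y, model, omega, variance_fn, dvariance_fn)
    return etas


# ---------------------------------------------------------------------------
# outer problem: linearized marginal likelihood
# ---------------------------------------------------------------------------

def _marginal_ofv(y, model, omega, variance_fn, dvariance_fn, eta0=None):
    """FOCE-I OFV (no 2*pi constant) and the MAP etas it used."""
    m, n = y.shape
    if np.all(np.diag(omega) < _OMEGA_ZERO_TOL):
        etas = np.zeros((m, omega.shape[0]))
        f = model.predict(etas)
        v = variance_fn(f)
        if np.any(v <= 0):
            raise NumericalError("non-positive residual variance")
        r = y - f
        return float(np.sum(np.log(v) + r * r / v)), etas

    etas, _ = _map_etas_batched(y, model, omega, variance_fn, dvariance_fn,
                                eta0=eta0)
    f, jac = model.predict_and_jac(etas)
    v = variance_fn(f)
    if np.any(v <= 0):
        raise NumericalError("non-positive residual variance")
    cov = np.einsum("mnk,kl,mjl->mnj", jac, omega, jac)
    cov[:, np.arange(n), np.arange(n)] += v
    sign, logdet = np.linalg.slogdet(cov)
    if np.any(sign <= 0):
        bad = int(np.argmax(sign <= 0))
        raise NumericalError(f"marginal covariance not positive definite "
                             f"(subject index {bad})")
    r = y - f + np.einsum("mnk,mk->mn", jac, etas)
    quad = np.einsum("mn,mn->", r, np.linalg.solve(cov, r[..., None])[..., 0])
    return float(np.sum(logdet) + quad), etas


def foce_ofv(dataset: Dataset, pop: PopulationParams,
             coding: ErrorCoding) -> float:
    """FOCE-I objective function value at a fixed parameter point.

    NONMEM-style: the additive constant n*log(2*pi) is excluded.
    """
    y, dose, times, _ = design_arrays(dataset)
    model = PKEtaModel(dose, times, pop.structural)
    variance_fn, dvariance_fn = _coding_fns(coding, pop.error_params)
    ofv, _ = _marginal_ofv(y, model, pop.omega(), variance_fn, dvariance_fn)
    return ofv


def marginal_ofv_general(y, model, omega, variance_fn,
                         dvariance_fn=None) -> float:
    """FOCE-I OFV for an arbitrary batched eta-model (oracle entry point)."""
    if dvariance_fn is None:
        dvariance_fn = lambda g: np.zeros_like(np.asarray(g, float))
    ofv, _ = _marginal_ofv(np.asarray(y, float), model,
                           np.asarray(omega, float), variance_fn, dvariance_fn)
    return ofv


# ---------------------------------------------------------------------------
# parameter packing: everything estimated on the log scale
# ---------------------------------------------------------------------------

_BASE_NAMES = ("tvcl", "tvv", "omega2_cl", "omega2_v")


def _param_names(coding: ErrorCoding):
    return _BASE_NAMES + coding.param_names


def _pack(pop: PopulationParams, coding: ErrorCoding) -> np.ndarray:
    values = [pop.structural.tvcl, pop.structural.tvv,
              pop.omega2_cl, pop.omega2_v]
    values += list(pop.error_params.require(*coding.param_names))
    return np.log(np.asarray(values, dtype=float))


def _unpack(x: np.ndarray, coding: ErrorCoding, ka: float) -> PopulationParams:
    values = np.exp(np.asarray(x, dtype=float))
    err = ErrorParams(**dict(zip(coding.param_names, values[4:])))
    return PopulationParams(
        structural=pk_model.StructuralParams(tvcl=values[0], tvv=values[1], ka=ka),
        omega2_cl=values[2], omega2_v=values[3], error_params=err,
    )


def default_init(coding: ErrorCoding, protocol: Optional[SimulationProtocol],
                 inflation: float = 1.2) -> PopulationParams:
    """Initial estimates: protocol truths inflated by 20% on the SD scale.

    Without a protocol, generic magnitudes of the study design are used.
    """
    if protocol is None:
        protocol = default_protocol_like(coding)
    struct = protocol.structural
    sd_add = (protocol.sigma_add or 0.5) * inflation
    cv_prop = (protocol.sigma_prop or 0.2) * inflation
    slots = {}
    for name in coding.param_names:
        if name == "sigma1":
            slots[name] = (cv_prop ** 2 if "PROP" in coding.id or
                           coding.id.startswith("COMB") else sd_add ** 2)
        elif name == "sigma2":
            slots[name] = sd_add ** 2
        elif name == "theta4":
            slots[name] = (sd_add if coding.id.startswith("ADD") else cv_prop)
        elif name == "theta5":
            slots[name] = sd_add
    return PopulationParams(
        structural=pk_model.StructuralParams(
            tvcl=struct.tvcl * inflation, tvv=struct.tvv * inflation, ka=struct.ka
        ),
        omega2_cl=protocol.omega2_cl * inflation,
        omega2_v=protocol.omega2_v * inflation,
        error_params=ErrorParams(**slots),
    )


def default_protocol_like(coding: ErrorCoding):
    """Generic protocol used only to seed initial estimates."""
    from .synthetic_data import default_protocol
    kind = ("additive" if coding.id.startswith("ADD")
            else "proportional" if coding.id.startswith("PROP")
            else "combined")
    return default_protocol(kind)


def fit(dataset: Dataset, coding, init: Optional[PopulationParams] = None,
        compute_se: bool = True) -> FitResult:
    """Fit one error-coding variant to a dataset by FOCE-I.

    KA is fixed at its structural value; everything else (typical
    clearance and volume, both between-subject variances, the coding's
    residual-error parameters) is estimated on the log scale.  A
    quasi-Newton (L-BFGS-B) pass with finite-difference gradients is
    followed by a Nelder-Mead polish for a tight optimum.
    """
    if isinstance(coding, str):
        coding = get_coding(coding)
    if init is None:
        init = default_init(coding, dataset.protocol)
    ka = init.structural.ka

    y, dose, times, ids = design_arrays(dataset)
    model = PKEtaModel(dose, times, init.structural)
    eta_cache = {"etas": None}
    n_evals = {"count": 0}

    def objective(x):
        pop = _unpack(x, coding, ka)
        model.structural = pop.structural
        variance_fn, dvariance_fn = _coding_fns(coding, pop.error_params)
        try:
            ofv, etas = _marginal_ofv(y, model, pop.omega(), variance_fn,
                                      dvariance_fn, eta0=eta_cache["etas"])
        except NumericalError:
            return 1e12
        eta_cache["etas"] = etas
        n_evals["count"] += 1
        return ofv

    x0 = _pack(init, coding)
    res = optimize.minimize(objective, x0, method="L-BFGS-B",
                            options=dict(maxiter=500, ftol=1e-12, gtol=1e-6,
                                         finite_diff_rel_step=1e-5))
    polish = optimize.minimize(objective, res.x, method="Nelder-Mead",
                               options=dict(maxfev=3000, fatol=1e-7,
                                            xatol=1e-6))
    best = polish if polish.fun <= res.fun else res

    pop = _unpack(best.x, coding, ka)
    # cold restart for deterministic reported etas and OFV
    model.structural = pop.structural
    variance_fn, dvariance_fn = _coding_fns(coding, pop.error_params)
    ofv, etas = _marginal_ofv(y, model, pop.omega(), variance_fn, dvariance_fn)

    grad_norm = _fd_grad_norm(objective, best.x)
    converged = bool(res.success or polish.success) and np.isfinite(ofv)
    result = FitResult(
        params=pop, ofv=ofv, etas=etas, coding_id=coding.id,
        converged=converged, n_iter=int(res.nit + polish.nit),
        n_ofv_evals=n_evals["count"], grad_norm=grad_norm,
        ofv_constant=y.size * LOG2PI, subject_ids=ids,
    )
    if compute_se:
        try:
            result.se = standard_errors(result, dataset, coding)
        except NumericalError as exc:
            logger.warning("standard errors omitted: %s", exc)
    return result


def _fd_grad_norm(objective, x, h=1e-5):
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (objective(x + e) - objective(x - e)) / (2 * h)
    return float(np.linalg.norm(g))


def standard_errors(fit_result: FitResult, dataset: Dataset,
                    coding) -> Dict[str, float]:
    """Asymptotic SEs from the finite-difference Hessian of OFV/2.

    The Hessian is taken on the log (estimation) scale and the SEs are
    delta-method transformed back to the natural reporting scale.
    """
    if isinstance(coding, str):
        coding = get_coding(coding)
    ka = fit_result.params.structural.ka
    y, dose, times, _ = design_arrays(dataset)
    model = PKEtaModel(dose, times, fit_result.params.structural)

    def objective(x):
        pop = _unpack(x, coding, ka)
        model.structural = pop.structural
        variance_fn, dvariance_fn = _coding_fns(coding, pop.error_params)
        ofv, _ = _marginal_ofv(y, model, pop.omega(), variance_fn, dvariance_fn)
        return 0.5 * ofv

    x = _pack(fit_result.params, coding)
    p = x.size
    h = 1e-3
    hess = np.empty((p, p))
    f0 = objective(x)
    steps = [h * np.eye(p)[i] for i in range(p)]
    fp = [objective(x + s) for s in steps]
    fm = [objective(x - s) for s in steps]
    for i in range(p):
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
        for j in range(i + 1, p):
            fpp = objective(x + steps[i] + steps[j])
            fmm = objective(x - steps[i] - steps[j])
            hess[i, j] = hess[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h**2)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"Hessian not invertible: {exc}") from exc
    var = np.diag(cov)
    if np.any(var <= 0):
        raise NumericalError("Hessian not positive definite at the optimum")
    # delta method: parameter p = exp(x) => SE_p = p * SE_x
    natural = np.exp(x)
    return dict(zip(_param_names(coding), natural * np.sqrt(var)))
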