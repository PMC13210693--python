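"""Diagnostic residuals: IPRED/IRES/IWRES, PRED/RES/WRES, CWRESI.

Three families of residuals are computed from a converged fit:

* individual (conditional) residuals — IPRED is the prediction at the
  empirical Bayes eta, IRES = DV - IPRED, and IWRES = IRES / W where W is
  the coding's diagnostic scale.  Only this family depends on W.

* population residuals — PRED is the prediction at eta = 0, RES = DV -
  PRED, and WRES whitens the residual vector by the first-order marginal
  covariance V0 = J(0) Omega J(0)' + diag(v(PRED)) via its lower
  Cholesky factor.

* conditional weighted residuals with interaction (CWRESI) — the
  marginal mean and covariance are linearized at the MAP eta, with the
  residual variance evaluated at the conditional prediction:
  E = f(eta) - J(eta) eta, V = J(eta) Omega J(eta)' + diag(v(f(eta))),
  CWRESI = L^-1 (y - E).

Whitening uses the lower-triangular Cholesky factor (forward
substitution); per-observation values depend on that convention, summary
statistics (means, SDs, norms) do not.

Epsilon-shrinkage is the departure of SD(IWRES) from unity,
``1 - SD(IWRES)``: empirical Bayes shrinkage pulls individual
predictions toward the data, compressing IRES toward zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .error_coding import ErrorCoding, get_coding
from .foce_engine import FitResult, NumericalError, PKEtaModel, design_arrays
from .synthetic_data import Dataset

__all__ = [
    "FIT_COLUMNS",
    "individual_residuals",
    "population_residuals",
    "conditional_residuals",
    "diagnostics_table",
    "write_diagnostics",
    "read_diagnostics",
    "epsilon_shrinkage",
]

logger = logging.getLogger(__name__)

#: column set and order of the exported diagnostics table
FIT_COLUMNS = ["ID", "TIME", "DV", "IPRED", "IWRES", "WRES", "CWRESI",
               "PRED", "RES"]


def _setup(fit: FitResult, dataset: Dataset, coding):
    if isinstance(coding, str):
        coding = get_coding(coding)
    y, dose, times, ids = design_arrays(dataset)
    model = PKEtaModel(dose, times, fit.params.structural)
    return coding, y, times, ids, model


def _base_frame(ids, times, y):
    m, n = y.shape
    return pd.DataFrame({
        "ID": np.repeat(ids, n),
        "TIME": np.tile(times, m),
        "DV": y.ravel(),
    })


def individual_residuals(fit: FitResult, dataset: Dataset, coding) -> pd.DataFrame:
    """IPRED, IRES and IWRES = IRES / W at the empirical Bayes etas."""
    coding, y, times, ids, model = _setup(fit, dataset, coding)
    ipred = model.predict(fit.etas)
    ires = y - ipred
    w = np.asarray(coding.w_fn(ipred, fit.params.error_params), dtype=float)
    w = np.broadcast_to(w, ipred.shape)
    bad = ~(w > 0)
    if np.any(bad):
        logger.warning("IWRES undefined at %d observation(s) with W <= 0",
                       int(bad.sum()))
    iwres = np.where(bad, np.nan, ires / np.where(bad, 1.0, w))
    out = _base_frame(ids, times, y)
    out["IPRED"] = ipred.ravel()
    out["IRES"] = ires.ravel()
    out["IWRES"] = iwres.ravel()
    return out


def _whiten(cov, resid):
    """Lower-Cholesky whitening, subject by subject."""
    m = cov.shape[0]
    out = np.empty_like(resid)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"covariance not positive definite: {exc}") from exc
    for i in range(m):
        out[i] = solve_triangular(chol[i], resid[i], lower=True)
    return out


def population_residuals(fit: FitResult, dataset: Dataset, coding) -> pd.DataFrame:
    """PRED, RES and first-order WRES at eta = 0."""
    coding, y, times, ids, model = _setup(fit, dataset, coding)
    m, n = y.shape
    zeros = np.zeros((m, 2))
    pred, jac0 = model.predict_and_jac(zeros)
    v = np.broadcast_to(
        np.asarray(coding.variance_fn(pred, fit.params.error_params), float),
        pred.shape)
    cov = np.einsum("mnk,kl,mjl->mnj", jac0, fit.params.omega(), jac0).copy()
    cov[:, np.arange(n), np.arange(n)] += v
    wres = _whiten(cov, y - pred)
    out = _base_frame(ids, times, y)
    out["PRED"] = pred.ravel()
    out["RES"] = (y - pred).ravel()
    out["WRES"] = wres.ravel()
    return out


def conditional_residuals(fit: FitResult, dataset: Dataset, coding) -> pd.DataFrame:
    """CWRESI: whitened residuals from the linearization at the MAP eta."""
    coding, y, times, ids, model = _setup(fit, dataset, coding)
    m, n = y.shape
    f, jac = model.predict_and_jac(fit.etas)
    v = np.broadcast_to(
        np.asarray(coding.variance_fn(f, fit.params.error_params), float),
        f.shape)
    mean = f - np.einsum("mnk,mk->mn", jac, fit.etas)
    cov = np.einsum("mnk,kl,mjl->mnj", jac, fit.params.omega(), jac).copy()
    cov[:, np.arange(n), np.arange(n)] += v
    cwresi = _whiten(cov, y - mean)
    out = _base_frame(ids, times, y)
    out["CWRESI"] = cwresi.ravel()
    return out


def diagnostics_table(fit: FitResult, dataset: Dataset, coding) -> pd.DataFrame:
    """Full per-observation diagnostics table (plus the IRES column)."""
    indiv = individual_residuals(fit, dataset, coding)
    popres = population_residuals(fit, dataset, coding)
    cond = conditional_residuals(fit, dataset, coding)
    out = indiv.copy()
    for col in ("PRED", "RES", "WRES"):
        out[col] = popres[col].to_numpy()
    out["CWRESI"] = cond["CWRESI"].to_numpy()
    return out.loc[:, FIT_COLUMNS + ["IRES"]]


def write_diagnostics(table: pd.DataFrame, path) -> None:
    """Write the table with exactly the standard column set and order."""
    table.loc[:, FIT_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_diagnostics(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FIT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing diagnostics column(s): {', '.join(missing)}")
    return table


def epsilon_shrinkage(iwres) -> float:
    """Epsilon-shrinkage 1 - SD(IWRES) (sample SD, denominator n-1)."""
    values = np.asarray(iwres, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("epsilon shrinkage needs at least two IWRES values")
    return float(1.0 - np.std(values, ddof=1))
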