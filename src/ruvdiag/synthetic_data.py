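"""Stochastic simulation of the three population PK study datasets.

The generator emulates a dense single-dose oral PK study: 500 subjects,
one 100 mg dose each, 12 samples per subject between 0.25 and 24 h, with
log-normal between-subject variability (variance 0.09, ~30% CV) on
clearance and volume, under one of three residual-error structures:

* additive        DV = IPRED + sigma_add * eps
* proportional    DV = IPRED * (1 + sigma_prop * eps)
* combined        DV = IPRED * (1 + sigma_prop * eps1) + sigma_add * eps2

Simulated concentrations below a floor (0.001 mg/L by default) are
truncated to the floor to avoid non-physical values; estimation treats
all records as exact observations (no censoring model).

Datasets are exchanged as NONMEM-style rectangular CSV records with
columns ID, TIME, AMT, DV, EVID, MDV: one dose row (EVID=1, MDV=1) per
subject followed by its observation rows (EVID=0, MDV=0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .pk_model import StructuralParams, predict_eta

__all__ = [
    "FormatError",
    "STUDY_TIMES",
    "ERROR_KINDS",
    "SimulationProtocol",
    "Dataset",
    "default_protocol",
    "simulate_dataset",
    "apply_floor",
    "read_dataset",
    "write_dataset",
]

logger = logging.getLogger(__name__)

#: nominal sampling grid of the study design (hours post dose)
STUDY_TIMES = (0.25, 0.5, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 18.0, 24.0)

ERROR_KINDS = ("additive", "proportional", "combined")

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "MDV")

#: true residual-error magnitudes of the study conditions, per structure
_TRUE_SIGMAS = {
    "additive": dict(sigma_add=0.5, sigma_prop=0.0),
    "proportional": dict(sigma_add=0.0, sigma_prop=0.20),
    "combined": dict(sigma_add=0.5, sigma_prop=0.15),
}


class FormatError(ValueError):
    """Dataset file does not conform to the expected column layout."""


@dataclass(frozen=True)
class SimulationProtocol:
    """Everything needed to regenerate a dataset deterministically."""

    error_kind: str
    n_subjects: int = 500
    dose: float = 100.0
    sample_times: tuple = STUDY_TIMES
    structural: StructuralParams = field(
        default_factory=lambda: StructuralParams(tvcl=5.0, tvv=50.0, ka=1.0)
    )
    omega2_cl: float = 0.09
    omega2_v: float = 0.09
    sigma_add: float = 0.0
    sigma_prop: float = 0.0
    floor: float = 1e-3
    seed: int = 20240101

    def __post_init__(self) -> None:
        if self.error_kind not in ERROR_KINDS:
            raise FormatError(
                f"unknown error_kind {self.error_kind!r}; expected one of {ERROR_KINDS}"
            )
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        times = np.asarray(self.sample_times, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("error magnitudes must be non-negative")
        if self.omega2_cl < 0 or self.omega2_v < 0:
            raise ValueError("variances must be non-negative")
        if self.floor <= 0:
            raise ValueError("floor must be positive")

    @property
    def n_times(self) -> int:
        return len(self.sample_times)


def default_protocol(error_kind: str, n_subjects: int = 500,
                     seed: int = 20240101, **overrides) -> SimulationProtocol:
    """Study-condition protocol for one of the three error structures.

    True residual magnitudes: additive sigma = 0.5 mg/L; proportional
    CV = 20%; combined sigma_prop = 0.15 with sigma_add = 0.5 mg/L.
    """
    if error_kind not in _TRUE_SIGMAS:
        raise FormatError(
            f"unknown error_kind {error_kind!r}; expected one of {ERROR_KINDS}"
        )
    kwargs = dict(_TRUE_SIGMAS[error_kind])
    kwargs.update(overrides)
    return SimulationProtocol(error_kind=error_kind, n_subjects=n_subjects,
                              seed=seed, **kwargs)


@dataclass
class Dataset:
    """Rectangular dose + observation records plus provenance metadata.

    ``truth`` (present only for freshly simulated data) holds the latent
    draws: per-subject etas and the noise-free individual predictions.
    """

    records: pd.DataFrame
    protocol: Optional[SimulationProtocol] = None
    truth: Optional[dict] = None

    @property
    def observations(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 0]

    @property
    def n_subjects(self) -> int:
        return int(self.records["ID"].nunique())

    @property
    def n_observations(self) -> int:
        return int((self.records["EVID"] == 0).sum())


def apply_floor(values, floor: float):
    """Truncate concentrations below ``floor`` up to the floor value."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return np.maximum(np.asarray(values, dtype=float), floor)


def simulate_dataset(protocol: SimulationProtocol) -> Dataset:
    """Simulate one dataset under the protocol's error structure.

    A single ``numpy.random.default_rng(seed)`` stream is used with a
    fixed draw order (eta matrix, then the noise matrices), so the same
    protocol always yields a bitwise-identical dataset.
    """
    rng = np.random.default_rng(protocol.seed)
    m, n = protocol.n_subjects, protocol.n_times
    times = np.asarray(protocol.sample_times, dtype=float)

    etas = rng.normal(size=(m, 2)) * np.sqrt(
        [protocol.omega2_cl, protocol.omega2_v]
    )
    ipred = predict_eta(protocol.dose, times, protocol.structural, etas)

    if protocol.error_kind == "additive":
        dv = ipred + protocol.sigma_add * rng.normal(size=(m, n))
    elif protocol.error_kind == "proportional":
        dv = ipred * (1.0 + protocol.sigma_prop * rng.normal(size=(m, n)))
    else:  # combined: two independent noise terms
        eps1 = rng.normal(size=(m, n))
        eps2 = rng.normal(size=(m, n))
        dv = ipred * (1.0 + protocol.sigma_prop * eps1) + protocol.sigma_add * eps2

    n_floored = int(np.sum(dv < protocol.floor))
    dv = apply_floor(dv, protocol.floor)
    logger.info("simulated %s dataset: %d subjects, %d observations, "
                "%d value(s) truncated to the %.3g mg/L floor",
                protocol.error_kind, m, m * n, n_floored, protocol.floor)

    ids = np.arange(1, m + 1)
    dose_rows = pd.DataFrame({
        "ID": ids, "TIME": 0.0, "AMT": protocol.dose, "DV": 0.0,
        "EVID": 1, "MDV": 1,
    })
    obs_rows = pd.DataFrame({
        "ID": np.repeat(ids, n),
        "TIME": np.tile(times, m),
        "AMT": 0.0,
        "DV": dv.ravel(),
        "EVID": 0,
        "MDV": 0,
    })
    records = (
        pd.concat([dose_rows, obs_rows], ignore_index=True)
        .sort_values(["ID", "EVID", "TIME"], ascending=[True, False, True],
                     kind="stable")
        .reset_index(drop=True)
    )
    truth = {"etas": etas, "ipred": ipred, "n_floored": n_floored}
    return Dataset(records=records, protocol=protocol, truth=truth)


def write_dataset(dataset: Dataset, path) -> None:
    """Write the records as comma-separated text with a header row."""
    out = dataset.records.loc[:, list(REQUIRED_COLUMNS)].copy()
    out.to_csv(path, index=False, float_format="%.12g")


def read_dataset(path) -> Dataset:
    """Read a NONMEM-style rectangular CSV written by :func:`write_dataset`."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)]
    df["ID"] = df["ID"].astype(int)
    df["EVID"] = df["EVID"].astype(int)
    df["MDV"] = df["MDV"].astype(int)
    for col in ("TIME", "AMT", "DV"):
        df[col] = df[col].astype(float)
    return Dataset(records=df)
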