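"""Pairwise residual comparisons and the nine-run study orchestration.

The study design: three simulated datasets (additive, proportional,
combined residual error), nine FOCE-I fits differing only in the
residual-error coding, and pairwise comparisons of the diagnostic
residuals between runs sharing a dataset.  The comparison metrics are

* the observation-by-observation IWRES ratio (mean, SD, min, max),
* Pearson correlations between matched residual vectors,
* SD(IWRES) per run as the measure of correct normalization,
* maximum absolute differences in WRES and CWRESI,
* the back-calculated implicit scaling factor IRES / IWRES.

The study report also exports the data series behind the four standard
diagnostic figures (IWRES or CWRESI versus IPRED, per run), so the plots
can be regenerated from CSV without any plotting dependency here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .error_coding import get_coding
from .foce_engine import FitResult, default_init, fit
from .residual_diagnostics import diagnostics_table, epsilon_shrinkage
from .synthetic_data import Dataset, default_protocol, simulate_dataset

__all__ = [
    "AlignmentError",
    "ComparisonSummary",
    "ImplicitW",
    "StudyConfig",
    "StudyReport",
    "pairwise_compare",
    "implicit_w",
    "flag_extremes",
    "run_study",
    "write_study",
    "DATASET_CODINGS",
    "REFERENCE_RUNS",
]

logger = logging.getLogger(__name__)

#: which codings are fitted to which simulated dataset
DATASET_CODINGS = {
    "additive": ("ADD.1", "ADD.2", "ADD.3"),
    "proportional": ("PROP.1", "PROP.2", "PROP.3"),
    "combined": ("COMB_VAR1", "COMB_VAR3", "COMB_SD"),
}

#: normalized reference run within each error type
REFERENCE_RUNS = {
    "additive": "ADD.1",
    "proportional": "PROP.1",
    "combined": "COMB_VAR1",
}

#: |IWRES_B| / |IWRES_A| ratios with |IWRES_A| below this are excluded
RATIO_DENOM_TOL = 1e-12

#: |ratio| threshold flagging extreme observations
EXTREME_RATIO_THRESHOLD = 5.0


class AlignmentError(ValueError):
    """Two diagnostics tables are not row-aligned on (ID, TIME)."""


@dataclass
class ComparisonSummary:
    """Numerical summary of one pairwise run comparison (B versus A)."""

    pair: Tuple[str, str]               # (id_A, id_B); ratios are B / A
    n_obs: int
    n_excluded: int                     # near-zero denominators dropped
    ratio_mean: float
    ratio_sd: float
    ratio_min: float
    ratio_max: float
    pearson_r: Dict[str, float]         # per residual type
    sd_iwres_a: float
    sd_iwres_b: float
    max_abs_diff_wres: float
    max_abs_diff_cwresi: float
    implicit_w_mean: float              # implicit W of run B
    implicit_w_sd: float
    n_extreme: int
    extreme_ipred_range: Optional[Tuple[float, float]]
    cross_dataset: bool = False
    rows: pd.DataFrame = field(repr=False, default=None)


@dataclass
class ImplicitW:
    """Back-calculated per-observation scaling factor IRES / IWRES."""

    values: pd.Series
    mean: float
    sd: float


def _check_aligned(table_a: pd.DataFrame, table_b: pd.DataFrame) -> None:
    if len(table_a) != len(table_b):
        raise AlignmentError("tables differ in row count")
    same = (table_a["ID"].to_numpy() == table_b["ID"].to_numpy()).all() and \
        np.allclose(table_a["TIME"].to_numpy(), table_b["TIME"].to_numpy())
    if not same:
        raise AlignmentError("tables are not aligned on (ID, TIME)")


def implicit_w(table: pd.DataFrame) -> ImplicitW:
    """IRES / IWRES per observation; equals the coding's W at that IPRED."""
    if "IRES" in table.columns:
        ires = table["IRES"].to_numpy(dtype=float)
    else:
        ires = (table["DV"] - table["IPRED"]).to_numpy(dtype=float)
    iwres = table["IWRES"].to_numpy(dtype=float)
    keep = np.abs(iwres) > 0
    if not keep.any():
        raise ValueError("implicit W undefined: all IWRES are zero")
    values = pd.Series(ires[keep] / iwres[keep], index=table.index[keep],
                       name="implicit_w")
    return ImplicitW(values=values, mean=float(values.mean()),
                     sd=float(values.std(ddof=1)))


def pairwise_compare(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     ids: Tuple[str, str] = ("A", "B"),
                     cross_dataset: bool = False) -> ComparisonSummary:
    """Compare two diagnostics tables aligned on (ID, TIME).

    Ratios are ``IWRES_B / IWRES_A``; rows with ``|IWRES_A|`` below
    ``RATIO_DENOM_TOL`` are excluded from the ratio summaries and
    counted in ``n_excluded``.
    """
    _check_aligned(table_a, table_b)
    iwres_a = table_a["IWRES"].to_numpy(dtype=float)
    iwres_b = table_b["IWRES"].to_numpy(dtype=float)
    keep = np.abs(iwres_a) >= RATIO_DENOM_TOL
    ratio = iwres_b[keep] / iwres_a[keep]

    pearson = {}
    for col in ("IWRES", "WRES", "CWRESI"):
        if col in table_a.columns and col in table_b.columns:
            pearson[col] = float(np.corrcoef(
                table_a[col].to_numpy(float), table_b[col].to_numpy(float))[0, 1])

    def _max_abs_diff(col):
        if col in table_a.columns and col in table_b.columns:
            return float(np.max(np.abs(
                table_a[col].to_numpy(float) - table_b[col].to_numpy(float))))
        return float("nan")

    rows = pd.DataFrame({
        "ID": table_a["ID"].to_numpy()[keep],
        "TIME": table_a["TIME"].to_numpy()[keep],
        "IPRED": table_a["IPRED"].to_numpy(float)[keep],
        "ratio": ratio,
    })
    extreme = rows[np.abs(rows["ratio"]) > EXTREME_RATIO_THRESHOLD]
    ipred_range = (
        (float(extreme["IPRED"].min()), float(extreme["IPRED"].max()))
        if len(extreme) else None
    )
    iw = implicit_w(table_b)
    return ComparisonSummary(
        pair=ids,
        n_obs=len(table_a),
        n_excluded=int((~keep).sum()),
        ratio_mean=float(ratio.mean()),
        ratio_sd=float(ratio.std(ddof=1)),
        ratio_min=float(ratio.min()),
        ratio_max=float(ratio.max()),
        pearson_r=pearson,
        sd_iwres_a=float(np.std(iwres_a, ddof=1)),
        sd_iwres_b=float(np.std(iwres_b, ddof=1)),
        max_abs_diff_wres=_max_abs_diff("WRES"),
        max_abs_diff_cwresi=_max_abs_diff("CWRESI"),
        implicit_w_mean=iw.mean,
        implicit_w_sd=iw.sd,
        n_extreme=len(extreme),
        extreme_ipred_range=ipred_range,
        cross_dataset=cross_dataset,
        rows=rows,
    )


def flag_extremes(comparison: ComparisonSummary,
                  threshold: float = EXTREME_RATIO_THRESHOLD) -> pd.DataFrame:
    """Rows whose |IWRES ratio| exceeds the threshold, with their IPRED."""
    rows = comparison.rows
    if rows is None:
        raise ValueError("comparison carries no per-row detail")
    return rows[np.abs(rows["ratio"]) > threshold].reset_index(drop=True)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the full nine-run comparison study."""

    n_subjects: int = 500
    seed: int = 20240101
    init_inflation: float = 1.2
    compute_se: bool = True

    def dataset_seed(self, error_kind: str) -> int:
        offset = {"additive": 0, "proportional": 1, "combined": 2}[error_kind]
        return int(self.seed) + offset


@dataclass
class StudyReport:
    """All study outputs: fits, tables, summaries and figure data."""

    config: StudyConfig
    datasets: Dict[str, Dataset]
    fits: Dict[str, FitResult]
    tables: Dict[str, pd.DataFrame]
    panel_a: pd.DataFrame
    panel_b: pd.DataFrame
    comparisons: List[ComparisonSummary]
    figure_data: Dict[str, pd.DataFrame]
    log_lines: List[str]


def _panel_a_row(run_id: str, result: FitResult) -> dict:
    """Per-run estimates on the reporting scales of the study tables.

    SIGMA-style runs report variance parameters with the derived SD/CV;
    THETA-style runs report the SD/CV directly.
    """
    p = result.params
    se = result.se or {}
    row = {
        "run": run_id,
        "ofv": result.ofv,
        "cl": p.structural.tvcl, "cl_se": se.get("tvcl", np.nan),
        "v": p.structural.tvv, "v_se": se.get("tvv", np.nan),
        "omega2_cl": p.omega2_cl, "omega2_cl_se": se.get("omega2_cl", np.nan),
        "omega2_v": p.omega2_v, "omega2_v_se": se.get("omega2_v", np.nan),
        "ruv_prop": np.nan, "ruv_prop_cv_pct": np.nan,
        "ruv_add": np.nan, "ruv_add_sd": np.nan,
        "converged": result.converged,
    }
    e = p.error_params
    if run_id.startswith("ADD"):
        if e.sigma1 is not None:
            row["ruv_add"], row["ruv_add_sd"] = e.sigma1, float(np.sqrt(e.sigma1))
        else:
            row["ruv_add"], row["ruv_add_sd"] = e.theta4, e.theta4
    elif run_id.startswith("PROP"):
        if e.sigma1 is not None:
            row["ruv_prop"] = e.sigma1
            row["ruv_prop_cv_pct"] = 100.0 * float(np.sqrt(e.sigma1))
        else:
            row["ruv_prop"] = e.theta4
            row["ruv_prop_cv_pct"] = 100.0 * e.theta4
    else:  # combined
        if e.sigma1 is not None:
            row["ruv_prop"] = e.sigma1
            row["ruv_prop_cv_pct"] = 100.0 * float(np.sqrt(e.sigma1))
            row["ruv_add"], row["ruv_add_sd"] = e.sigma2, float(np.sqrt(e.sigma2))
        else:
            row["ruv_prop"] = e.theta4
            row["ruv_prop_cv_pct"] = 100.0 * e.theta4
            row["ruv_add"], row["ruv_add_sd"] = e.theta5, e.theta5
    return row


def _panel_b_row(run_id: str, table: pd.DataFrame) -> dict:
    out = {"run": run_id}
    for col in ("IWRES", "CWRESI", "WRES"):
        values = table[col].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        out[f"{col.lower()}_mean"] = float(values.mean())
        out[f"{col.lower()}_sd"] = float(np.std(values, ddof=1))
    out["eps_shrinkage"] = epsilon_shrinkage(table["IWRES"])
    return out


def run_study(config: StudyConfig = StudyConfig()) -> StudyReport:
    """Simulate the three datasets, run the nine fits, compare the runs."""
    log_lines: List[str] = []
    datasets: Dict[str, Dataset] = {}
    fits: Dict[str, FitResult] = {}
    tables: Dict[str, pd.DataFrame] = {}

    for kind, codings in DATASET_CODINGS.items():
        protocol = default_protocol(kind, n_subjects=config.n_subjects,
                                    seed=config.dataset_seed(kind))
        dataset = simulate_dataset(protocol)
        datasets[kind] = dataset
        log_lines.append(
            f"{kind}: {dataset.n_subjects} subjects, "
            f"{dataset.n_observations} observations, "
            f"{dataset.truth['n_floored']} floored value(s)")
        for coding_id in codings:
            coding = get_coding(coding_id)
            init = default_init(coding, protocol,
                                inflation=config.init_inflation)
            try:
                result = fit(dataset, coding, init=init,
                             compute_se=config.compute_se)
            except Exception as exc:  # study continues past a failed run
                logger.exception("fit %s failed", coding_id)
                log_lines.append(f"run {coding_id}: FAILED ({exc})")
                continue
            fits[coding_id] = result
            tables[coding_id] = diagnostics_table(result, dataset, coding)
            log_lines.append(
                f"run {coding_id}: ofv={result.ofv:.4f} "
                f"converged={result.converged}")

    panel_a = pd.DataFrame([_panel_a_row(rid, fits[rid]) for rid in fits])
    panel_b = pd.DataFrame([_panel_b_row(rid, tables[rid]) for rid in tables])

    pairs = [
        ("ADD.1", "ADD.2", False), ("ADD.1", "ADD.3", False),
        ("PROP.1", "PROP.2", False), ("PROP.1", "PROP.3", False),
        ("COMB_VAR1", "COMB_VAR3", False), ("COMB_VAR1", "COMB_SD", False),
        ("COMB_VAR3", "COMB_SD", False),
        # cross-dataset overlay hazard: scatter-scale comparison only
        ("PROP.1", "ADD.2", True),
    ]
    comparisons = []
    for ref, other, cross in pairs:
        if ref in tables and other in tables:
            comparisons.append(pairwise_compare(
                tables[ref], tables[other], ids=(ref, other),
                cross_dataset=cross))

    figure_data = _figure_data(tables, comparisons)
    return StudyReport(config=config, datasets=datasets, fits=fits,
                       tables=tables, panel_a=panel_a, panel_b=panel_b,
                       comparisons=comparisons, figure_data=figure_data,
                       log_lines=log_lines)


def _figure_data(tables, comparisons) -> Dict[str, pd.DataFrame]:
    """Figure-ready long-format series (run id, IPRED, residual)."""
    figures: Dict[str, pd.DataFrame] = {}

    def series(run_ids, column):
        frames = []
        for rid in run_ids:
            if rid not in tables:
                continue
            t = tables[rid]
            frames.append(pd.DataFrame({
                "run": rid, "IPRED": t["IPRED"], column: t[column]}))
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    figures["figure1"] = series(("ADD.1", "ADD.2"), "IWRES")
    figures["figure2"] = series(("PROP.1", "PROP.2"), "IWRES")

    fig3 = series(("COMB_VAR1", "COMB_SD"), "CWRESI")
    if len(fig3):
        fig3["extreme"] = False
        sd_cmp = next((c for c in comparisons
                       if c.pair == ("COMB_VAR1", "COMB_SD")), None)
        if sd_cmp is not None:
            extreme = flag_extremes(sd_cmp)
            keys = set(zip(extreme["ID"], extreme["TIME"]))
            for rid in ("COMB_VAR1", "COMB_SD"):
                t = tables.get(rid)
                if t is None:
                    continue
                mask = [
                    (i, tt) in keys
                    for i, tt in zip(t["ID"], t["TIME"])
                ]
                fig3.loc[fig3["run"] == rid, "extreme"] = mask
    figures["figure3"] = fig3
    figures["figure4"] = series(("ADD.2", "PROP.1"), "IWRES")
    return figures


def _summary_record(c: ComparisonSummary) -> dict:
    rec = {
        "run_a": c.pair[0], "run_b": c.pair[1], "n_obs": c.n_obs,
        "n_excluded": c.n_excluded, "ratio_mean": c.ratio_mean,
        "ratio_sd": c.ratio_sd, "ratio_min": c.ratio_min,
        "ratio_max": c.ratio_max, "sd_iwres_a": c.sd_iwres_a,
        "sd_iwres_b": c.sd_iwres_b,
        "max_abs_diff_wres": c.max_abs_diff_wres,
        "max_abs_diff_cwresi": c.max_abs_diff_cwresi,
        "implicit_w_mean": c.implicit_w_mean,
        "implicit_w_sd": c.implicit_w_sd, "n_extreme": c.n_extreme,
        "cross_dataset": c.cross_dataset,
    }
    for col, r in c.pearson_r.items():
        rec[f"pearson_{col.lower()}"] = r
    if c.extreme_ipred_range is not None:
        rec["extreme_ipred_min"], rec["extreme_ipred_max"] = c.extreme_ipred_range
    return rec


def write_study(report: StudyReport, outdir) -> None:
    """Write panel tables, comparison summaries, figure data and run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.panel_a.to_csv(outdir / "panelA.csv", index=False,
                          float_format="%.6g")
    report.panel_b.to_csv(outdir / "panelB.csv", index=False,
                          float_format="%.6g")
    for c in report.comparisons:
        a = c.pair[0].replace(".", "_")
        b = c.pair[1].replace(".", "_")
        name = f"compare_{b}_vs_{a}.csv"
        pd.DataFrame([_summary_record(c)]).to_csv(outdir / name, index=False)
    for key, frame in report.figure_data.items():
        frame.to_csv(outdir / f"{key}_data.csv", index=False,
                     float_format="%.6g")
    summary = {
        "config": {
            "n_subjects": report.config.n_subjects,
            "seed": report.config.seed,
            "init_inflation": report.config.init_inflation,
        },
        "runs": {rid: {"ofv": float(report.fits[rid].ofv),
                       "converged": bool(report.fits[rid].converged)}
                 for rid in report.fits},
    }
    (outdir / "study.json").write_text(json.dumps(summary, indent=2))
    (outdir / "run.log").write_text("\n".join(report.log_lines) + "\n")
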