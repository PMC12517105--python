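"""CSV readers/writers and the measurement-to-observation mapping."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .fitting import FitResult, ObservationSet
from .mass_balance import ANALYTES, FRACTIONS, MeasurementTable
from .model import SimulationResult

logger = logging.getLogger("alidose")

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_observations",
    "write_observations",
    "measurements_to_observations",
    "write_simulation",
    "write_fit_results",
]

_MEAS_COLUMNS = ["time_h", "fraction", "analyte", "replicate", "beta_gluc",
                 "amount_nmol"]


def read_measurements(path) -> MeasurementTable:
    """Read a measurement CSV, validating rows with line numbers.

    A missing beta_gluc column defaults to False with a logged warning.
    """
    frame = pd.read_csv(path)
    if "beta_gluc" not in frame.columns:
        logger.warning("%s: no beta_gluc column; assuming untreated samples", path)
        frame["beta_gluc"] = False
    missing = set(_MEAS_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    problems = []
    # header is line 1, first data row line 2
    for i, row in frame.iterrows():
        line = i + 2
        if row["fraction"] not in FRACTIONS:
            problems.append(f"line {line}: unknown fraction {row['fraction']!r}")
        if row["analyte"] not in ANALYTES:
            problems.append(f"line {line}: unknown analyte {row['analyte']!r}")
        if not np.isfinite(row["amount_nmol"]) or row["amount_nmol"] < 0:
            problems.append(f"line {line}: invalid amount {row['amount_nmol']!r}")
        if row["time_h"] < 0:
            problems.append(f"line {line}: negative time {row['time_h']!r}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems[:10]))
    frame["beta_gluc"] = frame["beta_gluc"].astype(bool)
    return MeasurementTable(frame=frame[_MEAS_COLUMNS])


def write_measurements(table: MeasurementTable, path) -> None:
    table.frame[_MEAS_COLUMNS].to_csv(path, index=False)


def read_observations(path) -> ObservationSet:
    return ObservationSet(pd.read_csv(path))


def write_observations(obs: ObservationSet, path) -> None:
    obs.frame.to_csv(path, index=False)


def measurements_to_observations(
    table: MeasurementTable,
    beta_gluc: bool = False,
) -> ObservationSet:
    """Collapse a UPLC table into the calibration's observation streams.

    Uses one enzyme arm (default the untreated one).  Parent and M1 map
    fraction-wise; total_tetrol sums tetrol over fractions; and
    total_metabolites sums every Phase 1 metabolite over fractions (the
    minimum-metabolism aggregate).
    """
    df = table.frame[table.frame["beta_gluc"] == beta_gluc]
    if len(df) == 0:
        raise ValueError("requested enzyme arm has no rows")
    rows = []

    def add(stream, sub, by_fraction=None):
        if by_fraction is not None:
            sub = sub[sub["fraction"] == by_fraction]
        agg = sub.groupby(["time_h", "replicate"])["amount_nmol"].sum()
        for (t, rep), amount in agg.items():
            rows.append({"time_h": t, "stream": stream, "replicate": rep,
                         "amount_nmol": amount})

    parent = df[df["analyte"] == "BAP"]
    m1 = df[df["analyte"] == "BAP-7,8-dihydrodiol"]
    for fraction in FRACTIONS:
        add(f"parent_{fraction}", parent, fraction)
        add(f"m1_{fraction}", m1, fraction)
    add("total_tetrol", df[df["analyte"] == "BAP-tetrol"])
    add("total_metabolites", df[df["analyte"] != "BAP"])
    return ObservationSet(pd.DataFrame(rows))


def write_simulation(sim: SimulationResult, path) -> None:
    sim.frame.to_csv(path, index=False)


def write_fit_results(results: list[FitResult], path) -> None:
    rows = []
    for fr in results:
        for name, value in fr.estimates.items():
            rows.append({
                "stage": fr.stage, "parameter": name, "estimate": value,
                "log_likelihood": fr.log_likelihood, "aic": fr.aic,
                "k": fr.k, "converged": fr.converged, "n_iter": fr.n_iter,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
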