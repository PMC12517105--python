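"""Percent-recovery mass balance and conjugate estimation for UPLC tables.

Implements the recovery bookkeeping used on fraction-resolved analyte
measurements: percent of the applied parent recovered (parent alone, or
parent plus the six Phase 1 metabolites) relative to the amount measured
in the 0-hour samples, internal-standard recovery correction, and the
beta-glucuronidase difference estimate of Phase 2 conjugates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FRACTIONS",
    "ANALYTES",
    "PHASE1_METABOLITES",
    "MeasurementTable",
    "correct_recovery",
    "percent_parent_recovery",
    "percent_total_recovery",
    "glucuronide_difference",
]

FRACTIONS = ("mucus", "cells", "media")
PARENT = "BAP"
PHASE1_METABOLITES = (
    "BAP-3-phenol",
    "BAP-9-phenol",
    "BAP-4,5-dihydrodiol",
    "BAP-7,8-dihydrodiol",
    "BAP-9,10-dihydrodiol",
    "BAP-tetrol",
)
ANALYTES = (PARENT,) + PHASE1_METABOLITES


@dataclass
class MeasurementTable:
    """Fraction-resolved analyte amounts with replicate structure.

    frame columns: time_h, fraction, analyte, replicate, beta_gluc,
    amount_nmol.  metadata may record the nominal dose, surface area,
    internal-standard recovery, and the generator seed.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"time_h", "fraction", "analyte", "replicate",
                    "beta_gluc", "amount_nmol"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"measurement table missing columns {sorted(missing)}")
        if (self.frame["amount_nmol"] < 0).any():
            raise ValueError("amounts must be >= 0")
        bad = set(self.frame["fraction"].unique()) - set(FRACTIONS)
        if bad:
            raise ValueError(f"unknown fractions {sorted(bad)}")
        bad = set(self.frame["analyte"].unique()) - set(ANALYTES)
        if bad:
            raise ValueError(f"unknown analytes {sorted(bad)}")
        dup = self.frame.duplicated(
            subset=["time_h", "fraction", "analyte", "replicate", "beta_gluc"]
        )
        if dup.any():
            raise ValueError("replicate ids must be unique within "
                             "(time, fraction, analyte, beta_gluc)")
        self.frame = self.frame.reset_index(drop=True)

    def at_time(self, t: float) -> pd.DataFrame:
        return self.frame[self.frame["time_h"] == t]


def correct_recovery(amount: float, spike_recovery: float) -> float:
    """Divide out the internal-standard (spike) extraction recovery."""
    if spike_recovery <= 0:
        raise ValueError("spike recovery must be > 0")
    if spike_recovery > 1.5:
        raise ValueError("spike recovery above sanity bound 1.5")
    return amount / spike_recovery


def _reference_parent(table: MeasurementTable) -> float:
    """Applied amount: replicate-mean of summed parent in 0-h samples."""
    rows = table.at_time(0.0)
    rows = rows[rows["analyte"] == PARENT]
    if len(rows) == 0:
        raise ValueError("table has no 0-h parent rows to define the "
                         "applied amount")
    per_rep = rows.groupby(["replicate", "beta_gluc"])["amount_nmol"].sum()
    return float(per_rep.mean())


def _fraction_sum(rows: pd.DataFrame, analytes) -> float:
    """Replicate-mean of the per-sample analyte sum over all fractions."""
    rows = rows[rows["analyte"].isin(analytes)]
    if len(rows) == 0:
        return 0.0
    per_rep = rows.groupby(["replicate", "beta_gluc"])["amount_nmol"].sum()
    return float(per_rep.mean())


def percent_parent_recovery(table: MeasurementTable, t: float) -> float:
    """Parent recovered at t over the 0-h reference, as a percent."""
    ref = _reference_parent(table)
    return 100.0 * _fraction_sum(table.at_time(t), [PARENT]) / ref


def percent_total_recovery(
    table: MeasurementTable,
    t: float,
    metabolites=PHASE1_METABOLITES,
) -> float:
    """Parent plus Phase 1 metabolites recovered at t, as a percent."""
    unknown = set(metabolites) - set(PHASE1_METABOLITES)
    if unknown:
        raise KeyError(f"unknown metabolite names {sorted(unknown)}")
    ref = _reference_parent(table)
    total = _fraction_sum(table.at_time(t), [PARENT, *metabolites])
    return 100.0 * total / ref


def glucuronide_difference(table: MeasurementTable, t: float) -> pd.DataFrame:
    """Conjugate estimate per (analyte, fraction) from enzyme differencing.

    estimate = mean(with beta-glucuronidase) - mean(without); negative
    estimates (informative noise) are kept and flagged.  The difference
    may also include sulfate conjugates co-deconjugated by the enzyme
    preparation.
    """
    rows = table.at_time(t)
    has_arm = set(rows["beta_gluc"].unique())
    if has_arm != {True, False}:
        missing = "with" if True not in has_arm else "without"
        raise ValueError(
            f"no {missing}-enzyme replicates at t = {t} h; both arms required"
        )
    means = (rows.groupby(["analyte", "fraction", "beta_gluc"])["amount_nmol"]
                 .mean().unstack("beta_gluc"))
    means = means.dropna()  # pairs present in both arms
    out = means.reset_index()
    out["conjugate_nmol"] = out[True] - out[False]
    out["negative_flag"] = out["conjugate_nmol"] < 0
    return out[["analyte", "fraction", "conjugate_nmol", "negative_flag"]]
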