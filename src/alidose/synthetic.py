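"""Synthetic UPLC measurement tables and CYP1A1 activity curves.

Emulates the statistical structure of the two exposure experiments the
model is calibrated and validated against: an optimization design
(2.26 µg/cm² nominal, 8.6 nmol measured at 0 h; samples at 0, 1, 2, 4, 8,
24, 48 h; n = 4) and a validation design (4.67 µg/cm², 16.8 nmol; 0, 8,
24, 48 h; n = 8 of which 4 are treated with beta-glucuronidase).
Observations carry multiplicative lognormal noise and a limit of
detection below which values censor to zero.

The simulator's state maps onto the measured fractions as follows: the
dose compartment is what the mucus wash recovers for the parent, cells
and media are direct; the M1 metabolite maps its three compartments; the
cumulative M1-metabolized pool stands in for total tetrol; and the
cumulative non-M1 metabolite pool is distributed across the named Phase 1
metabolites by a fixed composition vector and across fractions in
proportion to M1's own fraction split.  A per-metabolite glucuronide
fraction hides conjugated material from the without-enzyme arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mass_balance import PHASE1_METABOLITES, MeasurementTable
from .model import simulate
from .params import InductionCoefficients, ParameterSet

__all__ = [
    "ExperimentDesign",
    "optimization_design",
    "validation_design",
    "generate_uplc_dataset",
    "generate_activity_dataset",
]

M1_NAME = "BAP-7,8-dihydrodiol"
TETROL_NAME = "BAP-tetrol"

# fixture convention for how the non-M1 metabolite pool splits across the
# other named Phase 1 metabolites (ranks follow the observed profiles:
# 3-phenol dominant, 9-phenol minor)
DEFAULT_COMPOSITION = {
    "BAP-3-phenol": 0.35,
    "BAP-9-phenol": 0.05,
    "BAP-4,5-dihydrodiol": 0.25,
    "BAP-9,10-dihydrodiol": 0.35,
}


@dataclass
class ExperimentDesign:
    """Sampling design plus the observation noise model."""

    dose_nmol: float
    timepoints: tuple = (0.0, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0)
    n_replicates: int = 4
    beta_gluc_arm: bool = False
    n_beta_gluc: int = 0
    cv: float = 0.15
    lod_nmol: float = 0.005
    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    glucuronide_fractions: dict = field(default_factory=dict)
    dose_ug_per_cm2: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dose_nmol <= 0:
            raise ValueError("dose must be > 0")
        if self.cv < 0:
            raise ValueError("CV must be >= 0")
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValueError("metabolite composition fractions must sum to 1")
        unknown = set(self.composition) - set(PHASE1_METABOLITES)
        unknown |= set(self.glucuronide_fractions) - set(PHASE1_METABOLITES)
        if unknown:
            raise ValueError(f"unknown metabolite names {sorted(unknown)}")
        for g in self.glucuronide_fractions.values():
            if not 0.0 <= g <= 1.0:
                raise ValueError("glucuronide fractions must lie in [0, 1]")
        if self.beta_gluc_arm and not 0 < self.n_beta_gluc <= self.n_replicates:
            raise ValueError("beta-glucuronidase arm size must be in "
                             "(0, n_replicates]")


def optimization_design(**overrides) -> ExperimentDesign:
    """The dense early-timepoint design used for parameter calibration."""
    kwargs = dict(
        dose_nmol=8.6, dose_ug_per_cm2=2.26,
        timepoints=(0.0, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0), n_replicates=4,
    )
    kwargs.update(overrides)
    return ExperimentDesign(**kwargs)


def validation_design(**overrides) -> ExperimentDesign:
    """The higher-dose design with a beta-glucuronidase arm."""
    kwargs = dict(
        dose_nmol=16.8, dose_ug_per_cm2=4.67,
        timepoints=(0.0, 8.0, 24.0, 48.0), n_replicates=8,
        beta_gluc_arm=True, n_beta_gluc=4,
    )
    kwargs.update(overrides)
    return ExperimentDesign(**kwargs)


def _true_amounts(params: ParameterSet, design: ExperimentDesign) -> pd.DataFrame:
    """Noise-free (analyte, fraction) amounts at every design timepoint."""
    t = np.asarray(sorted(set(design.timepoints)), dtype=float)
    grid = t if t[0] == 0 else np.concatenate([[0.0], t])
    sim = simulate(params, design.dose_nmol, grid)
    idx = np.isin(grid, t)

    rows = []

    def add(analyte, fraction, series):
        for ti, a in zip(grid[idx], np.asarray(series)[idx]):
            rows.append({"time_h": ti, "fraction": fraction,
                         "analyte": analyte, "amount_nmol": max(float(a), 0.0)})

    add("BAP", "mucus", sim.state("AD"))
    add("BAP", "cells", sim.state("AC"))
    add("BAP", "media", sim.state("AM"))
    m1 = {"cells": sim.state("MC"), "media": sim.state("MM"),
          "mucus": sim.state("MU")}
    for fraction, series in m1.items():
        add(M1_NAME, fraction, series)

    # split pooled metabolites across fractions like M1 distributes itself;
    # before any M1 exists, default to the cell fraction (site of formation)
    m1_total = sim.state("MC") + sim.state("MM") + sim.state("MU")
    split = {}
    for fraction, series in m1.items():
        frac = np.where(m1_total > 0, series / np.where(m1_total > 0, m1_total, 1.0),
                        1.0 if fraction == "cells" else 0.0)
        split[fraction] = frac
    for fraction in m1:
        add(TETROL_NAME, fraction, sim.state("X_m1") * split[fraction])
    for name, comp in design.composition.items():
        for fraction in m1:
            add(name, fraction, sim.state("X_other") * comp * split[fraction])
    return pd.DataFrame(rows)


def generate_uplc_dataset(
    params: ParameterSet,
    design: ExperimentDesign,
    seed: int | None = None,
) -> MeasurementTable:
    """Simulate the model and dress it up as a replicate UPLC table.

    Fully reproducible from the seed (``design.seed`` unless overridden).
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    truth = _true_amounts(params, design)

    sigma = float(np.sqrt(np.log1p(design.cv**2)))
    arms = []
    for rep in range(design.n_replicates):
        treated = design.beta_gluc_arm and rep < design.n_beta_gluc
        arms.append((rep, treated))

    out = []
    for _, row in truth.iterrows():
        g = design.glucuronide_fractions.get(row["analyte"], 0.0)
        for rep, treated in arms:
            amount = row["amount_nmol"]
            if not treated:
                amount *= (1.0 - g)
            if design.cv > 0:
                # mean-one multiplicative lognormal noise
                amount *= float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
            if amount < design.lod_nmol:
                amount = 0.0
            out.append({
                "time_h": row["time_h"], "fraction": row["fraction"],
                "analyte": row["analyte"], "replicate": rep,
                "beta_gluc": treated, "amount_nmol": amount,
            })
    frame = pd.DataFrame(out)
    metadata = {
        "seed": seed, "dose_nmol": design.dose_nmol,
        "dose_ug_per_cm2": design.dose_ug_per_cm2, "cv": design.cv,
        "lod_nmol": design.lod_nmol,
    }
    return MeasurementTable(frame=frame, metadata=metadata)


def generate_activity_dataset(
    coeffs: InductionCoefficients,
    timepoints=(0.0, 2.0, 4.0, 6.0, 8.0, 24.0, 48.0),
    replicates: int = 3,
    cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sampled CYP1A1 activity, peak-normalized, with optional noise.

    Returns columns time_h, replicate, activity; the noise-free maximum of
    the sampled curve is exactly 1.
    """
    t = np.asarray(timepoints, dtype=float)
    num = coeffs.A * t**2 + coeffs.B * t + coeffs.C
    den = coeffs.D * t**2 - coeffs.E * t + coeffs.F
    curve = num / den
    curve = curve / curve.max()
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2))) if cv > 0 else 0.0
    rows = []
    for rep in range(replicates):
        for ti, yi in zip(t, curve):
            y = yi
            if cv > 0:
                y *= float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
            rows.append({"time_h": ti, "replicate": rep, "activity": y})
    return pd.DataFrame(rows)
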