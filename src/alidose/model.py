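"""Compartmental ODE dosimetry model for a PAH parent and one metabolite.

The model tracks amounts (nmol) of the parent compound in the apical dose
compartment (operationally the mucus fraction), the cells and the basal
media, and of the M1 metabolite in cells, media and the growing mucus
layer.  Cumulative pools for metabolized and volatilized material are
carried as state so the system is exactly mass-conserving: the ten state
derivatives sum to zero by construction.

Processes: first-order absorption of parent from the dose compartment;
passive diffusion across the cell membrane driven by free
(partition-corrected) concentrations; first-order metabolic clearance
scaled allometrically by cell mass to the 3/4 power, with parent
metabolism optionally multiplied by a time-varying CYP1A1 induction
curve; optional carrier-mediated efflux of the metabolite from cells to
media and mucus; first-order volatilization from media (parent and M1)
and mucus (M1).  The mucus volume grows linearly with the secretion rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import InductionCoefficients, ParameterSet

__all__ = [
    "STATE_NAMES",
    "STREAM_STATE",
    "cyp_scale",
    "EffectiveRates",
    "derive_effective_rates",
    "rhs",
    "simulate",
    "SimulationResult",
]

STATE_NAMES = (
    "AD",       # parent, dose/apical compartment
    "AC",       # parent, cells
    "AM",       # parent, media
    "MC",       # M1, cells
    "MM",       # M1, media
    "MU",       # M1, mucus
    "X_other",  # cumulative parent metabolized to non-M1 products
    "X_m1",     # cumulative M1 metabolized (tetrol proxy)
    "VP",       # cumulative parent volatilized
    "V1",       # cumulative M1 volatilized
)

# Observation-stream labels -> state columns.  total_metabolites is the
# "minimum metabolism threshold" aggregate: everything the parent has been
# metabolized into, whether still present or further transformed.
STREAM_STATE = {
    "parent_mucus": ("AD",),
    "parent_cells": ("AC",),
    "parent_media": ("AM",),
    "m1_cells": ("MC",),
    "m1_media": ("MM",),
    "m1_mucus": ("MU",),
    "total_tetrol": ("X_m1",),
    "total_metabolites": ("X_other", "MC", "MM", "MU", "X_m1"),
}

_MUCUS_GUARD = 1e-6  # mL; floor for the mucus volume in concentration terms


def cyp_scale(t, coeffs: InductionCoefficients, induction_on: bool = True):
    """Relative CYP1A1 activity (A t^2 + B t + C)/(D t^2 - E t + F).

    Returns exactly 1 when the induction switch is off.  Accepts scalar or
    array ``t`` (hours).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if not induction_on:
        return np.ones_like(t) if t.ndim else 1.0
    num = coeffs.A * t**2 + coeffs.B * t + coeffs.C
    den = coeffs.D * t**2 - coeffs.E * t + coeffs.F
    out = num / den
    if not np.all(np.isfinite(out)) or np.any(out < 0):
        raise ValueError("induction curve non-finite or negative on the "
                         "requested times; coefficients invalid")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EffectiveRates:
    """Model rates reduced to the internal unit system (hr, nmol, mL).

    All L<->mL, g<->kg and µm<->cm conversions happen when this object is
    built; the RHS works purely in nmol, mL and hours.
    """

    media_volume: float          # mL
    cell_volume: float           # mL
    cell_mass_kg: float          # kg
    allometric_scale: float      # kg^(3/4)
    mucus_volume_initial: float  # mL
    mucus_growth: float          # mL/hr  (Q x SA)
    perm_parent_sa: float        # mL/hr  (permeability x SA)
    perm_m1_sa: float            # mL/hr
    cl_parent_eff: float         # mL/hr  (CL x W^(3/4), L->mL)
    cl_m1_eff: float             # mL/hr
    efflux_media_eff: float      # mL/hr
    efflux_mucus_eff: float      # mL/hr
    p_parent_cm: float
    p_m1_cm: float
    p_m1_cmuc: float
    k_abs: float
    k_vol_parent_media: float
    k_vol_m1_media: float
    k_vol_m1_mucus: float
    fraction_m1: float
    induction_on: bool
    efflux_on: bool

    def mucus_volume(self, t):
        """Apical mucus volume (mL) at time t (hours)."""
        return self.mucus_volume_initial + self.mucus_growth * np.asarray(t, float)


def derive_effective_rates(params: ParameterSet) -> EffectiveRates:
    """Collapse a ParameterSet to the effective quantities the RHS uses."""
    phys = params.physiology
    v_cell = phys.cell_volume  # mL
    if v_cell <= 0 or phys.media_volume <= 0:
        raise ValueError("compartment volumes must be positive")
    # cell mass in kg assuming density in g/mL; 3/4-power allometric scale
    w_kg = v_cell * phys.cell_density / 1000.0
    w34 = w_kg ** 0.75
    return EffectiveRates(
        media_volume=phys.media_volume,
        cell_volume=v_cell,
        cell_mass_kg=w_kg,
        allometric_scale=w34,
        mucus_volume_initial=phys.mucus_volume_initial,
        mucus_growth=phys.mucus_secretion_rate * phys.surface_area,
        perm_parent_sa=params.parent.permeability * phys.surface_area,
        perm_m1_sa=params.m1.permeability * phys.surface_area,
        cl_parent_eff=params.parent.clearance * w34 * 1000.0,
        cl_m1_eff=params.m1.clearance * w34 * 1000.0,
        efflux_media_eff=params.m1.efflux_media * 1000.0,
        efflux_mucus_eff=params.m1.efflux_mucus * 1000.0,
        p_parent_cm=params.partition.parent_cell_media,
        p_m1_cm=params.partition.m1_cell_media,
        p_m1_cmuc=params.partition.m1_cell_mucus,
        k_abs=params.parent.k_abs,
        k_vol_parent_media=params.parent.k_vol_media,
        k_vol_m1_media=params.m1.k_vol_media,
        k_vol_m1_mucus=params.m1.k_vol_mucus,
        fraction_m1=params.m1.fraction_m1,
        induction_on=params.switches.induction_on,
        efflux_on=params.switches.efflux_on,
    )


def _rhs(t: float, y, r: EffectiveRates, coeffs: InductionCoefficients):
    AD, AC, AM, MC, MM, MU = y[0], y[1], y[2], y[3], y[4], y[5]
    v_mu = r.mucus_volume_initial + r.mucus_growth * t
    if v_mu < _MUCUS_GUARD:
        v_mu = _MUCUS_GUARD

    # free (partition-corrected) cellular concentrations, nmol/mL
    c_pf = AC / (r.cell_volume * r.p_parent_cm)
    c_1f_med = MC / (r.cell_volume * r.p_m1_cm)
    c_1f_muc = MC / (r.cell_volume * r.p_m1_cmuc)

    if r.induction_on:
        num = coeffs.A * t * t + coeffs.B * t + coeffs.C
        den = coeffs.D * t * t - coeffs.E * t + coeffs.F
        phi = num / den
    else:
        phi = 1.0

    j_p = r.perm_parent_sa * (c_pf - AM / r.media_volume)
    rmet_p = phi * r.cl_parent_eff * c_pf
    j_1m = r.perm_m1_sa * (c_1f_med - MM / r.media_volume)
    j_1u = r.perm_m1_sa * (c_1f_muc - MU / v_mu)
    if r.efflux_on:
        e_med = r.efflux_media_eff * c_1f_med
        e_muc = r.efflux_mucus_eff * c_1f_muc
    else:
        e_med = e_muc = 0.0
    rmet_1 = r.cl_m1_eff * c_1f_med

    abs_p = r.k_abs * AD
    vol_p = r.k_vol_parent_media * AM
    vol_1m = r.k_vol_m1_media * MM
    vol_1u = r.k_vol_m1_mucus * MU
    f = r.fraction_m1

    return (
        -abs_p,                                            # AD
        abs_p - j_p - rmet_p,                              # AC
        j_p - vol_p,                                       # AM
        f * rmet_p - j_1m - j_1u - e_med - e_muc - rmet_1,  # MC
        j_1m + e_med - vol_1m,                             # MM
        j_1u + e_muc - vol_1u,                             # MU
        (1.0 - f) * rmet_p,                                # X_other
        rmet_1,                                            # X_m1
        vol_p,                                             # VP
        vol_1m + vol_1u,                                   # V1
    )


def rhs(state, t: float, params: ParameterSet):
    """Time derivative of the state vector (nmol/hr).

    Convenience wrapper deriving effective rates on each call; the solver
    path precomputes them once.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("state must be finite")
    if t < 0:
        raise ValueError("t must be >= 0")
    r = derive_effective_rates(params)
    return np.array(_rhs(t, state, r, params.induction))


@dataclass(frozen=True)
class SimulationResult:
    """Trajectory of the dosimetry model on an output time grid."""

    time_grid: np.ndarray       # hours
    states: np.ndarray          # (n_times, 10) nmol
    mucus_volume: np.ndarray    # mL
    dose: float                 # nmol
    params: ParameterSet

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.time_grid)
        df["mucus_volume_mL"] = self.mucus_volume
        return df

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def stream(self, name: str) -> np.ndarray:
        """Amount time series for an observation stream (nmol)."""
        cols = STREAM_STATE[name]
        return sum(self.state(c) for c in cols)

    def concentration(self, name: str) -> np.ndarray:
        """Concentration (nmol/mL) for a single-compartment stream."""
        volumes = {
            "parent_cells": None, "m1_cells": None,
            "parent_media": None, "m1_media": None,
            "m1_mucus": None,
        }
        if name not in volumes:
            raise KeyError(f"no concentration defined for stream {name!r}")
        r = derive_effective_rates(self.params)
        if name.endswith("cells"):
            vol = np.full_like(self.time_grid, r.cell_volume)
        elif name.endswith("media"):
            vol = np.full_like(self.time_grid, r.media_volume)
        else:
            vol = np.maximum(self.mucus_volume, _MUCUS_GUARD)
        return self.stream(name) / vol

    @property
    def total(self) -> np.ndarray:
        return self.states.sum(axis=1)

    def conservation_error(self) -> float:
        """Maximum relative deviation of total amount from the dose."""
        return float(np.max(np.abs(self.total - self.dose)) / self.dose)


def simulate(
    params: ParameterSet,
    dose: float,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the model from an all-in-the-dose-compartment start.

    dose is the measured 0-h amount in nmol; t_grid (hours) must start at
    0 and be strictly increasing.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if dose <= 0:
        raise ValueError("dose must be > 0")
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")
    r = derive_effective_rates(params)
    coeffs = params.induction
    y0 = np.zeros(len(STATE_NAMES))
    y0[0] = dose
    if len(t_grid) == 1:
        states = y0[None, :]
    else:
        sol = solve_ivp(
            _rhs, (0.0, float(t_grid[-1])), y0, t_eval=t_grid,
            args=(r, coeffs), method=method, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed at t = {sol.t[-1] if len(sol.t) else 0.0:g} h: "
                f"{sol.message}"
            )
        states = sol.y.T
    return SimulationResult(
        time_grid=t_grid,
        states=states,
        mucus_volume=np.asarray(r.mucus_volume(t_grid), dtype=float),
        dose=float(dose),
        params=params,
    )
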