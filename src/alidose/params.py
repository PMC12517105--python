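"""Parameter sets for the ALI-HBEC cellular dosimetry model.

Holds the physiological constants of the air-liquid-interface transwell
culture, equilibrium partition coefficients, kinetic parameters for the
parent PAH (benzo[a]pyrene) and its tracked metabolite M1
(BAP-7,8-dihydrodiol), the CYP1A1 induction-curve coefficients, and the
two model switches (metabolism induction, active efflux).

Parameter values ship as named presets: the parent kinetics come in
``no_induction`` / ``with_induction`` variants and the metabolite kinetics
in ``passive`` / ``efflux`` variants, matching the model configurations the
calibration compares.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "PhysiologyParams",
    "PartitionCoefficients",
    "ParentParams",
    "MetaboliteParams",
    "InductionCoefficients",
    "ModelSwitches",
    "ParameterSet",
    "default_parameter_set",
    "load_parameter_set",
    "dump_parameter_set",
    "PARENT_PRESETS",
    "M1_PRESETS",
]


@dataclass(frozen=True)
class PhysiologyParams:
    """Geometry and secretion constants of the transwell culture.

    Units: volumes mL, areas cm^2, heights µm, secretion mL/cm^2/hr,
    density g/mL.  ``cell_volume`` is derived as surface_area x height
    with the µm->cm conversion.
    """

    media_volume: float = 1.0
    surface_area: float = 1.12
    cell_height: float = 35.0
    mucus_secretion_rate: float = 0.004
    mucus_volume_initial: float = 0.0045
    cell_density: float = 1.0

    def __post_init__(self) -> None:
        for name in ("media_volume", "surface_area", "cell_height",
                     "mucus_secretion_rate", "cell_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.mucus_volume_initial < 0:
            raise ValueError("mucus_volume_initial must be >= 0")

    @property
    def cell_volume(self) -> float:
        """Cell-compartment volume in mL (= cm^3)."""
        return self.surface_area * self.cell_height * 1e-4


@dataclass(frozen=True)
class PartitionCoefficients:
    """Equilibrium cell:media and cell:mucus concentration ratios."""

    parent_cell_media: float = 110.0
    m1_cell_media: float = 73.0
    m1_cell_mucus: float = 10.4

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")


@dataclass(frozen=True)
class ParentParams:
    """Kinetic parameters of the parent PAH.

    k_abs: first-order absorption from the dose compartment, hr^-1.
    k_vol_media: volatilization from media, hr^-1.
    permeability: cell-membrane permeability, cm/hr.
    clearance: allometric metabolic clearance, L/hr/kg^(3/4).
    """

    k_abs: float
    k_vol_media: float
    permeability: float
    clearance: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclass(frozen=True)
class MetaboliteParams:
    """Kinetic parameters of the M1 metabolite (BAP-7,8-dihydrodiol).

    fraction_m1 is the fraction of total parent metabolism routed to M1;
    efflux terms are volumetric clearances (L/hr) for carrier-mediated
    export from cells to media and mucus.
    """

    fraction_m1: float
    k_vol_media: float
    k_vol_mucus: float
    permeability: float
    clearance: float
    efflux_media: float = 0.0
    efflux_mucus: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.fraction_m1 > 1:
            raise ValueError("fraction_m1 must lie in [0, 1]")


@dataclass(frozen=True)
class InductionCoefficients:
    """Coefficients of the rational CYP1A1 activity curve.

    activity(t) = (A t^2 + B t + C) / (D t^2 - E t + F), t in hours,
    scaled so the peak of the fitted data is 1.  The denominator must stay
    strictly positive on the 0-48 h exposure window.
    """

    A: float = 6.55
    B: float = 1.17
    C: float = 13.00
    D: float = 23.29
    E: float = 373.05
    F: float = 2032.59

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError("F must be > 0 (activity defined at t = 0)")
        t = np.linspace(0.0, 48.0, 4801)
        den = self.D * t**2 - self.E * t + self.F
        if np.any(den <= 0):
            raise ValueError(
                "induction denominator D t^2 - E t + F has a root in [0, 48] h"
            )


@dataclass(frozen=True)
class ModelSwitches:
    """Structural switches: time-varying metabolism and active efflux."""

    induction_on: bool = True
    efflux_on: bool = True


_FLAT_PARENT = ("k_abs", "k_vol_media", "permeability", "clearance")
_FLAT_M1 = {
    "fraction_m1": "fraction_m1",
    "m1_k_vol_media": "k_vol_media",
    "m1_k_vol_mucus": "k_vol_mucus",
    "m1_permeability": "permeability",
    "m1_clearance": "clearance",
    "efflux_media": "efflux_media",
    "efflux_mucus": "efflux_mucus",
}


@dataclass(frozen=True)
class ParameterSet:
    """Complete model parameterization.

    Construct through :func:`default_parameter_set` (or ``create``) so the
    efflux-mode contract is applied: with ``efflux_on`` the metabolite
    permeability is tied to the parent permeability.
    """

    physiology: PhysiologyParams = field(default_factory=PhysiologyParams)
    partition: PartitionCoefficients = field(default_factory=PartitionCoefficients)
    parent: ParentParams = field(default_factory=lambda: PARENT_PRESETS["with_induction"])
    m1: MetaboliteParams = field(default_factory=lambda: M1_PRESETS["efflux"])
    induction: InductionCoefficients = field(default_factory=InductionCoefficients)
    switches: ModelSwitches = field(default_factory=ModelSwitches)

    @classmethod
    def create(cls, **kwargs) -> "ParameterSet":
        """Build a set, enforcing the efflux-mode permeability tie."""
        ps = cls(**kwargs)
        if ps.switches.efflux_on and ps.m1.permeability != ps.parent.permeability:
            ps = replace(ps, m1=replace(ps.m1, permeability=ps.parent.permeability))
        return ps

    # -- flat kinetic-parameter access (used by sensitivity and fitting) --

    def flat_names(self) -> tuple[str, ...]:
        return tuple(_FLAT_PARENT) + tuple(_FLAT_M1)

    def get(self, name: str) -> float:
        if name in _FLAT_PARENT:
            return getattr(self.parent, name)
        if name in _FLAT_M1:
            return getattr(self.m1, _FLAT_M1[name])
        raise KeyError(f"unknown parameter {name!r}")

    def with_updates(self, updates: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with flat kinetic parameters replaced.

        In efflux mode an update to the parent ``permeability`` propagates
        to the metabolite permeability (the tied contract) unless
        ``m1_permeability`` is itself being set explicitly.
        """
        parent_upd = {k: v for k, v in updates.items() if k in _FLAT_PARENT}
        m1_upd = {_FLAT_M1[k]: v for k, v in updates.items() if k in _FLAT_M1}
        unknown = set(updates) - set(_FLAT_PARENT) - set(_FLAT_M1)
        if unknown:
            raise KeyError(f"unknown parameters {sorted(unknown)}")
        if (self.switches.efflux_on and "permeability" in parent_upd
                and "permeability" not in m1_upd):
            m1_upd["permeability"] = parent_upd["permeability"]
        new = self
        if parent_upd:
            new = replace(new, parent=replace(new.parent, **parent_upd))
        if m1_upd:
            new = replace(new, m1=replace(new.m1, **m1_upd))
        return new

    def items(self) -> Iterator[tuple[str, float]]:
        for name in self.flat_names():
            yield name, self.get(name)


# Shipped kinetic presets: calibrated parent values without / with the
# CYP1A1 induction scaling, and metabolite values under passive diffusion
# versus active efflux out of the cell compartment.
PARENT_PRESETS: dict[str, ParentParams] = {
    "no_induction": ParentParams(
        k_abs=0.47, k_vol_media=4.36e-3, permeability=6.93e-5, clearance=4.08
    ),
    "with_induction": ParentParams(
        k_abs=0.24, k_vol_media=1.85e-3, permeability=8.02e-5, clearance=7.95
    ),
}

M1_PRESETS: dict[str, MetaboliteParams] = {
    "passive": MetaboliteParams(
        fraction_m1=0.022, k_vol_media=1.85e-3, k_vol_mucus=1.85e-3,
        permeability=0.061, clearance=3.93,
    ),
    "efflux": MetaboliteParams(
        fraction_m1=0.099, k_vol_media=1.85e-3, k_vol_mucus=1.85e-3,
        permeability=8.02e-5, clearance=0.79,
        efflux_media=8.69e-4, efflux_mucus=4.45e-4,
    ),
}


def default_parameter_set(
    parent_preset: str = "with_induction",
    m1_preset: str = "efflux",
    induction_on: bool | None = None,
    efflux_on: bool | None = None,
) -> ParameterSet:
    """Assemble a ParameterSet from the shipped presets.

    Switches default to match the presets (induction on iff the
    with-induction parent column, efflux on iff the efflux metabolite
    column); pass them explicitly to override.
    """
    if parent_preset not in PARENT_PRESETS:
        raise KeyError(f"unknown parent preset {parent_preset!r}")
    if m1_preset not in M1_PRESETS:
        raise KeyError(f"unknown m1 preset {m1_preset!r}")
    if induction_on is None:
        induction_on = parent_preset == "with_induction"
    if efflux_on is None:
        efflux_on = m1_preset == "efflux"
    return ParameterSet.create(
        parent=PARENT_PRESETS[parent_preset],
        m1=M1_PRESETS[m1_preset],
        switches=ModelSwitches(induction_on=induction_on, efflux_on=efflux_on),
    )


# ---------------------------------------------------------------------------
# Config-file round trip (flat YAML with named sections)

def dump_parameter_set(params: ParameterSet, path=None) -> str:
    doc = {
        "physiology": dataclasses.asdict(params.physiology),
        "partition": dataclasses.asdict(params.partition),
        "parent": dataclasses.asdict(params.parent),
        "m1": dataclasses.asdict(params.m1),
        "induction": dataclasses.asdict(params.induction),
        "switches": dataclasses.asdict(params.switches),
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_parameter_set(source) -> ParameterSet:
    """Load from a YAML path/stream or an already-parsed mapping.

    Sections may name a preset (``parent: with_induction``) or give explicit
    values; omitted sections fall back to defaults.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
    doc = doc or {}

    def section(cls, key, presets=None):
        val = doc.get(key)
        if val is None:
            return None
        if isinstance(val, str):
            if presets is None or val not in presets:
                raise KeyError(f"unknown preset {val!r} for section {key!r}")
            return presets[val]
        return cls(**val)

    kwargs = {}
    for key, cls, presets in (
        ("physiology", PhysiologyParams, None),
        ("partition", PartitionCoefficients, None),
        ("parent", ParentParams, PARENT_PRESETS),
        ("m1", MetaboliteParams, M1_PRESETS),
        ("induction", InductionCoefficients, None),
        ("switches", ModelSwitches, None),
    ):
        got = section(cls, key, presets)
        if got is not None:
            kwargs[key] = got
    return ParameterSet.create(**kwargs)
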