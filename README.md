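# alidose

Cellular dosimetry of benzo[a]pyrene (BAP) and its 7,8-dihydrodiol
metabolite in air–liquid-interface human bronchial epithelial cell
(ALI-HBEC) cultures.

When airway epithelium grown at an air–liquid interface is dosed apically
with a PAH, the compound partitions among the mucus wash, the cells and
the basal media while being metabolized by induced CYP1A1. This package
implements a compartmental toxicokinetic model of that system for
toxicologists and in-vitro-to-in-vivo extrapolation modelers: it predicts
the time course of the parent compound and of BAP-7,8-dihydrodiol (M1,
the precursor of the ultimate carcinogen BPDE) in every culture fraction,
and provides the analysis tooling around the model — local sensitivity
analysis, staged maximum-likelihood calibration, AIC-based selection of
model variants, and UPLC mass-balance bookkeeping — plus a synthetic-data
generator that emulates the exposure experiments so the whole pipeline is
testable end to end.

## Model

Amounts (nmol) are tracked in a dose compartment `AD` (what a mucus wash
recovers for the parent), parent in cells `AC` and media `AM`, metabolite
in cells `MC`, media `MM` and mucus `MU`, plus cumulative pools for
metabolized and volatilized material, making the system exactly
mass-conserving. The processes are

- first-order absorption from the dose compartment, `dAD/dt = −k_abs·AD`;
- passive transmembrane diffusion driven by the free (partition-corrected)
  cellular concentration, e.g. `J_P = P·SA·(AC/(V_c·K_cm) − AM/V_med)`;
- metabolic clearance scaled allometrically by cell mass to the 3/4 power,
  `R_met = φ(t)·CL·W^{3/4}·C_free`, where `φ(t)` is a rational function
  `(A t² + B t + C)/(D t² − E t + F)` fitted to CYP1A1 activity
  (peak-normalized to 1, switchable off so that φ ≡ 1);
- optional carrier-mediated efflux of the metabolite from cells to media
  and mucus, parameterized as volumetric clearances (L/hr);
- first-order volatilization from media (parent, M1) and mucus (M1);
- a mucus layer growing linearly with the secretion rate.

Calibration maximizes a per-stream Gaussian log-likelihood (variance
profiled analytically, or fixed for noise-free data) with Nelder-Mead on
log-transformed parameters, in the staged order used for this system:
parent absorption + clearance on parent-in-cells, parent permeability +
volatilization on parent-in-media, metabolite volatilization tied to the
parent value, then the metabolite block (jointly in passive mode; with
the permeability tie and per-stream efflux fits in active-efflux mode).
Variants (induction on/off × efflux on/off) are ranked by
`AIC = 2k − 2 logL` with `k` counted identically across variants.

## Worked example

```python
import numpy as np
from alidose import default_parameter_set, simulate

params = default_parameter_set("with_induction", "efflux")
sim = simulate(params, dose=8.6, t_grid=np.array([0, 1, 2, 4, 8, 24, 48.0]))
print(sim.frame[["time_h", "AD", "AC", "AM", "MC", "MM", "MU",
                 "X_other", "X_m1"]].round(4).to_string(index=False))
print("max conservation error:", sim.conservation_error())
```

```
 time_h     AD     AC     AM     MC     MM     MU  X_other   X_m1
    0.0 8.6000 0.0000 0.0000 0.0000 0.0000 0.0000   0.0000 0.0000
    1.0 6.7650 1.8201 0.0002 0.0002 0.0003 0.0009   0.0132 0.0000
    2.0 5.3215 3.1776 0.0007 0.0010 0.0019 0.0068   0.0903 0.0002
    4.0 3.2929 4.2552 0.0024 0.0062 0.0209 0.0749   0.9457 0.0017
    8.0 1.2608 0.6460 0.0045 0.0063 0.1404 0.5013   6.0265 0.0113
   24.0 0.0271 0.0086 0.0046 0.0001 0.1787 0.6278   7.7122 0.0148
   48.0 0.0001 0.0000 0.0044 0.0000 0.1731 0.6016   7.7442 0.0150
max conservation error: 2.0655312086049425e-15
```

Reading the table: of the 8.6 nmol applied, absorption into cells peaks
near 4 h (`AC` = 4.26 nmol), after which induced metabolism consumes the
parent — by 48 h 7.74 nmol has been metabolized to non-M1 products
(`X_other`) and the parent has essentially vanished. The M1 metabolite
accumulates mostly in mucus (0.60 nmol) and media (0.17 nmol), driven by
active efflux out of the cells. The row sum including the cumulative
pools equals the dose to machine precision at every time.

The calibration layer follows scikit-learn conventions:

```python
from alidose import DosimetryCalibrator
cal = DosimetryCalibrator(induction_on=True, efflux_on=True, dose=8.6)
cal.fit(observations)          # tidy frame: time_h, stream, replicate, amount_nmol
cal.params_, cal.aic_          # fitted ParameterSet and its AIC
cal.predict([0, 8, 24, 48])    # stream predictions on a time grid
```

A `alidose` console script exposes the pipeline
(`simulate`, `sensitivity`, `fit`, `compare`, `massbal`, `synth`); run
`alidose --help`.

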