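# Methods

## Model structure and assumptions

The model is a ten-state linear (in state) time-varying compartmental ODE
system for amounts in nmol. Parent PAH: dose compartment `AD`, cells
`AC`, basal media `AM`. Metabolite M1 (BAP-7,8-dihydrodiol): cells `MC`,
media `MM`, apical mucus `MU`. Four cumulative pools close the mass
balance: `X_other` (parent metabolized to non-M1 products), `X_m1` (M1
further metabolized; compared against total tetrol as a minimum-metabolism
proxy), `VP` and `V1` (volatilized parent / M1). Because every loss term
deposits into one of these pools, the state sum is constant by
construction and conservation is checked, not imposed.

Assumptions worth making explicit:

- The parent has no mucus compartment; apical uptake is a single
  first-order absorption step from the dose compartment, and the measured
  parent "mucus fraction" is identified with `AD`.
- The dose compartment loses material only to absorption (no
  volatilization from the apical surface).
- Metabolism is first order in concentration (linear clearance). A
  saturable Michaelis–Menten form is deliberately out of scope; the model
  is therefore linear in dose, which several tests exploit.
- Driving concentrations for diffusion, clearance and efflux are **free**
  concentrations: the total cellular amount divided by cell volume and by
  the relevant partition coefficient (cell:media for exchange with media
  and for metabolism; cell:mucus for exchange with mucus). The total
  versus free choice is not uniquely determined by the source material;
  free is the convention consistent with partition coefficients describing
  a diffusive equilibrium, and is declared here once. It affects the
  absolute meaning of the printed clearance/efflux values but not any
  round-trip or selection result in this package.
- CYP1A1 induction scales **parent** metabolism only, as the rational
  function φ(t) = (A t² + B t + C)/(D t² − E t + F), peak-normalized so 1
  is the highest observed activity; the induction switch replaces φ by
  exactly 1. M1 clearance is never induction-scaled.
- In active-efflux mode the M1 permeability is tied to the parent
  permeability; the tie is enforced at construction and maintained when
  the parent permeability is refit (an explicit M1-permeability override
  releases it).

## Parameters and units

Internally everything is hours, nmol, mL. All unit conversions happen in
one place (`derive_effective_rates`): permeability (cm/hr) × area (cm²)
gives mL/hr; allometric clearances (L/hr/kg^{3/4}) are multiplied by cell
mass to the 3/4 power and by 1000 to give mL/hr; efflux clearances (L/hr)
by 1000. Cell mass uses a tissue density of 1.0 g/mL (tissue ≈ water),
turning the 0.00392 mL cell volume (1.12 cm² × 35 µm) into 3.92×10⁻⁶ kg.
The mucus volume grows linearly, V_mu(t) = V₀ + Q·SA·t with
Q = 0.004 mL/cm²/hr; V₀ defaults to 0.0045 mL (≈1 h of secretion, since
the apical surface is washed immediately before exposure) and a guard of
10⁻⁶ mL protects the mucus concentration at degenerate V₀ = 0.

Kinetic values ship as presets: parent `no_induction`/`with_induction`
and metabolite `passive`/`efflux` columns. The M1 cell:mucus partition
coefficient defaults to 10.4 (the tabulated value; a nearby 10.9 appears
elsewhere in the source material and the discrepancy is simply recorded).

## Simulation

`solve_ivp` with LSODA at rtol 1e-8 / atol 1e-10 (the system is only
mildly stiff; LSODA switches as needed). An independent fixed-step
explicit Euler integrator (dt = 1e-4 h) serves as the oracle in tests;
trajectories agree to better than 1e-4 **relative to each compartment's
peak amount** — pointwise relative error at sub-nanomole amounts is
dominated by the oracle's own truncation error and is not a meaningful
comparison.

## Sensitivity analysis

Normalized local coefficients S(t) = [(Y′(t) − Y(t))/Y(t)]/0.01 from a
one-sided +1% perturbation, on a grid starting at 0.01 h then every
0.05 h to 48 h; sensitivity runs use tightened solver tolerances
(rtol 1e-10, atol 1e-14) because the coefficient ratios perturbed to
baseline trajectories at amounts down to ~1e-9 nmol. Where the baseline
is below 1e-9 nmol — a decade above the default solver atol — S is
defined as 0; below that the ratio would be integration noise.
Classification follows the L/M/H brackets (<0.15, 0.15–0.5 inclusive,
>0.5) applied to max|S|.

Two maxima are exposed. The report table uses max|S| (magnitudes, as
sensitivity tables are conventionally printed). For parameters such as
absorption, the per-time relative coefficient grows without bound late in
the experiment as the compartment empties (|ΔY/Y| large while Y → 0);
the scientifically meaningful headline value is the early-time limiting
coefficient (+1 for absorption on parent-in-cells, since AC ≈ k_abs·D·t),
which is what the **signed** maximum returns because the coefficient
turns negative beyond the peak. The analytically forced identities — 1.00
for the M1 formation fraction on every M1 output (exact linearity), and
1.00 for absorption→cells and permeability→media at the early-time limit
— are asserted numerically; other tabulated maxima depend on reporting
conventions and are treated as qualitative anchors only.

## Likelihood, staging, AIC

Residuals are Gaussian and iid within each observation stream
(parent/M1 × cells/media/mucus, total tetrol, total metabolites). Two
error models: fixed σ (used for noise-free round-trip tests, where the
profiled form degenerates at zero residuals) and per-stream profiled
variance, σ̂_s² = RSS_s/n_s with logL_s = −(n_s/2)(ln 2πσ̂_s² + 1).

Staging: (1) k_abs + clearance on parent-in-cells; (2) permeability +
media volatilization on parent-in-media; (3) M1 volatilizations set equal
to the fitted parent value (they are low-sensitivity parameters); (4)
passive mode fits {f_M1, M1 permeability, M1 clearance} jointly on M1
cells + media + total tetrol, while efflux mode ties M1 permeability to
the parent and fits f_M1 (M1 cells+media+mucus), M1 clearance (tetrol),
efflux-to-media (M1 media) and efflux-to-mucus (M1 mucus) in sequence.
Later stages condition on earlier estimates and never revisit them.

Optimization is Nelder-Mead on log-transformed parameters (logit for the
formation fraction, which lives in [0,1]), parameter tolerance 1e-8,
objective tolerance 1e-8 scaled by the objective magnitude (the adaptive
solver leaves ~1e-7 noise on large log-likelihoods, so a tighter absolute
criterion would never be met), iteration cap 5000, one restart from the
incumbent. The search is kept within ±4 decades of the start by a smooth
penalty; beyond that the parameters are physically meaningless and the
ODE system numerically hostile. Fits are deterministic given data and
start; starting values are explicit arguments (`init` / `init_scale`)
rather than anything interactive.

For variant comparison, every variant's log-likelihood is evaluated on
the **same** stream set (parent cells/media, M1 cells/media/mucus, total
tetrol) regardless of which streams its stages fit — AICs on different
data are not comparable — and k counts every fitted kinetic parameter
plus one profiled variance per comparison stream, identically defined
across variants (k is 13 for passive variants, 14 for efflux variants).

Induction-curve selection fits four candidates to peak-normalized
activity data by Nelder-Mead least squares: the rational function (F
fixed to resolve the common-scalar degeneracy, A–E free and positive),
a quadratic, an exponential rise–decay a(e^{−k₂t} − e^{−k₁t}), and a Hill
curve. AIC uses the profiled-variance likelihood with k = free
coefficients + 1. Round-trip testing is at the curve level, not the
coefficient level, because the coefficients are only identified up to the
fixed scale.

## Mass balance

Percent recovery references the replicate-mean summed parent amount in
the 0-hour samples (the operational "amount added"), not the nominal
applied mass. Replicates are aggregated by arithmetic mean of per-sample
sums; for balanced designs this equals the sum of fraction means (a test
asserts the invariance). Parent-only recovery and parent-plus-Phase-1
recovery satisfy total ≥ parent by construction. The β-glucuronidase
difference (treated-arm mean − untreated-arm mean per analyte and
fraction) estimates conjugates; negative differences are informative
noise and are flagged, never clamped, and the estimate is labeled
conjugates (glucuronide + possible sulfate) since the enzyme preparation
may co-deconjugate sulfates.

## Synthetic data

The generator emulates the two exposure designs: optimization
(8.6 nmol measured at 0 h — the nominal 2.26 µg/cm² corrected by the 0-h
recovery convention — sampled at 0, 1, 2, 4, 8, 24, 48 h, n = 4) and
validation (16.8 nmol; 0, 8, 24, 48 h; n = 8 with 4 enzyme-treated).
States map to table rows as: AD/AC/AM → parent mucus/cells/media;
MC/MM/MU → M1 rows; X_m1 → tetrol; X_other is split across the named
Phase 1 metabolites by a fixed composition vector (3-phenol 0.35,
9-phenol 0.05, 4,5-dihydrodiol 0.25, 9,10-dihydrodiol 0.35 — a fixture
convention reflecting observed ranks, not a measured composition) and
across fractions in proportion to M1's own distribution. A per-metabolite
glucuronide fraction is hidden from the untreated arm. Noise is
multiplicative lognormal with mean 1 at CV 15% (a fixture convention; no
quantitative noise magnitude is available), and amounts below the 0.005
nmol detection limit censor to zero.

What the generator does **not** emulate: chromatographic artifacts,
co-eluting unknown peaks, inter-donor variability, or dose-dependent
shifts in the metabolite profile. Passing round-trip tests therefore
demonstrate self-consistency of the pipeline under the stated noise
model, not fidelity to any particular laboratory dataset.

One deliberate interaction is documented here: at the study's own dose
the model's parent-in-media amounts peak near 3e-3 nmol, below the
default detection limit, so a censored dataset carries no information in
that stream and the profiled likelihood degenerates (σ̂ → 0 rewards
predicting exact zeros). The model-selection and estimator-bias tests
therefore generate data with censoring disabled; the detection limit
remains in the generator defaults and is exercised by the synthetic-data
tests.

## Problem sizes used by the shipped checks

Sensitivity maxima are computed on the 961-point default grid; parameter
round-trips use a noise-free hourly 0–48 h trajectory and 3× starting
guesses; model selection runs ten replicate experiments (CV 15%, n = 4,
seven timepoints) through all four variant calibrations; the solver
oracle uses dt = 1e-4 h over 48 h; the conjugate-recovery check uses
1000 replicates per arm.

## Known limitations

- No parent mucus compartment and no saturable metabolism, so the model
  cannot represent the dose-dependent metabolite-profile shift seen at
  higher doses.
- The Gaussian iid error model ignores censoring; a tobit-style
  likelihood would use below-LOD observations properly.
- Efflux coefficients act on free concentration; if the original
  convention was total concentration their absolute values are not
  directly transferable (round-trips within this package are unaffected).
- The staged calibration is conditional, not joint: uncertainties do not
  propagate between stages and no confidence intervals are produced.
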