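"""Maximum-likelihood calibration, AIC model selection, and fit diagnostics.

Calibration follows the staged scheme used for the dosimetry model:
parent absorption and metabolism are fit together against parent-in-cells
data, then parent permeability and volatilization against parent-in-media;
metabolite volatilization is tied to the parent value (low sensitivity);
finally the metabolite block is fit, whose structure depends on the
transport mode (passive diffusion versus active efflux).  Each stage
conditions on the estimates of earlier stages.

The objective is a Gaussian iid log-likelihood per observation stream,
either with a fixed residual standard deviation or with the per-stream
variance profiled out analytically.  Optimization is Nelder-Mead on
log-transformed parameters (logit for the M1 formation fraction), with
one restart from the incumbent.  Model variants are compared by AIC with
a parameter count that includes one profiled variance per fitted stream,
defined identically across variants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .model import STREAM_STATE, SimulationResult, cyp_scale, simulate
from .params import (
    InductionCoefficients,
    ModelSwitches,
    ParameterSet,
    default_parameter_set,
)

__all__ = [
    "ObservationSet",
    "FitResult",
    "log_likelihood",
    "aic",
    "fit_stage",
    "staged_calibration",
    "DosimetryCalibrator",
    "fit_induction_curve",
    "InductionCurveFitter",
    "compare_models",
    "prediction_deviation",
]

STREAMS = tuple(STREAM_STATE)

_NM_OPTIONS = {"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000, "maxfev": 10000}
_LOGIT_PARAMS = {"fraction_m1"}  # constrained to [0, 1]


class ObservationSet:
    """Tidy table of stream observations: time_h, stream, replicate, amount_nmol."""

    COLUMNS = ("time_h", "stream", "replicate", "amount_nmol")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"observation table missing columns {sorted(missing)}")
        bad = set(frame["stream"].unique()) - set(STREAMS)
        if bad:
            raise ValueError(f"unknown streams {sorted(bad)}")
        if (frame["time_h"] < 0).any():
            raise ValueError("times must be >= 0")
        if (frame["amount_nmol"] < 0).any():
            raise ValueError("amounts must be >= 0")
        if len(frame) == 0:
            raise ValueError("observation table is empty")
        self.frame = frame.reset_index(drop=True)

    def streams(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["stream"].unique()))

    def subset(self, streams) -> "ObservationSet":
        streams = [streams] if isinstance(streams, str) else list(streams)
        missing = set(streams) - set(self.frame["stream"].unique())
        if missing:
            raise ValueError(
                f"observation set lacks required stream(s) {sorted(missing)}"
            )
        return ObservationSet(self.frame[self.frame["stream"].isin(streams)])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class FitResult:
    """Outcome of one calibration stage."""

    stage: str
    estimates: dict
    log_likelihood: float
    aic: float
    k: int
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list, repr=False)


def _predict_rows(params: ParameterSet, dose: float, frame: pd.DataFrame) -> np.ndarray:
    """Model prediction for every observation row, one ODE solve total."""
    times = np.unique(frame["time_h"].to_numpy(dtype=float))
    grid = times if times[0] == 0 else np.concatenate([[0.0], times])
    sim = simulate(params, dose, grid)
    lookup = {}
    for stream in frame["stream"].unique():
        series = sim.stream(stream)
        lookup[stream] = dict(zip(grid, series))
    return np.array([
        lookup[s][t] for s, t in zip(frame["stream"], frame["time_h"].astype(float))
    ])


def _stream_loglik(residuals: np.ndarray, error_model: str, sigma: float) -> float:
    n = len(residuals)
    rss = float(np.dot(residuals, residuals))
    if error_model == "fixed":
        return -0.5 * n * math.log(2 * math.pi * sigma**2) - rss / (2 * sigma**2)
    if error_model == "profiled":
        if rss <= 0:
            raise ValueError(
                "profiled likelihood degenerates at zero residuals; "
                "use the fixed-sigma error model for noise-free data"
            )
        s2 = rss / n
        return -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)
    raise ValueError(f"unknown error model {error_model!r}")


def log_likelihood(
    obs: ObservationSet,
    params: ParameterSet,
    dose: float,
    error_model: str = "profiled",
    sigma: float = 1.0,
) -> float:
    """Gaussian iid log-likelihood, summed over observation streams."""
    frame = obs.frame
    pred = _predict_rows(params, dose, frame)
    resid = frame["amount_nmol"].to_numpy(dtype=float) - pred
    total = 0.0
    for stream in frame["stream"].unique():
        mask = (frame["stream"] == stream).to_numpy()
        total += _stream_loglik(resid[mask], error_model, sigma)
    return total


def aic(logL: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 logL."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * logL


def _to_internal(name: str, value: float) -> float:
    if name in _LOGIT_PARAMS:
        value = min(max(value, 1e-12), 1 - 1e-12)
        return math.log(value / (1.0 - value))
    if value <= 0:
        raise ValueError(f"initial value for {name} must be strictly positive")
    return math.log(value)


def _from_internal(name: str, x: float) -> float:
    if name in _LOGIT_PARAMS:
        return 1.0 / (1.0 + math.exp(-x))
    return math.exp(x)


def fit_stage(
    obs: ObservationSet,
    free_params,
    fixed: ParameterSet,
    init=None,
    error_model: str = "profiled",
    sigma: float = 1.0,
    dose: float = 8.6,
    stage: str = "stage",
) -> FitResult:
    """Maximize the log-likelihood over a set of free kinetic parameters.

    Positive parameters are optimized on a log scale and the M1 formation
    fraction on a logit scale.  Deterministic given the starting point;
    non-convergence is flagged, not raised.
    """
    free_params = list(free_params)
    init = dict(init or {})
    x0 = np.array([
        _to_internal(name, init.get(name, fixed.get(name))) for name in free_params
    ])
    trace: list = []
    # keep the search inside four decades of the start: beyond that the
    # model is in a physically meaningless, numerically hostile regime
    box = math.log(1e4)

    def objective(x):
        excess = np.abs(np.asarray(x) - x0) - box
        if np.any(excess > 0):
            return 1e10 * (1.0 + float(np.sum(np.maximum(excess, 0.0))))
        updates = {n: _from_internal(n, xi) for n, xi in zip(free_params, x)}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ll = log_likelihood(obs, fixed.with_updates(updates), dose,
                                    error_model=error_model, sigma=sigma)
        except (RuntimeError, OverflowError):
            return 1e12
        trace.append((updates, ll))
        return -ll

    # objective tolerance scaled to the objective magnitude: the adaptive
    # ODE solver leaves ~1e-7 numerical noise on the log-likelihood, so an
    # absolute 1e-10 criterion would never be met on large likelihoods
    f0 = objective(x0)
    options = dict(_NM_OPTIONS, fatol=1e-8 * (1.0 + abs(f0)))
    res = minimize(objective, x0, method="Nelder-Mead", options=options)
    res = minimize(objective, res.x, method="Nelder-Mead", options=options)
    estimates = {n: _from_internal(n, xi) for n, xi in zip(free_params, res.x)}
    logL = -float(res.fun)
    k = len(free_params)
    return FitResult(
        stage=stage,
        estimates=estimates,
        log_likelihood=logL,
        aic=aic(logL, k),
        k=k,
        converged=bool(res.success),
        n_iter=int(res.nit),
        trace=trace,
    )


# streams each calibration stage fits against
_STAGE_STREAMS = {
    "parent_absorption_metabolism": ("parent_cells",),
    "parent_permeability_volatilization": ("parent_media",),
    "m1_passive_block": ("m1_cells", "m1_media", "total_tetrol"),
    "m1_formation": ("m1_cells", "m1_media", "m1_mucus"),
    "m1_metabolism": ("total_tetrol",),
    "m1_efflux_media": ("m1_media",),
    "m1_efflux_mucus": ("m1_mucus",),
}


def staged_calibration(
    obs: ObservationSet,
    switches: ModelSwitches,
    base_params: ParameterSet | None = None,
    init=None,
    init_scale: float = 1.0,
    error_model: str = "profiled",
    sigma: float = 1.0,
    dose: float = 8.6,
) -> tuple[ParameterSet, list[FitResult]]:
    """Run the full staged calibration for one model variant.

    Stage order: (1) parent absorption + metabolic clearance on
    parent-in-cells; (2) parent permeability + media volatilization on
    parent-in-media; (3) metabolite volatilizations tied to the fitted
    parent value; (4) the metabolite block -- jointly (formation,
    permeability, clearance) in passive mode, or with permeability tied to
    the parent and formation / clearance / efflux terms fit against their
    own streams in efflux mode.

    ``init`` maps parameter names to explicit starting values;
    ``init_scale`` multiplies the incumbent value for parameters without an
    explicit entry (e.g. 3.0 starts every search at 3x).
    """
    if base_params is None:
        base_params = default_parameter_set(
            parent_preset="with_induction" if switches.induction_on else "no_induction",
            m1_preset="efflux" if switches.efflux_on else "passive",
            induction_on=switches.induction_on,
            efflux_on=switches.efflux_on,
        )
    params = base_params
    init = dict(init or {})

    def stage_init(names):
        return {n: init.get(n, params.get(n) * init_scale) for n in names}

    def run(stage_name, names):
        streams = _STAGE_STREAMS[stage_name]
        sub = obs.subset(streams)  # raises naming the missing stream
        return fit_stage(
            sub, names, params, init=stage_init(names),
            error_model=error_model, sigma=sigma, dose=dose, stage=stage_name,
        )

    results = []
    fr = run("parent_absorption_metabolism", ["k_abs", "clearance"])
    params = params.with_updates(fr.estimates)
    results.append(fr)

    fr = run("parent_permeability_volatilization", ["permeability", "k_vol_media"])
    params = params.with_updates(fr.estimates)
    results.append(fr)

    # metabolite volatilization tied to parent volatilization from media
    tied_vol = params.get("k_vol_media")
    params = params.with_updates(
        {"m1_k_vol_media": tied_vol, "m1_k_vol_mucus": tied_vol}
    )

    if switches.efflux_on:
        # permeability tie is maintained by with_updates in efflux mode
        for stage_name, names in (
            ("m1_formation", ["fraction_m1"]),
            ("m1_metabolism", ["m1_clearance"]),
            ("m1_efflux_media", ["efflux_media"]),
            ("m1_efflux_mucus", ["efflux_mucus"]),
        ):
            fr = run(stage_name, names)
            params = params.with_updates(fr.estimates)
            results.append(fr)
    else:
        fr = run("m1_passive_block",
                 ["fraction_m1", "m1_permeability", "m1_clearance"])
        params = params.with_updates(fr.estimates)
        results.append(fr)
    return params, results


class DosimetryCalibrator(BaseEstimator):
    """Staged maximum-likelihood calibration as a scikit-learn estimator.

    Parameters
    ----------
    induction_on, efflux_on : bool
        Model-variant switches (time-varying CYP1A1 metabolism scaling,
        carrier-mediated metabolite efflux).
    dose : float
        Applied dose in nmol (the measured 0-h amount).
    error_model : {"profiled", "fixed"}
        Per-stream Gaussian error with profiled variance, or fixed sigma.
    init_scale : float
        Multiplier on the base parameter values used as starting points.

    Attributes
    ----------
    params_ : ParameterSet
        Calibrated parameter set.
    stage_results_ : list of FitResult
    log_likelihood_ : float
        Joint likelihood over all fitted streams at the optimum.
    aic_ : float
        2k - 2 logL with k = fitted kinetic parameters + one profiled
        variance per fitted stream.
    """

    def __init__(self, induction_on=True, efflux_on=True, dose=8.6,
                 error_model="profiled", sigma=1.0, init_scale=1.0,
                 base_params=None):
        self.induction_on = induction_on
        self.efflux_on = efflux_on
        self.dose = dose
        self.error_model = error_model
        self.sigma = sigma
        self.init_scale = init_scale
        self.base_params = base_params

    def fit(self, X, y=None):
        obs = X if isinstance(X, ObservationSet) else ObservationSet(X)
        switches = ModelSwitches(induction_on=self.induction_on,
                                 efflux_on=self.efflux_on)
        params, results = staged_calibration(
            obs, switches, base_params=self.base_params,
            init_scale=self.init_scale, error_model=self.error_model,
            sigma=self.sigma, dose=self.dose,
        )
        # likelihood/AIC are evaluated on a stream set common to every
        # variant (not just the streams this variant's stages fit), so
        # AICs are comparable across variants
        comparison = ("parent_cells", "parent_media", "m1_cells",
                      "m1_media", "m1_mucus", "total_tetrol")
        fitted_streams = sorted(set(comparison)
                                & set(obs.frame["stream"].unique()))
        self.params_ = params
        self.stage_results_ = results
        self.n_kinetic_params_ = sum(fr.k for fr in results)
        self.fitted_streams_ = fitted_streams
        self.log_likelihood_ = log_likelihood(
            obs.subset(fitted_streams), params, self.dose,
            error_model=self.error_model, sigma=self.sigma,
        )
        # one profiled variance per fitted stream counts as a parameter
        n_var = len(fitted_streams) if self.error_model == "profiled" else 0
        self.k_ = self.n_kinetic_params_ + n_var
        self.aic_ = aic(self.log_likelihood_, self.k_)
        return self

    def predict(self, t_grid) -> pd.DataFrame:
        """Stream predictions (nmol) on a time grid for the fitted model."""
        if not hasattr(self, "params_"):
            raise AttributeError("calibrator is not fitted")
        t_grid = np.asarray(t_grid, dtype=float)
        grid = t_grid if t_grid[0] == 0 else np.concatenate([[0.0], t_grid])
        sim = simulate(self.params_, self.dose, grid)
        keep = np.isin(grid, t_grid)
        out = pd.DataFrame({"time_h": grid[keep]})
        for stream in STREAMS:
            out[stream] = sim.stream(stream)[keep]
        return out


# ---------------------------------------------------------------------------
# CYP1A1 induction-curve fitting and candidate selection


def _rational_curve(t, A, B, C, D, E, F):
    return (A * t**2 + B * t + C) / (D * t**2 - E * t + F)


_CANDIDATES = ("rational", "quadratic", "exp_rise_decay", "hill")


def _candidate_model(name):
    """Return (n_free, init, curve(t, x)) with x the internal coordinates."""
    if name == "rational":
        # F fixed to resolve the common-scalar degeneracy; A-E free, all
        # positive (log scale).  Started from the shipped coefficients.
        c0 = InductionCoefficients()
        init = np.log([c0.A, c0.B, c0.C, c0.D, c0.E])

        def curve(t, x):
            A, B, C, D, E = np.exp(x)
            den = D * t**2 - E * t + c0.F
            if np.any(den <= 0):
                return None
            return (A * t**2 + B * t + C) / den

        return 5, init, curve
    if name == "quadratic":
        init = np.array([0.0, 0.05, 0.0])

        def curve(t, x):
            a, b, c = x
            return a * t**2 + b * t + c

        return 3, init, curve
    if name == "exp_rise_decay":
        # a (e^{-k2 t} - e^{-k1 t}), rise rate k1 > decay rate k2
        init = np.log([1.0, 0.5, 0.02])

        def curve(t, x):
            a, k1, k2 = np.exp(x)
            return a * (np.exp(-k2 * t) - np.exp(-k1 * t))

        return 3, init, curve
    if name == "hill":
        init = np.log([1.0, 8.0, 2.0])

        def curve(t, x):
            a, half, n = np.exp(x)
            return a * t**n / (half**n + t**n)

        return 3, init, curve
    raise KeyError(f"unknown induction-curve candidate {name!r}")


@dataclass
class InductionFitResult:
    candidate: str
    coefficients: np.ndarray
    curve: object
    rss: float
    log_likelihood: float
    aic: float
    k: int


def fit_induction_curve(
    activity: pd.DataFrame,
    candidates=_CANDIDATES,
) -> tuple[dict, str]:
    """Fit candidate activity curves to normalized CYP1A1 data, select by AIC.

    ``activity`` has columns time_h and activity (replicates as extra rows).
    Activity is normalized to [0, 1] by its maximum observed value before
    fitting.  Returns (per-candidate results, name of the AIC argmin).
    """
    t = activity["time_h"].to_numpy(dtype=float)
    y = activity["activity"].to_numpy(dtype=float)
    ymax = y.max()
    if ymax <= 0:
        raise ValueError("activity data are all zero; nothing to normalize")
    y = y / ymax
    if len(np.unique(t)) < 6:
        raise ValueError("need at least 6 distinct time points")

    results: dict[str, InductionFitResult] = {}
    for name in candidates:
        n_free, init, curve = _candidate_model(name)

        def objective(x):
            pred = curve(t, x)
            if pred is None or not np.all(np.isfinite(pred)):
                return 1e12
            r = y - pred
            return float(np.dot(r, r))

        res = minimize(objective, init, method="Nelder-Mead", options=_NM_OPTIONS)
        res = minimize(objective, res.x, method="Nelder-Mead", options=_NM_OPTIONS)
        rss = float(res.fun)
        n = len(y)
        # profiled Gaussian likelihood of the least-squares fit
        s2 = max(rss / n, 1e-300)
        logL = -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)
        k = n_free + 1  # + profiled variance
        results[name] = InductionFitResult(
            candidate=name, coefficients=res.x,
            curve=(lambda x_, c_: (lambda tt: c_(np.asarray(tt, float), x_)))(res.x, curve),
            rss=rss, log_likelihood=logL, aic=aic(logL, k), k=k,
        )
    best = min(results, key=lambda nm: results[nm].aic)
    return results, best


class InductionCurveFitter(BaseEstimator):
    """Candidate-curve fit to CYP1A1 activity data, sklearn-style.

    fit(X, y) with X = times (hours) and y = activity; after fitting,
    ``best_candidate_`` names the AIC-selected curve and ``predict`` returns
    the selected curve's normalized activity.
    """

    def __init__(self, candidates=_CANDIDATES):
        self.candidates = candidates

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        frame = pd.DataFrame({"time_h": X, "activity": y})
        self.results_, self.best_candidate_ = fit_induction_curve(
            frame, candidates=self.candidates
        )
        self.aic_table_ = pd.DataFrame([
            {"candidate": nm, "rss": r.rss, "aic": r.aic, "k": r.k}
            for nm, r in self.results_.items()
        ])
        return self

    def predict(self, X):
        if not hasattr(self, "results_"):
            raise AttributeError("fitter is not fitted")
        return self.results_[self.best_candidate_].curve(np.asarray(X, float))


def compare_models(
    obs: ObservationSet,
    variants,
    dose: float = 8.6,
    error_model: str = "profiled",
    init_scale: float = 1.0,
) -> pd.DataFrame:
    """Calibrate each model variant on the same data and rank by AIC.

    ``variants`` is a list of ModelSwitches.  k counts every fitted kinetic
    parameter plus one profiled variance per fitted stream, identically
    defined across variants.  Returns a table sorted as given, with a
    ``best`` flag on the AIC minimizer.
    """
    if len(variants) < 2:
        raise ValueError("need at least two variants to compare")
    rows = []
    for sw in variants:
        cal = DosimetryCalibrator(
            induction_on=sw.induction_on, efflux_on=sw.efflux_on,
            dose=dose, error_model=error_model, init_scale=init_scale,
        ).fit(obs)
        rows.append({
            "induction_on": sw.induction_on,
            "efflux_on": sw.efflux_on,
            "log_likelihood": cal.log_likelihood_,
            "k": cal.k_,
            "aic": cal.aic_,
        })
    table = pd.DataFrame(rows)
    table["best"] = table["aic"] == table["aic"].min()
    return table


def prediction_deviation(
    sim: SimulationResult,
    obs: ObservationSet,
    stream: str,
    time: float,
) -> float:
    """Percent deviation of the model from the observed mean at one point.

    Negative values are underprediction (-72 = underpredicts by 72%).
    """
    rows = obs.frame[(obs.frame["stream"] == stream)
                     & (obs.frame["time_h"] == time)]
    if len(rows) == 0:
        raise ValueError(f"no observations for {stream!r} at t = {time} h")
    observed = float(rows["amount_nmol"].mean())
    if observed <= 0:
        raise ZeroDivisionError(
            f"observed mean for {stream!r} at t = {time} h is zero; "
            "percent deviation undefined"
        )
    i = np.where(sim.time_grid == time)[0]
    if len(i) == 0:
        raise ValueError(f"t = {time} h not on the simulation grid")
    predicted = float(sim.stream(stream)[i[0]])
    return (predicted - observed) / observed * 100.0
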