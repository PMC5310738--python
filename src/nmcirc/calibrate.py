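"""Dose-response curve fitting and baseline calibration of release parameters.

``fit_sigmoid`` and ``fit_threshold_linear`` are ordinary damped least-squares
fits (Levenberg-Marquardt via scipy) with data-quantile starting values.
``calibrate_release`` re-tunes free per-stimulus release parameters (y_p of a
Michaelis-Menten projection, or the rise factor of a linear projection) so the
coupled circuit's steady state reproduces target baseline rates and
concentrations: each free parameter has a closed-form solution given the
source population's steady firing rate, so the procedure is a fixed-point
iteration ending in a verification simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dynamics import linear_steady_state, mm_steady_state
from .model import (
    C_FLOOR,
    CircuitSpec,
    CircuitState,
    CircuitValidationError,
    PopulationSpec,
    ReleaseKineticsLinear,
    ReleaseKineticsMM,
    SigmoidParams,
    sigmoid_response,
    threshold_linear,
)
from .simulate import SimulationConfig, steady_state

__all__ = [
    "DoseResponseTable",
    "BaselineTargets",
    "SigmoidFit",
    "ThresholdLinearFit",
    "CalibrationResult",
    "CalibrationError",
    "fit_sigmoid",
    "fit_threshold_linear",
    "calibrate_release",
    "fixed_point_estimate",
]


class CalibrationError(RuntimeError):
    pass


@dataclass
class DoseResponseTable:
    """Rows of (concentration nM, response) with a response-mode flag."""

    concentrations: np.ndarray
    responses: np.ndarray
    mode: str = "current"  # {"current", "rate"}

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise CircuitValidationError("concentration and response columns differ in length")
        if np.any(self.concentrations < 0):
            raise CircuitValidationError("concentrations must be >= 0")
        if self.mode not in ("current", "rate"):
            raise CircuitValidationError(f"mode must be 'current' or 'rate', got {self.mode!r}")

    def __len__(self):
        return len(self.concentrations)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration_nM": self.concentrations,
                "response": self.responses,
                "mode": self.mode,
            }
        )

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DoseResponseTable":
        df = pd.read_csv(path)
        required = {"concentration_nM", "response", "mode"}
        missing = required - set(df.columns)
        if missing:
            raise CircuitValidationError(f"dose-response table missing columns: {sorted(missing)}")
        modes = set(df["mode"].astype(str))
        if len(modes) != 1:
            raise CircuitValidationError(f"dose-response table mixes response modes: {sorted(modes)}")
        return cls(
            df["concentration_nM"].to_numpy(float),
            df["response"].to_numpy(float),
            mode=modes.pop(),
        )


@dataclass
class BaselineTargets:
    """Target basal rates (Hz, per population) and concentrations (nM, per projection key)."""

    rates: dict[str, float] = field(default_factory=dict)
    concentrations: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "BaselineTargets":
        for name, v in {**self.rates, **self.concentrations}.items():
            if not v > 0:
                raise CircuitValidationError(f"baseline target {name!r} must be > 0, got {v}")
        return self


# ---------------------------------------------------------------------------
# Sigmoid fitting
# ---------------------------------------------------------------------------

@dataclass
class SigmoidFit:
    params: SigmoidParams
    rss: float
    converged: bool
    degenerate: bool
    message: str


def _sigmoid_vec(logc, lower, upper, shift, slope):
    return lower + (upper - lower) / (1.0 + np.exp(-(logc - shift) / slope))


def fit_sigmoid(data: DoseResponseTable, init: SigmoidParams | None = None) -> SigmoidFit:
    """Least-squares estimate of the four sigmoid parameters.

    Starting values come from the data unless ``init`` is given: lower/upper
    from the extreme responses, shift from the log-concentration whose
    response is closest to mid-range, slope 0.5.  Constant-response data are
    flagged degenerate (range ~ 0, slope unidentifiable) instead of fitted.
    """
    if len(data) < 4:
        raise CalibrationError(f"need >= 4 points for a 4-parameter fit, got {len(data)}")
    logc = np.log10(np.maximum(data.concentrations, C_FLOOR))
    y = data.responses
    if np.ptp(logc) == 0:
        raise CalibrationError("all concentrations equal: curve parameters unidentifiable")

    yspan = float(np.ptp(y))
    scale = max(abs(y).max(), 1.0)
    if yspan <= 1e-12 * scale:
        p = SigmoidParams(float(y[0]), float(y[0]), float(np.median(logc)), 1.0, mode=data.mode)
        return SigmoidFit(p, rss=float(np.sum((y - y[0]) ** 2)), converged=True,
                          degenerate=True, message="constant response: range ~ 0, slope unidentifiable")

    if init is None:
        order = np.argsort(logc)
        lo, hi = float(y[order[0]]), float(y[order[-1]])
        mid = 0.5 * (lo + hi)
        shift0 = float(logc[np.argmin(np.abs(y - mid))])
        x0 = np.array([lo, hi, shift0, 0.5])
    else:
        x0 = np.array([init.lower, init.upper, init.shift, init.slope])

    def resid(x):
        return _sigmoid_vec(logc, x[0], x[1], x[2], max(x[3], 1e-8)) - y

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                            max_nfev=20000)
    lower, upper, shift, slope = sol.x
    if slope < 0:  # logistic is invariant under (slope, lower<->upper) sign flip
        slope, lower, upper = -slope, upper, lower
    params = SigmoidParams(float(lower), float(upper), float(shift), float(max(slope, 1e-8)),
                           mode=data.mode)
    rss = float(np.sum(sol.fun ** 2))
    degenerate = abs(upper - lower) <= 1e-6 * scale
    return SigmoidFit(params, rss=rss, converged=bool(sol.success), degenerate=degenerate,
                      message=sol.message)


# ---------------------------------------------------------------------------
# Threshold-linear fitting
# ---------------------------------------------------------------------------

@dataclass
class ThresholdLinearFit:
    gain: float
    threshold: float  # I_0 given the supplied bias
    bias: float
    rss: float
    converged: bool
    degenerate: bool
    message: str

    def population(self, name: str = "fitted") -> PopulationSpec:
        return PopulationSpec(name=name, gain=self.gain, threshold=self.threshold, bias=self.bias)


def fit_threshold_linear(currents, rates, bias: float = 0.0) -> ThresholdLinearFit:
    """Least-squares (gain, threshold) of f = gain*[I - threshold + bias]_+.

    Needs >= 3 (I, f) points.  All-sub-threshold data (every response zero)
    leave the gain unidentifiable and are flagged degenerate.
    """
    i = np.asarray(currents, dtype=float)
    f = np.asarray(rates, dtype=float)
    if i.shape != f.shape:
        raise CalibrationError("current and rate arrays differ in length")
    if i.size < 3:
        raise CalibrationError(f"need >= 3 (I, f) points, got {i.size} (under-determined)")
    if np.all(f <= 0):
        return ThresholdLinearFit(0.0, float(i.max() + bias), bias, rss=0.0, converged=True,
                                  degenerate=True,
                                  message="all responses at zero: gain unidentifiable")

    # start from an ordinary line through the supra-threshold points
    act = f > 0
    if act.sum() >= 2 and np.ptp(i[act]) > 0:
        k0, b0 = np.polyfit(i[act], f[act], 1)
        k0 = max(k0, 1e-6)
        th0 = (-b0 / k0) + bias  # current where the line crosses zero, expressed as I_0
    else:
        k0, th0 = 1.0, float(np.median(i)) + bias

    def resid(x):
        k, th = x
        return np.maximum(k, 0.0) * np.maximum(i - th + bias, 0.0) - f

    sol = least_squares(resid, np.array([k0, th0]), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=10000)
    gain, threshold = float(max(sol.x[0], 0.0)), float(sol.x[1])
    return ThresholdLinearFit(gain, threshold, bias, rss=float(np.sum(sol.fun ** 2)),
                              converged=bool(sol.success), degenerate=False, message=sol.message)


# ---------------------------------------------------------------------------
# Release-parameter calibration
# ---------------------------------------------------------------------------

def _projection_steady_conc(proj, f_src: float) -> float:
    if isinstance(proj.kinetics, ReleaseKineticsMM):
        return mm_steady_state(f_src, proj.kinetics)
    return linear_steady_state(f_src, proj.kinetics)


def fixed_point_estimate(
    spec: CircuitSpec,
    rates0: dict[str, float] | None = None,
    damping: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 10000,
) -> CircuitState:
    """Semi-analytic circuit steady state by damped self-consistent iteration.

    Uses the closed-form per-projection steady concentrations and the
    algebraic rate map; valid for current-coupled circuits (rate-coupled
    targets are handled through their response curve directly).
    """
    rates = {
        p.name: (p.clamped_rate if p.clamped_rate is not None else 1.0)
        for p in spec.populations
    }
    if rates0:
        rates.update(rates0)
    rate_targets = {p.target: p for p in spec.rate_projections}
    for _ in range(max_iter):
        concs = {p.key: _projection_steady_conc(p, rates[p.source]) for p in spec.projections}
        currents = {p.key: sigmoid_response(concs[p.key], p.response)
                    for p in spec.current_projections}
        new = {}
        for pop in spec.populations:
            if pop.clamped_rate is not None:
                new[pop.name] = pop.clamped_rate
            elif pop.name in rate_targets:
                pr = rate_targets[pop.name]
                new[pop.name] = max(sigmoid_response(concs[pr.key], pr.response), 0.0)
            else:
                i_tot = sum(currents[p.key] for p in spec.projections_into(pop.name)
                            if p.coupling == "current")
                new[pop.name] = threshold_linear(i_tot, pop)
        err = max(abs(new[n] - rates[n]) for n in new) if new else 0.0
        rates = {n: (1 - damping) * rates[n] + damping * new[n] for n in new}
        if err < tol:
            break
    concs = {p.key: _projection_steady_conc(p, rates[p.source]) for p in spec.projections}
    currents = {p.key: sigmoid_response(concs[p.key], p.response)
                for p in spec.current_projections}
    return CircuitState(time=0.0, rates=rates, currents=currents, concentrations=concs)


@dataclass
class CalibrationResult:
    spec: CircuitSpec
    achieved: BaselineTargets
    iterations: int
    residuals: dict[str, float]
    converged: bool


def _solve_release(proj, c_target: float, f_src: float) -> float:
    if f_src <= 0:
        raise CalibrationError(
            f"projection {proj.key}: source rate is zero, target concentration unreachable"
        )
    kin = proj.kinetics
    if isinstance(kin, ReleaseKineticsMM):
        return kin.v_max * c_target / ((kin.k_m + c_target) * f_src)
    return kin.decay * c_target / f_src


def calibrate_release(
    spec: CircuitSpec,
    targets: BaselineTargets,
    free: list[str],
    cfg: SimulationConfig | None = None,
    rtol: float = 0.01,
    max_iter: int = 50,
    verify: bool = True,
) -> CalibrationResult:
    """Tune the free release parameters so steady baselines meet ``targets``.

    ``free`` lists projection keys whose y_p (MM) or rise factor (linear) may
    move; each must have a concentration target.  At every outer iteration the
    free parameters are solved in closed form from the current estimate of the
    steady source rates (target rates where specified), then the steady state
    is recomputed; iteration stops when every targeted quantity is within
    ``rtol`` relative.  A final forward-Euler simulation verifies the result
    when ``verify`` is set.
    """
    spec = spec.validate()
    targets.validate()
    for key in free:
        spec.projection(key)  # raises KeyError on dangling keys
    n_targets = len(targets.rates) + len(targets.concentrations)
    if len(free) > n_targets:
        raise CalibrationError(
            f"{len(free)} free parameters exceed {n_targets} targets (under-determined)"
        )
    for key in free:
        if key not in targets.concentrations:
            raise CalibrationError(f"free parameter {key} has no concentration target")

    def residual_map(state: CircuitState) -> dict[str, float]:
        res = {}
        for name, tv in targets.rates.items():
            res[f"rate:{name}"] = (state.rates[name] - tv) / tv
        for key, tv in targets.concentrations.items():
            res[f"conc:{key}"] = (state.concentrations[key] - tv) / tv
        return res

    current = spec
    state = fixed_point_estimate(current, rates0=dict(targets.rates))
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        res = residual_map(state)
        if all(abs(v) <= rtol for v in res.values()):
            converged = True
            break
        for key in free:
            proj = current.projection(key)
            f_src = targets.rates.get(proj.source, state.rates[proj.source])
            value = _solve_release(proj, targets.concentrations[key], f_src)
            if isinstance(proj.kinetics, ReleaseKineticsMM):
                kin = replace(proj.kinetics, release_per_stimulus=value)
            else:
                kin = replace(proj.kinetics, rise=value)
            current = current.with_projection(key, kinetics=kin)
        state = fixed_point_estimate(current, rates0=dict(state.rates))

    res = residual_map(state)
    converged = all(abs(v) <= rtol for v in res.values())
    if not converged:
        raise CalibrationError(
            f"calibration did not meet targets after {iterations} iterations; "
            f"last relative residuals: { {k: round(v, 6) for k, v in res.items()} }"
        )

    if verify:
        vcfg = cfg or SimulationConfig(dt=0.02, duration=2000.0, stride=1000)
        state = steady_state(current, init=state, cfg=vcfg)
        res = residual_map(state)

    achieved = BaselineTargets(
        rates=dict(state.rates),
        concentrations=dict(state.concentrations),
    )
    return CalibrationResult(
        spec=current, achieved=achieved, iterations=iterations,
        residuals=res, converged=converged,
    )
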