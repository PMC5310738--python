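"""Forward-Euler time integration, steady-state detection and trajectories.

The integrator is the plain first-order forward Euler scheme at a default
step of 1 ms; higher-order schemes are deliberately out of scope.  A circuit
is "compiled" once into flat numpy arrays so the per-step cost is a handful
of vectorised operations regardless of circuit size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .dynamics import UnboundedReleaseError
from .model import (
    C_FLOOR,
    CircuitSpec,
    CircuitState,
    CircuitValidationError,
    ReleaseKineticsMM,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "ConvergenceError",
    "DivergenceError",
    "simulate",
    "steady_state",
    "state_columns",
]

#: K_m used to embed the linear decay law in the Michaelis-Menten uptake
#: expression inside the compiled stepper: v*c/(k+c) with k = 1e12 nM and
#: v = decay*k reproduces decay*c to ~c/1e12 relative error.
_LINEAR_KM = 1e12


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and convergence settings.

    Convergence requires every |derivative| to stay below its per-quantity
    tolerance (nM/s, pA/s, Hz/s) for ``sustain`` contiguous simulated seconds.
    ``seed`` is accepted for forward compatibility with stochastic
    extensions; the core integrator is deterministic and ignores it.
    """

    dt: float = 0.001  # s
    duration: float = 600.0  # s
    tol_conc: float = 1e-6  # nM/s
    tol_current: float = 1e-6  # pA/s
    tol_rate: float = 1e-6  # Hz/s
    sustain: float = 1.0  # s
    stride: int = 100  # record every stride-th step
    overflow: float = 1e12
    seed: int | None = None

    def __post_init__(self):
        if not self.dt > 0:
            raise CircuitValidationError(f"dt must be > 0, got {self.dt}")
        if not (self.tol_conc > 0 and self.tol_current > 0 and self.tol_rate > 0):
            raise CircuitValidationError("steady-state tolerances must be > 0")
        if self.stride < 1:
            raise CircuitValidationError("stride must be >= 1")


class ConvergenceError(RuntimeError):
    """The simulation did not reach a steady state within the configured duration."""


class DivergenceError(RuntimeError):
    """A state component exceeded the overflow guard."""


def state_columns(spec: CircuitSpec) -> list[str]:
    """Deterministic column order for trajectory/state tables.

    ``rate_<population>`` in declaration order, then ``current_<src>-><tgt>``
    per current-coupled projection, then ``conc_<src>-><tgt>`` for every
    projection.  The species tag is appended only if (source, target) alone
    would be ambiguous.
    """
    pairs = [(p.source, p.target) for p in spec.projections]
    dup = {pair for pair in pairs if pairs.count(pair) > 1}

    def label(p):
        base = f"{p.source}->{p.target}"
        return f"{base}_{p.species}" if (p.source, p.target) in dup else base

    cols = [f"rate_{p.name}" for p in spec.populations]
    cols += [f"current_{label(p)}" for p in spec.current_projections]
    cols += [f"conc_{label(p)}" for p in spec.projections]
    return cols


@dataclass
class Trajectory:
    """Recorded simulation output on a uniform time grid."""

    times: np.ndarray  # (T,)
    values: np.ndarray  # (T, n_components) in state_columns order
    columns: list[str]
    spec: CircuitSpec
    converged: bool
    convergence_time: float | None

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "time", self.times)
        return df

    def terminal_state(self) -> CircuitState:
        return _row_to_state(self.spec, self.times[-1], self.values[-1])


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

class _Compiled:
    """Flat-array view of a circuit for the inner Euler loop."""

    def __init__(self, spec: CircuitSpec):
        spec.validate()
        self.spec = spec
        pops = spec.populations
        self.pop_index = {p.name: i for i, p in enumerate(pops)}
        self.gain = np.array([p.gain for p in pops])
        self.thr_bias = np.array([-p.threshold + p.bias for p in pops])
        self.clamp_idx = np.array(
            [i for i, p in enumerate(pops) if p.clamped_rate is not None], dtype=int
        )
        self.clamp_val = np.array(
            [p.clamped_rate for p in pops if p.clamped_rate is not None]
        )

        projs = spec.projections
        self.projs = projs
        self.n_proj = len(projs)
        self.src = np.array([self.pop_index[p.source] for p in projs], dtype=int)
        self.tau = np.array([p.tau for p in projs])
        self.lo = np.array([p.response.lower for p in projs])
        self.span = np.array([p.response.upper - p.response.lower for p in projs])
        self.shift = np.array([p.response.shift for p in projs])
        self.slope = np.array([p.response.slope for p in projs])

        is_mm = np.array(
            [isinstance(p.kinetics, ReleaseKineticsMM) for p in projs], dtype=bool
        )
        self.is_mm = is_mm
        self.yp = np.array(
            [
                p.kinetics.release_per_stimulus if m else p.kinetics.rise
                for p, m in zip(projs, is_mm)
            ]
        )
        self.vmax = np.array(
            [
                p.kinetics.v_max if m else p.kinetics.decay * _LINEAR_KM
                for p, m in zip(projs, is_mm)
            ]
        )
        self.km = np.array(
            [p.kinetics.k_m if m else _LINEAR_KM for p, m in zip(projs, is_mm)]
        )
        # Unbounded-release guard (genuine MM projections only): rho >= 1 is
        # only an error once the concentration has also run far past uptake
        # saturation — transient rho >= 1 crossings with bounded
        # concentrations are legitimate dynamics.
        self.vmax_guard = np.where(is_mm, self.vmax, np.inf)
        self.km_guard = np.where(is_mm, 10.0 * self.km, np.inf)

        self.cm = np.array([p.coupling == "current" for p in projs], dtype=bool)
        self.cm_idx = np.flatnonzero(self.cm)
        self.dr_idx = np.flatnonzero(~self.cm)
        self.tau_cm = self.tau[self.cm_idx]
        self.tau_dr = self.tau[self.dr_idx]
        self.dr_pop = np.array(
            [self.pop_index[projs[i].target] for i in self.dr_idx], dtype=int
        )
        # incidence: population x current-coupled projection
        self.M = np.zeros((len(pops), len(self.cm_idx)))
        for col, i in enumerate(self.cm_idx):
            self.M[self.pop_index[projs[i].target], col] = 1.0
        # populations whose rate is algebraic (not clamped, not rate-coupled)
        alg = np.ones(len(pops), dtype=bool)
        alg[self.clamp_idx] = False
        alg[self.dr_pop] = False
        self.alg = alg

    # -- state packing ---------------------------------------------------
    def pack(self, state: CircuitState):
        c = np.array([state.concentrations[p.key] for p in self.projs])
        i = np.array([state.currents[self.projs[k].key] for k in self.cm_idx])
        fdyn = np.array([state.rates[self.projs[k].target] for k in self.dr_idx])
        return c, i, fdyn

    def rates(self, i, fdyn):
        f = self.gain * np.maximum(self.M @ i + self.thr_bias, 0.0)
        if self.clamp_idx.size:
            f[self.clamp_idx] = self.clamp_val
        if self.dr_pop.size:
            f[self.dr_pop] = fdyn
        return f

    def response(self, c):
        logc = np.log10(np.maximum(c, C_FLOOR))
        return self.lo + self.span * expit((logc - self.shift) / self.slope)

    def unpack(self, t, c, i, fdyn) -> CircuitState:
        f = self.rates(i, fdyn)
        return CircuitState(
            time=float(t),
            rates={p.name: float(f[k]) for k, p in enumerate(self.spec.populations)},
            currents={self.projs[k].key: float(v) for k, v in zip(self.cm_idx, i)},
            concentrations={p.key: float(v) for p, v in zip(self.projs, c)},
        )

    def row(self, c, i, fdyn):
        return np.concatenate([self.rates(i, fdyn), i, c])


def _row_to_state(spec: CircuitSpec, t: float, row: np.ndarray) -> CircuitState:
    npop = len(spec.populations)
    ncm = len(spec.current_projections)
    rates = {p.name: float(row[k]) for k, p in enumerate(spec.populations)}
    currents = {
        p.key: float(row[npop + k]) for k, p in enumerate(spec.current_projections)
    }
    concs = {
        p.key: float(row[npop + ncm + k]) for k, p in enumerate(spec.projections)
    }
    return CircuitState(time=t, rates=rates, currents=currents, concentrations=concs)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def simulate(
    spec: CircuitSpec,
    init: CircuitState | None = None,
    cfg: SimulationConfig | None = None,
    stop_on_converged: bool = True,
) -> Trajectory:
    """Forward-Euler trajectory from ``init`` (zeros if omitted).

    Concentrations (and rate-coupled rates) are clamped at zero after each
    step; Euler can overshoot into negative territory when reuptake is large.
    Integration stops early once every |derivative| has stayed below its
    tolerance for ``cfg.sustain`` seconds (unless ``stop_on_converged`` is
    False, in which case the full duration is integrated and the convergence
    flag reports whether the criterion was met at the end).
    """
    cfg = cfg or SimulationConfig()
    comp = _Compiled(spec)
    if init is None:
        init = CircuitState.zeros(spec)
    init.validate(spec)
    c, i, fdyn = comp.pack(init)

    dt = cfg.dt
    n_steps = max(int(round(cfg.duration / dt)), 1)
    sustain_steps = max(int(round(cfg.sustain / dt)), 1)

    rec_rows = [comp.row(c, i, fdyn)]
    rec_times = [init.time]

    below = 0
    converged = False
    conv_time: float | None = None
    t = init.time
    for step in range(1, n_steps + 1):
        f = comp.rates(i, fdyn)
        fsrc = f[comp.src]
        release = comp.yp * fsrc
        runaway = (release >= comp.vmax_guard) & (c > comp.km_guard)
        if np.any(runaway):
            k = int(np.argmax(runaway))
            raise UnboundedReleaseError(
                f"projection {comp.projs[k].key}: release {release[k]:.4g} nM/s >= "
                f"V_max {comp.vmax[k]:.4g} nM/s (rho >= 1) with concentration "
                f"{c[k]:.4g} nM far past uptake saturation at t = {t:.3f} s"
            )
        dc = release - comp.vmax * c / (comp.km + c)
        g = comp.response(c)
        di = (g[comp.cm_idx] - i) / comp.tau_cm
        dfd = (g[comp.dr_idx] - fdyn) / comp.tau_dr

        c = np.maximum(c + dt * dc, 0.0)
        i = i + dt * di
        fdyn = np.maximum(fdyn + dt * dfd, 0.0)
        t = init.time + step * dt

        # convergence bookkeeping (tolerance-normalised max derivative)
        r = 0.0
        if dc.size:
            r = max(r, float(np.max(np.abs(dc))) / cfg.tol_conc)
        if di.size:
            r = max(r, float(np.max(np.abs(di))) / cfg.tol_current)
        if dfd.size:
            r = max(r, float(np.max(np.abs(dfd))) / cfg.tol_rate)
        below = below + 1 if r < 1.0 else 0

        if step % cfg.stride == 0 or (below >= sustain_steps and stop_on_converged):
            rec_rows.append(comp.row(c, i, fdyn))
            rec_times.append(t)

        if below >= sustain_steps:
            converged = True
            conv_time = t
            if stop_on_converged:
                break

        if step % 256 == 0:
            m = max(
                float(np.max(np.abs(c))) if c.size else 0.0,
                float(np.max(np.abs(i))) if i.size else 0.0,
            )
            if m > cfg.overflow:
                bad = comp.projs[int(np.argmax(np.abs(c)))].key
                raise DivergenceError(
                    f"state magnitude exceeded {cfg.overflow:g} at t = {t:.3f} s "
                    f"(around projection {bad})"
                )

    if rec_times[-1] != t:
        rec_rows.append(comp.row(c, i, fdyn))
        rec_times.append(t)

    return Trajectory(
        times=np.array(rec_times),
        values=np.vstack(rec_rows),
        columns=state_columns(spec),
        spec=spec,
        converged=converged,
        convergence_time=conv_time,
    )


def steady_state(
    spec: CircuitSpec,
    init: CircuitState | None = None,
    cfg: SimulationConfig | None = None,
) -> CircuitState:
    """Converged terminal state, or ConvergenceError if not reached in time."""
    cfg = cfg or SimulationConfig()
    traj = simulate(spec, init=init, cfg=cfg)
    if not traj.converged:
        raise ConvergenceError(
            f"no steady state within {cfg.duration} s "
            f"(tolerances conc {cfg.tol_conc} nM/s, current {cfg.tol_current} pA/s, "
            f"rate {cfg.tol_rate} Hz/s sustained {cfg.sustain} s)"
        )
    return traj.terminal_state()
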