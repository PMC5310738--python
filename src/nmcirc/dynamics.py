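"""Right-hand sides of the coupled circuit ODEs and their closed-form steady states.

Population rates are treated algebraically (the firing-rate time constant,
tens of milliseconds, is far below the neuromodulator-induced time constants
of seconds to a minute), except for populations driven through the reduced
rate-coupled mode, whose rate is itself a slow dynamical variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CircuitSpec,
    CircuitState,
    CircuitValidationError,
    ProjectionSpec,
    ReleaseKineticsLinear,
    ReleaseKineticsMM,
    SigmoidParams,
    sigmoid_response,
    threshold_linear,
)

__all__ = [
    "DerivativeBundle",
    "UnboundedReleaseError",
    "current_rhs",
    "mm_release_rhs",
    "linear_release_rhs",
    "direct_rate_rhs",
    "circuit_rhs",
    "mm_steady_state",
    "linear_steady_state",
    "algebraic_rates",
]


class UnboundedReleaseError(RuntimeError):
    """Michaelis-Menten release exceeds the maximum reuptake rate (rho >= 1).

    When per-stimulus release times the source rate reaches V_max the reuptake
    term can never balance release and the concentration grows without bound.
    """


@dataclass
class DerivativeBundle:
    """Time derivatives of every dynamical component, keyed like CircuitState."""

    currents: dict[str, float]  # pA/s, current-coupled projections
    concentrations: dict[str, float]  # nM/s, all projections
    rates: dict[str, float]  # Hz/s, rate-coupled target populations only

    def max_abs(self) -> float:
        vals = (
            list(self.currents.values())
            + list(self.concentrations.values())
            + list(self.rates.values())
        )
        return max((abs(v) for v in vals), default=0.0)


def current_rhs(i: float, c: float, sp: SigmoidParams, tau: float) -> float:
    """dI/dt = (-I + G([y]))/tau for a neuromodulator-induced current (pA/s)."""
    if not tau > 0:
        raise CircuitValidationError(f"tau must be > 0, got {tau}")
    return (-i + sigmoid_response(c, sp)) / tau


def mm_release_rhs(c: float, f_source: float, kin: ReleaseKineticsMM) -> float:
    """d[y]/dt = y_p*f - V_max*[y]/(K_m + [y])  (nM/s)."""
    return kin.release_per_stimulus * f_source - kin.v_max * c / (kin.k_m + c)


def linear_release_rhs(c: float, f_source: float, kin: ReleaseKineticsLinear) -> float:
    """d[y]/dt = rise*f - decay*[y]  (nM/s)."""
    return kin.rise * f_source - kin.decay * c


def direct_rate_rhs(f: float, c: float, sp: SigmoidParams, tau: float) -> float:
    """df/dt = (-f + K([y]))/tau for the reduced rate-coupled form (Hz/s)."""
    if not tau > 0:
        raise CircuitValidationError(f"tau must be > 0, got {tau}")
    if sp.mode != "rate":
        raise CircuitValidationError("direct_rate_rhs requires a rate-mode sigmoid")
    return (-f + sigmoid_response(c, sp)) / tau


# ---------------------------------------------------------------------------
# Closed-form per-projection steady states (the oracles the simulator is
# checked against)
# ---------------------------------------------------------------------------

def mm_steady_state(f_source: float, kin: ReleaseKineticsMM) -> float:
    """Steady concentration K_m*rho/(1-rho), rho = y_p*f/V_max; requires rho < 1."""
    rho = kin.release_per_stimulus * f_source / kin.v_max
    if rho >= 1:
        raise UnboundedReleaseError(
            f"release/reuptake ratio rho = {rho:.4g} >= 1: no finite steady state"
        )
    return kin.k_m * rho / (1.0 - rho)


def linear_steady_state(f_source: float, kin: ReleaseKineticsLinear) -> float:
    """Steady concentration rise*f/decay."""
    return kin.rise * f_source / kin.decay


# ---------------------------------------------------------------------------
# Whole-circuit assembly
# ---------------------------------------------------------------------------

def algebraic_rates(spec: CircuitSpec, state: CircuitState) -> dict[str, float]:
    """Instantaneous rates: threshold-linear on summed incoming currents.

    Clamped populations return their clamp value; rate-coupled targets return
    the dynamical rate stored in the state.
    """
    rate_targets = {p.target for p in spec.rate_projections}
    rates: dict[str, float] = {}
    for pop in spec.populations:
        if pop.clamped_rate is not None:
            rates[pop.name] = pop.clamped_rate
        elif pop.name in rate_targets:
            rates[pop.name] = state.rates[pop.name]
        else:
            i_total = sum(
                state.currents[p.key]
                for p in spec.projections_into(pop.name)
                if p.coupling == "current"
            )
            rates[pop.name] = threshold_linear(i_total, pop)
    return rates


def circuit_rhs(state: CircuitState, spec: CircuitSpec) -> DerivativeBundle:
    """Assemble all derivatives at ``state``.

    Rates are recomputed algebraically from the instantaneous currents before
    evaluating the release terms, so the bundle is a pure function of the
    dynamical variables (currents, concentrations, rate-coupled rates).
    """
    if not state.conforms_to(spec):
        raise CircuitValidationError("state does not conform to circuit spec")
    rates = algebraic_rates(spec, state)

    d_conc: dict[str, float] = {}
    d_curr: dict[str, float] = {}
    d_rate: dict[str, float] = {}
    for p in spec.projections:
        f_src = rates[p.source]
        c = state.concentrations[p.key]
        if isinstance(p.kinetics, ReleaseKineticsMM):
            d_conc[p.key] = mm_release_rhs(c, f_src, p.kinetics)
        else:
            d_conc[p.key] = linear_release_rhs(c, f_src, p.kinetics)
        if p.coupling == "current":
            d_curr[p.key] = current_rhs(state.currents[p.key], c, p.response, p.tau)
        else:
            d_rate[p.target] = direct_rate_rhs(
                state.rates[p.target], c, p.response, p.tau
            )
    return DerivativeBundle(currents=d_curr, concentrations=d_conc, rates=d_rate)
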