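"""Domain types for neuromodulator circuits and the static response functions.

A circuit is a set of neural *populations* (described by threshold-linear
frequency-current curves) coupled by *projections*: one neuromodulator species
travelling from a source population to a target population.  Each projection
carries

* a release/reuptake law turning source firing into an extracellular
  concentration (Michaelis-Menten reuptake, or a linear rise/decay form used
  when voltammetric data are unavailable), and
* a sigmoid concentration-response curve turning that concentration into an
  induced post-synaptic current (pA) or, in the reduced two-region coupling
  mode, directly into a target firing rate (Hz).

Units are normalised throughout: concentrations in nM, currents in pA, rates
in Hz, time in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Union

import numpy as np
from scipy.special import expit

__all__ = [
    "C_FLOOR",
    "PopulationSpec",
    "SigmoidParams",
    "ReleaseKineticsMM",
    "ReleaseKineticsLinear",
    "ProjectionSpec",
    "CircuitSpec",
    "CircuitState",
    "CircuitValidationError",
    "threshold_linear",
    "sigmoid_response",
]

#: Concentration floor (nM) applied before taking log10 in the sigmoid
#: response, so zero concentration maps to the lower asymptote.  It must lie
#: below every concentration a bundled circuit visits (the smallest baseline
#: in the three-region preset is ~1.1e-7 nM).
C_FLOOR = 1e-9


class CircuitValidationError(ValueError):
    """A circuit or one of its components violates a structural constraint."""


@dataclass(frozen=True)
class PopulationSpec:
    """Threshold-linear f-I description of one neural population.

    The population firing rate is ``gain * max(I_total - threshold + bias, 0)``
    where ``I_total`` is the summed neuromodulator-induced afferent current,
    ``threshold`` the current for non-zero firing and ``bias`` a constant
    afferent current from areas outside the modelled circuit.

    ``clamped_rate`` pins the population at a fixed firing rate regardless of
    input (used for open-loop calibration and single-pathway experiments).
    """

    name: str
    gain: float  # Hz/pA
    threshold: float  # pA
    bias: float = 0.0  # pA
    clamped_rate: float | None = None

    def validate(self) -> None:
        if not self.name:
            raise CircuitValidationError("population name must be non-empty")
        if not math.isfinite(self.gain) or self.gain < 0:
            raise CircuitValidationError(
                f"population {self.name!r}: gain must be finite and >= 0, got {self.gain}"
            )
        if self.clamped_rate is not None and self.clamped_rate < 0:
            raise CircuitValidationError(
                f"population {self.name!r}: clamped_rate must be >= 0"
            )


@dataclass(frozen=True)
class SigmoidParams:
    """Four-parameter logistic response curve in log10 concentration.

    ``lower`` and ``upper`` bound the response range (pA in ``current`` mode,
    Hz in ``rate`` mode); ``shift`` is the lateral position (log10 of nM) at
    which the response is halfway between the bounds and ``slope`` (> 0, in
    inverse log10-concentration units) sets the steepness.  Inhibitory
    responses are encoded by signed values (``upper`` < ``lower`` or both
    negative); there is no separate inhibition flag.
    """

    lower: float
    upper: float
    shift: float
    slope: float
    mode: str = "current"  # {"current", "rate"}

    def validate(self) -> None:
        if self.mode not in ("current", "rate"):
            raise CircuitValidationError(f"sigmoid mode must be 'current' or 'rate', got {self.mode!r}")
        if not (self.slope > 0) or not math.isfinite(self.slope):
            raise CircuitValidationError(f"sigmoid slope must be finite and > 0, got {self.slope}")
        for name in ("lower", "upper", "shift"):
            if not math.isfinite(getattr(self, name)):
                raise CircuitValidationError(f"sigmoid {name} must be finite")

    def __call__(self, c):
        return sigmoid_response(c, self)


@dataclass(frozen=True)
class ReleaseKineticsMM:
    """Release with saturating Michaelis-Menten reuptake.

    d[y]/dt = release_per_stimulus * f_source - v_max * [y] / (k_m + [y])

    ``release_per_stimulus`` ([y]_p, nM per Hz of source firing), ``v_max``
    (maximum uptake rate, nM/s) and ``k_m`` (concentration of half-maximal
    uptake, nM) are all strictly positive.
    """

    release_per_stimulus: float  # nM
    v_max: float  # nM/s
    k_m: float  # nM

    def validate(self) -> None:
        for name in ("release_per_stimulus", "v_max", "k_m"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise CircuitValidationError(f"MM kinetics: {name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class ReleaseKineticsLinear:
    """Two-parameter rise/decay release law, d[y]/dt = rise*f_source - decay*[y].

    Used where voltammetric reuptake measurements are unavailable (orexin in
    the bundled circuit).  ``rise`` (nM) >= 0; ``decay`` (1/s) > 0.
    """

    rise: float  # nM (per Hz of source firing)
    decay: float  # 1/s

    def validate(self) -> None:
        if not math.isfinite(self.rise) or self.rise < 0:
            raise CircuitValidationError(f"linear kinetics: rise must be finite and >= 0, got {self.rise}")
        if not math.isfinite(self.decay) or self.decay <= 0:
            raise CircuitValidationError(f"linear kinetics: decay must be finite and > 0, got {self.decay}")


ReleaseKinetics = Union[ReleaseKineticsMM, ReleaseKineticsLinear]


@dataclass(frozen=True)
class ProjectionSpec:
    """One neuromodulator pathway source -> target.

    ``coupling`` selects how the concentration acts on the target:

    * ``"current"`` — through a relaxing induced current with time constant
      ``tau`` (the general mechanism), response curve in current mode;
    * ``"rate"`` — the reduced two-region form in which the target rate itself
      relaxes towards the rate-mode response curve with time constant ``tau``.
    """

    source: str
    target: str
    species: str
    tau: float  # s
    response: SigmoidParams
    kinetics: ReleaseKinetics
    coupling: str = "current"  # {"current", "rate"}

    @property
    def key(self) -> str:
        return f"{self.species}:{self.source}->{self.target}"

    def validate(self) -> None:
        if not (self.tau > 0) or not math.isfinite(self.tau):
            raise CircuitValidationError(f"projection {self.key}: tau must be finite and > 0, got {self.tau}")
        if self.coupling not in ("current", "rate"):
            raise CircuitValidationError(
                f"projection {self.key}: coupling must be 'current' or 'rate', got {self.coupling!r}"
            )
        self.response.validate()
        expected_mode = "current" if self.coupling == "current" else "rate"
        if self.response.mode != expected_mode:
            raise CircuitValidationError(
                f"projection {self.key}: {self.coupling}-coupled projection requires a "
                f"{expected_mode}-mode response curve, got {self.response.mode!r}"
            )
        self.kinetics.validate()


@dataclass(frozen=True)
class CircuitSpec:
    """A validated collection of populations and projections."""

    populations: tuple[PopulationSpec, ...]
    projections: tuple[ProjectionSpec, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "projections", tuple(self.projections))

    # -- lookups ---------------------------------------------------------
    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def projection(self, key: str) -> ProjectionSpec:
        for p in self.projections:
            if p.key == key:
                return p
        raise KeyError(key)

    def projections_into(self, name: str) -> tuple[ProjectionSpec, ...]:
        return tuple(p for p in self.projections if p.target == name)

    # -- functional updates (specs are immutable) ------------------------
    def with_projection(self, key: str, **changes) -> "CircuitSpec":
        """Return a copy with the named projection's fields replaced."""
        new = tuple(
            replace(p, **changes) if p.key == key else p for p in self.projections
        )
        if new == self.projections and key not in [p.key for p in self.projections]:
            raise KeyError(key)
        return replace(self, projections=new)

    def validate(self) -> "CircuitSpec":
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise CircuitValidationError(f"duplicate population names: {sorted(names)}")
        for p in self.populations:
            p.validate()
        keys = [pr.key for pr in self.projections]
        if len(set(keys)) != len(keys):
            raise CircuitValidationError(f"duplicate projection (species, source, target): {sorted(keys)}")
        declared = set(names)
        for pr in self.projections:
            pr.validate()
            for end, role in ((pr.source, "source"), (pr.target, "target")):
                if end not in declared:
                    raise CircuitValidationError(
                        f"projection {pr.key}: {role} population {end!r} is not declared"
                    )
        # Coupling-mode consistency per target population.
        for name in declared:
            incoming = self.projections_into(name)
            modes = {pr.coupling for pr in incoming}
            if modes == {"current", "rate"}:
                raise CircuitValidationError(
                    f"population {name!r} receives both current- and rate-coupled "
                    "projections; mixed coupling onto one population is not supported"
                )
            if sum(pr.coupling == "rate" for pr in incoming) > 1:
                raise CircuitValidationError(
                    f"population {name!r} receives more than one rate-coupled projection; "
                    "at most one is supported"
                )
        return self

    # -- canonical component ordering ------------------------------------
    @property
    def current_projections(self) -> tuple[ProjectionSpec, ...]:
        return tuple(p for p in self.projections if p.coupling == "current")

    @property
    def rate_projections(self) -> tuple[ProjectionSpec, ...]:
        return tuple(p for p in self.projections if p.coupling == "rate")


@dataclass
class CircuitState:
    """All rates, induced currents and concentrations at one instant.

    ``currents`` is keyed by the current-coupled projections only;
    ``concentrations`` by every projection.  Keys are ``species:src->tgt``.
    """

    time: float
    rates: dict[str, float]
    currents: dict[str, float]
    concentrations: dict[str, float]

    @classmethod
    def zeros(cls, spec: CircuitSpec) -> "CircuitState":
        return cls(
            time=0.0,
            rates={p.name: 0.0 for p in spec.populations},
            currents={p.key: 0.0 for p in spec.current_projections},
            concentrations={p.key: 0.0 for p in spec.projections},
        )

    def conforms_to(self, spec: CircuitSpec) -> bool:
        return (
            set(self.rates) == {p.name for p in spec.populations}
            and set(self.currents) == {p.key for p in spec.current_projections}
            and set(self.concentrations) == {p.key for p in spec.projections}
        )

    def validate(self, spec: CircuitSpec) -> "CircuitState":
        if not self.conforms_to(spec):
            raise CircuitValidationError("state does not conform to circuit spec")
        for name, r in self.rates.items():
            if r < 0:
                raise CircuitValidationError(f"rate of {name!r} is negative: {r}")
        for key, c in self.concentrations.items():
            if c < 0:
                raise CircuitValidationError(f"concentration of {key} is negative: {c}")
        return self


# ---------------------------------------------------------------------------
# Static response functions
# ---------------------------------------------------------------------------

def threshold_linear(i_total, pop: PopulationSpec):
    """Population firing rate (Hz) for total afferent current ``i_total`` (pA).

    ``gain * [i_total - threshold + bias]_+`` — continuous, piecewise linear,
    exactly zero at and below threshold.  Accepts scalars or arrays.
    """
    x = np.asarray(i_total, dtype=float) - pop.threshold + pop.bias
    out = pop.gain * np.maximum(x, 0.0)
    return float(out) if np.isscalar(i_total) else out


def sigmoid_response(c, sp: SigmoidParams, floor: float = C_FLOOR):
    """Sigmoid concentration-response: logistic in log10 concentration.

    ``lower + (upper - lower) * expit((log10(max(c, floor)) - shift)/slope)``.
    Monotone non-decreasing in ``c`` for ``slope > 0`` and ``upper > lower``;
    values never leave ``[min(lower, upper), max(lower, upper)]``.
    """
    logc = np.log10(np.maximum(np.asarray(c, dtype=float), floor))
    out = sp.lower + (sp.upper - sp.lower) * expit((logc - sp.shift) / sp.slope)
    return float(out) if np.isscalar(c) else out
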