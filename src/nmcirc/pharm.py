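"""Declarative drug perturbations and steady-state dose scans.

Acute drug actions are modelled as pure transformations of a circuit spec:

* reuptake inhibitors (SSRI/NRI) scale the Michaelis-Menten K_m of every
  projection carrying the inhibited species (transporter affinity drops,
  V_max untouched);
* competitive antagonists shift a response curve laterally (ED50 grows, the
  maximum stays reachable);
* irreversible antagonists compress the response range towards the lower
  bound (maximum effect shrinks, ED50 location untouched);
* explicit overrides replace response-curve parameters verbatim, for drugs
  whose measured effect does not reduce to either idealised operator.

Chronic adaptations (receptor-density changes) are out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import pandas as pd

from .model import (
    CircuitSpec,
    CircuitState,
    CircuitValidationError,
    ReleaseKineticsMM,
)
from .simulate import SimulationConfig, state_columns, steady_state

__all__ = [
    "DrugPerturbation",
    "apply_drug",
    "km_scaling_family",
    "drug_response_scan",
]


@dataclass(frozen=True)
class DrugPerturbation:
    """One drug as a set of parameter transformations.

    ``km_factors`` maps a species name (or ``(species, target_population)``)
    to a positive K_m multiplier.  ``overrides`` maps a projection key to a
    dict of SigmoidParams field replacements (explicit-override class).
    ``shifts`` maps a projection key to an additive lateral shift in log10
    concentration (competitive class, positive = rightward/higher doses).
    ``range_scales`` maps a projection key to a factor in (0, 1] compressing
    ``upper`` towards ``lower`` (irreversible class).
    """

    name: str
    km_factors: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)
    shifts: dict = field(default_factory=dict)
    range_scales: dict = field(default_factory=dict)

    def validate(self, spec: CircuitSpec) -> None:
        for key, factor in self.km_factors.items():
            if not factor > 0:
                raise CircuitValidationError(
                    f"drug {self.name!r}: K_m factor for {key!r} must be > 0, got {factor}"
                )
        sig_fields = {"lower", "upper", "shift", "slope"}
        for key, repl in self.overrides.items():
            spec.projection(key)
            unknown = set(repl) - sig_fields
            if unknown:
                raise CircuitValidationError(
                    f"drug {self.name!r}: unknown sigmoid fields {sorted(unknown)} for {key}"
                )
        for key in self.shifts:
            spec.projection(key)
        for key, factor in self.range_scales.items():
            spec.projection(key)
            if not 0 < factor <= 1:
                raise CircuitValidationError(
                    f"drug {self.name!r}: range scale for {key} must be in (0, 1], got {factor}"
                )

    def is_identity(self) -> bool:
        return (
            all(f == 1 for f in self.km_factors.values())
            and not self.overrides
            and all(s == 0 for s in self.shifts.values())
            and all(f == 1 for f in self.range_scales.values())
        )


def _km_factor_for(drug: DrugPerturbation, species: str, target: str) -> float:
    factor = 1.0
    if species in drug.km_factors:
        factor *= drug.km_factors[species]
    if (species, target) in drug.km_factors:
        factor *= drug.km_factors[(species, target)]
    return factor


def apply_drug(spec: CircuitSpec, drug: DrugPerturbation) -> CircuitSpec:
    """Return a new spec with the drug's transformations applied; pure."""
    try:
        drug.validate(spec)
    except KeyError as exc:
        raise CircuitValidationError(
            f"drug {drug.name!r}: override references missing projection {exc.args[0]!r}"
        ) from None
    new_projs = []
    for p in spec.projections:
        q = p
        factor = _km_factor_for(drug, p.species, p.target)
        if factor != 1.0:
            if not isinstance(p.kinetics, ReleaseKineticsMM):
                raise CircuitValidationError(
                    f"drug {drug.name!r}: K_m factor targets {p.key}, which has no "
                    "Michaelis-Menten reuptake"
                )
            q = replace(q, kinetics=replace(p.kinetics, k_m=p.kinetics.k_m * factor))
        resp = q.response
        if p.key in drug.shifts:
            resp = replace(resp, shift=resp.shift + drug.shifts[p.key])
        if p.key in drug.range_scales:
            s = drug.range_scales[p.key]
            resp = replace(resp, upper=resp.lower + s * (resp.upper - resp.lower))
        if p.key in drug.overrides:
            resp = replace(resp, **drug.overrides[p.key])
        if resp is not q.response:
            q = replace(q, response=resp)
        new_projs.append(q)
    return replace(spec, projections=tuple(new_projs)).validate()


def apply_drugs(spec: CircuitSpec, drugs) -> CircuitSpec:
    """Apply a drug combination sequentially (order-independent when the
    drugs touch disjoint parameters)."""
    for d in drugs:
        spec = apply_drug(spec, d)
    return spec


def km_scaling_family(species: str, name: str | None = None):
    """Parameterised reuptake-inhibitor family: level -> K_m x level drug."""

    def make(level: float) -> DrugPerturbation:
        return DrugPerturbation(
            name=name or f"{species}-reuptake-inhibitor-x{level:g}",
            km_factors={species: float(level)},
        )

    return make


def drug_response_scan(
    spec: CircuitSpec,
    family,
    levels,
    cfg: SimulationConfig | None = None,
    init: CircuitState | None = None,
    second: tuple | None = None,
) -> pd.DataFrame:
    """Steady-state table over drug levels (optionally a two-family grid).

    ``family`` maps a level to a DrugPerturbation.  When ``second`` is a
    ``(family2, levels2)`` pair, the scan covers the full cross product and
    the drugs are applied sequentially.  Each steady state is warm-started
    from the previous one along the scan.  A non-converged level aborts the
    scan, naming the level.
    """
    levels = list(levels)
    rows = []
    cols = state_columns(spec)
    if second is None:
        grid = [(lv,) for lv in levels]
        families = (family,)
        level_names = ["level"]
    else:
        family2, levels2 = second
        grid = list(itertools.product(levels, list(levels2)))
        families = (family, family2)
        level_names = ["level", "level2"]

    prev = init
    for combo in grid:
        drugged = spec
        for fam, lv in zip(families, combo):
            drugged = apply_drug(drugged, fam(lv))
        try:
            ss = steady_state(drugged, init=prev, cfg=cfg)
        except Exception as exc:
            raise RuntimeError(f"drug scan failed at level {combo}: {exc}") from exc
        prev = ss
        row = dict(zip(level_names, combo))
        vals = (
            [ss.rates[p.name] for p in spec.populations]
            + [ss.currents[p.key] for p in spec.current_projections]
            + [ss.concentrations[p.key] for p in spec.projections]
        )
        row.update(dict(zip(cols, vals)))
        rows.append(row)
    return pd.DataFrame(rows, columns=level_names + cols)
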