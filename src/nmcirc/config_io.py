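"""YAML circuit-configuration reading/writing, CSV export and run manifests.

One documented dialect: a top-level ``circuit`` mapping with ``populations``
and ``projections`` lists, plus optional ``simulation`` and ``drugs``
sections.  The writer is canonical (sorted keys, block style, full-precision
floats), so ``write(read(write(read(p))))`` is byte-stable after one
normalisation pass.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from .calibrate import BaselineTargets
from .model import (
    CircuitSpec,
    CircuitState,
    CircuitValidationError,
    PopulationSpec,
    ProjectionSpec,
    ReleaseKineticsLinear,
    ReleaseKineticsMM,
    SigmoidParams,
)
from .pharm import DrugPerturbation
from .simulate import SimulationConfig

__all__ = [
    "ConfigBundle",
    "RunManifest",
    "read_config",
    "write_config",
    "circuit_to_dict",
    "circuit_from_dict",
]


@dataclass
class ConfigBundle:
    circuit: CircuitSpec
    drugs: dict[str, DrugPerturbation]
    simulation: SimulationConfig | None
    baselines: BaselineTargets | None = None


# ---------------------------------------------------------------------------
# to/from plain dicts
# ---------------------------------------------------------------------------

def _pop_to_dict(p: PopulationSpec) -> dict:
    d = {"name": p.name, "gain": p.gain, "threshold": p.threshold, "bias": p.bias}
    if p.clamped_rate is not None:
        d["clamped_rate"] = p.clamped_rate
    return d


def _sig_to_dict(s: SigmoidParams) -> dict:
    return {"lower": s.lower, "upper": s.upper, "shift": s.shift,
            "slope": s.slope, "mode": s.mode}


def _kin_to_dict(k) -> dict:
    if isinstance(k, ReleaseKineticsMM):
        return {"kind": "michaelis-menten", "release_per_stimulus": k.release_per_stimulus,
                "v_max": k.v_max, "k_m": k.k_m}
    return {"kind": "linear", "rise": k.rise, "decay": k.decay}


def _proj_to_dict(p: ProjectionSpec) -> dict:
    return {
        "source": p.source, "target": p.target, "species": p.species,
        "coupling": p.coupling, "tau": p.tau,
        "response": _sig_to_dict(p.response), "kinetics": _kin_to_dict(p.kinetics),
    }


def circuit_to_dict(spec: CircuitSpec) -> dict:
    return {
        "populations": [_pop_to_dict(p) for p in spec.populations],
        "projections": [_proj_to_dict(p) for p in spec.projections],
    }


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise CircuitValidationError(f"{where}: missing key {key!r}")
    return d[key]


def _kin_from_dict(d: dict, where: str):
    kind = _require(d, "kind", where)
    if kind == "michaelis-menten":
        return ReleaseKineticsMM(
            release_per_stimulus=float(_require(d, "release_per_stimulus", where)),
            v_max=float(_require(d, "v_max", where)),
            k_m=float(_require(d, "k_m", where)),
        )
    if kind == "linear":
        return ReleaseKineticsLinear(
            rise=float(_require(d, "rise", where)), decay=float(_require(d, "decay", where))
        )
    raise CircuitValidationError(f"{where}: unknown kinetics kind {kind!r}")


def circuit_from_dict(d: dict) -> CircuitSpec:
    pops = []
    for pd_ in _require(d, "populations", "circuit"):
        where = f"population {pd_.get('name', '?')!r}"
        pops.append(
            PopulationSpec(
                name=str(_require(pd_, "name", where)),
                gain=float(_require(pd_, "gain", where)),
                threshold=float(_require(pd_, "threshold", where)),
                bias=float(pd_.get("bias", 0.0)),
                clamped_rate=(None if pd_.get("clamped_rate") is None
                              else float(pd_["clamped_rate"])),
            )
        )
    projs = []
    for jd in d.get("projections", []):
        where = (f"projection {jd.get('species', '?')}:"
                 f"{jd.get('source', '?')}->{jd.get('target', '?')}")
        rd = _require(jd, "response", where)
        projs.append(
            ProjectionSpec(
                source=str(_require(jd, "source", where)),
                target=str(_require(jd, "target", where)),
                species=str(_require(jd, "species", where)),
                tau=float(_require(jd, "tau", where)),
                coupling=str(jd.get("coupling", "current")),
                response=SigmoidParams(
                    lower=float(_require(rd, "lower", where)),
                    upper=float(_require(rd, "upper", where)),
                    shift=float(_require(rd, "shift", where)),
                    slope=float(_require(rd, "slope", where)),
                    mode=str(rd.get("mode", "current")),
                ),
                kinetics=_kin_from_dict(_require(jd, "kinetics", where), where),
            )
        )
    return CircuitSpec(populations=tuple(pops), projections=tuple(projs)).validate()


def _drug_to_dict(d: DrugPerturbation) -> dict:
    out: dict = {"name": d.name}
    if d.km_factors:
        out["km_factors"] = {
            (k if isinstance(k, str) else f"{k[0]}@{k[1]}"): v for k, v in d.km_factors.items()
        }
    if d.overrides:
        out["overrides"] = {k: dict(v) for k, v in d.overrides.items()}
    if d.shifts:
        out["shifts"] = dict(d.shifts)
    if d.range_scales:
        out["range_scales"] = dict(d.range_scales)
    return out


def _drug_from_dict(d: dict) -> DrugPerturbation:
    km = {}
    for k, v in d.get("km_factors", {}).items():
        km[tuple(k.split("@", 1)) if "@" in k else k] = float(v)
    return DrugPerturbation(
        name=str(_require(d, "name", "drug")),
        km_factors=km,
        overrides={k: {fk: float(fv) for fk, fv in v.items()}
                   for k, v in d.get("overrides", {}).items()},
        shifts={k: float(v) for k, v in d.get("shifts", {}).items()},
        range_scales={k: float(v) for k, v in d.get("range_scales", {}).items()},
    )


def _sim_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    if d.get("seed") is None:
        d.pop("seed")
    return d


# ---------------------------------------------------------------------------
# File-level read/write
# ---------------------------------------------------------------------------

def read_config(path) -> ConfigBundle:
    """Read and validate a circuit configuration; errors name the offending key."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise CircuitValidationError(f"cannot parse {path}: {exc}") from None
    if not isinstance(doc, dict) or "circuit" not in doc:
        raise CircuitValidationError(f"{path}: missing top-level 'circuit' section")
    circuit = circuit_from_dict(doc["circuit"])
    drugs = {d["name"]: _drug_from_dict(d) for d in doc.get("drugs", [])}
    for drug in drugs.values():
        drug.validate(circuit)
    sim = SimulationConfig(**doc["simulation"]) if "simulation" in doc else None
    baselines = None
    if "baselines" in doc:
        b = doc["baselines"]
        baselines = BaselineTargets(
            rates={k: float(v) for k, v in b.get("rates", {}).items()},
            concentrations={k: float(v) for k, v in b.get("concentrations", {}).items()},
        )
    return ConfigBundle(circuit=circuit, drugs=drugs, simulation=sim, baselines=baselines)


class _CanonicalDumper(yaml.SafeDumper):
    pass


def _float_representer(dumper, value):
    # repr() round-trips doubles exactly and is stable across runs
    return dumper.represent_scalar("tag:yaml.org,2002:float", repr(float(value)))


_CanonicalDumper.add_representer(float, _float_representer)
_CanonicalDumper.add_multi_representer(np.floating, _float_representer)


def write_config(
    path,
    circuit: CircuitSpec,
    drugs: dict[str, DrugPerturbation] | None = None,
    simulation: SimulationConfig | None = None,
    baselines: BaselineTargets | None = None,
) -> None:
    doc: dict = {"circuit": circuit_to_dict(circuit)}
    if drugs:
        doc["drugs"] = [_drug_to_dict(d) for _, d in sorted(drugs.items())]
    if simulation is not None:
        doc["simulation"] = _sim_to_dict(simulation)
    if baselines is not None:
        doc["baselines"] = {
            "rates": dict(sorted(baselines.rates.items())),
            "concentrations": dict(sorted(baselines.concentrations.items())),
        }
    text = yaml.dump(doc, Dumper=_CanonicalDumper, sort_keys=True,
                     default_flow_style=False, width=100)
    Path(path).write_text(text)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to replay a run bit-identically."""

    config_path: str
    drugs: list[str]
    simulation: dict
    outputs: list[str]
    package_version: str
    timestamp: str

    @classmethod
    def create(cls, config_path, drugs, cfg: SimulationConfig, outputs) -> "RunManifest":
        from . import __version__

        return cls(
            config_path=str(config_path),
            drugs=list(drugs),
            simulation=_sim_to_dict(cfg),
            outputs=[str(o) for o in outputs],
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
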