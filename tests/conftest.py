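"""Shared fixtures: the calibrated three-region preset and small test circuits."""

from __future__ import annotations

import numpy as np
import pytest

from nmcirc import (
    CircuitSpec,
    CircuitState,
    PopulationSpec,
    ProjectionSpec,
    ReleaseKineticsLinear,
    ReleaseKineticsMM,
    SigmoidParams,
    SimulationConfig,
)
from nmcirc.pharm import km_scaling_family, drug_response_scan
from nmcirc.preset import baseline_state, build_preset

#: Integration settings for long preset runs (coarser step than the 1 ms
#: default, still well inside the Euler stability limit set by the fastest
#: reuptake rate ~10.6/s).
COARSE = SimulationConfig(dt=0.05, duration=40000.0, stride=2000)


@pytest.fixture(scope="session")
def preset():
    return build_preset()


@pytest.fixture(scope="session")
def preset_init(preset):
    return baseline_state(preset)


@pytest.fixture(scope="session")
def ssri_scan(preset, preset_init):
    """Steady states of the preset under K_m,5-HT scaling 1..5 (warm-started)."""
    return drug_response_scan(
        preset.circuit, km_scaling_family("5-HT"), [1, 2, 3, 4, 5],
        cfg=COARSE, init=preset_init,
    )


def single_projection_circuit(kinetics, source_rate=2.0, response=None, tau=1.0):
    """Clamped source A -> sink B through one projection; minimal test circuit."""
    response = response or SigmoidParams(0.0, 1.0, 0.0, 0.5)
    return CircuitSpec(
        populations=(
            PopulationSpec("A", gain=1.0, threshold=0.0, clamped_rate=source_rate),
            PopulationSpec("B", gain=0.1, threshold=0.0, bias=0.0),
        ),
        projections=(
            ProjectionSpec(
                source="A", target="B", species="y", tau=tau,
                response=response, kinetics=kinetics,
            ),
        ),
    ).validate()


@pytest.fixture
def mm_circuit():
    kin = ReleaseKineticsMM(release_per_stimulus=12.14, v_max=1800.0, k_m=170.0)
    return single_projection_circuit(kin, source_rate=0.8)


@pytest.fixture
def linear_circuit():
    kin = ReleaseKineticsLinear(rise=0.2314, decay=0.85)
    return single_projection_circuit(kin, source_rate=2.15)
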