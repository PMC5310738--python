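"""Static response functions, domain-type validation, serialization round-trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmcirc import (
    CircuitSpec,
    CircuitValidationError,
    PopulationSpec,
    ProjectionSpec,
    ReleaseKineticsLinear,
    ReleaseKineticsMM,
    SigmoidParams,
    sigmoid_response,
    threshold_linear,
)
from nmcirc.config_io import circuit_from_dict, circuit_to_dict

LHA = PopulationSpec("LHA", gain=0.2, threshold=0.0, bias=11.5)
DRN = PopulationSpec("DRN", gain=0.033, threshold=24.82, bias=24.82)
OX_LC = SigmoidParams(lower=3.8, upper=54.0, shift=-2.3, slope=0.341)


class TestThresholdLinear:
    @pytest.mark.parametrize(
        "pop, current, expected",
        [
            # below-threshold currents rectify to exactly zero
            (PopulationSpec("p", 0.5, 10.0, 0.0), 0.0, 0.0),
            (PopulationSpec("p", 0.5, 10.0, 0.0), 10.0, 0.0),
            # orexin neurons fire at their basal 2.3 Hz from bias current alone
            (LHA, 0.0, 2.3),
            # serotonergic basal rate recovered by inverting the f-I line:
            # I = 0.8 Hz / 0.033 Hz/pA with threshold and bias cancelling
            (DRN, 0.8 / 0.033, 0.8),
        ],
    )
    def test_values(self, pop, current, expected):
        assert threshold_linear(current, pop) == pytest.approx(expected, rel=1e-12)

    @given(
        gain=st.floats(0.0, 10.0),
        threshold=st.floats(-50, 50),
        bias=st.floats(-50, 50),
        i=st.floats(-200, 200),
        di=st.floats(0.0, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_nonneg_and_monotone(self, gain, threshold, bias, i, di):
        pop = PopulationSpec("p", gain=gain, threshold=threshold, bias=bias)
        f0, f1 = threshold_linear(i, pop), threshold_linear(i + di, pop)
        assert f0 >= 0.0
        assert f1 >= f0 - 1e-12
        # (numerically) zero at the threshold point itself
        assert threshold_linear(threshold - bias, pop) <= gain * 1e-9


class TestSigmoidResponse:
    def test_midpoint_is_half_range(self):
        # at c = 10**shift the logistic sits exactly halfway: (3.8+54)/2
        assert sigmoid_response(10 ** -2.3, OX_LC) == pytest.approx(28.9, abs=1e-12)

    def test_asymptotes(self):
        assert sigmoid_response(1e12, OX_LC) == pytest.approx(54.0, abs=1e-6)
        # far-left curve evaluated at the concentration floor ~ lower bound
        sp = SigmoidParams(lower=3.8, upper=54.0, shift=5.0, slope=0.341)
        assert sigmoid_response(0.0, sp) == pytest.approx(3.8, abs=1e-6)

    def test_degenerate_range_is_constant(self):
        sp = SigmoidParams(lower=-7.5, upper=-7.5, shift=0.0, slope=1.0)
        for c in [0.0, 1e-3, 1.0, 1e6]:
            assert sigmoid_response(c, sp) == -7.5

    @given(
        lower=st.floats(-100, 100),
        upper=st.floats(-100, 100),
        shift=st.floats(-9, 4),
        slope=st.floats(0.05, 3.0),
        c=st.lists(st.floats(0, 1e6), min_size=2, max_size=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone(self, lower, upper, shift, slope, c):
        sp = SigmoidParams(lower=lower, upper=upper, shift=shift, slope=slope)
        vals = sigmoid_response(np.sort(np.array(c)), sp)
        lo, hi = min(lower, upper), max(lower, upper)
        assert np.all(vals >= lo - 1e-9) and np.all(vals <= hi + 1e-9)
        if upper > lower:
            assert np.all(np.diff(vals) >= -1e-9)


class TestValidation:
    def test_duplicate_population_names_rejected(self):
        with pytest.raises(CircuitValidationError, match="duplicate population"):
            CircuitSpec(
                populations=(PopulationSpec("A", 1, 0), PopulationSpec("A", 1, 0))
            ).validate()

    def test_dangling_projection_endpoint_rejected(self):
        proj = ProjectionSpec(
            source="A", target="GHOST", species="y", tau=1.0,
            response=SigmoidParams(0, 1, 0, 1),
            kinetics=ReleaseKineticsLinear(rise=1.0, decay=1.0),
        )
        with pytest.raises(CircuitValidationError, match="GHOST"):
            CircuitSpec(populations=(PopulationSpec("A", 1, 0),),
                        projections=(proj,)).validate()

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(CircuitValidationError, match="tau"):
            ProjectionSpec(
                source="A", target="B", species="y", tau=0.0,
                response=SigmoidParams(0, 1, 0, 1),
                kinetics=ReleaseKineticsLinear(rise=1.0, decay=1.0),
            ).validate()

    def test_mixed_coupling_onto_one_population_rejected(self):
        pops = (
            PopulationSpec("A", 1, 0, clamped_rate=1.0),
            PopulationSpec("B", 1, 0),
        )
        kin = ReleaseKineticsLinear(rise=1.0, decay=1.0)
        projs = (
            ProjectionSpec("A", "B", "y1", 1.0, SigmoidParams(0, 1, 0, 1), kin),
            ProjectionSpec("A", "B", "y2", 1.0,
                           SigmoidParams(0, 1, 0, 1, mode="rate"), kin,
                           coupling="rate"),
        )
        with pytest.raises(CircuitValidationError, match="mixed coupling"):
            CircuitSpec(populations=pops, projections=projs).validate()

    def test_mm_parameters_strictly_positive(self):
        with pytest.raises(CircuitValidationError):
            ReleaseKineticsMM(release_per_stimulus=0.0, v_max=1.0, k_m=1.0).validate()


# -- serialization ----------------------------------------------------------

@st.composite
def circuits(draw):
    n_pop = draw(st.integers(2, 4))
    names = [f"P{i}" for i in range(n_pop)]
    finite = st.floats(-50, 50, allow_nan=False)
    pops = tuple(
        PopulationSpec(
            n, gain=draw(st.floats(0, 5)), threshold=draw(finite), bias=draw(finite),
            clamped_rate=draw(st.one_of(st.none(), st.floats(0, 10))),
        )
        for n in names
    )
    n_proj = draw(st.integers(0, 4))
    projs = []
    used = set()
    for k in range(n_proj):
        src, tgt = draw(st.sampled_from(names)), draw(st.sampled_from(names))
        key = (f"s{k}", src, tgt)
        if key in used:
            continue
        used.add(key)
        if draw(st.booleans()):
            kin = ReleaseKineticsMM(
                release_per_stimulus=draw(st.floats(0.01, 50)),
                v_max=draw(st.floats(1, 2000)), k_m=draw(st.floats(1, 500)),
            )
        else:
            kin = ReleaseKineticsLinear(
                rise=draw(st.floats(0, 10)), decay=draw(st.floats(0.01, 5))
            )
        projs.append(
            ProjectionSpec(
                source=src, target=tgt, species=f"s{k}",
                tau=draw(st.floats(0.1, 100)),
                response=SigmoidParams(
                    draw(finite), draw(finite), draw(st.floats(-9, 4)),
                    draw(st.floats(0.05, 3)),
                ),
                kinetics=kin,
            )
        )
    return CircuitSpec(populations=pops, projections=tuple(projs)).validate()


@given(spec=circuits())
@settings(max_examples=50, deadline=None)
def test_serialization_round_trip_identity(spec):
    assert circuit_from_dict(circuit_to_dict(spec)) == spec
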