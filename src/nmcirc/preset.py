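"""The bundled LHA-DRN-LC orexin/serotonin/norepinephrine circuit.

Three populations — orexin (Ox) neurons of the lateral hypothalamic area
(LHA), serotonin (5-HT) neurons of the dorsal raphe nucleus (DRN) and
norepinephrine (NE) neurons of the locus coeruleus (LC) — coupled by six
current-mediated projections:

    5-HT: DRN->LHA (inhibitory GIRK), DRN->LC (inhibitory)
    NE:   LC->DRN (excitatory),       LC->LHA (inhibitory GIRK)
    Ox:   LHA->DRN (excitatory),      LHA->LC (excitatory)

Parameter sources fall in four provenance classes:

* ``reported``   — published values installed verbatim (f-I parameters, time
                   constants, Michaelis-Menten V_max/K_m, basal rates and
                   concentrations, the Ox->LC response curve and the
                   Ox->DRN shift/slope);
* ``assumed``    — response-curve shape choices this package makes where no
                   numbers are published (shifts, slopes, saturation levels
                   of the remaining curves), constrained by the published
                   qualitative descriptions;
* ``anchored``   — curve bounds solved in closed form at build time so the
                   published basal state is an exact current-balance fixed
                   point of the coupled circuit;
* ``calibrated`` — the free per-stimulus release parameters (four y_p, two
                   rise factors), re-tuned by ``calibrate_release`` so the
                   steady concentrations meet the basal targets; published
                   seed values are kept in ``seed_release``.

All concentrations are stored in nM.  Two rows of the basal table are
printed elsewhere on other scales and are re-expressed here: basal NE at the
DRN, 500 pg/mg ~ 2.95 uM = 2950 nM; basal 5-HT at the LC, 6.7 fM/min ~ 0.11
fM/s, stored as 1.1e-7 nM (the display scale is kept in ``display_units``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .calibrate import (
    BaselineTargets,
    CalibrationResult,
    DoseResponseTable,
    calibrate_release,
)
from .model import (
    CircuitSpec,
    CircuitState,
    PopulationSpec,
    ProjectionSpec,
    ReleaseKineticsLinear,
    ReleaseKineticsMM,
    SigmoidParams,
    sigmoid_response,
)
from .pharm import DrugPerturbation
from .simulate import SimulationConfig

__all__ = [
    "PresetBundle",
    "SyntheticDoseResponseSpec",
    "build_preset",
    "baseline_state",
    "generate_dose_response",
]

# ---------------------------------------------------------------------------
# Published values (all "reported" provenance)
# ---------------------------------------------------------------------------

_POPS = {
    # name: (gain Hz/pA, threshold pA, bias pA, basal rate Hz)
    "LHA": (0.2, 0.0, 11.5, 2.3),
    "DRN": (0.033, 24.82, 24.82, 0.8),
    "LC": (0.058, 0.028, 37.41, 2.15),
}

_BASAL_CONC = {  # nM
    "5-HT:DRN->LHA": 1.6,
    "5-HT:DRN->LC": 1.1e-7,  # 0.11 on the fM scale
    "NE:LC->DRN": 2950.0,  # 2.95 uM
    "NE:LC->LHA": 0.83,
    "Ox:LHA->DRN": 3.4,  # 10 pg/mg
    "Ox:LHA->LC": 0.56,  # 2 pg/mg
}

_TAU = {  # s
    "5-HT:DRN->LHA": 2.0,
    "5-HT:DRN->LC": 20.0,
    "NE:LC->DRN": 20.0,
    "NE:LC->LHA": 1.0,
    "Ox:LHA->DRN": 60.0,
    "Ox:LHA->LC": 20.0,
}

_MM_5HT = dict(v_max=1800.0, k_m=170.0)  # nM/s, nM — all 5-HT sites
_MM_NE = dict(v_max=74.0, k_m=400.0)  # all NE sites
_ETA_OX = 0.85  # 1/s, both Ox pathways

#: Published per-stimulus release seeds, re-tuned by calibration.
_SEED_RELEASE = {
    "5-HT:DRN->LHA": 12.14,  # nM
    "5-HT:DRN->LC": 0.852e-6,  # 0.852 fM, in nM
    "NE:LC->DRN": 27.272,
    "NE:LC->LHA": 0.0642,
    "Ox:LHA->DRN": 1.405,  # rise factor, nM
    "Ox:LHA->LC": 0.2314,
}

#: Published control response curve for Ox on LC neurons, and the published
#: shift/slope of the Ox curve on DRN neurons.
_OX_LC_CURVE = dict(lower=3.8, upper=54.0, shift=-2.3, slope=0.341)
_OX_DRN_SHIFT, _OX_DRN_SLOPE = -2.08, 0.452

# ---------------------------------------------------------------------------
# Assumed response-curve shapes (see module docstring / methods note)
# ---------------------------------------------------------------------------

#: Ox->DRN excitatory range (bounds unpublished): zero at zero orexin, a
#: moderate maximum so the NE pathway carries the larger share of the DRN's
#: basal drive (the published basal NE current balance is the anchor).
_OX_DRN_LOWER, _OX_DRN_UPPER = 0.0, 12.0
#: 5-HT GIRK on LHA: saturating inhibition of ~35 pA with its steep section
#: inside the 10-100 nM decade.
_5HT_LHA_SAT, _5HT_LHA_SHIFT, _5HT_LHA_SLOPE = -35.0, 1.5, 0.35
#: NE GIRK on LHA: weaker saturating inhibition, transition above baseline.
_NE_LHA_SAT, _NE_LHA_SHIFT, _NE_LHA_SLOPE = -25.0, 1.2, 0.4
#: 5-HT inhibition of LC: near-saturated at the (fM-scale) basal level so the
#: serotonergic influence on LC stays minimal under reuptake inhibition.
_5HT_LC_SHIFT, _5HT_LC_SLOPE = -8.3, 0.35
#: NE->DRN excitation: basal concentration sits at the curve midpoint.
_NE_DRN_SLOPE = 0.5

# Drug presets: a fluoxetine-like SSRI (K_m,5-HT x5, V_max untouched), NE
# reuptake inhibitors at x3 and x5, and the Ox-1 antagonist SB-334867-A as
# explicit response-curve overrides on both orexin pathways.
_SB_OVERRIDES = {
    "Ox:LHA->LC": dict(lower=2.0, upper=51.0, shift=-4.192, slope=0.592),
    "Ox:LHA->DRN": dict(shift=-2.97, slope=0.367),
}


@dataclass
class PresetBundle:
    circuit: CircuitSpec
    baselines: BaselineTargets
    drugs: dict[str, DrugPerturbation]
    provenance: dict[str, str]
    display_units: dict[str, tuple[str, float]]  # key -> (unit, factor from nM)
    seed_release: dict[str, float]
    calibration: CalibrationResult | None = None


def _basal_current_sum(name: str) -> float:
    """Summed basal afferent current a population needs for its basal rate."""
    gain, threshold, bias, rate = _POPS[name]
    return rate / gain + threshold - bias


def _anchor_lower(sat: float, shift: float, slope: float, c0: float) -> SigmoidParams:
    """GIRK curve with saturation ``sat`` whose value is exactly 0 at ``c0``."""
    s0 = float(expit((math.log10(c0) - shift) / slope))
    lower = -sat * s0 / (1.0 - s0)
    return SigmoidParams(lower=lower, upper=sat, shift=shift, slope=slope)


def _solve_upper(lower: float, shift: float, slope: float, c0: float, g0: float) -> SigmoidParams:
    """Curve through (c0, g0) with the given lower bound and shape."""
    s0 = float(expit((math.log10(c0) - shift) / slope))
    upper = lower + float(g0 - lower) / s0
    return SigmoidParams(lower=lower, upper=upper, shift=shift, slope=slope)


def build_preset(calibrate: bool = True) -> PresetBundle:
    """Construct (and by default calibrate) the three-region circuit."""
    pops = tuple(
        PopulationSpec(name=n, gain=g, threshold=t, bias=b)
        for n, (g, t, b, _) in _POPS.items()
    )

    # -- response curves -------------------------------------------------
    ox_lc = SigmoidParams(**_OX_LC_CURVE)
    ox_drn = SigmoidParams(
        lower=_OX_DRN_LOWER, upper=_OX_DRN_UPPER, shift=_OX_DRN_SHIFT, slope=_OX_DRN_SLOPE
    )
    # LHA: its bias current alone accounts for the basal rate, so both GIRK
    # curves are anchored to zero induced current at the basal concentrations.
    girk_5ht_lha = _anchor_lower(
        _5HT_LHA_SAT, _5HT_LHA_SHIFT, _5HT_LHA_SLOPE, _BASAL_CONC["5-HT:DRN->LHA"]
    )
    girk_ne_lha = _anchor_lower(
        _NE_LHA_SAT, _NE_LHA_SHIFT, _NE_LHA_SLOPE, _BASAL_CONC["NE:LC->LHA"]
    )
    # LC: the 5-HT inhibition picks up whatever the published Ox->LC curve
    # leaves over in the basal current balance.
    need_lc = _basal_current_sum("LC") - sigmoid_response(_BASAL_CONC["Ox:LHA->LC"], ox_lc)
    inh_5ht_lc = _solve_upper(
        0.0, _5HT_LC_SHIFT, _5HT_LC_SLOPE, _BASAL_CONC["5-HT:DRN->LC"], need_lc
    )
    # DRN: NE excitation balances the remainder, basal NE at the midpoint.
    need_drn = _basal_current_sum("DRN") - sigmoid_response(_BASAL_CONC["Ox:LHA->DRN"], ox_drn)
    ne_drn = _solve_upper(
        0.0, math.log10(_BASAL_CONC["NE:LC->DRN"]), _NE_DRN_SLOPE,
        _BASAL_CONC["NE:LC->DRN"], need_drn,
    )

    curves = {
        "5-HT:DRN->LHA": girk_5ht_lha,
        "5-HT:DRN->LC": inh_5ht_lc,
        "NE:LC->DRN": ne_drn,
        "NE:LC->LHA": girk_ne_lha,
        "Ox:LHA->DRN": ox_drn,
        "Ox:LHA->LC": ox_lc,
    }

    def kinetics_for(key: str):
        species = key.split(":")[0]
        seed = _SEED_RELEASE[key]
        if species == "5-HT":
            return ReleaseKineticsMM(release_per_stimulus=seed, **_MM_5HT)
        if species == "NE":
            return ReleaseKineticsMM(release_per_stimulus=seed, **_MM_NE)
        return ReleaseKineticsLinear(rise=seed, decay=_ETA_OX)

    projections = tuple(
        ProjectionSpec(
            source=key.split(":")[1].split("->")[0],
            target=key.split("->")[1],
            species=key.split(":")[0],
            tau=_TAU[key],
            response=curves[key],
            kinetics=kinetics_for(key),
        )
        for key in _BASAL_CONC
    )
    circuit = CircuitSpec(populations=pops, projections=projections).validate()

    baselines = BaselineTargets(
        rates={n: r for n, (_, _, _, r) in _POPS.items()},
        concentrations=dict(_BASAL_CONC),
    )

    provenance = {}
    for n in _POPS:
        for fld in ("gain", "threshold", "bias", "basal_rate"):
            provenance[f"{n}.{fld}"] = "reported"
    for key in _BASAL_CONC:
        provenance[f"{key}.tau"] = "reported"
        provenance[f"{key}.basal_concentration"] = "reported"
        provenance[f"{key}.kinetics.v_max/k_m"] = "reported"
        provenance[f"{key}.kinetics.release"] = "calibrated" if calibrate else "seed"
    provenance.update(
        {
            "Ox:LHA->LC.response": "reported",
            "Ox:LHA->DRN.response.shift/slope": "reported",
            "Ox:LHA->DRN.response.lower/upper": "assumed",
            "5-HT:DRN->LHA.response.shift/slope/upper": "assumed",
            "5-HT:DRN->LHA.response.lower": "anchored",
            "NE:LC->LHA.response.shift/slope/upper": "assumed",
            "NE:LC->LHA.response.lower": "anchored",
            "5-HT:DRN->LC.response.shift/slope/lower": "assumed",
            "5-HT:DRN->LC.response.upper": "anchored",
            "NE:LC->DRN.response.shift/slope/lower": "assumed",
            "NE:LC->DRN.response.upper": "anchored",
        }
    )

    drugs = {
        "fluoxetine": DrugPerturbation(name="fluoxetine", km_factors={"5-HT": 5.0}),
        "nri-x3": DrugPerturbation(name="nri-x3", km_factors={"NE": 3.0}),
        "nri-x5": DrugPerturbation(name="nri-x5", km_factors={"NE": 5.0}),
        "sb-334867-a": DrugPerturbation(
            name="sb-334867-a", overrides={k: dict(v) for k, v in _SB_OVERRIDES.items()}
        ),
    }

    display_units = {key: ("nM", 1.0) for key in _BASAL_CONC}
    display_units["5-HT:DRN->LC"] = ("fM", 1e6)
    display_units["NE:LC->DRN"] = ("uM", 1e-3)

    calibration = None
    if calibrate:
        calibration = calibrate_release(
            circuit, baselines, free=list(_BASAL_CONC), verify=True
        )
        circuit = calibration.spec

    return PresetBundle(
        circuit=circuit,
        baselines=baselines,
        drugs=drugs,
        provenance=provenance,
        display_units=display_units,
        seed_release=dict(_SEED_RELEASE),
        calibration=calibration,
    )


def baseline_state(bundle: PresetBundle) -> CircuitState:
    """The basal state: target rates/concentrations, currents at their curve values.

    For the calibrated preset this is the circuit's fixed point and the
    default initial condition.
    """
    spec = bundle.circuit
    concs = dict(bundle.baselines.concentrations)
    currents = {
        p.key: sigmoid_response(concs[p.key], p.response)
        for p in spec.current_projections
    }
    return CircuitState(
        time=0.0,
        rates=dict(bundle.baselines.rates),
        currents=currents,
        concentrations=concs,
    )


# ---------------------------------------------------------------------------
# Synthetic dose-response generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticDoseResponseSpec:
    """Sigmoid curve + additive Gaussian noise, emulating a pharmacology
    concentration-response experiment.

    The concentration grid is log-spaced over ``decades_below``/``above``
    decades around the curve midpoint 10**shift, so the transition region is
    always covered; defaults span 2 decades either side at 8 points per
    replicate with 2%-of-range noise — typical of the small hand-digitised
    response tables such curves are fitted to in practice.
    """

    true_params: SigmoidParams
    n_points: int = 8
    decades_below: float = 2.0
    decades_above: float = 2.0
    noise_sd: float = 0.0  # response units
    replicates: int = 1
    seed: int = 0

    def grid(self) -> np.ndarray:
        lo = self.true_params.shift - self.decades_below
        hi = self.true_params.shift + self.decades_above
        if hi - lo < 3.0:
            raise ValueError("concentration grid must span at least 3 decades")
        return np.logspace(lo, hi, self.n_points)


def generate_dose_response(s: SyntheticDoseResponseSpec) -> DoseResponseTable:
    """Noisy samples of the true curve; bit-reproducible under the seed."""
    rng = np.random.default_rng(s.seed)
    c = np.tile(s.grid(), s.replicates)
    y = sigmoid_response(c, s.true_params)
    if s.noise_sd > 0:
        y = y + rng.normal(0.0, s.noise_sd, size=c.shape)
    return DoseResponseTable(c, y, mode=s.true_params.mode)
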