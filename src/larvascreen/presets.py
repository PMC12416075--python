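"""Reference study design: a heart-drug x calcineurin-inhibitor screen.

The preset emulates a 31-arm screen: a DMSO vehicle control, fourteen
heart medications at 10 uM, the same fourteen at 5 uM combined with
5 uM cyclosporine A (CsA), and CsA alone at 5 and 10 uM, with 30
larvae per arm.  Effect presets are illustrative parameter offsets,
not calibrated to any measured dataset: CsA carries the calcineurin-
inhibitor signature (raised activity and excitability, slowed
habituation, blunted optomotor response, more scoot/burst movement)
and each heart drug carries a scaled, perturbed variant of it --
strong for the drugs reported to phenocopy CsA, weak for the rest.
Offsets are defined at a 10 uM reference dose and scale linearly with
dose, so the 5 uM combination arms apply half of each component.
"""

from __future__ import annotations

from .simulate import BehaviorParams, DrugEffect
from .tracks import TreatmentArm

CSA = "cyclosporine_a"

#: The calcineurin-inhibitor signature at the 10 uM reference dose.
CSA_OFFSETS = {
    "p_move": 0.10,
    "startle_boost": 0.18,
    "habituation_rate": -0.0012,
    "optomotor_gain": -0.16,
    "burst_given_move": 0.10,
}

# per-drug scale on the CsA signature plus drug-specific quirks;
# strong scalers are the drugs that phenocopy CsA, weak scalers the
# ones that cluster with the vehicle.
_HEART_DRUGS: dict[str, tuple[float, dict[str, float]]] = {
    "simvastatin": (0.95, {"edge_attraction": 0.04}),
    "nebivolol": (1.05, {"cw_bias": 0.5}),
    "doxazosin": (0.90, {"edge_attraction": -0.05}),
    "irbesartan": (0.85, {"p_move": 0.06, "optomotor_gain": 0.20, "turn_sd_deg": 6.0}),
    "cilostazol": (0.80, {"burst_given_move": 0.08, "optomotor_gain": 0.18}),
    "droperidol": (0.70, {"up_bias": 0.05}),
    "carvedilol": (0.60, {"turn_sd_deg": 4.0}),
    "calcifediol": (0.55, {"optomotor_gain": 0.12}),
    "eprosartan": (0.35, {"p_move": -0.04, "optomotor_gain": 0.15}),
    "prazosin": (0.25, {"p_move": -0.05}),
    "losartan": (0.20, {"startle_boost": -0.08}),
    "telmisartan": (0.20, {"p_move": -0.03, "startle_boost": -0.06}),
    "trifluoperazine": (0.15, {"p_move": -0.06}),
    "mirtazapine": (0.15, {"startle_boost": -0.10, "up_bias": -0.04}),
}

REFERENCE_DOSE_UM = 10.0
SINGLE_DOSE_UM = 10.0
COMBO_DOSE_UM = 5.0
N_PER_ARM = 30


def heart_screen_effects() -> dict[str, DrugEffect]:
    """Effect library: CsA plus the fourteen heart drugs."""
    library = {
        CSA: DrugEffect(CSA, dict(CSA_OFFSETS), reference_dose_uM=REFERENCE_DOSE_UM)
    }
    for drug, (scale, quirks) in _HEART_DRUGS.items():
        offsets = {k: v * scale for k, v in CSA_OFFSETS.items()}
        for k, v in quirks.items():
            offsets[k] = offsets.get(k, 0.0) + v
        library[drug] = DrugEffect(drug, offsets, reference_dose_uM=REFERENCE_DOSE_UM)
    return library


def heart_screen_arms(n_per_arm: int = N_PER_ARM) -> list[TreatmentArm]:
    """The 31 arms: vehicle, 14 singles, 14 CsA combinations, CsA 5/10 uM."""
    arms = [TreatmentArm("DMSO", "vehicle_control", (), n_per_arm)]
    for drug in _HEART_DRUGS:
        arms.append(
            TreatmentArm(drug, "single", ((drug, SINGLE_DOSE_UM),), n_per_arm)
        )
    for drug in _HEART_DRUGS:
        arms.append(
            TreatmentArm(
                f"{drug}+csa",
                "combination",
                ((drug, COMBO_DOSE_UM), (CSA, COMBO_DOSE_UM)),
                n_per_arm,
            )
        )
    arms.append(TreatmentArm("csa_5uM", "single", ((CSA, COMBO_DOSE_UM),), n_per_arm))
    arms.append(TreatmentArm("csa_10uM", "single", ((CSA, SINGLE_DOSE_UM),), n_per_arm))
    return arms


def heart_screen_pairs() -> list[tuple[str, str]]:
    """(combination, single) labels for the synergy table."""
    return [(f"{drug}+csa", drug) for drug in _HEART_DRUGS]


def default_base_params() -> BehaviorParams:
    return BehaviorParams()
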