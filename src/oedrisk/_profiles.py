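"""Calibrated synthetic-cohort dose profiles (plain data).

Produced once by ``calibrate_profiles(default_calibration_targets(), ...)``
with seed 20405 against the published group summaries; see ``cohort.py``.
"""

from .cohort import OrganDoseProfile

DEFAULT_PROFILES = {
    ("PBI_CTL", "breast_contralateral"): OrganDoseProfile(
        organ="breast_contralateral", group="PBI_CTL",
        p_high=0.214754, high_mean=2.08612, high_sd=0.4,
        bath_scale=0.429509, organ_volume_mean=700,
        organ_volume_sd=120, patient_sd_log=0.396686,
    ),
    ("PBI_CTL", "esophagus"): OrganDoseProfile(
        organ="esophagus", group="PBI_CTL",
        p_high=0, high_mean=0, high_sd=0,
        bath_scale=0.522797, organ_volume_mean=35,
        organ_volume_sd=8, patient_sd_log=0.325882,
    ),
    ("PBI_CTL", "lung_contralateral"): OrganDoseProfile(
        organ="lung_contralateral", group="PBI_CTL",
        p_high=0.0263535, high_mean=2.5, high_sd=0.8,
        bath_scale=0.474363, organ_volume_mean=1000,
        organ_volume_sd=150, patient_sd_log=0.368886,
    ),
    ("PBI_CTL", "lung_ipsilateral"): OrganDoseProfile(
        organ="lung_ipsilateral", group="PBI_CTL",
        p_high=0.278002, high_mean=8, high_sd=2.5,
        bath_scale=0.992866, organ_volume_mean=1100,
        organ_volume_sd=150, patient_sd_log=0.22196,
    ),
    ("PBI_CTL", "thyroid"): OrganDoseProfile(
        organ="thyroid", group="PBI_CTL",
        p_high=0, high_mean=0, high_sd=0,
        bath_scale=0.145309, organ_volume_mean=18,
        organ_volume_sd=4, patient_sd_log=0.770413,
    ),
    ("PBI_MRL", "breast_contralateral"): OrganDoseProfile(
        organ="breast_contralateral", group="PBI_MRL",
        p_high=0.0796324, high_mean=1.36878, high_sd=0.35,
        bath_scale=0.341282, organ_volume_mean=700,
        organ_volume_sd=120, patient_sd_log=0.339104,
    ),
    ("PBI_MRL", "esophagus"): OrganDoseProfile(
        organ="esophagus", group="PBI_MRL",
        p_high=0, high_mean=0, high_sd=0,
        bath_scale=0.612225, organ_volume_mean=35,
        organ_volume_sd=8, patient_sd_log=0.418628,
    ),
    ("PBI_MRL", "lung_contralateral"): OrganDoseProfile(
        organ="lung_contralateral", group="PBI_MRL",
        p_high=0.0260992, high_mean=2.5, high_sd=0.8,
        bath_scale=0.321891, organ_volume_mean=1000,
        organ_volume_sd=150, patient_sd_log=0.297724,
    ),
    ("PBI_MRL", "lung_ipsilateral"): OrganDoseProfile(
        organ="lung_ipsilateral", group="PBI_MRL",
        p_high=0.276476, high_mean=8, high_sd=2.5,
        bath_scale=0.987414, organ_volume_mean=1100,
        organ_volume_sd=150, patient_sd_log=0.390469,
    ),
    ("PBI_MRL", "thyroid"): OrganDoseProfile(
        organ="thyroid", group="PBI_MRL",
        p_high=0, high_mean=0, high_sd=0,
        bath_scale=0.365279, organ_volume_mean=18,
        organ_volume_sd=4, patient_sd_log=0.335869,
    ),
    ("WBI_CTL", "breast_contralateral"): OrganDoseProfile(
        organ="breast_contralateral", group="WBI_CTL",
        p_high=0.244839, high_mean=8.34566, high_sd=0.3,
        bath_scale=0.342774, organ_volume_mean=700,
        organ_volume_sd=120, patient_sd_log=0.319112,
    ),
    ("WBI_CTL", "esophagus"): OrganDoseProfile(
        organ="esophagus", group="WBI_CTL",
        p_high=0, high_mean=0, high_sd=0,
        bath_scale=0.771536, organ_volume_mean=35,
        organ_volume_sd=8, patient_sd_log=0.28994,
    ),
    ("WBI_CTL", "lung_contralateral"): OrganDoseProfile(
        organ="lung_contralateral", group="WBI_CTL",
        p_high=0.0264223, high_mean=2.5, high_sd=0.8,
        bath_scale=0.405142, organ_volume_mean=1000,
        organ_volume_sd=150, patient_sd_log=0.343911,
    ),
    ("WBI_CTL", "lung_ipsilateral"): OrganDoseProfile(
        organ="lung_ipsilateral", group="WBI_CTL",
        p_high=0.303742, high_mean=8, high_sd=2.5,
        bath_scale=1.01247, organ_volume_mean=1100,
        organ_volume_sd=150, patient_sd_log=0.0950959,
    ),
    ("WBI_CTL", "thyroid"): OrganDoseProfile(
        organ="thyroid", group="WBI_CTL",
        p_high=0, high_mean=0, high_sd=0,
        bath_scale=0.52246, organ_volume_mean=18,
        organ_volume_sd=4, patient_sd_log=0.406768,
    ),
}
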