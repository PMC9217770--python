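"""Seeded synthetic DVH cohorts for the three breast-irradiation groups.

No per-patient planning data are published for the cohorts this package
re-analyses, so analyses run on synthetic patients.  Each organ's dose
distribution is a two-component mixture — a near-field high-dose component
(truncated normal) holding a fraction ``p_high`` of the organ volume, and an
exponential low-dose "bath" for the remainder — the simplest family able to
match both the published group-mean EARs and the contralateral-breast
maximum doses; organ-at-risk DVHs in breast radiotherapy are bimodal in this
way.  Inter-patient heterogeneity is one lognormal multiplier per patient,
shared across that patient's organs (each organ applies its own log-sd to a
common standard-normal draw), so within-patient organ doses correlate as
anatomy induces in reality.

The prescription is 40.05 Gy in 15 fractions; sampled voxel doses are capped
at 110% of prescription.  The combined-lungs DVH is derived per patient by
merging the ipsilateral and contralateral lung histograms, which makes the
lung volume and OED mixture identities hold exactly.

The shipped default profiles (:data:`DEFAULT_PROFILES`) were produced by
:func:`calibrate_profiles` against the published group summaries and are
stored as plain data in ``_profiles.py``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from . import reference
from .dvh import GROUPS, DifferentialDVH, PatientRecord, max_dose
from .risk import DEFAULT_ALPHAS, DEFAULT_RISK_COEFFICIENTS, ear_from_oed, oed

__all__ = [
    "PRESCRIPTION_GY",
    "N_FRACTIONS",
    "GENERATED_ORGANS",
    "OrganDoseProfile",
    "CohortConfig",
    "CalibrationTarget",
    "CalibrationError",
    "sample_patient_dvh",
    "generate_cohort",
    "merge_dvhs",
    "calibrate_profiles",
    "default_calibration_targets",
    "sample_ptv_volumes",
    "DEFAULT_PROFILES",
]

PRESCRIPTION_GY = 40.05
N_FRACTIONS = 15
DOSE_CAP_GY = 1.1 * PRESCRIPTION_GY

#: Organs sampled directly; the combined lungs are merged from the two sides.
GENERATED_ORGANS = (
    "breast_contralateral",
    "lung_ipsilateral",
    "lung_contralateral",
    "thyroid",
    "esophagus",
)

_MIN_ORGAN_VOLUME = 10.0  # cm^3
_P_HIGH_CAP = 0.9


@dataclass(frozen=True)
class OrganDoseProfile:
    """Parameters of one group x organ synthetic dose distribution.

    ``p_high`` of the organ volume receives ~N(``high_mean``, ``high_sd``) Gy,
    the rest an exponential bath of scale ``bath_scale`` Gy.  A per-patient
    lognormal multiplier ``exp(patient_sd_log * z)`` (z standard normal,
    shared across the patient's organs) scales ``p_high`` and ``bath_scale``.
    """

    organ: str
    group: str
    p_high: float
    high_mean: float
    high_sd: float
    bath_scale: float
    organ_volume_mean: float
    organ_volume_sd: float
    patient_sd_log: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_high < 1:
            raise ValueError(f"{self.group}/{self.organ}: p_high must be in [0, 1)")
        for name in ("high_mean", "high_sd", "bath_scale", "organ_volume_mean",
                     "organ_volume_sd", "patient_sd_log"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.group}/{self.organ}: {name} must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Reproducible cohort recipe: same seed and config give the same cohort."""

    seed: int
    n_per_group: int = reference.N_PER_GROUP
    profiles: Mapping[tuple[str, str], OrganDoseProfile] | None = None
    bin_width: float = 0.1
    n_voxels: int = 4000

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_voxels < 10:
            raise ValueError("n_voxels must be >= 10")


def sample_patient_dvh(
    profile: OrganDoseProfile,
    rng: np.random.Generator,
    patient_z: float = 0.0,
    bin_width: float = 0.1,
    n_voxels: int = 4000,
) -> DifferentialDVH:
    """Draw one organ DVH: volume, voxel doses, histogram at ``bin_width``."""
    mult = float(np.exp(profile.patient_sd_log * patient_z))
    p_eff = min(profile.p_high * mult, _P_HIGH_CAP)
    bath_eff = profile.bath_scale * mult

    volume = max(
        rng.normal(profile.organ_volume_mean, profile.organ_volume_sd), _MIN_ORGAN_VOLUME
    )
    n_high = int(round(p_eff * n_voxels))
    d_high = rng.normal(profile.high_mean, profile.high_sd, size=n_high)
    n_bath = n_voxels - n_high
    if bath_eff > 0:
        d_bath = rng.exponential(bath_eff, size=n_bath)
    else:
        d_bath = np.zeros(n_bath)
    doses = np.clip(np.concatenate([d_high, d_bath]), 0.0, DOSE_CAP_GY)

    n_bins = max(int(np.floor(doses.max() / bin_width)) + 1, 1)
    counts, edges = np.histogram(doses, bins=n_bins, range=(0.0, n_bins * bin_width))
    return DifferentialDVH(profile.organ, edges, counts * (volume / n_voxels), volume)


def merge_dvhs(organ: str, parts: Sequence[DifferentialDVH], bin_width: float) -> DifferentialDVH:
    """Volume-additive union of DVHs sharing a uniform grid from 0 Gy."""
    n_bins = max(p.bin_volumes.size for p in parts)
    vols = np.zeros(n_bins)
    for p in parts:
        if abs(p.bin_edges[0]) > 1e-12 or abs(p.bin_widths[0] - bin_width) > 1e-9:
            raise ValueError(f"{organ}: parts must share the uniform grid from 0 Gy")
        vols[: p.bin_volumes.size] += p.bin_volumes
    edges = bin_width * np.arange(n_bins + 1)
    return DifferentialDVH(organ, edges, vols, float(sum(p.total_volume for p in parts)))


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate ``n_per_group`` synthetic patients for each treatment group.

    Per-patient random streams are spawned from the master seed by patient
    index, so results do not depend on iteration or insertion order.
    """
    profiles = DEFAULT_PROFILES if config.profiles is None else dict(config.profiles)
    for group in GROUPS:
        for organ in GENERATED_ORGANS:
            if (group, organ) not in profiles:
                raise KeyError(f"no dose profile for group {group!r} x organ {organ!r}")

    streams = np.random.SeedSequence(config.seed).spawn(len(GROUPS) * config.n_per_group)
    records: list[PatientRecord] = []
    for gi, group in enumerate(GROUPS):
        for i in range(config.n_per_group):
            rng = np.random.default_rng(streams[gi * config.n_per_group + i])
            z = float(rng.standard_normal())
            dvhs: dict[str, DifferentialDVH] = {}
            for organ in GENERATED_ORGANS:
                dvhs[organ] = sample_patient_dvh(
                    profiles[(group, organ)], rng, z, config.bin_width, config.n_voxels
                )
            dvhs["lungs_both"] = merge_dvhs(
                "lungs_both",
                [dvhs["lung_ipsilateral"], dvhs["lung_contralateral"]],
                config.bin_width,
            )
            records.append(PatientRecord(f"{group}-{i + 1:02d}", group, dvhs))
    return records


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationTarget:
    """Group x organ targets: mean/SD of EAR and, optionally, mean Dmax (Gy)."""

    mean_ear: float
    sd_ear: float
    dmax_mean: float | None = None

    def __post_init__(self) -> None:
        if self.mean_ear <= 0 or self.sd_ear <= 0:
            raise ValueError("calibration targets must be positive")


class CalibrationError(RuntimeError):
    """Raised when coordinate search exhausts its iteration cap."""


def default_calibration_targets() -> dict[tuple[str, str], CalibrationTarget]:
    """Published group summaries as calibration targets for sampled organs."""
    targets: dict[tuple[str, str], CalibrationTarget] = {}
    for organ in GENERATED_ORGANS:
        for group in GROUPS:
            mean, sd = reference.EAR_SUMMARIES[organ][group]
            dmax = (
                reference.DMAX_BREAST_CONTRALATERAL[group][0]
                if organ == "breast_contralateral"
                else None
            )
            targets[(group, organ)] = CalibrationTarget(mean, sd, dmax)
    return targets


def _simulate_profile(
    profile: OrganDoseProfile,
    seed_seq: np.random.SeedSequence,
    n_patients: int,
    bin_width: float,
    n_voxels: int,
) -> tuple[float, float, float]:
    """Mean EAR, SD EAR and mean Dmax over simulated patients of one profile."""
    rng = np.random.default_rng(seed_seq)
    ears = np.empty(n_patients)
    dmaxes = np.empty(n_patients)
    for i in range(n_patients):
        z = float(rng.standard_normal())
        d = sample_patient_dvh(profile, rng, z, bin_width, n_voxels)
        o = oed(d, DEFAULT_ALPHAS.model_for_organ(profile.organ))
        ears[i] = ear_from_oed(o, profile.organ, DEFAULT_RISK_COEFFICIENTS)
        dmaxes[i] = max_dose(d)
    return float(ears.mean()), float(ears.std(ddof=1)), float(dmaxes.mean())


def calibrate_profiles(
    targets: Mapping[tuple[str, str], CalibrationTarget],
    initial: Mapping[tuple[str, str], OrganDoseProfile],
    seed: int = 20405,
    n_patients_sim: int = 400,
    max_iter: int = 60,
    mean_tol: float = 0.10,
    sd_tol: float = 0.30,
    dmax_tol: float = 0.20,
    bin_width: float = 0.1,
    n_voxels: int = 4000,
    aim_fraction: float = 0.5,
) -> dict[tuple[str, str], OrganDoseProfile]:
    """Coordinate search scaling each profile until simulated summaries match.

    Per iteration: ``p_high`` and ``bath_scale`` are scaled by the target/
    simulated mean-EAR ratio (EAR is near-linear in both at sub-Gy organ
    doses), ``high_mean`` by the Dmax ratio where a Dmax target exists, and
    ``patient_sd_log`` by the coefficient-of-variation ratio.  A fixed inner
    seed per profile (common random numbers) keeps the search stable.

    The search aims at ``aim_fraction`` of each tolerance so accepted
    profiles sit inside the band rather than on its edge; a profile passes if
    its best iterate is within the full tolerances.  Raises
    :class:`CalibrationError` with a best-so-far report otherwise.
    """
    calibrated: dict[tuple[str, str], OrganDoseProfile] = {}
    failures: list[str] = []
    for key, target in targets.items():
        profile = initial[key]
        # stable per-profile stream (zlib.crc32 is platform- and run-stable,
        # unlike hash() on strings)
        inner = np.random.SeedSequence((seed, zlib.crc32("/".join(key).encode())))
        best: tuple[float, OrganDoseProfile, tuple] | None = None
        for _ in range(max_iter):
            mean, sd, dmax = _simulate_profile(
                profile, inner, n_patients_sim, bin_width, n_voxels
            )
            err_mean = abs(mean / target.mean_ear - 1)
            err_sd = abs(sd / target.sd_ear - 1)
            err_dmax = (
                abs(dmax / target.dmax_mean - 1) if target.dmax_mean is not None else 0.0
            )
            score = max(err_mean / mean_tol, err_sd / sd_tol,
                        err_dmax / dmax_tol if target.dmax_mean is not None else 0.0)
            if best is None or score < best[0]:
                best = (score, profile, (mean, sd, dmax))
            if score <= aim_fraction:
                calibrated[key] = profile
                break
            r = (target.mean_ear / mean) ** 0.9
            updates = {
                "p_high": min(profile.p_high * r, _P_HIGH_CAP),
                "bath_scale": profile.bath_scale * r,
            }
            if target.dmax_mean is not None and dmax > 0:
                updates["high_mean"] = profile.high_mean * (target.dmax_mean / dmax) ** 0.5
            cv_sim, cv_target = sd / mean, target.sd_ear / target.mean_ear
            updates["patient_sd_log"] = float(
                np.clip(
                    profile.patient_sd_log * np.clip((cv_target / cv_sim) ** 0.7, 0.6, 1.6),
                    0.01,
                    1.5,
                )
            )
            profile = replace(profile, **updates)
        else:
            assert best is not None
            if best[0] <= 1.0:  # within the full tolerance band
                calibrated[key] = best[1]
            else:
                failures.append(
                    f"{key}: best mean/sd/dmax = {best[2]} vs target "
                    f"({target.mean_ear}, {target.sd_ear}, {target.dmax_mean})"
                )
                calibrated[key] = best[1]
    if failures:
        raise CalibrationError(
            "calibration did not converge for: " + "; ".join(failures)
        )
    return calibrated


#: group -> (mean, sd) lognormal planning-target-volume model, cm^3.  Means
#: are the published group means; spreads chosen so the published min-max
#: ranges are plausible extremes of 11 lognormal draws.
PTV_VOLUME_PROFILES = {
    "PBI_MRL": (265.3, 120.0),
    "PBI_CTL": (299.0, 140.0),
}


def sample_ptv_volumes(group: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample planning-target volumes (cm^3) for a PBI group."""
    if group not in PTV_VOLUME_PROFILES:
        raise KeyError(f"no PTV volume model for group {group!r}")
    mean, sd = PTV_VOLUME_PROFILES[group]
    cv2 = (sd / mean) ** 2
    s2 = np.log1p(cv2)
    mu = np.log(mean) - s2 / 2
    return np.exp(rng.normal(mu, np.sqrt(s2), size=n))


from ._profiles import DEFAULT_PROFILES  # noqa: E402  (data module)
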