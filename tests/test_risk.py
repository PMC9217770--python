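"""Risk-equivalent dose, OED and EAR projection."""

import numpy as np
import pytest

from oedrisk.dvh import DifferentialDVH, PatientRecord, mean_dose, rebin
from oedrisk.risk import (
    DEFAULT_ALPHAS,
    DEFAULT_RISK_COEFFICIENTS,
    AlphaTable,
    DoseResponseModel,
    ear_from_oed,
    excess_cases,
    oed,
    patient_risk_profile,
    red,
)

from conftest import make_random_dvh, make_uniform_dvh

LINEXP_025 = DoseResponseModel("linear_exponential", alpha=0.25)


class TestRed:
    def test_zero_dose_maps_to_zero(self):
        for model in (
            DoseResponseModel("linear"),
            LINEXP_025,
            DoseResponseModel("plateau", delta=0.1),
        ):
            assert red(0.0, model) == 0.0

    def test_linear_exponential_closed_form(self):
        assert red(2.0, LINEXP_025) == pytest.approx(2 * np.exp(-0.5), rel=1e-12)
        assert red(2.0, LINEXP_025) == pytest.approx(1.21306, abs=1e-5)

    def test_cell_killing_never_exceeds_linear(self, rng):
        d = rng.uniform(0, 45, 100)
        assert np.all(red(d, LINEXP_025) <= d + 1e-12)

    def test_peak_at_inverse_alpha(self):
        lung = DoseResponseModel("linear_exponential", alpha=0.129)
        grid = np.linspace(0, 40, 40001)
        assert grid[np.argmax(red(grid, lung))] == pytest.approx(1 / 0.129, abs=2e-3)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            red(-1.0, LINEXP_025)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            DoseResponseModel("linear_exponential")  # alpha required
        with pytest.raises(ValueError):
            DoseResponseModel("plateau", delta=0.0)
        with pytest.raises(ValueError):
            DoseResponseModel("quadratic")


class TestOed:
    def test_uniform_dose_closed_form(self):
        d = make_uniform_dvh(2.0)
        assert oed(d, LINEXP_025) == pytest.approx(2 * np.exp(-0.5), rel=1e-9)

    def test_linear_form_recovers_mean_dose(self, rng):
        d = make_random_dvh(rng)
        assert oed(d, DoseResponseModel("linear")) == pytest.approx(
            mean_dose(d), rel=1e-12
        )

    def test_monotone_in_alpha_and_zero_alpha_limit(self, rng):
        d = make_random_dvh(rng)
        alphas = [0.0, 0.05, 0.1, 0.2, 0.4]
        vals = [oed(d, DoseResponseModel("linear_exponential", alpha=a)) for a in alphas]
        assert np.all(np.diff(vals) < 1e-12)
        assert vals[0] == pytest.approx(mean_dose(d), rel=1e-12)

    def test_mixture_oed_is_volume_weighted_mean(self, rng):
        a, b = make_random_dvh(rng), make_random_dvh(rng)
        grid_a, grid_b = rebin(a, 0.1), rebin(b, 0.1)
        # place both on a common 0.1 Gy grid anchored at 0
        start_a = round(grid_a.bin_edges[0] / 0.1)
        start_b = round(grid_b.bin_edges[0] / 0.1)
        n = max(start_a + grid_a.bin_volumes.size, start_b + grid_b.bin_volumes.size)
        vols = np.zeros(n)
        vols[start_a : start_a + grid_a.bin_volumes.size] += grid_a.bin_volumes
        vols[start_b : start_b + grid_b.bin_volumes.size] += grid_b.bin_volumes
        union = DifferentialDVH("thyroid", 0.1 * np.arange(n + 1), vols)
        expected = (
            grid_a.total_volume * oed(grid_a, LINEXP_025)
            + grid_b.total_volume * oed(grid_b, LINEXP_025)
        ) / (grid_a.total_volume + grid_b.total_volume)
        assert oed(union, LINEXP_025) == pytest.approx(expected, rel=1e-9)

    def test_voxel_sampling_oracle_fifty_bins(self, rng):
        """OED equals the mean RED of voxel doses sampled from the DVH."""
        d = make_random_dvh(rng, max_bins=51)
        idx = rng.choice(d.bin_volumes.size, size=1_000_000,
                         p=d.bin_volumes / d.bin_volumes.sum())
        doses = rng.uniform(d.bin_edges[idx], d.bin_edges[idx + 1])
        sample_red = red(doses, LINEXP_025)
        se = sample_red.std() / np.sqrt(sample_red.size)
        assert abs(oed(d, LINEXP_025) - sample_red.mean()) < 3 * se + 1e-4


class TestEar:
    def test_default_coefficient_tables(self):
        assert dict(DEFAULT_ALPHAS.items()) == {
            "lung": 0.129, "thyroid": 0.033, "esophagus": 0.274, "breast": 0.25
        }
        assert dict(DEFAULT_RISK_COEFFICIENTS.items()) == {
            "lung": 9.47, "thyroid": 0.86, "esophagus": 1.9, "breast": 2.49
        }

    @pytest.mark.parametrize(
        "organ, expected",
        [("lung_ipsilateral", 9.47), ("lungs_both", 9.47), ("thyroid", 0.86),
         ("esophagus", 1.9), ("breast_contralateral", 2.49)],
    )
    def test_unit_oed_yields_mu(self, organ, expected):
        assert ear_from_oed(1.0, organ) == pytest.approx(expected)
        assert ear_from_oed(0.0, organ) == 0.0

    def test_unknown_organ_error_lists_known(self):
        with pytest.raises(KeyError, match="esophagus"):
            ear_from_oed(1.0, "kidney")

    @pytest.mark.parametrize(
        "ear, persons, years, expected",
        [(1, 10_000, 1, 1.0), (1, 1000, 10, 1.0), (0, 5000, 30, 0.0)],
    )
    def test_excess_cases_unit_definition(self, ear, persons, years, expected):
        assert excess_cases(ear, persons, years) == pytest.approx(expected)


class TestPatientRiskProfile:
    def test_zero_dose_patient_has_zero_risk(self):
        dvhs = {
            "thyroid": DifferentialDVH("thyroid", [0, 1e-9], [20.0]),
            "esophagus": DifferentialDVH("esophagus", [0, 1e-9], [40.0]),
        }
        profile = patient_risk_profile(PatientRecord("p0", "PBI_MRL", dvhs))
        assert all(r.ear == pytest.approx(0, abs=1e-9) for r in profile.values())

    def test_uniform_thyroid_closed_form_chain(self):
        d = make_uniform_dvh(2.0, organ="thyroid")
        rec = PatientRecord("p1", "PBI_MRL", {"thyroid": d})
        profile = patient_risk_profile(rec)
        assert profile["thyroid"].ear == pytest.approx(0.86 * 2 * np.exp(-0.066), rel=1e-9)
        assert profile["thyroid"].ear == pytest.approx(1.6101, abs=1e-4)

    def test_missing_organ_names_patient_and_organ(self, two_bin_dvh):
        rec = PatientRecord("p7", "WBI_CTL", {"thyroid": two_bin_dvh})
        with pytest.raises(KeyError, match=r"p7.*esophagus"):
            patient_risk_profile(rec, organs=("thyroid", "esophagus"))

    def test_profile_stable_under_rebinning(self, small_cohort):
        rec = small_cohort[0]
        base = patient_risk_profile(rec)
        fine = patient_risk_profile(
            rec.with_dvhs({o: rebin(d, 0.01) for o, d in rec.dvhs.items()})
        )
        for organ in base:
            assert fine[organ].ear == pytest.approx(base[organ].ear, rel=5e-3)

    def test_dose_doubling_sublinear_at_treatment_doses(self):
        # at ~40 Gy cell killing suppresses risk: doubling dose must not double EAR
        lung = DoseResponseModel("linear_exponential", alpha=0.129)
        low, high = make_uniform_dvh(20.0, organ="lung_ipsilateral"), make_uniform_dvh(
            40.0, organ="lung_ipsilateral"
        )
        assert oed(high, lung) < 2 * oed(low, lung)

    def test_custom_alpha_table_changes_result(self):
        d = make_uniform_dvh(2.0, organ="thyroid")
        rec = PatientRecord("p1", "PBI_MRL", {"thyroid": d})
        hot = patient_risk_profile(rec, alphas=AlphaTable({"thyroid": 0.3}))
        assert hot["thyroid"].oed == pytest.approx(2 * np.exp(-0.6), rel=1e-9)
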