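"""Welch comparisons, Shapiro screening, uncapped Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oedrisk.cohort import sample_ptv_volumes
from oedrisk.reference import EAR_SUMMARIES, N_PER_GROUP
from oedrisk.stats import (
    CBCT_PSEUDO_GROUP,
    DEFAULT_PAIRS,
    auxiliary_compare,
    bonferroni,
    build_comparison_table,
    normality_check,
    welch_from_samples,
    welch_from_summary,
)


class TestWelch:
    def test_equal_means_give_zero_t_unit_p(self):
        t, df, p = welch_from_summary(5.0, 1.0, 11, 5.0, 2.0, 11)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_published_nonsignificant_lung_cell(self):
        # ipsilateral lung, conventional-linac PBI vs MR-linac PBI
        _, _, p = welch_from_summary(12.441, 2.276, 11, 12.423, 3.987, 11)
        assert 4 * p == pytest.approx(3.96, abs=0.01)

    def test_published_significant_thyroid_cell(self):
        _, _, p = welch_from_summary(0.168, 0.136, 11, 0.326, 0.11, 11)
        assert 4 * p == pytest.approx(0.029, abs=0.001)

    def test_samples_match_their_summary_exactly(self, rng):
        a, b = rng.normal(1, 0.5, 11), rng.normal(1.4, 0.8, 11)
        t1, df1, p1 = welch_from_samples(a, b)
        t2, df2, p2 = welch_from_summary(
            a.mean(), a.std(ddof=1), 11, b.mean(), b.std(ddof=1), 11
        )
        assert (t1, df1, p1) == pytest.approx((t2, df2, p2), rel=1e-12)

    def test_agrees_with_scipy_welch(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(0.7, 2, 14)
        t, _, p = welch_from_samples(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_permutation_oracle_close_for_normal_data(self, rng):
        a, b = rng.normal(0.0, 1.0, 11), rng.normal(0.9, 1.0, 11)
        _, _, p_welch = welch_from_samples(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        idx = np.argsort(rng.random((100_000, 22)), axis=1)  # vectorized shuffles
        perms = pooled[idx]
        diffs = np.abs(perms[:, :11].mean(axis=1) - perms[:, 11:].mean(axis=1))
        p_perm = (np.sum(diffs >= obs - 1e-12) + 1) / (diffs.size + 1)
        assert abs(p_welch - p_perm) < 0.03

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_from_summary(1.0, 0.0, 11, 2.0, 0.0, 11)


class TestNormalityCheck:
    def test_degenerate_and_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])

    def test_null_coverage_for_normal_samples(self):
        rng = np.random.default_rng(77)
        hits = sum(
            normality_check(rng.normal(size=11))[1] > 0.05 for _ in range(1000)
        )
        assert hits >= 900

    def test_power_against_exponential_samples(self):
        rng = np.random.default_rng(78)
        hits = sum(
            normality_check(rng.exponential(size=50))[1] < 0.05 for _ in range(500)
        )
        assert hits >= 0.8 * 500


class TestBonferroni:
    @pytest.mark.parametrize("p, m, expected", [(0.05, 4, 0.2), (0.25, 4, 1.0), (0.5, 4, 2.0)])
    def test_uncapped_product(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_monotone_in_both_arguments(self):
        assert bonferroni(0.02, 4) < bonferroni(0.03, 4) < bonferroni(0.03, 5)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            bonferroni(0.0, 4)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


def _ear_frame(rng, shift=0.0):
    rows = []
    for group in ("PBI_CTL", "PBI_MRL", "WBI_CTL", CBCT_PSEUDO_GROUP):
        for i in range(6):
            for organ in ("thyroid", "esophagus"):
                base = 1.0 if organ == "thyroid" else 2.0
                offset = shift if group == "PBI_MRL" else 0.0
                rows.append((f"{group}-{i}", group, organ,
                             base + offset + rng.normal(0, 0.2)))
    return pd.DataFrame(rows, columns=["patient_id", "group", "organ", "ear"])


class TestComparisonTable:
    def test_identical_groups_all_adjusted_to_four(self, rng):
        df = _ear_frame(rng)
        for g in ("PBI_MRL", "WBI_CTL", CBCT_PSEUDO_GROUP):
            ref = df[df["group"] == "PBI_CTL"].copy()
            ref["group"] = g
            df = pd.concat([df[df["group"] != g], ref])
        _, results = build_comparison_table(df, organs=("thyroid", "esophagus"))
        assert all(r.p_adjusted == pytest.approx(4.0) for r in results)
        assert all(r.m == 4 for r in results)

    def test_missing_group_is_an_error(self, rng):
        df = _ear_frame(rng)
        with pytest.raises(ValueError, match="WBI_CTL"):
            build_comparison_table(
                df[df["group"] != "WBI_CTL"], organs=("thyroid", "esophagus")
            )

    def test_significance_symmetric_under_pair_reversal(self, rng):
        df = _ear_frame(rng, shift=0.8)
        _, forward = build_comparison_table(
            df, pairs=(("PBI_CTL", "PBI_MRL"),), organs=("thyroid",), m=4
        )
        _, backward = build_comparison_table(
            df, pairs=(("PBI_MRL", "PBI_CTL"),), organs=("thyroid",), m=4
        )
        assert forward[0].t == pytest.approx(-backward[0].t, rel=1e-12)
        assert forward[0].significant == backward[0].significant

    def test_summary_statistics_use_sample_sd(self, rng):
        df = _ear_frame(rng)
        summaries, _ = build_comparison_table(df, organs=("thyroid", "esophagus"))
        s = next(x for x in summaries if x.group == "PBI_CTL" and x.organ == "thyroid")
        vals = df[(df["group"] == "PBI_CTL") & (df["organ"] == "thyroid")]["ear"]
        assert s.sd == pytest.approx(vals.std(ddof=1))
        assert s.n == 6

    def test_published_summaries_reproduce_significance_pattern(self):
        """Feeding the printed group summaries reproduces every bold call."""
        significant_cells = set()
        for organ, by_group in EAR_SUMMARIES.items():
            for pair in DEFAULT_PAIRS:
                (ma, sa), (mb, sb) = by_group[pair[0]], by_group[pair[1]]
                _, _, p = welch_from_summary(ma, sa, N_PER_GROUP, mb, sb, N_PER_GROUP)
                if bonferroni(p, 4) < 0.05:
                    significant_cells.add((organ, pair))
        expected = {
            ("breast_contralateral", ("PBI_CTL", "PBI_MRL")),
            ("breast_contralateral", (CBCT_PSEUDO_GROUP, "PBI_MRL")),
            ("lungs_both", (CBCT_PSEUDO_GROUP, "PBI_MRL")),
            ("lung_contralateral", (CBCT_PSEUDO_GROUP, "PBI_MRL")),
            ("thyroid", ("PBI_CTL", "PBI_MRL")),
            ("thyroid", ("PBI_CTL", "WBI_CTL")),
            ("esophagus", (CBCT_PSEUDO_GROUP, "PBI_MRL")),
        }
        assert significant_cells == expected


class TestAuxiliaryCompare:
    def test_identical_samples_and_identity_multiplier(self, rng):
        x = rng.normal(300, 100, 11)
        r = auxiliary_compare(x, x + 0.0, correction_m=1)
        assert r.p_raw == pytest.approx(1.0)
        assert r.p_adjusted == r.p_raw

    def test_ptv_volume_difference_usually_not_significant(self):
        """The small PTV difference between the PBI groups rarely reaches
        significance at n=11 (distributional check, not per-seed)."""
        rng = np.random.default_rng(9)
        nonsig = 0
        for _ in range(200):
            mrl = sample_ptv_volumes("PBI_MRL", 11, rng)
            ctl = sample_ptv_volumes("PBI_CTL", 11, rng)
            r = auxiliary_compare(mrl, ctl, correction_m=1, label="ptv_volume")
            nonsig += r.p_raw > 0.05
        assert nonsig >= 0.75 * 200

    def test_configurable_family_size(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        r1 = auxiliary_compare(a, b, correction_m=1)
        r3 = auxiliary_compare(a, b, correction_m=3)
        assert r3.p_adjusted == pytest.approx(3 * r1.p_adjusted)
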