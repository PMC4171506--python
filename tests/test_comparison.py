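import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dystroquant import (
    StudyDesign,
    compare_visits,
    cv_percent,
    hierarchical_visit_test,
    percent_difference,
    permutation_visit_test,
    rank_samples,
    summarize_biopsy,
)
from dystroquant import datasets
from dystroquant.comparison import round_half_away
from dystroquant.simulate import generate_study


class TestCvPercent:
    @pytest.mark.parametrize(
        "sample, values, expected",
        [
            (s, datasets.CONTROL_SETTINGS_MEANS[s], cv)
            for s, cv in datasets.CONTROL_SETTINGS_CV.items()
        ]
        + [
            (s, datasets.HIGH_SETTINGS_MEANS[s], cv)
            for s, cv in datasets.HIGH_SETTINGS_CV.items()
        ],
    )
    def test_reference_inter_assay_values(self, sample, values, expected):
        """Sample-SD CV of per-experiment means matches the reference tables."""
        result = cv_percent(list(values.values()), kind="inter")
        assert result.cv_percent_rounded == expected

    def test_identical_replicates_zero_cv(self):
        assert cv_percent([321.0, 321.0]).cv_percent == 0.0

    def test_two_value_closed_form(self):
        # for two values a, b: CV% = |a-b| / (a+b) * sqrt(2) * 100
        a, b = 929.0, 768.0
        result = cv_percent([a, b])
        assert result.cv_percent == pytest.approx(
            abs(a - b) / (a + b) * math.sqrt(2) * 100.0
        )

    @given(
        st.lists(st.floats(min_value=1, max_value=4000), min_size=2, max_size=8),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_scale_invariance(self, values, g):
        base = cv_percent(values).cv_percent
        scaled = cv_percent([v * g for v in values]).cv_percent
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="two replicate"):
            cv_percent([100.0])
        with pytest.raises(ValueError, match="nonpositive"):
            cv_percent([-10.0, 5.0])


@pytest.mark.parametrize(
    "x, expected", [(13.42, 13), (8.68, 9), (16.5, 17), (-2.5, -3), (0.4, 0)]
)
def test_round_half_away(x, expected):
    assert round_half_away(x) == expected


class TestRanking:
    def test_sort_oracle_single_experiment(self):
        table, _ = rank_samples({"exp1": {"A": 929.0, "B": 415.0, "C": 58.0}})
        ranks = dict(zip(table["sample"], table["rank"]))
        assert ranks == {"A": 1, "B": 2, "C": 3}

    def test_concordance_when_orders_identical(self):
        means = {
            "exp1": {"A": 900.0, "B": 400.0},
            "exp2": {"A": 700.0, "B": 350.0},
        }
        _, concordant = rank_samples(means)
        assert concordant

    def test_discordance_detected(self):
        means = {
            "exp1": {"A": 900.0, "B": 400.0},
            "exp2": {"A": 300.0, "B": 350.0},
        }
        _, concordant = rank_samples(means)
        assert not concordant

    def test_reference_high_settings_ranking(self):
        # exp7 is the one experiment measuring all four biopsies; its sort
        # order must reproduce the reference ranking DMD5 > DMD4 > DMD1 > DMD3
        table, _ = rank_samples(
            {"exp7": {s: m["exp7"] for s, m in datasets.HIGH_SETTINGS_MEANS.items()}}
        )
        exp7 = table[table["experiment"] == "exp7"]
        ranks = dict(zip(exp7["sample"], exp7["rank"]))
        assert ranks == datasets.HIGH_SETTINGS_RANKING

    def test_ties_flagged_and_deterministic(self):
        table, _ = rank_samples({"e": {"B": 100.0, "A": 100.0, "C": 50.0}})
        assert table["tied"].sum() == 2
        assert table.loc[table["rank"] == 1, "sample"].iloc[0] == "A"  # label order


class TestPercentDifference:
    @pytest.mark.parametrize(
        "pre, post, expected", [(100, 130, 30.0), (100, 100, 0.0), (200, 150, -25.0)]
    )
    def test_formula(self, pre, post, expected):
        assert percent_difference(pre, post) == expected

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 100.0)

    @given(
        st.floats(min_value=1, max_value=4000), st.floats(min_value=1, max_value=4000)
    )
    def test_forward_backward_differences_compose_to_identity(self, pre, post):
        d1 = percent_difference(pre, post)
        d2 = percent_difference(post, pre)
        assert (1 + d1 / 100) * (1 + d2 / 100) == pytest.approx(1.0)


class TestHierarchicalVisitTest:
    def test_zero_noise_limit_exact_log_ratio(self):
        _, _, design = generate_study(
            n_sections_per_visit=2, n_images_per_section=3,
            visit_effect_log=math.log(1.30), section_sd_log=0.0,
            image_sd_log=0.0, fiber_log_sigma=0.0, seed=0,
        )
        result = hierarchical_visit_test(design)
        assert result.effect_log == pytest.approx(math.log(1.30), abs=1e-12)
        assert result.ratio == pytest.approx(1.30)
        assert result.p_value == 0.0

    def test_single_section_design_rejected_with_guidance(self):
        table = pd.DataFrame(
            {
                "visit": ["pre"] * 2 + ["post"] * 4,
                "section_id": ["p1", "p1", "q1", "q1", "q2", "q2"],
                "image_id": list("abcdef"),
                "value": [100.0, 110.0, 120.0, 130.0, 125.0, 135.0],
            }
        )
        with pytest.raises(ValueError, match="permutation"):
            hierarchical_visit_test(StudyDesign(table=table))

    def test_nonpositive_values_rejected(self):
        _, _, design = generate_study(seed=1)
        design.table.loc[0, "value"] = 0.0
        with pytest.raises(ValueError, match="> 0"):
            hierarchical_visit_test(design)

    def test_section_in_two_visits_rejected(self):
        table = pd.DataFrame(
            {
                "visit": ["pre", "post"],
                "section_id": ["s1", "s1"],
                "image_id": ["a", "b"],
                "value": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="multiple visits"):
            StudyDesign(table=table)

    def test_variance_components_nonnegative_and_effect_sensible(self):
        _, _, design = generate_study(
            n_sections_per_visit=3, n_images_per_section=4,
            visit_effect_log=math.log(1.5), section_sd_log=0.05,
            image_sd_log=0.05, fiber_log_sigma=0.2, seed=9,
        )
        result = hierarchical_visit_test(design)
        assert result.var_section >= 0
        assert result.var_image > 0
        assert result.effect_log == pytest.approx(math.log(1.5), abs=0.2)

    def test_permutation_exact_small_design(self):
        _, _, design = generate_study(
            n_sections_per_visit=3, n_images_per_section=3,
            visit_effect_log=0.8, section_sd_log=0.02, image_sd_log=0.02,
            fiber_log_sigma=0.1, seed=3,
        )
        stat, p = permutation_visit_test(design, seed=0)
        # 6 sections -> C(6,3)=20 reassignments, exact p has 1/20 granularity
        assert stat == pytest.approx(0.8, abs=0.15)
        assert p == pytest.approx(2 / 20)  # observed split and its mirror

    def test_permutation_null_uniformish(self):
        ps = []
        for seed in range(40):
            _, _, design = generate_study(
                n_sections_per_visit=4, n_images_per_section=3,
                visit_effect_log=0.0, seed=seed, n_fibers_per_image=20,
            )
            ps.append(permutation_visit_test(design, seed=0)[1])
        assert 0.0 < np.mean(ps) < 1.0
        assert np.mean(np.array(ps) <= 0.10) <= 0.35  # no gross anti-conservatism


class TestCompareVisits:
    def _summaries(self, pre_vals, post_vals):
        def frame(vals, biopsy):
            return pd.DataFrame(
                {
                    "biopsy_id": [biopsy] * len(vals),
                    "section_id": ["s1"] * len(vals),
                    "image_id": ["i1"] * len(vals),
                    "dys_mean": vals,
                    "dys_max": vals,
                    "dys_q90_mean": vals,
                    "spec_mean": vals,
                    "csa_um2": [2000.0] * len(vals),
                }
            )

        return (
            summarize_biopsy(frame(pre_vals, "pre")),
            summarize_biopsy(frame(post_vals, "post")),
        )

    def test_constructed_30_percent_shift_is_exact(self):
        pre_vals = [100.0, 200.0, 300.0]
        post_vals = [v * 1.3 for v in pre_vals]
        pre, post = self._summaries(pre_vals, post_vals)
        _, _, design = generate_study(
            visit_effect_log=math.log(1.3), section_sd_log=0.0,
            image_sd_log=0.0, fiber_log_sigma=0.0, seed=0,
        )
        report = compare_visits(
            pre, post, design, pre_fiber_values=pre_vals,
            post_fiber_values=post_vals,
        )
        assert report.percent_difference == pytest.approx(30.0)
        assert report.percent_difference_rounded == 30
        assert report.right_shifted

    def test_identical_arms_zero_difference_not_significant(self):
        vals = [150.0, 250.0, 350.0]
        pre, post = self._summaries(vals, vals)
        _, _, design = generate_study(
            visit_effect_log=0.0, section_sd_log=0.05, image_sd_log=0.05,
            fiber_log_sigma=0.2, n_sections_per_visit=3, seed=5,
        )
        report = compare_visits(pre, post, design,
                                pre_fiber_values=vals, post_fiber_values=vals)
        assert report.percent_difference == 0.0
        assert report.visit_test.p_value > 0.05 or report.permutation_p > 0.05

    def test_staining_combo_mismatch_warned_not_fatal(self):
        pre, post = self._summaries([100.0], [130.0])
        pre.staining_combo, post.staining_combo = "MANDYS106", "ab15277"
        _, _, design = generate_study(seed=2)
        report = compare_visits(pre, post, design)
        assert any("staining_combo" in w for w in report.warnings)
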