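import numpy as np
import pandas as pd
import pytest

from reference import auc_by_pairs

from rnvgphase import cohort_stats as cs
from rnvgphase import synthetic_data as sd


def two_group_frame(x1, x2, feature="apen"):
    return pd.DataFrame(
        {
            feature: np.concatenate([x1, x2]),
            "group": ["stable"] * len(x1) + ["ctrcd"] * len(x2),
        }
    )


class TestCompareFeature:
    def test_identical_groups_t_path(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20)
        res = cs.compare_feature(two_group_frame(x, x.copy()), "apen")
        assert res.test == "welch-t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_gate_routes_nonnormal_to_ranksum(self):
        rng = np.random.default_rng(1)
        x1 = np.exp(rng.normal(0, 1.5, 200))  # heavily lognormal
        x2 = np.exp(rng.normal(0, 1.5, 50))
        res = cs.compare_feature(two_group_frame(x1, x2), "apen")
        assert res.test == "rank-sum"

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(2)
        res = cs.compare_feature(
            two_group_frame(rng.normal(0, 1, 166), rng.normal(3, 1, 11)), "apen"
        )
        assert res.p_value < 0.001

    def test_zero_variance_rejected(self):
        res_frame = two_group_frame(np.zeros(10), np.random.default_rng(0).normal(0, 1, 10))
        with pytest.raises(ValueError, match="zero variance"):
            cs.compare_feature(res_frame, "apen")

    def test_small_group_rejected(self):
        frame = two_group_frame(np.arange(10.0), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="at least 3"):
            cs.compare_feature(frame, "apen")

    def test_reports_group_summaries(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(5, 1, 30), rng.normal(7, 1, 10)
        res = cs.compare_feature(two_group_frame(x1, x2), "apen")
        assert res.mean_sd["stable"][0] == pytest.approx(x1.mean())
        assert res.mean_sd["ctrcd"][1] == pytest.approx(x2.std(ddof=1))


class TestHotellingT2:
    def test_identical_means_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (30, 3))
        res = cs.hotelling_t2(x, x.copy())
        assert res.t2 == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)

    def test_p1_reduces_to_squared_t(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        x1 = rng.normal(0, 1, (40, 1))
        x2 = rng.normal(0.5, 1, (15, 1))
        res = cs.hotelling_t2(x1, x2)
        t = stats.ttest_ind(x1.ravel(), x2.ravel(), equal_var=True).statistic
        assert res.t2 == pytest.approx(t**2, rel=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(0, 1, (50, 3))
        x2 = rng.normal(0.3, 1, (20, 3))
        a = rng.normal(0, 1, (3, 3)) + 3 * np.eye(3)
        b = rng.normal(0, 5, 3)
        base = cs.hotelling_t2(x1, x2)
        mapped = cs.hotelling_t2(x1 @ a + b, x2 @ a + b)
        assert mapped.t2 == pytest.approx(base.t2, rel=1e-8)
        assert mapped.p_value == pytest.approx(base.p_value, rel=1e-8)

    def test_singular_covariance_rejected(self):
        x1 = np.column_stack([np.arange(20.0), np.arange(20.0)])  # collinear
        x2 = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError, match="singular"):
            cs.hotelling_t2(x1, x2)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            cs.hotelling_t2(np.zeros((2, 3)), np.zeros((3, 3)))


class TestHenzeZirkler:
    def test_normal_data_passes(self):
        rng = np.random.default_rng(0)
        res = cs.henze_zirkler(rng.normal(0, 1, (200, 2)))
        assert res.pval > 0.05

    def test_lognormal_data_fails(self):
        rng = np.random.default_rng(1)
        res = cs.henze_zirkler(np.exp(rng.normal(0, 1, (200, 2))))
        assert res.pval < 0.01


class TestAuc:
    def test_perfect_separation(self):
        assert cs.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_half(self):
        assert cs.auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_pair_enumeration_example(self):
        scores = [3.0, 2.0, 1.0, 2.0]
        labels = [1, 1, 0, 0]
        assert cs.auc(scores, labels) == pytest.approx(0.875)
        assert cs.auc(scores, labels) == pytest.approx(auc_by_pairs(scores, labels))

    def test_matches_pair_enumeration_random(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            scores = rng.normal(0, 1, 30).round(1)  # rounding forces ties
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            assert cs.auc(scores, labels) == pytest.approx(
                auc_by_pairs(scores.tolist(), labels.tolist())
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        assert cs.auc(np.exp(scores), labels) == pytest.approx(cs.auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cs.auc([0.1, 0.2], [1, 1])


class TestFitLogistic:
    @staticmethod
    def _named_cohort(n, coef, seed):
        df = sd.make_logistic_cohort(n, coef, seed)
        out = pd.DataFrame(
            {
                "apen": df["x1"],
                "baseline_lvef": df["x2"],
                "synchrony": np.random.default_rng(seed + 1).normal(0, 1, n),
                "entropy": np.random.default_rng(seed + 2).normal(0, 1, n),
                "phase_sd": np.random.default_rng(seed + 3).normal(0, 1, n),
                "group": np.where(df["y"] == 1, "ctrcd", "stable"),
            }
        )
        return out

    def test_reduced_model_recovers_coefficients(self):
        coef = (-1.0, 0.8, -0.6, 0.4)
        res = cs.fit_logistic(self._named_cohort(4000, coef, 0), "reduced")
        assert res.coefficients["apen"] == pytest.approx(0.8, abs=0.15)
        assert res.coefficients["baseline_lvef"] == pytest.approx(-0.6, abs=0.15)
        assert res.coefficients["apen_x_lvef"] == pytest.approx(0.4, abs=0.15)
        assert 0.5 < res.auc <= 1.0
        assert res.model_chi2_p < 1e-6

    def test_full_model_has_all_predictors(self):
        res = cs.fit_logistic(self._named_cohort(1000, (-1.0, 0.8, -0.6, 0.4), 1), "full")
        assert set(res.coefficients) == {"const", *cs.FULL_PREDICTORS}

    def test_single_class_rejected(self):
        cohort = self._named_cohort(100, (0.0, 0.0, 0.0, 0.0), 2)
        cohort["group"] = "stable"
        with pytest.raises(ValueError, match="single class"):
            cs.fit_logistic(cohort, "reduced")

    def test_perfect_separation_rejected(self):
        n = 60
        cohort = pd.DataFrame(
            {
                "apen": np.r_[np.zeros(30), np.ones(30)],
                "baseline_lvef": np.random.default_rng(0).normal(0, 1, n),
                "group": ["stable"] * 30 + ["ctrcd"] * 30,
            }
        )
        with pytest.raises(ValueError, match="logistic fit"):
            cs.fit_logistic(cohort, "reduced")

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            cs.fit_logistic(self._named_cohort(100, (0.0,) * 4, 3), "huge")


class TestCvClassifiers:
    def test_deterministic_under_seed(self):
        cohort = sd.make_cohort(sd.CohortSpec(n_stable=60, n_ctrcd=20, seed=6))
        a = cs.cv_classifiers(cohort, folds=5, repeats=2, seed=3)
        b = cs.cv_classifiers(cohort, folds=5, repeats=2, seed=3)
        assert a["random-forest"].fold_aucs == b["random-forest"].fold_aucs
        assert a["naive-bayes"].mean_auc == b["naive-bayes"].mean_auc

    def test_strong_separation_high_auc(self):
        rng = np.random.default_rng(7)
        n1, n2 = 80, 40
        cohort = pd.DataFrame(
            {
                "apen": np.r_[rng.normal(0, 1, n1), rng.normal(5, 1, n2)],
                "synchrony": np.r_[rng.normal(0, 1, n1), rng.normal(5, 1, n2)],
                "entropy": rng.normal(0, 1, n1 + n2),
                "phase_sd": rng.normal(0, 1, n1 + n2),
                "baseline_lvef": rng.normal(70, 5, n1 + n2),
                "group": ["stable"] * n1 + ["ctrcd"] * n2,
            }
        )
        res = cs.cv_classifiers(cohort, seed=0)
        assert res["random-forest"].mean_auc > 0.95
        assert res["naive-bayes"].mean_auc > 0.95
        assert res["random-forest"].n_valid_resamples == 30

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(8)
        aucs = []
        for rep in range(10):
            n = 120
            cohort = pd.DataFrame(
                {
                    "apen": rng.normal(0, 1, n),
                    "synchrony": rng.normal(0, 1, n),
                    "entropy": rng.normal(0, 1, n),
                    "phase_sd": rng.normal(0, 1, n),
                    "baseline_lvef": rng.normal(70, 5, n),
                    "group": ["stable"] * 90 + ["ctrcd"] * 30,
                }
            )
            res = cs.cv_classifiers(cohort, folds=5, repeats=1, seed=rep)
            aucs.append(res["naive-bayes"].mean_auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_single_class_rejected(self):
        cohort = sd.make_cohort(sd.CohortSpec(n_stable=20, n_ctrcd=2, seed=9))
        cohort["group"] = "stable"
        with pytest.raises(ValueError):
            cs.cv_classifiers(cohort)


class TestExcludeBaseline:
    def test_low_lvef_excluded(self):
        cohort = pd.DataFrame(
            {"patient_id": list("abcde"), "baseline_lvef": [60, 62, 54, 70, 58]}
        )
        kept, report = cs.exclude_baseline(cohort)
        assert len(kept) == 4
        assert report["lvef"] == 1
        assert report["remaining"] == 4

    def test_no_exclusions_identity(self):
        cohort = pd.DataFrame({"patient_id": ["a", "b"], "baseline_lvef": [60.0, 70.0]})
        kept, report = cs.exclude_baseline(cohort)
        pd.testing.assert_frame_equal(kept, cohort)
        assert report["excluded"] == 0

    def test_study_accounting_fixture_193_to_177(self):
        # 193 candidates: 11 gating problems, 4 low LVEF, 1 poor quality
        n = 193
        rng = np.random.default_rng(10)
        cohort = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "baseline_lvef": rng.uniform(56, 80, n),
                "gating_problem": False,
                "poor_quality": False,
            }
        )
        cohort.loc[:10, "gating_problem"] = True
        cohort.loc[11:14, "baseline_lvef"] = 50.0
        cohort.loc[15, "poor_quality"] = True
        kept, report = cs.exclude_baseline(cohort)
        assert len(kept) == 177
        assert report == {
            "gating_problem": 11,
            "poor_quality": 1,
            "lvef": 4,
            "excluded": 16,
            "remaining": 177,
        }

    def test_each_record_counted_once(self):
        cohort = pd.DataFrame(
            {
                "patient_id": ["a"],
                "baseline_lvef": [40.0],
                "gating_problem": [True],
            }
        )
        _, report = cs.exclude_baseline(cohort)
        assert report["gating_problem"] == 1
        assert report["lvef"] == 0
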