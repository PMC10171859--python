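"""Concordance tabulation, kappa, point-biserial, correlations, group tests."""

import numpy as np
import pandas as pd
import pytest

from remyetrack.core import LesionClass
from remyetrack.stats import (
    ConfusionMatrix2x2,
    binarize_and_tabulate,
    cohen_kappa,
    concordance_report,
    correlate_age_opc,
    group_compare,
    point_biserial,
    point_biserial_permutation_p,
    sensitivity_specificity,
)

CLASSES = ["early_active", "chronic_demyelinated", "remyelinated"]


def table(mri, histo, **extra):
    df = pd.DataFrame({"mri_category": mri, "histo_category": histo})
    for k, v in extra.items():
        df[k] = v
    return df


class TestBinarizeAndTabulate:
    def test_reference_cohort_reconstruction(self):
        # 19 concordant demyelinated, 3 MRI-remyel/histo-demyel,
        # 0 MRI-demyel/histo-remyel, 9 concordant remyelinated
        mri = (["early_active"] * 10 + ["chronic_demyelinated"] * 9
               + ["remyelinated"] * 3 + ["remyelinated"] * 9)
        histo = (["early_active"] * 10 + ["chronic_demyelinated"] * 9
                 + ["chronic_demyelinated"] * 3 + ["remyelinated"] * 9)
        cm = binarize_and_tabulate(table(mri, histo))
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (9, 0, 3, 19)

    def test_all_concordant_has_no_errors(self):
        cm = binarize_and_tabulate(table(CLASSES, CLASSES))
        assert cm.fp == 0 and cm.fn == 0

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            mri = [CLASSES[i] for i in rng.integers(0, 3, n)]
            histo = [CLASSES[i] for i in rng.integers(0, 3, n)]
            cm = binarize_and_tabulate(table(mri, histo))
            tp = fn = fp = tn = 0
            for m, h in zip(mri, histo):
                mr, hr = m == "remyelinated", h == "remyelinated"
                tp += mr and hr
                fp += mr and not hr
                fn += hr and not mr
                tn += not mr and not hr
            assert (cm.tp, cm.fn, cm.fp, cm.tn) == (tp, fn, fp, tn)
            assert cm.total == n

    def test_rows_without_histology_excluded(self):
        df = table(["remyelinated", "early_active"], ["remyelinated", None])
        cm = binarize_and_tabulate(df)
        assert cm.total == 1


class TestSensitivitySpecificity:
    def test_reference_confusion_matrix_values(self):
        cm = ConfusionMatrix2x2(tp=9, fn=0, fp=3, tn=19)
        sens, spec = sensitivity_specificity(cm)
        assert sens == 1.0
        assert spec == pytest.approx(19 / 22)

    def test_perfect_matrix(self):
        assert sensitivity_specificity(
            ConfusionMatrix2x2(tp=5, fn=0, fp=0, tn=7)) == (1.0, 1.0)

    def test_zero_denominator_names_quantity(self):
        with pytest.raises(ValueError, match="sensitivity"):
            sensitivity_specificity(ConfusionMatrix2x2(tp=0, fn=0, fp=1, tn=1))
        with pytest.raises(ValueError, match="specificity"):
            sensitivity_specificity(ConfusionMatrix2x2(tp=1, fn=1, fp=0, tn=0))

    def test_matches_definition_on_random_matrices(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            tp, fn, fp, tn = rng.integers(1, 30, 4)
            cm = ConfusionMatrix2x2(int(tp), int(fn), int(fp), int(tn))
            sens, spec = sensitivity_specificity(cm)
            assert sens == pytest.approx(tp / (tp + fn))
            assert spec == pytest.approx(tn / (tn + fp))


class TestCohenKappa:
    def test_identical_vectors_give_one(self):
        v = ["a", "b", "c", "a", "b"]
        assert cohen_kappa(v, v) == 1.0

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(11)
        a = list(rng.integers(0, 3, 10_000))
        b = list(rng.integers(0, 3, 10_000))
        assert abs(cohen_kappa(a, b)) < 0.03

    def test_hand_computed_contingency(self):
        # 50 items, 94% raw agreement (47 matches), 3 systematic confusions
        a = [0] * 20 + [1] * 15 + [2] * 15
        b = [0] * 20 + [1] * 12 + [2] * 3 + [2] * 15
        # oracle: explicit p_o / p_e arithmetic
        n = 50
        p_o = 47 / n
        pa = [20 / n, 15 / n, 15 / n]
        pb = [20 / n, 12 / n, 18 / n]
        p_e = sum(x * y for x, y in zip(pa, pb))
        expected = (p_o - p_e) / (1 - p_e)
        assert cohen_kappa(a, b) == pytest.approx(expected)
        assert p_o == pytest.approx(0.94)

    def test_matches_sklearn_on_random_vectors(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            a = list(rng.integers(0, 3, n))
            b = list(rng.integers(0, 3, n))
            if len(set(a)) == 1 and a == b:
                continue  # degenerate marginals
            assert cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)

    def test_bounds_and_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            cohen_kappa([1, 2], [1, 2, 3])
        rng = np.random.default_rng(13)
        for _ in range(50):
            a = list(rng.integers(0, 2, 10))
            b = list(rng.integers(0, 2, 10))
            assert -1.0 - 1e-12 <= cohen_kappa(a, b) <= 1.0 + 1e-12


class TestPointBiserial:
    def test_perfect_prediction(self):
        r, p = point_biserial([0, 0, 0, 1, 1, 1], [0, 0, 0, 1, 1, 1])
        assert r == pytest.approx(1.0)

    def test_constant_outcome_raises(self):
        with pytest.raises(ValueError, match="constant"):
            point_biserial([0, 1, 0, 1], [2.0, 2.0, 2.0, 2.0])

    def test_steroid_subgroups_not_significant(self):
        from remyetrack.datasets import steroid_binary_vectors
        treated, remyel = steroid_binary_vectors()
        r, p = point_biserial(treated, remyel)
        p_perm = point_biserial_permutation_p(treated, remyel)
        assert p > 0.05 and p_perm > 0.05
        assert abs(p - p_perm) < 0.15  # t approximation near the exact p

    def test_permutation_p_matches_montecarlo_for_binary(self):
        rng = np.random.default_rng(14)
        x = np.array([1] * 8 + [0] * 7)
        y = rng.integers(0, 2, 15).astype(float)
        p_exact = point_biserial_permutation_p(x, y)
        r_obs, _ = point_biserial(x, y)
        hits = 0
        n_mc = 4000
        for _ in range(n_mc):
            r_p = np.corrcoef(x, rng.permutation(y))[0, 1]
            hits += abs(r_p) >= abs(r_obs) - 1e-12
        assert p_exact == pytest.approx(hits / n_mc, abs=0.03)


class TestCorrelateAgeOpc:
    def test_perfect_antimonotone(self):
        df = pd.DataFrame({"lesion_age_weeks": [1, 2, 3, 4],
                           "opc_count": [40, 30, 20, 10]})
        r, p = correlate_age_opc(df)
        assert r == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({"lesion_age_weeks": rng.normal(size=1000),
                           "opc_count": rng.normal(size=1000)})
        r, _ = correlate_age_opc(df)
        assert abs(r) < 0.1

    def test_synthetic_cohorts_recover_negative_sign(self):
        from remyetrack.synthgen import SimulationConfig, sample_ground_truth
        sign_correct = 0
        for seed in range(100):
            cfg = SimulationConfig(n_lesions=30, seed=seed,
                                   grid_shape=(8, 8, 4))
            _, lesions = sample_ground_truth(cfg, place_geometry=False)
            terminal = (cfg.n_timepoints - 1) * cfg.scan_interval_weeks
            df = pd.DataFrame({
                "lesion_age_weeks": [terminal - l.onset_week for l in lesions],
                "opc_count": [l.histo_truth.opc_count for l in lesions],
            })
            r, _ = correlate_age_opc(df)
            sign_correct += r < 0
        assert sign_correct >= 95

    def test_insufficient_rows_raise(self):
        df = pd.DataFrame({"lesion_age_weeks": [1, 2], "opc_count": [3, 4]})
        with pytest.raises(ValueError, match=">= 3"):
            correlate_age_opc(df)


class TestGroupCompare:
    def test_identical_groups_t_statistic_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        stat, p = group_compare({"a": g, "b": g}, "t_test")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_histology_moments_highly_significant(self):
        # NAWM 2.6 +- 0.3 vs remyelinated 4.5 +- 1.1 unstained PLP, n=30
        rng_master = np.random.default_rng(16)
        hits = 0
        for _ in range(100):
            nawm = rng_master.normal(2.6, 0.3, 30)
            remyel = rng_master.normal(4.5, 1.1, 30)
            _, p = group_compare({"nawm": nawm, "remyel": remyel}, "t_test")
            hits += p < 0.001
        assert hits >= 95

    def test_anova_three_groups(self):
        rng = np.random.default_rng(17)
        groups = {k: rng.normal(loc, 1.0, 20)
                  for k, loc in (("a", 0.0), ("b", 0.0), ("c", 3.0))}
        stat, p = group_compare(groups, "anova")
        assert p < 1e-6

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValueError):
            group_compare({"a": [1.0], "b": [1.0, 2.0]}, "t_test")
        with pytest.raises(ValueError, match="unknown test"):
            group_compare({"a": [1.0, 2.0], "b": [3.0, 4.0]}, "wilcoxon")


class TestConcordanceReport:
    def test_flags_discrepant_stated_specificity(self):
        mri = ["remyelinated"] * 12 + ["chronic_demyelinated"] * 19
        histo = (["remyelinated"] * 9 + ["chronic_demyelinated"] * 3
                 + ["chronic_demyelinated"] * 19)
        rep = concordance_report(table(mri, histo), stated_specificity_pct=90.0)
        assert rep["sensitivity_pct"] == 100.0
        assert rep["specificity_pct"] == pytest.approx(100 * 19 / 22)
        assert rep["specificity_discrepancy"] is True
        assert rep["accuracy_pct"] == pytest.approx(100 * 28 / 31)
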