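"""Concordance/ROC, step-down selection, bootstrap optimism, calibration, LOO."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tp53conform.logistic import fit_logistic
from tp53conform.validation import (
    StepdownPhenotypeLogit,
    auc,
    backward_stepdown,
    bootstrap_calibrate,
    bootstrap_validate,
    concordance_statistic,
    loo_cross_validate,
    manual_reduce,
    roc_curve,
    term_pvalues,
)


class TestConcordance:
    def test_perfect_separation(self):
        probs = [0.9, 0.8, 0.2, 0.1]
        assert concordance_statistic(probs, [1, 1, 0, 0]) == 1.0

    def test_constant_scores_all_ties(self):
        assert concordance_statistic([0.4] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        probs = rng.random(20)
        probs[5] = probs[11]  # force a tie across classes
        y = rng.integers(0, 2, 20)
        y[:2], y[-2:] = 1, 0  # both classes guaranteed
        pos = probs[y == 1]
        neg = probs[y == 0]
        count = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        oracle = count / (len(pos) * len(neg))
        assert concordance_statistic(probs, y) == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn_auroc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        probs = rng.random(60)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 1, 0
        assert concordance_statistic(probs, y) == pytest.approx(
            roc_auc_score(y, probs), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            concordance_statistic([0.5, 0.6], [1, 1])


class TestROC:
    def test_perfect_separation_passes_corner(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ((curve["fpr"] == 0.0) & (curve["tpr"] == 1.0)).any()
        assert auc(curve) == 1.0

    def test_constant_scores_give_diagonal(self):
        curve = roc_curve([0.4] * 8, [1, 0, 1, 0, 1, 0, 1, 0])
        assert auc(curve) == pytest.approx(0.5)

    def test_auc_equals_concordance_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            probs = np.round(rng.random(50), 2)  # rounding forces ties
            y = rng.integers(0, 2, 50)
            y[0], y[1] = 1, 0
            assert auc(roc_curve(probs, y)) == pytest.approx(
                concordance_statistic(probs, y), abs=1e-12
            )


class TestStepdown:
    def test_all_significant_terms_kept(self):
        rng = np.random.default_rng(4)
        n = 300
        df = pd.DataFrame(
            {"x1": rng.normal(size=n), "x2": rng.normal(size=n)},
            index=[f"v{i}" for i in range(n)],
        )
        lp = 1.5 * df["x1"] - 1.5 * df["x2"]
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        model = backward_stepdown(df, y, ["x1", "x2"], sls=0.13)
        assert set(model.terms) == {"x1", "x2"}

    def test_true_predictor_survives_noise(self):
        """One real effect among 5 noise terms is retained in >=90% of runs."""
        hits, drops = 0, 0
        n_runs = 12
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            n = 400
            df = pd.DataFrame(
                {"signal": rng.normal(size=n),
                 **{f"noise{i}": rng.normal(size=n) for i in range(5)}},
                index=[f"v{i}" for i in range(n)],
            )
            lp = 1.2 * df["signal"]
            y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
            model = backward_stepdown(df, y, list(df.columns), sls=0.13)
            hits += "signal" in model.terms
            n_noise_kept = sum(t.startswith("noise") for t in model.terms)
            drops += (5 - n_noise_kept) >= 4
        assert hits >= 0.9 * n_runs
        assert drops >= 0.9 * n_runs

    def test_stepdown_estimator_exposes_selected_terms(self, cohort_features):
        est = StepdownPhenotypeLogit(terms=["Bur", "comp_dif", "xray_dif"], sls=0.13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(cohort_features, cohort_features["outcome"])
        assert set(est.terms_) <= {"Bur", "comp_dif", "xray_dif"}
        assert est.predict_proba(cohort_features).shape[0] == len(cohort_features)


class TestManualReduce:
    def test_drops_single_least_significant_term(self):
        rng = np.random.default_rng(6)
        n = 200
        df = pd.DataFrame(
            {"strong": rng.normal(size=n), "weak": rng.normal(size=n)},
            index=[f"v{i}" for i in range(n)],
        )
        lp = 1.5 * df["strong"]
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        model = fit_logistic(df, y, ["strong", "weak"])
        pv = term_pvalues(model)
        assert pv["weak"] > pv["strong"]
        reduced = manual_reduce(model, df, y)
        assert reduced.terms == ("strong",)

    def test_single_term_model_rejected(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(5), np.ones(5)]},
                          index=[f"v{i}" for i in range(10)])
        y = [0, 0, 0, 1, 0, 1, 1, 1, 0, 1]
        model = fit_logistic(df, y, ["x"])
        with pytest.raises(ValueError):
            manual_reduce(model, df, y)


def noise_cohort(seed, n=48, p=10):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(p)},
                      index=[f"v{i}" for i in range(n)])
    y = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
    return df, y


class TestBootstrapValidate:
    def test_seeded_reproducibility(self):
        df, y = noise_cohort(0)
        a = bootstrap_validate(df, y, list(df.columns), n_boot=25, seed=42)
        b = bootstrap_validate(df, y, list(df.columns), n_boot=25, seed=42)
        assert a == b

    def test_overfitting_detected_on_pure_noise(self):
        """corrected_C < apparent_C on pure-noise 10-variable n=48 cohorts."""
        wins = 0
        n_exp = 12
        for seed in range(n_exp):
            df, y = noise_cohort(seed)
            rep = bootstrap_validate(df, y, list(df.columns), n_boot=200, seed=seed)
            wins += rep.corrected_C < rep.apparent_C
            assert rep.corrected_C == pytest.approx(rep.apparent_C - rep.optimism)
        assert wins >= 0.95 * n_exp

    def test_low_overfit_regime_with_strong_signal(self):
        rng = np.random.default_rng(10)
        n = 500
        df = pd.DataFrame({"x": rng.normal(size=n)}, index=[f"v{i}" for i in range(n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-2.0 * df["x"]))).astype(float)
        rep = bootstrap_validate(df, y, ["x"], n_boot=60, seed=3, stepdown=False)
        assert rep.optimism < 0.02

    def test_selected_terms_recorded(self):
        df, y = noise_cohort(1)
        rep = bootstrap_validate(df, y, list(df.columns), n_boot=10, seed=0)
        assert len(rep.selected_terms_per_replicate) == rep.n_boot


class TestBootstrapCalibrate:
    def test_well_specified_model_is_calibrated(self):
        rng = np.random.default_rng(8)
        n = 3000  # per-bin binomial noise must sit well below the 0.1 band
        df = pd.DataFrame({"x": rng.normal(size=n)}, index=[f"v{i}" for i in range(n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * df["x"]))).astype(float)
        curve = bootstrap_calibrate(df, y, ["x"], n_boot=60, seed=5)
        mask = curve.n_per_bin >= 30
        assert mask.any()
        assert np.nanmax(np.abs(curve.corrected[mask] - curve.bin_midpoints[mask])) < 0.1

    def test_same_seed_reproducible(self):
        df, y = noise_cohort(2)
        a = bootstrap_calibrate(df, y, ["x0", "x1"], n_boot=20, seed=7)
        b = bootstrap_calibrate(df, y, ["x0", "x1"], n_boot=20, seed=7)
        np.testing.assert_array_equal(a.corrected, b.corrected)

    def test_overfit_model_calibrates_worse(self, cohort_features):
        """A 12-variable fit on n=48 mis-calibrates more than a 2-term fit."""
        from tp53conform.features import DIF_VARIABLES

        y = cohort_features["outcome"]
        maes = {}
        for label, terms in {
            "full": ["Bur", *DIF_VARIABLES],
            "small": ["Bur", "comp_dif"],
        }.items():
            errs = []
            for seed in range(5):
                curve = bootstrap_calibrate(
                    cohort_features, y, terms, n_boot=40, seed=seed
                )
                mask = curve.n_per_bin > 0
                errs.append(
                    np.nanmean(np.abs(curve.corrected[mask] - curve.bin_midpoints[mask]))
                )
            maes[label] = np.mean(errs)
        assert maes["full"] > maes["small"]


class TestLoo:
    def test_contract_one_prediction_per_row(self, cohort_features):
        y = cohort_features["outcome"]
        preds = loo_cross_validate(
            cohort_features, y, ["Bur", "comp_dif", "PPI6_dif"], sls=0.16
        )
        assert len(preds) == len(cohort_features)
        assert [p.variant_id for p in preds] == list(cohort_features.index)
        assert all(0.0 <= p.probability_LFS <= 1.0 for p in preds)

    def test_left_out_label_cannot_influence_its_prediction(self, cohort_features):
        """Perturbing row i's outcome leaves fold i's prediction unchanged."""
        y = cohort_features["outcome"].copy()
        terms = ["Bur", "comp_dif", "PPI6_dif"]
        base = loo_cross_validate(cohort_features, y, terms, sls=0.16)
        i = 5
        y_flipped = y.copy()
        y_flipped.iloc[i] = "HBC" if y.iloc[i] == "LFS" else "LFS"
        perturbed = loo_cross_validate(cohort_features, y_flipped, terms, sls=0.16)
        assert perturbed[i].probability_LFS == pytest.approx(
            base[i].probability_LFS, abs=1e-12
        )

    def test_separable_data_mostly_correct_at_half(self):
        rng = np.random.default_rng(12)
        n = 40
        df = pd.DataFrame({"x": np.r_[rng.normal(2.5, 1, n // 2),
                                      rng.normal(-2.5, 1, n // 2)]},
                          index=[f"v{i}" for i in range(n)])
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        preds = loo_cross_validate(df, y, ["x"], sls=0.16)
        correct = sum(
            (p.probability_LFS > 0.5) == (y[i] == 1) for i, p in enumerate(preds)
        )
        assert correct >= 0.9 * n

    def test_too_small_input_rejected(self):
        df = pd.DataFrame({"x": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            loo_cross_validate(df, ["LFS", "HBC"], ["x"])
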