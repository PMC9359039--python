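import json

import numpy as np
import pandas as pd
import pytest

from contourqa import (
    MULTI_METRIC_COMBINATIONS,
    REFERENCE_THRESHOLDS,
    average_thresholds,
    cross_validate,
    fit_multi_metric,
    fit_single_metric,
    fixed_sensitivity_threshold,
    reference_model,
    roc_auc,
    sweep_C,
)
from contourqa.qa_classifier import QAModel, resolve_metric_set, threshold_accuracy
from contourqa.surface_metrics import METRIC_NAMES, MetricVector, SDSC_TOLERANCES_MM

from _oracles import hinge_threshold, pair_counting_auc, sweep_operating_point


def make_labels(n_bad, n_good):
    return ["unacceptable"] * n_bad + ["acceptable"] * n_good


def gaussian_1d(seed=0, n=40, mu_bad=0.45, mu_good=0.85, sd=0.12):
    rng = np.random.default_rng(seed)
    vals = np.concatenate([rng.normal(mu_bad, sd, n), rng.normal(mu_good, sd, n)])
    return vals, make_labels(n, n)


def labelled_frame(values, labels, metric="sdsc_2"):
    n = len(values)
    return pd.DataFrame({metric: values, "label": labels,
                         "source_set": ["synthetic"] * n})


class TestSingleMetricFit:
    def test_separable_similarity_metric(self):
        vals = [0.10, 0.20, 0.30, 0.70, 0.80, 0.90]
        m = fit_single_metric(vals, make_labels(3, 3), 10.0, "sdsc_2")
        assert 0.30 < m.threshold < 0.70
        assert m.direction == "flag_if_below"
        assert all(m.predict({"sdsc_2": v}) == lab
                   for v, lab in zip(vals, make_labels(3, 3)))

    def test_separable_distance_metric_flags_above(self):
        vals = [9.0, 8.0, 7.0, 2.0, 1.5, 1.0]  # high distance = bad
        m = fit_single_metric(vals, make_labels(3, 3), 10.0, "msd")
        assert m.direction == "flag_if_above"
        assert 2.0 < m.threshold < 7.0

    @pytest.mark.parametrize("C", [1.0, 10.0, 50.0])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_threshold_matches_hinge_loss_oracle(self, C, seed):
        """SVC threshold equals direct primal minimisation of the soft margin."""
        vals, labels = gaussian_1d(seed)
        m = fit_single_metric(vals, labels, C, "m")
        t_oracle = hinge_threshold(vals, labels, C)
        assert m.threshold == pytest.approx(t_oracle, abs=5e-3)

    def test_threshold_reproduces_decision_function(self):
        vals, labels = gaussian_1d(3)
        m = fit_single_metric(vals, labels, 10.0, "m")
        rng = np.random.default_rng(99)
        probes = rng.uniform(vals.min() - 0.2, vals.max() + 0.2, 10_000)
        via_threshold = m.predict_many(probes.reshape(-1, 1))
        via_df = (m.decision_function(probes.reshape(-1, 1)) > 0).astype(int)
        np.testing.assert_array_equal(via_threshold, via_df)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_single_metric([0.1, 0.2, 0.3], ["acceptable"] * 3, 10.0)

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fit_single_metric([0.1, np.inf, 0.8, 0.9], make_labels(2, 2), 10.0)


class TestMultiMetricFit:
    def test_named_combinations_resolve(self):
        assert resolve_metric_set("Three_SDSC") == ("sdsc_1", "sdsc_2", "sdsc_3")
        assert resolve_metric_set("All_metrics") == tuple(METRIC_NAMES)
        assert MULTI_METRIC_COMBINATIONS["DSC_HD"] == ("dsc", "hd_100")

    def test_unknown_combination_rejected(self):
        with pytest.raises(KeyError):
            resolve_metric_set("Best_metrics")

    def test_linearly_separable_two_metric_data(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal([0.3, 0.2], 0.05, (20, 2)),
                       rng.normal([0.8, 0.9], 0.05, (20, 2))])
        df = pd.DataFrame(X, columns=["sdsc_1", "sdsc_2"])
        m = fit_multi_metric(df, make_labels(20, 20), kernel="linear")
        pred = m.predict_many(X)
        assert (pred == np.array([1] * 20 + [0] * 20)).all()

    @pytest.mark.parametrize("kernel", ["linear", "poly", "rbf", "sigmoid"])
    def test_all_four_kernels_fit_and_predict(self, kernel):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0.3, 0.08, (25, 3)),
                       rng.normal(0.8, 0.08, (25, 3))])
        m = fit_multi_metric(X, make_labels(25, 25), kernel=kernel,
                             metric_set=("sdsc_1", "sdsc_2", "sdsc_3"))
        acc = (m.predict_many(X) == np.array([1] * 25 + [0] * 25)).mean()
        assert acc > 0.8  # sigmoid is allowed to be worse, but not broken


class TestPredictContract:
    def test_reference_threshold_application(self):
        m = reference_model("sdsc_2")
        assert m.threshold == 0.54
        vec = {name: 0.9 for name in METRIC_NAMES}
        vec["sdsc_2"] = 0.60
        assert m.predict(vec) == "acceptable"
        vec["sdsc_2"] = 0.50
        assert m.predict(vec) == "unacceptable"

    def test_value_exactly_at_threshold_passes(self):
        m = reference_model("sdsc_2")
        assert m.predict({"sdsc_2": 0.54}) == "acceptable"

    def test_degenerate_vector_always_flags(self):
        m = reference_model("sdsc_2")
        vec = MetricVector(dsc=1.0, hd_100=0.0, hd_95=0.0, msd=0.0,
                           sdsc={t: 1.0 for t in SDSC_TOLERANCES_MM},
                           degenerate_flag=True)
        assert m.predict(vec) == "unacceptable"

    def test_missing_metric_rejected(self):
        m = reference_model("sdsc_2")
        with pytest.raises(KeyError):
            m.predict({"dsc": 0.9})

    def test_all_reference_thresholds_load(self):
        for metric, threshold in REFERENCE_THRESHOLDS.items():
            m = reference_model(metric)
            assert m.threshold == threshold and m.direction == "flag_if_below"


class TestSerialization:
    @pytest.mark.parametrize("kernel", ["linear", "rbf"])
    def test_json_round_trip_preserves_predictions(self, kernel):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0.4, 0.1, (15, 2)),
                       rng.normal(0.8, 0.1, (15, 2))])
        m = fit_multi_metric(X, make_labels(15, 15), kernel=kernel,
                             metric_set=("sdsc_1", "sdsc_2"))
        back = QAModel.from_json(m.to_json())
        probes = rng.uniform(0, 1, (200, 2))
        np.testing.assert_array_equal(m.predict_many(probes),
                                      back.predict_many(probes))
        json.loads(m.to_json())  # valid JSON


class TestCrossValidation:
    def test_perfectly_separable_gives_unit_accuracy(self):
        vals = np.concatenate([np.linspace(0.0, 0.4, 12),
                               np.linspace(0.7, 1.0, 12)])
        df = labelled_frame(vals, make_labels(12, 12))
        rep = cross_validate(df, "sdsc_2", seed=0)
        assert rep.mean_accuracy == 1.0 and rep.sd_accuracy == 0.0

    def test_fold_sizes_balanced_within_source_set(self):
        rng = np.random.default_rng(0)
        sets = (["ref_vs_verif_internal"] * 10 + ["ref_vs_verif_external"] * 8
                + ["acceptable_manual"] * 7 + ["unacceptable_manual"] * 9)
        n = len(sets)
        df = pd.DataFrame({
            "sdsc_2": np.concatenate([rng.uniform(0.7, 1, n - 9),
                                      rng.uniform(0, 0.4, 9)]),
            "label": make_labels(0, n - 9) + ["unacceptable"] * 9,
            "source_set": sets[:n - 9] + ["unacceptable_manual"] * 9,
        })
        rep = cross_validate(df, "sdsc_2", seed=1)
        folds = rep.fold_assignments
        for s in set(sets):
            counts = np.bincount(folds[np.asarray(df["source_set"]) == s],
                                 minlength=3)
            assert counts.max() - counts.min() <= 1

    def test_shuffled_labels_accuracy_near_class_prior(self):
        rng = np.random.default_rng(7)
        n = 300
        vals = rng.uniform(0, 1, n)
        labels = np.array(make_labels(n // 3, n - n // 3))
        rng.shuffle(labels)
        df = labelled_frame(vals, list(labels))
        rep = cross_validate(df, "sdsc_2", seed=7)
        prior = max((labels == "acceptable").mean(),
                    (labels == "unacceptable").mean())
        # mean accuracy should sit near the majority-class rate
        sd = np.sqrt(prior * (1 - prior) / n)
        assert abs(rep.mean_accuracy - prior) < 3 * sd + 0.05

    def test_seeded_folds_bit_reproducible(self):
        vals, labels = gaussian_1d(5, n=15)
        df = labelled_frame(vals, labels)
        r1 = cross_validate(df, "sdsc_2", seed=11)
        r2 = cross_validate(df, "sdsc_2", seed=11)
        np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)
        np.testing.assert_array_equal(r1.accuracy, r2.accuracy)

    def test_too_few_rows_per_set_rejected(self):
        df = labelled_frame([0.1, 0.9], make_labels(1, 1))
        with pytest.raises(ValueError, match="fewer than"):
            cross_validate(df, "sdsc_2")


class TestSweepC:
    def test_separable_data_ties_resolve_to_ten(self):
        vals = np.concatenate([np.linspace(0, 0.3, 9), np.linspace(0.7, 1, 9)])
        df = labelled_frame(vals, make_labels(9, 9))
        out = sweep_C(df, "sdsc_2", C_grid=range(1, 51), seed=0)
        assert (out["mean_accuracy"] == 1.0).all()
        assert out.attrs["best_C"] == 10

    def test_single_value_grid(self):
        vals, labels = gaussian_1d(2, n=9)
        out = sweep_C(labelled_frame(vals, labels), "sdsc_2", C_grid=[10], seed=0)
        assert len(out) == 1 and out.attrs["best_C"] == 10

    def test_empty_grid_rejected(self):
        vals, labels = gaussian_1d(2, n=9)
        with pytest.raises(ValueError):
            sweep_C(labelled_frame(vals, labels), "sdsc_2", C_grid=[])

    def test_bit_reproducible_under_seed(self):
        vals, labels = gaussian_1d(8, n=12)
        df = labelled_frame(vals, labels)
        a = sweep_C(df, "sdsc_2", C_grid=[1, 10, 25], seed=3)
        b = sweep_C(df, "sdsc_2", C_grid=[1, 10, 25], seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestFixedSensitivity:
    def test_fully_separable_reaches_both_unit_rates(self):
        vals = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        op = fixed_sensitivity_threshold(vals, make_labels(3, 3), 0.95)
        assert op.sensitivity == 1.0 and op.specificity == 1.0

    def test_target_one_flags_every_unacceptable(self):
        vals, labels = gaussian_1d(1, n=30)
        op = fixed_sensitivity_threshold(vals, labels, 1.0)
        assert op.sensitivity == 1.0
        bad = vals[:30]
        assert op.threshold > bad.max()  # beyond the worst unacceptable value

    @pytest.mark.parametrize("target", [0.8, 0.9, 0.95])
    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_matches_exhaustive_sweep_oracle(self, target, seed):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([rng.normal(0.45, 0.2, 25),
                               rng.normal(0.8, 0.15, 35)])
        labels = make_labels(25, 35)
        op = fixed_sensitivity_threshold(vals, labels, target)
        spec, sens, acc = sweep_operating_point(vals, labels, target)
        assert op.specificity == pytest.approx(spec, abs=1e-12)
        assert op.sensitivity >= target
        assert op.accuracy == pytest.approx(acc, abs=1e-12)

    def test_achieved_sensitivity_never_below_target(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n_bad = int(rng.integers(3, 15))
            n_good = int(rng.integers(3, 15))
            vals = rng.uniform(0, 1, n_bad + n_good)
            target = float(rng.uniform(0.5, 1.0))
            op = fixed_sensitivity_threshold(vals, make_labels(n_bad, n_good),
                                             target)
            assert op.sensitivity >= target


class TestAverageThresholds:
    def _model(self, threshold, structure, metric="sdsc_2",
               direction="flag_if_below"):
        m = reference_model("sdsc_2")
        m.threshold = threshold
        m.direction = direction
        m.structure_name = structure
        m.metric_set = (metric,)
        return m

    def test_pooled_is_arithmetic_mean(self):
        out = average_thresholds([self._model(0.5, "bladder"),
                                  self._model(0.7, "rectum")])
        assert (out["pooled_threshold"] == 0.6).all()

    def test_mixed_directions_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            average_thresholds([
                self._model(0.5, "bladder"),
                self._model(0.7, "rectum", direction="flag_if_above"),
            ])

    def test_single_structure_rejected(self):
        with pytest.raises(ValueError, match="2 structures"):
            average_thresholds([self._model(0.5, "bladder")])

    def test_pooled_accuracy_never_beats_own_optimum(self):
        # own threshold is refit per structure, pooled is the average:
        # on training data the structure-optimal sweep dominates
        rng = np.random.default_rng(3)
        models, data = [], {}
        for structure, mu_bad in [("bladder", 0.35), ("rectum", 0.55)]:
            vals = np.concatenate([rng.normal(mu_bad, 0.1, 30),
                                   rng.normal(0.9, 0.05, 30)])
            labels = make_labels(30, 30)
            m = fit_single_metric(vals, labels, 10.0, "sdsc_2",
                                  structure_name=structure)
            models.append(m)
            data[structure] = (pd.DataFrame({"sdsc_2": vals}), labels)
        out = average_thresholds(models, data)
        for _, row in out.iterrows():
            vals, labels = data[row["structure"]]
            best = max(
                threshold_accuracy(vals["sdsc_2"], labels, t, row["direction"])
                for t in np.linspace(0, 1, 2001)
            )
            assert row["pooled_accuracy"] <= best + 1e-12


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        vals = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        r = roc_auc(vals, make_labels(3, 3), n_boot=200, seed=0)
        assert r.auc == 1.0

    def test_auc_equals_pair_counting_for_small_n(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n_bad = int(rng.integers(2, 7))
            n_good = int(rng.integers(2, 7))
            vals = np.round(rng.uniform(0, 1, n_bad + n_good), 2)  # allow ties
            labels = make_labels(n_bad, n_good)
            r = roc_auc(vals, labels, n_boot=10, seed=0,
                        direction="flag_if_below")
            assert r.auc == pytest.approx(
                pair_counting_auc(vals, labels), abs=1e-12)

    def test_labels_independent_of_values_gives_half(self):
        rng = np.random.default_rng(30)
        n = 2000
        vals = rng.uniform(0, 1, n)
        labels = list(np.where(rng.random(n) < 0.4, "unacceptable",
                               "acceptable"))
        r = roc_auc(vals, labels, n_boot=50, seed=1)
        assert abs(r.auc - 0.5) < 0.05

    def test_bootstrap_ci_brackets_and_reproduces(self):
        vals, labels = gaussian_1d(21, n=40)
        r1 = roc_auc(vals, labels, n_boot=500, seed=42)
        r2 = roc_auc(vals, labels, n_boot=500, seed=42)
        assert r1.ci_low <= r1.ci_high
        assert r1.ci_low <= r1.auc + 1e-9
        np.testing.assert_array_equal(r1.boot_aucs, r2.boot_aucs)

    def test_roc_curve_monotone(self):
        vals, labels = gaussian_1d(2, n=25)
        r = roc_auc(vals, labels, n_boot=10, seed=0)
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], ["acceptable", "acceptable"], n_boot=10, seed=0)
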