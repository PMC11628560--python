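"""Feature assembly, detection models, evaluation statistics, TOO gating."""

import numpy as np
import pandas as pd
import pytest

from mefi.models import (
    N_FEATURES,
    assemble_features,
    evaluate,
    feature_names,
    leave_one_batch_out,
    mefi_score,
    predict_too,
    too_gate,
    train_detection,
    train_too,
    youden_cutoff,
)


def brute_force_auc(scores, y):
    """U-statistic oracle: fraction of (case, control) pairs ranked correctly,
    ties counted half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestFeatureAssembly:
    def test_vector_has_1029_named_entries(self):
        names = feature_names()
        assert len(names) == N_FEATURES == 1029
        assert len(set(names)) == 1029
        vec = assemble_features(
            1.0, 0, np.zeros(255), np.zeros(255), np.zeros(255), 128.0,
            {b: 1.0 for b in "ACGT"}, np.full(256, 1 / 256), 1.0,
        )
        assert list(vec.index) == names

    def test_reference_like_sample_has_null_profile_features(self):
        vec = assemble_features(
            1.0, 0, np.zeros(255), np.zeros(255), np.zeros(255), 128.0,
            {b: 1.0 for b in "ACGT"}, np.full(256, 1 / 256), 1.0,
        )
        assert vec["profile_correlation"] == 1.0
        assert vec["new_peak_count"] == 0
        assert (vec.filter(like="euclid_") == 0).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assemble_features(1.0, 0, np.zeros(10), np.zeros(255), np.zeros(255),
                              128.0, {b: 1.0 for b in "ACGT"},
                              np.full(256, 1 / 256), 1.0)
        with pytest.raises(ValueError):
            assemble_features(1.0, 0, np.zeros(255), np.zeros(255), np.zeros(255),
                              128.0, {b: 1.0 for b in "ACGT"},
                              np.full(100, 0.01), 1.0)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            assemble_features(np.nan, 0, np.zeros(255), np.zeros(255),
                              np.zeros(255), 128.0, {b: 1.0 for b in "ACGT"},
                              np.full(256, 1 / 256), 1.0)

    def test_extraction_is_deterministic(self, ref, gc_track, ref_profile_z, ref_peaks):
        from mefi.models import extract_features
        from mefi.simulate import SimConfig, simulate_sample

        cfg = SimConfig(seed=5, n_fragments=15000)
        a = simulate_sample(cfg, "HC", ref=ref, seed=55)
        b = simulate_sample(cfg, "HC", ref=ref, seed=55)
        va = extract_features(a, ref, gc_track, ref_profile_z, ref_peaks)
        vb = extract_features(b, ref, gc_track, ref_profile_z, ref_peaks)
        assert va.equals(vb)


class TestEvaluate:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array(["HC", "HC", "MT", "MT"])
        rep = evaluate(scores, labels)
        assert rep.auc == 1.0
        assert 0.2 < rep.cutoff <= 0.8
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.confusion.tolist() == [[2, 0], [0, 2]]

    def test_identical_scores_give_chance_auc(self):
        rep = evaluate(np.full(10, 0.5), np.array([0, 1] * 5))
        assert rep.auc == 0.5

    def test_matches_u_statistic_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(6, 20)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)  # with ties
            rep = evaluate(scores, y, cutoff=0.5)
            assert rep.auc == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_confidence_intervals_bracket_estimates(self):
        rng = np.random.default_rng(8)
        scores = np.concatenate([rng.normal(0.3, 0.1, 50), rng.normal(0.7, 0.1, 50)])
        y = np.array([0] * 50 + [1] * 50)
        rep = evaluate(scores, y)
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
        assert rep.sensitivity_ci[0] <= rep.sensitivity <= rep.sensitivity_ci[1]
        assert rep.specificity_ci[0] <= rep.specificity <= rep.specificity_ci[1]

    def test_raising_cutoff_never_increases_sensitivity(self):
        rng = np.random.default_rng(9)
        scores = rng.random(60)
        y = (rng.random(60) < 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        sens = [evaluate(scores, y, cutoff=c).sensitivity for c in (0.2, 0.5, 0.8)]
        assert sens[0] >= sens[1] >= sens[2]

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_youden_ties_break_to_higher_specificity(self):
        # J = 0.5 at cutoffs 0.9 and 0.5; the higher cutoff is chosen
        scores = np.array([0.1, 0.5, 0.5, 0.9])
        y = np.array([0, 1, 0, 1])
        assert youden_cutoff(scores, y) == 0.9


class TestTooGate:
    def test_order_statistic_threshold(self):
        rng = np.random.default_rng(1)
        controls = rng.random(200)
        scores = np.concatenate([controls, rng.random(50) * 0.5 + 0.5])
        labels = np.array(["HC"] * 200 + ["MT"] * 50)
        thr, selected = too_gate(scores, labels, 0.995)
        assert (controls > thr).sum() <= 1  # floor(0.005 * 200) = 1
        assert selected.sum() == (scores[200:] > thr).sum()

    def test_perfect_separation_selects_all_cases(self):
        scores = np.array([0.0] * 20 + [1.0] * 10)
        labels = np.array(["HC"] * 20 + ["MT"] * 10)
        thr, selected = too_gate(scores, labels)
        assert selected.sum() == 10

    def test_target_one_puts_threshold_at_max_control(self):
        scores = np.array([0.1, 0.5, 0.9, 0.95])
        labels = np.array(["HC", "HC", "MT", "MT"])
        thr, selected = too_gate(scores, labels, target_specificity=1.0)
        assert thr == 0.5
        assert selected.sum() == 2


class TestTooClassifier:
    @pytest.fixture
    def typed_features(self):
        rng = np.random.default_rng(3)
        rows, types = [], []
        for i, t in enumerate(["NSCLC", "HCC", "CRC"]):
            X = rng.normal(0, 1, (30, 20))
            X[:, i] += 4.0  # distinct per-type signature
            rows.append(X)
            types += [t] * 30
        X = pd.DataFrame(np.vstack(rows), columns=[f"f{j}" for j in range(20)])
        return X, pd.Series(types, index=X.index)

    def test_distinct_types_recovered(self, typed_features):
        X, types = typed_features
        model = train_too(X, types, seed=0)
        res = predict_too(model, X, types)
        assert res["top1_accuracy"] >= 0.9
        assert res["top2_accuracy"] >= res["top1_accuracy"]
        trace = np.trace(res["confusion"].to_numpy())
        assert trace / len(types) == pytest.approx(res["top1_accuracy"])

    def test_single_sample_class_refused(self, typed_features):
        X, types = typed_features
        types = types.copy()
        types.iloc[0] = "BC"  # class of size 1
        with pytest.raises(ValueError, match="<2 samples"):
            train_too(X, types)

    def test_single_class_refused(self, typed_features):
        X, types = typed_features
        with pytest.raises(ValueError):
            train_too(X, pd.Series(["HCC"] * len(X), index=X.index))


def gaussian_cohort(n_per_class=40, shift=2.0, seed=0, n_feat=12):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        np.vstack([
            rng.normal(0, 1, (n_per_class, n_feat)),
            rng.normal(shift / np.sqrt(n_feat), 1, (n_per_class, n_feat)),
        ]),
        columns=[f"f{j}" for j in range(n_feat)],
    )
    labels = pd.Series(["HC"] * n_per_class + ["MT"] * n_per_class, index=X.index)
    return X, labels


class TestDetectionTraining:
    def test_separable_cohort_reaches_high_cv_auc(self):
        X, labels = gaussian_cohort(shift=4.0)
        model = train_detection(X, labels, "HC", seed=1)
        assert model.cv_auc >= 0.95

    def test_fixed_seed_is_bit_reproducible(self):
        X, labels = gaussian_cohort(shift=2.0)
        a = train_detection(X, labels, "HC", seed=3)
        b = train_detection(X, labels, "HC", seed=3)
        assert a.cv_scores.equals(b.cv_scores)
        assert a.youden_cutoff == b.youden_cutoff
        assert np.array_equal(mefi_score(a, X), mefi_score(b, X))

    def test_single_class_rejected(self):
        X, labels = gaussian_cohort()
        only_mt = labels == "MT"
        with pytest.raises(ValueError):
            train_detection(X[only_mt], labels[only_mt], "HC")

    def test_scores_are_probabilities(self):
        X, labels = gaussian_cohort()
        model = train_detection(X, labels, "HC", seed=0)
        s = mefi_score(model, X)
        assert ((0 <= s) & (s <= 1)).all()

    def test_feature_name_mismatch_rejected(self):
        X, labels = gaussian_cohort()
        model = train_detection(X, labels, "HC", seed=0)
        bad = X.rename(columns={"f0": "wrong"})
        with pytest.raises(ValueError):
            mefi_score(model, bad)

    def test_column_order_is_normalized(self):
        X, labels = gaussian_cohort()
        model = train_detection(X, labels, "HC", seed=0)
        shuffled = X[list(X.columns[::-1])]
        assert np.allclose(mefi_score(model, shuffled), mefi_score(model, X))


class TestLeaveOneBatchOut:
    def test_identical_batches_match_pooled_auc(self):
        X, labels = gaussian_cohort(n_per_class=60, shift=3.0, seed=5)
        batches = pd.Series(np.arange(len(X)) % 2, index=X.index).map(
            {0: "b0", 1: "b1"}
        )
        reports = leave_one_batch_out(X, labels, batches, "HC", seed=0)
        model = train_detection(X, labels, "HC", seed=0)
        pooled = model.cv_auc
        for rep in reports.values():
            assert rep is not None
            assert abs(rep.auc - pooled) < 0.15

    def test_single_batch_rejected(self):
        X, labels = gaussian_cohort()
        batches = pd.Series(["b0"] * len(X), index=X.index)
        with pytest.raises(ValueError):
            leave_one_batch_out(X, labels, batches)

    def test_batch_confounding_detected(self):
        """When labels track batches and features encode only batch, pooled
        AUC is inflated but held-out batches collapse toward (or below)
        chance."""
        rng = np.random.default_rng(11)
        n = 120
        batch = np.repeat(["b0", "b1"], n // 2)
        # features = batch indicator + noise; labels 90% aligned with batch
        X = pd.DataFrame({
            "f0": (batch == "b1") + rng.normal(0, 0.3, n),
            "f1": rng.normal(0, 1, n),
        })
        flip = rng.random(n) < 0.1
        labels = pd.Series(np.where((batch == "b1") ^ flip, "MT", "HC"))
        batches = pd.Series(batch)
        pooled = train_detection(X, labels, "HC", seed=0).cv_auc
        reports = leave_one_batch_out(X, labels, batches, "HC", seed=0)
        lobo_aucs = [r.auc for r in reports.values() if r is not None]
        assert pooled > 0.8
        assert np.mean(lobo_aucs) < 0.7
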