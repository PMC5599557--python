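"""LOCO evaluation, greedy integration and the kernel-level comparator."""

import numpy as np
import pytest

from oncosnv.dataset import LabelledDataset
from oncosnv.features import FeatureGroup
from oncosnv.io import MutationRecord
from oncosnv.train import (
    GreedyTrace,
    TrainerConfig,
    _gaussian_kernel,
    evaluate_group,
    evaluate_groups,
    greedy_integrate,
    loco_folds,
    mkl_integrate,
    rank_groups,
    select_prefix,
    train_final,
    tune_parameter,
)

from conftest import make_labelled


def synthetic_ds(chroms, n_per=6):
    recs = []
    for c in chroms:
        for i in range(n_per):
            label = "driver" if i % 2 == 0 else "neutral"
            recs.append(MutationRecord(c, 100 * (i + 1), "A", "C",
                                       recurrence=5 if label == "driver" else 0,
                                       label=label))
    return LabelledDataset(recs)


def label_builder(name="oracle"):
    """A one-column group equal to the class label — a perfect separator."""
    def build(records):
        col = np.array([[1.0 if r.label == "driver" else 0.0] for r in records])
        return FeatureGroup(name, col, np.zeros_like(col, dtype=bool), ["label"])
    return build


def noise_builder(name, seed, d=3):
    def build(records):
        rng = np.random.default_rng(seed + len(records))
        # deterministic per record so features stay pure functions of inputs
        vals = np.vstack([
            np.random.default_rng(hash((name, r.key)) % 2**31).normal(size=d)
            for r in records])
        return FeatureGroup(name, vals, np.zeros_like(vals, dtype=bool),
                            [f"{name}{i}" for i in range(d)])
    return build


class TestLocoFolds:
    def test_one_fold_per_autosome(self):
        ds = synthetic_ds([str(i) for i in range(1, 23)], n_per=2)
        assert len(loco_folds(ds)) == 22

    def test_allosomes_train_only(self):
        ds = synthetic_ds(["1", "2", "X"], n_per=2)
        folds = loco_folds(ds)
        assert [t for _, t in folds] == ["1", "2"]
        assert all("X" in train for train, _ in folds)

    def test_folds_partition_autosomal_records(self):
        ds = synthetic_ds(["1", "2", "3"], n_per=4)
        folds = loco_folds(ds)
        test_sets = [frozenset(r.key for r in ds.by_chrom(t)) for _, t in folds]
        all_keys = frozenset(r.key for r in ds.records)
        assert frozenset().union(*test_sets) == all_keys
        for i in range(len(test_sets)):
            for j in range(i + 1, len(test_sets)):
                assert not test_sets[i] & test_sets[j]

    def test_no_leakage(self):
        ds = synthetic_ds(["1", "2", "3", "X"], n_per=4)
        for train_chroms, test_chrom in loco_folds(ds):
            train_keys = {r.key for c in train_chroms for r in ds.by_chrom(c)}
            test_keys = {r.key for r in ds.by_chrom(test_chrom)}
            assert not train_keys & test_keys

    def test_single_autosome_errors(self):
        with pytest.raises(ValueError):
            loco_folds(synthetic_ds(["1"]))


class TestEvaluateGroup:
    def test_perfect_separator_scores_one(self, fast_cfg):
        ds = synthetic_ds(["1", "2", "3", "4"], n_per=20)
        mean, _ = evaluate_group(ds, {"oracle": label_builder()}, "oracle", fast_cfg)
        assert mean == 1.0

    def test_noise_group_near_chance(self, labelled_ds, fast_cfg):
        builders = {"noise": noise_builder("noise", 1)}
        mean, _ = evaluate_group(labelled_ds, builders, "noise",
                                 fast_cfg.with_(n_repeats_model=3))
        # binomial null at the fixture's test sizes (300 records)
        assert abs(mean - 0.5) < 3 * np.sqrt(0.25 / 300)

    def test_informative_beats_noise(self, labelled_ds, track_builders, fast_cfg):
        info, _ = evaluate_group(labelled_ds, track_builders, "cons46", fast_cfg)
        noise, _ = evaluate_group(labelled_ds, track_builders, "noise1", fast_cfg)
        assert info > noise

    def test_seed_stability(self, labelled_ds, track_builders, fast_cfg):
        a = evaluate_group(labelled_ds, track_builders, "cons46", fast_cfg)
        b = evaluate_group(labelled_ds, track_builders, "cons46", fast_cfg)
        assert a == b

    def test_label_permutation_null_centred(self, labelled_ds, track_builders, fast_cfg):
        rng = np.random.default_rng(0)
        labels = [r.label for r in labelled_ds.records]
        perm = rng.permutation(labels)
        permuted = LabelledDataset([r.with_fields(label=l)
                                    for r, l in zip(labelled_ds.records, perm)])
        mean, _ = evaluate_group(permuted, track_builders, "cons46",
                                 fast_cfg.with_(n_repeats_model=3))
        assert abs(mean - 0.5) < 3 * np.sqrt(0.25 / 300)


class TestGreedy:
    def test_informative_ranked_first(self, labelled_ds, track_builders, fast_cfg):
        ranked, _, _ = rank_groups(labelled_ds, track_builders, fast_cfg)
        assert set(ranked[:2]) == {"cons46", "cons100"}

    def test_ranking_invariant_to_registry_order(self, labelled_ds, track_builders, fast_cfg):
        fwd, _, _ = rank_groups(labelled_ds, track_builders, fast_cfg)
        rev, _, _ = rank_groups(labelled_ds,
                                dict(reversed(list(track_builders.items()))), fast_cfg)
        assert fwd == rev

    def test_two_informative_groups_integrate(self, labelled_ds, track_builders, fast_cfg):
        sub = {g: track_builders[g] for g in ("cons46", "cons100", "noise1")}
        trace = greedy_integrate(labelled_ds, sub, fast_cfg,
                                 evaluate_both_scalings=False)
        best_single = max(trace.individual_accuracy.values())
        assert max(trace.cumulative_accuracy) >= best_single - 3 * 0.03
        assert trace.selected_prefix[:2] == trace.ranked_groups[:2]

    def test_all_noise_registry_still_selects(self, fast_cfg):
        ds = synthetic_ds(["1", "2", "3"], n_per=20)
        builders = {f"n{i}": noise_builder(f"n{i}", i) for i in range(3)}
        trace = greedy_integrate(ds, builders, fast_cfg, evaluate_both_scalings=False)
        assert len(trace.selected_prefix) >= 2


class TestSelectPrefix:
    def make_trace(self, cumulative):
        groups = [f"g{i}" for i in range(len(cumulative) + 1)]
        return GreedyTrace(groups, {g: 0.5 for g in groups}, {g: 0.0 for g in groups},
                           list(cumulative), [False] * len(cumulative))

    def test_plateau_rule(self):
        trace = self.make_trace([0.60, 0.65, 0.65, 0.64])
        assert select_prefix(trace, 0.002) == ["g0", "g1", "g2"]

    def test_strictly_increasing_selects_all(self):
        trace = self.make_trace([0.60, 0.65, 0.70])
        assert select_prefix(trace, 0.002) == ["g0", "g1", "g2", "g3"]

    def test_epsilon_zero_unique_max(self):
        trace = self.make_trace([0.60, 0.72, 0.65])
        assert select_prefix(trace, 0.0) == ["g0", "g1", "g2"]


class TestTuneParameter:
    def test_single_value_grid(self, labelled_ds, track_builders, fast_cfg):
        cfg = fast_cfg.with_(param_grid=(1.0,))
        sub = {"cons46": track_builders["cons46"]}
        assert tune_parameter(labelled_ds, sub, cfg) == 1.0

    def test_ties_take_smallest(self, fast_cfg):
        # gradient boosting ignores C entirely -> all grid values tie
        ds = synthetic_ds(["1", "2", "3"], n_per=20)
        cfg = fast_cfg.with_(param_grid=(0.1, 1.0, 10.0))
        assert tune_parameter(ds, {"oracle": label_builder()}, cfg) == 0.1


class TestMKL:
    def test_gaussian_kernel_psd(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        K = _gaussian_kernel(X, X, sigma=1.3)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_single_group_reduces_to_rbf_svm(self, labelled_ds, track_builders, fast_cfg):
        cfg = fast_cfg.with_(classifier="svm_gaussian", standardise=True)
        sub = {"cons46": track_builders["cons46"]}
        macc, _ = mkl_integrate(labelled_ds, sub, cfg, n_repeats=1,
                                group_accuracies={"cons46": 0.7})
        dacc, _ = evaluate_groups(labelled_ds, sub, cfg, n_repeats=1)
        assert abs(macc - dacc) < 0.1  # same kernel family, same folds

    def test_uniform_fallback_when_all_floor(self, labelled_ds, track_builders, fast_cfg):
        cfg = fast_cfg.with_(classifier="svm_gaussian")
        sub = {g: track_builders[g] for g in ("noise1", "noise2")}
        with pytest.warns(UserWarning, match="uniform"):
            mkl_integrate(labelled_ds, sub, cfg, n_repeats=1,
                          group_accuracies={"noise1": 0.45, "noise2": 0.49})


class TestFinalModel:
    def test_retrain_deterministic(self, labelled_ds, track_builders, fast_cfg):
        sel = ["cons46", "cons100"]
        m1 = train_final(labelled_ds, sel, track_builders, fast_cfg)
        m2 = train_final(labelled_ds, sel, track_builders, fast_cfg)
        probe = labelled_ds.records[:25]
        np.testing.assert_array_equal(m1.predict_pscores(probe), m2.predict_pscores(probe))

    def test_training_accuracy_above_chance(self, labelled_ds, track_builders, fast_cfg):
        model = train_final(labelled_ds, ["cons46"], track_builders, fast_cfg)
        scores = model.decision_scores(labelled_ds.records)
        y = labelled_ds.labels
        pred = scores >= 0
        balacc = (pred[y == 1].mean() + (~pred[y == 0]).mean()) / 2
        assert balacc > 0.5

    def test_predicts_with_missing_track_values(self, labelled_ds, track_builders, fast_cfg):
        model = train_final(labelled_ds, ["cons46"], track_builders, fast_cfg)
        novel = [MutationRecord("1", 99_999, "A", "C")]  # no track data there
        p = model.predict_pscores(novel)
        assert 0.0 <= p[0] <= 1.0

    def test_single_class_errors(self, track_builders, fast_cfg):
        recs = [MutationRecord("1", 10 * i + 1, "A", "C", label="driver")
                for i in range(10)]
        with pytest.raises(ValueError):
            train_final(LabelledDataset(recs), ["cons46"], track_builders, fast_cfg)
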