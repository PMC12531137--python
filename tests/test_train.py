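"""Cross-validation protocol, training sanity, metrics, ablation switches."""

import numpy as np
import pytest

from dhclham import (
    AssociationDataset,
    RunConfig,
    ablate,
    evaluate,
    generate_dataset,
    make_cv_folds,
    predict,
    run_cv,
    train_model,
)
from dhclham.synthetic import SyntheticSpec


def _ds(A):
    A = np.asarray(A, dtype=float)
    return AssociationDataset(
        tuple(f"m{i}" for i in range(A.shape[0])),
        tuple(f"d{j}" for j in range(A.shape[1])),
        A,
    )


class TestFoldPlan:
    def test_balanced_partition_arithmetic(self, rng):
        A = np.zeros((5, 10))
        pos = rng.choice(50, 10, replace=False)
        A.ravel()[pos] = 1.0
        plan = make_cv_folds(_ds(A), n_folds=5, seed=0)
        assert len(plan.pairs) == 20
        assert plan.labels.sum() == 10
        for f in range(5):
            pairs, labels = plan.fold_pairs(f)
            assert len(pairs) == 4
            assert labels.sum() == 2  # stratified: 2 positives, 2 negatives
        # partition: disjoint union covers everything
        seen = {tuple(p) for p in plan.pairs}
        assert len(seen) == 20

    def test_deterministic_given_seed(self, small_synth):
        a = make_cv_folds(small_synth.ds, 5, seed=3)
        b = make_cv_folds(small_synth.ds, 5, seed=3)
        assert np.array_equal(a.pairs, b.pairs)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        c = make_cv_folds(small_synth.ds, 5, seed=4)
        assert not np.array_equal(a.pairs, c.pairs)

    def test_too_few_positives(self):
        with pytest.raises(ValueError):
            make_cv_folds(_ds(np.eye(2)), n_folds=5, seed=0)


class TestTraining:
    def test_loss_trace_finite_and_decreasing(self, small_synth, tiny_config):
        cfg = tiny_config.replace(epochs=25)
        plan = make_cv_folds(small_synth.ds, 5, cfg.seed)
        model = train_model(small_synth.ds, small_synth.ms1, small_synth.ds1, plan, 0, cfg)
        trace = np.array(model.loss_trace)
        assert np.isfinite(trace).all()
        assert trace[-1] < trace[0]

    def test_deterministic_given_seed(self, small_synth, tiny_config):
        plan = make_cv_folds(small_synth.ds, 5, 0)
        args = (small_synth.ds, small_synth.ms1, small_synth.ds1, plan, 0, tiny_config)
        a = train_model(*args)
        b = train_model(*args)
        assert a.loss_trace == b.loss_trace
        assert np.array_equal(a.scores, b.scores)

    def test_test_fold_labels_cannot_leak(self, small_synth, tiny_config):
        """Flipping held-out entries of A leaves the training loss unchanged."""
        plan = make_cv_folds(small_synth.ds, 5, 0)
        test_pairs, _ = plan.fold_pairs(0)
        A2 = small_synth.ds.A.copy()
        A2[test_pairs[:, 0], test_pairs[:, 1]] = 1.0 - A2[test_pairs[:, 0], test_pairs[:, 1]]
        ds2 = AssociationDataset(small_synth.ds.microbe_ids, small_synth.ds.drug_ids, A2)
        a = train_model(small_synth.ds, small_synth.ms1, small_synth.ds1, plan, 0, tiny_config)
        b = train_model(ds2, small_synth.ms1, small_synth.ds1, plan, 0, tiny_config)
        assert a.loss_trace == b.loss_trace

    def test_predict_extracts_scores(self, small_synth, tiny_config):
        plan = make_cv_folds(small_synth.ds, 5, 0)
        model = train_model(small_synth.ds, small_synth.ms1, small_synth.ds1, plan, 0, tiny_config)
        pairs = [(i, j) for i in range(3) for j in range(4)]
        s = predict(model, pairs)
        assert s.shape == (12,)
        assert np.allclose(s, [model.scores[i, j] for i, j in pairs])
        with pytest.raises(IndexError):
            predict(model, [(0, 10**6)])


class TestEvaluate:
    def test_perfect_separation(self):
        m = evaluate([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m["auc"] == 1.0 and m["aupr"] == 1.0

    def test_confusion_hand_values(self):
        # TP=FP=TN=FN=1 at threshold 0.5 on raw scores
        m = evaluate([0.9, 0.2, 0.9, 0.2], [1, 1, 0, 0], threshold=0.5)
        assert m["f1"] == 0.5 and m["acc"] == 0.5

    def test_auc_matches_pair_counting_oracle(self, rng):
        scores = rng.normal(size=150)
        scores[::7] = scores[::5][: len(scores[::7])]  # inject ties
        labels = (rng.random(150) < 0.4).astype(int)
        m = evaluate(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert np.isclose(m["auc"], wins / (len(pos) * len(neg)))

    def test_auc_invariant_to_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        a = evaluate(scores, labels)["auc"]
        b = evaluate(np.exp(2 * scores), labels)["auc"]
        assert np.isclose(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0.1, 0.2], [1, 1])


class TestAblation:
    def test_nocl_zeroes_contrastive_weights(self):
        cfg = ablate(RunConfig(), "NoCL")
        assert cfg.lambda_m == 0.0 and cfg.gamma_d == 0.0 and cfg.variant == "NoCL"

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            ablate(RunConfig(), "Bogus")

    def test_ms2ds2_ignores_provided_similarities(self, small_synth, tiny_config):
        cfg = ablate(tiny_config, "MS2DS2")
        plan = make_cv_folds(small_synth.ds, 5, 0)
        a = train_model(small_synth.ds, small_synth.ms1, small_synth.ds1, plan, 0, cfg)
        b = train_model(small_synth.ds, None, None, plan, 0, cfg)
        assert a.loss_trace == b.loss_trace

    def test_linear_and_snf_fusion_differ(self, small_synth, tiny_config):
        from dhclham import SimilarityView, gip_kernel, linear_fuse, snf_fuse

        gip = gip_kernel(small_synth.ds.A, axis="rows")
        lin = linear_fuse([small_synth.ms1, gip]).S_final
        snf = snf_fuse([small_synth.ms1, gip], k=3).S_final
        assert not np.allclose(lin, snf)

    def test_nodha_trains(self, small_synth, tiny_config):
        cfg = ablate(tiny_config, "NoDHA")
        plan = make_cv_folds(small_synth.ds, 5, 0)
        model = train_model(small_synth.ds, small_synth.ms1, small_synth.ds1, plan, 0, cfg)
        assert np.isfinite(model.loss_trace).all()


class TestRunCv:
    def test_report_consistency(self):
        sd = generate_dataset(SyntheticSpec(n_microbes=20, n_drugs=25, target_density=0.1, seed=2))
        cfg = RunConfig(embed_dim=8, epochs=5, n_heads=2, knn_k=3, ko_c=3, cv_folds=3, seed=0)
        rep = run_cv(sd.ds, sd.ms1, sd.ds1, cfg)
        for k in ("auc", "aupr", "f1", "acc"):
            vals = rep.per_fold[k]
            assert len(vals) == 3
            assert np.isclose(rep.mean[k], np.mean(vals))
            # population-SD loop oracle
            mu = sum(vals) / len(vals)
            sd_loop = (sum((v - mu) ** 2 for v in vals) / len(vals)) ** 0.5
            assert np.isclose(rep.sd[k], sd_loop)
            assert all(0.0 <= v <= 1.0 for v in vals)
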