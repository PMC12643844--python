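import numpy as np
import pytest

from miltext.classifier import (
    CascadeResult,
    ClassifierConfig,
    MILClassifier,
    TrainConfig,
    class_weight_rule,
    conv_head_forward,
    correlate,
    joint_accuracy,
    predict_cascade,
    stack_cls,
    stratified_sample,
    user_mil_proportion,
    _forward,
    _init_params,
)
from miltext.encoder import ToyEncoder
from miltext import synthgen as syn


class TestStackCls:
    def test_shape_matches_adapter(self, toy_encoder):
        mat = stack_cls(toy_encoder, toy_encoder.tokenize("life has meaning"), 32)
        assert mat.shape == (4, 32)

    def test_deterministic(self, toy_encoder):
        t = toy_encoder.tokenize("searching for purpose")
        assert np.array_equal(stack_cls(toy_encoder, t, 32),
                              stack_cls(toy_encoder, t, 32))

    def test_wrong_shape_rejected(self):
        class BadEncoder:
            n_blocks, dim = 4, 32
            def tokenize(self, text): return [1]
            def encode(self, ids, max_len): return np.zeros((3, 32))
        with pytest.raises(ValueError, match="shape"):
            stack_cls(BadEncoder(), [1], 32)


class TestConvHead:
    def test_feature_map_lengths(self):
        # L=12, windows (3,4,5): conv over the block axis gives maps 10, 9, 8
        cfg = ClassifierConfig(L=12, d=8, windows=(3, 4, 5), m=2)
        rng = np.random.default_rng(0)
        params = _init_params(cfg, rng)
        X = rng.normal(size=(1, 12, 8))
        from miltext.classifier import _sliding
        assert _sliding(X, 3).shape[1] == 10
        assert _sliding(X, 4).shape[1] == 9
        assert _sliding(X, 5).shape[1] == 8
        # fused vector length |windows| * m = 6 feeds the output layer
        assert params["W_out"].shape[1] == 6

    def test_probabilities_normalized(self, tiny_ccfg):
        rng = np.random.default_rng(1)
        params = _init_params(tiny_ccfg, rng)
        probs = conv_head_forward(rng.normal(size=(4, 32)), params, tiny_ccfg)
        assert probs.shape == (2,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert (probs >= 0).all()

    def test_window_larger_than_L_is_config_error(self):
        with pytest.raises(ValueError):
            ClassifierConfig(L=4, d=8, windows=(5,), m=2)

    def test_batch_permutation_equivariant(self, tiny_ccfg):
        rng = np.random.default_rng(2)
        params = _init_params(tiny_ccfg, rng)
        X = rng.normal(size=(6, 4, 32))
        perm = rng.permutation(6)
        out = _forward(X, params, tiny_ccfg)
        assert np.allclose(_forward(X[perm], params, tiny_ccfg), out[perm])


class TestClassWeights:
    def test_balanced_rule(self):
        labels = ["A"] * 80 + ["B"] * 20
        w = class_weight_rule(labels)
        assert w["A"] == pytest.approx(0.625)
        assert w["B"] == pytest.approx(2.5)


class TestTraining:
    def test_overfits_separable_posts(self, toy_encoder, tiny_ccfg):
        cfg = syn.SynthConfig(n_posts=40, seed=3, p_related=0.5, margin=1.0)
        posts = syn.gen_posts(cfg)
        texts = [p.text for p in posts]
        labels = [p.rel for p in posts]
        clf = MILClassifier(toy_encoder, tiny_ccfg, "RELATED", "NOT_RELATED")
        tcfg = TrainConfig(batch_size=40, learning_rate=0.01, patience_steps=100,
                           max_steps=400, folds=2, split=(1.0, 0.0, 0.0), seed=0)
        clf.fit(texts, labels, tcfg)
        pred = [lab for lab, _ in clf.predict(texts)]
        assert np.mean([p == g for p, g in zip(pred, labels)]) == 1.0

    def test_seeded_metrics_reproduce(self, toy_encoder, tiny_ccfg, overfit_tcfg):
        cfg = syn.SynthConfig(n_posts=50, seed=4, p_related=0.5)
        posts = syn.gen_posts(cfg)
        texts, labels = [p.text for p in posts], [p.rel for p in posts]
        runs = []
        for _ in range(2):
            clf = MILClassifier(toy_encoder, tiny_ccfg, "RELATED", "NOT_RELATED")
            res = clf.fit(texts, labels, overfit_tcfg)
            runs.append(([f.accuracy for f in res.fold_metrics], res.test_metrics))
        assert runs[0] == runs[1]

    def test_single_class_rejected(self, toy_encoder, tiny_ccfg, overfit_tcfg):
        clf = MILClassifier(toy_encoder, tiny_ccfg, "RELATED", "NOT_RELATED")
        with pytest.raises(ValueError):
            clf.fit(["a b", "c d"], ["RELATED", "RELATED"], overfit_tcfg)

    def test_split_and_folds_reported(self, toy_encoder, tiny_ccfg, overfit_tcfg):
        cfg = syn.SynthConfig(n_posts=50, seed=5, p_related=0.5)
        posts = syn.gen_posts(cfg)
        clf = MILClassifier(toy_encoder, tiny_ccfg, "RELATED", "NOT_RELATED")
        res = clf.fit([p.text for p in posts], [p.rel for p in posts], overfit_tcfg)
        assert res.n_test == 5 and res.n_val == 5 and res.n_train == 40
        assert len(res.fold_metrics) == overfit_tcfg.folds
        assert set(res.test_metrics) == {"accuracy", "precision", "recall", "f1"}


def _fit_cascade(encoder, ccfg, n=80, seed=7):
    cfg = syn.SynthConfig(n_posts=n, seed=seed, p_related=0.5, margin=1.0)
    posts = syn.gen_posts(cfg)
    tcfg = TrainConfig(batch_size=64, learning_rate=0.01, patience_steps=80,
                       max_steps=400, folds=2, split=(1.0, 0.0, 0.0), seed=0)
    m1 = MILClassifier(encoder, ccfg, "RELATED", "NOT_RELATED")
    m1.fit([p.text for p in posts], [p.rel for p in posts], tcfg)
    related = [p for p in posts if p.rel == "RELATED"]
    m2 = MILClassifier(encoder, ccfg, "HIGH", "LOW")
    m2.fit([p.text for p in related], [p.sfm for p in related], tcfg)
    m3 = MILClassifier(encoder, ccfg, "HIGH", "LOW")
    m3.fit([p.text for p in related], [p.pom for p in related], tcfg)
    return posts, m1, m2, m3


class TestCascade:
    def test_gate_consistency_and_id_preservation(self, toy_encoder, tiny_ccfg):
        posts, m1, m2, m3 = _fit_cascade(toy_encoder, tiny_ccfg)
        results = predict_cascade(posts, m1, m2, m3)
        assert len(results) == len(posts)
        assert [r.post_id for r in results] == [p.post_id for p in posts]
        for r in results:
            if r.relevance == "NOT_RELATED":
                assert r.sfm is None and r.pom is None and r.quadrant is None
            else:
                assert r.sfm in ("HIGH", "LOW") and r.pom in ("HIGH", "LOW")
                assert r.quadrant in ("S0P0", "S0P1", "S1P0", "S1P1")

    def test_gated_result_type_enforces_invariant(self):
        with pytest.raises(ValueError):
            CascadeResult("p0", "NOT_RELATED", 0.2, sfm="HIGH", sfm_prob=0.9)

    def test_mismatched_encoders_rejected(self, toy_encoder, tiny_ccfg):
        posts, m1, m2, m3 = _fit_cascade(toy_encoder, tiny_ccfg)
        other = ToyEncoder(n_blocks=4, dim=32, seed=99)
        m2b = MILClassifier(other, tiny_ccfg, "HIGH", "LOW")
        m2b.params = m2.params
        with pytest.raises(ValueError, match="share"):
            predict_cascade(posts, m1, m2b, m3)


def _make_results(counts, seed=0):
    rng = np.random.default_rng(seed)
    results = []
    i = 0
    for quad, n in counts.items():
        sfm = "HIGH" if quad[1] == "1" else "LOW"
        pom = "HIGH" if quad[3] == "1" else "LOW"
        for _ in range(n):
            results.append(CascadeResult(f"p{i}", "RELATED", 0.9,
                                         sfm=sfm, sfm_prob=0.8,
                                         pom=pom, pom_prob=0.8))
            i += 1
    return results


class TestStratifiedSample:
    def test_minimum_floor_applied(self, rng):
        # quadrants near the floor: each contributes max(100, 1% of N) items
        results = _make_results({"S1P1": 102, "S1P0": 111, "S0P1": 134, "S0P0": 115})
        sample = stratified_sample(results, frac=0.01, min_per_stratum=100, rng=rng)
        assert len(sample) == 400  # floor dominates all four quadrants

    def test_large_stratum_uses_fraction(self, rng):
        results = _make_results({"S1P1": 20000, "S1P0": 150, "S0P1": 150, "S0P0": 150})
        sample = stratified_sample(results, frac=0.01, min_per_stratum=100, rng=rng)
        quads = [r.quadrant for r in sample]
        assert quads.count("S1P1") == 200
        assert quads.count("S1P0") == 100

    def test_small_quadrant_errors_by_name(self, rng):
        results = _make_results({"S1P1": 50, "S1P0": 150, "S0P1": 150, "S0P0": 150})
        with pytest.raises(ValueError, match="S1P1"):
            stratified_sample(results, 0.01, 100, rng)

    def test_seeded_sample_reproducible(self):
        results = _make_results({"S1P1": 200, "S1P0": 150, "S0P1": 150, "S0P0": 150})
        a = stratified_sample(results, 0.5, 100, np.random.default_rng(5))
        b = stratified_sample(results, 0.5, 100, np.random.default_rng(5))
        assert [r.post_id for r in a] == [r.post_id for r in b]


class TestEvaluation:
    def test_joint_accuracy_counts_both_labels(self):
        preds = _make_results({"S1P1": 2, "S1P0": 1, "S0P0": 1})
        gold = {r.post_id: (r.sfm, r.pom) for r in preds}
        # corrupt one gold POM: that item no longer jointly correct
        gold["p0"] = ("HIGH", "LOW")
        assert joint_accuracy(preds, gold) == pytest.approx(0.75)

    def test_all_correct_and_all_wrong(self):
        preds = _make_results({"S1P1": 4})
        gold_ok = {r.post_id: ("HIGH", "HIGH") for r in preds}
        gold_bad = {r.post_id: ("HIGH", "LOW") for r in preds}
        assert joint_accuracy(preds, gold_ok) == 1.0
        assert joint_accuracy(preds, gold_bad) == 0.0

    def test_id_mismatch_errors(self):
        preds = _make_results({"S1P1": 2})
        with pytest.raises(ValueError):
            joint_accuracy(preds, {"zzz": ("HIGH", "HIGH")})

    def test_user_proportion(self):
        results = [CascadeResult(f"p{i}", "RELATED" if i < 3 else "NOT_RELATED",
                                 0.9, sfm="HIGH" if i < 3 else None,
                                 sfm_prob=0.8 if i < 3 else None,
                                 pom="LOW" if i < 3 else None,
                                 pom_prob=0.8 if i < 3 else None)
                   for i in range(10)]
        user_of = {f"p{i}": "u1" for i in range(10)}
        assert user_mil_proportion(results, user_of) == {"u1": 0.3}

    def test_correlation_perfect_and_inverse(self):
        props = [0.1, 0.2, 0.3, 0.4, 0.5]
        r, p = correlate(props, props)
        assert r == pytest.approx(1.0)
        r_inv, _ = correlate(props, list(reversed(props)))
        assert r_inv < 0

    def test_correlation_guards(self):
        with pytest.raises(ValueError):
            correlate([0.1, 0.2], [1.0, 2.0])       # too few users
        with pytest.raises(ValueError):
            correlate([0.1, 0.1, 0.1], [1, 2, 3])   # zero variance
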