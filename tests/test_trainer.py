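"""Stratification, staged training, metrics and ensembling."""

import numpy as np
import pytest

from triagonist.gatnet import ModelConfig, init_model
from triagonist.graphrep import NormStats, build_graph, fit_norm_stats
from triagonist.seqio import ActivityRecord, tokenize
from triagonist.synthdata import SynthConfig, generate_dataset
from triagonist.trainer import (
    EnsemblePredictor,
    TrainConfig,
    evaluate,
    label_matrix,
    make_strat_key,
    run_transfer_learning,
    similarity_filter,
    stratified_kfold,
    stratified_split,
)

TINY_MODEL = ModelConfig(n_layers=2, n_heads=2, hidden_dim=12, repr_dim=12,
                         head_hidden=(8, 4), set2set_steps=2, dropout=0.0)


def record(i, seq="ACDEFGHIKL", **ec50):
    full = {"GCGR": None, "GLP1R": None, "GIPR": None}
    full.update(ec50)
    return ActivityRecord.from_ec50(f"r{i}", tokenize(seq), full)


class TestStratKey:
    def test_key_format(self):
        rec = record(0, GCGR=10.0, GLP1R=5000.0)
        assert make_strat_key(rec) == "1|0|m"

    def test_all_missing(self):
        assert make_strat_key(record(0)) == "m|m|m"

    def test_key_space(self):
        # 3 receptors x 3 states
        keys = set()
        states = [None, 10.0, 5000.0]
        for a in states:
            for b in states:
                for c in states:
                    keys.add(make_strat_key(record(0, GCGR=a, GLP1R=b, GIPR=c)))
        assert len(keys) == 27


class TestStratifiedKfold:
    def test_single_key_even_split(self):
        records = [record(i, GCGR=10.0) for i in range(100)]
        folds = stratified_kfold(records, k=5, seed=0)
        assert sorted(len(f) for f in folds) == [20] * 5

    def test_partition_and_disjoint(self, rng):
        records = [record(i, GCGR=float(rng.uniform(1, 1e5)),
                          GLP1R=None if i % 4 == 0 else 10.0)
                   for i in range(53)]
        folds = stratified_kfold(records, k=5, seed=1)
        flat = sorted(i for f in folds for i in f)
        assert flat == list(range(53))

    def test_per_key_balance(self, rng):
        records = ([record(i, GCGR=10.0) for i in range(23)]
                   + [record(100 + i, GCGR=5000.0) for i in range(7)])
        folds = stratified_kfold(records, k=5, seed=2)
        for f_counts in (
            [sum(1 for i in f if i < 23) for f in folds],
            [sum(1 for i in f if i >= 23) for f in folds],
        ):
            assert max(f_counts) - min(f_counts) <= 1

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            stratified_kfold([record(0)], k=5)

    def test_synthetic_fold_positive_fractions(self):
        records, _ = generate_dataset(SynthConfig(n_sequences=150, seed=3))
        folds = stratified_kfold(records, k=5, seed=0)
        labels, mask = label_matrix(records)
        global_frac = labels[:, 1][mask[:, 1]].mean()  # GLP1R: fully labelled
        for f in folds:
            lf = labels[f, 1][mask[f, 1]]
            assert abs(lf.mean() - global_frac) <= 0.1


class TestEvaluate:
    def test_perfect_separation(self):
        p = np.array([[0.9], [0.8], [0.2], [0.1]])
        y = np.array([[1.0], [1.0], [0.0], [0.0]])
        m = np.ones((4, 1), bool)
        res = evaluate(p, y, m, receptors=("GCGR",))["GCGR"]
        assert res.auc_roc == 1.0 and res.f1 == 1.0

    def test_constant_scores_are_chance(self):
        p = np.full((10, 1), 0.5)
        y = np.array([[1.0]] * 5 + [[0.0]] * 5)
        res = evaluate(p, y, np.ones((10, 1), bool), receptors=("GCGR",))["GCGR"]
        assert res.auc_roc == pytest.approx(0.5)

    def test_single_class_auc_missing(self):
        p = np.random.default_rng(0).uniform(size=(5, 1))
        y = np.ones((5, 1))
        res = evaluate(p, y, np.ones((5, 1), bool), receptors=("GCGR",))["GCGR"]
        assert res.auc_roc is None and res.auc_pr is None
        assert res.n == 5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, 30).astype(float)
            if len(np.unique(y)) < 2:
                continue
            p = rng.uniform(size=30)
            res = evaluate(p[:, None], y[:, None], np.ones((30, 1), bool),
                           receptors=("GCGR",))["GCGR"]
            pos, neg = p[y == 1], p[y == 0]
            wins = sum((pp > pn) + 0.5 * (pp == pn)
                       for pp in pos for pn in neg)
            assert res.auc_roc == pytest.approx(wins / (len(pos) * len(neg)),
                                                abs=1e-9)


class _StubModel:
    def __init__(self, value, receptors=("GCGR", "GLP1R", "GIPR")):
        self.value = value
        self.config = ModelConfig()

    def predict_proba(self, graphs):
        return np.full((len(graphs), 3), self.value)


class TestEnsemble:
    def setup_method(self):
        self.stats = fit_norm_stats([tokenize("ACDEFGHIKLMNPQRSTVWY")])

    def test_identical_members_equal_single(self):
        ens = EnsemblePredictor([(_StubModel(0.3), self.stats)] * 3)
        out = ens.predict_proba([tokenize("ACD")])
        assert np.allclose(out, 0.3)

    def test_mean_of_two_members(self):
        ens = EnsemblePredictor([(_StubModel(0.2), self.stats),
                                 (_StubModel(0.8), self.stats)])
        assert np.allclose(ens.predict_proba([tokenize("ACD")]), 0.5)

    def test_stats_mismatch_rejected(self):
        other = fit_norm_stats([tokenize("AAAA")])
        with pytest.raises(ValueError, match="normalization"):
            EnsemblePredictor([(_StubModel(0.2), self.stats),
                               (_StubModel(0.8), other)])

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            EnsemblePredictor([])

    def test_ensemble_variance_bounded(self, rng):
        records, _ = generate_dataset(SynthConfig(n_sequences=40, seed=5))
        seqs = [r.seq for r in records]
        members = [(_StubModel(v), self.stats) for v in (0.2, 0.5, 0.8)]
        single = [m.predict_proba(seqs) for m, _ in members]
        ens = EnsemblePredictor(members).predict_proba(seqs)
        assert ens.var() <= max(s.var() for s in single) + 1e-12


@pytest.fixture(scope="module")
def small_synth():
    records, _ = generate_dataset(SynthConfig(n_sequences=60, seed=21))
    tr, va = stratified_split(records, 0.8, seed=0)
    return [records[i] for i in tr], [records[i] for i in va]


class TestTransferLearning:
    def test_stage2_freezes_encoder_bit_exactly(self, small_synth):
        train_recs, val_recs = small_synth
        cfg = TrainConfig(stage1_epochs=2, stage2_epochs=2, stage3_epochs=1,
                          warmup_epochs=0, seed=0)
        captured = {}
        import triagonist.trainer as tr_mod
        orig = tr_mod._run_stage

        def spy(model, params, *args, **kwargs):
            stage = args[-1] if args else kwargs.get("stage_name")
            out = orig(model, params, *args, **kwargs)
            captured[stage] = {
                k: v.copy() for k, v in model._named_state().items()
                if not k.startswith("head")}
            return out

        tr_mod._run_stage = spy
        try:
            run_transfer_learning(train_recs, val_recs, config=cfg,
                                  model_config=TINY_MODEL)
        finally:
            tr_mod._run_stage = orig
        assert set(captured) >= {"stage1", "stage2", "stage3"}
        for key, v1 in captured["stage1"].items():
            assert np.array_equal(v1, captured["stage2"][key]), key

    def test_training_reduces_stage1_loss(self, small_synth):
        train_recs, val_recs = small_synth
        cfg = TrainConfig(stage1_epochs=8, stage2_epochs=1, stage3_epochs=1,
                          warmup_epochs=0, patience=50, seed=1)
        res = run_transfer_learning(train_recs, val_recs, config=cfg,
                                    model_config=TINY_MODEL)
        s1 = [h["train_loss"] for h in res.history if h["stage"] == "stage1"]
        assert s1[-1] < s1[0]

    def test_early_stopping_returns_best_validation_weights(self, small_synth):
        train_recs, val_recs = small_synth
        cfg = TrainConfig(stage1_epochs=6, stage2_epochs=1, stage3_epochs=1,
                          warmup_epochs=0, patience=2, seed=2)
        res = run_transfer_learning(train_recs, val_recs, config=cfg,
                                    model_config=TINY_MODEL)
        # recompute the validation loss of the returned weights per stage-3
        # weighting; it must not exceed the best stage-3 epoch seen
        from triagonist.gatnet import make_batch
        from triagonist.trainer import _dataset_loss
        val_batch = make_batch([build_graph(r.seq, res.stats) for r in val_recs])
        labels, mask = label_matrix(val_recs)
        final = _dataset_loss(res.model, val_batch, labels, mask,
                              [0.5, 0.5, 0.5], 0.25, 2.0)
        best_seen = min(h["val_loss"] for h in res.history
                        if h["stage"] == "stage3")
        assert final <= best_seen + 1e-6

    def test_no_gipr_labels_skips_stage2(self, small_synth, caplog):
        train_recs, val_recs = small_synth
        stripped = []
        for rec in train_recs:
            ec50 = dict(rec.ec50)
            ec50["GIPR"] = None
            stripped.append(ActivityRecord.from_ec50(rec.id, rec.seq, ec50))
        cfg = TrainConfig(stage1_epochs=2, stage2_epochs=2, stage3_epochs=1,
                          warmup_epochs=0, seed=3)
        import logging
        with caplog.at_level(logging.WARNING):
            res = run_transfer_learning(stripped, val_recs, config=cfg,
                                        model_config=TINY_MODEL)
        assert not any(h["stage"] == "stage2" for h in res.history)
        assert any("stage 2 skipped" in m for m in caplog.messages)


class TestSimilarityFilter:
    def _recs(self, seqs):
        return [ActivityRecord(id=f"s{i}", seq=tokenize(s))
                for i, s in enumerate(seqs)]

    def test_exact_matches_removed(self):
        train = self._recs(["ACDEFGHIKL", "MNPQRSTVWY"])
        val = self._recs(["ACDEFGHIKL", "WWWWWWWWWW"])
        novel, full, sims = similarity_filter(val, train)
        assert [r.seq.text for r in full] == ["WWWWWWWWWW"]
        assert sims["s0"] == 1.0

    def test_threshold_splits_novel(self):
        train = self._recs(["ACDEFGHIKL"])
        val = self._recs(["ACDEFGHIKV",   # 0.9 similar
                          "ACDEFWWWWW",   # 0.5 similar
                          "WWWWWWWWWW"])  # 0.0 similar
        novel, full, sims = similarity_filter(val, train, threshold=0.8)
        assert len(full) == 3
        assert [r.id for r in novel] == ["s1", "s2"]
        assert sims["s0"] == pytest.approx(0.9)

    def test_max_similarity_matches_brute_force_dp(self, rng):
        from conftest import random_tokenseq

        def dp_distance(a, b):
            la, lb = len(a), len(b)
            d = np.zeros((la + 1, lb + 1), dtype=int)
            d[:, 0] = np.arange(la + 1)
            d[0, :] = np.arange(lb + 1)
            for i in range(1, la + 1):
                for j in range(1, lb + 1):
                    cost = 0 if a.tokens[i - 1] == b.tokens[j - 1] else 1
                    d[i, j] = min(d[i - 1, j] + 1, d[i, j - 1] + 1,
                                  d[i - 1, j - 1] + cost)
            return d[la, lb]

        train = self._recs([random_tokenseq(rng, 8, 14).text for _ in range(3)])
        val = self._recs([random_tokenseq(rng, 8, 14).text for _ in range(3)])
        _, _, sims = similarity_filter(val, train)
        for rec in val:
            expected = max(
                1 - dp_distance(rec.seq, t.seq) / max(len(rec.seq), len(t.seq))
                for t in train)
            assert sims[rec.id] == pytest.approx(expected, abs=1e-12)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            similarity_filter([], self._recs(["ACD"]))
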