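"""Two-stage model: architecture contracts, thresholding, training, IO."""
import numpy as np
import pytest

from arnet2 import nn
from arnet2.datatypes import SEVERITY_LEVELS
from arnet2.model import (ArNet2Model, ModelConfig, build_gru_pool,
                          build_stage1_cnn, choose_threshold,
                          default_pos_weight, _history_stack)
from arnet2.synthetic import CohortSpec, make_cohort
from arnet2.windowing import apply_exclusion_cascade, segment_windows


SMALL = dict(n_b=2, n_f=8, n_d=64, max_epochs=4, batch_size=64,
             h=3, gru_units=16, stage2_dense=16)


def _small_cohort(seed=3, n=12):
    spec = CohortSpec(n_patients=n, duration_h=0.5, seed=seed, min_episode_s=35.0)
    beats, truth = make_cohort(spec)
    recs = [apply_exclusion_cascade(segment_windows(b)) for b in beats]
    # interleave so both halves span all severity strata
    return recs[0::2], recs[1::2], truth


class TestArchitecture:
    def test_default_filter_sequence_doubles_every_two_blocks(self):
        assert ModelConfig().filter_sequence() == [64, 64, 128, 128, 256]

    def test_default_embedding_dimension(self):
        assert ModelConfig().embedding_dim == 128

    def test_degenerate_single_block_builds_and_runs(self):
        cfg = ModelConfig(n_b=1, n_f=64)
        net = build_stage1_cnn(cfg)
        assert cfg.filter_sequence() == [64]
        out = net.logits(np.random.default_rng(0).normal(850, 100, (3, 59)))
        assert out.shape == (3,)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(n_b=0)
        with pytest.raises(ValueError):
            ModelConfig(h=-1)
        with pytest.raises(ValueError):
            ModelConfig(lr=0)

    def test_forward_outputs_are_valid_probabilities(self, rng):
        net = build_stage1_cnn(ModelConfig(**SMALL))
        p = nn.sigmoid(net.logits(rng.normal(850, 200, (16, 59))))
        assert np.all(np.isfinite(p)) and np.all((p >= 0) & (p <= 1))

    def test_batch_composition_invariance(self, rng):
        net = build_stage1_cnn(ModelConfig(**SMALL))
        X = rng.normal(850, 100, (10, 59))
        full = net.logits(X)
        singles = np.array([net.logits(X[i:i + 1])[0] for i in range(10)])
        # float32 summation order differs between batch sizes; the result
        # must agree to numerical accumulation precision
        assert np.allclose(full, singles, rtol=1e-4, atol=1e-3)

    def test_gru_pool_has_four_heads_with_default_history(self):
        cfg = ModelConfig()
        heads = build_gru_pool(cfg)
        assert set(heads) == set(SEVERITY_LEVELS)
        seqs = np.zeros((2, cfg.h + 1, cfg.embedding_dim), dtype=np.float32)
        assert seqs.shape[1] == 7
        for head in heads.values():
            assert head.logits(seqs).shape == (2,)

    def test_history_zero_means_single_window(self):
        cfg = ModelConfig(h=0, **{k: v for k, v in SMALL.items() if k != "h"})
        heads = build_gru_pool(cfg)
        seqs = np.zeros((3, 1, cfg.embedding_dim), dtype=np.float32)
        assert heads["NON_AFL"].logits(seqs).shape == (3,)


class TestEmbeddings:
    def test_one_embedding_per_window_fixed_dim(self, rng):
        cfg = ModelConfig(**SMALL)
        net = build_stage1_cnn(cfg)
        emb = net.embeddings(rng.normal(850, 100, (7, 59)))
        assert emb.shape == (7, cfg.embedding_dim)

    def test_identical_windows_identical_embeddings(self, rng):
        net = build_stage1_cnn(ModelConfig(**SMALL))
        w = rng.normal(850, 100, 59)
        emb = net.embeddings(np.stack([w, w]))
        assert np.array_equal(emb[0], emb[1])

    def test_history_stack_zero_pads_first_windows(self):
        emb = np.arange(12, dtype=np.float32).reshape(4, 3)
        seqs = _history_stack(emb, 2)
        assert seqs.shape == (4, 3, 3)
        # first window: two zero rows then itself
        assert np.array_equal(seqs[0], np.vstack([np.zeros((2, 3)), emb[:1]]))
        # later window: full history
        assert np.array_equal(seqs[3], emb[1:4])


class TestThreshold:
    @pytest.mark.parametrize("p,y,expected", [
        ([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.8),
        ([0.6, 0.6], [1, 0], 0.6),
    ])
    def test_worked_examples(self, p, y, expected):
        assert choose_threshold(p, y) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            choose_threshold([0.2, 0.8], [1, 1])

    @staticmethod
    def _brute_force(p, y):
        p, y = np.asarray(p), np.asarray(y)
        best_f1, best_thr = -1.0, None
        for thr in sorted(set(p.tolist())):
            yh = (p >= thr).astype(int)
            tp = int(((y == 1) & (yh == 1)).sum())
            fp = int(((y == 0) & (yh == 1)).sum())
            fn = int(((y == 1) & (yh == 0)).sum())
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            if f1 > best_f1 + 1e-15:
                best_f1, best_thr = f1, thr
        return best_thr, best_f1

    def test_matches_brute_force_scan(self, rng):
        """Fast sweep vs exhaustive candidate enumeration on 100 instances."""
        for _ in range(100):
            n = int(rng.integers(4, 60))
            p = np.round(rng.random(n), 2)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            thr_bf, f1_bf = self._brute_force(p, y)
            thr = choose_threshold(p, y)
            assert thr == pytest.approx(thr_bf, abs=1e-12)


class TestTraining:
    def test_pos_weight_formula(self):
        y = np.array([0] * 900 + [1] * 100)
        assert default_pos_weight(y) == 9.0

    def test_single_class_training_rejected(self):
        train, val, _ = _small_cohort()
        only_neg = [r for r in train if all(w.y == 0 for w in r.included_windows)]
        with pytest.raises(ValueError, match="single class"):
            ArNet2Model.train(only_neg, val, ModelConfig(seed=0, **SMALL))

    def test_training_is_deterministic(self):
        train, val, _ = _small_cohort()
        cfg = ModelConfig(seed=5, max_epochs=2, **{k: v for k, v in SMALL.items()
                                                   if k != "max_epochs"})
        m1 = ArNet2Model.train(train, val, cfg)
        m2 = ArNet2Model.train(train, val, cfg)
        assert m1.stage1_log.final_val_loss == m2.stage1_log.final_val_loss
        assert m1.stage1_threshold == m2.stage1_threshold
        for a, b in zip(m1.stage1.params(), m2.stage1.params()):
            assert np.array_equal(a.value, b.value)

    def test_severity_partition_covers_all_training_windows(self):
        from arnet2.model import _severity_partition
        train, _, _ = _small_cohort()
        parts = _severity_partition(train)
        n_windows = sum(len(r.included_windows) for r in train)
        n_parts = sum(len(r.included_windows) for recs in parts.values()
                      for r in recs)
        ids = [r.record_id for recs in parts.values() for r in recs]
        assert n_parts == n_windows
        assert len(ids) == len(set(ids))

    def test_heads_trained_on_different_strata_diverge(self):
        train, val, _ = _small_cohort(n=16)
        cfg = ModelConfig(seed=5, **SMALL)
        m = ArNet2Model.train(train, val, cfg)
        trained = [lvl for lvl, log in m.head_logs.items() if log.epochs]
        assert len(trained) >= 2
        a, b = (m.heads[trained[0]], m.heads[trained[1]])
        assert any(not np.array_equal(pa.value, pb.value)
                   for pa, pb in zip(a.params(), b.params()))


@pytest.fixture(scope="module")
def trained():
    train, val, truth = _small_cohort(n=16)
    cfg = ModelConfig(seed=5, **SMALL)
    model = ArNet2Model.train(train[:10], train[10:], cfg)
    return model, val, truth


class TestPredictAndCheckpoint:
    def test_prediction_contract(self, trained):
        model, val, _ = trained
        pred = model.predict(val[0])
        n = len(val[0].included_windows)
        assert len(pred) == n
        assert np.all((pred.p_stage2 > 0) & (pred.p_stage2 < 1))
        assert np.array_equal(pred.y_hat, (pred.p_stage2 >= pred.threshold).astype(int))
        assert pred.severity_used in SEVERITY_LEVELS

    def test_empty_recording_gives_missing_burden(self, trained):
        from arnet2.datatypes import WindowedRecording
        model, _, _ = trained
        pred = model.predict(WindowedRecording(record_id="empty"))
        assert len(pred) == 0 and pred.estimated_afb is None

    def test_head_selection_follows_estimated_burden(self, trained):
        """Stage-1 all-negative -> Non-AF_l head; all-positive -> severe."""
        model, val, _ = trained
        rec = val[0]
        thr = model.stage1_threshold
        model.stage1_threshold = 1.1  # no window can reach it
        assert model.predict(rec).severity_used == "NON_AFL"
        model.stage1_threshold = -0.1  # every window passes
        assert model.predict(rec).severity_used == "AF_SEV"
        model.stage1_threshold = thr

    def test_checkpoint_round_trip(self, trained, tmp_path):
        model, val, _ = trained
        path = tmp_path / "model.ckpt"
        model.save(path)
        back = ArNet2Model.load(path)
        a, b = model.predict(val[1]), back.predict(val[1])
        assert np.array_equal(a.p_stage2, b.p_stage2)
        assert a.severity_used == b.severity_used
        assert back.stage1_threshold == model.stage1_threshold

    def test_corrupt_format_tag_rejected(self, trained, tmp_path):
        import json, zipfile
        model, _, _ = trained
        path = tmp_path / "bad.ckpt"
        model.save(path)
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            weights = zf.read("weights.npz")
        meta["format"] = "other"
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("weights.npz", weights)
        with pytest.raises(ValueError, match="format"):
            ArNet2Model.load(path)
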