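"""PU training loop: loss forms, balanced sampling, purging, reproducibility."""

import math

import numpy as np
import pytest

from pairzyme.chem import SubstrateProductPair
from pairzyme.embeddings import FallbackReactionEncoder, VOCAB_SIZE, default_vocab, EmbeddingTable
from pairzyme.model import ModelConfig, PromiscuityNet
from pairzyme.train import (
    RAdam,
    TrainConfig,
    fit,
    purge_unlabeled,
    sample_epoch_negatives,
    smoothed_bce_loss,
)
from pairzyme.triads import EnzymeRecord, POSITIVE, Triad, UNLABELED


def _pair(rid="r1", prod="CC=O"):
    return SubstrateProductPair("CCO", prod, 1.0, rid)


def _triad(i, label, length=30, seed=None):
    rng = np.random.default_rng(seed if seed is not None else i)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    return Triad(_pair(), EnzymeRecord(f"e{i}", seq), label, triad_id=f"t{i}")


class TestSmoothedLoss:
    def test_eps_zero_reduces_to_plain_bce(self):
        p = np.array([0.5])
        y = np.array([1.0])
        assert smoothed_bce_loss(p, y, eps=0.0) == pytest.approx(
            math.log(2.0), abs=1e-10
        )
        grid_p = np.array([0.1, 0.3, 0.7, 0.9])
        grid_y = np.array([0.0, 1.0, 0.0, 1.0])
        expected = -np.mean(
            grid_y * np.log(grid_p) + (1 - grid_y) * np.log(1 - grid_p)
        )
        assert smoothed_bce_loss(grid_p, grid_y, eps=0.0) == pytest.approx(
            expected, abs=1e-10
        )

    def test_as_printed_hand_evaluation(self):
        # y=1, eps=0.1, p=0.5: -(0.1 log .5 + (1-0.9) log .5) = 0.2 log 2
        loss = smoothed_bce_loss(
            np.array([0.5]), np.array([1.0]), eps=0.1, variant="as_printed"
        )
        assert loss == pytest.approx(0.2 * math.log(2.0), abs=1e-10)

    @pytest.mark.parametrize("y", [0.0, 1.0])
    @pytest.mark.parametrize("eps", [0.0, 0.1, 0.3])
    def test_standard_matches_closed_form_on_grid(self, y, eps):
        p = np.linspace(0.05, 0.95, 19)
        y_arr = np.full_like(p, y)
        y_s = y * (1 - eps) + eps / 2
        expected = -np.mean(y_s * np.log(p) + (1 - y_s) * np.log(1 - p))
        assert smoothed_bce_loss(p, y_arr, eps=eps) == pytest.approx(
            expected, abs=1e-9
        )

    def test_standard_minimized_at_smoothed_target(self):
        # numeric grid search: for y=0, eps=0.1 the optimum is p = 0.05
        eps = 0.1
        grid = np.linspace(0.001, 0.999, 999)
        losses = [
            smoothed_bce_loss(np.array([p]), np.array([0.0]), eps=eps)
            for p in grid
        ]
        assert grid[int(np.argmin(losses))] == pytest.approx(0.05, abs=2e-3)

    def test_as_printed_positive_class_degenerates(self):
        # the literal published form is minimized away from p=1 for y=1 —
        # the reason "standard" is the default
        lo = smoothed_bce_loss(np.array([0.5]), np.array([1.0]), 0.1,
                               "as_printed")
        hi = smoothed_bce_loss(np.array([0.99]), np.array([1.0]), 0.1,
                               "as_printed")
        assert lo < hi

    def test_nonnegative_for_both_variants(self, rng):
        p = rng.uniform(1e-6, 1 - 1e-6, size=50)
        y = (rng.random(50) > 0.5).astype(float)
        for variant in ("standard", "as_printed"):
            assert smoothed_bce_loss(p, y, 0.1, variant) >= 0

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            smoothed_bce_loss(np.array([0.5]), np.array([0.5]))


class TestSampling:
    def test_balanced_draw(self):
        pos = [_triad(i, POSITIVE) for i in range(100)]
        pool = [_triad(1000 + i, UNLABELED) for i in range(2000)]
        neg = sample_epoch_negatives(pos, pool, seed=0)
        assert len(neg) == 100
        assert len({t.triad_id for t in neg}) == 100  # without replacement

    def test_epoch_draws_differ_across_seeds(self):
        pos = [_triad(i, POSITIVE) for i in range(50)]
        pool = [_triad(1000 + i, UNLABELED) for i in range(500)]
        a = {t.triad_id for t in sample_epoch_negatives(pos, pool, seed=1)}
        b = {t.triad_id for t in sample_epoch_negatives(pos, pool, seed=2)}
        assert a != b
        assert a == {t.triad_id for t in sample_epoch_negatives(pos, pool, seed=1)}

    def test_small_pool_degrades_with_warning(self, caplog):
        pos = [_triad(i, POSITIVE) for i in range(100)]
        pool = [_triad(1000 + i, UNLABELED) for i in range(50)]
        neg = sample_epoch_negatives(pos, pool, seed=0)
        assert len(neg) == 50
        assert "smaller" in caplog.text

    def test_empty_pool_is_error(self):
        with pytest.raises(ValueError):
            sample_epoch_negatives([_triad(0, POSITIVE)], [], seed=0)


class _StubNet:
    """Deterministic stand-in scoring by enzyme id suffix (synthetic scores)."""

    def __init__(self, scores):
        self._scores = scores

    def score(self, triads):
        return np.array([self._scores[t.triad_id] for t in triads])


class TestPurge:
    def _pool(self, scores):
        return [
            _triad(i, UNLABELED) for i in range(len(scores))
        ], _StubNet({f"t{i}": s for i, s in enumerate(scores)})

    def test_no_trigger_no_change(self):
        pool, net = self._pool([0.99, 0.95])
        cfg = TrainConfig()
        kept, report = purge_unlabeled(net, pool, 0.85, cfg)
        assert kept == pool and not report.triggered

    def test_trigger_removes_high_scores(self):
        pool, net = self._pool([0.1, 0.85, 0.79, 0.99])
        cfg = TrainConfig()
        kept, report = purge_unlabeled(net, pool, 0.95, cfg)
        assert report.triggered
        assert len(kept) == 2
        assert {t.triad_id for t in kept} == {"t0", "t2"}
        # post-condition: nothing surviving scores above the threshold
        assert np.all(net.score(kept) <= cfg.purge_score_threshold)

    def test_boundary_score_kept(self):
        # the rule is strict: exactly 0.8 survives
        pool, net = self._pool([0.8])
        kept, _ = purge_unlabeled(net, pool, 0.95, TrainConfig())
        assert len(kept) == 1


def _tiny_net(seed=0):
    rng = np.random.default_rng(0)
    table = EmbeddingTable(
        vocab=default_vocab(),
        W=rng.normal(size=(VOCAB_SIZE, 100)) * 0.5,
        U=rng.normal(size=(100, VOCAB_SIZE)),
    )
    return PromiscuityNet(
        cfg=ModelConfig.small(), table=table,
        encoder=FallbackReactionEncoder(dim=16, seed=1), seed=seed,
    )


def _tiny_dataset(n_pos=12, n_unl=40):
    pos = [_triad(i, POSITIVE, length=25) for i in range(n_pos)]
    unl = [_triad(100 + i, UNLABELED, length=25) for i in range(n_unl)]
    return pos + unl


class TestFit:
    def _run(self, seed=0, epochs=2):
        cfg = TrainConfig.small(seed=seed, epochs=epochs, batch_size=8)
        net = _tiny_net(seed=seed)
        return fit(_tiny_dataset(), net, cfg)

    def test_history_and_pool_monotone(self):
        net, hist = self._run(epochs=3)
        assert len(hist.epochs) == 3
        sizes = hist.pool_sizes
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        for e in hist.epochs:
            assert np.isfinite(e["loss"]) and 0 <= e["val_auc"] <= 1

    def test_seeded_reruns_identical(self):
        _, h1 = self._run(seed=7)
        _, h2 = self._run(seed=7)
        assert h1.epochs == h2.epochs

    def test_frozen_encoder_untouched_and_head_trains(self):
        net = _tiny_net(seed=1)
        hash_before = net.encoder.params_hash()
        adapter_before = net.params["adapter_W1"].copy()
        cfg = TrainConfig.small(seed=1, epochs=1, batch_size=8)
        net, _ = fit(_tiny_dataset(), net, cfg)
        assert net.encoder.params_hash() == hash_before
        assert not np.array_equal(net.params["adapter_W1"], adapter_before)

    def test_positives_never_purged(self):
        net, hist = self._run(epochs=2)
        # the trained net object keeps all positives; purge only ever sees
        # the unlabeled pool, so pool size can never exceed its start
        assert hist.pool_sizes[0] <= 40


class TestRAdam:
    def test_converges_on_quadratic(self):
        params = {"w": np.array([5.0, -3.0])}
        opt = RAdam(lr=0.1)
        for _ in range(300):
            opt.step(params, {"w": 2 * params["w"]})
        assert np.allclose(params["w"], 0.0, atol=1e-3)

    def test_weight_decay_shrinks_parameters(self):
        params = {"w": np.array([1.0])}
        opt = RAdam(lr=0.1, weight_decay=0.5)
        opt.step(params, {"w": np.array([0.0])})
        assert params["w"][0] < 1.0
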