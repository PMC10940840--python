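"""Positive-unlabeled training: undersampling, smoothed loss, dynamic purge.

Each epoch draws, uniformly without replacement, as many unlabeled triads as
there are positives (balanced undersampling); the loss is a binary
cross-entropy / label-smoothing hybrid with rate eps = 0.1.  Once the
validation ROC-AUC exceeds 0.9, unlabeled pool members the model scores
above 0.8 are permanently purged — they are presumed to be hidden positives
and must not keep masquerading as negatives.  Optimization uses rectified
Adam (lr 5e-6, weight decay 1e-5 at full scale) with gradient clipping.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from . import nn
from .metrics import roc_auc
from .model import PromiscuityNet, forward
from .triads import POSITIVE, UNLABELED, Triad

logger = logging.getLogger(__name__)

P_CLAMP = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 64
    batch_size: int = 64
    lr: float = 5e-6
    weight_decay: float = 1e-5
    label_smoothing: float = 0.1
    purge_trigger_auc: float = 0.9
    purge_score_threshold: float = 0.8
    neg_ratio: int = 20
    seed: int = 0
    loss_variant: str = "standard"
    grad_clip: float = 1.0
    optimizer: str = "radam"  # or "adam"
    val_fraction: float = 0.05
    lr_schedule: str = "constant"  # or "cosine" (decays to 5% of lr)

    def __post_init__(self):
        if not 0.0 <= self.label_smoothing < 0.5:
            raise ValueError("label smoothing must be in [0, 0.5)")
        for t in (self.purge_trigger_auc, self.purge_score_threshold):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.loss_variant not in ("standard", "as_printed"):
            raise ValueError(f"unknown loss variant {self.loss_variant!r}")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")

    @classmethod
    def small(cls, **overrides) -> "TrainConfig":
        """Desk-scale schedule for the small model and synthetic data.

        The aggressive base learning rate needs the cosine decay: constant
        1e-2 learns fast but can destabilize late in a 30-epoch run."""
        base = cls(epochs=30, batch_size=8, lr=1e-2, weight_decay=1e-5,
                   lr_schedule="cosine")
        return replace(base, **overrides)


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)  # dicts: loss, val_auc, pool
    purge_events: list = field(default_factory=list)

    @property
    def pool_sizes(self) -> list:
        return [e["pool_size"] for e in self.epochs]


def smoothed_bce_loss(p, y, eps: float = 0.1, variant: str = "standard"):
    """Label-smoothed binary cross-entropy (mean over the batch).

    ``standard``: targets are softened to y' = y(1-eps) + eps/2 and the loss
    is the usual BCE against y'.  ``as_printed`` evaluates the published
    hybrid literally: -mean[(eps*y) log p + (1 - (1-eps) y) log(1-p)]; it is
    kept for fidelity experiments (for y = 1 it is minimized away from p = 1,
    which is why it is not the default).
    """
    y_arr = np.asarray(y, dtype=float)
    if not np.all((y_arr == 0.0) | (y_arr == 1.0)):
        raise ValueError("labels must be 0 or 1")
    p = anp.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    if variant == "standard":
        y_s = y_arr * (1.0 - eps) + eps / 2.0
        terms = y_s * anp.log(p) + (1.0 - y_s) * anp.log(1.0 - p)
    elif variant == "as_printed":
        terms = (eps * y_arr) * anp.log(p) + (
            1.0 - (1.0 - eps) * y_arr
        ) * anp.log(1.0 - p)
    else:
        raise ValueError(f"unknown loss variant {variant!r}")
    return -anp.mean(terms)


def sample_epoch_negatives(
    positives: Sequence[Triad],
    unlabeled_pool: Sequence[Triad],
    seed: int = 0,
) -> list[Triad]:
    """Draw |positives| unlabeled triads uniformly without replacement.

    When the pool is smaller than the positive set, the whole pool is used
    (with a warning) rather than failing.
    """
    if len(unlabeled_pool) == 0:
        raise ValueError("unlabeled pool is empty")
    n = len(positives)
    if len(unlabeled_pool) < n:
        logger.warning(
            "pool (%d) smaller than positives (%d); using all",
            len(unlabeled_pool), n,
        )
        return list(unlabeled_pool)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(unlabeled_pool), size=n, replace=False)
    return [unlabeled_pool[i] for i in sorted(idx)]


@dataclass
class PurgeReport:
    triggered: bool
    n_before: int
    n_after: int
    purged_ids: tuple = ()


def purge_unlabeled(
    net: PromiscuityNet,
    unlabeled_pool: Sequence[Triad],
    current_val_auc: float,
    cfg: TrainConfig,
) -> tuple[list[Triad], PurgeReport]:
    """Permanently drop pool members scored above the purge threshold.

    A no-op unless ``current_val_auc`` exceeds the trigger (default 0.9);
    when it does, every unlabeled triad the model currently scores above the
    score threshold (default 0.8) is removed — it is too positive-looking to
    keep serving as a presumed negative.
    """
    pool = list(unlabeled_pool)
    if not current_val_auc > cfg.purge_trigger_auc or not pool:
        return pool, PurgeReport(False, len(pool), len(pool))
    scores = net.score(pool)
    keep = [t for t, s in zip(pool, scores) if s <= cfg.purge_score_threshold]
    purged = tuple(
        t.triad_id or t.enzyme.enzyme_id
        for t, s in zip(pool, scores)
        if s > cfg.purge_score_threshold
    )
    if purged:
        logger.info("purged %d unlabeled triads", len(purged))
    return keep, PurgeReport(True, len(pool), len(keep), purged)


# ---------------------------------------------------------------------------
# optimizers


class RAdam:
    """Rectified Adam with decoupled weight decay, on a dict of arrays."""

    def __init__(self, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 rectify: bool = True):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.rectify = rectify
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        t, b1, b2 = self.t, self.b1, self.b2
        rho_t = self.rho_inf - 2.0 * t * b2**t / (1.0 - b2**t)
        for k, g in grads.items():
            m = self.m.setdefault(k, np.zeros_like(params[k]))
            v = self.v.setdefault(k, np.zeros_like(params[k]))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**t)
            if self.rectify and rho_t <= 4.0:
                update = self.lr * m_hat  # un-rectified warmup: SGD-with-momentum
            else:
                v_hat = np.sqrt(v / (1 - b2**t)) + self.eps
                if self.rectify:
                    r = np.sqrt(
                        ((rho_t - 4) * (rho_t - 2) * self.rho_inf)
                        / ((self.rho_inf - 4) * (self.rho_inf - 2) * rho_t)
                    )
                else:
                    r = 1.0
                update = self.lr * r * m_hat / v_hat
            params[k] = params[k] - update - self.lr * self.wd * params[k]


# ---------------------------------------------------------------------------
# fit


def _epoch_seed(base_seed: int, epoch: int) -> int:
    return int(
        np.random.SeedSequence([base_seed, epoch]).generate_state(1)[0] % (2**31)
    )


def fit(
    train_triads: Sequence[Triad],
    net: PromiscuityNet,
    cfg: TrainConfig,
    val_triads: Optional[Sequence[Triad]] = None,
    callback: Optional[Callable] = None,
) -> tuple[PromiscuityNet, TrainHistory]:
    """Run the PU training loop; returns the net (best-AUC weights) + history.

    When ``val_triads`` is not given, a fixed validation slice
    (``cfg.val_fraction`` of positives plus an equal number of unlabeled) is
    carved from the training triads before training starts; it drives both
    the purge trigger and best-checkpoint selection.
    """
    positives = [t for t in train_triads if t.label == POSITIVE]
    pool = [t for t in train_triads if t.label == UNLABELED]
    if not positives:
        raise ValueError("no positive triads")
    if not pool:
        raise ValueError("no unlabeled triads")

    rng = np.random.default_rng(cfg.seed)
    if val_triads is None:
        # the configured fraction, but never fewer than 8 positives (or a
        # third of them) — an AUC on a handful of points is too noisy to
        # drive the purge trigger and checkpoint selection
        n_val_pos = max(8, int(round(cfg.val_fraction * len(positives))))
        n_val_pos = max(1, min(n_val_pos, len(positives) // 3))
        # unlabeled are plentiful; 3x negatives makes the validation AUC a
        # much finer-grained signal for the purge trigger and checkpointing
        n_val_neg = min(3 * n_val_pos, len(pool) - 1)
        vp = rng.choice(len(positives), size=n_val_pos, replace=False)
        vn = rng.choice(len(pool), size=n_val_neg, replace=False)
        val_triads = [positives[i] for i in vp] + [pool[i] for i in vn]
        positives = [t for i, t in enumerate(positives) if i not in set(vp)]
        pool = [t for i, t in enumerate(pool) if i not in set(vn)]
    val_labels = np.array([1 if t.label == POSITIVE else 0 for t in val_triads])

    opt = RAdam(
        cfg.lr, cfg.weight_decay, rectify=(cfg.optimizer == "radam")
    )
    history = TrainHistory()
    best_auc = -np.inf
    best_params = copy.deepcopy(net.params)
    # stochastic weight average over the schedule's tail: a second
    # checkpoint candidate that damps epoch-to-epoch oscillation
    swa_start = max(cfg.epochs - max(cfg.epochs // 3, 1), 1)
    swa_params: Optional[dict] = None
    swa_count = 0

    def loss_fn(params, pb, pm, ef, em, labels, drop_rng):
        p = forward(params, net.cfg, pb, pm, ef, em, train=True, rng=drop_rng)
        return smoothed_bce_loss(
            p, labels, eps=cfg.label_smoothing, variant=cfg.loss_variant
        )

    grad_fn = value_and_grad(loss_fn)

    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            frac = epoch / max(cfg.epochs - 1, 1)
            opt.lr = cfg.lr * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac)))
        ep_seed = _epoch_seed(cfg.seed, epoch)
        negatives = sample_epoch_negatives(positives, pool, seed=ep_seed)
        epoch_set = list(positives) + list(negatives)
        labels = np.array(
            [1.0] * len(positives) + [0.0] * len(negatives), dtype=np.float32
        )
        # batch by enzyme length (random tie-break) to keep padding small,
        # then visit the batches in random order
        ep_rng = np.random.default_rng(ep_seed + 1)
        jitter = ep_rng.random(len(epoch_set))
        order = np.lexsort(
            (jitter, np.array([t.enzyme.length for t in epoch_set]))
        )
        starts = list(range(0, len(order), cfg.batch_size))
        ep_rng.shuffle(starts)
        drop_rng = np.random.default_rng(ep_seed + 2)

        losses = []
        for start in starts:
            sel = order[start : start + cfg.batch_size]
            batch = [epoch_set[i] for i in sel]
            pb, pm, ef, em = net.featurize(batch)
            loss, grads = grad_fn(
                net.params, pb, pm, ef, em, labels[sel], drop_rng
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch}: {loss!r}; lower the "
                    f"learning rate or inspect the input features"
                )
            grads = nn.clip_grad_norm(grads, cfg.grad_clip)
            opt.step(net.params, grads)
            losses.append(float(loss))

        if epoch >= swa_start:
            if swa_params is None:
                swa_params = {k: v.copy() for k, v in net.params.items()}
            else:
                for k, v in net.params.items():
                    swa_params[k] = (swa_params[k] * swa_count + v) / (
                        swa_count + 1
                    )
            swa_count += 1

        val_scores = net.score(list(val_triads))
        val_auc = roc_auc(val_scores, val_labels)
        pool, report = purge_unlabeled(net, pool, val_auc, cfg)
        if report.triggered and report.n_after < report.n_before:
            history.purge_events.append(
                {"epoch": epoch, "n_purged": report.n_before - report.n_after}
            )
        history.epochs.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "val_auc": float(val_auc),
                "pool_size": len(pool),
            }
        )
        # ties go to the later epoch: with equal validation AUC the longer-
        # trained weights have the lower training loss
        if val_auc >= best_auc:
            best_auc = val_auc
            best_params = copy.deepcopy(net.params)
        if callback is not None:
            callback(epoch, history)

    net.params = best_params
    if swa_params is not None:
        live = net.params
        net.params = swa_params
        swa_auc = roc_auc(net.score(list(val_triads)), val_labels)
        if swa_auc >= best_auc:
            best_auc = swa_auc
        else:
            net.params = live
    history.epochs[-1]["selected_val_auc"] = float(best_auc)
    return net, history
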