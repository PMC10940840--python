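"""Desk-scale end-to-end benchmark runs on the planted-signal fixtures.

These drive both the validation suite and the reproduction script: generate
a synthetic triad dataset, train the small transformer (2+2 layers, 2 heads,
H = 32) for at most 30 epochs, and measure held-out discrimination.  The
label-shuffled control re-runs the identical pipeline with training labels
permuted; a sound setup must collapse to chance there.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
from threadpoolctl import threadpool_limits

from .api import PromiscuityModel
from .metrics import evaluate
from .model import ModelConfig
from .synth import SyntheticSpec, gen_triad_dataset
from .train import TrainConfig, fit
from .triads import split_test, subset


def learnability_run(
    seed: int = 1,
    shuffled: bool = False,
    spec: Optional[SyntheticSpec] = None,
    train_config: Optional[TrainConfig] = None,
    n_test_pos: int = 12,
    n_test_neg: int = 48,
):
    """Train the small model on the planted-signal fixture; return results.

    Returns a dict with the held-out metric report, training history, the
    fitted network and the held-out triads.
    """
    spec = spec if spec is not None else SyntheticSpec(seed=seed)
    ds = gen_triad_dataset(spec)
    split, triads = split_test(
        ds.triads, n_pos=n_test_pos, n_neg=n_test_neg, seed=seed
    )
    train_triads = subset(triads, split.train_ids)
    test_triads = subset(triads, split.test_ids)
    if shuffled:
        rng = np.random.default_rng(seed + 1000)
        labels = [t.label for t in train_triads]
        rng.shuffle(labels)
        train_triads = [
            replace(t, label=label) for t, label in zip(train_triads, labels)
        ]
    cfg = train_config if train_config is not None else TrainConfig.small(seed=seed)
    model = PromiscuityModel(
        train_triads,
        model_config=ModelConfig.small(),
        train_config=cfg,
    )
    # single BLAS thread: reduction order, and hence the exact training
    # trajectory, must not depend on the host's core count
    with threadpool_limits(limits=1):
        net, history = fit(model.triads, model.net, cfg)
        report = evaluate(net, test_triads)
    return {
        "report": report,
        "history": history,
        "net": net,
        "dataset": ds,
        "test_triads": test_triads,
    }
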