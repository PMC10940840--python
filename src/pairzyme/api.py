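"""Model/Results front door: fit a promiscuity model, inspect, screen.

`PromiscuityModel` is constructed from triad data (plus optional embedding
table / reaction encoder) and `fit()` returns a `PromiscuityResults` holding
the trained network, the training history, validation diagnostics and the
screening entry points — the statsmodels-flavoured surface over the
lower-level modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .embeddings import EmbeddingTable, ReactionEncoderInterface, train_cbow
from .metrics import MetricReport, evaluate
from .model import ModelConfig, PromiscuityNet
from .screen import ScoredEnzyme, multi_pair_screen, rank_of, screen
from .train import TrainConfig, TrainHistory, fit
from .triads import POSITIVE, Triad, read_enzymes_fasta, read_triads_tsv

logger = logging.getLogger(__name__)


class PromiscuityModel:
    """A substrate-product-pair promiscuity model over a triad dataset.

    Parameters
    ----------
    triads
        Training triads (positive + unlabeled).
    model_config, train_config
        Architecture and optimization settings; defaults are the full-scale
        published settings (12 layers, 8 heads, H=64; 64 epochs at lr 5e-6).
        Use ``ModelConfig.small()`` / ``TrainConfig.small()`` for desk-scale
        runs.
    embedding_table
        A trained CBOW table; when omitted, one is fitted on the triads'
        enzyme sequences at construction time.
    reaction_encoder
        Frozen reaction encoder; defaults to the seeded built-in.

    Examples
    --------
    >>> model = PromiscuityModel(triads, model_config=ModelConfig.small(),
    ...                          train_config=TrainConfig.small())
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        triads: Sequence[Triad],
        model_config: Optional[ModelConfig] = None,
        train_config: Optional[TrainConfig] = None,
        embedding_table: Optional[EmbeddingTable] = None,
        reaction_encoder: Optional[ReactionEncoderInterface] = None,
        cbow_epochs: int = 3,
    ):
        self.triads = list(triads)
        if not self.triads:
            raise ValueError("no triads given")
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        if embedding_table is None:
            sequences = sorted({t.enzyme.sequence for t in self.triads})
            embedding_table = train_cbow(
                sequences, epochs=cbow_epochs, seed=self.train_config.seed
            )
        self.embedding_table = embedding_table
        self.net = PromiscuityNet(
            cfg=self.model_config,
            table=embedding_table,
            encoder=reaction_encoder,
            seed=self.train_config.seed,
        )

    @classmethod
    def from_files(
        cls,
        triads_tsv,
        enzymes_fasta,
        **kwargs,
    ) -> "PromiscuityModel":
        """Build from a triads TSV plus the enzyme FASTA it references."""
        enzymes = {e.enzyme_id: e for e in read_enzymes_fasta(enzymes_fasta)}
        triads = read_triads_tsv(triads_tsv, enzymes)
        return cls(triads, **kwargs)

    def fit(
        self, val_triads: Optional[Sequence[Triad]] = None
    ) -> "PromiscuityResults":
        net, history = fit(
            self.triads, self.net, self.train_config, val_triads=val_triads
        )
        return PromiscuityResults(
            model=self, net=net, history=history
        )


@dataclass
class PromiscuityResults:
    """Fitted promiscuity model: history, diagnostics, screening."""

    model: PromiscuityModel
    net: PromiscuityNet
    history: TrainHistory

    @property
    def best_val_auc(self) -> float:
        return max(e["val_auc"] for e in self.history.epochs)

    def predict(self, triads: Sequence[Triad]) -> np.ndarray:
        """Deterministic catalysis probabilities."""
        return self.net.score(list(triads))

    def evaluate(self, triads: Sequence[Triad], threshold: float = 0.5) -> MetricReport:
        return evaluate(self.net, triads, threshold=threshold)

    def screen(self, pair, library) -> list[ScoredEnzyme]:
        return screen(pair, library, self.net)

    def multi_pair_screen(self, pairs, library, threshold: float = 0.5):
        return multi_pair_screen(pairs, library, self.net, threshold=threshold)

    def rank_of(self, target_id: str, ranked, threshold: float = 0.5):
        return rank_of(target_id, ranked, threshold=threshold)

    def attention_map(self, triad: Triad):
        return self.net.attention_for(triad)

    def save(self, out_dir) -> None:
        self.net.save(out_dir)

    def summary(self) -> str:
        cfg, tc = self.model.model_config, self.model.train_config
        ep = self.history.epochs
        n_pos = sum(1 for t in self.model.triads if t.label == POSITIVE)
        n_unl = len(self.model.triads) - n_pos
        lines = [
            "Promiscuity Model Results",
            "=" * 58,
            f"{'Triads (positive / unlabeled)':38s} {n_pos} / {n_unl}",
            f"{'Encoder/decoder layers':38s} {cfg.n_layers}",
            f"{'Attention heads':38s} {cfg.n_heads}",
            f"{'Hidden width / norm shape':38s} {cfg.hidden}",
            f"{'Dropout':38s} {cfg.dropout}",
            f"{'Epochs run':38s} {len(ep)}",
            f"{'Learning rate / weight decay':38s} {tc.lr} / {tc.weight_decay}",
            f"{'Label smoothing (variant)':38s} "
            f"{tc.label_smoothing} ({tc.loss_variant})",
            "-" * 58,
            f"{'Final training loss':38s} {ep[-1]['loss']:.4f}",
            f"{'Best validation ROC-AUC':38s} {self.best_val_auc:.4f}",
            f"{'Unlabeled pool (start -> end)':38s} "
            f"{ep[0]['pool_size']} -> {ep[-1]['pool_size']}",
            f"{'Purge events':38s} {len(self.history.purge_events)}",
            "=" * 58,
        ]
        return "\n".join(lines)
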