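"""Enzyme library screening: single-pair ranking and multi-pair intersection.

Given one substrate-product pair and a candidate library, every enzyme gets
a catalysis-likelihood score and a rank (1 = best; ties broken by enzyme id
for determinism); the relative rank is rank / library size.  For a multi-step
conversion the screen is run pair by pair and an enzyme survives only if it
clears the threshold for *every* pair; survivors are ordered by their
minimum per-pair score, the conservative aggregate that reproduces the
intersection of the per-pair shortlists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import SubstrateProductPair
from .triads import EnzymeRecord, Triad, UNLABELED

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoredEnzyme:
    enzyme_id: str
    score: float
    rank: int
    relative_rank: float


def _score_library(pair, library, net) -> tuple[list[EnzymeRecord], np.ndarray]:
    usable, skipped = [], []
    for enz in library:
        if enz.length > net.cfg.max_enzyme_len:
            skipped.append(enz.enzyme_id)
        else:
            usable.append(enz)
    if skipped:
        logger.warning(
            "skipped %d over-length enzymes: %s%s",
            len(skipped), ", ".join(skipped[:5]),
            "..." if len(skipped) > 5 else "",
        )
    if not usable:
        raise ValueError("no usable enzymes in library")
    triads = [Triad(pair=pair, enzyme=e, label=UNLABELED) for e in usable]
    return usable, net.score(triads)


def screen(
    pair: SubstrateProductPair,
    library: Sequence[EnzymeRecord],
    net,
) -> list[ScoredEnzyme]:
    """Rank a library against one pair (descending score, 1 = best)."""
    usable, scores = _score_library(pair, library, net)
    order = sorted(
        range(len(usable)), key=lambda i: (-scores[i], usable[i].enzyme_id)
    )
    n = len(usable)
    return [
        ScoredEnzyme(
            enzyme_id=usable[i].enzyme_id,
            score=float(scores[i]),
            rank=r + 1,
            relative_rank=(r + 1) / n,
        )
        for r, i in enumerate(order)
    ]


def multi_pair_screen(
    pairs: Sequence[SubstrateProductPair],
    library: Sequence[EnzymeRecord],
    net,
    threshold: float = 0.5,
) -> tuple[list[ScoredEnzyme], pd.DataFrame]:
    """Intersection screening over several pairs.

    Returns (shortlist, score matrix).  The matrix holds one row per enzyme
    and one column per pair; the shortlist contains enzymes whose score
    exceeds ``threshold`` for every pair, ranked by their minimum score.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    matrix: dict[str, list[float]] = {}
    ids_order: list[str] = []
    for pair in pairs:
        usable, scores = _score_library(pair, library, net)
        for enz, s in zip(usable, scores):
            if enz.enzyme_id not in matrix:
                matrix[enz.enzyme_id] = []
                ids_order.append(enz.enzyme_id)
            matrix[enz.enzyme_id].append(float(s))
    n_pairs = len(pairs)
    df = pd.DataFrame(
        {
            "enzyme_id": ids_order,
            **{
                f"pair_{j}": [matrix[i][j] for i in ids_order]
                for j in range(n_pairs)
            },
        }
    )
    df["min_score"] = df[[f"pair_{j}" for j in range(n_pairs)]].min(axis=1)
    survivors = df[df["min_score"] > threshold].copy()
    survivors = survivors.sort_values(
        ["min_score", "enzyme_id"], ascending=[False, True]
    )
    n = len(survivors)
    shortlist = [
        ScoredEnzyme(
            enzyme_id=row.enzyme_id,
            score=float(row.min_score),
            rank=r + 1,
            relative_rank=(r + 1) / n,
        )
        for r, row in enumerate(survivors.itertuples())
    ]
    return shortlist, df


def rank_of(
    target_id: str,
    ranked: Sequence[ScoredEnzyme],
    threshold: float = 0.5,
) -> tuple[int, float, int]:
    """Locate a target enzyme in a ranked screen.

    Returns (rank, relative rank, number of enzymes scoring above the
    positive-call threshold).
    """
    positive_count = sum(1 for s in ranked if s.score > threshold)
    for s in ranked:
        if s.enzyme_id == target_id:
            return s.rank, s.relative_rank, positive_count
    raise KeyError(f"enzyme {target_id!r} not in ranked list")


def write_scores_tsv(ranked: Sequence[ScoredEnzyme], path) -> None:
    pd.DataFrame(
        [
            {
                "enzyme_id": s.enzyme_id,
                "score": s.score,
                "rank": s.rank,
                "relative_rank": s.relative_rank,
            }
            for s in ranked
        ]
    ).to_csv(path, sep="\t", index=False)
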