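"""End-to-end mining: reactions + enzyme FASTA -> pairs + PU triads.

Enzymes are attached to reactions through their EC annotation: an enzyme
whose EC number matches one of a reaction's EC numbers counts as that
reaction's (positive) enzyme, mirroring how curated reaction databases link
the two.  Reactions without EC numbers yield no positives and no unlabeled
draws (logged).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .chem import MappedReaction, extract_pairs, filter_pairs
from .triads import (
    EnzymeRecord,
    Triad,
    assign_triad_ids,
    build_triads,
    deduplicate,
    generate_unlabeled_dataset,
)

logger = logging.getLogger(__name__)


def mine_dataset(
    reactions: Sequence[MappedReaction],
    enzymes: Sequence[EnzymeRecord],
    cofactors: Optional[set] = None,
    threshold: float = 0.5,
    neg_ratio: int = 20,
    max_len: int = 1000,
    seed: int = 0,
    exclude_three_level: bool = False,
) -> tuple[list, list]:
    """Extract filtered pairs and build deduplicated positive+unlabeled triads."""
    pairs = []
    enzymes_by_reaction = {}
    reaction_ecs = {}
    for rxn in reactions:
        rxn_pairs = filter_pairs(
            extract_pairs(rxn, threshold=threshold), cofactors=cofactors
        )
        pairs.extend(rxn_pairs)
        ecs = list(rxn.ec_numbers)
        reaction_ecs[rxn.reaction_id] = ecs
        if ecs:
            enzymes_by_reaction[rxn.reaction_id] = [
                e for e in enzymes if e.ec in ecs
            ]
        else:
            logger.warning(
                "reaction %s has no EC numbers; no enzymes attached and no "
                "unlabeled drawn", rxn.reaction_id,
            )
            enzymes_by_reaction[rxn.reaction_id] = []
    positives = build_triads(pairs, enzymes_by_reaction, max_len=max_len)
    # the length cap applies to the whole dataset, so over-length enzymes
    # are not eligible as unlabeled draws either
    pool = [e for e in enzymes if e.length <= max_len]
    unlabeled = generate_unlabeled_dataset(
        positives, reaction_ecs, pool, k=neg_ratio, seed=seed,
        exclude_three_level=exclude_three_level,
    )
    triads = assign_triad_ids(deduplicate(positives + unlabeled))
    return pairs, triads
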