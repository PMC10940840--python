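"""Seeded synthetic fixtures: mapped reactions, enzyme pools, triad datasets.

The generator emulates the *shape* of curated reaction-database inputs
without any download: atom-mapped reaction SMILES built from small templated
transformations (alcohol oxidations, ether condensations, a decarboxylation
releasing CO2, and an exact-50/50 provenance boundary case), and enzyme
pools in which every reaction class carries a short sequence motif.  The
motif is the planted, sequence-detectable signal: an enzyme truly catalyzes
a pair iff it contains the motif of the pair's reaction class, which gives
learnability and screening tests an unambiguous ground truth.  Biochemical
realism of the reactions is a non-goal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import chem
from .chem import MappedReaction, SubstrateProductPair, extract_pairs, filter_pairs
from .triads import (
    EnzymeRecord,
    Triad,
    assign_triad_ids,
    build_triads,
    deduplicate,
    generate_unlabeled_dataset,
    write_enzymes_fasta,
    write_triads_tsv,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    n_reaction_classes: int = 3
    reactions_per_class: int = 4
    enzymes_per_class: int = 20
    enzymes_per_reaction: int = 6
    motif_length: int = 6
    decoy_pool_size: int = 400
    neg_ratio: int = 20
    seed: int = 0
    seq_len_range: tuple = (80, 200)
    include_boundary_cases: bool = True

    def __post_init__(self):
        for name in (
            "n_reaction_classes", "reactions_per_class", "enzymes_per_class",
            "enzymes_per_reaction", "motif_length", "decoy_pool_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def class_ec(c: int) -> str:
    """Distinct four-level EC string for reaction class ``c``."""
    return f"{c % 6 + 1}.1.1.{c + 1}"


def _oxidation_line(k: int) -> str:
    """Primary alcohol (k heavy atoms) -> aldehyde; full provenance."""
    chain = "[CH3:1]" + "".join(f"[CH2:{i}]" for i in range(2, k - 1))
    sub = chain + f"[CH2:{k-1}][OH:{k}]"
    prod = chain + f"[CH:{k-1}]=[O:{k}]"
    return f"{sub}>>{prod}"


def _condensation_line(k: int) -> str:
    """Chain alcohol + methanol -> methyl ether + water."""
    chain = "[CH3:1]" + "".join(f"[CH2:{i}]" for i in range(2, k))
    sub1 = chain + f"[OH:{k}]"
    sub2 = f"[CH3:{k+1}][OH:{k+2}]"
    prod = chain + f"[O:{k}][CH3:{k+1}]"
    water = f"[OH2:{k+2}]"
    return f"{sub1}.{sub2}>>{prod}.{water}"


BOUNDARY_5050 = (
    "[CH3:1][CH2:2][OH:5].[CH3:3][CH2:4][OH:6]"
    ">>[CH3:1][CH2:2][CH2:4][CH3:3].[OH:5][OH:6]"
)
DECARBOXYLATION = "[CH3:1][C:2](=[O:3])[OH:4]>>[CH4:1].[O:3]=[C:2]=[O:4]"


@dataclass
class SyntheticReactionSet:
    reactions: list
    lines: dict  # reaction_id -> mapped reaction SMILES line
    class_of_reaction: dict  # reaction_id -> class index (edge cases: 0)
    reaction_ecs: dict  # reaction_id -> [ec]


def gen_mapped_reactions(spec: SyntheticSpec) -> SyntheticReactionSet:
    """Templated, map-conserving reactions; one EC per class.

    Boundary cases (when enabled) are attached to class 0: an exactly-50%
    provenance condensation (every pair must be rejected downstream) and a
    decarboxylation whose products are a single heavy atom and CO2 (both
    removed by the filter).
    """
    out = SyntheticReactionSet([], {}, {}, {})

    def add(rid: str, line: str, c: int):
        rxn = chem.parse_mapped_reaction(line, reaction_id=rid, ec=[class_ec(c)])
        out.reactions.append(rxn)
        out.lines[rid] = line
        out.class_of_reaction[rid] = c
        out.reaction_ecs[rid] = [class_ec(c)]

    # chain lengths advance with a global counter per template so that every
    # reaction (and hence every extracted pair) is unique across classes —
    # a pair occurring in two classes would make the planted labels ambiguous
    n_ox = n_cond = 0
    for c in range(spec.n_reaction_classes):
        for r in range(spec.reactions_per_class):
            if r % 2 == 0:
                line = _oxidation_line(4 + n_ox)
                n_ox += 1
            else:
                line = _condensation_line(4 + n_cond)
                n_cond += 1
            add(f"rxn_c{c}_{r}", line, c)
    if spec.include_boundary_cases:
        add("rxn_edge_half", BOUNDARY_5050, 0)
        add("rxn_edge_cofactor", DECARBOXYLATION, 0)
    return out


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def gen_motifs(spec: SyntheticSpec, rng) -> list:
    motifs: list[str] = []
    while len(motifs) < spec.n_reaction_classes:
        m = _random_seq(rng, spec.motif_length)
        if m not in motifs:
            motifs.append(m)
    return motifs


def gen_enzyme_pool(spec: SyntheticSpec):
    """Class enzymes (motif planted at a random position) plus motif-free decoys.

    Decoy ECs are scattered over ten labels disjoint from every class EC.
    With boundary cases enabled the pool also contains motif-free sequences
    of exactly 1000 and 1001 residues to exercise the length cap.
    """
    rng = np.random.default_rng(spec.seed + 1)
    motifs = gen_motifs(spec, rng)
    lo, hi = spec.seq_len_range
    pool: list[EnzymeRecord] = []
    for c in range(spec.n_reaction_classes):
        for i in range(spec.enzymes_per_class):
            length = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, length)
            pos = int(rng.integers(0, length - spec.motif_length + 1))
            seq = seq[:pos] + motifs[c] + seq[pos + spec.motif_length:]
            pool.append(
                EnzymeRecord(f"enz_c{c}_{i:03d}", seq, ec=class_ec(c))
            )
    decoy_ecs = [f"9.9.{j + 1}.{j + 1}" for j in range(10)]
    n_decoys = 0
    while n_decoys < spec.decoy_pool_size:
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        if any(m in seq for m in motifs):
            continue
        pool.append(
            EnzymeRecord(
                f"enz_decoy_{n_decoys:04d}", seq,
                ec=decoy_ecs[n_decoys % len(decoy_ecs)],
            )
        )
        n_decoys += 1
    if spec.include_boundary_cases:
        for length in (1000, 1001):
            while True:
                seq = _random_seq(rng, length)
                if not any(m in seq for m in motifs):
                    break
            pool.append(
                EnzymeRecord(f"enz_len{length}", seq, ec=decoy_ecs[0])
            )
    return pool, motifs


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    reaction_set: SyntheticReactionSet
    pool: list
    motifs: list
    pairs: list
    triads: list  # deduplicated, id-assigned
    truth: dict  # triad_id -> bool (enzyme carries the pair's class motif)
    enzymes_by_reaction: dict

    @property
    def positives(self):
        return [t for t in self.triads if t.label == "positive"]

    @property
    def unlabeled(self):
        return [t for t in self.triads if t.label == "unlabeled"]

    def truly_catalytic(self, triad: Triad) -> bool:
        c = self.reaction_set.class_of_reaction[triad.pair.reaction_id]
        return self.motifs[c] in triad.enzyme.sequence

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "reaction_id": rid,
                    "mapped_rxn_smiles": self.reaction_set.lines[rid],
                    "ec_numbers": ";".join(self.reaction_set.reaction_ecs[rid]),
                }
                for rid in sorted(self.reaction_set.lines)
            ]
        ).to_csv(out_dir / "reactions.tsv", sep="\t", index=False)
        write_enzymes_fasta(self.pool, out_dir / "enzymes.fasta")
        write_triads_tsv(self.triads, out_dir / "triads.tsv")
        chem.write_pairs_tsv(self.pairs, out_dir / "pairs.tsv")
        (out_dir / "manifest.json").write_text(
            json.dumps(
                {
                    "seed": self.spec.seed,
                    "motifs": self.motifs,
                    "class_of_reaction": self.reaction_set.class_of_reaction,
                    "truth": self.truth,
                    "enzymes_by_reaction": {
                        rid: [e.enzyme_id for e in enzymes]
                        for rid, enzymes in self.enzymes_by_reaction.items()
                    },
                },
                indent=2, sort_keys=True,
            )
        )


def gen_triad_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Run the mining pipeline end to end on generated inputs.

    Each reaction is assigned a random subset of its class's enzymes (a
    reaction in a curated database typically lists a handful of annotated
    enzymes, not the whole family); unlabeled triads are drawn per reaction
    at the configured ratio from EC-mismatched pool members.
    """
    rset = gen_mapped_reactions(spec)
    pool, motifs = gen_enzyme_pool(spec)
    rng = np.random.default_rng(spec.seed + 2)

    by_class: dict[int, list[EnzymeRecord]] = {}
    for e in pool:
        if e.enzyme_id.startswith("enz_c"):
            c = int(e.enzyme_id.split("_")[1][1:])
            by_class.setdefault(c, []).append(e)

    enzymes_by_reaction: dict[str, list[EnzymeRecord]] = {}
    for rxn in rset.reactions:
        c = rset.class_of_reaction[rxn.reaction_id]
        members = by_class[c]
        n = min(spec.enzymes_per_reaction, len(members))
        idx = rng.choice(len(members), size=n, replace=False)
        enzymes_by_reaction[rxn.reaction_id] = [members[i] for i in sorted(idx)]

    pairs: list[SubstrateProductPair] = []
    for rxn in rset.reactions:
        pairs.extend(filter_pairs(extract_pairs(rxn)))

    positives = build_triads(pairs, enzymes_by_reaction)
    # over-length enzymes are excluded from the dataset entirely, so they
    # must not surface as unlabeled draws either
    eligible_pool = [e for e in pool if e.length <= 1000]
    unlabeled = generate_unlabeled_dataset(
        positives, rset.reaction_ecs, eligible_pool, k=spec.neg_ratio,
        seed=spec.seed + 3,
    )
    triads = assign_triad_ids(deduplicate(positives + unlabeled))
    ds = SyntheticDataset(
        spec=spec,
        reaction_set=rset,
        pool=pool,
        motifs=motifs,
        pairs=pairs,
        triads=triads,
        truth={},
        enzymes_by_reaction=enzymes_by_reaction,
    )
    ds.truth = {t.triad_id: ds.truly_catalytic(t) for t in triads}
    return ds
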