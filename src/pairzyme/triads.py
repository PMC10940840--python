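"""Substrate-product-enzyme triads: construction, PU labelling, splits.

Positive triads pair each extracted substrate-product pair with the enzymes
annotated on its source reaction.  Because true negatives are essentially
never catalogued, the negative side is *unlabeled*: for every reaction,
enzymes whose four-level EC number differs from all of the reaction's EC
numbers are sampled (20 per reaction by default) and provisionally treated
as negatives during training — the positive-unlabeled setting.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .chem import SubstrateProductPair

logger = logging.getLogger(__name__)

POSITIVE = "positive"
UNLABELED = "unlabeled"

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class EnzymeRecord:
    enzyme_id: str
    sequence: str
    ec: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"enzyme {self.enzyme_id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Triad:
    pair: SubstrateProductPair
    enzyme: EnzymeRecord
    label: str
    triad_id: Optional[str] = None

    def __post_init__(self):
        if self.label not in (POSITIVE, UNLABELED):
            raise ValueError(f"bad label {self.label!r}")

    def key(self):
        return (self.pair.key(), self.enzyme.sequence, self.label)


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple
    test_ids: tuple
    seed: int

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def build_triads(
    pairs: Sequence[SubstrateProductPair],
    enzymes_by_reaction: Mapping[str, Sequence[EnzymeRecord]],
    max_len: int = 1000,
) -> list[Triad]:
    """One positive triad per (pair, enzyme) combination of each reaction.

    Enzymes longer than ``max_len`` residues (default 1000, strictly greater)
    are skipped; the number skipped is logged.
    """
    out: list[Triad] = []
    n_skipped = 0
    for pair in pairs:
        enzymes = enzymes_by_reaction.get(pair.reaction_id)
        if enzymes is None:
            raise KeyError(f"no enzyme list for reaction {pair.reaction_id}")
        for enz in enzymes:
            if enz.length > max_len:
                n_skipped += 1
                continue
            out.append(Triad(pair=pair, enzyme=enz, label=POSITIVE))
    if n_skipped:
        logger.info("build_triads: skipped %d over-length enzymes", n_skipped)
    return out


def _ec_eligible(enzyme_ec: Optional[str], reaction_ecs: Sequence[str],
                 exclude_three_level: bool) -> bool:
    if not enzyme_ec:
        return False
    if enzyme_ec in reaction_ecs:
        return False
    if exclude_three_level:
        prefix = enzyme_ec.rsplit(".", 1)[0]
        if any(ec.rsplit(".", 1)[0] == prefix for ec in reaction_ecs):
            return False
    return True


def generate_unlabeled(
    reaction_triads: Sequence[Triad],
    reaction_ecs: Sequence[str],
    pool: Sequence[EnzymeRecord],
    k: int = 20,
    seed: int = 0,
    exclude_three_level: bool = False,
) -> list[Triad]:
    """Sample ``k`` EC-mismatched pool enzymes for one reaction's pairs.

    The draw is uniform without replacement over pool enzymes whose EC
    differs from every EC of the reaction; each drawn enzyme is attached to
    every distinct pair among ``reaction_triads`` as an unlabeled triad.
    A pool shortfall degrades to "all eligible" with a warning.
    """
    if not reaction_ecs:
        raise ValueError("reaction has no EC number; cannot generate unlabeled")
    eligible = [
        e for e in pool if _ec_eligible(e.ec, reaction_ecs, exclude_three_level)
    ]
    rng = np.random.default_rng(seed)
    if len(eligible) < k:
        logger.warning(
            "unlabeled shortfall: %d eligible < k=%d", len(eligible), k
        )
        chosen = list(eligible)
    else:
        idx = rng.choice(len(eligible), size=k, replace=False)
        chosen = [eligible[i] for i in sorted(idx)]
    pairs: list[SubstrateProductPair] = []
    seen = set()
    for t in reaction_triads:
        pk = t.pair.key()
        if pk not in seen:
            seen.add(pk)
            pairs.append(t.pair)
    return [
        Triad(pair=p, enzyme=e, label=UNLABELED) for p in pairs for e in chosen
    ]


def generate_unlabeled_dataset(
    positives: Sequence[Triad],
    reaction_ecs: Mapping[str, Sequence[str]],
    pool: Sequence[EnzymeRecord],
    k: int = 20,
    seed: int = 0,
    exclude_three_level: bool = False,
) -> list[Triad]:
    """Apply :func:`generate_unlabeled` reaction by reaction, reproducibly."""
    by_rxn: dict[str, list[Triad]] = {}
    for t in positives:
        by_rxn.setdefault(t.pair.reaction_id, []).append(t)
    out: list[Triad] = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(by_rxn))
    for child, rid in zip(children, sorted(by_rxn)):
        ecs = list(reaction_ecs.get(rid, ()))
        if not ecs:
            logger.warning("reaction %s lacks EC numbers; no unlabeled drawn", rid)
            continue
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out.extend(
            generate_unlabeled(
                by_rxn[rid], ecs, pool, k=k, seed=sub_seed,
                exclude_three_level=exclude_three_level,
            )
        )
    return out


def deduplicate(triads: Sequence[Triad]) -> list[Triad]:
    """One triad per (pair, enzyme sequence, label); positive beats unlabeled.

    First occurrence wins within a label.  If the same (pair, enzyme) occurs
    both as positive and unlabeled, only the positive survives: a verified
    positive cannot double as a presumed negative.
    """
    positives_keys = {
        (t.pair.key(), t.enzyme.sequence) for t in triads if t.label == POSITIVE
    }
    seen = set()
    out = []
    for t in triads:
        pk = (t.pair.key(), t.enzyme.sequence)
        if t.label == UNLABELED and pk in positives_keys:
            continue
        k = t.key()
        if k in seen:
            continue
        seen.add(k)
        out.append(t)
    return out


def assign_triad_ids(triads: Sequence[Triad]) -> list[Triad]:
    return [
        t if t.triad_id is not None else replace(t, triad_id=f"t{i:06d}")
        for i, t in enumerate(triads)
    ]


def split_test(
    triads: Sequence[Triad],
    n_pos: int = 5000,
    n_neg: int = 5000,
    seed: int = 0,
) -> tuple[DatasetSplit, list[Triad]]:
    """Hold out ``n_pos`` positives + ``n_neg`` unlabeled, uniformly at random.

    Returns the split and the id-annotated triad list (ids are assigned here
    when absent).  The remainder forms the training set.
    """
    triads = assign_triad_ids(triads)
    pos = [t for t in triads if t.label == POSITIVE]
    neg = [t for t in triads if t.label == UNLABELED]
    if len(pos) < n_pos:
        raise ValueError(f"need {n_pos} positives, have {len(pos)}")
    if len(neg) < n_neg:
        raise ValueError(f"need {n_neg} unlabeled, have {len(neg)}")
    rng = np.random.default_rng(seed)
    test_pos = rng.choice(len(pos), size=n_pos, replace=False)
    test_neg = rng.choice(len(neg), size=n_neg, replace=False)
    test_ids = {pos[i].triad_id for i in test_pos} | {
        neg[i].triad_id for i in test_neg
    }
    train_ids = tuple(t.triad_id for t in triads if t.triad_id not in test_ids)
    test_ids = tuple(t.triad_id for t in triads if t.triad_id in test_ids)
    return DatasetSplit(train_ids=train_ids, test_ids=test_ids, seed=seed), triads


def subset(triads: Sequence[Triad], ids: Iterable[str]) -> list[Triad]:
    wanted = set(ids)
    return [t for t in triads if t.triad_id in wanted]


# ---------------------------------------------------------------------------
# sequence identity


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    al.mode = "global"
    return al


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment percent identity (BLOSUM62, gap open 10 / extend 0.5).

    Identity = matches / alignment length x 100, alignment length counting
    gapped columns.
    """
    for s in (a, b):
        if not s:
            raise ValueError("empty sequence")
        bad = set(s) - AA_ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    aln_len = aln.length
    return 100.0 * counts.identities / aln_len


@dataclass(frozen=True)
class IdentitySummary:
    mean_identity: float
    frac_below_30: float
    n_used: int
    subsampled: bool


def dataset_identity_summary(
    sequences: Sequence[str],
    sample_cap: Optional[int] = None,
    seed: int = 0,
) -> IdentitySummary:
    """All-vs-all average sequence identity of a set (optionally subsampled).

    Reports the mean over sequences of each sequence's average identity to
    the others, and the fraction of sequences whose average is below 30%.
    """
    seqs = list(sequences)
    subsampled = False
    if sample_cap is not None and len(seqs) > sample_cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(seqs), size=sample_cap, replace=False)
        seqs = [seqs[i] for i in sorted(idx)]
        subsampled = True
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two sequences")
    ident = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(seqs[i], seqs[j])
    avg = ident.sum(axis=1) / (n - 1)
    return IdentitySummary(
        mean_identity=float(avg.mean()),
        frac_below_30=float((avg < 30.0).mean()),
        n_used=n,
        subsampled=subsampled,
    )


# ---------------------------------------------------------------------------
# I/O

_EC_RE = re.compile(r"EC=([0-9]+\.[0-9]+\.[0-9]+\.[0-9n]+)")


def read_enzymes_fasta(path) -> list[EnzymeRecord]:
    """Read enzymes from FASTA; EC parsed from a header token ``EC=a.b.c.d``."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _EC_RE.search(rec.description)
        out.append(
            EnzymeRecord(
                enzyme_id=rec.id,
                sequence=str(rec.seq).upper(),
                ec=m.group(1) if m else None,
            )
        )
    return out


def write_enzymes_fasta(enzymes: Sequence[EnzymeRecord], path) -> None:
    with open(path, "w") as fh:
        for e in enzymes:
            ec = f" EC={e.ec}" if e.ec else ""
            fh.write(f">{e.enzyme_id}{ec}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i : i + 60] + "\n")


def write_triads_tsv(triads: Sequence[Triad], path) -> None:
    triads = assign_triad_ids(triads)
    pd.DataFrame(
        [
            {
                "triad_id": t.triad_id,
                "reaction_id": t.pair.reaction_id,
                "substrate_smiles": t.pair.substrate_smiles,
                "product_smiles": t.pair.product_smiles,
                "enzyme_id": t.enzyme.enzyme_id,
                "label": t.label,
            }
            for t in triads
        ]
    ).to_csv(path, sep="\t", index=False)


def read_triads_tsv(path, enzymes: Mapping[str, EnzymeRecord]) -> list[Triad]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples():
        pair = SubstrateProductPair(
            substrate_smiles=row.substrate_smiles,
            product_smiles=row.product_smiles,
            provenance_fraction=float("nan"),
            reaction_id=str(row.reaction_id),
        )
        out.append(
            Triad(
                pair=pair,
                enzyme=enzymes[row.enzyme_id],
                label=row.label,
                triad_id=row.triad_id,
            )
        )
    return out


def write_split_manifest(split: DatasetSplit, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "train_ids.txt").write_text("\n".join(split.train_ids) + "\n")
    (out_dir / "test_ids.txt").write_text("\n".join(split.test_ids) + "\n")
    (out_dir / "split.json").write_text(
        json.dumps(
            {
                "seed": split.seed,
                "n_train": len(split.train_ids),
                "n_test": len(split.test_ids),
            },
            indent=2,
        )
    )


def read_split_manifest(out_dir) -> DatasetSplit:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "split.json").read_text())
    return DatasetSplit(
        train_ids=tuple((out_dir / "train_ids.txt").read_text().split()),
        test_ids=tuple((out_dir / "test_ids.txt").read_text().split()),
        seed=meta["seed"],
    )
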