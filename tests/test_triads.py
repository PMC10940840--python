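"""Triad building, EC-mismatch unlabeled generation, dedup, splits, identity."""

import numpy as np
import pytest

from pairzyme.chem import SubstrateProductPair
from pairzyme.triads import (
    POSITIVE,
    UNLABELED,
    DatasetSplit,
    EnzymeRecord,
    Triad,
    build_triads,
    dataset_identity_summary,
    deduplicate,
    generate_unlabeled,
    generate_unlabeled_dataset,
    pairwise_identity,
    read_enzymes_fasta,
    read_triads_tsv,
    split_test,
    subset,
    write_enzymes_fasta,
    write_triads_tsv,
)


def _pair(rid="r1", sub="CCO", prod="CC=O"):
    return SubstrateProductPair(sub, prod, 1.0, rid)


def _enzyme(i, length=50, ec="1.1.1.1"):
    rng = np.random.default_rng(i)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    return EnzymeRecord(f"e{i}", seq, ec=ec)


class TestBuildTriads:
    def test_cartesian_product(self):
        pairs = [_pair(), _pair(prod="CCC=O")]
        enzymes = {"r1": [_enzyme(i) for i in range(3)]}
        triads = build_triads(pairs, enzymes)
        assert len(triads) == 6
        assert all(t.label == POSITIVE for t in triads)

    def test_length_cap_boundary(self):
        enzymes = {"r1": [_enzyme(1, length=1000), _enzyme(2, length=1001)]}
        triads = build_triads([_pair()], enzymes)
        assert [t.enzyme.enzyme_id for t in triads] == ["e1"]

    def test_reaction_without_enzymes(self):
        assert build_triads([_pair()], {"r1": []}) == []


class TestGenerateUnlabeled:
    def _pool(self):
        # 100 enzymes spread over 10 four-level ECs, 10 each
        return [
            _enzyme(i, ec=f"1.1.1.{i % 10 + 1}") for i in range(100)
        ]

    def test_draws_exactly_k_ec_mismatched(self):
        pool = self._pool()
        positives = [Triad(_pair(), pool[0], POSITIVE)]
        unl = generate_unlabeled(positives, ["1.1.1.1"], pool, k=20, seed=4)
        assert len(unl) == 20
        assert all(t.label == UNLABELED for t in unl)
        assert all(t.enzyme.ec != "1.1.1.1" for t in unl)

    def test_no_eligible_gives_empty_with_warning(self, caplog):
        pool = [_enzyme(i, ec="1.1.1.1") for i in range(5)]
        positives = [Triad(_pair(), pool[0], POSITIVE)]
        unl = generate_unlabeled(positives, ["1.1.1.1"], pool, k=20, seed=0)
        assert unl == []
        assert "shortfall" in caplog.text

    def test_seed_reproducibility(self):
        pool = self._pool()
        positives = [Triad(_pair(), pool[0], POSITIVE)]
        ids = lambda s: [t.enzyme.enzyme_id for t in
                         generate_unlabeled(positives, ["1.1.1.1"], pool,
                                            k=20, seed=s)]
        assert ids(7) == ids(7)
        assert ids(7) != ids(8)

    def test_three_level_exclusion_flag(self):
        pool = [_enzyme(1, ec="1.1.1.2"), _enzyme(2, ec="2.2.2.2")]
        positives = [Triad(_pair(), pool[0], POSITIVE)]
        loose = generate_unlabeled(positives, ["1.1.1.1"], pool, k=2, seed=0)
        strict = generate_unlabeled(
            positives, ["1.1.1.1"], pool, k=2, seed=0, exclude_three_level=True
        )
        assert {t.enzyme.ec for t in loose} == {"1.1.1.2", "2.2.2.2"}
        assert {t.enzyme.ec for t in strict} == {"2.2.2.2"}

    def test_attached_to_every_pair_of_reaction(self):
        pool = self._pool()
        p1, p2 = _pair(), _pair(prod="CCC=O")
        positives = [
            Triad(p1, pool[0], POSITIVE), Triad(p2, pool[0], POSITIVE)
        ]
        unl = generate_unlabeled(positives, ["1.1.1.1"], pool, k=5, seed=0)
        assert len(unl) == 10  # 5 enzymes x 2 pairs

    def test_dataset_level_ratio(self):
        """With one positive enzyme per reaction and an ample pool, the
        unlabeled:positive ratio equals the per-reaction draw count."""
        pool = self._pool()
        positives = [
            Triad(_pair(rid=f"r{j}", prod=f"C{'C' * j}=O"), pool[j], POSITIVE)
            for j in range(5)
        ]
        ecs = {f"r{j}": ["1.1.1.1"] for j in range(5)}
        unl = generate_unlabeled_dataset(positives, ecs, pool, k=20, seed=0)
        assert len(unl) == 20 * len(positives)


class TestDeduplicate:
    def test_exact_duplicate_collapses(self):
        t = Triad(_pair(), _enzyme(1), POSITIVE)
        assert len(deduplicate([t, t])) == 1

    def test_positive_beats_unlabeled(self):
        e = _enzyme(1)
        pos = Triad(_pair(), e, POSITIVE)
        unl = Triad(_pair(), e, UNLABELED)
        for order in ([pos, unl], [unl, pos]):
            survivors = deduplicate(order)
            assert len(survivors) == 1
            assert survivors[0].label == POSITIVE

    def test_disjoint_unchanged_and_idempotent(self):
        triads = [
            Triad(_pair(), _enzyme(1), POSITIVE),
            Triad(_pair(prod="CCC=O"), _enzyme(2), UNLABELED),
        ]
        once = deduplicate(triads)
        assert once == triads
        assert deduplicate(once) == once


class TestSplit:
    def _triads(self, n_pos=60, n_neg=600):
        return (
            [Triad(_pair(), _enzyme(i), POSITIVE) for i in range(n_pos)]
            + [Triad(_pair(), _enzyme(1000 + i), UNLABELED)
               for i in range(n_neg)]
        )

    def test_counts_and_partition(self):
        split, triads = split_test(self._triads(), n_pos=10, n_neg=10, seed=0)
        assert len(split.test_ids) == 20
        assert len(split.train_ids) == 640
        assert set(split.train_ids).isdisjoint(split.test_ids)
        assert len(split.train_ids) + len(split.test_ids) == len(triads)
        test = subset(triads, split.test_ids)
        assert sum(t.label == POSITIVE for t in test) == 10

    def test_insufficient_positives_raises(self):
        with pytest.raises(ValueError, match="positives"):
            split_test(self._triads(n_pos=5), n_pos=10, n_neg=10, seed=0)

    def test_seed_reproducibility(self):
        s1, _ = split_test(self._triads(), n_pos=10, n_neg=10, seed=3)
        s2, _ = split_test(self._triads(), n_pos=10, n_neg=10, seed=3)
        assert s1 == s2

    def test_overlapping_split_rejected(self):
        with pytest.raises(ValueError):
            DatasetSplit(train_ids=("a", "b"), test_ids=("b",), seed=0)


def needleman_wunsch_identity(a, b, blosum, gap_open=-10.0, gap_extend=-0.5):
    """Independent affine-gap global DP (Gotoh) returning percent identity."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (deletion)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (insertion)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    # traceback for identity count
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    matches = 0
    length = 0
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            s = blosum[a[i - 1], b[j - 1]]
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            matches += a[i - 1] == b[j - 1]
            length += 1
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 and i > 0:
            length += 1
            prev_m = M[i - 1, j] + gap_open
            prev_x = X[i - 1, j] + gap_extend
            i -= 1
            state = 0 if prev_m >= prev_x else 1
        else:
            length += 1
            prev_m = M[i, j - 1] + gap_open
            prev_y = Y[i, j - 1] + gap_extend
            j -= 1
            state = 0 if prev_m >= prev_y else 2
    return 100.0 * matches / length


class TestIdentity:
    def test_identical_is_100(self):
        assert pairwise_identity("ACDEFGHIK", "ACDEFGHIK") == 100.0

    def test_fully_mismatched_is_0(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_symmetry(self):
        a, b = "ACDEFGHIKLMNP", "ACDEYGHIKLMNQ"
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_rejects_non_amino_acids(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            pairwise_identity("ACDB!", "ACDEF")

    @pytest.mark.parametrize(
        "a,b",
        [
            ("ACDEFG", "ACDEYG"),
            ("MKTAYI", "MKTAYI"),
            ("ACDEFGHIKL", "ACDEGHIKL"),  # forces a gap
            ("WWWWCC", "CCWWWW"),
        ],
    )
    def test_matches_dp_oracle_on_short_sequences(self, a, b):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        expected = needleman_wunsch_identity(a, b, blosum)
        assert pairwise_identity(a, b) == pytest.approx(expected, abs=1e-9)


class TestIdentitySummary:
    def test_identical_sequences(self):
        s = dataset_identity_summary(["MKTAYIAK"] * 3)
        assert s.mean_identity == pytest.approx(100.0)
        assert s.frac_below_30 == 0.0

    def test_random_sequences_are_dissimilar(self):
        rng = np.random.default_rng(0)
        seqs = [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
            for _ in range(3)
        ]
        s = dataset_identity_summary(seqs)
        assert s.mean_identity < 30.0
        assert s.frac_below_30 == 1.0

    def test_cap_flags_subsampling(self):
        s = dataset_identity_summary(["MKTAYIAK"] * 5, sample_cap=3, seed=0)
        assert s.subsampled and s.n_used == 3


class TestIO:
    def test_fasta_round_trip_with_ec(self, tmp_path):
        enzymes = [_enzyme(1, ec="1.2.3.4"), _enzyme(2, ec=None)]
        path = tmp_path / "enzymes.fasta"
        write_enzymes_fasta(enzymes, path)
        back = read_enzymes_fasta(path)
        assert [e.enzyme_id for e in back] == ["e1", "e2"]
        assert back[0].ec == "1.2.3.4" and back[1].ec is None
        assert back[0].sequence == enzymes[0].sequence

    def test_triads_tsv_round_trip(self, tmp_path):
        enzymes = [_enzyme(1), _enzyme(2)]
        triads = [
            Triad(_pair(), enzymes[0], POSITIVE),
            Triad(_pair(prod="CCC=O"), enzymes[1], UNLABELED),
        ]
        path = tmp_path / "triads.tsv"
        write_triads_tsv(triads, path)
        back = read_triads_tsv(path, {e.enzyme_id: e for e in enzymes})
        assert len(back) == 2
        assert back[0].label == POSITIVE
        assert back[1].enzyme.enzyme_id == "e2"
        assert back[0].pair.product_smiles == "CC=O"
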