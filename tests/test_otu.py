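"""Dereplication, greedy clustering semantics, and rarefaction."""

from __future__ import annotations

import math

import numpy as np
import pytest

from abyssotu.hpalign import hp_distance
from abyssotu.otu import (
    UniqueTag,
    dereplicate,
    drop_single_singletons,
    greedy_cluster,
    otu_table,
    saturation_curve,
)
from abyssotu.seqio import Read


def _reads(seqs: list[str], sample: str = "S1") -> list[Read]:
    return [Read(id=f"r{i}", sequence=s, sample=sample) for i, s in enumerate(seqs)]


def _tag(seq: str, abundance: int) -> UniqueTag:
    return UniqueTag(seq, abundance, {"S1": abundance}, rep_id=seq)


class TestDereplicate:
    def test_counting(self):
        tags = dereplicate(_reads(["ACGT", "ACGT", "AAAA"]))
        assert [(t.sequence, t.abundance) for t in tags] == [("ACGT", 2), ("AAAA", 1)]
        assert tags[0].rep_id == "r0"

    def test_single_read(self):
        tags = dereplicate(_reads(["ACGT"]))
        assert len(tags) == 1 and tags[0].abundance == 1

    def test_sorted_by_abundance_then_sequence(self):
        # 10 reads over 4 strings with counts 4, 3, 2, 1
        seqs = ["TTTT"] * 4 + ["AAAA"] * 3 + ["GGGG"] * 2 + ["CCCC"]
        tags = dereplicate(_reads(seqs))
        assert [(t.sequence, t.abundance) for t in tags] == [
            ("TTTT", 4), ("AAAA", 3), ("GGGG", 2), ("CCCC", 1),
        ]
        # lexicographic tie-break
        tags = dereplicate(_reads(["GG", "AA", "CC"]))
        assert [t.sequence for t in tags] == ["AA", "CC", "GG"]

    def test_read_conservation_and_per_sample(self):
        reads = _reads(["ACGT"] * 3, "S1") + [
            Read(id="x1", sequence="ACGT", sample="S2"),
            Read(id="x2", sequence="TTTT", sample="S2"),
        ]
        tags = dereplicate(reads)
        assert sum(t.abundance for t in tags) == len(reads)
        assert tags[0].per_sample == {"S1": 3, "S2": 1}


class TestGreedyCluster:
    def test_worked_example_at_k0(self):
        """The two run-length variants group at 0 differences."""
        tags = [_tag("ATGTGGGGTAT", 5), _tag("ATGTGGGTAT", 2)]
        otus = greedy_cluster(tags, k=0)
        assert len(otus) == 1
        assert otus[0].reads == 7
        assert otus[0].seed.sequence == "ATGTGGGGTAT"

    def test_single_tag(self):
        otus = greedy_cluster([_tag("ACGT", 9)], k=3)
        assert len(otus) == 1
        assert [m.sequence for m in otus[0].members] == ["ACGT"]
        assert otus[0].seed.sequence == "ACGT" and otus[0].reads == 9

    def test_members_join_first_seed_only(self):
        """A tag near an earlier member but far from the seed still becomes
        its own seed: members are never used as cluster centres.

        d(A,B)=1, d(B,C)=0 (run extension), but d(A,C)=2 because the two
        insertions extend a run A does not share.
        """
        a, b, c = "TCT", "TCAT", "TCAAT"
        assert hp_distance(a, b).distance == 1
        assert hp_distance(b, c).distance == 0
        assert hp_distance(a, c).distance == 2
        tags = [_tag(a, 5), _tag(b, 3), _tag(c, 2)]
        otus = greedy_cluster(tags, k=1)
        assert [[m.sequence for m in o.members] for o in otus] == [[a, b], [c]]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            greedy_cluster([_tag("AAAA", 1), _tag("TTTT", 5)], k=1)

    def test_partition_and_seed_separation(self):
        rng = np.random.default_rng(5)
        seqs = {
            "".join(rng.choice(list("ACGT"), 20)): int(a)
            for a in rng.integers(1, 30, size=40)
        }
        tags = sorted(
            (_tag(s, a) for s, a in seqs.items()),
            key=lambda t: (-t.abundance, t.sequence),
        )
        k = 3
        otus = greedy_cluster(tags, k)
        members = [m.sequence for o in otus for m in o.members]
        assert sorted(members) == sorted(seqs)  # exactly one OTU per tag
        seeds = [o.seed.sequence for o in otus]
        for i, s1 in enumerate(seeds):
            for s2 in seeds[i + 1:]:
                assert hp_distance(s1, s2).distance > k
        assert sum(o.reads for o in otus) == sum(seqs.values())

    def test_otu_count_non_increasing_in_k(self, small_corpus):
        params, bundle, reads, truth = small_corpus
        from abyssotu.seqio import screen_primers

        sample = params.samples[0][0]
        kept, _ = screen_primers(reads[sample][:400], params.primers)
        tags = dereplicate(kept)
        counts = [len(greedy_cluster(tags, k)) for k in range(0, 9)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic(self):
        tags = [_tag("ATGTGGGGTAT", 5), _tag("ATGTGGGTAT", 5), _tag("CCCC", 1)]
        r1 = greedy_cluster(tags, 0)
        r2 = greedy_cluster(tags, 0)
        assert otu_table(r1).equals(otu_table(r2))


class TestSingleSingletons:
    @pytest.mark.parametrize(
        ("members", "dropped"),
        [
            ([("AAAA", 1)], True),
            ([("AAAA", 2)], False),
            ([("AAAA", 1), ("AAAT", 1)], False),
        ],
    )
    def test_definition(self, members, dropped):
        tags = [_tag(s, a) for s, a in members]
        otu = greedy_cluster(tags, 3)[0] if len(members) == 1 else None
        if otu is None:
            otus = greedy_cluster(tags, 3)
            assert len(otus) == 1
            otu = otus[0]
        kept, gone = drop_single_singletons([otu])
        assert (len(gone) == 1) == dropped
        assert len(kept) + len(gone) == 1


class TestSaturationCurve:
    def test_endpoints(self):
        labels = [f"O{i % 5}" for i in range(50)]
        df = saturation_curve(labels, n_points=10, n_perm=20, seed=1)
        assert df.iloc[0]["reads"] == 1 and df.iloc[0]["mean_otus"] == 1.0
        assert df.iloc[-1]["reads"] == 50 and df.iloc[-1]["mean_otus"] == 5.0
        assert (df["mean_otus"].diff().dropna() >= 0).all()

    def test_hypergeometric_expectation(self):
        """100 reads over 10 equal OTUs, subsample 50: mean distinct OTUs
        matches the closed-form hypergeometric expectation."""
        labels = [f"O{i % 10}" for i in range(100)]
        df = saturation_curve(labels, n_points=3, n_perm=1000, seed=7)
        row = df[df["reads"] == 50].iloc[0]
        p_absent = math.comb(90, 50) / math.comb(100, 50)
        expect = 10 * (1 - p_absent)
        sem = row["sd"] / math.sqrt(1000)
        assert abs(row["mean_otus"] - expect) < max(3 * sem, 0.05)

    def test_clipping_warns(self):
        with pytest.warns(UserWarning, match="clipping"):
            saturation_curve(["A", "B"], n_points=10, n_perm=2, seed=1)
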