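"""Hit similarity, consensus assignment, triage, rollup and the
resolution-profile experiment, including a cross-check of the internal
search engine against command-line BLAST XML output."""

from __future__ import annotations

import itertools
import subprocess

import numpy as np
import pytest

from abyssotu.seqio import PrimerPair
from abyssotu.taxonomy import (
    HSP,
    AssignParams,
    GroupingTable,
    Hit,
    ReferenceDB,
    ReferenceRecord,
    assign_consensus,
    classify_domain,
    extract_v9,
    hit_similarity,
    load_reference,
    parse_blast_xml,
    parse_lineage,
    resolution_profile,
    rollup_major_group,
    search,
    triage_domain,
)


def _ref(rid: str, lineage: str, seq: str = "ACGT" * 10) -> ReferenceRecord:
    return ReferenceRecord(id=rid, sequence=seq, lineage=parse_lineage(lineage))


def _hit(rid: str, lineage: str, sim: float) -> Hit:
    return Hit(
        reference=_ref(rid, lineage),
        hsps=(HSP(0, 100, int(sim * 100), 0, sim * 100),),
        similarity=sim,
    )


class TestLoadReference:
    def test_load(self, tmp_path):
        (tmp_path / "r.fa").write_text(">a\nACGT\n>b\nGGGG\n>c\nTTTT\n")
        (tmp_path / "r.tsv").write_text(
            "a\tEukaryota;Alveolata;Ciliophora\n"
            "b\tEukaryota;Rhizaria;Cercozoa;Cl;Or;Fa;GenB\n"
            "c\tBacteria;K;P\n"
        )
        db = load_reference(tmp_path / "r.fa", tmp_path / "r.tsv")
        assert len(db) == 3
        assert db.by_id["b"].name_at("genus") == "GenB"
        assert len(db.by_id["b"].lineage) == 7

    def test_missing_lineage_listed(self, tmp_path):
        (tmp_path / "r.fa").write_text(">a\nACGT\n>orphan\nGGGG\n")
        (tmp_path / "r.tsv").write_text("a\tEukaryota;K;P\n")
        with pytest.raises(ValueError, match="orphan"):
            load_reference(tmp_path / "r.fa", tmp_path / "r.tsv")


class TestExtractV9:
    PRIMERS = PrimerPair(proximal="TTGTACAC", distal="GTAGGTGA")

    def test_between_primer_region(self):
        rec = _ref("a", "Eukaryota;K", seq="CCCC" + "TTGTACAC" + "ACGTACGT" + "GTAGGTGA" + "GGGG")
        out = extract_v9([rec], self.PRIMERS)
        assert out[0].sequence == "ACGTACGT"
        assert out[0].lineage == rec.lineage

    def test_missing_site_skipped_with_count_contract(self):
        with_sites = [
            _ref(f"y{i}", "Eukaryota;K", seq="TTGTACAC" + "AAAA" + "GTAGGTGA")
            for i in range(7)
        ]
        without = [_ref(f"n{i}", "Eukaryota;K", seq="ACGTACGTACGT") for i in range(3)]
        out = extract_v9(with_sites + without, self.PRIMERS)
        assert len(out) == 7


class TestHitSimilarity:
    def test_printed_formula(self):
        assert hit_similarity([HSP(0, 100, 95, 2, 500)], 100) == pytest.approx(0.93)

    def test_two_non_overlapping(self):
        hsps = [HSP(0, 50, 49, 1, 60), HSP(50, 100, 30, 0, 40)]
        assert hit_similarity(hsps, 100) == pytest.approx(0.78)

    def test_overlap_resolved_by_score(self):
        hsps = [HSP(0, 60, 40, 0, 40.0), HSP(0, 60, 50, 0, 50.0)]
        assert hit_similarity(hsps, 100) == pytest.approx(0.50)

    def test_floor_at_zero(self):
        assert hit_similarity([HSP(0, 10, 1, 8, 5)], 100) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_set_is_valid_and_matches_bruteforce_on_disjoint_chains(self, seed):
        """When HSPs are either disjoint or exact duplicates of an interval,
        the greedy selection provably equals the max-score non-overlapping
        subset; verify against brute-force enumeration."""
        rng = np.random.default_rng(seed)
        hsps = []
        for block in range(4):
            for _ in range(rng.integers(1, 3)):
                ident = int(rng.integers(5, 20))
                # unique scores so the max-score subset is unambiguous
                score = float(ident) + float(rng.random()) * 0.1
                hsps.append(
                    HSP(block * 25, block * 25 + 20, ident,
                        int(rng.integers(0, 3)), score)
                )
        best_score, best_sim = -1.0, 0.0
        for r in range(1, len(hsps) + 1):
            for combo in itertools.combinations(hsps, r):
                ok = all(
                    h1.query_end <= h2.query_start or h2.query_end <= h1.query_start
                    for h1, h2 in itertools.combinations(combo, 2)
                )
                score = sum(h.score for h in combo)
                if ok and score > best_score:
                    best_score = score
                    best_sim = max(
                        sum(h.identities - h.gaps for h in combo), 0
                    ) / 100
        assert hit_similarity(hsps, 100) == pytest.approx(best_sim)

    def test_monotonicity(self):
        base = hit_similarity([HSP(0, 100, 80, 5, 100)], 100)
        assert hit_similarity([HSP(0, 100, 85, 5, 100)], 100) > base
        assert hit_similarity([HSP(0, 100, 80, 8, 100)], 100) < base


class TestAssignConsensus:
    def test_majority_genus(self):
        hits = [_hit(f"h{i}", "Eukaryota;K;P;C;O;F;GenX", 0.9) for i in range(8)]
        hits += [_hit("h8", "Eukaryota;K;P;C;O;F;GenY", 0.9),
                 _hit("h9", "Eukaryota;K;P;C;O;F;GenZ", 0.9)]
        a = assign_consensus(hits)
        assert (a.status, a.label, a.rank) == ("assigned", "GenX", "genus")

    def test_walk_up_to_family(self):
        hits = [_hit(f"x{i}", "Eukaryota;K;P;C;O;FamF;GenX", 0.9) for i in range(6)]
        hits += [_hit(f"y{i}", "Eukaryota;K;P;C;O;FamF;GenY", 0.9) for i in range(4)]
        a = assign_consensus(hits)
        assert (a.status, a.label, a.rank) == ("assigned", "FamF", "family")

    def test_unassigned_below_threshold(self):
        a = assign_consensus([_hit("h", "Eukaryota;K;P;C;O;F;G", 0.79)])
        assert a.status == "unassigned"
        assert a.best_similarity == pytest.approx(0.79)

    def test_empty_hits(self):
        a = assign_consensus([])
        assert a.status == "unassigned" and a.best_similarity == 0.0

    def test_undetermined_when_no_rank_agrees(self):
        hits = [
            _hit("a", "Eukaryota;K1;P1;C1;O1;F1;G1", 0.9),
            _hit("b", "Bacteria;K2;P2;C2;O2;F2;G2", 0.9),
        ]
        a = assign_consensus(hits)
        assert a.status == "undetermined"

    def test_ragged_lineage_excluded_from_denominator(self):
        # two hits named at genus agree; a third lacks a genus entirely
        hits = [
            _hit("a", "Eukaryota;K;P;C;O;F;G1", 0.9),
            _hit("b", "Eukaryota;K;P;C;O;F;G1", 0.9),
            _hit("c", "Eukaryota;K;P", 0.9),
        ]
        a = assign_consensus(hits)
        assert (a.label, a.rank) == ("G1", "genus")

    @pytest.mark.parametrize("seed", range(10))
    def test_never_deeper_than_bruteforce_consensus(self, seed):
        rng = np.random.default_rng(seed)
        hits = [
            _hit(
                f"h{i}",
                ";".join(
                    ["Eukaryota", f"K{rng.integers(2)}", f"P{rng.integers(2)}",
                     f"C{rng.integers(2)}", f"O{rng.integers(2)}",
                     f"F{rng.integers(3)}", f"G{rng.integers(4)}"]
                ),
                0.9,
            )
            for i in range(10)
        ]
        params = AssignParams()
        a = assign_consensus(hits, params)
        # brute force: walk genus->domain, find first rank with consensus
        from collections import Counter

        from abyssotu.taxonomy import RANKS

        expected = ("undetermined", "", "")
        for rank in list(RANKS[:7])[::-1]:
            names = [h.reference.name_at(rank) for h in hits]
            names = [n for n in names if n is not None]
            top = Counter(names).most_common(1)
            if top and top[0][1] / len(names) >= params.consensus_fraction:
                expected = ("assigned", top[0][0], rank)
                break
        assert (a.status, a.label, a.rank) == expected

    def test_threshold_ladder_monotonicity(self):
        hits = [_hit(f"h{i}", "Eukaryota;K;P;C;O;F;G", s)
                for i, s in enumerate([0.95, 0.91, 0.86, 0.81, 0.76, 0.71])]
        was_assigned = True
        for thr in AssignParams().threshold_ladder:
            a = assign_consensus(hits, AssignParams(assignment_threshold=thr))
            if a.status == "unassigned":
                was_assigned = False
            else:
                # once unassigned at some threshold, never assigned above it
                assert was_assigned


class TestSearch:
    @pytest.fixture()
    def toy_db(self):
        rng = np.random.default_rng(3)
        recs = [
            ReferenceRecord(
                id=f"ref{i}",
                sequence="".join(rng.choice(list("ACGT"), 50)),
                lineage=parse_lineage(f"Eukaryota;K;P;C;O;F;Gen{i}"),
            )
            for i in range(6)
        ]
        return ReferenceDB(recs)

    def test_identical_query_tops(self, toy_db):
        ref = toy_db.records[2]
        hits = search(ref.sequence, toy_db)
        assert hits[0].reference.id == ref.id
        assert hits[0].similarity == pytest.approx(1.0)

    def test_no_word_match_empty(self, toy_db):
        assert search("A" * 30, toy_db) == []

    def test_single_substitution_similarity(self, toy_db):
        ref = toy_db.records[0]
        seq = list(ref.sequence)
        seq[25] = {"A": "C"}.get(seq[25], "A")
        hits = search("".join(seq), toy_db)
        assert hits[0].reference.id == ref.id
        assert hits[0].similarity == pytest.approx((50 - 1) / 50)

    def test_empty_db_raises(self):
        with pytest.raises(ValueError, match="empty"):
            search("ACGTACGTACGT", ReferenceDB([]))


class TestBlastXml:
    def test_external_blast_agrees_with_internal_engine(self, tmp_path):
        """makeblastdb + blastn XML parsed into Hits must agree with the
        internal seeded aligner on the top reference and its similarity."""
        rng = np.random.default_rng(17)
        refs = [
            ReferenceRecord(
                id=f"ref{i}",
                sequence="".join(rng.choice(list("ACGT"), 120)),
                lineage=parse_lineage(f"Eukaryota;K;P;C;O;F;Gen{i}"),
            )
            for i in range(5)
        ]
        db = ReferenceDB(refs)
        query = refs[1].sequence
        ref_fa = tmp_path / "refs.fa"
        ref_fa.write_text("".join(f">{r.id}\n{r.sequence}\n" for r in refs))
        q_fa = tmp_path / "q.fa"
        q_fa.write_text(f">q1\n{query}\n")
        subprocess.run(
            ["makeblastdb", "-in", str(ref_fa), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        xml = tmp_path / "out.xml"
        subprocess.run(
            ["blastn", "-query", str(q_fa), "-db", str(ref_fa),
             "-word_size", "7", "-reward", "5", "-penalty", "-4",
             "-gapopen", "8", "-gapextend", "6", "-outfmt", "5",
             "-out", str(xml)],
            check=True, capture_output=True,
        )
        parsed = parse_blast_xml(xml, db)
        ext_hits = parsed["q1"]
        int_hits = search(query, db)
        assert ext_hits[0].reference.id == int_hits[0].reference.id == "ref1"
        assert ext_hits[0].similarity == pytest.approx(1.0)
        assert int_hits[0].similarity == pytest.approx(1.0)


class TestTriage:
    def test_domain_classes(self):
        arch = [_hit("a", "Archaea;K;P", 0.9)]
        bact = [_hit("b", "Bacteria;K;P", 0.85)]
        assert classify_domain(arch) == "archaeal"
        assert classify_domain(bact) == "bacterial"
        assert classify_domain([]) == "non_rRNA"

    def test_subthreshold_uses_best_hit_domain(self):
        hits = [_hit("a", "Eukaryota;K;P", 0.6)]
        assert classify_domain(hits) == "eukaryotic"

    def test_counts_partition_reads(self):
        tag_hits = [
            (10, [_hit("a", "Archaea;K", 0.9)]),
            (5, [_hit("b", "Eukaryota;K", 0.9)]),
            (2, []),
        ]
        counts = triage_domain(tag_hits)
        assert counts == {"eukaryotic": 5, "archaeal": 10, "bacterial": 0,
                          "non_rRNA": 2}
        assert sum(counts.values()) == 17


class TestRollup:
    @pytest.fixture()
    def grouping(self):
        from pathlib import Path

        import abyssotu

        return GroupingTable.load(
            Path(abyssotu.__file__).parent / "data" / "major_groups.tsv"
        )

    def test_deepest_rule_wins(self, grouping):
        hits = [_hit("a", "Eukaryota;Alveolata;Ciliophora;C;O;F;GenC", 0.95)] * 4
        a = assign_consensus(hits)
        assert rollup_major_group(a, grouping) == "Ciliophora"

    def test_haptophyta_goes_to_ccth(self, grouping):
        hits = [_hit("a", "Eukaryota;Hacrobia;Haptophyta;C;O;F;GenH", 0.95)] * 4
        a = assign_consensus(hits)
        assert rollup_major_group(a, grouping) == "CCTH"

    def test_unmatched_lineage_is_undetermined(self, grouping):
        hits = [_hit("a", "Eukaryota;Mystery;Unplaced;C;O;F;GenM", 0.95)] * 4
        a = assign_consensus(hits)
        assert rollup_major_group(a, grouping) == "Undetermined"

    def test_unassigned_stays_separate(self, grouping):
        a = assign_consensus([_hit("a", "Eukaryota;K;P", 0.5)])
        assert rollup_major_group(a, grouping) == "Unassigned"

    def test_overlapping_rules_rejected(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("Ciliophora\tCiliophora\nCiliophora\tother Alveolata\n")
        with pytest.raises(ValueError, match="overlapping"):
            GroupingTable.load(p)


class TestResolutionProfile:
    def test_singleton_clusters_give_full_genus_consensus(self):
        rng = np.random.default_rng(9)
        recs = [
            ReferenceRecord(
                id=f"r{i}",
                sequence="".join(rng.choice(list("ACGT"), 80)),
                lineage=parse_lineage(f"Eukaryota;K;P;C;O;F;Gen{i}"),
            )
            for i in range(8)
        ]
        df = resolution_profile(ReferenceDB(recs), [0.85])
        assert df.iloc[0]["consensus_genus_or_deeper"] == pytest.approx(1.0)

    def test_identical_sequences_from_different_phyla(self):
        seq = "ACGTTGCA" * 10
        recs = [
            ReferenceRecord(id="a", sequence=seq,
                            lineage=parse_lineage("Eukaryota;K1;P1;C;O;F;G1")),
            ReferenceRecord(id="b", sequence=seq,
                            lineage=parse_lineage("Eukaryota;K2;P2;C;O;F;G2")),
        ]
        df = resolution_profile(ReferenceDB(recs), [0.95])
        row = df.iloc[0]
        assert row["consensus_domain_or_deeper"] == pytest.approx(1.0)
        assert row["consensus_kingdom_or_deeper"] == 0.0
        assert row["consensus_genus_or_deeper"] == 0.0

    def test_synthetic_db_resolves_genera_at_high_similarity(self, small_corpus):
        """Congeners ~2% apart: at the 99% level nearly all reference
        sequences should sit in genus-consensus clusters."""
        _, bundle, _, _ = small_corpus
        df = resolution_profile(bundle.euk_db, [0.99], method="identity")
        assert df.iloc[0]["consensus_genus_or_deeper"] >= 0.90

    def test_empty_db_raises(self):
        with pytest.raises(ValueError, match="empty"):
            resolution_profile(ReferenceDB([]), [0.9])
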