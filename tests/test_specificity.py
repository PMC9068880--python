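"""Uniqueness screen: k-mer index, mismatch-bounded hit counting, SAM import."""

import textwrap

import pytest

import hcrprobe as hp
from hcrprobe import DesignParameters, ParseError, ValidationError
from hcrprobe.specificity import _scan_hits, _seed_hits

from oracles import brute_force_loci, revcomp


def mk_candidate(seq, start=0, tid="t", passed=True):
    return hp.ProbeCandidate(
        transcript_id=tid,
        window=(start, start + len(seq)),
        target_seq=seq,
        binding_seq=hp.reverse_complement(seq),
        passed_thermo=passed,
    )


@pytest.fixture(scope="module")
def dup_fixture():
    """600-nt transcript, 3-kb genome with one planted 150-nt duplication."""
    return hp.generate_fixture(
        seed=23, length=600, gc=0.5, cds=(50, 500),
        n_duplications=1, dup_len=150, flank=900,
    )


class TestBuildIndex:
    def test_entry_bound_and_both_strands(self, dup_fixture):
        genome = dup_fixture.genome
        k = 15
        index = hp.build_index(genome, k=k)
        total = sum(len(v) for v in index.index.values())
        n = len(next(iter(genome.values())))
        assert total <= 2 * (n - k + 1)
        # a forward k-mer and its reverse complement both resolve
        seq = next(iter(genome.values()))
        kmer = seq[100:100 + k]
        strands = {s for _, _, s in index.index[kmer]}
        rc_strands = {s for _, _, s in index.index.get(revcomp(kmer), [])}
        assert "+" in strands and "-" in rc_strands

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            hp.build_index({"empty": ""}, k=11)

    def test_duplicated_block_kmers_list_two_positions(self, dup_fixture):
        (start, end) = dup_fixture.planted_duplications[0]
        tx = dup_fixture.transcript.sequence
        index = hp.build_index(dup_fixture.genome, k=15)
        kmer = tx[start + 10 : start + 25]
        plus_hits = [h for h in index.index[kmer] if h[2] == "+"]
        assert len(plus_hits) >= 2


class TestCountHits:
    def test_unique_region_single_locus(self, dup_fixture, params):
        tx = dup_fixture.transcript.sequence
        dup = dup_fixture.planted_duplications[0]
        start = dup[1] + 30  # outside the duplication
        index = hp.build_index(dup_fixture.genome, k=params.seed_k)
        summary = hp.count_hits(mk_candidate(tx[start:start + 25], start), index)
        assert summary.n_loci == 1

    def test_duplicated_region_two_loci(self, dup_fixture, params):
        tx = dup_fixture.transcript.sequence
        start = dup_fixture.planted_duplications[0][0] + 20
        index = hp.build_index(dup_fixture.genome, k=params.seed_k)
        summary = hp.count_hits(mk_candidate(tx[start:start + 25], start), index)
        assert summary.n_loci == 2

    def test_all_windows_match_brute_force_scan(self, dup_fixture):
        """Built-in counting equals the full both-strand scan, both code paths."""
        tx = dup_fixture.transcript.sequence
        genome = dup_fixture.genome
        targets = [tx[s:s + 25] for s in range(0, len(tx) - 24, 7)]
        for mm, k in ((2, 11), (1, 11), (0, 12)):
            index = hp.build_index(genome, k=k)
            for target in targets:
                got = hp.count_hits(mk_candidate(target), index, max_mismatches=mm)
                expected = brute_force_loci(target, genome, mm)
                assert got.n_loci == len(expected)
                assert sorted(got.loci) == expected

    def test_seed_and_scan_paths_agree(self, dup_fixture):
        # pigeonhole holds at mm=1, k=11: both paths must give identical loci
        tx = dup_fixture.transcript.sequence
        index = hp.build_index(dup_fixture.genome, k=11)
        for s in range(0, 400, 13):
            target = tx[s:s + 25]
            assert _seed_hits(target, index, 1) == _scan_hits([target], index, 1)[0]

    def test_reverse_strand_hit_detected(self, params):
        core = "ACGGATTCACGGTCCAGGATACGGT"
        genome = {"c1": "T" * 40 + core + "G" * 40 + revcomp(core) + "A" * 40}
        index = hp.build_index(genome, k=params.seed_k)
        summary = hp.count_hits(mk_candidate(core), index, max_mismatches=2)
        assert summary.n_loci == 2
        assert {s for _, _, s in summary.loci} == {"+", "-"}

    def test_monotone_in_max_mismatches(self, dup_fixture):
        tx = dup_fixture.transcript.sequence
        index = hp.build_index(dup_fixture.genome, k=11)
        for s in range(0, 500, 50):
            cand = mk_candidate(tx[s:s + 25], s)
            counts = [
                hp.count_hits(cand, index, max_mismatches=mm).n_loci
                for mm in (0, 1, 2, 3)
            ]
            assert counts == sorted(counts)


class TestApplyUniqueness:
    def test_planted_duplication_windows_dropped(self, dup_fixture, params):
        cands = [
            mk_candidate(
                dup_fixture.transcript.sequence[s:s + 25], s
            )
            for s in range(len(dup_fixture.transcript) - 24)
        ]
        index = hp.build_index(dup_fixture.genome, k=params.seed_k)
        hp.apply_uniqueness(cands, index, params)
        by_start = {c.window[0]: c for c in cands}
        for s in dup_fixture.expected_dropped_windows:
            assert by_start[s].unique is False
        # windows not overlapping any duplication survive
        dup = dup_fixture.planted_duplications[0]
        for s, cand in by_start.items():
            if s + 25 <= dup[0] or s >= dup[1]:
                assert cand.unique is True, f"window {s} wrongly dropped"

    def test_both_members_rule_drops_pair(self, dup_fixture, params):
        tx = dup_fixture.transcript
        dup = dup_fixture.planted_duplications[0]
        # P1 just before the duplication is unique, P2 inside it is not
        p1_start = dup[0] - 60
        cands = [
            mk_candidate(tx.sequence[s:s + 25], s)
            for s in (p1_start, p1_start + 27, dup[0] + 10, dup[0] + 37)
        ]
        index = hp.build_index(dup_fixture.genome, k=params.seed_k)
        hp.apply_uniqueness(cands, index, params)
        pairs = hp.pair_candidates(cands, params)
        starts = {p.p1.window[0] for p in pairs}
        assert p1_start in starts  # unique + unique pair survives
        assert dup[0] + 10 not in starts  # multi-mapping member kills the pair

    def test_unique_self_match_kept(self, small_fixture, params):
        tx = small_fixture.transcript
        cands = [mk_candidate(tx.sequence[0:25], 0)]
        index = hp.build_index(small_fixture.genome, k=params.seed_k)
        hp.apply_uniqueness(cands, index, params)
        assert cands[0].n_loci == 1 and cands[0].unique is True

    def test_zero_hit_candidate_dropped_unless_kept(self, params):
        cand = mk_candidate("ACGTGACTGTACAGTCAGTCAGTCA")
        genome = {"c": "T" * 400}
        index = hp.build_index(genome, k=params.seed_k)
        hp.apply_uniqueness([cand], index, params)
        assert cand.n_loci == 0 and cand.unique is False
        cand2 = mk_candidate("ACGTGACTGTACAGTCAGTCAGTCA")
        keep = DesignParameters(keep_unmapped=True)
        hp.apply_uniqueness([cand2], index, keep)
        assert cand2.unique is True

    def test_planting_copy_flips_probe_to_dropped(self, small_fixture, params):
        tx = small_fixture.transcript.sequence
        target = tx[300:325]
        cand = mk_candidate(target, 300)
        index = hp.build_index(small_fixture.genome, k=params.seed_k)
        hp.apply_uniqueness([cand], index, params)
        assert cand.unique is True
        genome2 = {
            "fixture_genome": next(iter(small_fixture.genome.values())) + "TTTT" + target
        }
        cand2 = mk_candidate(target, 300)
        hp.apply_uniqueness([cand2], hp.build_index(genome2, k=params.seed_k), params)
        assert cand2.unique is False


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:chr1\tLN:10000\n@SQ\tSN:chr2\tLN:10000\n"


def sam_line(name, flag, rname="chr1", pos=100):
    return (
        f"{name}\t{flag}\t{rname}\t{pos}\t42\t25M\t*\t0\t0\t"
        f"{'A' * 25}\t*\n"
    )


class TestImportSamHits:
    def test_primary_only(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(SAM_HEADER + sam_line("t:0-25", 0))
        hits = hp.import_sam_hits(sam)
        assert hits["t:0-25"].n_loci == 1

    def test_primary_plus_secondary_on_other_contig(self, tmp_path):
        sam = tmp_path / "b.sam"
        sam.write_text(
            SAM_HEADER
            + sam_line("t:0-25", 0, "chr1", 100)
            + sam_line("t:0-25", 256, "chr2", 500)
        )
        assert hp.import_sam_hits(sam)["t:0-25"].n_loci == 2

    def test_supplementary_not_counted(self, tmp_path):
        sam = tmp_path / "c.sam"
        sam.write_text(
            SAM_HEADER
            + sam_line("t:0-25", 0, "chr1", 100)
            + sam_line("t:0-25", 2048, "chr2", 500)
        )
        assert hp.import_sam_hits(sam)["t:0-25"].n_loci == 1

    def test_unmapped_yields_zero_and_candidate_dropped(self, tmp_path, params):
        sam = tmp_path / "d.sam"
        sam.write_text(SAM_HEADER + "t:0-25\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
        hits = hp.import_sam_hits(sam)
        assert hits["t:0-25"].n_loci == 0
        cand = mk_candidate("ACGT" * 6 + "A", 0)
        hp.apply_sam_hits([cand], hits, params)
        assert cand.unique is False

    def test_malformed_line_reports_line_number(self, tmp_path):
        sam = tmp_path / "e.sam"
        sam.write_text(SAM_HEADER + "broken\trecord\n")
        with pytest.raises(ParseError, match="line 4"):
            hp.import_sam_hits(sam)

    def test_score_floor(self, tmp_path):
        sam = tmp_path / "f.sam"
        good = sam_line("t:0-25", 0).rstrip("\n") + "\tAS:i:50\n"
        weak = sam_line("t:0-25", 256, "chr2").rstrip("\n") + "\tAS:i:5\n"
        sam.write_text(SAM_HEADER + good + weak)
        assert hp.import_sam_hits(sam, min_score=40)["t:0-25"].n_loci == 1
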