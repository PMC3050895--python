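"""Search core: Karlin statistics, seeding, extension, translated search."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from activeflora import search as S
from activeflora.refsim import Read
from activeflora.sequtils import (decode_nt, encode_aa, encode_nt, revcomp,
                                  reverse_translate)


class TestKarlinLambda:
    def test_match1_mismatch1_closed_form(self):
        # 0.25 x + 0.75/x = 1 has root x = e^lambda = 3
        scheme = S.ScoringScheme.nucleotide(1, -1)
        assert S.karlin_lambda(scheme) == pytest.approx(math.log(3), abs=1e-9)

    def test_match2_mismatch3_matches_grid_scan(self):
        scheme = S.ScoringScheme.nucleotide(2, -3)
        lam = S.karlin_lambda(scheme)
        grid = np.arange(1e-6, 2.0, 1e-6)
        vals = 0.25 * np.exp(grid * 2) + 0.75 * np.exp(grid * -3) - 1.0
        root = grid[np.argmin(np.abs(vals))]
        assert lam == pytest.approx(root, abs=2e-6)

    def test_scaling_scores_halves_lambda(self):
        lam1 = S.karlin_lambda(S.ScoringScheme.nucleotide(1, -1))
        lam2 = S.karlin_lambda(S.ScoringScheme.nucleotide(2, -2))
        assert lam2 == pytest.approx(lam1 / 2, rel=1e-8)

    def test_nonnegative_expected_score_rejected(self):
        with pytest.raises(S.InvalidScheme):
            S.karlin_lambda(S.ScoringScheme.nucleotide(3, -1))

    def test_blosum62_lambda_positive(self):
        lam = S.karlin_lambda(S.ScoringScheme.protein_blosum62())
        assert 0.1 < lam < 1.0


class TestEvalue:
    def test_zero_score_gives_Kmn(self):
        sch = S.ScoringScheme.nucleotide()
        assert S.evalue(0, 100, 1000, sch) == pytest.approx(sch.K * 100 * 1000)

    def test_linear_in_database_size(self):
        sch = S.ScoringScheme.nucleotide()
        assert S.evalue(30, 50, 2_000_000, sch) == \
            pytest.approx(2 * S.evalue(30, 50, 1_000_000, sch))

    def test_worked_example(self):
        sch = S.ScoringScheme("nt", S.ScoringScheme.nucleotide(1, -1).matrix,
                              np.full(4, 0.25), K=0.1)
        assert S.evalue(60, 100, 10 ** 6, sch) == pytest.approx(1e7 * 3.0 ** -60,
                                                                rel=1e-6)

    @given(st.integers(min_value=0, max_value=200))
    def test_strictly_decreasing_in_score(self, s):
        sch = S.ScoringScheme.nucleotide()
        assert S.evalue(s + 1, 100, 1000, sch) < S.evalue(s, 100, 1000, sch)


class TestSeedIndex:
    def test_kmer_count_single_reference(self):
        idx = S.build_index([("r1", "ACGTACGT")], k=4)
        assert idx.n_kmers() == 5

    def test_union_property(self, rng):
        refs = [(f"r{i}", decode_nt(rng.integers(0, 4, 60).astype(np.uint8)))
                for i in range(4)]
        whole = S.build_index(refs, k=5).entries()
        parts = set()
        for r in refs:
            parts |= S.build_index([r], k=5).entries()
        assert whole == parts

    def test_no_shared_kmer_means_no_hits(self):
        idx = S.build_index([("r1", "A" * 50)], k=6)
        hits = S.search("CT" * 30, idx, S.ScoringScheme.nucleotide(), max_e=10)
        assert hits == []

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            S.build_index([("r1", "ACGTACGT")], k=3)


def _sw_ungapped_best(query, refs, match=1, mismatch=-2):
    """Brute-force ungapped Smith-Waterman: best positive segment over all
    diagonals of all references, both strands."""
    best = 0
    for qseq in (query, revcomp(query)):
        q = encode_nt(qseq)
        for _, rseq in refs:
            r = encode_nt(rseq)
            H = np.zeros((q.size + 1, r.size + 1))
            for i in range(1, q.size + 1):
                s = np.where(q[i - 1] == r, match, mismatch)
                H[i, 1:] = np.maximum(0, H[i - 1, :-1] + s)
            best = max(best, int(H.max()))
    return best


class TestSearch:
    def test_exact_slice_has_full_identity_hit(self, rng):
        ref = decode_nt(rng.integers(0, 4, 400).astype(np.uint8))
        idx = S.build_index([("ref", ref)], k=11)
        sch = S.ScoringScheme.nucleotide()
        hits = S.search(ref[100:300], idx, sch, max_e=1e-4)
        assert hits and hits[0].identity == 100.0
        assert (hits[0].sstart, hits[0].send) == (100, 300)
        assert hits[0].length == 200

    def test_reverse_complement_symmetry(self, rng):
        ref = decode_nt(rng.integers(0, 4, 300).astype(np.uint8))
        idx = S.build_index([("ref", ref)], k=11)
        sch = S.ScoringScheme.nucleotide()
        fwd = S.search(ref[50:200], idx, sch, max_e=1e-4)
        rev = S.search(revcomp(ref[50:200]), idx, sch, max_e=1e-4)
        assert [(h.subject_id, h.score, h.sstart, h.send) for h in fwd] == \
               [(h.subject_id, h.score, h.sstart, h.send) for h in rev]
        assert {h.strand for h in fwd} == {"+"} and {h.strand for h in rev} == {"-"}

    def test_scores_match_bruteforce_dp(self, rng):
        """On small planted-homology instances the seeded ungapped search
        attains the exact ungapped Smith-Waterman optimum."""
        sch = S.ScoringScheme.nucleotide()
        for trial in range(10):
            refs = [(f"r{i}", decode_nt(rng.integers(0, 4, 50).astype(np.uint8)))
                    for i in range(5)]
            src = encode_nt(refs[trial % 5][1])[10:40].copy()
            nmut = trial % 4
            pos = rng.choice(30, size=nmut, replace=False)
            src[pos] = (src[pos] + 1 + rng.integers(0, 3, nmut)) % 4
            query = decode_nt(src)
            idx = S.build_index(refs, k=4)
            hits = S.search(query, idx, sch, max_e=1e9)
            got = max((h.score for h in hits), default=0)
            assert got == _sw_ungapped_best(query, refs)

    def test_empty_query_rejected(self):
        idx = S.build_index([("r", "ACGTACGTACGT")], k=4)
        with pytest.raises(ValueError):
            S.search("", idx, S.ScoringScheme.nucleotide())

    def test_deterministic_tie_break_on_subject_id(self, rng):
        ref = decode_nt(rng.integers(0, 4, 120).astype(np.uint8))
        idx = S.build_index([("b", ref), ("a", ref)], k=11)
        hits = S.search(ref[10:90], idx, S.ScoringScheme.nucleotide(), max_e=1)
        assert [h.subject_id for h in hits[:2]] == ["a", "b"]


@pytest.fixture(scope="module")
def protein_world():
    rng = np.random.default_rng(7)
    prots = [(f"p{i}", "".join("ACDEFGHIKLMNPQRSTVWY"[c]
                               for c in rng.integers(0, 20, 120)))
             for i in range(5)]
    idx = S.build_index(prots, k=4, alphabet="aa")
    return prots, idx, S.ScoringScheme.protein_blosum62(), rng


class TestTranslatedSearch:
    def test_reverse_translated_read_found_exactly(self, protein_world):
        prots, idx, sch, rng = protein_world
        nt = reverse_translate(encode_aa(prots[2][1][20:70]), rng)
        hits = S.translated_search(decode_nt(nt), idx, sch, max_e=1e-3)
        assert hits and hits[0].subject_id == "p2" and hits[0].identity == 100.0
        assert hits[0].frame == 1

    def test_frame_shift_still_found_with_shifted_frame(self, protein_world):
        prots, idx, sch, rng = protein_world
        nt = reverse_translate(encode_aa(prots[2][1][20:70]), rng)
        shifted = "G" + decode_nt(nt)
        hits = S.translated_search(shifted, idx, sch, max_e=1e-3)
        assert hits and hits[0].subject_id == "p2" and hits[0].frame == 2

    def test_reverse_strand_frame_negative(self, protein_world):
        prots, idx, sch, rng = protein_world
        nt = reverse_translate(encode_aa(prots[1][1][10:60]), rng)
        hits = S.translated_search(revcomp(decode_nt(nt)), idx, sch, max_e=1e-3)
        assert hits and hits[0].subject_id == "p1" and hits[0].frame < 0

    def test_all_stop_query_yields_nothing(self, protein_world):
        _, idx, sch, _ = protein_world
        assert S.translated_search("TAATAGTGA" * 8, idx, sch, max_e=10) == []


@pytest.fixture(scope="module")
def contig_index():
    rng = np.random.default_rng(3)
    contig = decode_nt(rng.integers(0, 4, 800).astype(np.uint8))
    return contig, S.build_index([("c0", contig)], k=11)


class TestMapToContigs:
    def test_exact_substring_maps(self, contig_index):
        contig, idx = contig_index
        mapped, hit = S.map_to_contigs(Read("q", "s", contig[100:250]), idx)
        assert mapped and hit.identity == 100.0

    def test_half_coverage_fails_fraction_rule(self, contig_index):
        contig, idx = contig_index
        rng = np.random.default_rng(4)
        novel = decode_nt(rng.integers(0, 4, 100).astype(np.uint8))
        query = contig[100:200] + novel  # 50 % coverage at 100 % identity
        mapped, hit = S.map_to_contigs(Read("q", "s", query), idx)
        assert not mapped
        assert hit is not None and hit.identity == 100.0

    def test_85pct_coverage_92pct_identity_maps(self, contig_index):
        contig, idx = contig_index
        rng = np.random.default_rng(5)
        core = encode_nt(contig[100:270])  # 170 bp of a 200 bp read
        pos = rng.choice(np.arange(10, 160), size=13, replace=False)
        core[pos] = (core[pos] + 1 + rng.integers(0, 3, 13)) % 4  # ~92 % id
        query = decode_nt(core) + decode_nt(rng.integers(0, 4, 30).astype(np.uint8))
        mapped, hit = S.map_to_contigs(Read("q", "s", query), idx)
        assert mapped
        assert hit.length >= 0.8 * len(query) and hit.identity >= 90.0


def test_outfmt6_writer_roundtrip(tmp_path, rng):
    ref = decode_nt(rng.integers(0, 4, 200).astype(np.uint8))
    idx = S.build_index([("ref", ref)], k=11)
    sch = S.ScoringScheme.nucleotide()
    hits = S.search(Read("q1", "s", ref[20:160]), idx, sch, max_e=1)
    out = tmp_path / "hits.tsv"
    S.write_outfmt6(hits, out, scheme=sch)
    fields = out.read_text().strip().split("\n")[0].split("\t")
    assert len(fields) == 12
    assert fields[0] == "q1" and fields[1] == "ref"
    assert int(fields[6]) == 1 and int(fields[7]) == 140  # 1-based inclusive
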