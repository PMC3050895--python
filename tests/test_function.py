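"""COG assignment, enrichment, taxon-function structure, sRNA, accounting."""

import numpy as np
import pandas as pd
import pytest

from activeflora import function as F, refsim
from activeflora.refsim import Read
from activeflora.search import AlignmentHit
from activeflora.sequtils import decode_nt, revcomp


@pytest.fixture(scope="module")
def pdb(refs):
    return F.ProteinDatabase.from_records(refs)


@pytest.fixture(scope="module")
def mrna_reads(refs, tree):
    spec = refsim.CommunitySpec(
        n_samples=2, reads_per_sample=900, seed=21,
        class_mixture={"SSU": 0.0, "LSU": 0.0, "mRNA": 1.0, "sRNA": 0.0})
    reads = refsim.simulate_reads(spec, refs, tree)
    return [r for v in reads.values() for r in v if len(r) >= 60]


@pytest.fixture(scope="module")
def protein_calls(mrna_reads, pdb):
    return F.call_protein_coding(mrna_reads, pdb)


class TestProteinCall:
    def test_true_mrna_reads_are_called(self, mrna_reads, protein_calls):
        hits, unchar = protein_calls
        assert len(hits) / len(mrna_reads) > 0.98

    def test_random_reads_rarely_pass(self, pdb, rng):
        """False-positive rate bounded by the Karlin expectation: at
        E <= 1e-3 the expected hit count per read is at most 1e-3."""
        reads = [Read(f"rnd{i}", "s", decode_nt(rng.integers(0, 4, 150).astype(np.uint8)))
                 for i in range(2000)]
        hits, unchar = F.call_protein_coding(reads, pdb, max_e=1e-3)
        assert len(hits) <= 10  # ~5x slack over the expectation of 2

    def test_empty_database_impossible(self, refs, tree):
        empty = refsim.ReferenceSet(refs.by_class("SSU"), tree, cds={})
        with pytest.raises(ValueError):
            F.ProteinDatabase.from_records(empty)


def _hit(subject, score, qs, qe, e=1e-9):
    return AlignmentHit("q", subject, score, e, 99.0, qe - qs, qs, qe, 0, qe - qs)


class TestAssignCog:
    @pytest.fixture()
    def toy_db(self, pdb):
        return pdb

    def test_single_cog_assigned(self, pdb):
        sid = pdb.index.ids[0]
        read = Read("q", "s", "ACGT" * 40)
        res = F.assign_cog([read], pdb, hits={"q": [_hit(sid, 90, 0, 120)]})
        assert not res[0].discarded
        assert res[0].cog_id == pdb.cog_of[sid]

    def test_disjoint_functions_discarded_as_multi_cog(self, pdb):
        ids = pdb.index.ids
        a = next(i for i in ids if pdb.cog_of[i].startswith("COGJ"))
        b = next(i for i in ids if pdb.cog_of[i].startswith("COGK"))
        hits = [_hit(a, 90, 0, 60), _hit(b, 85, 80, 150)]
        res = F.assign_cog([Read("q", "s", "ACGT" * 40)], pdb, hits={"q": hits})
        assert res[0].discarded and res[0].reason == "multi_cog"

    def test_same_region_competitors_resolved_by_score(self, pdb):
        ids = pdb.index.ids
        a = next(i for i in ids if pdb.cog_of[i].startswith("COGJ"))
        b = next(i for i in ids if pdb.cog_of[i].startswith("COGK"))
        hits = [_hit(a, 90, 0, 100), _hit(b, 85, 5, 95)]  # overlap 0.9
        res = F.assign_cog([Read("q", "s", "ACGT" * 40)], pdb, hits={"q": hits})
        assert not res[0].discarded
        assert res[0].cog_id == pdb.cog_of[a]

    def test_no_hit_reason(self, pdb):
        res = F.assign_cog([Read("q", "s", "ACGT" * 40)], pdb, hits={"q": []})
        assert res[0].discarded and res[0].reason == "no_hit"

    def test_true_cog_recovered_on_synthetic_reads(self, mrna_reads, pdb,
                                                   protein_calls):
        hits, _ = protein_calls
        reads = [r for r in mrna_reads if r.id in hits]
        res = F.assign_cog(reads, pdb, hits=hits)
        by_id = {r.id: r for r in reads}
        kept = [a for a in res if not a.discarded]
        acc = np.mean([a.cog_id == by_id[a.read_id].true_cog for a in kept])
        assert acc > 0.95
        # one COG ortholog family per lineage -> no constructible fusions
        assert np.mean([a.discarded for a in res]) < 0.02


class TestCategoryDistribution:
    def test_single_category_sample(self):
        asg = [F.COGAssignment(f"r{i}", "A", "COGG01", "G", 50, 1e-8, False)
               for i in range(4)]
        d = F.category_distribution(asg)
        assert d.loc["G", "A"] == 1.0 and d["A"].sum() == 1.0

    def test_order_invariance(self):
        asg = [F.COGAssignment(f"r{i}", "A", f"COG{c}01", c, 50, 1e-8, False)
               for i, c in enumerate("GGIJC")]
        a = F.category_distribution(asg)
        b = F.category_distribution(asg[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_recovery_of_injected_profile(self, mrna_reads, pdb, protein_calls):
        hits, _ = protein_calls
        reads = [r for r in mrna_reads if r.id in hits]
        res = F.assign_cog(reads, pdb, hits=hits)
        d = F.category_distribution(res)
        profile = refsim.default_cog_profile()
        pooled = d.mean(axis=1)
        l1 = sum(abs(pooled[c] - profile[c]) for c in profile)
        assert l1 <= 0.10


class TestRateRatios:
    def test_direct_formula(self):
        db = pd.Series({c: 10 if c == "G" else 90 / 24 for c in F.COG_CATEGORIES})
        db = db / db.sum() * 100
        asg = ([F.COGAssignment(f"g{i}", "A", "COGG01", "G", 50, 1e-8, False)
                for i in range(30)]
               + [F.COGAssignment(f"x{i}", "A", "COGJ01", "J", 50, 1e-8, False)
                  for i in range(70)])
        rr = F.rate_ratios(asg, db)
        assert rr.ratio("G") == pytest.approx((30 / 100) / (10 / 100))

    def test_database_against_itself_is_unity(self, pdb):
        ratios = F.database_self_ratios(pdb)
        defined = ratios.dropna()
        assert (defined == 1.0).all()

    def test_zero_database_category_flagged_undefined(self):
        db = pd.Series({c: (0 if c == "B" else 1) for c in F.COG_CATEGORIES})
        asg = [F.COGAssignment("r", "A", "COGJ01", "J", 50, 1e-8, False)]
        rr = F.rate_ratios(asg, db)
        assert np.isnan(rr.ratio("B"))
        assert bool(rr.table.loc["B", "undefined"])

    def test_counts_conserved_after_discards(self, mrna_reads, pdb, protein_calls):
        hits, _ = protein_calls
        reads = [r for r in mrna_reads if r.id in hits]
        res = F.assign_cog(reads, pdb, hits=hits)
        rr = F.rate_ratios(res, pdb)
        kept = sum(not a.discarded for a in res)
        assert int(rr.table["n_c"].sum()) == kept == int(rr.table["n"].iloc[0])


class TestTaxonFunctionMatrix:
    def _asg(self, rid, cat):
        return F.COGAssignment(rid, "A", f"COG{cat}01", cat, 50, 1e-8, False)

    def test_columns_sum_to_one_and_planted_blocks_split_first(self):
        asg, fam = [], {}
        for i in range(30):
            cat = "JKL"[i % 3]          # block 1 from family X
            asg.append(self._asg(f"x{i}", cat))
            fam[f"x{i}"] = "FamilyX"
        for i in range(30):
            cat = "CEF"[i % 3]          # block 2 from family Y
            asg.append(self._asg(f"y{i}", cat))
            fam[f"y{i}"] = "FamilyY"
        props, Z, empty = F.taxon_function_matrix(asg, fam)
        assert np.allclose(props.sum(axis=0), 1.0)
        from scipy.cluster.hierarchy import fcluster
        groups = fcluster(Z, t=2, criterion="maxclust")
        lab = dict(zip(props.columns, groups))
        assert {lab["J"], lab["K"], lab["L"]} != {lab["C"], lab["E"], lab["F"]}
        assert len({lab["J"], lab["K"], lab["L"]}) == 1
        assert len({lab["C"], lab["E"], lab["F"]}) == 1

    def test_identical_profiles_merge_at_zero_height(self):
        asg, fam = [], {}
        for i in range(10):
            for cat in "JK":
                rid = f"{cat}{i}"
                asg.append(self._asg(rid, cat))
                fam[rid] = "FamilyX"
        props, Z, _ = F.taxon_function_matrix(asg, fam)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_empty_categories_listed(self):
        asg = [self._asg("r0", "J")]
        props, Z, empty = F.taxon_function_matrix(asg, {"r0": "FamilyX"})
        assert "J" in props.columns and set(empty) == set(F.COG_CATEGORIES) - {"J"}

    def test_newick_serialization(self):
        asg, fam = [], {}
        for i, cat in enumerate("JKC"):
            asg.append(self._asg(f"r{i}", cat))
            fam[f"r{i}"] = ["FamilyX", "FamilyY", "FamilyX"][i]
        props, Z, _ = F.taxon_function_matrix(asg, fam)
        nwk = F.dendrogram_newick(Z, list(props.columns))
        assert nwk.endswith(";") and all(c in nwk for c in "JKC")


class TestSRNAScan:
    def test_planted_consensus_scores_maximally(self, refs):
        motifs = F.motifs_from_references(refs)
        m = motifs[0]
        consensus = refs.record(m.family_id).seq
        pad = "A" * 20
        hits, frac = F.srna_scan([Read("q", "s", pad + consensus + pad)], [m])
        assert frac == 1.0
        assert hits[0].score == pytest.approx(m.max_score())
        assert (hits[0].qstart, hits[0].strand) == (20, "+")

    def test_reverse_complement_planting_found_on_minus(self, refs):
        motifs = F.motifs_from_references(refs)
        m = motifs[1]
        consensus = refs.record(m.family_id).seq
        hits, _ = F.srna_scan([Read("q", "s", revcomp("AC" * 10 + consensus))], [m])
        assert hits and hits[0].strand == "-"
        assert hits[0].score == pytest.approx(m.max_score())

    def test_threshold_above_max_yields_nothing(self, refs):
        motifs = F.motifs_from_references(refs)
        m = motifs[0]
        strict = F.PWMMotif(m.family_id, m.matrix, m.max_score() + 1.0)
        hits, frac = F.srna_scan([Read("q", "s", refs.record(m.family_id).seq)],
                                 [strict])
        assert hits == [] and frac == 0.0

    def test_motif_longer_than_read_skipped(self, refs):
        motifs = F.motifs_from_references(refs)
        hits, frac = F.srna_scan([Read("q", "s", "ACGT" * 5)], motifs)
        assert hits == [] and frac == 0.0

    def test_family_counts(self, refs):
        motifs = F.motifs_from_references(refs)[:2]
        reads = [Read(f"q{i}", "s", refs.record(m.family_id).seq)
                 for i, m in enumerate(motifs)]
        hits, _ = F.srna_scan(reads, motifs)
        counts = F.srna_family_counts(hits)
        assert counts.sum() == 2 and set(counts.index) == {m.family_id
                                                           for m in motifs}


class TestFractionAccounting:
    def _reads(self, n):
        return [Read(f"r{i}", "s", "ACGT" * 20) for i in range(n)]

    def test_all_protein_and_mapped_single_cell(self):
        reads = self._reads(10)
        ids = {r.id for r in reads}
        acc = F.fraction_accounting(reads, ids, ids, set())
        assert acc.percentages["protein_mapped"] == 100.0
        assert sum(acc.counts.values()) == 10

    def test_percentages_sum_to_100(self, rng):
        reads = self._reads(200)
        ids = [r.id for r in reads]
        prot = set(rng.choice(ids, 120, replace=False))
        mapped = set(rng.choice(ids, 90, replace=False))
        srna = set(rng.choice(sorted(set(ids) - prot), 10, replace=False))
        acc = F.fraction_accounting(reads, prot, mapped, srna)
        assert sum(acc.percentages.values()) == pytest.approx(100.0, abs=0.1)
        assert acc.srna_fraction == pytest.approx(10 / 80)

    def test_truth_label_recount(self, mrna_reads, pdb, protein_calls, refs):
        """Accounting equals a direct recount from the constituent sets."""
        hits, unchar = protein_calls
        mapped = {r.id for i, r in enumerate(mrna_reads) if i % 3 == 0}
        srna = set()
        acc = F.fraction_accounting(mrna_reads, set(hits), mapped, srna)
        prot = set(hits)
        uni = {r.id for r in mrna_reads}
        assert acc.counts["protein_mapped"] == len(prot & mapped)
        assert acc.counts["uncharacterized_unmapped"] == len((uni - prot) - mapped)
        assert sum(acc.counts.values()) == len(uni)

    def test_inconsistent_universe_rejected(self):
        reads = self._reads(5)
        with pytest.raises(ValueError):
            F.fraction_accounting(reads, {"alien"}, set(), set())
        with pytest.raises(ValueError):
            F.fraction_accounting(reads, {"r0"}, set(), {"r0"})  # sRNA ⊄ unchar
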