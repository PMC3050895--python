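"""Functional profiling of the non-rRNA read fraction.

Protein-homology calling by six-frame translated search (E ≤ 1e-3), COG
assignment with the multi-COG discard rule (reads supporting two distinct
COG functions on genuinely non-overlapping parts of the read are treated
as chimeric and discarded), per-sample COG category distributions,
rate-ratio enrichment against the reference database, the family ×
category matrix with hierarchical clustering, a PWM-based sRNA scan of
the uncharacterized fraction, and the mapped/unmapped fraction
accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .refsim import COG_CATEGORIES, Read, ReferenceSet
from .search import AlignmentHit, ScoringScheme, SeedIndex, translated_search
from .sequtils import encode_nt, revcomp_codes


@dataclass
class ProteinDatabase:
    """Protein seed index plus COG id/category and taxonomy annotations."""
    index: SeedIndex
    scheme: ScoringScheme
    cog_of: dict[str, str]
    category_of: dict[str, str]
    taxon_of: dict[str, str]

    @classmethod
    def from_records(cls, refs: ReferenceSet, k: int = 4,
                     scheme: ScoringScheme | None = None) -> "ProteinDatabase":
        if scheme is None:
            scheme = ScoringScheme.protein_blosum62()
        prots = sorted(refs.by_class("protein"), key=lambda r: r.id)
        if not prots:
            raise ValueError("no protein records")
        idx = SeedIndex([(r.id, r.seq) for r in prots], k=k, alphabet="aa")
        return cls(idx,
                   scheme,
                   {r.id: r.cog_id for r in prots},
                   {r.id: r.cog_category for r in prots},
                   {r.id: r.node for r in prots})

    def category_counts(self) -> pd.Series:
        """One count per database protein's COG function."""
        s = pd.Series(0, index=list(COG_CATEGORIES), dtype=np.int64)
        for cat in self.category_of.values():
            s[cat] += 1
        return s


def call_protein_coding(non_rrna_reads: list[Read], protein_db: ProteinDatabase,
                        max_e: float = 1e-3, min_seeds: int = 2,
                        max_diagonals: int = 16
                        ) -> tuple[dict[str, list[AlignmentHit]], list[Read]]:
    """Split non-rRNA reads into putative-protein and uncharacterized.

    A read is putative-protein iff the translated search yields any hit
    with E ≤ ``max_e``; its full hit list is kept for downstream COG and
    LCA assignment.  Returns (hits per protein read id, uncharacterized
    reads).
    """
    protein_hits: dict[str, list[AlignmentHit]] = {}
    uncharacterized: list[Read] = []
    for read in non_rrna_reads:
        hits = translated_search(read, protein_db.index, protein_db.scheme,
                                 max_e=max_e, min_seeds=min_seeds,
                                 max_diagonals=max_diagonals)
        if hits:
            protein_hits[read.id] = hits
        else:
            uncharacterized.append(read)
    return protein_hits, uncharacterized


@dataclass
class COGAssignment:
    """COG call for one read (or the reason it was discarded)."""
    read_id: str
    sample: str
    cog_id: str | None
    category: str | None
    score: int | None
    evalue: float | None
    discarded: bool
    reason: str | None = None      # no_hit | multi_cog


def _overlap_fraction(a: AlignmentHit, b: AlignmentHit) -> float:
    inter = min(a.qend, b.qend) - max(a.qstart, b.qstart)
    if inter <= 0:
        return 0.0
    return inter / min(a.qend - a.qstart, b.qend - b.qstart)


def assign_cog(protein_reads: list[Read], cog_db: ProteinDatabase,
               max_e: float = 1e-3, overlap_fraction: float = 0.5,
               hits: dict[str, list[AlignmentHit]] | None = None
               ) -> list[COGAssignment]:
    """Assign each putative-protein read to one COG function, or discard it.

    Hits with E ≤ ``max_e`` are grouped by COG function.  If two distinct
    functions are supported on query regions that overlap each other by
    less than ``overlap_fraction`` — genuinely non-overlapping signals,
    the signature of a chimeric/fused fragment — the read is discarded
    (reason ``multi_cog``).  Functions competing over the same region are
    ordinary homologs and the best-scoring one wins.  Precomputed hit
    lists (from the protein-coding call) may be supplied to avoid
    re-searching.
    """
    out: list[COGAssignment] = []
    for read in protein_reads:
        hlist = hits.get(read.id) if hits is not None else None
        if hlist is None:
            hlist = translated_search(read, cog_db.index, cog_db.scheme, max_e=max_e,
                                      min_seeds=2, max_diagonals=16)
        hlist = [h for h in hlist if h.evalue <= max_e and h.subject_id in cog_db.cog_of]
        if not hlist:
            out.append(COGAssignment(read.id, read.sample, None, None, None, None,
                                     True, "no_hit"))
            continue
        best_by_cog: dict[str, AlignmentHit] = {}
        for h in hlist:
            cid = cog_db.cog_of[h.subject_id]
            if cid not in best_by_cog or h.score > best_by_cog[cid].score:
                best_by_cog[cid] = h
        multi = False
        cogs = sorted(best_by_cog)
        for i in range(len(cogs)):
            for j in range(i + 1, len(cogs)):
                if _overlap_fraction(best_by_cog[cogs[i]],
                                     best_by_cog[cogs[j]]) < overlap_fraction:
                    multi = True
        if multi and len(cogs) > 1:
            out.append(COGAssignment(read.id, read.sample, None, None, None, None,
                                     True, "multi_cog"))
            continue
        top = max(best_by_cog.values(), key=lambda h: (h.score, h.subject_id))
        cid = cog_db.cog_of[top.subject_id]
        out.append(COGAssignment(read.id, read.sample, cid,
                                 cog_db.category_of[top.subject_id],
                                 top.score, top.evalue, False))
    return out


def category_distribution(assignments: list[COGAssignment]) -> pd.DataFrame:
    """Category × sample proportion matrix over non-discarded assignments."""
    kept = [a for a in assignments if not a.discarded]
    samples = sorted({a.sample for a in assignments})
    mat = pd.DataFrame(0, index=list(COG_CATEGORIES), columns=samples,
                       dtype=np.int64)
    for a in kept:
        mat.loc[a.category, a.sample] += 1
    totals = mat.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        import warnings
        warnings.warn(f"samples with no COG assignment: {empty}")
        totals = totals.replace(0, 1)
    return mat / totals


@dataclass
class RateRatioTable:
    """Per-category over/under-representation of the pooled sample.

    ratio = (n_c/n)/(N_c/N): the category's share among sample hits
    relative to its share among database proteins; > 1 over-represented,
    < 1 under-represented, NaN (flagged) where the database has no member.
    """
    table: pd.DataFrame

    def ratio(self, category: str) -> float:
        return float(self.table.loc[category, "ratio"])


def rate_ratios(assignments: list[COGAssignment],
                cog_db: ProteinDatabase | pd.Series) -> RateRatioTable:
    """Rate ratios of the pooled assignments against the database.

    ``cog_db`` may be a ProteinDatabase (N_c = one count per database
    protein's function) or a precomputed per-category count Series.
    """
    db_counts = (cog_db if isinstance(cog_db, pd.Series)
                 else cog_db.category_counts())
    db_counts = db_counts.reindex(list(COG_CATEGORIES), fill_value=0)
    kept = [a for a in assignments if not a.discarded]
    n = len(kept)
    if n == 0:
        raise ValueError("no non-discarded assignments")
    n_c = pd.Series(0, index=list(COG_CATEGORIES), dtype=np.int64)
    for a in kept:
        n_c[a.category] += 1
    N = int(db_counts.sum())
    if N == 0:
        raise ValueError("empty database category table")
    ratio = (n_c / n) / (db_counts / N)
    ratio[db_counts == 0] = np.nan
    table = pd.DataFrame({"n_c": n_c, "n": n, "N_c": db_counts, "N": N,
                          "ratio": ratio, "undefined": db_counts == 0})
    return RateRatioTable(table)


def database_self_ratios(cog_db: ProteinDatabase) -> pd.Series:
    """Rate ratios of the database against itself (identically 1 where
    defined) — the null of the enrichment statistic."""
    counts = cog_db.category_counts()
    share = counts / counts.sum()
    out = share / share
    out[counts == 0] = np.nan
    return out


def taxon_function_matrix(assignments: list[COGAssignment],
                          family_of_read: dict[str, str | None],
                          linkage_method: str = "average"
                          ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Family × category proportion matrix and a category dendrogram.

    Each category column is the distribution of its reads over families
    (reads without a family-level bin pooled as "unassigned"), columns sum
    to one.  Categories are clustered by L1 distance between their family
    profiles with average linkage; categories with zero reads are excluded
    and returned in the third element.
    """
    kept = [a for a in assignments if not a.discarded]
    fams = sorted({f for f in family_of_read.values() if f} | {"unassigned"})
    counts = pd.DataFrame(0, index=fams, columns=list(COG_CATEGORIES),
                          dtype=np.int64)
    for a in kept:
        fam = family_of_read.get(a.read_id) or "unassigned"
        counts.loc[fam, a.category] += 1
    empty = [c for c in counts.columns if counts[c].sum() == 0]
    mat = counts.drop(columns=empty)
    mat = mat.reindex(sorted(mat.columns), axis=1)  # deterministic leaf tie-break
    props = mat / mat.sum(axis=0)
    if props.shape[1] >= 2:
        Z = hierarchy.linkage(pdist(props.T.to_numpy(), metric="cityblock"),
                              method=linkage_method)
    else:
        Z = np.empty((0, 4))
    return props, Z, empty


def dendrogram_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    if Z.shape[0] == 0:
        return (labels[0] + ";") if labels else ";"
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.4f}"
    return rec(tree) + ";"


# --- sRNA scan -----------------------------------------------------------

@dataclass
class PWMMotif:
    """Log-odds position weight matrix with a per-family score threshold."""
    family_id: str
    matrix: np.ndarray            # (L, 4) log-odds vs background
    threshold: float

    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())


def motifs_from_references(refs: ReferenceSet, consensus_prob: float = 0.9,
                           threshold_fraction: float = 0.6) -> list[PWMMotif]:
    """Derive PWMs from the sRNA consensus references.

    Consensus bases get probability ``consensus_prob`` (the remainder
    split evenly), log-odds are taken against the uniform background and
    the reporting threshold is ``threshold_fraction`` of the maximal
    attainable score.
    """
    motifs = []
    for r in sorted(refs.by_class("sRNA"), key=lambda x: x.id):
        codes = encode_nt(r.seq)
        L = codes.size
        m = np.full((L, 4), np.log((1 - consensus_prob) / 3 / 0.25))
        m[np.arange(L), codes] = np.log(consensus_prob / 0.25)
        motifs.append(PWMMotif(r.id, m, threshold_fraction * m.max(axis=1).sum()))
    return motifs


@dataclass
class sRNAHit:
    read_id: str
    family_id: str
    score: float
    qstart: int
    qend: int
    strand: str


def srna_scan(reads: list[Read], motifs: list[PWMMotif]
              ) -> tuple[list[sRNAHit], float]:
    """Best-window PWM scan of each read against each motif, both strands.

    Reports a hit when the best window score reaches the motif threshold;
    motifs longer than the read are skipped for that read.  Returns the
    hits and the fraction of reads with at least one hit.
    """
    hits: list[sRNAHit] = []
    n_with = 0
    for read in reads:
        codes = encode_nt(read.seq)
        found = False
        for motif in motifs:
            L = motif.matrix.shape[0]
            if L > codes.size:
                continue
            best = (-np.inf, 0, "+")
            for strand, c in (("+", codes), ("-", revcomp_codes(codes))):
                windows = np.lib.stride_tricks.sliding_window_view(c, L)
                valid = ~(windows >= 4).any(axis=1)
                if not valid.any():
                    continue
                # scores of every window: gather per-position log-odds
                sc = motif.matrix[np.arange(L)[None, :],
                                  np.minimum(windows, 3)].sum(axis=1)
                sc[~valid] = -np.inf
                w = int(np.argmax(sc))
                if sc[w] > best[0]:
                    best = (float(sc[w]), w, strand)
            if best[0] >= motif.threshold:
                found = True
                s, w, strand = best
                qs = w if strand == "+" else codes.size - w - L
                hits.append(sRNAHit(read.id, motif.family_id, s, qs, qs + L, strand))
        n_with += found
    frac = n_with / len(reads) if reads else 0.0
    return hits, frac


def srna_family_counts(hits: list[sRNAHit]) -> pd.Series:
    """Reads per sRNA family (a read may support several families)."""
    s: dict[str, int] = {}
    for h in hits:
        s[h.family_id] = s.get(h.family_id, 0) + 1
    return pd.Series(s, dtype=np.int64).sort_index()


# --- fraction accounting -------------------------------------------------

@dataclass
class FractionAccounting:
    """Four-way partition of the non-rRNA fraction, plus the sRNA share.

    Counts and percentages (over the non-rRNA total) for protein-coding ×
    contig-mapped status; ``srna_fraction`` is the share of the
    uncharacterized reads with an sRNA motif hit.
    """
    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    srna_in_uncharacterized: int = 0
    srna_fraction: float = 0.0

    CELLS = ("protein_mapped", "protein_unmapped",
             "uncharacterized_mapped", "uncharacterized_unmapped")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": pd.Series(self.counts),
                             "percent": pd.Series(self.percentages)})


def fraction_accounting(non_rrna_reads: list[Read],
                        protein_read_ids: set[str],
                        mapped_read_ids: set[str],
                        srna_read_ids: set[str]) -> FractionAccounting:
    """Cross the protein-coding call with contig mapping over one read
    universe; percentages are over the non-rRNA total.

    ``srna_read_ids`` must be a subset of the uncharacterized reads (the
    scan's input universe); inconsistent universes raise.
    """
    universe = {r.id for r in non_rrna_reads}
    for name, ids in (("protein", protein_read_ids), ("mapped", mapped_read_ids),
                      ("sRNA", srna_read_ids)):
        if not ids <= universe:
            raise ValueError(f"{name} read ids outside the non-rRNA universe")
    unchar = universe - protein_read_ids
    if not srna_read_ids <= unchar:
        raise ValueError("sRNA hits must come from the uncharacterized fraction")
    total = len(universe)
    acc = FractionAccounting()
    acc.counts = {
        "protein_mapped": len(protein_read_ids & mapped_read_ids),
        "protein_unmapped": len(protein_read_ids - mapped_read_ids),
        "uncharacterized_mapped": len(unchar & mapped_read_ids),
        "uncharacterized_unmapped": len(unchar - mapped_read_ids),
    }
    acc.percentages = {k: 100.0 * v / total if total else 0.0
                       for k, v in acc.counts.items()}
    acc.srna_in_uncharacterized = len(srna_read_ids)
    acc.srna_fraction = len(srna_read_ids) / len(unchar) if unchar else 0.0
    return acc
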