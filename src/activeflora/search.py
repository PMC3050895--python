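"""Self-contained homology search with Karlin–Altschul statistics.

Seed-and-extend, ungapped: exact k-mer seeds are grouped by diagonal and
extended in both directions with an X-drop rule; hit significance uses the
gapless Karlin–Altschul E-value E = K·m·n·e^(−λS), for which the theory is
exact, so E-value thresholds carry their textbook meaning.  Nucleotide
search scans both strands of the query; translated search runs all six
reading frames against a protein index.  This one engine stands in for
BLASTN/BLASTX/BLAT wherever the pipeline needs similarity search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sequtils import (
    AA_ALPHABET,
    encode_aa,
    encode_nt,
    kmer_codes,
    revcomp_codes,
    six_frame_peptides,
)


class InvalidScheme(ValueError):
    """Scoring scheme admits no positive Karlin lambda."""


@dataclass
class ScoringScheme:
    """Substitution scores, background frequencies and Karlin parameters.

    ``matrix`` is an integer substitution matrix over the coding alphabet
    (4 letters for nucleotides, 20 for amino acids).  The expected
    per-letter score under ``background`` must be negative and the maximum
    score positive, otherwise no positive λ solves
    Σ_ij p_i p_j e^(λ s_ij) = 1.  K defaults to the conventional gapless
    approximation value 0.1 and may be overridden.
    """
    alphabet: str                      # "nt" or "aa"
    matrix: np.ndarray
    background: np.ndarray
    gap_open: int = 0                  # reserved for a future gapped mode
    gap_extend: int = 0
    K: float = 0.1
    _lambda: float | None = field(default=None, repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int32)
        self.background = np.asarray(self.background, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or self.background.shape != (n,):
            raise ValueError("matrix/background shape mismatch")

    @property
    def expected_score(self) -> float:
        p = self.background
        return float(p @ self.matrix @ p)

    @property
    def lam(self) -> float:
        if self._lambda is None:
            self._lambda = karlin_lambda(self)
        return self._lambda

    @classmethod
    def nucleotide(cls, match: int = 1, mismatch: int = -2, K: float = 0.1) -> "ScoringScheme":
        m = np.full((4, 4), mismatch, dtype=np.int32)
        np.fill_diagonal(m, match)
        return cls("nt", m, np.full(4, 0.25), K=K)

    @classmethod
    def protein_blosum62(cls, K: float = 0.1) -> "ScoringScheme":
        from Bio.Align import substitution_matrices
        b = substitution_matrices.load("BLOSUM62")
        order = [b.alphabet.index(a) for a in AA_ALPHABET]
        m = np.asarray(b)[np.ix_(order, order)].astype(np.int32)
        return cls("aa", m, np.full(20, 0.05), K=K)


def karlin_lambda(scheme: ScoringScheme, tol: float = 1e-12) -> float:
    """Unique positive root of Σ_ij p_i p_j e^(λ s_ij) = 1, by bisection.

    λ = 0 is always a root; the positive root exists iff the expected score
    is negative and the maximum score positive.
    """
    if scheme.expected_score >= 0:
        raise InvalidScheme("expected per-letter score must be negative")
    if scheme.matrix.max() <= 0:
        raise InvalidScheme("maximum score must be positive")
    p = scheme.background
    outer = np.outer(p, p)
    s = scheme.matrix.astype(float)

    def f(lam: float) -> float:
        return float((outer * np.exp(lam * s)).sum()) - 1.0

    hi = 1.0
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 2.0
    else:  # pragma: no cover
        raise InvalidScheme("no finite positive root")
    lo = 1e-12
    fx = f(lo)
    if fx > 0:  # pragma: no cover - f < 0 just right of zero when E[s] < 0
        raise InvalidScheme("scheme degenerate near zero")
    for _ in range(500):
        mid = 0.5 * (lo + hi)
        fx = f(mid)
        if abs(fx) < tol:
            return mid
        if fx < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def evalue(S: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin–Altschul expectation E = K·m·n·e^(−λS)."""
    if S < 0 or m < 0 or n < 0:
        raise ValueError("S, m, n must be >= 0")
    return scheme.K * m * n * math.exp(-scheme.lam * S)


@dataclass
class AlignmentHit:
    """One ungapped local alignment.

    Coordinates are 0-based half-open on the forward strand of both
    sequences; for translated hits the query interval is in nucleotide
    coordinates of the read and ``frame`` is in {±1, ±2, ±3} (0 for plain
    nucleotide search).
    """
    query_id: str
    subject_id: str
    score: int
    evalue: float
    identity: float                    # percent, 0..100
    length: int                        # alignment columns
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str = "+"
    frame: int = 0


class SeedIndex:
    """Exact k-mer inverted index over a sequence collection.

    Forward k-mer positions are stored once; reverse-strand matches are
    found by scanning the reverse complement of the query, which is
    equivalent to indexing both strands.  ``entries()`` exposes the
    (subject, position) pairs per k-mer for set-level reasoning.
    """

    def __init__(self, records: list[tuple[str, str]], k: int, alphabet: str = "nt"):
        if k < 4:
            raise ValueError("k must be >= 4")
        if not records:
            raise ValueError("empty reference collection")
        self.k = k
        self.alphabet = alphabet
        self.alphabet_size = 4 if alphabet == "nt" else 20
        enc = encode_nt if alphabet == "nt" else encode_aa
        self.ids = [rid for rid, _ in records]
        self.seqs = [enc(seq) for _, seq in records]
        if any(s.size == 0 for s in self.seqs):
            raise ValueError("empty reference sequence")
        self.total_letters = int(sum(s.size for s in self.seqs))

        kmers, refidx, pos = [], [], []
        for i, s in enumerate(self.seqs):
            kc, valid = kmer_codes(s, k, self.alphabet_size)
            idx = np.flatnonzero(valid)
            kmers.append(kc[idx])
            refidx.append(np.full(idx.size, i, dtype=np.int64))
            pos.append(idx.astype(np.int64))
        km = np.concatenate(kmers) if kmers else np.empty(0, dtype=np.int64)
        if km.size == 0:
            import warnings
            warnings.warn("k longer than every reference: index is empty")
        ri = np.concatenate(refidx)
        po = np.concatenate(pos)
        order = np.lexsort((po, ri, km))
        self._kmers_sorted = km[order]
        self._ref_sorted = ri[order]
        self._pos_sorted = po[order]
        self._unique, self._starts = np.unique(self._kmers_sorted, return_index=True)
        self._ends = np.append(self._starts[1:], self._kmers_sorted.size)

    def n_kmers(self) -> int:
        return int(self._kmers_sorted.size)

    def entries(self) -> set[tuple[str, int, int]]:
        """All (subject id, position, kmer code) triples in the index."""
        return {(self.ids[r], int(p), int(c))
                for r, p, c in zip(self._ref_sorted, self._pos_sorted, self._kmers_sorted)}

    def lookup(self, qkmers: np.ndarray, qvalid: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Seed matches for an array of query k-mer codes.

        Returns ``(qpos, ref_idx, rpos)`` arrays over all seed matches.
        """
        if self._unique.size == 0 or qkmers.size == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z, z
        loc = np.searchsorted(self._unique, qkmers)
        loc_c = np.minimum(loc, self._unique.size - 1)
        ok = qvalid & (self._unique[loc_c] == qkmers)
        qpos_sel = np.flatnonzero(ok)
        if qpos_sel.size == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z, z
        u = loc_c[qpos_sel]
        starts = self._starts[u]
        counts = self._ends[u] - starts
        total = int(counts.sum())
        gather = np.repeat(starts, counts) + (np.arange(total)
                                              - np.repeat(np.cumsum(counts) - counts, counts))
        qpos = np.repeat(qpos_sel, counts)
        return qpos, self._ref_sorted[gather], self._pos_sorted[gather]


def build_index(records: list[tuple[str, str]], k: int, alphabet: str = "nt") -> SeedIndex:
    """Build an exact k-mer seed index (see SeedIndex)."""
    return SeedIndex(records, k, alphabet)


# --- extension -----------------------------------------------------------

def _xdrop_best(scores: np.ndarray, xdrop: int) -> tuple[int, int]:
    """Best prefix sum of an extension score array under the X-drop rule.

    Scanning stops at the first position where the running score falls more
    than ``xdrop`` below its running maximum; returns (best_sum, length).
    """
    if scores.size == 0:
        return 0, 0
    c = np.cumsum(scores, dtype=np.int64)
    peak = np.maximum.accumulate(c)
    bad = (peak - c) > xdrop
    if bad.any():
        c = c[: int(np.argmax(bad))]
    if c.size == 0:
        return 0, 0
    i = int(np.argmax(c))
    if c[i] <= 0:
        return 0, 0
    return int(c[i]), i + 1


def _extend_seed(qc: np.ndarray, sc: np.ndarray, qpos: int, rpos: int, k: int,
                 matrix: np.ndarray, xdrop: int) -> tuple[int, int, int, int, int, int]:
    """Ungapped X-drop extension of an exact seed on its diagonal.

    Returns (score, qstart, qend, sstart, send, n_identical).
    """
    word = qc[qpos: qpos + k].astype(np.int64)
    score = int(matrix[word, word].sum())  # seed is an exact match
    n_id = k
    # left
    lmax = min(qpos, rpos)
    if lmax > 0:
        ql = qc[qpos - lmax: qpos][::-1].astype(np.int64)
        sl = sc[rpos - lmax: rpos][::-1].astype(np.int64)
        s, ln = _xdrop_best(matrix[ql, sl], xdrop)
        score += s
        n_id += int((ql[:ln] == sl[:ln]).sum())
        left = ln
    else:
        left = 0
    # right
    rmax = min(qc.size - (qpos + k), sc.size - (rpos + k))
    if rmax > 0:
        qr = qc[qpos + k: qpos + k + rmax].astype(np.int64)
        sr = sc[rpos + k: rpos + k + rmax].astype(np.int64)
        s, ln = _xdrop_best(matrix[qr, sr], xdrop)
        score += s
        n_id += int((qr[:ln] == sr[:ln]).sum())
        right = ln
    else:
        right = 0
    return (score, qpos - left, qpos + k + right, rpos - left, rpos + k + right, n_id)


def _search_one_strand(qc: np.ndarray, index: SeedIndex, matrix: np.ndarray,
                       xdrop: int, max_diagonals: int, min_seeds: int):
    """Candidate (score, ref, intervals, n_id) tuples for one query orientation."""
    qk, qv = kmer_codes(qc, index.k, index.alphabet_size)
    qpos, ref, rpos = index.lookup(qk, qv)
    if qpos.size == 0:
        return []
    span = qc.size + max(s.size for s in index.seqs)
    key = ref * 2 * span + (rpos - qpos + qc.size)
    uniq, first, counts = np.unique(key, return_index=True, return_counts=True)
    keep = counts >= min_seeds
    first, counts = first[keep], counts[keep]
    if first.size > max_diagonals:
        top = np.argsort(-counts, kind="stable")[:max_diagonals]
        first = first[top]
    out = []
    for fi in first:
        r = int(ref[fi])
        out.append((_extend_seed(qc, index.seqs[r], int(qpos[fi]), int(rpos[fi]),
                                 index.k, matrix, xdrop), r))
    return out


def _merge_and_rank(raw_hits: list[AlignmentHit], max_e: float) -> list[AlignmentHit]:
    """Drop duplicates/overlaps (same subject+strand, both intervals overlap),
    keep the higher score, filter by E and rank deterministically."""
    raw_hits.sort(key=lambda h: (-h.score, h.subject_id, h.strand, h.qstart))
    kept: list[AlignmentHit] = []
    for h in raw_hits:
        redundant = False
        for g in kept:
            if (g.subject_id == h.subject_id and g.strand == h.strand
                    and g.frame == h.frame
                    and h.qstart < g.qend and g.qstart < h.qend
                    and h.sstart < g.send and g.sstart < h.send):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return [h for h in kept if h.evalue <= max_e]


def search(query, index: SeedIndex, scheme: ScoringScheme, max_e: float = 10.0,
           xdrop: int = 20, max_diagonals: int = 32, min_seeds: int = 1
           ) -> list[AlignmentHit]:
    """Nucleotide search of a read against an indexed reference collection.

    Both strands are scanned; exact k-mer seeds are grouped by diagonal,
    the densest diagonals extended ungapped with X-drop ``xdrop``, and hits
    with E ≤ ``max_e`` returned sorted by descending score with ties broken
    by subject id.  ``query`` may be a string or any object with ``id`` and
    ``seq`` attributes.
    """
    qid, seq = (query.id, query.seq) if hasattr(query, "seq") else ("query", query)
    if len(seq) == 0:
        raise ValueError("empty query")
    qc = encode_nt(seq)
    return _search_codes(qid, qc, index, scheme, max_e, xdrop, max_diagonals, min_seeds)


def _search_codes(qid: str, qc: np.ndarray, index: SeedIndex, scheme: ScoringScheme,
                  max_e: float, xdrop: int, max_diagonals: int, min_seeds: int
                  ) -> list[AlignmentHit]:
    m = qc.size
    n = index.total_letters
    lam, K = scheme.lam, scheme.K
    raw: list[AlignmentHit] = []
    for strand, codes in (("+", qc), ("-", revcomp_codes(qc))):
        for (score, qs, qe, ss, se, nid), r in _search_one_strand(
                codes, index, scheme.matrix, xdrop, max_diagonals, min_seeds):
            if strand == "-":
                qs, qe = m - qe, m - qs
            e = K * m * n * math.exp(-lam * score)
            length = qe - qs
            raw.append(AlignmentHit(qid, index.ids[r], score, e,
                                    100.0 * nid / length, length,
                                    qs, qe, ss, se, strand=strand))
    return _merge_and_rank(raw, max_e)


def translated_search(query, protein_index: SeedIndex, scheme: ScoringScheme,
                      max_e: float = 1e-3, xdrop: int = 20, max_diagonals: int = 32,
                      min_seeds: int = 1) -> list[AlignmentHit]:
    """Six-frame translated search of a nucleotide read against proteins.

    Each frame is translated with the standard genetic code, split at stop
    codons, and every peptide searched as in :func:`search`.  The reported
    query interval is mapped back to nucleotide coordinates on the forward
    strand of the read; ``m`` in the E-value is the peptide length.
    """
    qid, seq = (query.id, query.seq) if hasattr(query, "seq") else ("query", query)
    if len(seq) == 0:
        raise ValueError("empty query")
    qc = encode_nt(seq)
    if qc.size < 3 * protein_index.k:
        return []
    lam, K = scheme.lam, scheme.K
    n = protein_index.total_letters
    raw: list[AlignmentHit] = []
    for frame, aa_off, pep in six_frame_peptides(qc):
        if pep.size < protein_index.k:
            continue
        for (score, qs, qe, ss, se, nid), r in _search_one_strand(
                pep, protein_index, scheme.matrix, xdrop, max_diagonals, min_seeds):
            e = K * pep.size * n * math.exp(-lam * score)
            length = qe - qs
            # peptide -> nucleotide coordinates on the read's forward strand
            nt_s = (abs(frame) - 1) + 3 * (aa_off + qs)
            nt_e = (abs(frame) - 1) + 3 * (aa_off + qe)
            if frame < 0:
                nt_s, nt_e = qc.size - nt_e, qc.size - nt_s
            raw.append(AlignmentHit(qid, protein_index.ids[r], score, e,
                                    100.0 * nid / length, length,
                                    nt_s, nt_e, ss, se,
                                    strand="+" if frame > 0 else "-", frame=frame))
    return _merge_and_rank(raw, max_e)


def map_to_contigs(query, contig_index: SeedIndex, scheme: ScoringScheme | None = None,
                   min_fraction: float = 0.8, min_identity: float = 0.9
                   ) -> tuple[bool, AlignmentHit | None]:
    """BLAT-style contig mapping criterion.

    A read is mapped iff some hit aligns at least ``min_fraction`` of the
    read length (the maximum possible alignment is taken to be the query
    length) at identity ≥ ``min_identity``.  Returns the mapped flag
    and the best qualifying hit (or the best hit overall when unmapped).
    """
    if scheme is None:
        scheme = ScoringScheme.nucleotide()
    hits = search(query, contig_index, scheme, max_e=10.0)
    seq = query.seq if hasattr(query, "seq") else query
    qlen = len(seq)
    for h in hits:  # already ranked by score
        if h.length >= min_fraction * qlen and h.identity >= 100.0 * min_identity:
            return True, h
    return False, (hits[0] if hits else None)


def write_outfmt6(hits: list[AlignmentHit], path, scheme: ScoringScheme | None = None) -> None:
    """Write hits as 12-column BLAST outfmt-6 records (1-based inclusive
    coordinates, subject interval reversed on the minus strand).  The last
    column is the bit score (λS − ln K)/ln 2 when a scheme is given, else
    the raw score."""
    with open(path, "w") as fh:
        for h in hits:
            mism = round(h.length * (1.0 - h.identity / 100.0))
            ss, se = (h.send, h.sstart + 1) if h.strand == "-" else (h.sstart + 1, h.send)
            if scheme is not None:
                bits = f"{(scheme.lam * h.score - math.log(scheme.K)) / math.log(2):.1f}"
            else:
                bits = str(h.score)
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, f"{h.identity:.2f}", h.length, mism, 0,
                h.qstart + 1, h.qend, ss, se, f"{h.evalue:.2e}", bits])) + "\n")
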