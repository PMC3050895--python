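"""Step-wise rRNA/mRNA read sorting and E-value threshold calibration.

Reads shorter than 60 bp are dropped; the remainder is compared first to
the SSU rRNA database (default E ≤ 1e-16), then — if unassigned — to the
LSU database (default E ≤ 1e-4); what is left is the putative mRNA /
non-rRNA fraction.  The calibration sweep rebuilds the published
threshold-selection experiment: known 100 bp fragments of each RNA class
are scored against both databases across an E-value grid and the
thresholds with the lowest cross-contamination are selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .refsim import Read, ReferenceSet
from .search import ScoringScheme, SeedIndex, search
from .sequtils import decode_nt, encode_aa, encode_nt, mutate_codes, reverse_translate

TRIAGE_CLASSES = ("too_short", "SSU_prok", "SSU_euk", "LSU", "non_rRNA")


@dataclass
class rRNADatabase:
    """A nucleotide reference database: seed index plus per-record lineage."""
    index: SeedIndex
    scheme: ScoringScheme
    lineage: dict[str, str]

    @classmethod
    def from_records(cls, records: list, tree, k: int = 11,
                     scheme: ScoringScheme | None = None) -> "rRNADatabase":
        if scheme is None:
            scheme = ScoringScheme.nucleotide()
        idx = SeedIndex([(r.id, r.seq) for r in records], k=k, alphabet="nt")
        lin = {r.id: tree.lineage_string(r.node) for r in records}
        return cls(idx, scheme, lin)

    def domain_of(self, subject_id: str) -> str:
        return self.lineage.get(subject_id, "").split(";")[0]


@dataclass
class ReadPartition:
    """Per-read triage class and the per-sample count table.

    ``table`` rows are total (retained, ≥ min length), SSU (prokaryotic),
    SSU_euk, LSU and non_rRNA; columns are samples.  Classes are mutually
    exclusive and exhaustive, so per sample
    SSU + SSU_euk + LSU + non_rRNA = total.
    """
    classes: dict[str, str]
    table: pd.DataFrame
    dropped: int = 0

    def check_conservation(self) -> bool:
        t = self.table
        parts = t.loc[["SSU", "SSU_euk", "LSU", "non_rRNA"]].sum(axis=0)
        return bool((parts == t.loc["total"]).all())


def length_filter(reads: list[Read], min_len: int = 60) -> tuple[list[Read], int]:
    """Retain reads of length ≥ ``min_len`` (order preserved), count the rest."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in reads if len(r) >= min_len]
    return kept, len(reads) - len(kept)


def _flatten(reads) -> list[Read]:
    if isinstance(reads, dict):
        out = []
        for sample in reads:
            out.extend(reads[sample])
        return out
    return list(reads)


def stepwise_triage(reads, ssu_db: rRNADatabase, lsu_db: rRNADatabase,
                    e_ssu: float = 1e-16, e_lsu: float = 1e-4,
                    min_len: int = 60, max_diagonals: int = 8,
                    min_seeds: int = 2) -> ReadPartition:
    """Classify length-filtered reads as SSU, LSU or non-rRNA, in that order.

    A read is SSU if any SSU-database hit reaches E ≤ ``e_ssu`` (sub-classed
    prokaryotic/eukaryotic by the best hit's domain), else LSU if any LSU
    hit reaches E ≤ ``e_lsu``, else non-rRNA.  Reads below ``min_len``
    violate the precondition (they belong upstream, in the length filter).
    """
    flat = _flatten(reads)
    if any(len(r) < min_len for r in flat):
        raise ValueError(f"reads shorter than {min_len} bp present; "
                         "apply length_filter first")
    classes: dict[str, str] = {}
    samples: list[str] = []
    counts: dict[str, dict[str, int]] = {}
    for read in flat:
        if read.sample not in counts:
            samples.append(read.sample)
            counts[read.sample] = {c: 0 for c in TRIAGE_CLASSES[1:]}
        hits = search(read, ssu_db.index, ssu_db.scheme, max_e=e_ssu,
                      max_diagonals=max_diagonals, min_seeds=min_seeds)
        if hits:
            dom = ssu_db.domain_of(hits[0].subject_id)
            cls = "SSU_euk" if dom == "Eukaryota" else "SSU_prok"
        else:
            hits = search(read, lsu_db.index, lsu_db.scheme, max_e=e_lsu,
                          max_diagonals=max_diagonals, min_seeds=min_seeds)
            cls = "LSU" if hits else "non_rRNA"
        classes[read.id] = cls
        counts[read.sample][cls] += 1
    rows = {"total": [sum(counts[s].values()) for s in samples],
            "SSU": [counts[s]["SSU_prok"] for s in samples],
            "SSU_euk": [counts[s]["SSU_euk"] for s in samples],
            "LSU": [counts[s]["LSU"] for s in samples],
            "non_rRNA": [counts[s]["non_rRNA"] for s in samples]}
    table = pd.DataFrame(rows, index=samples).T
    return ReadPartition(classes, table)


def triage_reads(reads, ssu_db: rRNADatabase, lsu_db: rRNADatabase,
                 e_ssu: float = 1e-16, e_lsu: float = 1e-4,
                 min_len: int = 60, **kw) -> ReadPartition:
    """Length filter followed by step-wise triage; dropped reads are
    recorded with class ``too_short``."""
    flat = _flatten(reads)
    kept, dropped = length_filter(flat, min_len)
    part = stepwise_triage(kept, ssu_db, lsu_db, e_ssu, e_lsu, min_len=min_len, **kw)
    for r in flat:
        if len(r) < min_len:
            part.classes[r.id] = "too_short"
    part.dropped = dropped
    return part


# --- calibration ---------------------------------------------------------

DEFAULT_EVALUE_GRID = (1e-30, 1e-24, 1e-20, 1e-16, 1e-12, 1e-8, 1e-4, 1e-2, 1.0)


@dataclass
class CalibrationReport:
    """Sweep results: per (database, threshold) sensitivity and
    cross-contamination, plus the selected threshold per database.

    Cross-contamination is the out-of-class acceptance rate averaged over
    the two foreign classes; selection is lexicographic — minimum
    contamination, then maximum sensitivity, then the smallest E-value.
    """
    table: pd.DataFrame
    selected: dict[str, float]
    n_per_class: dict[str, int]


def make_calibration_sets(refs: ReferenceSet, n_per_class: int = 1000,
                          frag_len: int = 100, seed: int = 0,
                          divergence: float = 0.0) -> dict[str, list[Read]]:
    """Labelled test fragments of the three RNA classes.

    ``n_per_class`` fragments of ``frag_len`` bp are cut at uniform random
    positions from the SSU, LSU and (reverse-translated) protein
    references.  ``divergence`` optionally substitutes each fragment
    position i.i.d. at that rate, emulating test sequences collected from
    organisms related, but not identical, to the database entries.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA11]))
    sources: dict[str, list[np.ndarray]] = {"SSU": [], "LSU": [], "mRNA": []}
    for r in refs.by_class("SSU"):
        sources["SSU"].append(encode_nt(r.seq))
    for r in refs.by_class("LSU"):
        sources["LSU"].append(encode_nt(r.seq))
    for r in sorted(refs.by_class("protein"), key=lambda x: x.id):
        if r.id in refs.cds:
            sources["mRNA"].append(encode_nt(refs.cds[r.id]))
        else:
            sources["mRNA"].append(reverse_translate(encode_aa(r.seq), rng))
    out: dict[str, list[Read]] = {}
    for cls, seqs in sources.items():
        eligible = [s for s in seqs if s.size >= frag_len]
        if not eligible:
            raise ValueError(f"no {cls} reference of length >= {frag_len}")
        frags = []
        src_idx = rng.integers(0, len(eligible), n_per_class)
        for i in range(n_per_class):
            s = eligible[src_idx[i]]
            start = int(rng.integers(0, s.size - frag_len + 1))
            frag = s[start: start + frag_len]
            if divergence > 0:
                frag = mutate_codes(frag, divergence, rng)
            frags.append(Read(f"cal_{cls}_{i:05d}", "cal", decode_nt(frag),
                              true_class=cls))
        out[cls] = frags
    return out


def plant_ssu_insertions(cal_sets: dict[str, list[Read]], refs: ReferenceSet,
                         fraction: float = 0.1, insert_len: int = 40,
                         seed: int = 0) -> dict[str, list[Read]]:
    """Contaminate a fraction of the mRNA test fragments with an SSU slice.

    Models chimeric/rRNA-carryover test sequences: in the selected mRNA
    fragments a window of ``insert_len`` bp is overwritten with an exact
    SSU database slice, so loose thresholds accept them as SSU.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x915]))
    ssu = [encode_nt(r.seq) for r in refs.by_class("SSU")]
    out = {c: list(v) for c, v in cal_sets.items()}
    mrna = out["mRNA"]
    n_plant = int(round(fraction * len(mrna)))
    which = rng.choice(len(mrna), size=n_plant, replace=False)
    for j in which:
        frag = encode_nt(mrna[j].seq)
        if frag.size < insert_len:
            continue
        src = ssu[int(rng.integers(0, len(ssu)))]
        s0 = int(rng.integers(0, src.size - insert_len + 1))
        at = int(rng.integers(0, frag.size - insert_len + 1))
        frag = frag.copy()
        frag[at: at + insert_len] = src[s0: s0 + insert_len]
        mrna[j] = Read(mrna[j].id, mrna[j].sample, decode_nt(frag), true_class="mRNA")
    return out


def _best_evalues(frags: list[Read], db: rRNADatabase, max_e: float) -> np.ndarray:
    out = np.full(len(frags), np.inf)
    for i, f in enumerate(frags):
        hits = search(f, db.index, db.scheme, max_e=max_e, max_diagonals=16)
        if hits:
            out[i] = min(h.evalue for h in hits)
    return out


def sweep_thresholds(cal_sets: dict[str, list[Read]], ssu_db: rRNADatabase,
                     lsu_db: rRNADatabase,
                     evalue_grid=DEFAULT_EVALUE_GRID) -> CalibrationReport:
    """Scan the E-value grid and select a threshold per database.

    For each grid value, sensitivity is the in-class acceptance rate and
    cross-contamination the out-of-class acceptance rate averaged over the
    two foreign classes; the selected threshold per database minimizes
    (contamination, −sensitivity, E) lexicographically.
    """
    grid = list(evalue_grid)
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("evalue grid must be non-empty and sorted ascending")
    classes = ("SSU", "LSU", "mRNA")
    max_e = max(grid)
    best = {("SSU", c): _best_evalues(cal_sets[c], ssu_db, max_e) for c in classes}
    best.update({("LSU", c): _best_evalues(cal_sets[c], lsu_db, max_e) for c in classes})

    rows = []
    selected: dict[str, float] = {}
    for db in ("SSU", "LSU"):
        foreign = [c for c in classes if c != db]
        ranking = []
        for t in grid:
            sens = float((best[(db, db)] <= t).mean())
            acc = {c: int((best[(db, c)] <= t).sum()) for c in classes}
            contam = float(np.mean([(best[(db, c)] <= t).mean() for c in foreign]))
            rows.append({"database": db, "threshold": t, "sensitivity": sens,
                         "contamination": contam,
                         **{f"accepted_{c}": acc[c] for c in classes}})
            ranking.append(((contam, -sens, t), t))
        selected[db] = min(ranking)[1]
    table = pd.DataFrame(rows)
    return CalibrationReport(table, selected,
                             {c: len(cal_sets[c]) for c in classes})
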