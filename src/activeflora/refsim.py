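"""Synthetic community, reference databases and labelled reads.

This module builds everything the analysis pipeline needs to be exercised
without external downloads: a rank-complete bacterial taxonomy, SSU/LSU
rRNA, COG-annotated protein and sRNA reference sets evolved along that
taxonomy, and per-sample cDNA reads with ground-truth labels.

The default read regime mirrors a 454 gut metatranscriptome: ~174 bp mean
length with a tail below the 60 bp analysis cutoff, an RNA pool dominated
by rRNA (SSU ~17 %, LSU several-fold SSU, non-rRNA ~7 %), mRNA fragments
drawn from COG-annotated proteins with a deliberately skewed category
profile (carbohydrate metabolism G over-expressed, lipid metabolism I
under-expressed), and a small sRNA fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .sequtils import (
    AA_ALPHABET,
    decode_aa,
    decode_nt,
    encode_aa,
    encode_nt,
    mutate_codes,
    reverse_translate,
    revcomp_codes,
)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: the 25 single-letter COG functional categories
COG_CATEGORIES = "JAKLBDYVTMNZWUOCGEFHIPQRS"

COG_CATEGORY_NAMES = {
    "J": "Translation, ribosomal structure and biogenesis",
    "A": "RNA processing and modification",
    "K": "Transcription",
    "L": "Replication, recombination and repair",
    "B": "Chromatin structure and dynamics",
    "D": "Cell cycle control, cell division, chromosome partitioning",
    "Y": "Nuclear structure",
    "V": "Defense mechanisms",
    "T": "Signal transduction mechanisms",
    "M": "Cell wall/membrane/envelope biogenesis",
    "N": "Cell motility",
    "Z": "Cytoskeleton",
    "W": "Extracellular structures",
    "U": "Intracellular trafficking, secretion, and vesicular transport",
    "O": "Posttranslational modification, protein turnover, chaperones",
    "C": "Energy production and conversion",
    "G": "Carbohydrate transport and metabolism",
    "E": "Amino acid transport and metabolism",
    "F": "Nucleotide transport and metabolism",
    "H": "Coenzyme transport and metabolism",
    "I": "Lipid transport and metabolism",
    "P": "Inorganic ion transport and metabolism",
    "Q": "Secondary metabolites biosynthesis, transport and catabolism",
    "R": "General function prediction only",
    "S": "Function unknown",
}


# --- taxonomy ------------------------------------------------------------

@dataclass(frozen=True)
class TaxNode:
    id: str
    name: str
    rank: str
    parent: str | None


class TaxonomyTree:
    """Rooted taxonomy with the fixed rank ladder domain..genus.

    The root is the single domain node; ranks strictly increase in depth
    along any root-to-leaf path and names are unique within a rank.
    """

    def __init__(self, nodes: list[TaxNode]):
        self.nodes: dict[str, TaxNode] = {n.id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise ValueError("duplicate node ids")
        roots = [n for n in nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = roots[0]
        self._children: dict[str, list[str]] = {n.id: [] for n in nodes}
        for n in nodes:
            if n.parent is not None:
                if n.parent not in self.nodes:
                    raise ValueError(f"parent {n.parent!r} of {n.id!r} missing")
                self._children[n.parent].append(n.id)
        self.validate()

    def __len__(self) -> int:
        return len(self.nodes)

    def children(self, node_id: str) -> list[str]:
        return list(self._children[node_id])

    def lineage(self, node_id: str) -> list[TaxNode]:
        """Nodes from the root down to ``node_id`` inclusive."""
        out = []
        cur: str | None = node_id
        while cur is not None:
            n = self.nodes[cur]
            out.append(n)
            cur = n.parent
        return out[::-1]

    def lineage_string(self, node_id: str) -> str:
        return ";".join(n.name for n in self.lineage(node_id))

    def ancestor_at_rank(self, node_id: str, rank: str) -> str | None:
        for n in self.lineage(node_id):
            if n.rank == rank:
                return n.id
        return None

    def nodes_at_rank(self, rank: str) -> list[str]:
        return sorted(n.id for n in self.nodes.values() if n.rank == rank)

    def lca(self, node_ids: list[str]) -> str:
        if not node_ids:
            raise ValueError("lca of empty set")
        paths = [[n.id for n in self.lineage(i)] for i in node_ids]
        lca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            step = {p[depth] for p in paths}
            if len(step) == 1:
                lca = step.pop()
            else:
                break
        return lca

    def validate(self) -> None:
        rank_depth = {r: i for i, r in enumerate(RANKS)}
        seen: dict[str, set[str]] = {r: set() for r in RANKS}
        for n in self.nodes.values():
            if n.rank not in rank_depth:
                raise ValueError(f"unknown rank {n.rank!r}")
            if n.name in seen[n.rank]:
                raise ValueError(f"duplicate name {n.name!r} within rank {n.rank}")
            seen[n.rank].add(n.name)
            if n.parent is not None:
                p = self.nodes[n.parent]
                if rank_depth[p.rank] >= rank_depth[n.rank]:
                    raise ValueError("ranks must strictly increase with depth")

    # -- writers --

    def to_parent_child_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tname\trank\tparent\n")
            for n in sorted(self.nodes.values(), key=lambda x: x.id):
                fh.write(f"{n.id}\t{n.name}\t{n.rank}\t{n.parent or ''}\n")

    def to_newick(self) -> str:
        def rec(node_id: str) -> str:
            kids = sorted(self._children[node_id])
            name = self.nodes[node_id].name
            if not kids:
                return name
            return "(" + ",".join(rec(k) for k in kids) + ")" + name
        return rec(self.root.id) + ";"


def build_taxonomy(n_phyla: int, families_per_phylum: int,
                   genera_per_family: int = 1, seed: int = 0) -> TaxonomyTree:
    """Build a complete rank ladder with one class/order lineage per phylum.

    Deterministic for fixed arguments; ``seed`` is accepted for interface
    symmetry with the other generators.
    """
    del seed
    if n_phyla < 1 or families_per_phylum < 1 or genera_per_family < 1:
        raise ValueError("counts must be >= 1")
    nodes = [TaxNode("Bacteria", "Bacteria", "domain", None)]
    for p in range(1, n_phyla + 1):
        nodes.append(TaxNode(f"Phylum{p:02d}", f"Phylum{p:02d}", "phylum", "Bacteria"))
        nodes.append(TaxNode(f"Class{p:02d}", f"Class{p:02d}", "class", f"Phylum{p:02d}"))
        nodes.append(TaxNode(f"Order{p:02d}", f"Order{p:02d}", "order", f"Class{p:02d}"))
        for f in range(1, families_per_phylum + 1):
            fam = f"Family{p:02d}_{f:02d}"
            nodes.append(TaxNode(fam, fam, "family", f"Order{p:02d}"))
            for g in range(1, genera_per_family + 1):
                gen = f"Genus{p:02d}_{f:02d}" if genera_per_family == 1 \
                    else f"Genus{p:02d}_{f:02d}_{g:02d}"
                nodes.append(TaxNode(gen, gen, "genus", fam))
    return TaxonomyTree(nodes)


# --- reference sets ------------------------------------------------------

@dataclass
class RefRecord:
    id: str
    seq: str
    cls: str                      # SSU | LSU | protein | sRNA
    node: str                     # taxonomy node id
    cog_id: str | None = None
    cog_category: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SubstitutionModel:
    """Per-branch substitution process used to evolve the references.

    ``branch_sub_prob`` is the per-position substitution probability on
    each branch of the rank ladder; conserved SSU positions substitute at
    ``branch_sub_prob * conserved_rate_factor``.  Values are bounded by
    0.75 (the saturation point of a 4-letter alphabet).
    """
    branch_sub_prob: float = 0.03
    conserved_rate_factor: float = 0.1
    conserved_fraction: float = 0.5
    conserved_block: int = 150
    ssu_len: int = 1500
    lsu_len: int = 2900
    protein_len: int = 250
    protein_branch_sub_prob: float = 0.03
    proteins_per_pair: int = 1
    n_srna_families: int = 8
    srna_len: int = 90

    def validate(self) -> None:
        for p in (self.branch_sub_prob, self.protein_branch_sub_prob):
            if not 0.0 <= p <= 0.75:
                raise ValueError("substitution probabilities must be in [0, 0.75]")
        if not 0.0 <= self.conserved_rate_factor <= 1.0:
            raise ValueError("conserved_rate_factor must be in [0, 1]")


@dataclass
class ReferenceSet:
    """Annotated SSU/LSU/protein/sRNA sequence collections over a taxonomy.

    ``cds`` holds the genomic coding sequence of every protein record: one
    fixed (seeded, uniform-codon) nucleotide realization per protein, the
    sequence that both mRNA reads and metagenome contigs derive from.
    """
    records: list[RefRecord]
    tree: TaxonomyTree
    ssu_conserved_mask: np.ndarray | None = None
    cds: dict[str, str] = field(default_factory=dict)

    def by_class(self, cls: str) -> list[RefRecord]:
        return [r for r in self.records if r.cls == cls]

    def record(self, rec_id: str) -> RefRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def taxon_of(self) -> dict[str, str]:
        return {r.id: r.node for r in self.records}

    def lineage_of(self) -> dict[str, str]:
        return {r.id: self.tree.lineage_string(r.node) for r in self.records}

    def validate(self) -> None:
        for r in self.records:
            if r.node not in self.tree.nodes:
                raise ValueError(f"record {r.id}: unknown taxonomy node {r.node}")
            if r.cls == "protein":
                bad = set(r.seq) - set(AA_ALPHABET)
                if bad:
                    raise ValueError(f"protein record {r.id} has invalid residues {bad}")

    # -- writers --

    def write_fasta(self, path: str | Path, classes: tuple[str, ...] | None = None) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        recs = [SeqRecord(Seq(r.seq), id=r.id, description=r.cls)
                for r in self.records
                if classes is None or r.cls in classes]
        SeqIO.write(recs, str(path), "fasta")

    def write_sidecar_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tclass\tlineage\tcog_id\tcog_category\n")
            for r in self.records:
                lin = self.tree.lineage_string(r.node)
                fh.write(f"{r.id}\t{r.cls}\t{lin}\t{r.cog_id or ''}\t{r.cog_category or ''}\n")


def conserved_mask(length: int, fraction: float, block: int) -> np.ndarray:
    """Alternating conserved/variable blocks covering ``fraction`` of positions."""
    mask = np.zeros(length, dtype=bool)
    pos = 0
    conserved_len = int(round(block * fraction / (1.0 - fraction))) if fraction < 1 else length
    while pos < length:
        mask[pos: pos + conserved_len] = True
        pos += conserved_len + block
    return mask


def evolve_references(tree: TaxonomyTree, model: SubstitutionModel | None = None,
                      seed: int = 0) -> ReferenceSet:
    """Evolve one SSU and one LSU per genus plus COG proteins and sRNA motifs.

    Each class starts from an i.i.d.-uniform ancestral sequence at the root
    and accumulates substitutions independently on every branch, so related
    genera share more sequence than distant ones.  Conserved SSU regions
    substitute at a reduced rate, mimicking the conserved/variable block
    structure of real 16S genes.  Proteins are orthologous families: one
    ancestral protein per (COG id) evolved down to every genus.
    """
    if model is None:
        model = SubstitutionModel()
    model.validate()
    if len(tree) == 0:
        raise ValueError("empty tree")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11CE]))

    mask = conserved_mask(model.ssu_len, model.conserved_fraction, model.conserved_block)
    p_ssu = np.where(mask, model.branch_sub_prob * model.conserved_rate_factor,
                     model.branch_sub_prob)

    # ancestral sequences
    anc: dict[str, np.ndarray] = {
        "SSU": rng.integers(0, 4, model.ssu_len).astype(np.uint8),
        "LSU": rng.integers(0, 4, model.lsu_len).astype(np.uint8),
    }
    cog_ids = [f"COG{cat}{slot:02d}" for cat in COG_CATEGORIES
               for slot in range(model.proteins_per_pair)]
    anc_prot = {cid: rng.integers(0, 20, model.protein_len).astype(np.uint8)
                for cid in cog_ids}

    records: list[RefRecord] = []

    def descend(node_id: str, seqs: dict[str, np.ndarray],
                prots: dict[str, np.ndarray]) -> None:
        node = tree.nodes[node_id]
        if node.parent is not None:  # mutate along the incoming branch
            seqs = {
                "SSU": mutate_codes(seqs["SSU"], p_ssu, rng),
                "LSU": mutate_codes(seqs["LSU"], model.branch_sub_prob, rng),
            }
            prots = {cid: mutate_codes(p, model.protein_branch_sub_prob, rng,
                                       alphabet_size=20)
                     for cid, p in prots.items()}
        if node.rank == "genus":
            records.append(RefRecord(f"SSU|{node_id}", decode_nt(seqs["SSU"]),
                                     "SSU", node_id))
            records.append(RefRecord(f"LSU|{node_id}", decode_nt(seqs["LSU"]),
                                     "LSU", node_id))
            for cid in cog_ids:
                records.append(RefRecord(f"{cid}|{node_id}", decode_aa(prots[cid]),
                                         "protein", node_id, cog_id=cid,
                                         cog_category=cid[3]))
        else:
            for child in sorted(tree.children(node_id)):
                descend(child, seqs, prots)

    descend(tree.root.id, anc, anc_prot)

    for i in range(model.n_srna_families):
        s = rng.integers(0, 4, model.srna_len).astype(np.uint8)
        records.append(RefRecord(f"sRNA{i:02d}", decode_nt(s), "sRNA", tree.root.id))

    cds = {r.id: decode_nt(reverse_translate(encode_aa(r.seq), rng))
           for r in records if r.cls == "protein"}
    refs = ReferenceSet(records, tree, ssu_conserved_mask=mask, cds=cds)
    refs.validate()
    return refs


# --- community spec and read simulation ----------------------------------

DEFAULT_SAMPLE_NAMES = ("A", "B", "C", "D", "E", "F", "K", "L", "N", "O")

DEFAULT_CLASS_MIXTURE = {"SSU": 0.172, "LSU": 0.755, "mRNA": 0.063, "sRNA": 0.010}


def default_cog_profile() -> dict[str, float]:
    """Category expression skew: G at twice and I at half the database share."""
    base = 1.0 / len(COG_CATEGORIES)
    prof = {c: base for c in COG_CATEGORIES}
    prof["G"] = 2.0 * base
    prof["I"] = 0.5 * base
    rest = 1.0 - prof["G"] - prof["I"]
    others = [c for c in COG_CATEGORIES if c not in "GI"]
    for c in others:
        prof[c] = rest / len(others)
    return prof


@dataclass
class CommunitySpec:
    """Statistical law of the simulated community.

    ``family_base_weights`` (geometric decay by default) times
    ``dirichlet_concentration`` gives the per-family Dirichlet
    concentration; one Dirichlet draw is made per sample, so family
    abundances vary between samples around a common profile, while the
    class mixture and the COG expression profile are fixed across samples.
    """
    n_samples: int = 10
    reads_per_sample: int = 20000
    dirichlet_concentration: float = 30.0
    family_decay: float = 0.75
    family_weights: dict[str, float] | None = None
    class_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE))
    cog_profile: dict[str, float] = field(default_factory=default_cog_profile)
    length_mean: float = 174.0
    length_sd: float = 80.0
    length_min: int = 30
    length_max: int = 1000
    error_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.reads_per_sample < 0 or self.n_samples < 0:
            raise ValueError("read budget and sample count must be >= 0")
        for name, mix in (("class_mixture", self.class_mixture),
                          ("cog_profile", self.cog_profile)):
            vals = np.array(list(mix.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"{name} fractions must be in [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.length_min < 1 or self.length_max < self.length_min:
            raise ValueError("invalid length bounds")

    def sample_names(self) -> list[str]:
        names = list(DEFAULT_SAMPLE_NAMES)
        while len(names) < self.n_samples:
            names.append(f"S{len(names) + 1:02d}")
        return names[: self.n_samples]

    def family_alphas(self, families: list[str]) -> np.ndarray:
        if self.family_weights is not None:
            w = np.array([self.family_weights[f] for f in families], dtype=float)
        else:
            w = self.family_decay ** np.arange(len(families), dtype=float)
        w = w / w.sum()
        return w * self.dirichlet_concentration

    # -- serialization --

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "CommunitySpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


@dataclass
class Read:
    """One cDNA fragment, optionally with ground-truth labels."""
    id: str
    sample: str
    seq: str
    true_class: str | None = None
    true_node: str | None = None
    true_cog: str | None = None
    true_cog_category: str | None = None
    source_ref: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


def _draw_lengths(rng: np.random.Generator, n: int, spec: CommunitySpec) -> np.ndarray:
    """Discretized normal truncated to [length_min, length_max] by redraw."""
    out = np.rint(rng.normal(spec.length_mean, spec.length_sd, n)).astype(np.int64)
    bad = (out < spec.length_min) | (out > spec.length_max)
    while bad.any():
        out[bad] = np.rint(rng.normal(spec.length_mean, spec.length_sd,
                                      int(bad.sum()))).astype(np.int64)
        bad = (out < spec.length_min) | (out > spec.length_max)
    return out


def simulate_reads(spec: CommunitySpec, refs: ReferenceSet,
                   tree: TaxonomyTree) -> dict[str, list[Read]]:
    """Simulate labelled reads for every sample.

    Per read: family from the sample's Dirichlet-realized abundances, class
    from the fixed mixture, then a uniformly placed substring of a reference
    of that family and class.  mRNA reads are reverse-translated protein
    fragments (uniform codon usage) taken at a uniform nucleotide offset,
    so strand and frame are random; i.i.d. substitution errors are applied
    last.  Deterministic for a fixed spec seed.
    """
    spec.validate()
    families = sorted({tree.nodes[r.node].parent for r in refs.by_class("SSU")})
    if not families:
        raise ValueError("reference set has no SSU records")
    alphas = spec.family_alphas(families)

    genera_by_family: dict[str, list[str]] = {f: [] for f in families}
    ssu_by_genus: dict[str, RefRecord] = {}
    lsu_by_genus: dict[str, RefRecord] = {}
    for r in refs.by_class("SSU"):
        fam = tree.nodes[r.node].parent
        genera_by_family[fam].append(r.node)
        ssu_by_genus[r.node] = r
    for fam in genera_by_family:
        genera_by_family[fam].sort()
    for r in refs.by_class("LSU"):
        lsu_by_genus[r.node] = r
    prot_by_genus_cat: dict[tuple[str, str], list[RefRecord]] = {}
    for r in refs.by_class("protein"):
        prot_by_genus_cat.setdefault((r.node, r.cog_category), []).append(r)
    for v in prot_by_genus_cat.values():
        v.sort(key=lambda r: r.id)
    srna_records = sorted(refs.by_class("sRNA"), key=lambda r: r.id)

    class_names = sorted(spec.class_mixture)
    class_p = np.array([spec.class_mixture[c] for c in class_names])
    cats = sorted(spec.cog_profile)
    cat_p = np.array([spec.cog_profile[c] for c in cats])

    nt_cache = {r.id: encode_nt(r.seq) for r in refs.records if r.cls != "protein"}
    cds_cache = {rid: encode_nt(s) for rid, s in refs.cds.items()}

    out: dict[str, list[Read]] = {}
    for s_idx, sample in enumerate(spec.sample_names()):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1 + s_idx]))
        n = spec.reads_per_sample
        abund = rng.dirichlet(alphas)
        fam_idx = rng.choice(len(families), size=n, p=abund)
        cls_idx = rng.choice(len(class_names), size=n, p=class_p)
        lengths = _draw_lengths(rng, n, spec)
        flip = rng.random(n) < 0.5
        reads: list[Read] = []
        for i in range(n):
            fam = families[fam_idx[i]]
            cls = class_names[cls_idx[i]]
            genera = genera_by_family[fam]
            genus = genera[rng.integers(0, len(genera))]
            cog_id = cog_cat = None
            if cls == "SSU":
                rec = ssu_by_genus[genus]
                src = nt_cache[rec.id]
                node = genus
            elif cls == "LSU":
                rec = lsu_by_genus[genus]
                src = nt_cache[rec.id]
                node = genus
            elif cls == "sRNA":
                rec = srna_records[rng.integers(0, len(srna_records))]
                src = nt_cache[rec.id]
                node = rec.node
            else:  # mRNA: a fragment of the protein's genomic CDS, so the
                   # nucleotide offset makes strand and frame random
                cat = cats[int(rng.choice(len(cats), p=cat_p))]
                group = prot_by_genus_cat[(genus, cat)]
                rec = group[rng.integers(0, len(group))]
                src = cds_cache[rec.id]
                node, cog_id, cog_cat = genus, rec.cog_id, rec.cog_category
            if src.size == 0:
                raise ValueError(f"zero-length reference {rec.id}")
            length = min(int(lengths[i]), src.size)
            start = int(rng.integers(0, src.size - length + 1))
            frag = src[start: start + length]
            if flip[i]:
                frag = revcomp_codes(frag)
            if spec.error_rate > 0:
                frag = mutate_codes(frag, spec.error_rate, rng)
            reads.append(Read(f"{sample}_{i:06d}", sample, decode_nt(frag),
                              true_class=cls, true_node=node, true_cog=cog_id,
                              true_cog_category=cog_cat, source_ref=rec.id))
        out[sample] = reads
    return out


def make_contig_catalogue(refs: ReferenceSet, seed: int = 0,
                          protein_coverage: float = 0.85,
                          srna_coverage: float = 0.05,
                          genes_per_contig: int = 5) -> list[tuple[str, str]]:
    """Synthetic metagenome contig catalogue.

    Concatenates the genomic CDSs of a random subset of the protein
    references (plus a small share of the sRNA consensus sequences) into
    multi-gene contigs, so a tunable fraction of mRNA reads has a contig
    home and the rest does not — the structure needed by the
    mapped/unmapped accounting.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC017]))
    prots = sorted(refs.by_class("protein"), key=lambda r: r.id)
    keep = [r for r in prots if rng.random() < protein_coverage]
    pieces = [encode_nt(refs.cds[r.id]) for r in keep]
    for r in sorted(refs.by_class("sRNA"), key=lambda r: r.id):
        if rng.random() < srna_coverage:
            pieces.append(encode_nt(r.seq))
    contigs: list[tuple[str, str]] = []
    for i in range(0, len(pieces), genes_per_contig):
        chunk = pieces[i: i + genes_per_contig]
        contigs.append((f"contig{i // genes_per_contig:04d}",
                        decode_nt(np.concatenate(chunk))))
    return contigs


# --- read/reference file IO ----------------------------------------------

def write_reads_fasta(reads: dict[str, list[Read]], outdir: str | Path) -> None:
    """One FASTA per sample plus a combined truth-label TSV."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("read_id\tsample\tclass\tnode\tcog_id\tcog_category\tsource_ref\n")
        for sample, rs in reads.items():
            SeqIO.write([SeqRecord(Seq(r.seq), id=r.id, description="") for r in rs],
                        str(outdir / f"reads_{sample}.fasta"), "fasta")
            for r in rs:
                fh.write(f"{r.id}\t{r.sample}\t{r.true_class or ''}\t{r.true_node or ''}"
                        f"\t{r.true_cog or ''}\t{r.true_cog_category or ''}"
                        f"\t{r.source_ref or ''}\n")


def load_reads_fasta(path: str | Path, sample: str) -> list[Read]:
    from Bio import SeqIO
    return [Read(rec.id, sample, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]
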