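"""End-to-end orchestration: simulate (or load) reads, triage, classify,
estimate diversity, profile function, and bundle the report tables.

The bundle mirrors the data products of a metatranscriptome survey: a
per-sample read-partition table, the family × sample composition of 16S
transcripts, per-sample diversity estimators, COG category distributions
and rate ratios, the family × function matrix with its category
dendrogram, the sRNA family counts, and the mapped/unmapped fraction
accounting — all cross-consistent over one read universe.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecology, function as func, refsim, taxonomy, triage
from .refsim import CommunitySpec, Read, ReferenceSet, TaxonomyTree
from .search import SeedIndex, map_to_contigs


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name folded with
    the master seed (kept below 2^31 so downstream consumers stay happy)."""
    return (zlib.crc32(stage.encode()) ^ (master_seed * 2654435761)) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    Thresholds default to the calibrated values used throughout: 60 bp
    length cutoff, E ≤ 1e-16 (SSU) and 1e-4 (LSU) for rRNA triage,
    E ≤ 1e-3 for protein and COG calls, 80 % coverage / 90 % identity for
    contig mapping, and bootstrap confidence > 0.5 for taxonomic calls.
    """
    outdir: str = "activeflora_out"
    seed: int = 0
    # simulation scale (used when no external reads are supplied)
    n_phyla: int = 5
    families_per_phylum: int = 4
    community: CommunitySpec = field(default_factory=CommunitySpec)
    # thresholds
    min_len: int = 60
    e_ssu: float = 1e-16
    e_lsu: float = 1e-4
    e_protein: float = 1e-3
    e_cog: float = 1e-3
    map_fraction: float = 0.8
    map_identity: float = 0.9
    nb_confidence: float = 0.5
    log_level: str = "INFO"

    def validate(self) -> None:
        for name, v, lo, hi in (("map_fraction", self.map_fraction, 0, 1),
                                ("map_identity", self.map_identity, 0, 1),
                                ("nb_confidence", self.nb_confidence, 0, 1)):
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}]")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        for name, e in (("e_ssu", self.e_ssu), ("e_lsu", self.e_lsu),
                        ("e_protein", self.e_protein), ("e_cog", self.e_cog)):
            if e <= 0:
                raise ValueError(f"{name} must be positive")
        self.community.validate()

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "community" in d:
            d["community"] = CommunitySpec(**d["community"])
        return cls(**d)


@dataclass
class ReportBundle:
    """Every table of one run plus the manifest that reproduces it."""
    partition_table: pd.DataFrame
    composition: taxonomy.CompositionTable
    diversity: pd.DataFrame
    rarefaction: pd.DataFrame
    ordination: ecology.OrdinationResult | None
    category_distribution: pd.DataFrame
    rate_ratios: pd.DataFrame
    taxon_function: pd.DataFrame
    dendrogram: str
    srna_families: pd.Series
    accounting: func.FractionAccounting
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        ff = "%.6g"
        self.partition_table.to_csv(out / "partition_table.tsv", sep="\t")
        self.composition.counts.to_csv(out / "composition_counts.tsv", sep="\t")
        props = self.composition.proportions.copy()
        props["average"] = self.composition.average
        props.to_csv(out / "composition.tsv", sep="\t", float_format=ff)
        self.diversity.to_csv(out / "diversity.tsv", sep="\t", float_format=ff)
        self.rarefaction.to_csv(out / "rarefaction.tsv", sep="\t",
                                float_format=ff, index=False)
        if self.ordination is not None:
            self.ordination.row_coords.to_csv(out / "ca_rows.tsv", sep="\t",
                                              float_format=ff)
            self.ordination.col_coords.to_csv(out / "ca_samples.tsv", sep="\t",
                                              float_format=ff)
        self.category_distribution.to_csv(out / "cog_distribution.tsv", sep="\t",
                                          float_format=ff)
        self.rate_ratios.to_csv(out / "rate_ratios.tsv", sep="\t", float_format=ff)
        self.taxon_function.to_csv(out / "taxon_function.tsv", sep="\t",
                                   float_format=ff)
        (out / "cog_dendrogram.nwk").write_text(self.dendrogram + "\n")
        self.srna_families.rename("reads").to_csv(out / "srna_families.tsv", sep="\t")
        self.accounting.to_frame().to_csv(out / "accounting.tsv", sep="\t",
                                          float_format=ff)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2,
                                                      sort_keys=True))


def run(config: RunConfig, reads: dict[str, list[Read]] | None = None,
        refs: ReferenceSet | None = None,
        contigs: list[tuple[str, str]] | None = None,
        log=print) -> ReportBundle:
    """Execute the full pipeline and return the report bundle.

    When ``reads``/``refs`` are not supplied, a synthetic community is
    generated from ``config`` (simulation is the default exercise mode).
    Stages run in the published order: length filter → SSU → LSU triage;
    16S classification, composition, diversity and ordination on the SSU
    branch; protein call → COG assignment → rate ratios → family×function
    matrix on the non-rRNA branch, with the uncharacterized remainder
    scanned for sRNA motifs and folded into the fraction accounting.
    """
    config.validate()

    def say(stage, msg):
        if log is not None and config.log_level != "QUIET":
            log(f"[{stage}] {msg}")

    tree: TaxonomyTree
    if refs is None:
        tree = refsim.build_taxonomy(config.n_phyla, config.families_per_phylum,
                                     seed=stage_seed(config.seed, "taxonomy"))
        refs = refsim.evolve_references(tree, seed=stage_seed(config.seed, "references"))
    else:
        tree = refs.tree
    if reads is None:
        spec = config.community
        spec.seed = stage_seed(config.seed, "reads")
        reads = refsim.simulate_reads(spec, refs, tree)
        say("simulate", f"{sum(len(v) for v in reads.values())} reads, "
            f"{len(reads)} samples")
    if contigs is None:
        contigs = refsim.make_contig_catalogue(refs, seed=stage_seed(config.seed, "contigs"))

    ssu_db = triage.rRNADatabase.from_records(refs.by_class("SSU"), tree)
    lsu_db = triage.rRNADatabase.from_records(refs.by_class("LSU"), tree)
    part = triage.triage_reads(reads, ssu_db, lsu_db, e_ssu=config.e_ssu,
                               e_lsu=config.e_lsu, min_len=config.min_len)
    say("triage", f"dropped {part.dropped} short reads; table:\n{part.table}")

    flat = triage._flatten(reads)
    by_id = {r.id: r for r in flat}
    ssu_reads = [by_id[i] for i, c in part.classes.items() if c == "SSU_prok"]
    non_rrna = [by_id[i] for i, c in part.classes.items() if c == "non_rRNA"]

    # -- SSU branch: classification, composition, diversity, ordination
    model = taxonomy.train_word_model(refs)
    nb_seed = stage_seed(config.seed, "bootstrap")
    results = [taxonomy.classify_nb(r, model, conf_threshold=config.nb_confidence,
                                    seed=nb_seed) for r in ssu_reads]
    comp = taxonomy.composition(results, tree, rank="family")
    say("classify", f"{len(results)} 16S reads over {comp.counts.shape[0] - 1} families")
    assigned = comp.assigned_counts()
    diversity = ecology.diversity_table(assigned, seed=stage_seed(config.seed, "ace"))
    rare_rows = []
    for sample in assigned.columns:
        c = assigned[sample].to_numpy()
        c = c[c > 0]
        total = int(c.sum())
        if total == 0:
            continue
        depths = np.unique(np.linspace(1, total, 10).astype(int))
        for d, v in zip(depths, ecology.rarefaction(c, depths)):
            rare_rows.append({"sample": sample, "depth": int(d),
                              "expected_richness": v})
    rarefaction = pd.DataFrame(rare_rows)
    ordination = None
    if assigned.shape[0] >= 2 and assigned.shape[1] >= 2:
        ordination = ecology.correspondence_analysis(assigned)

    # -- non-rRNA branch: protein call, COG, rate ratios, taxon×function
    protein_db = func.ProteinDatabase.from_records(refs)
    protein_hits, unchar = func.call_protein_coding(non_rrna, protein_db,
                                                    max_e=config.e_protein)
    protein_reads = [by_id[i] for i in protein_hits]
    say("protein", f"{len(protein_reads)} putative protein reads, "
        f"{len(unchar)} uncharacterized")
    assignments = func.assign_cog(protein_reads, protein_db, max_e=config.e_cog,
                                  hits=protein_hits)
    cat_dist = func.category_distribution(assignments)
    ratios = func.rate_ratios(assignments, protein_db)
    fam_of: dict[str, str | None] = {}
    for read in protein_reads:
        # min_support=1: the synthetic database holds one ortholog per
        # genus, so a unique best hit is informative rather than spurious
        node = taxonomy.lca_assign(protein_hits[read.id], tree,
                                   protein_db.taxon_of, min_support=1)
        fam_of[read.id] = tree.ancestor_at_rank(node, "family") if node else None
    tf_matrix, Z, _ = func.taxon_function_matrix(assignments, fam_of)
    newick = func.dendrogram_newick(Z, list(tf_matrix.columns))

    # -- uncharacterized branch: sRNA scan and contig accounting
    motifs = func.motifs_from_references(refs)
    srna_hits, srna_frac = func.srna_scan(unchar, motifs)
    say("srna", f"{len(srna_hits)} motif hits over {srna_frac:.1%} of the "
        "uncharacterized fraction")
    contig_index = SeedIndex(contigs, k=11, alphabet="nt")
    mapped = set()
    for read in non_rrna:
        ok, _ = map_to_contigs(read, contig_index, min_fraction=config.map_fraction,
                               min_identity=config.map_identity)
        if ok:
            mapped.add(read.id)
    acc = func.fraction_accounting(non_rrna, set(protein_hits), mapped,
                                   {h.read_id for h in srna_hits})

    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "n_samples": len(reads),
        "n_reads": sum(len(v) for v in reads.values()),
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("taxonomy", "references", "reads", "contigs",
                                  "bootstrap", "ace")},
        "thresholds": {"min_len": config.min_len, "e_ssu": config.e_ssu,
                       "e_lsu": config.e_lsu, "e_protein": config.e_protein,
                       "e_cog": config.e_cog, "map_fraction": config.map_fraction,
                       "map_identity": config.map_identity,
                       "nb_confidence": config.nb_confidence},
    }
    return ReportBundle(part.table, comp, diversity, rarefaction, ordination,
                        cat_dist, ratios.table, tf_matrix, newick,
                        func.srna_family_counts(srna_hits), acc, manifest)


def validate_bundle(bundle: ReportBundle) -> list[str]:
    """Cross-consistency checks; an empty list means the bundle is sound."""
    errors: list[str] = []
    t = bundle.partition_table
    parts = t.loc[["SSU", "SSU_euk", "LSU", "non_rRNA"]].sum(axis=0)
    if not (parts == t.loc["total"]).all():
        errors.append("partition classes do not sum to per-sample totals")
    comp_sums = bundle.composition.proportions.sum(axis=0)
    if not np.allclose(comp_sums, 1.0, atol=1e-9):
        errors.append("composition proportions do not sum to 1")
    ssu_samples = set(bundle.composition.counts.columns)
    if not ssu_samples <= set(t.columns):
        errors.append("composition samples are not a subset of partition samples")
    else:
        ssu_totals = bundle.composition.counts.sum(axis=0)
        for s in ssu_samples:
            if ssu_totals[s] != t.loc["SSU", s]:
                errors.append(f"composition total for sample {s} != SSU count")
                break
    cd = bundle.category_distribution
    if cd.shape[1] and not np.allclose(cd.sum(axis=0), 1.0, atol=1e-9):
        errors.append("COG category distributions do not sum to 1")
    tf = bundle.taxon_function
    if tf.shape[1] and not np.allclose(tf.sum(axis=0), 1.0, atol=1e-9):
        errors.append("taxon-function columns do not sum to 1")
    acc = bundle.accounting
    if acc.counts:
        pct = sum(acc.percentages.values())
        if acc.counts and sum(acc.counts.values()) > 0 and abs(pct - 100.0) > 0.1:
            errors.append("accounting percentages do not sum to 100")
        non_r = int(t.loc["non_rRNA"].sum())
        if sum(acc.counts.values()) != non_r:
            errors.append("accounting universe differs from the non-rRNA total")
    return errors


# --- bundled survey table -------------------------------------------------

def load_survey_table1() -> pd.DataFrame:
    """The published ten-sample read-partition table bundled with the
    package (rows: total/SSU/LSU/non-rRNA counts of reads ≥ 60 bp)."""
    path = Path(__file__).parent / "data" / "table1.tsv"
    return pd.read_csv(path, sep="\t", index_col=0)


def load_survey_counts() -> dict:
    """Headline read counts of the same survey (non-rRNA reads with
    protein homologs, and those assigned to COG categories)."""
    path = Path(__file__).parent / "data" / "survey_counts.json"
    return json.loads(path.read_text())
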