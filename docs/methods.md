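# Methods

`activeflora` reimplements, as a tested library, the computational core of
a whole-community RNA (metatranscriptome) survey of the human gut: decide
what each sequenced cDNA fragment is (rRNA, mRNA, something else), who it
came from, and what function it encodes — then summarize the community's
active composition, diversity and functional profile.  Because the
original analysis depended on external reference databases and a specific
sequencing run, the package ships a synthetic-community generator that
reproduces the *statistical structure* of such data, so every stage is
exercised end to end with known ground truth.

## The synthetic community (`refsim`)

**Taxonomy.** A fixed rank ladder domain → phylum → class → order →
family → genus, with one class/order lineage per phylum; defaults of 5
phyla × 4 families give 20 families, the order of magnitude observed in
active gut communities.

**References.** Each sequence class starts from an i.i.d.-uniform
ancestral sequence and accumulates substitutions independently on every
branch (per-branch probability 0.03, excluding the current base), so
related genera share more sequence than distant ones.  SSU genes (1.5 kb)
carry alternating conserved/variable blocks (150 bp, half the gene);
conserved positions substitute at 10 % of the branch rate — the
conserved-region structure that makes taxonomic assignment of short 16S
fragments genuinely ambiguous in places.  LSU genes are 2.9 kb with no
conserved mask.  Proteins are orthologous families: one 250-aa ancestral
protein per COG id (25 single-letter functional categories × 1 slot),
evolved down to every genus.  Every protein also receives one fixed
genomic CDS — a seeded uniform-codon realization — which is what mRNA
reads and metagenome contigs are both cut from; a per-read codon draw
would destroy the nucleotide identity between reads and contigs that the
mapping stage measures.  Eight sRNA consensus sequences (90 nt) complete
the reference set.

**Reads.** Per sample, family abundances are one Dirichlet draw
(concentration 30 over a geometric base profile with decay 0.75 —
a few dominant families, a long tail, moderate inter-individual
variability); the class mixture is fixed across samples at
SSU 17.2 %, LSU 75.5 %, mRNA 6.3 %, sRNA 1.0 %, matching the rRNA-
dominated pools such surveys report.  Read lengths are a discretized
normal (mean 174, sd 80) truncated to [30, 1000]; roughly 5–8 % of reads
fall under the 60 bp analysis cutoff, exercising the length filter.
Reads are uniformly placed substrings of a reference of the drawn family
and class (mRNA: of the CDS, so strand and frame are random), reverse-
complemented with probability ½, with i.i.d. substitution errors at
0.5 % — a plausible per-base error for the pyrosequencing regime
emulated.  The mRNA category profile injects a known skew: carbohydrate
metabolism (G) at twice and lipid metabolism (I) at half the database
share, the directions the enrichment statistic must recover.

## Homology search (`search`)

A single self-contained engine replaces BLASTN/BLASTX/BLAT: exact k-mer
seeds (nucleotide k=11, match +1/mismatch −2; protein k=4, BLOSUM62) are
grouped by diagonal and extended ungapped in both directions under an
X-drop rule (X=20); extension is deliberately gapless because gapless
Karlin–Altschul theory is exact, so the E-values attached to hits —
E = K·m·n·e^(−λS), λ the positive root of Σ pᵢpⱼe^(λsᵢⱼ)=1 found by
bisection to |f|<1e-12, K = 0.1 (the conventional gapless approximation,
overridable) — carry their textbook meaning and the published thresholds
(1e-16, 1e-4, 1e-3) can be applied as stated.  n is total database
letters; for translated search m is the peptide length and all six frames
are translated and split at stops.  Coordinates are 0-based half-open,
ties broken by subject id; hits can be exported in the 12-column tabular
BLAST dialect (1-based there).  Diagonals are ranked by seed count and
capped (`max_diagonals`), and callers may require ≥2 seeds per diagonal
(`min_seeds`); the triage and functional stages use these settings, and
the measured recall/precision (≥0.999 at default conditions) is the
accuracy *at those settings*.  The BLAT-style contig criterion requires
at least 80 % of the read to align — the conservative reading of a
maximum-possible-alignment fraction — at ≥90 % identity.

## Read triage and calibration (`triage`)

Reads <60 bp are dropped; the rest are compared to the SSU database
(accept at E ≤ 1e-16, sub-classed 16S/18S by the best hit's domain), the
remainder to the LSU database (E ≤ 1e-4), and what is left is the
non-rRNA (putative mRNA) fraction.  Classes are mutually exclusive and
exhaustive, so the per-sample table always conserves totals.

The calibration sweep rebuilds the threshold-selection experiment: 1000
fragments of 100 bp per class (SSU, LSU, mRNA), cut at uniform positions
from the references — optionally with a per-base divergence, emulating
test sequences collected from relatives of the database entries rather
than the entries themselves — are scored against both databases over a
grid of E-values (1e-30 … 1).  Cross-contamination at a threshold is the
out-of-class acceptance rate averaged over the two foreign classes (the
quantity is usually named without being defined; this is the natural
definition), and selection is lexicographic: minimum contamination, then
maximum sensitivity, then smallest E — a deterministic rule where
"lowest contamination" alone would leave ties.  A planted-contamination fixture (10 % of mRNA
fragments carrying an exact 40 bp SSU insert, fragments at divergence
0.2) demonstrates the sweep selecting a strictly stricter SSU than LSU
threshold; without fragment divergence every sensitivity saturates at 1
and the tie-break alone would pick the grid minimum for both databases.

## Taxonomic assignment (`taxonomy`)

The 16S classifier is the classical word-based naive Bayes: 8-mer
document frequencies over the SSU references give P(w) = (n(w)+0.5)/(N+1)
and P(w|g) = (m_g(w)+P(w))/(M_g+1); a read's genus maximizes Σ log P(w|g)
over its word set (both strands, set semantics).  One hundred bootstrap
trials redraw ⅛ of the words with replacement; per-rank confidence is the
fraction of trials whose winner shares the ancestor at that rank, and the
assignment stops at the deepest rank with confidence strictly above 0.5,
deeper ranks reported "uc".  Word size, subsample and trial count are the
classical parameters of this classifier family and are exposed.

mRNA reads are binned by lowest common ancestor of near-best hits
(retain within 10 % of the best score; default min_support 2 hits).  With
the synthetic database's one ortholog per genus, a unique best hit is
informative rather than spurious, so the pipeline's mRNA LCA stage uses
min_support 1 (explicitly, and documented here).

Composition tables aggregate at a requested rank, pool truncated reads
into `uc_<rank>`, and compute the "average" column from pooled counts
(not the mean of per-sample proportions).  The recovery experiments
compare the inferred composition, renormalized over family-assigned
reads, against the truth-label composition of the same reads, so
read-sampling noise cancels and the measured L1 error isolates
classification error.

## Diversity and ordination (`ecology`)

Rarefaction is the analytic hypergeometric form
E[S_n] = Σᵢ [1 − C(N−Nᵢ,n)/C(N,n)] in log-gamma arithmetic (a seeded
Monte-Carlo mode exists only as a cross-check).  Chao1 uses the classic
form S_obs + F1²/(2F2) with its matching variance when doubletons exist,
otherwise the bias-corrected form S_obs + F1(F1−1)/2; the branch is
reported.  ACE splits rare/abundant at 10 reads, with coverage
C = 1 − F1/N_rare and the standard CV correction; when every rare family
is a singleton (C=0) the estimator is undefined and Chao1 is returned
with a flag.  The ACE standard error is a seeded multinomial bootstrap —
the published closed-form ACE variances differ between tools and none is
canonical, so a resampling SE was preferred to picking one silently.
Shannon uses natural log: the per-sample values such family-level tables
report (≈1.5–2.4 over ~20 families) are only consistent with ln.
Correspondence analysis is the SVD of the standardized residuals
D_r^{−1/2}(P−rcᵀ)D_c^{−1/2}; total inertia equals Pearson χ²/N (tested to
1e-10), axis signs are fixed by making the first nonzero row loading
positive.

## Functional profiling (`function`)

Non-rRNA reads with any translated hit at E ≤ 1e-3 are putative
protein-coding.  COG assignment groups hits by COG function; when two
distinct functions are supported on query regions overlapping each other
by less than 50 % — genuinely non-overlapping signals, the signature of a
chimeric/fused cDNA — the read is discarded (`multi_cog`), whereas
functions competing over the same region are ordinary homologs and the
best score wins.  The published rule states the discard but not the
geometry test; the 50 % overlap fraction operationalizes it and is
configurable.  Rate ratios use exactly (n_c/n)/(N_c/N) with N_c counted
one-per-database-protein (the database-side counting is ambiguous in
prose; per-protein weighting is the default and a per-category Series can
be supplied instead).  Categories with N_c=0 are flagged undefined, never
0.  The family × category matrix normalizes each category's reads over
families (family-less reads pooled as "unassigned", keeping columns
honest) and clusters categories by average linkage on L1 profile
distance.  The sRNA scan is a log-odds PWM sweep over both strands
(consensus probability 0.9, threshold 60 % of the maximal score per
motif) — covariance-model scoring of secondary structure is explicitly
out of scope.  Fraction accounting crosses the protein call with contig
mapping over one read universe and reports the sRNA share of the
uncharacterized remainder; inconsistent universes are a hard error.

## Pipeline (`pipeline`) and reproducibility

One master seed fans out to per-stage seeds by CRC32 of the stage name,
so any stage can be rerun in isolation; a manifest records seeds,
thresholds and a config hash.  Identical config + seed yields
byte-identical bundles (tested).  `validate_bundle` re-checks partition
sums, normalizations and universe consistency.

## Problem sizes and what the tests show

The recovery experiments run at: triage — 10 samples × 20,000 reads
(~3 min, one CPU); composition — 10 × 5,000 SSU reads; calibration —
1,000 fragments/class × 2 scenarios; enrichment — ~5,800 pooled COG
assignments.  Unit tests use smaller draws of the same laws.

Passing these tests shows the *algorithms* are correct and that the
stated thresholds behave as designed under a realistic divergence/error
regime; it does not certify performance on real gut data, where
references are incomplete and taxonomies disagree.  In particular the
synthetic reference databases are complete by construction, so the
uncharacterized fraction here is small and mostly sRNA, whereas real
surveys leave about half the non-rRNA fraction unassigned; the published
headline percentages that depend on real external databases are therefore
out of scope by design.  Known limitations: no indel errors or chimeras
in the simulator, no gapped alignment statistics, no rRNA secondary
structure, genus-level resolution claims are not made, and the archaeal/
eukaryotic domains are absent from the synthetic taxonomy (the 18S
sub-classing path is unit-tested against a lineage fixture instead).
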