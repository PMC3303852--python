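# Methods

This note documents the models and procedures implemented in `viromekit`,
the choices made where the design was genuinely open, and what the
synthetic validation experiments do and do not demonstrate.

## Scope and data model

The package analyses shotgun viral metagenomes ("viromes"): collections
of reads from the purified viral fraction of an environmental sample. A
virome is a `ReadSet` (ordered reads plus a biome label). Cross-virome
comparisons assume normalised inputs — exact duplicates removed, equal
read numbers, equal read lengths — produced by `seqio.dedup_exact` and
`seqio.subsample`. Length normalisation takes a random window of each
sampled read rather than a prefix, to avoid 5′ composition bias; a
`trim_mode="prefix"` flag restores the simpler convention. Reads
containing `N` are retained: no quality information is modelled, and the
only read-level filtering implemented is exact-duplicate removal
(duplicate reads are a sequencing artefact of emulsion-PCR platforms; the
simulator reproduces them as verbatim copies).

## Synthetic communities (synthdata)

Virotype abundances follow one of five classical rank-abundance laws:
power (`a_i ∝ i^{-b}`), exponential (`a_i ∝ e^{-b i}`), logarithmic /
log-series (`a_i ∝ x^i / i`), lognormal, and the broken stick
(`a_i = (1/S) Σ_{k=i}^{S} 1/k`). All five constructions are
deterministic; the lognormal uses quantile slicing at probabilities
`(i − ½)/S` instead of sampling, so fitting tests have exact targets. No
family is privileged: nothing in the estimation stack assumes which law
generated the data, and the fitter always tries all five.

Genomes are i.i.d. uniform-composition random sequences. This gives the
assembly and clustering stages the easiest possible background (no
repeats, no shared genes, no GC structure), which is exactly what makes
planted signal recoverable and countable; conclusions about repetitive
or mosaic real genomes are out of reach of these tests.

Reads are drawn genome-proportionally to abundance with uniform start
positions (wrapping if the genome is declared circular), i.i.d.
substitution errors, and an optional fraction of verbatim duplicate
copies appended at the end. Indels are not modelled: no downstream stage
depends on indel statistics, and substitution-only errors keep every
alignment problem ungapped. Three allocation modes split reads across
genomes: `multinomial` (default; read-by-read sampling), `exact`
(largest-remainder deterministic counts) and `poisson` (independent
Poisson counts per genome). The Poisson mode exists because
shotgun-coverage theory describes a Poisson read-arrival process; it is
the mode under which the expected contig spectrum formula is exact (see
below). Read ids carry the ground truth
(`…|src:<genome>|pos:<start>|dup:<0/1>`, parsed by `parse_read_id`).

`make_panel` builds multi-virome panels with controlled genome sharing:
each virome's genome set is a union of a panel-wide common pool
(`between_share` of its genomes), a group core
(`within_share − between_share`) and private genomes. Within-virome
abundances are uniform so every genome is equally discoverable.
`plant_marker` writes a reverse-translated (one fixed codon per amino
acid), controllably diverged copy of a marker protein over a random
locus of each genome, conserving genome length, and returns a truth
table (genome → divergence, locus, strand).

## Cluster richness (clusterdiv)

Cluster richness is the number of clusters formed at a fixed nucleotide
identity threshold (default 75%, chosen for the high divergence of viral
genes; the comparison thresholds 90% and 98% behave monotonically).
Published clustering engines are heuristic and order-dependent, so the
policy here is fixed: reads sorted by (length descending, id ascending);
each read joins the first centroid, in creation order, reaching the
threshold, else founds a cluster. Identity is `1 − d/m` where `d` is the
minimum edit distance of the best semi-global (infix) alignment of the
shorter sequence (length `m`) inside the longer — the denominator is the
shorter read so 100-bp windows can join 400-bp centroids. Equal-length
ties choose the lexicographically smaller sequence as the query, making
the definition symmetric and deterministic. The production path uses
banded edit-distance alignment (edlib) plus a lossless q-gram count
prefilter; a deliberately naive quadratic re-implementation with an
explicit DP serves as the validation reference, and the two agree
exactly on randomized instances (boundary cases such as threshold 0.9 on
length-80 reads are handled by computing the distance band with the same
floating-point comparison the identity uses). Rarefaction consumes a
single seeded permutation in increments of `step`, extending the
clustering state incrementally, which is identical to re-clustering each
prefix in the permutation order; the curve's final point therefore
matches a full clustering under that ordering, not under the default
length-sorted ordering.

## Species richness from the contig spectrum (specrich)

### Assembly

`assemble_strict` performs a greedy overlap-merge at high stringency
(98% identity over ≥ 35 bp): candidate suffix/prefix overlaps are found
by exact 20-mer seeding, verified ungapped by mismatch counting, and
merged longest-overlap-first with each read end consumed at most once;
contained reads are absorbed. On substitution-only reads this reproduces
the position-truth "island" structure of the reads exactly (verified
against islands computed from true read positions). With sequencing
errors, short overlaps (35–49 bp, where 98% identity permits zero
mismatches) are frequently broken, inflating the singleton count, so
the estimator is sharply sensitive to error rate. The analysis scripts
use the error-corrected regime the method assumes; real applications
need upstream error handling that is out of scope here.

### Expected spectrum

For a virotype with `n_i = a_i·n` reads of length `l` on a genome of
(average) length `L`, coverage `c_i = n_i·l/L` and overlap factor
`σ = 1 − t/l` (minimum detectable overlap `t`), the expected number of
contigs of exactly `q` reads is

    E[c_q] = Σ_i n_i · e^{−2 c_i σ} · (1 − e^{−c_i σ})^{q−1}

whose series satisfies `Σ_q q·E[c_q] = n` exactly (geometric identity;
verified to 1e−6 relative). The formula is the classical
shotgun-coverage result for a Poisson read-arrival process on an
unbounded (edge-free) genome. The validation experiment therefore
simulates the matching regime — circular genomes (no edges) and Poisson
per-genome read counts — and compares mean spectra over 500 replicates
per configuration (S ∈ {1, 20} × coverage ∈ {0.2, 1, 3}) entrywise in
Monte-Carlo standard errors. Two deliberate restrictions: entries are
compared only while the expected count is ≥ 2 (below that the
per-replicate distribution is too skewed for the ±3 SE normal band to be
meaningful — the usual expected-count rule), and per-configuration read
numbers are kept moderate (50–600) because reads start at integer
positions, which biases link probabilities by order `coverage/l` (a few
percent at coverage 3); with moderate counts this lattice effect
stays below Monte-Carlo resolution, while the formula's own
implementation is checked at full precision by the closure identity.
Genome lengths per configuration follow from the coverage identity
`L = n·l/(cov·S)`; the multi-virotype grid uses a steep power law
(b = 1.5) so the compared entries span per-virotype coverages from ~0.2
to far beyond saturation.

### Fitting

`fit_richness` minimises, per rank-abundance family, the weighted squared
error between observed and expected spectra with approximate Poisson
weights `w_q = 1/max(E_q, 1)`. The spectrum is compared bin-by-bin for
q = 1..30 plus one aggregate bin holding the read mass of larger contigs
(deeply covered virotypes produce contigs of hundreds of reads; the
aggregate bin keeps them informative without inflating the comparison
length). Richness S is searched on a log grid (coarse pass at 8 points
per decade over [1, max(10·n, 1000)], refinement at 40 points per decade
around the coarse optimum) with each family's single shape parameter
optimised by bounded scalar minimisation at every S — fully
deterministic, no random restarts. The winning family is the error
minimiser; Shannon H (nats) and Pielou evenness `J = H/ln S` come from
the fitted abundance vector, with `J = 1` by convention when `S_hat = 1`.
Parameter-recovery checks: a power-law community with S = 300 (b = 1.1,
5-kb genomes, 20,000 100-bp reads) is recovered with median error well
inside ±30% over 10 seeds, and S = 50 vs S = 500 communities are ordered
correctly in ≥ 9/10 seeds. The average genome length L is an input, as
in practice (where it comes from an external genome-size estimator);
mis-specifying L propagates multiplicatively into S_hat.

## Translated similarity engine (simsearch)

Reads are translated in six frames, peptides split at stop codons;
segment pairs sharing an exact amino-acid 5-mer are extended ungapped
along the seed diagonal under BLOSUM62 (Kadane maximum-subarray over the
diagonal), batched in numpy. Gapped extension is unnecessary under the
substitution-only error model; the 5-mer seed (where 4-mers are common
elsewhere) keeps the random-collision candidate load tractable at panel
scale without costing sensitivity for the ≥ 10-aa identical stretches
that matter here. A pair of reads "hit" when their best segment score
reaches a cutoff calibrated on random read pairs:
`calibrate_score_cutoff(fp=1e-3)` gives 37 for 100-bp and 45 for 420-bp
reads; the default is 45 (false-hit rate < 1e-3 in both regimes).
Byte-identical reads always count as hits — a self-alignment is
trivially significant even when stop codons fragment every frame.
Marker-gene recruitment searches a read against a whole reference panel
(a larger null space), so it uses its own cutoff of 50, calibrated the
same way against 8 × 400-aa reference panels.

## Cross-virome comparison (viromecomp)

The similarity of viromes A and B is the symmetrised significant-hit
fraction `½(|{r∈A: hit(r,B)}|/|A| + |{r∈B: hit(r,A)}|/|B|)` — bounded,
symmetric, and invariant to the common subsample size. A summed-score
variant is available behind a flag but is not the default: it is
unbounded and dominated by a few deeply conserved genes. For fidelity
runs with an external translated search engine,
`cross_score_from_hits` computes the same score from tabular hit files
at the conventional significance thresholds (e ≤ 1e-3, bit ≥ 50). Viromes are clustered on `1 − score` with
average linkage (ties broken by scipy's deterministic pair ordering).
Clade support is the plain bootstrap probability: reads are resampled
with replacement within each virome, pairwise scores are recomputed from
cached read-level hit matrices (no re-alignment), and support is the
fraction of replicate trees containing the same leaf set. When all
viromes hold the same number of reads, one index vector per replicate is
shared across viromes — the analogue of resampling the rows of a data
matrix once per replicate, as multiscale-bootstrap clustering packages
do — so identical viromes remain identical under resampling;
multiscale/approximately-unbiased corrections are intentionally not
implemented (plain bootstrap probability is the transparent, testable
core). On synthetic 3-group × 3-virome panels (within-group genome share
0.6, between 0.05, 2,000 × 100-bp reads) the three group clades appear
with support ≥ 0.8 in ≥ 9/10 seeds; within-group scores run ≈ 0.5–0.6
against ≈ 0.06 between groups. The one-way fixed-effects ANOVA
(`richness_anova`) is the textbook between/within mean-square ratio with
explicit handling of degenerate inputs (all-identical values → F = 0,
p = 1; zero within-group variance → F = ∞, p = 0); it matches
`scipy.stats.f_oneway` on regular inputs.

## Taxonomic decision logic (taxcomp)

All operations act on externally produced tabular hit tables (12
standard columns plus subject taxon path and subject genome length; a
`query_len` column is required for coverage filtering). A read is
"known" iff some hit has e-value ≤ 1e-3 AND bit score ≥ 50 — thresholds
inclusive, since they are stated as thresholds, not strict bounds; the
boundary rows are tested explicitly. Domains come from the best hit (max
bit score, ties by min e-value, then lexicographic subject id). Reads
whose best hit is non-viral but which also hit a complete viral genome
at the same thresholds are rescued as "similar to at least one viral
sequence" (provirus-derived reads otherwise masquerade as cellular).
Family composition follows the genome-length-normalised top-hit rule:
hits are eligible at ≥ 50% identity and alignment length ≥ 20% of the
query (filters applied before top-hit selection; alignment length ×3
when the table is in protein space), and each read's top eligible hit
contributes `1/subject_genome_len` to its family — longer genomes shed
more reads per particle, so raw counts over-represent them. A missing
genome length falls back to weight 1 with a warning. Iterative
re-weighting refinements of this scheme are out of scope.

## Marker phylogeny (markerphylo)

Short reads cannot span a marker gene, so the pipeline lengthens and
groups them: translated recruitment against the ungapped references →
stringent assembly (delegated to `assemble_strict` at 98%/35 bp, so only
same-virotype reads merge) → ungapped sliding placement of the best
six-frame peptide of each contig against each degapped reference
(substitution-only data make gapped placement unnecessary; insertions
relative to the reference would be discarded and counted) → column
bounds on the fixed reference alignment → grouping of contigs whose
bounds overlap reciprocally by ≥ 0.5 of the shorter interval (connected
components — exclusive assignment, each contig in exactly one
sub-alignment; the threshold is a parameter) → a window per component
covered by ≥ 75% of members → block curation (drop columns with > 50%
gaps, keep runs of ≥ 10 surviving columns, reject alignments under 20
columns) → the 10 longest curated alignments → neighbor-joining on
pairwise-deletion amino-acid p-distances with support from column
bootstrap (100 replicates; bipartition counting). Coordinates are
0-based half-open reference columns throughout; everything after
recruitment is in amino-acid space. Maximum-likelihood inference is
delegated to an `external-ml-hook` callable rather than re-implemented;
NJ is the testable built-in default, and trees are unrooted.

The validation design plants copies of a clade-A reference from a
synthetic two-clade terminase-like family (400 aa; clade ancestors at
0.18 divergence from a random root, references at 0.10 from their clade
ancestor) into 10 genomes at divergences 0.05–0.40, sequences 5,000
420-bp reads, and requires every ≤ 0.2-divergence copy to be recruited
and every contig built purely from low-divergence copies to sit on the
clade-A side of a bipartition with bootstrap support ≥ 0.8 (≥ 9/10
seeds). Because the synthetic family evolves by substitution only, the
reference alignment is gap-free; the gap-handling paths of curation are
exercised separately on constructed alignments.

## Pipeline orchestration

`pipeline.run` executes a YAML-configured stage list (simulate, dedup,
subsample, cluster, rarefy, spectrum, fit_richness) with per-stage seeds
derived from the global seed by hashing (stable across runs, so stages
can be re-run in isolation), and writes a manifest with parameters,
seeds and SHA-256 checksums of every output; identical configs reproduce
identical checksums.

## Problem sizes

Validation experiments are sized to run in minutes on one core: 100
random clustering instances (10–500 reads), 500 replicates × 6
configurations for the spectrum comparison, 10 seeds each for the
richness-recovery, ordering, panel and marker experiments. The analysis
scripts use two 30,000-read viromes (S = 800 vs 200) and the panel and
marker designs above.

## Known limitations

* The contig-spectrum estimator assumes error-free overlaps; raw-read
  substitution errors bias S_hat upward strongly (see above).
* A single average genome length is shared by all virotypes; the
  circular-genome variant of the coverage model is not implemented
  (linear/edge-free only), and no confidence intervals are attached to
  S_hat.
* The translated scorer is ungapped; real frameshifting indels would
  fragment alignments and lower scores.
* Recruitment and placement were validated on substitution-only
  divergence; insertion-rich marker families would exercise the
  discarded-insertion bookkeeping differently.
* Bootstrap clade support is plain bootstrap probability, which is known
  to be conservative relative to approximately-unbiased corrections.
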