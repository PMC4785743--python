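# Methods

`metaprofiler` implements a tufA amplicon-metabarcoding framework for
surveying endolithic phototroph communities (cyanobacteria and eukaryotic
algae boring into marine calcium carbonate): degenerate-primer evaluation,
paired-end read processing, dual OTU clustering with a core-OTU consensus,
abundance profiling, and — the centre of the package — calibration of
per-rank percent-identity thresholds used to annotate OTUs against a
taxonomy-curated reference alignment.

## Identity conventions

All downstream statistics rest on two identity computations
(`metaprofiler.seqcore`):

* **Aligned mode** treats two equal-length strings as rows of one multiple
  alignment. Identity = 100 × (matching columns) / (columns where *both*
  rows carry a non-gap, non-missing character). This pairwise-deletion
  denominator is why records with more than 20 bp of leading or trailing
  missing data are excluded from the identity matrix: a short overlap
  inflates identity. The boundary is strict (exactly 20 missing bp is
  kept); internal gap columns can instead be counted as mismatches via
  `gap_as_mismatch`.
* **Global-align mode** computes a unit-cost end-to-end alignment (edlib)
  first; indel columns are excluded from the denominator, matching the
  aligned-mode convention. IUPAC ambiguity codes match whenever their base
  sets intersect (`W` matches `A`); a strict flag demands identical
  concrete bases.

A consequence worth knowing: identity under an edit-distance-optimal
alignment is *not* 100·(L − Hamming)/L when substitutions cluster — the
aligner can trade adjacent mismatches for indel columns that leave the
denominator. Unrelated random sequences score ≈ 53–56 %, not the ~25 %
naive expectation; the decontamination floor (60 %) sits above this noise
band.

## Threshold calibration

For a rank r, every record pair resolvable at r is intra- or inter-clade.

* The **conservative** threshold is the maximum inter-clade identity —
  the worst-case similarity between members of different clades — rounded
  *up* to the next integer. A best hit at or above it cannot come from
  another clade, which is the annotation guarantee the leave-one-out test
  asserts (zero misannotations on databases whose margins respect the
  thresholds).
* The **relaxed** threshold comes from leave-one-out self-classification:
  each record's best hit (highest identity, ties resolved by the majority
  lineage of co-maximal hits) is scored correct iff the labels agree at r.
  The threshold is the maximum identity among incorrect hits. If no best
  hit is ever wrong the threshold is reported as *unbounded below* together
  with the weakest correct-hit identity, rather than invented.

Raw values are snapped to 6 decimals before the ceiling so float artefacts
of exact percentages (342/375 = 91.2) cannot round one integer too high.
Thresholds at a high rank may exceed those at a lower rank; that
non-monotonicity is a property of real databases (uneven sampling, rate
variation) and is deliberately not "corrected". High and low ranks can be
calibrated on different record subsets (`run_calibration(low_rank_class=…)`),
mirroring the common practice of calibrating order/suborder/family only
within one well-sampled class.

Annotation copies the best hit's labels down to the deepest rank whose
threshold the identity reaches; deeper ranks stay `UNRESOLVED`; species is
assigned only within the species band (default ≥ 97.87 %, i.e. ≤ 8
substitutions over 375 bp). Conflicting equal-identity hits leave the
disputed rank unresolved.

## Read processing

The chain is merge → demultiplex → expected-error filter → size filter +
fixed trim → dereplicate → abundance denoise → chimera screen →
decontaminate. Boundary semantics are one-off-error traps and therefore
explicit: keep iff expected errors E = Σ 10^(−Q/10) ≤ 0.5 (a 50 × Q20 read
is exactly 0.5 and is kept; an epsilon guards float accumulation); size
bounds inclusive; denoising removes dataset-wide totals ≤ 3. Index
matching allows zero mismatches; the forward primer may mismatch within a
budget (default 2). Merging picks the ungapped overlap with most matches
(ties to the longer overlap); disagreements resolve to the higher-quality
base, agreements keep the maximum quality. No post-merge quality mask is
applied — the merge tool's quality floor in the original pipelines is a
tool detail, not a property of the data, and the expected-error filter
downstream already bounds read quality.

The chimera screen is a reference-based bimera test: an amplicon is
flagged when the best two-parent model (left prefix from one reference,
right suffix from another, maximized over all crossovers and parent pairs)
beats the best single parent by ≥ 3 identity points *and* reaches ≥ 99 %.
Parents are pre-screened by shared 8-mers; a parent without a single
shared 8-mer cannot support a ≥ 99 % two-parent model over a ~375 bp
amplicon, so the prescreen cannot change a decision (the exhaustive-oracle
test checks exactly this). Decontamination keeps an amplicon iff some
reference aligns at ≥ 60 % identity with ≥ 50 % query coverage under infix
alignment.

## Dual clustering and core OTUs

Global clustering is greedy and abundance-ordered at a 97 % identity
threshold: an amplicon joins the qualifying centroid of highest identity
(ties to the more abundant centroid), else founds an OTU. Local
clustering is swarm-style: transitive closure of the ≤ d Levenshtein
relation (d = 10 by default), seeded in abundance order, so OTUs are
connected components of the d-difference graph. Core OTUs are those whose
global centroid is exactly some local seed sequence; a member-set Jaccard
criterion (≥ 0.5) is available behind a flag because the concordance rule
is a genuine design freedom. The d-scan reports local and core counts for
d = 1…16 and calls the widest plateau of constant core count the optimum.
Everything is deterministic: ordering is always (abundance, then sequence
lexicographic).

## Abundance

Reads surviving the quality filter — including the low-abundance sequences
denoising later removes — are mapped to core centroids at 97 %. Cells of
the OTU × sample table with fewer than 3 reads are then zeroed (per-sample
counts of 1–2 are indistinguishable from tag jumps and index errors) and
their reads reported as a "corrected" delta, before any profile is
computed. Community profiles report, per taxon at a chosen rank, richness
(% of OTUs) and abundance (% of mapped reads) per sample and overall, with
optional pooling of taxa below a mean-abundance floor into "Others".

## Species delimitation

`subs_to_identity`/`identity_to_subs` convert substitution counts over the
metabarcode (100·(L−k)/L, half-up to 2 dp). The barcode-gap partitioner is
an explicitly simplified take on automatic barcode-gap discovery and is
labelled "barcode-gap (simplified)" in outputs: priors sweep a log grid
(0.001–1, 100 steps); for each prior the first gap in the pairwise
p-distance distribution that reaches above the prior and is ≥ 0.5 × prior
wide triggers a single-linkage split at the gap's lower edge, recursively
within groups; the returned partition is the one stable over the widest
contiguous prior range, with gap-bearing partitions taking precedence over
the trivial single group (which is only the no-gap fallback). No
model-corrected distances.

## Synthetic study conditions

The generator (`metaprofiler.synthetic`) produces what the framework
consumes, with full ground truth: a root 375 bp metabarcode evolves down
domain → … → species; sibling clades at a rank are separated by a planned
substitution count (each child branch receives half, at positions not
already mutated along its lineage, so back-substitution cannot erode the
plan). Defaults: 2 domains × 2 phyla × 2 classes × 2 orders × 1 suborder ×
2 families × 2 species = 64 records; separations 100/76/62/50/40/30/20
substitutions from domain down to species. Species sit ~20 substitutions
(≈ 94.7 % identity) apart so that the canonical 97 % global and d = 10
local clustering conventions resolve them with margin for alignment
ambiguity. Real cryptic species in this marker sit at 1–8 substitutions
and are *not* separable at 97 %; passing tests therefore demonstrate
pipeline correctness on separable communities, not species-level
resolution of real endolith data.

Reads: per sample, a seeded subset of species (25 % of the database) with
Dirichlet(α = 5) proportions, 600 reads per sample; a read's template is
index (8 bp, exact per sample) + forward primer (24 bp) + 20 bp conserved
pad + species marker (375 bp) + 50 bp conserved pad whose start is the
reverse-complemented reverse primer — 445 bp after demultiplexing, so runs
on synthetic data raise the size ceiling to 450. Paired reads are the
template's first and (reverse-complemented) last 250 bp (23 bp overlap);
substitution errors at 0.1 % per base with flat Q38 qualities; two-parent
chimeras and random off-target templates replace normal reads at
configurable rates (0 by default). Every event — lineages, species
sequences, per-read species, error positions, chimera parents and
crossovers — lands in the manifest, and tests compare against *realized*
divergences from the manifest rather than the nominal plan, because
substitution draws can collide. Not modelled: PCR amplification bias,
indel sequencing errors (an indel knob exists but defaults off), quality
decay along the read, tag jumping.

## Numerical and degenerate-input choices

* GC of a degenerate primer uses fractional ambiguity weighting (each
  position contributes the G+C fraction of its ambiguity set), which
  equals the mean over all expansions; printed to 1 dp, half-up. Melting
  temperature is informational only (Wallace rule); it is not validated
  against any published table and deliberately untested.
* Identities print at 2 dp; table percentages at 1 dp; ledger percentages
  are integers of the raw read count.
* Entropy profiles exclude gaps from column counts; the moving-average
  window (default 11 columns, odd) shrinks at alignment edges.
* Farthest-point representative selection runs a deterministic 1-swap
  refinement after the greedy phase; greedy alone is not 1-swap optimal.
* Reference-DB dereplication is longest-first (ties lexicographic), never
  merges records whose resolved lineages conflict at any rank, and at
  100 % collapses exact substrings as duplicates.
* Empty pipelines are legal: an empty read set yields a ledger of zeros
  and no OTU table; a single-clade rank yields an empty inter distribution
  and an explicit "threshold undefined" error rather than a number.

## Problem sizes

Default test-scale conditions (64-record databases, 2 × 600 reads,
20-seed calibration sweeps) run the full suite in well under a minute on
one CPU; these sizes are the package's chosen desk-scale study conditions,
with every quantitative check tied to manifest ground truth rather than to
absolute counts of any particular dataset.
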