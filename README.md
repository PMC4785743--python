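# metaprofiler

A toolkit for **tufA amplicon metabarcoding** of phototroph communities —
in particular the endolithic algae and cyanobacteria (e.g. *Ostreobium*
spp., Ulvophyceae) that bore into marine calcium carbonate. The chloroplast
elongation-factor gene *tufA* amplifies phototrophs in large read
proportions where universal 16S assays drown them in heterotroph signal,
which makes it an attractive metabarcode — provided OTUs can be annotated
at defensible identity cutoffs.

The package covers the full desk side of such a study:

* **`seqcore`** — IUPAC sequences, ranked lineages
  (domain…suborder…species), pairwise percent identity (aligned and
  global-alignment modes, pairwise-deletion denominator), identity matrices
  over a metabarcode window with end-missing exclusion.
* **`primertools`** — degenerate-primer degeneracy/GC (fractional ambiguity
  weighting), primer matching, in-silico PCR, alignment conservation
  profiles (percent of maximum entropy, moving average).
* **`readproc`** — paired-end merging, exact-index demultiplexing,
  expected-error filtering (keep iff E = Σ 10^(−Q/10) ≤ 0.5), size
  filter + fixed 5′/3′ trimming, dereplication, abundance denoising
  (totals ≤ 3 removed), reference-based bimera screening, non-marker
  decontamination.
* **`otucluster`** — greedy 97 % global-threshold clustering, swarm-style
  local clustering (≤ d edit steps, transitive), **core OTUs** produced
  concordantly by both, and the d = 1…16 scan with its plateau optimum.
* **`abundance`** — read-to-OTU mapping, the OTU × sample table with the
  <3-reads cell filter, rank-abundance curves, richness/abundance
  community profiles.
* **`calibrate`** — the centrepiece: per-rank **conservative** thresholds
  (ceiling of the maximum inter-clade identity, so identity ≥ threshold
  guarantees the hit's clade) and **relaxed** thresholds (maximum identity
  of a misclassified leave-one-out best hit), plus multi-rank OTU
  annotation and database-performance distributions.
* **`speciesdelim`** — substitution↔identity arithmetic and a simplified
  barcode-gap species partitioner.
* **`refdb`** — reference-database curation: identity dereplication,
  maximally distant representative selection, lineage exclusion rules,
  composition summaries.
* **`synthetic`** — a first-class generator of taxonomy-structured
  reference databases and paired-end runs with complete ground-truth
  manifests, so every claim above is testable without downloads.

## The thresholds in one formula

Over an alignment window, identity of a pair is
`100 · matches / columns-where-both-have-bases`. For a taxonomic rank *r*:

```
conservative(r) = ceil( max { identity(a,b) : a, b in different clades at r } )
relaxed(r)      = ceil( max { identity(q, besthit(q)) : besthit label ≠ q label at r } )
```

A best hit at or above `conservative(r)` *cannot* come from another clade
of the calibration database; `relaxed(r)` is the empirical
no-misclassification line. Annotation copies the best hit's lineage down
to the deepest rank whose threshold the identity reaches; species
membership additionally requires the species band (≥ 97.87 %, i.e. ≤ 8
substitutions over the 375 bp metabarcode).

## Worked example

Simulate a community, calibrate thresholds, run the pipeline:

```bash
echo 'error_rate: 0.0' > sim.yaml
metaprofiler simulate --seed 7 --config sim.yaml --out sim
metaprofiler calibrate --refs sim/reference.fasta --taxonomy sim/taxonomy.tsv --out cal
echo 'max_len: 450' > run.yaml
metaprofiler run --r1 sim/reads_R1.fastq --r2 sim/reads_R2.fastq \
  --indexes sim/indexes.tsv --fwd-primer TGGGTAGAGAAGATTTACAACTTG \
  --refs sim/reference.fasta --taxonomy sim/taxonomy.tsv \
  --config run.yaml --thresholds cal/thresholds.tsv --out run
```

`cal/thresholds.tsv` (conservative rows; raw values are the worst-case
inter-clade identities, rounded up):

```
rank     mode          raw    rounded  provenance
domain   conservative  38.67  39       Eukaryota...spe1_h1|Bacteria...spe1_h1
phylum   conservative  51.20  52       ...
class    conservative  61.87  62       ...
order    conservative  72.00  72       ...
family   conservative  88.80  89       Eukaryota.phy2...fam1.spe1_h1|...fam2.spe2_h1
```

Every planted cross-family pair of this database sits at or below
88.80 % identity, so any hit ≥ 89 % is guaranteed to name the right
family. `run/ledger.tsv` tracks the read-processing chain (clean channel:
nothing is lost):

```
stage                reads  percent_of_raw
raw                  1200   100
paired_end_merging   1200   100
demultiplexing       1200   100
quality_filter       1200   100
size_filter          1200   100
denoising            1200   100
decontamination      1200   100
```

The run yields 29 core OTUs — exactly the planted species sampled deeply
enough to survive denoising — and `run/annotation.tsv` assigns each a full
lineage, e.g.:

```
otu      domain     ...  family                          species                       identity
OTU0001  Eukaryota  ...  Eukaryota.phy2.cla1.ord1...fam2  ...fam2.spe2                  99.73
```

(identity 99.73 = one substitution over 375 bp between the OTU centroid
and its closest reference haplotype — within the species band, hence the
species-rank call).

## Scope notes

Alignments are inputs (no MSA construction); primer *design* is out of
scope (primers are evaluated, not generated); no tree-based placement —
truth lineages stand in for topology-derived taxonomy. See
`docs/methods.md` for the model, parameter defaults and limitations.
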