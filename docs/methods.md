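# Methods

`taxatlas` turns droplet-barcoded shotgun reads from single microbial cells
into a reference-free taxonomic cell atlas, then resolves strains and mobile
elements within it. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not establish.

## Barcode groups

A *barcode group* is the set of read pairs sharing one corrected droplet
barcode and proxies a single cell. Barcodes are parsed from a configured
window of R1 (default offsets 0–18) and corrected against a whitelist within
Hamming distance 1. Correction is deliberately conservative: when two
whitelist entries are equidistant at distance 1 the pair is discarded rather
than guessed, because downstream purity filtering makes false merges far
more damaging than lost reads. The combinatorial two-block barcode layouts
of commercial droplet platforms are abstracted to a single contiguous
barcode field with configurable offsets; the constant linker after the
barcode is trimmed by exact-prefix match with at most one mismatch. Quality
strings are preserved verbatim; no quality trimming is applied.

Groups with fewer than `min_reads` pairs (default 1000, the conventional
barcode-rank cut) are removed before classification.

## k-mer LCA classification and abundance vectors

The built-in classifier is a minimal Kraken-style k-mer LCA scheme. Every
canonical k-mer (lexicographic minimum of a k-mer and its reverse
complement) of every reference genome maps to the lowest common ancestor of
the genomes containing it. A read pair is classified jointly: k-mer hits
from both mates accumulate, every taxid with at least one direct hit is a
candidate, each candidate is scored by the summed hit count along its
root-to-leaf path, and the deepest maximal-scoring candidate wins (ties
break to the smaller taxid). Default k = 21: on kilobase-scale genomes this
keeps random 21-mer collisions negligible (4^21 ≈ 4.4e12) while leaving
~130 informative k-mers per 150 bp read. The implementation is exact, not
performant — no minimizers or probabilistic structures — and is intended for
validation-scale databases; real runs can instead feed Kraken2 report or
Bracken output files through `parse_classifier_report`. Bracken's Bayesian
read redistribution is not reimplemented; the rank-lift step below stands in
for it, and external Bracken tables are accepted as-is.

Per-barcode classifications collapse to an *abundance vector* at a working
rank (default genus): each classified read is lifted to its ancestor at that
rank, reads classified only above the rank are excluded from the vector but
still count as classified, and the vector is renormalised over included
reads. Two statistics accompany it: `mapped_fraction` (classified reads /
total reads) and *purity* (abundance of the dominant taxon), the multiplet
and contamination filter. Excluding above-rank reads rather than spreading
them across descendants keeps purity interpretable as "fraction of rank-level
evidence agreeing with the dominant taxon".

## Atlas construction

Vectors are filtered by `mapped_fraction >= m` and `purity > p`. The purity
inequality is strict (a 0.80 vector fails a 0.80 threshold) to mirror the
conventional ">80%" phrasing of such cut-offs; both thresholds are
configurable because different sample types warrant different stringency
(0.8 for complex communities, 0.9 for mock communities and contigs — no
single canonical value is claimed). Retained vectors are combined into a
row-per-barcode matrix over the union of observed taxa, zero-filled.

Clustering is Leiden (RBConfiguration partition, resolution 1.0) on a
k-nearest-neighbour graph (Euclidean, `n_neighbors` 15) whose edge weights
are the fuzzy-simplicial-set connectivities of the UMAP framework — the
locally scaled kernel the standard single-cell toolkits hand to Leiden.
Local scaling matters at validation scale: with tens of retained barcodes
per population, an unweighted k-NN graph is dominated by cross-population
edges and communities dissolve, while the scaled kernel keeps
within-population edges strong regardless of dataset size. Abundance
fractions are used directly — no log, CLR, or PCA transform — and the 2-D
UMAP embedding is for display only; labels always come from the graph. All
stochastic steps take an explicit seed, and identical seeds give identical
labels, coordinates, and output bytes.

Each cluster is annotated with the arg-max taxon of its summed member
vectors (lexicographic tie-break). Genus is the working rank; species-rank
vectors are used only to subcluster a chosen cluster (`subcluster`), which
re-runs the same embedding/clustering on the member subset.

Metagenomic contigs enter the atlas as pseudo-barcodes carrying the same
abundance vectors, filtered at purity > 0.90. Integration is k-NN label
transfer: each contig receives the majority cluster label of its k = 10
nearest single-cell rows in abundance space and sits at the mean of their
2-D coordinates. This implements the contract that matters — contigs placed
near taxonomically similar cells, reference labels untouched — without
re-deriving any toolkit's internal projection machinery.

Cluster evaluation: pooled per-cluster reads (both mates of every member
group) can be written as FASTQ for external assembly; the *clustering error
rate* is the fraction of a cluster's pooled reads that fail to align to the
cluster's reference genome under the mini-aligner. Rarefaction curves
subsample aligned read intervals without replacement (default cap 10 000
reads) and report covered-base fraction per step. `compare_to_metagenome`
union-aligns two taxon profiles, supports an exclusion list (e.g. lineages
with known lysis bias), and reports Pearson r, declining to report when
fewer than three taxa are shared.

## Mini-aligner

A deliberately small seed-and-extend engine backs every alignment step:
exact 21-mer seeds (one per non-overlapping window plus the read tail)
looked up in a reference index, ungapped extension over the full read, and
*every* placement within the mismatch budget reported — multi-mapping
preserved, as an external aligner run in report-all mode would. With a
default budget of 4 mismatches on 150 bp reads, at least one seed window is
always clean, so the seed heuristic loses nothing relative to exhaustive
scanning (verified against a brute-force oracle in the tests). No indels,
no soft clipping: reads must lie entirely within the reference, which the
simulator's substitution-only error model guarantees. A SAM adapter
(`sam_to_records`) imports multi-hit alignments from external aligners
instead, taking mismatch counts from NM (or MD) tags.

## Strain resolution

Candidate strain genomes are treated like isoforms of one gene competing
for the multi-mapping reads of a barcode group. Each alignment becomes a
likelihood

    p_rs = prod_matches (1 - e_i) * prod_mismatches (e_j / 3),

with e_i the Phred base-error; computed in log space, strictly decreasing
in mismatch count at constant quality. When mismatch positions are unknown
(SAM import) the mean base error substitutes for per-position errors. A
Dirichlet–categorical mixture is then fitted by coordinate-ascent
variational Bayes:

    phi_rs  ∝  p_rs · exp(ψ(α_s) − ψ(Σ α)),
    α_s     =  α0 + Σ_r phi_rs,

iterated until the ELBO changes by < 1e-6 (cap 1000 iterations; the ELBO is
non-decreasing at every step, asserted in tests). Full transcript-
quantification machinery — sequence-specific bias correction and the
log-normal replicate-variance layer — is deliberately omitted: those terms
model biological replicate variance and library-level bias that have no
analogue inside a single barcode group, while the essential mechanism
(multi-mapping reads weighted by alignment probability, posterior strain
proportions by VB) is retained.

Parameters: `alpha0` = 0.01, a sparse prior under which pure barcodes
concentrate; the strain panel is declared up front so θ has constant
dimension across barcodes (unaligned strains stay at prior mass); reads
aligning to no panel strain are dropped rather than modelled as noise.
Barcodes with overall alignment rate < 50% are excluded before fitting —
the source material phrases this filter once as "coverage rate" and
elsewhere as alignment rate; alignment rate is implemented as the
measurable intent.

A barcode is assigned to the arg-max strain iff its posterior mean
abundance exceeds 0.15 (strictly; lexicographic tie-break), else left
unassigned. The population standard deviation of θ across the panel is the
assignment diagnostic: concentrated posteriors score high, while barcodes
whose reads fall only in strain-shared regions stay near-uniform, score
near zero, and end unassigned — the mechanism behind unassignable cells in
real data.

## Element association

*Plasmid presence*: group reads are aligned to the plasmid panel; only
mismatch-free placements are kept, duplicates (same reference, position,
strand, and read sequence) collapse to one, and presence means at least one
surviving read. The SAM route honours the literal MAPQ >= 42 filter that
proxies "unique, mismatch-free" in common aligner output; the internal
route implements that intent directly. Per-species host ratios are the
fraction of a species' barcodes with plasmid reads. Cross-species signal
from shared homology is expected and is what the ANI estimator explains.

*Fragment ANI*: the query is tiled into non-overlapping 1 kb fragments
(1 kb rather than the 3 kb common for genome-scale tools, because toy
plasmids are kilobase-scale; configurable), each fragment's best ungapped
placement gives identity = matches / length, and ANI is the mean identity
over fragments exceeding 0.7, as a percentage, with the mapped-fragment
fraction alongside. Unrelated sequences yield no mapped fragments and a
null ANI.

*Gene abundance*: pooled cluster reads are aligned to a gene panel
(accession tokens of the form `ARO:...` are parsed out of FASTA headers
when present, passed through opaquely otherwise), filtered and deduplicated
as above; RPM[cluster][gene] = unique hits × 1e6 / total cluster reads.

*Gene presence/absence subpopulations*: a barcode × gene count table is
binarised (count >= 1), genes present in fewer than `min_cells_per_gene`
cells are dropped first, then cells with fewer than `min_genes_per_cell`
genes (single pass, genes before cells — the order is fixed here because
the upstream description does not state one). Defaults are 5/5; 10/10 is
equally defensible and both are exposed. The filtered binary matrix feeds
the same embedding/clustering as the atlas.

## Simulator

The generator reproduces the validation design of the droplet protocol:
per-species barcode groups of 150 bp paired-end reads from amplicons of
400–1000 bp, 1000–10 000 read pairs per barcode, contamination fraction
drawn uniformly from 0–49% per barcode with contaminant pairs sourced
uniformly from the other community members. Amplicon starts are uniform on
the genome treated as linear (no origin wrap); R1 reads the fragment 5' end
forward and R2 the 3' end reverse-complemented, the standard paired-end
convention. Read titles encode barcode, pair index, true source, and origin
class, so every downstream claim can be checked against truth without
bookkeeping files. Reads are error-free by default — the validation design
does not state a sequencing-error model — with an opt-in uniform
substitution rate rendered as a matching constant Phred quality. Strain
structure comes from independent per-site substitutions at a configured
divergence (SNP truth table recorded; replaying it reproduces each strain
exactly). Plasmid carriage is Bernoulli per host barcode; carried-plasmid
reads are drawn with weight copies × plasmid length against the chromosome
(default 5 copies). Barcodes are random 18-mers kept at pairwise Hamming
distance >= 3 so whitelist correction is never ambiguous; they are written
to a whitelist file, and optionally embedded at the start of R1 behind a
constant linker so the demultiplexer is exercised end-to-end. Contigs are
verbatim substrings of member genomes, sources drawn proportional to
abundance × length.

Not modelled: PCR/GC bias, chimeras, indel errors, quality-score
heterogeneity. Random genomes at these lengths share essentially no
21-mers, so simulated populations are taxonomically separable by
construction. Passing tests therefore establish correctness of the
machinery — demultiplexing, classification, filtering, clustering,
inference, bookkeeping — under the stated design, not classifier
performance on real genomes with shared content, nor robustness to
alignment artefacts the simulator cannot produce.

## Validation scale and determinism

The test suite and `scripts/acceptance.py` run a reduced replica of the
validation design — 10 species × 20 barcodes at 1000–2000 read pairs
(~300 000 pairs), 100 contigs, 20 strain barcodes of 1000 pairs — chosen so
the whole validation completes in minutes on one core while every
population still has enough retained barcodes (purity > 0.9 retains roughly
the ~20% of barcodes with contamination below 10%) to measure recovery.
All randomness flows through explicit integer seeds; gzip members are
written with a zero mtime so repeated runs are byte-identical, which the
pipeline tests assert by checksum.

## Pipeline

`run_pipeline` executes demux → classify → filter → atlas → [integrate] →
[pool] → [strain] → [elements] from a schema-validated config (unknown keys
rejected, every seed explicit), writes each stage's output under one run
directory together with a manifest and a resolved-config snapshot, and
fails fast naming the offending stage while keeping earlier outputs and a
failure record. Because outputs are deterministic given config and seed,
re-running a completed stage rewrites identical bytes; `overwrite` exists
to make clobbering intent explicit. The `taxatlas` CLI exposes the stages
as subcommands (`simulate`, `demux`, `classify`, `atlas`, `integrate`,
`strain`, `elements`, `run`, `evaluate`) as thin wrappers over the library.

## Known limitations

- The classifier and aligner are exact but naive: suitable for
  validation-scale references (megabases at most), not full databases.
- No indel handling anywhere; real data with indel errors should enter via
  the SAM/report adapters, not the internal engines.
- Strain resolution requires a declared panel; there is no de novo strain
  discovery and no MCMC alternative to VB.
- Contig integration transfers labels; it never revises the reference
  clustering, so reference-side errors propagate to contigs.
- `parse_classifier_report` takes Bracken tables at face value (no
  unclassified row exists there, so mapped_fraction defaults to 1).
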