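# Methods

## Model overview

`varsense` treats variant detection sensitivity in RNA-Seq as a function of
the total library size, mediated by gene expression. The chain is:

1. a gene expressed at RPKM *r* sequenced with reads of length *L* (paired
   factor *f* = 2 for PE) at library size *N* fragments yields an expected
   total depth at a site of that gene of `d = r · L · f · N / 1e9`;
2. shrinking the library to a target size is equivalent to keeping each
   fragment independently with probability `p = target/initial`, so the
   alt-supporting and reference read counts at a site are thinned
   binomially and the VAF is preserved in expectation while depth scales
   by `p`;
3. whether a variant is *called* then depends on the caller's reporting
   behaviour and the filtering strategy, both of which act on the thinned
   counts.

Inverting step 1 gives the planning formula quoted in the README; the two
are exact inverses and are tested as such.

## Filtering strategies

*default-filters*: keep a call iff the caller flagged it PASS and its
normalised key is not "present in normals". Presence in the panel of
normals (PON) is the literal rule: seen in more than 2 normal samples, or
in fewer than 2 but with VAF > 0.03. The rule as stated leaves exactly-2
unclassified; we implement it literally (n = 2 → absent) and expose
`min_samples` / `vaf_threshold` so users can adopt inclusive semantics.
PON calls are counted regardless of their own FILTER flags.

*annotation-filters*: ignore caller FILTER flags entirely and keep a call
iff all of the following hold —

* not (in PON and absent from COSMIC): COSMIC membership rescues hotspots
  that leak into normals at low VAF;
* not (absent from COSMIC, present in dbSNP **and** ExAC): germline-like
  removal requires both databases;
* not overlapping an exon-boundary window, homopolymer run (single-base
  runs strictly longer than 5 bp) or repeat interval — even when the key
  is in COSMIC;
* mean alt base quality > 18, alt depth ≥ 5, total depth ≥ 15, VAF ≥ 0.03.

The joint alt-depth/VAF rule implies a variant with true VAF below 0.03 can
survive only at ≥ 167 reads of coverage (`min_depth_for_vaf_below`).

The exon-boundary window defaults to the literal intronic-flank reading —
within 4 bp upstream of an exon start or downstream of an exon end — with a
`boundary_symmetric` option for the common ±4 bp splice-junction
interpretation. "Overlap" with context tracks means any base of the
variant's reference span intersects the interval; insertions contribute
their anchor base. Filter evaluation records **all** failing reasons rather
than short-circuiting, so removal-reason histograms are complete; kept
status is unaffected. Removal of RNA-editing sites is implemented but off
by default. Database membership is by exact normalised key, not position,
matching the allele-aware matching used elsewhere.

## Matching

SNVs match on exact `(chrom, pos, ref, alt)` equality after normalisation;
when a truth record has no published alt allele, the allele called on the
initial (largest) library stands in. Indels admit any same-chromosome indel
call within ±50 bp; `exact` mode then requires allele equality, `partial`
mode requires a longest common contiguous substring of ≥ 3 bp between call
and truth alt alleles (refs too, for deletions) — the strictest reading of
"3 bp overlap" that still joins composite events reported as split SNV +
indel pieces. Sequence overlap (not reference-span overlap) is the default;
ties among candidates break on smallest positional distance, then
lexicographic alt, replacing manual curation with a deterministic,
auditable rule. Assignment is greedy one-to-one: a kept call satisfies at
most one truth variant. Normalisation is the standard left-align +
parsimony-trim procedure (right-trim shared suffix bases, extending one
reference base leftward when an allele would empty; finally left-trim to a
single anchor); it is idempotent and haplotype-preserving, which a
reconstruction oracle property-tests on small windows.

## Sensitivity

Recall is `TP/(TP+FN)` per (caller, library size, replicate, truth
subset); an empty truth set yields an explicit NA, never 0. Depth strata
are `[0,10), [10,20), …, [90,100), [100,130)` and a final closed bin from
130X to the maximum observed depth. Cumulative recall at threshold *d*
counts a variant as called only when its site depth is ≥ *d* and restricts
the denominator the same way; at *d* = 0 it coincides exactly with plain
recall. The depth of a *missed* variant comes from the per-site depth
track each thinned library carries (the simulator emits it; a real
pipeline would pileup). Replicate summaries report median/min/max.
Sensitivities are stored as fractions rounded to 4 decimals; percent
formatting happens only at report rendering. The VAF × expression
detection grid averages the per-variant-per-caller called indicator within
each (VAF bin × log2-expression bin); averaging happens within bins, after
pooling callers.

## Downsampling

Replicate seeds default to {100, 26880, 56745, 7234, 9999}; a target size
whose sampling proportion exceeds 0.7 runs 3 replicates, others 5
(generalising the published 3-replicates-at-80M scheme; overridable). A
target above the initial size caps p at 1 with a warning. A mapping-rate
adjustment factor (reference rate / observed rate; 93.4/75.6 ≈ 1.24)
multiplies the proportion when cohorts with different mapping rates must
be made comparable. Thinning is fragment-level — one Bernoulli per
fragment — so overlapping-mate double counting is ignored. Paired FASTQ
subsampling uses a one-pass reservoir for exact counts and a seeded
per-fragment Bernoulli for proportions; both apply one fragment index set
to both mates and pass records through byte-identically. All randomness
uses numpy's PCG64 with explicit seeding for bit-reproducibility.

## The synthetic cohort

The generator is a pure function of (config, seed) and emulates the study
conditions rather than raw reads:

* **Truth set** (default 88): 58 SNVs, 15 short insertions (< 10 bp), 9
  composite indels, 3 long insertions, 2 short deletions, 1 indel with no
  reported allele. Per-type VAFs are triangular over the published
  (min, mean, max), the mean standing in for the mode since only those
  three numbers are printed. The no-allele record is excluded from
  allele-aware matching but stays in every denominator.
* **Genome layout**: single-exon genes on a 1 kb grid, one variant per
  gene except a planted triplet of three truth SNVs 30 bp apart (the
  clustered-events scenario). Homopolymer runs exist only where planted.
* **Expression and depth**: gene log2 RPKM ~ Normal(3.5, 1.2); genes
  hosting variants are floored at 2.0 (≈ 90X initial depth at the default
  113M-fragment initial size), reflecting that RNA-validated truth
  variants sit in expressed genes. Site depth is Poisson around the
  planning-formula expectation (negative-binomial overdispersion is an
  option); truth alt support in the initial library is binomial
  conditioned on ≥ 6 reads and VAF ≥ 0.035 — the generator's model of
  "validated variants are detectable in the deep initial libraries",
  which also makes planted filter-reason counts exact by construction.
* **PON** (17 normals): four artifact keys recurring in 10 normals, the
  hotspot truth SNV at VAF 0.005–0.02 in 3 normals (removed by
  default-filters, rescued by annotation-filters via COSMIC), singleton
  noise on both sides of the 0.03 VAF rule. One caller-agnostic normal
  call-set collection serves all caller profiles; per-caller PONs differ
  only by label.
* **Decoys**: each planted decoy call fails exactly one annotation filter
  (germline-like in dbSNP+ExAC; PON artifacts; homopolymer, repeat and
  exon-boundary context hits placed in COSMIC to exercise the
  context-beats-COSMIC rule; one pair each of low base quality, low alt
  depth, low total depth and low VAF with the other fields clean), so the
  removal-reason histogram equals the planted counts exactly.
* **Caller profiles**: SNV reporting probability 1.0 everywhere; indel
  probabilities chosen so the block-mode profile recovers roughly 60 % of
  indels and the split-mode profiles fewer; split mode decomposes
  composites into an SNV piece plus an indel piece that reassemble to the
  block allele (so exact matching fails but partial matching succeeds);
  one profile applies a clustered-events flag to any call with ≥ 3 calls
  within 100 bp.

What the generator does **not** emulate: read-level errors and mapping
artifacts, transcript structure and splicing (single-exon genes), strand
bias, copy-number or purity effects on VAF, and caller-specific scoring
beyond the profile parameters. Passing tests therefore demonstrate that
the pipeline arithmetic, filtering logic and matching rules behave as
specified under controlled conditions — not that any particular caller
will achieve these sensitivities on real data.

## Numerical and design choices

* Coordinates are 1-based closed (VCF convention) everywhere public;
  interval tracks are 0-based half-open internally with a single,
  property-tested conversion boundary.
* Multi-allelic VCF rows are split before filtering; per-allele alt depth
  comes from AD when present, else a caller-specific field per the
  configurable field map. Duplicate-read handling is upstream of this
  package; depths are taken as reported.
* Base-quality filtering is strictly `> 18` on the mean alt base quality
  as mapped at ingest.
* Truth records are keyed per-allele when multi-allelic.
* Depth bins are left-closed right-open except the final closed bin.
* The benchmark grid (3 profiles × 2 strategies × 5 sizes × 3–5
  replicates plus the initial library, 88 truth variants and ~25 decoys)
  runs in a few seconds; problem sizes in tests (e.g. 200-variant oracle
  cohorts, 10,000-replicate thinning Monte Carlo, 500-site depth
  calibration) were chosen to give 3-SE statistical resolution while
  keeping the suite quick.

## Known limitations

* Specificity / false-positive rates are out of scope by design; only
  recall against a truth set is computed.
* The clustered-events model flags by a simple within-window call count,
  not haplotype phasing.
* Indel sensitivity comparisons across real callers depend on
  representation conventions the profiles only approximate.
* The PON rule's n = 2 gap is inherited from its literal statement;
  change `min_samples` to close it.
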