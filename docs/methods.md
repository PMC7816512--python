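# Methods

## The measurement model

Every intron defines an intron-retention (IR) event and every internal
exon an exon-skipping (ES) event.  The analysis is strictly
junction-based: a read is evidence only if it pins down one side of an
event unambiguously.

* A spliced read (CIGAR `N` gap) supports an exon–exon junction iff its
  gap equals the intron's coordinates exactly and at least
  `min_overhang` aligned bases flank the gap on both sides.
* A read aligned contiguously across an exon–intron boundary supports
  that boundary iff it covers the boundary with at least `min_overhang`
  bases on each side.
* A read may support several junctions (both boundaries of an intron
  shorter than `read_length − 2·min_overhang`, or junctions of two
  neighbouring introns), and one genomic junction may feed several
  events: an intron's splice junction is simultaneously inclusion
  evidence for an adjacent internal exon.
* Reads interior to an intron (touching no boundary) are not used;
  intron-body coverage estimators are out of scope.
* The per-gene count is the number of reads whose leftmost aligned base
  lies in the gene span.  Genes are assumed non-overlapping, which
  holds for the simulator's genomes; no fractional assignment is done.
* Strand is ignored throughout: the modelled library (random-hexamer
  primed, single-end) is unstranded.  `EI5`/`EI3` labels follow the
  transcriptional direction but the PIR statistic is symmetric in them.

`min_overhang` defaults to 6 bases — a conventional junction anchor
length; it is a parameter of every counting entry point.

## PIR, PSI and the per-event test

With pooled counts r = EI5 + EI3 (retained) and s = 2·EE (spliced),

PIR = 100·r/(r+s),   and symmetrically   PSI = 100·(INC1+INC2)/((INC1+INC2)+2·SKP).

The doubling of EE/SKP reflects that a retained molecule exposes two
measurable boundaries while a spliced molecule exposes one junction; at
equal sampling intensity the estimator is then consistent for the true
retention fraction (see the simulator section).  Events with no
evidence at all have undefined PIR/PSI and are reported as
`not_expressed`.

Replicates are pooled (summed) within condition before testing: a 2×2
Fisher's exact test admits exactly two groups, and pooling is the
minimal treatment of replication for this test.  The cost is that
between-replicate biological variability in the retention fraction is
not propagated — see Limitations.

`fisher_event` implements the two-sided minimum-likelihood convention:
the sum of hypergeometric probabilities of all tables with the observed
margins that are no more probable than the observed table.  Table
probabilities are computed with log-gamma arithmetic; ties are detected
with a 1e-7 relative tolerance so mathematically equal probabilities
are not split by rounding.  The suite verifies agreement with an exact
integer-arithmetic enumeration to 1e-10 over every table with margins
up to 30, and with an independent library implementation on random
larger tables.  A zero row or column margin yields p = 1 (no evidence).

The *expressed* filter makes an event testable only if r + s ≥
`min_reads` (default 10) in each condition; this prevents undefined
estimates and near-zero-power tests from diluting the FDR family.  All
testable events of one type (IR or ES) form one BH family per
contrast.  Classification uses the dual threshold: `increased` iff
adjusted p < alpha (0.05) and Δ > +delta_min (10 points); `decreased`
symmetrically; Δ is condition 2 − condition 1, with the contrast order
taken from the design.

The MA x-axis is log2(1 + mean over samples of the event's total
junction reads); the pseudocount keeps zero-count events finite.

## Differential expression

The DE stage is intentionally small — a calibrated NB test, not a
reimplementation of a full DE package:

* **Size factors**: median over genes (restricted to genes nonzero in
  every sample) of the ratio to the per-gene geometric mean.  Factors
  are defined up to a common constant.
* **Dispersion**: one common α (var = μ + αμ²) estimated by the method
  of moments — within each condition the normalised sample variance in
  excess of the shot-noise term, scaled by the squared mean, averaged
  over genes and conditions, floored at 1e-8.  The mean (not the
  median) of the per-gene ratios is used because the per-gene estimates
  are individually unbiased but extremely noisy at 2–4 replicates, and
  the mean preserves calibration.
* **Test**: conditional on the total K = K_A + K_B of the per-condition
  count sums, the two-sided p is the probability of a split no more
  likely than the observed one, with K_A and K_B modelled as NB with
  the pooled mean and the dispersion scaled by Σs² / (Σs)² to account
  for the sum over replicates with unequal size factors.  Computed in
  log space over the full support; an all-zero gene is excluded and
  flagged rather than tested.
* **Fold change**: log2 of the ratio of normalised per-condition means
  with a pseudocount of 1.

## The simulator

The generator emulates the statistical structure of a two-condition
fission-yeast-style experiment.  Defaults (all overridable in
`SimConfig`):

| parameter | default | rationale |
|---|---|---|
| exons per gene | 2–4 | genes with few, short introns |
| exon length | 150–400 bp | must be ≥ read length so junction reads fit |
| intron length | 40–120 bp | short introns typical of compact genomes |
| replicates | 3 per condition | standard design |
| mean expression | 200 fragments/gene, lognormal sdlog 0.5 | moderate depth, realistic spread |
| NB dispersion | 0.02 | isogenic cultures are highly reproducible |
| retention / inclusion | 0.10 / 0.90 | mostly-spliced baseline |
| library size factors | lognormal, sdlog 0.15 | mild depth imbalance |
| read length | 100, single-end | 1×100 sequencing |

Per gene and sample, the fragment count is NB with mean
μ·2^log2fc·size_factor.  Each fragment belongs to one isoform pattern —
a joint assignment of retained/spliced per intron and included/skipped
per internal exon (a skipped exon removes its flanking introns with
it).  Patterns are sampled with probability proportional to
prior × molecule length: fragmentation of a real library yields
fragments in proportion to molecule length, and this weighting is what
makes the boundary-read PIR estimator exactly consistent — each
intron's boundary and junction windows then collect reads in proportion
2ρ : (1−ρ), so PIR → 100ρ as depth grows, with error shrinking as
1/√depth.  Read starts are uniform along the molecule; reads are
emitted pre-aligned (blocks and `N` gaps) because alignment is outside
the pipeline.  All randomness flows from one seed through fixed stream
keys per stage, so annotation, truth tables and reads are
byte-reproducible.

`make_truth(..., junction_depth=D)` sets per-gene expression so each
intron collects ≈D pooled junction-informative reads per condition,
using the window count w = read_length − 2·min_overhang + 1.

**What the simulator does not model**: sequencing errors and quality
variation, paired ends, positional coverage bias, multi-mapping and
alignment artefacts, overlapping or multi-isoform genes, and — most
importantly — replicate-to-replicate variability of the retention
fractions themselves (retention is a fixed per-condition probability).
Passing tests therefore demonstrate correctness of the counting and
inference machinery under the stated sampling model, not robustness to
those real-data effects.

## Problem sizes and thresholds in the statistical tests

The large statistical checks run at: 2,000 introns with ~100 pooled
junction reads per event per condition for null calibration; 2,000
introns (200 true +30-point shifts) at ~400 for recovery; 500 introns
at ~400 for estimator accuracy; 2,000 genes for DE calibration.  The
recovery and accuracy depths were fixed by power analysis before the
tests were run: the zero-false-call requirement needs the null ΔPIR
noise (sd ≈ 2 points at depth 400, baseline retention 0.10) to sit well
below the 10-point filter, and the 3-point estimator bound needs the
Monte-Carlo error (≈1–2 points at depth 400) clearly inside it.  The
DE 4-fold recovery asserts the mean log2FC within ±0.5 of 2 and ≥90% of
genes individually within ±0.5, since the per-gene estimator's sampling
sd at dispersion 0.02 and 3 replicates is ≈0.2 and a per-gene bound
cannot hold with certainty.

## Numerical and tie-breaking choices

* Coordinates are 0-based half-open internally; GFF3 I/O is 1-based
  inclusive, SAM I/O follows pysam.
* One transcript model per gene; the analysis is intron-centric.
* BH adjustment delegates to the standard step-up implementation in
  statsmodels; the suite checks it against the literal definition.
* Counting is order-independent by construction (pure tallies).
* TSV output uses a fixed float format (`%.10g`) and sorted event ids;
  SAM headers carry only HD/SQ lines — together this makes the file
  pipeline byte-deterministic for a fixed seed.
* Degenerate inputs: empty read sets give all-zero counts; events on
  chromosomes absent from the annotation are ignored; molecules shorter
  than the read length produce no reads.

## Limitations

Pooling replicates means the Fisher p-values treat junction reads as
the unit of replication; with strong biological variability between
replicate cultures the test would be anticonservative, and a
beta-binomial or GLM treatment would be the upgrade path.  A single
read can contribute two boundary counts for a short retained intron,
which slightly inflates the variance of the retained count relative to
the multinomial ideal.  The DE stage has no per-gene dispersion
shrinkage and will not reproduce a full DE package's gene lists.  GO
enrichment, isoform quantification and alignment are out of scope.
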