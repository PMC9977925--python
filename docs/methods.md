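# Methods

## The assay and its count model

RRHP sequences junction fragments produced by MspI digestion (CCGG, cut
C^CGG). Adapter ligation reconstitutes the CCGG at the P5 end; after
β-glucosylation of 5hmC, a second MspI digestion cleaves every junction that
is *not* glucosyl-protected, so only 5hmC-bearing junctions amplify. A
sequenced read therefore begins with CCGG and its 5′ end coincides with a
junction: at site start `s` on the plus strand, or at `s + 3` on the minus
strand (CCGG is its own reverse complement, so both strand reads start with
CCGG). The per-junction read count is an abundance measure of 5hmC, and the
dataset is analysed like an RNA-Seq count matrix.

The control library omits the second digestion: every adapterized fragment
amplifies regardless of 5hmC, which measures library complexity and
flow-cell behaviour, not hydroxymethylation. Controls are carried through
quantification and MDS diagnostics but excluded from filtering and from the
differential design matrix.

## Coordinates and counting rules

All internal coordinates are 0-based half-open; BED/bedGraph output keeps
that convention and SAM input (1-based) is converted by pysam. The scanner
is an exact step-1 sliding window; N never matches (the enzyme is
sequence-exact, no IUPAC expansion). A read is assigned to a junction only
if it is mapped, its 5′ terminus is aligned (no 5′ soft-clip — clipping
breaks the coordinate identity with the site), its biological first four
bases are exactly CCGG (zero mismatches: the junction is
adapter-reconstituted sequence, so a mismatch means mis-assignment), and its
5′ coordinate equals the junction's. Duplicates are counted, not removed:
libraries are sequenced at equal volume precisely because abundance carries
the signal. Multi-mapper policy belongs to the aligner; every mapped record
supplied is counted once.

## Synthetic data generator

The generator emulates the two-groups-of-five-plus-control design of the
profiled study. Design choices and defaults:

- **Genome.** Background sequence is scrubbed of accidental CCGGs and the
  requested number of motifs is planted with T guards, ≥ read_length + 30 bp
  apart and away from contig ends. This makes the site count exact, keeps
  every fragment long enough for a full-length (75 bp) read, and is what
  makes the simulate→quantify round trip exact rather than approximate.
- **Ground truth.** Per-site baseline levels π ~ Beta(2, 38) (mean 0.05);
  both strand junctions share a site's π because glucosylation protects the
  CCGG duplex, not a strand. A fraction `diff_fraction` of sites is
  differential: the large group's level is shifted by `effect_logit_shift`
  on the logit scale (default 1.5581, a 4-fold count effect at the baseline
  mean), upward with probability `fraction_up`. The default
  `fraction_up = 0.5` is deliberate: a strongly one-directional effect set
  inflates the affected group's library size, and under plain CPM
  normalization (no TMM, matching the analysis pipeline) that biases every
  null site's log-fold-change — a compositional artefact a simulation
  should expose only when asked to (set `fraction_up` near 1 to study it).
- **Counts.** Negative binomial (Gamma–Poisson) with
  var = μ + φμ², the standard model for sequencing counts with biological
  replication; φ → 0 recovers Poisson. Default φ = 0.1, i.e. a biological
  coefficient of variation of ≈ 0.32 — the conventional figure for
  genetically related laboratory animals (here full-sib fish raised in one
  tank); outbred human-tissue-like values (BCV ≥ 0.5) are available through
  `nb_dispersion`. `depth_factor = 400` puts the global count median near
  the high teens, the scale at which the real study's second filter
  operated (its Ymax was 19).
- **Library sizes.** Default multipliers are 1; `study_design_config()`
  instead scales them to the real study's raw-read depths (a ~9× spread,
  reflecting equal-volume sequencing of unequal-yield libraries).
- **Reads.** 75 bp single-end, CCGG-prefixed, constant Phred 35 quality and
  no substitution errors by default (an optional uniform error rate exists);
  the validation surface is counting, not base calling. Reads truncate at
  fragment boundaries and are dropped below 20 bp, mirroring size selection.
- **Reproducibility.** One run seed fans out into named per-stage RNG
  streams (genome / truth / per-library counts / errors), so stages are
  individually reproducible and whole runs are byte-identical.

What the generator does *not* emulate: adapter read-through, PCR
duplicates, per-cycle quality decay, mappability and multi-mapping, CpG
density structure, or PhiX spike-ins. Passing tests therefore demonstrate
the correctness and calibration of the counting and testing machinery under
the stated count model, not robustness to alignment artefacts in real data.

## Filtering

Sites with ≥ `max_zero_samples` (default 6) zero counts among the ten
biological libraries are removed first; the global median Ymax of the
remaining matrix (all entries, zeros included, controls excluded) then
defines the second pass, which removes sites with ≥ `max_below_median`
(default 6) counts strictly below Ymax. "Below" is strict (<), the plain
reading; the boundary is covered by tests and both thresholds are
parameters. The median is computed after the zero filter because it exists
for the second step — i.e. on the matrix that step sees; a
`median_override` reproduces an externally fixed Ymax (the study's was 19).
Both filters are idempotent and monotone in their thresholds, and survivors
pass through bit-identical; the tests assert all three properties.

## Differential testing

The transform and weights follow the published voom recipe exactly:
`logcpm = log2((c + 0.5)/(L + 1)·10⁶)` with L the column sum of the matrix
supplied; an unweighted first-pass fit; a lowess trend (span 0.5, 3
robustifying iterations, interpolation interval 1% of the x-range) of
sqrt(residual SD) on average log-count; weights are the predicted SD⁻⁴ at
each observation's fitted log-count, clipped to a configurable ceiling
(default 10⁶) so constant sites cannot produce infinite weights. Per-site
weighted least squares is solved in closed form through the 2×2 normal
equations. Hyperparameters (d₀, s₀²) come from the method of moments on
log s² via digamma/trigamma identities, with one monotone Newton root-find
(trigamma inverse); when the observed spread of log s² does not exceed its
sampling expectation, d₀ = ∞ and the prior variance is the arithmetic mean
of the observed variances. Moderated t uses d₀ + d degrees of freedom,
capped at the pooled residual df. BH adjustment is the step-up minimum,
implemented in-package and cross-checked against statsmodels. DhmC calls
use q < 0.05 strictly, with no fold-change threshold. The whole stack
agrees with the R `limma` reference (`voom` → `lmFit` → `eBayes` →
`topTable`) to ~10⁻⁸ on seeded fixtures, and with independent brute-force
normal-equation and moment-equation oracles to 10⁻⁸.

MDS uses pairwise leading-logFC distances (root mean square of the 500
largest absolute logCPM differences per pair) and classical Torgerson
scaling; controls are included there as a lane/complexity diagnostic.

Calibration at desk scale (seeded, 1,000 sites × 2 strands, 5 vs 5): with
no planted effects the p < 0.05 fraction sits within 3 binomial SEs of 0.05
and q < 0.05 calls are ~0; with 10% differential sites at a ~4-fold shift,
observed FDR ≤ 0.10 and sensitivity ≥ 0.8 at q < 0.05 (realized values in
the suite: FDR ≈ 0.03–0.09, sensitivity ≈ 0.95 across seeds). These problem
sizes are the package's test-scale study conditions; the same machinery
runs unchanged on genome-scale matrices.

## Annotation

Gene models come from GFF3 (gene/mRNA/exon; an exonless transcript is one
exon). Categories are decided by priority promoter-TSS > TTS > exon >
intron > intergenic, with strand-relative windows (−1000, +100) around the
TSS and (−100, +1000) around the TES — explicit parameters, since peak
annotators differ here. Among overlapping candidates the gene with the
nearest TSS wins, ties broken lexicographically by gene id for determinism;
nearest-gene reporting is within-contig only. Interval trees provide the
lookups and a linear-scan oracle verifies them in the tests.

## Sample-size formula

`n = 2·(SD·(z_α + z_power)/d)²` with SD the population (divisor N) standard
deviation of all individuals pooled and d the difference of group means.
Note a structural floor: with no within-group variation the pooled SD
collapses to d/2, so n can never fall below
2·((z_α + z_power)/2)² ≈ 3.92 at α = 0.05, power 0.80; SD = 0 is impossible
whenever the means differ (and d = 0 is rejected as undefined).

## Known limitations

- The first MspI digestion is modelled as complete; methylation sensitivity
  of the initial cut is not modelled.
- CPM-only normalization (by design, matching the analysis it implements)
  is vulnerable to strongly compositional effect sets; see the
  `fraction_up` discussion above.
- The annotator is a simplified feature-assignment scheme, not a full peak
  annotator: no CpG islands, repeats, or transcript-isoform resolution.
- The quantifier trusts the aligner's mapping decisions; it applies no
  mapping-quality or multi-mapping filter of its own.
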