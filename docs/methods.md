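# Methods

## The admixture model

Every computation in this package rests on one observation: a tumour
specimen is a mixture of neoplastic cells at purity *t* and diploid
non-neoplastic cells at fraction *f = 1 − t*. For a locus at tumour
copy state *c* ∈ {0, 1, 2}:

* relative depth (tumour/normal), after library scaling:
  *r(c, t) = t·c/2 + (1 − t)*;
* copies per diploid genome in a DNA mixture with normal fraction
  *f*: *2f + (1 − f)·c*;
* expected variant allele fraction of a point mutation:
  *t/2* if heterozygous, *t/(2 − t)* if hemizygous after loss of the
  other allele (one mutant allele among *t + 2(1 − t)* total), *t* if
  homozygous copy-neutral.

Working defaults assume 30% non-neoplastic content in
low-/intermediate-risk GISTs and 20% in high-risk/metastatic GISTs;
both are overridable per case.

## Deletion calling

Depths are normalized in two steps. A library-size factor scales the
tumour profile: the median of per-amplicon tumour/normal count ratios
**over the flanking anchor genes FNTB and FUT8 only** (≥ 4 usable
anchor amplicons required; whole-panel median as fallback, total-count
scaling when > 50% of amplicons are masked). Restricting the median to
the anchors matters: when a deletion covers a large fraction of the
panel, a whole-panel median slides into the wild-type tail and
inflates the deleted ratios by ~10%, eroding the criterion margin.
Amplicons with zero normal depth are masked, never dropped; > 20%
masked amplicons fails the track's QC and suppresses calling.

A homozygous deletion is called by the union of two criteria:

1. **run criterion** — ≥ 9 consecutive amplicons (within one gene;
   masked amplicons break runs, conservatively) with ratio below the
   cutoff *f* + 0.10, i.e. 0.40 at *f* = 0.30 and 0.30 at *f* = 0.20.
   The margin 0.10 places the cutoff midway between the homozygous
   expectation (*f*) and safely below the hemizygous expectation
   ((1 + *f*)/2); a cutoff reaching the hemizygous expectation warns
   and is capped.
2. **gene-end criterion** — mean ratio of the terminal `end_size`
   (default 5) amplicons at either gene end, divided by the mean over
   all of the case's unmasked markers, below a fixed 0.4 threshold
   (the derived cutoff can be substituted). "How many markers
   constitute the gene end" is not externally defined; 5 is our
   choice and configurable.

Overlapping calls from the two criteria merge into one call annotated
with both. Flanking-gene amplicons never join a MAX run.

## qPCR copy number

Comparative-Ct with *FNTB*/*FUT8* as reference assays and a
non-neoplastic DNA sample as calibrator:
ΔCt = Ct(target) − mean Ct(references) (arithmetic mean of Ct,
equivalent to the geometric mean of quantities); ΔΔCt relative to the
calibrator; copies = 2·E^(−ΔΔCt). Amplification efficiency E defaults
to 2.0 (perfect doubling) and is configurable; no standard-curve
fitting is attempted. Replicates are averaged with a dispersion flag
above sd 0.5 cycles; absent Ct is censored at 38 cycles (flagging the
estimate as an upper bound); any no-template-control amplification
before 38 cycles aborts the run as contaminated. How the three MAX
exon assays and two references combine into a single figure is not
externally specified: per-target estimates are emitted alongside
their mean.

## Variant interpretation

HGVS c.-notation substitutions and small del/ins/dup (with ±n
intronic offsets) are parsed against a packaged transcript model —
five exons, 483-nt CDS (160 codons + stop), with the 151-aa isoform
as a 27-nt in-frame difference. The packaged sequence is a
**synthetic stand-in** (`data/max_transcript_synthetic.fasta`): the
classification logic depends only on exon/CDS structure, and the
variant fixtures are generated against the packaged sequence so every
HGVS string validates. Scope limits: 3′-UTR (`c.*`) positions are
rejected (outside the targeted region), in-frame
insertions/duplications are rejected, in-frame deletions map to
`intragenic_deletion`.

Consequence assignment is deterministic: intronic offsets ±1/±2 are
splice-site (the invariant GT/AG dinucleotides) and report **both**
canonical aberrant outcomes — skip of the adjacent exon and retention
of the adjacent intron — as candidates, since the realized transcript
is an experimental outcome, not a sequence-derivable one; deeper
offsets are intronic; negative positions are 5′-UTR (no
binding-site modelling); coding substitutions are classified by
mutating and retranslating the codon (nonsense/start
loss/synonymous/missense); length-changing coding variants not a
multiple of 3 are frameshifts; deletions covering a whole exon are
intragenic deletions.

Zygosity inference is nearest-expectation under the VAF model with
tolerance 0.05: every class within tolerance is reported (ambiguity
is surfaced, never resolved silently); with unknown purity the
compatible purity interval per class is returned instead. Somatic
status: a matched normal decides; without one, a VAF incompatible
with a heterozygous germline variant but compatible with a
hemizygous/homozygous state at plausible purity (0.5–1.0) is
`consistent_with_somatic`.

## Cohort statistics

Protein status per case: immunoblot expression, normalized to a
MAX-wild-type control line, below 0.4 (strict) is loss; a case is
protein-loss when **any** performed assay (immunoblot or IHC) shows
loss. The union rule reflects assay physics: IHC resolves clonal loss
within the neoplastic compartment, while a whole-lysate immunoblot
can be pushed above threshold by non-neoplastic cells — so a loss
call by either assay stands. Untested cases leave the denominator of
each comparison; nothing is imputed. Percentages print as integers,
round half up.

Fisher's exact test (two-tailed) uses the point-probability
definition — the p-value sums hypergeometric probabilities of every
same-margin table no more probable than the observed one — computed
with exact integer combinatorics, so ties between equally probable
tables are handled exactly rather than to floating-point tolerance;
the doubling rule (twice the smaller tail, capped at 1) is available
behind a flag. Degenerate tables (a zero margin) return p = 1. No
multiple-testing correction is applied.

## Synthetic data: what it emulates and what it does not

Depth profiles: per-amplicon efficiency factors are drawn log-normal
(σ = 0.15) once per panel and shared between the paired tumour and
normal — modelling amplicon bias that paired normalization cancels —
and counts are negative-binomial with variance μ + α·μ². The default
α = 0.002 gives variance 2× Poisson at the default depth 500,
per-amplicon ratio CV ≈ 10%: the noise level at which a fixed-cutoff
criterion with a 0.10 margin retains a ≥ 3σ per-amplicon margin, as a
working assay must. α = 0 switches every generator to exact
expectations, so closed-form checks hold bit-exactly. Ct values
follow Ct = intercept − log(q)/log(E) with Gaussian replicate noise
(default sd 0.2 cycles); zero template never amplifies. Cohorts are
stratified Bernoulli draws; the 76-case fixture is hard-coded, not
sampled, and reproduces the study's marginal counts cell by cell.

Not emulated: read-level errors, alignment, GC bias, batch effects,
inter-plate qPCR variation, or subclonal heterogeneity (every tumour
cell carries the simulated genotype). Passing recovery tests
therefore demonstrates the calling logic under the admixture model's
own assumptions, not performance on real libraries.

Recovery operating point (property, not an external claim): over 200
simulated cases at purity 0.7/0.8, mean depth 500, default
overdispersion, deletion spans of 10 and 14 amplicons, sensitivity is
≥ 0.95 with false-positive rate ≤ 0.01. The binding constraint is the
purity-0.7 minimal-span case, where the expected deleted ratio (0.30)
sits 0.10 below the cutoff; heavier overdispersion than the default
rapidly destroys this margin, which is why the default is what it is.

## Numerical and formatting choices

* Seeds: a single integer seeds `numpy.random.default_rng`; identical
  seed + configuration is bit-identical output.
* BED intervals 0-based half-open; HGVS transcript coordinates
  1-based; reports state both conventions.
* Missing values are empty fields (an empty Ct field is censored,
  never zero); floats are written at 6 significant digits; writers
  order rows deterministically.
* Integer percentages round half up. The one published frequency
  where printing conventions disagree is IHC (14/22 = 63.6%): this
  package prints 64.

## Known limitations

* The packaged transcript sequence is synthetic; consequence calls on
  real MAX variants require substituting the genuine mRNA record.
* Zygosity inference assumes copy-neutral classes only (no
  amplification states, no subclonality).
* The gene-end criterion's marker count (5) and the cutoff margin
  (0.10) are package choices exposed as parameters, not externally
  fixed values.
* The deletion caller reports homozygous loss only; hemizygous-level
  depth (ratio ≈ (1 + f)/2) is deliberately not called.
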