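# Methods

## Depth-requirement model

The quantity estimated is the minimum required sequencing depth (MRSD):
the number of uniquely mapping reads, in millions, at which a fresh
RNA-seq run of the same tissue would give at least *r* reads to at least
proportion *p* of a transcript's splice junctions, with that guarantee
holding for at least proportion *m* of control samples.

Per control sample the computation is purely empirical — no parametric
model is fitted. With junction counts *R* sorted ascending and
*R<sub>p</sub>* the largest-index order statistic whose suffix
proportion is still ≥ *p*, the sample's required depth is
*r·d/R<sub>p</sub>*: junction coverage is assumed to scale linearly with
total depth, which is exact in expectation for subsampling a library and
a good approximation across libraries of the same preparation. When
*R<sub>p</sub>* = 0 the sample provides no evidence that the critical
junction is sequenceable at any depth, and contributes "unfeasible"
(treated as +∞). The cohort-level MRSD is the ⌈*m·n*⌉-th smallest
per-sample value; if that order statistic is +∞ the transcript is
reported unfeasible. Modelled assumptions, stated plainly:

- linear scaling of junction counts with depth within a sample;
- control samples are exchangeable draws from the tissue's coverage
  distribution (no disease-state or eQTL/sQTL expression shifts);
- junction counts reflect uniquely mapping split reads only.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| *r* | reads required per junction | 8 | MRSD is exactly linear in *r* |
| *p* | proportion of junctions covered | 0.75 | order statistic, no interpolation |
| *m* | proportion of controls for which the depth holds | 0.95 | 0.99 for stricter guarantees |
| threshold | low/high bracket boundary | 100 M reads | boundary value classes as high |
| min_reads | event read-count filter | 2 | |
| min_nrc | non-singleton NRC filter (strict >) | 0.25 | singletons exempt |

### Numerical conventions

Order-statistic indices are computed as exact integer arithmetic
(⌈*p·n*⌉, ⌈*m·n*⌉) with a 10⁻⁹ guard against floating-point products
landing a ulp above an integer; both are validated against brute-force
suffix-proportion enumeration over thousands of random vectors. No
quantile interpolation is used anywhere: counts are integers and
interpolation would manufacture values never observed. Boundary
conventions are ≥ for *p* and *m* satisfaction, < threshold for the
low-MRSD bracket, strict > for the event NRC filters, and ≥ 0.5
(inclusive) for the splice-impact score cut-off. Unfeasible values are
+∞ in memory and the literal string `unfeasible` on disk, never a
numeric sentinel.

## Transcript models

One junction set per gene, chosen hierarchically: the gene's MANE
transcript when every one of its junctions coordinate-matches a junction
derivable from the working annotation (the strictest testable reading of
"supported"); otherwise the union of the gene's RefSeq transcripts'
junctions ("RefSeq composite"); otherwise the union over the working
annotation's transcripts. An unsupported MANE transcript falls through
to the next tier rather than being excluded. Junctions are 1-based,
fully-closed intron intervals — the STAR `SJ.out.tab` convention — so
STAR output needs no coordinate conversion; GTF exons are converted as
junction = (exon end + 1, next exon start − 1). Strand `unknown` matches
only `unknown`; there is no strand-relaxed joining. Inter-transcript
MRSD variability is summarised by the population coefficient of
variation over a gene's feasible transcripts; unfeasible transcripts are
excluded from the CV and surfaced through the feasibility counts
instead, since a CV over infinities is undefined.

## Splice-event scoring

Case junctions falling inside a gene model's span are scored by: read
count; normalized read count (NRC), the event count divided by the
highest-count *adjoining* canonical junction, where adjoining means
sharing the event's donor or acceptor coordinate and, when no canonical
junction shares a splice site, the nearest flanking canonical junction
on each side; NRC fold change, the case NRC over the highest NRC for the
same junction among controls; and the number of samples carrying the
junction. Each control's NRC is computed against that control's own
canonical counts, so a control with globally low coverage is not
penalised. Events with no expressed adjoining canonical junction are
flagged rather than scored.

Filtering retains singletons (no control carries the junction) and
events whose NRC strictly exceeds every control's. Read-count and NRC
thresholds are applied separately so their sensitivity cost is
inspectable. Ranking places singletons (by decreasing read count) above
all non-singletons (by decreasing fold change); ties break by read count
and then junction coordinates, an arbitrary but deterministic total
order.

## Evaluation experiments

**PPV/NPV.** A prediction is positive when a test sample's depth meets
or equals a finite MRSD (unfeasible ⇒ negative); the target is achieved
when ≥ ⌈*p·n*⌉ junctions carry ≥ *r* reads — the same rule the critical
count encodes, making self-evaluation exactly consistent. PPV and NPV
are the achieved fraction of positives and the unachieved fraction of
negatives; either is undefined (NaN) when its denominator is empty.

**Held-out calibration.** Fresh cohorts are drawn from the generative
model, thinned per transcript to exactly the predicted MRSD (binomial
thinning of a count drawn at depth D to depth t is distributionally a
fresh draw at depth t), and scored for target achievement. Coverage is
pooled over (transcript, sample) pairs; its Monte-Carlo standard error
is quoted at the resolution of the held-out samples, which are the
Monte-Carlo unit shared across transcripts. The ⌈*m·n*⌉-th order
statistic of *n* = 150 samples has expected coverage ≈ 143/151 ≈ 0.947
at *m* = 0.95 — slightly conservative-of-nominal by construction — and
the observed pooled coverage matches this.

**Downsampling.** Gene-level read removal is implemented as binomial
thinning of junction counts with retention probability 1 − f, the exact
count-marginal of removing a uniform random read subset. Rank stability
re-runs the full event pipeline at each thinning level and records
detection losses.

**Bootstrap background.** Control subsets of size 30/60/90 are drawn
with replacement (2,000 replicates by default) and the event filter
applied against each draw; medians of singleton and non-singleton
retained-event counts are reported. Because a control's own-sample NRC
does not depend on which controls are drawn, the per-junction control
NRCs are precomputed once and each replicate reduces to presence/max
reductions over the drawn rows — a vectorisation proven equivalent to
re-running the object pipeline by a dedicated test, and bit-reproducible
under a fixed seed. No p-values are attached; the analysis is
descriptive.

**TPM comparison.** Ordinary least squares of log₁₀ MRSD on log₁₀ TPM
over genes with finite MRSD and TPM > 0 (zero-TPM and unfeasible genes
are tabulated in the bracket summary instead). When coverage is exactly
proportional to expression the relation is log-log linear with slope −1;
3′ bias breaks the proportionality for 5′ junctions and degrades r²,
producing high-expression genes with high depth requirements — the
mechanism by which TPM over-promises assayability.

## Synthetic-data generator

Counts for gene g, junction j, sample s are drawn
NegBin(mean = expr_g · d_s · bias_{g,j}, var = μ + φμ²) via
gamma–Poisson mixing; φ = 0 gives the Poisson limit and `exact_counts`
the noiseless rounded-mean limit used for closed-form checks. Defaults,
chosen once as a realistic bulk cohort: 150 samples; depths log-normal
with mean 75 M uniquely mapping reads (σ_log = 0.3); per-gene junction
rates log-normal with median 0.3 reads per million and σ_log = 1.5, which
spans clearly-feasible through unfeasible genes at default parameters;
φ = 0.1, a moderate bulk-RNA-seq overdispersion; 3–15 junctions per
gene; 3′ bias off. The bias model is a multiplicative exponential ramp
across a gene's junction order with geometric mean 1, so total gene
expression (hence TPM) is nearly invariant while 5′ junction coverage
falls. Injected aberrant junctions share a donor with a canonical
"anchor" junction whose case count is set so the event NRC hits the
requested target (nearest attainable integer ratio, recorded in the
ground truth); non-singleton injections give carrier controls support at
about half the case NRC, always strictly below it.

What the generator does **not** emulate: mappability and GC artefacts,
PCR duplication, isoform switching between tissues, correlated
junction usage within a transcript beyond the shared gene mean, sample
quality failures, and annotation errors. Passing tests therefore
demonstrate the estimator's arithmetic, calibration and ranking logic
under a faithful count model — not robustness to every artefact of real
cohorts, for which the published tissue-specific behaviour of such
cohorts remains the reference.

## Problem sizes

The validation suite uses a 150-sample × 200-gene cohort (seed 1) for
the depth-model properties, 500 held-out samples for calibration, 10,000
random vectors for the order-statistic oracles, 2,000 replicates for
thinning and bootstrap experiments, and 100 × 150 cohorts for the TPM
experiments — sizes at which every Monte-Carlo band in the tests is
comfortably resolved.

## Known limitations

- Depth is the only lever modelled: differential expression,
  allele-specific expression and isoform-similarity questions are out of
  scope.
- The per-sample linear-scaling assumption ignores saturation and
  duplication effects at extreme depths.
- `d` must be supplied by the user (manifest); it cannot be recovered
  from junction counts alone.
- The aggregation order statistic is conservative at small cohort sizes
  (expected coverage k/(n+1), not m exactly).
- Intergenic case junctions, and genes absent from the annotation, are
  not scored.
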