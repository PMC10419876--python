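# Methods

## Observation model for bisulfite counts

Bisulfite treatment converts unmethylated cytosine to uracil (read as T);
methylated cytosine is protected.  Two error channels matter at the
count level: the non-conversion rate `r` (an unmethylated C read as
methylated) and the under-conversion rate `f` (a methylated C read as
converted).  For a site with true methylation probability `θ`, a read
reports "methylated" with probability

```
p_read = θ·(1 − f) + (1 − θ)·r
```

and the simulator draws coverage `n ~ Poisson(coverage_mean)` and
methylated count `m ~ Binomial(n, p_read)` independently per site,
sample and replicate.  Defaults: `coverage_mean = 20` (Poisson is the
simplest count model matching a stated mean depth), `r = 0.004`
(mirroring a 99.6 % conversion rate), `f = 0`.  The control contig has
`θ = 0` everywhere, so its pooled methylated-read fraction is a
consistent estimator of `r`; `estimate_r` uses exactly that pooled
fraction.

## Site calling

A site is called methylated when the one-sided upper-tail binomial
p-value `P(X ≥ m)` with `X ~ Binomial(m+u, r)` survives BH correction at
`α = 0.05`.  The test is one-sided because the alternative — "this site
is methylated above the error rate" — is directional.  Sites with fewer
than 4 reads are excluded from the test and from the BH family: below
that coverage the test is vacuous (`P(X ≥ m)` cannot reach conventional
significance) and including such sites only dilutes the correction.
Calling is per strand and per sample; symmetric-CG merging is left to
region-level pooling, and replicate pooling is deferred to the DMR
stage.

Under a complete null (`θ = r` everywhere) every discovery is false; BH
then bounds the probability of any discovery by `α`, and with the highly
discrete binomial p-values at ~20× coverage the realized false-call rate
is essentially zero.  The calibration test asserts exactly this.

## Methylation levels

`ML = mC / (mC + non-mC)` pooled over the reads of a region — never the
unweighted mean of per-site fractions.  Two conservation identities
follow and are asserted exactly: the pooled ML of a bin equals the
coverage-weighted mean of its per-site MLs, and bulk ML equals the
coverage-weighted aggregate of the ~10 kb bin MLs (an integer-count
identity, so the test uses exact equality of pooled counts).  A region
with zero pooled coverage is *undefined* (NaN), which is distinct from
an ML of 0.  Genome bins tile each chromosome with the final partial bin
retained, so bin widths always sum to the chromosome length.

## DMR calling

Per context, fixed windows (200 bp, step 50 bp) slide over each
chromosome.  Replicate counts are pooled by summation within each
condition, and the window's 2×2 table
`[[m_case, u_case], [m_control, u_control]]` is tested with a two-sided
Fisher's exact test; windows with zero pooled coverage in either
condition are skipped.  BH runs across all covered windows of a context
(all chromosomes).  Windows with `q < 0.05` and `|ΔML| ≥ 0.1` are merged
when they share a direction and lie within 100 bp; merging never joins
opposite directions.  Merged-region statistics (MLs, Δ, p) are
recomputed on the pooled counts of the whole region, and BH is re-applied
across the merged regions of a context so the emitted `q` honours the
same contract (`q < α`, `|Δ| ≥ δ_min`) as the selection step.

The Fisher p-value is computed from the full hypergeometric support via
log-gamma (the same two-sided "sum of probabilities ≤ observed" rule as
`scipy.stats.fisher_exact`, which serves as the independent cross-check
in the tests); this keeps the ~12 000-window scan under a second.

Sign convention: Δ = case − control, so `hyper` means methylation gained
under the stress/knockdown condition.  Defaults (window 200, step 50,
δ_min 0.1, α 0.05, merge gap 100) follow common plant-methylome
practice and are all exposed in the configuration.

A condition given with a single sample runs with a logged "no
replication" warning — the pooled test is still defined — while an empty
condition is an error, since no 2×2 table exists.

## Gene association

The promoter is the 2 000 bp upstream of the TSS, strand-aware and
truncated at contig edges — the span typically used for promoter-reporter
constructs in this field.  A DMR links to a gene when it overlaps the
promoter or any gene-body feature by ≥1 bp; every overlapped feature
kind is recorded (a DMR across an exon/intron junction carries both),
and a single representative feature is chosen by the precedence
promoter > exon > intron > 5′-UTR > 3′-UTR when one label is needed.
Introns are derived as gene body minus annotated subfeatures.  A gene
with both hyper and hypo DMRs appears in both direction tallies.

## Expression

RPKM = counts / (kb of transcript × millions of mapped reads).  DEGs:
Welch (unequal-variance) two-sample t on log2(RPKM + 1), BH across
genes, called when `|log2FC| ≥ 1` and `q < 0.05`; log2FC is the mean
log2(RPKM+1) difference, case − control.  The pseudocount of 1 makes
zero handling explicit.  Zero-variance identical groups get p = 1; a
deterministic offset with no within-group noise gets p = 0.  The
procedure is deliberately self-contained rather than delegating to a
negative-binomial GLM framework, keeping every stage of the pipeline
specified by its own code.

## Integration

DMG–DEG records are the gene-id intersection, one row per (gene, DMR
link).  The quadrant tally counts each (gene, direction) pair once per
direction the gene carries, so totals can exceed the record count — the
convention implied when hyper/hypo tallies are reported per gene
direction.  Feature/context distributions are computed over DMR links
(not genes), with every overlapped kind counted.  For scatter plots each
gene contributes its largest-|Δ| DMR; three gene sets are supported
(strict DMG∩DEG records, all DEGs with links, all linked genes) because
which set a published scatter uses is often ambiguous.  Correlations
report Pearson R² and Spearman ρ (average ranks on ties) per stratum
with at least 3 pairs; zero-variance strata are reported as undefined.

## The synthetic study generator

The generator emulates the design of a two-timepoint nutrient-stress
methylome/transcriptome experiment: 2 conditions × 3 replicates, two
50 kb chromosomes with 24 strand-alternating genes (fixed body template:
5′-UTR, 3 exons, 2 introns, 3′-UTR; 2 kb promoter clearance), repeats in
intergenic space, and a 10 kb fully unmethylated control contig.

Baseline methylation probabilities are CG 0.35 / CHG 0.20 / CHH 0.05 —
ordered like a plant methylome but compressed so that a symmetric
±0.5 planted effect stays inside [0, 1]; configurations that would push
θ outside the unit interval are rejected.  Planted DMRs are 200 bp and
default to 20 per run, allocated 70/10/20 % to CHH/CHG/CG under
`short_term` and 70/10/20 % to CG/CHG/CHH under `long_term`, matching
the qualitative dynamic of short-term-CHH vs long-term-CG differential
methylation.  Directions alternate hyper/hypo.  CG regions are planted
in promoters of distinct genes; CHG/CHH regions alternate between gene
bodies and intergenic space so that feature-stratified analyses see
every stratum.  A hyper region raises case θ to baseline + Δ; a hypo
region raises *control* θ instead, so |Δ| is constant and both
conditions stay in range.

`met1_knockdown` reuses the long-term layout and multiplies every CG
site's case-condition θ by a retention factor (default 0.25), emulating
genome-wide CG maintenance loss; CHG/CHH are untouched.

Expression: per-gene base means are log-normal (median 200 counts,
log-sd 1), counts are gamma-Poisson (negative binomial) with dispersion
0.1 — standard RNA-seq overdispersion.  Planted DEGs shift the case mean
by 2^±3.  *Coupled* genes — a configurable fraction of the genes with a
planted promoter-CG hyper region — get
`log2FC = planted_log2fc × (realized promoter ΔML) / planted_delta`,
tying transcription to methylation.  In the short/long scenarios the
realized Δ is +planted_delta, so coupled genes are exactly the planted
up-DEGs; under `met1_knockdown` the realized promoter Δ turns negative
and coupled genes lose their upregulation — the pattern expected when a
methylation-dependent activator loses its promoter methylation.  Because
the annotated panel is a tiny window of a transcriptome, each sample's
mapped-read total adds a Poisson background of 10⁶ reads to the panel's
count sum; this keeps the RPKM denominator stable against planted fold
changes, as in a genome-scale library where DEGs are ~1 % of genes.

What the generator does **not** emulate: read-level artefacts (M-bias,
PCR duplicates, mapping error), per-site θ heterogeneity within a
context, linked methylation of neighbouring sites, batch effects, and
realistic gene-length/GC variation.  Passing recovery tests therefore
demonstrate the *statistical machinery* (calibration, thresholds,
bookkeeping, conservation) on data generated by the stated model — not
performance on real libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run the default study (≈55 000 cytosine
sites × 12 samples) a handful of times with fixed seeds; a full
simulate-and-call cycle takes ~1.5 s, the whole suite well under five
minutes.  Sensitivity/FDR assertions aggregate over 3–5 seeds to damp
Monte-Carlo noise at these sizes.  All randomness flows through
`numpy.random.default_rng` seeded per stage from the study seed, so
every artifact is a pure function of (config, seed); identical seeds
give byte-identical outputs.  Exact identities are asserted on integer
pooled counts; floating comparisons use relative tolerances ≤ 1e-9.

## Known limitations

* The Fisher window test ignores biological replicate variance
  (replicates are pooled), so its FDR control is conditional on the
  simulator's exchangeable-replicate model; dispersion-aware callers
  exist for real data where replicates disagree.
* DMG deduplication is direction-aware by design (a gene can count as
  both hyper- and hypo-DMG); a unique-gene count is available from the
  aggregated DMG table.
* The DEG rule (Welch + BH on log2 RPKM) is intentionally simple; with
  n = 3 replicates its per-gene power at |log2FC| = 3 is ≈ 0.9, which
  the recovery tests reflect.
* Correlation strata need ≥ 3 pairs; at desk scale the gene-body strata
  are small, so stratified ρ values carry wide Monte-Carlo error and are
  compared only qualitatively (promoter-CG vs gene body).
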