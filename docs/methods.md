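# Methods

This note documents the models and procedures implemented in
`coderep`, the defaults that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Discovery pipeline

### Differential expression and cooperative induction

Input is a genes × samples matrix of normalized log₂ intensities with
≥2 replicates in each of four arms (DMSO, EZH2i, HDACi, Combo).  For a
contrast treatment-vs-reference, each gene gets

* `log2fc` — mean(treatment) − mean(reference);
* `p` — two-sided moderated t: the pooled within-group variance
  s² (df = n₁+n₂−2) is shrunk toward a prior fitted across all genes
  by empirical Bayes, s̃² = (d₀s₀² + d·s²)/(d₀+d), with (d₀, s₀²)
  estimated by the method of moments on log variances (Smyth 2004);
  the t statistic uses s̃² and d₀+d degrees of freedom.  At 2–4
  replicates a gene-wise variance estimate has ~2 df and an
  unmoderated test has essentially no power at genome-wide significance
  regardless of effect size; moderation is the standard remedy and is
  what array-analysis suites apply by default.  The implementation was
  verified against Bioconductor limma to machine precision (prior fit
  and p-values; frozen oracle values in the test suite).  A plain
  Welch t is available via `moderated=False`.
* `q` — Benjamini–Hochberg step-up over all genes of the matrix,
  computed per contrast (no independent filtering).

Degenerate convention: when there is no variance information at all
(both groups constant — e.g. noiseless simulations), equal means give
p = 1 and unequal means give the smallest positive double, so
threshold behavior is deterministic.

A gene is *induced* when `log2fc > 1` and `q < 0.05`, strict
inequalities.  *Cooperatively induced* genes are the intersection of
the induced sets of Combo-vs-DMSO, Combo-vs-HDACi, Combo-vs-EZH2i;
this is always a subset of the Combo-vs-DMSO induced set.

### Peak loss at promoters

Coordinates are 0-based half-open throughout; touching intervals do
not overlap.  Each retained transcript (protein-coding only, unless
disabled) gets the window [TSS − W, TSS + W) clipped at 0, W = 10 kb
by default.  Windows are strand-blind — strand matters upstream only
in choosing the TSS.  A peak is assigned to a window on ≥1 bp overlap
and may serve several transcripts.  A control peak assigned to a
window is **lost** when no treated peak overlaps it by ≥1 bp; matching
is by overlap only (no peak identities, no reciprocal fraction, no
score thresholds — peak calling is upstream of this package).
Transcript lost = ≥1 lost peak; gene lost = ≥1 lost transcript.  This
rule is monotone: adding treated peaks can only flip lost → retained.
Genes losing H3K27me3 under EZH2i are the putative PRC2 targets.

### Candidate intersection

Candidates = cooperatively induced ∩ PRC2 targets.  An optional
user-supplied exclusion list (symbol → reason) removes symbols after
the intersection, mirroring manual biological deprioritization as
declarative configuration; excluded symbols and reasons are recorded.
Every report embeds provenance: SHA-256 digests of all inputs, all
thresholds, and a config hash stamped into each output file.

## Downstream analyses

### ssGSEA

For one sample, genes are ranked by expression descending (ties broken
by stable input order).  Walking the ranked list, in-set positions add
rank^α / Σ(in-set rank^α) and out-of-set positions add 1/(N−|S|); the
score is the summed difference of the two running fractions, α = 0.75.
No cross-set range normalization is applied, because scores are
immediately z-scored per signature across samples ((x−mean)/SD, n−1
denominator), which absorbs any affine rescaling.  The score depends
on ranks only (invariant to monotone shifts) and is bounded by N in
absolute value.

### Classic GSEA

Ranking metric: signal-to-noise (μ₁−μ₂)/(σ₁+σ₂), each σ floored at
0.2·|μ| (0.2 when μ = 0) to avoid degenerate small-replicate metrics.
Running sum: in-set steps add |metric|^w normalized by the in-set
total (w = 1), out-of-set steps subtract 1/(N−|S|); ES is the signed
maximal excursion.  The null is **gene-set permutation** (random
same-size sets) because phenotype permutation is undefined at the
replicate counts this pipeline targets.  Significance is one-sided
within the same-sign null pool with a +1 guard,
p = (1 + #{|ES₀| ≥ |ES|, same sign}) / (1 + #same-sign nulls), which
calibrates correctly under the null (verified by simulation: rejection
at 0.05 within Monte-Carlo slack); NES = ES / mean(|ES₀| same sign).

### Cohort stratification and survival

z-scores of a gene are computed against the *normal-tissue* class:
zᵢ = (xᵢ − mean_ref)/SD_ref with the n−1 SD, for all samples including
the reference class; the headline statistic is the fraction of a class
at or above a threshold (≥3 SD, inclusive).  High/low stratification
takes the top and bottom floor(0.10·n) samples with deterministic
sample-id tie-breaking.  Survival uses the Kaplan–Meier product-limit
estimator and the two-group log-rank test (χ², 1 df), both via
lifelines; a no-event input is rejected as undefined.

### HSA synergy

Responses are % inhibition relative to the vehicle (0,0) well,
100·(1 − raw/vehicle), not clipped.  For each well with both doses
positive, the Gaddum/HSA reference is max(response(a,0),
response(0,b)); the score is the mean excess over those wells only —
margins have zero excess by definition and would dilute it.  Replicate
matrices are averaged well-wise before scoring.  Score > 10
(percentage points, strict) flags synergy.

## Synthetic data generator

A single master seed is split into named substreams (annotation,
truth, peaks, expression, cohort, dose), so regenerating one input
never perturbs the others; identical configs give byte-identical
files.

* **Annotation** — 1–2 transcripts per gene, TSSs spaced ≥3× the
  window halfwidth so no window captures a neighbor's peaks; ~10% of
  genes are noncoding to exercise the protein-coding filter.  A genome
  too small for the requested layout raises a sizing error naming the
  required minimum length.
* **Gene classes** — defaults: 1000 genes, 30 `cooperative_prc2`, 20
  `additive`, 20 `ezh2i_only`, 20 `hdaci_only`, remainder null.
  Cooperative and additive genes gain `effect_log2fc` (2.0) in Combo
  only; single-agent classes gain it in their agent *and* Combo (so
  they fail the Combo-vs-single contrast); noise is Gaussian on the
  log₂ scale (σ = 0.25, array-like — not count-based, matching the
  contrast model), 3 replicates per arm.  σ = 0 is accepted to
  exercise the noiseless limit, in which the selected set equals
  {cooperative ∪ additive} exactly.
* **Peaks** — a 1 kb promoter peak at every cooperative transcript in
  DMSO/HDACi, absent from EZH2i/Combo; a stable promoter peak at 30%
  of other transcripts and 200 background peaks (kept clear of planted
  TSSs) in all conditions.  Only cooperative genes lose peaks, so
  peak-loss calling must recover exactly that class.
* **Cohort** — 50 normal / 150 primary / 200 metastatic samples.
  EZH2 class means 0/2/4 (unit within-class SD), so the expected
  metastatic fraction ≥3 SD above normal is Φ(1) ≈ 0.84; the observed
  fraction additionally varies with the sampling error of the
  normal-class mean and SD estimates (n = 50).  ATF3 means fall
  0/−1/−2, and tumor samples flagged ATF3-low (fair coin) are shifted
  a further −1.5.  Survival is exponential with proportional hazards —
  the simplest model with a closed-form median (ln 2/λ): baseline
  median 60 time units, hazard ×3 for ATF3-low samples; with
  probability `censor_rate` (0.2) a sample is censored uniformly
  before its event.  Two 40-gene signature blocks track a pair of
  latent activities (PRC2-derepression u, ATF3 activity v) drawn
  bivariate standard normal with correlation ρ = 0.7, each gene =
  latent + N(0, 0.5), on top of 400 null genes.  The null panel is
  deliberately large: rank-based set scores are computed against the
  whole panel, and if the two signature blocks dominate the universe
  they displace each other's ranks and distort the score coupling —
  real signatures are a negligible fraction of a transcriptome.
* **Dose matrices** — saturating Hill curves for the single agents
  (doses 0–10 and 0–8, grids include 0) and combination wells equal to
  the HSA reference plus a constant planted excess (15 points), so the
  recovered score equals the planted excess exactly.

### What the generator does not emulate

No probe-level array structure, no sequencing reads or realistic
chromatin domains, no copy-number or purity effects in the cohort, no
dose-response measurement noise, and independent Gaussian gene noise
rather than correlated expression programs.  Passing recovery tests
therefore demonstrates correctness of the *procedures* under the
stated generative model, not robustness to every property of real
data.

### A note on signature-score correlation

The latent coupling ρ is faithfully recovered (within sampling error)
by *linear* signature scores (mean over set members).  Rank-based
ssGSEA scores are a nonlinear monotone transform of the latent, which
intrinsically attenuates a Pearson correlation of 0.7 to roughly
0.5–0.65 depending on panel composition; the tests assert exact
recovery for the linear score and a strong positive association for
the ssGSEA route.  This mirrors the spread of signature correlations
seen across real cohorts.

## Problem sizes and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `fc_threshold` | 1.0 (log₂) | induction fold-change cut, strict |
| `q_threshold` | 0.05 | BH-adjusted p cut, strict |
| `halfwidth` | 10 000 bp | TSS window half-width |
| `protein_coding_only` | true | biotype filter before windows |
| α (ssGSEA) | 0.75 | rank-weight exponent |
| decile | 0.10 | high/low stratification fraction |
| z threshold | 3 SD (inclusive) | overexpression call vs normal |
| HSA threshold | 10 points (strict) | synergy classification |

The test suite and acceptance script run the full default study
(1000 genes, 3 replicates, 400-sample cohort, 5×6 dose grid) plus
Monte-Carlo calibrations (200 GSEA-null repetitions at 199
permutations; 500 log-rank null simulations at n = 40/arm) — sizes
chosen to give stable estimates at interactive runtimes.

## Known limitations

* Peak matching is any-overlap; reciprocal-overlap or signal-aware
  matching would distinguish peak shrinkage from loss.
* The moderated test assumes a common variance across the two arms of
  a contrast (pooled model); arm-specific variance with moderation is
  not implemented.
* Gene identity is the case-sensitive symbol string; no alias
  resolution or probe summarization.
* Single-signature analyses only: no FDR across gene-set collections,
  no leading-edge extraction, no Cox regression or multivariate
  survival adjustment, and no Bliss/Loewe/ZIP synergy references.
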