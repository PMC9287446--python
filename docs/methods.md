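# Methods

This note documents the statistical procedures implemented in `uvmeth`, the
assumptions behind the synthetic cohort generator, the numerical choices,
and the design decisions taken where the methodology was genuinely open.

## UV mutational-signature inference

Somatic SNVs are folded onto the pyrimidine strand (records with a purine
reference are reverse-complemented together with their trinucleotide
context) and counted over the 96 canonical substitution-by-context channels
in lexicographic order. Tandem CC>TT events are collected from two encodings
that real variant callers emit: explicit dinucleotide (DNP) records with
ref CC / alt TT after folding, and pairs of genomically adjacent C>T SNVs,
which are merged into one event and removed from the SNV channels. The
*total mutation burden* is defined as remaining SNV events plus DNP events —
counting events rather than alleles keeps the two branches of the
classification rule on a common scale.

A sample is called **UV-mutant** when

- C>T at dipyrimidine sites > 60% of the total burden, or
- CC>TT events > 5% of the total burden,

with strict inequalities. *Dipyrimidine* is interpreted as either flanking
base of the folded context being a pyrimidine (12 of the 16 C>T channels);
the rule is scale-invariant by construction. Zero-burden samples yield a
flagged non-call.

De-novo signature extraction uses Frobenius multiplicative-update NMF
(Lee-Seung), max 2000 iterations, relative-loss tolerance 1e-6, best of 10
seeded random restarts; H rows are renormalized to sum 1 with the scale
moved into W, so each row is a profile comparable by cosine similarity to a
user-supplied reference matrix (match threshold 0.8). The rule-based call is
authoritative; the NMF/cosine result is attached as annotation. This
ordering is a deliberate design choice: the threshold rule is deterministic
and auditable, while factorization results depend on rank and restarts.

The shipped UV-like reference profile is synthetic: 0.95 of its mass lies on
the 12 dipyrimidine C>T channels (weight 2:1 favoring 5'-pyrimidine
contexts, where UV photoproducts form), 0.05 uniform elsewhere. This
reproduces the near-total C>T-dipyrimidine dominance of real UV signatures
without copying any published signature table, and leaves the rule's 60%
threshold a clear margin at mixture weights ≥ 0.7 (expected fraction
≈ 0.70 at weight 0.7 against a flat background at 0.125).

## Differential methylome analysis

Beta values are clipped to [1e-6, 1−1e-6] and logit2-transformed to M-values
(M = log2(β/(1−β))), the variance-stabilized scale for regression. Probes
flagged cross-reactive or on sex chromosomes are removed first.

**DMPs.** Each probe is fit with a Huber robust linear model of M on the UV
indicator plus optional covariates (the *crude* model — group only — is the
default; sex/age/tumor-type adjusted models are covariate configurations).
The implementation is an IRLS vectorized across probes sharing one design
matrix: tuning constant c = 1.345, scale re-estimated each iteration as
MAD/0.6745, max 50 iterations, tolerance 1e-8. Standard errors use the
Huber sandwich with the standard small-sample correction
(k² · s² Σψ(u)² / ((n−p) · mean(ψ′)²) · (XᵀX)⁻¹ with
k = 1 + (p/n)·var(ψ′)/mean(ψ′)²); when no observation is downweighted this
reduces exactly to OLS. Two-sided p-values come from the t reference on
n−p df, BH-adjusted across probes. Constant probes are returned flagged
with p = 1. Effect sizes are reported as Δβ, the difference of group mean
beta values, alongside the M-scale coefficient; an OLS variant is exposed
as an option. Calibration was verified on null simulations (median-based
λ within 0.96-1.05 across seeds at n = 25/group, 20,000 probes).

**Genomic inflation.** λ = median(χ²₁-quantile of 1−p) / 0.4549364, the
standard median-based inflation factor; λ ≈ 1 indicates calibrated tests.

**DMRs.** Per chromosome, probes with per-CpG FDR < 0.05 are chained while
consecutive gaps are ≤ 1000 bp; chains of ≥ 2 CpGs become regions
(coordinates 1-based inclusive, [min pos, max pos] of members). The region
statistic is a Stouffer sum of member z-scores with a Brown-style
correction for the mean pairwise M-value correlation r̄ (clipped to [0,1)):

    Z_region = Σ z_i / sqrt(n + n(n−1)·r̄)

with two-sided normal p and BH adjustment across regions. The pooled region
coefficient (mean of member coefficients) carries an equicorrelation-based
SE so regions can be meta-analysed. This transparent combiner replaces
kernel-smoothing DMR machinery on purpose: the proximity window is the only
parameter the upstream method pins down, and the closed form is directly
testable (independent members with equal z = 2 and n = 4 give exactly
Z = 4).

**Prioritization cascade**, applied in order with attrition counts:
≥ 3 CpGs → all member Δβ share one sign (strictest reading of "consistent
direction") → |mean Δβ| ≥ 0.10 → member SNP-flag fraction < 0.5. SNP
"enrichment" has no standard definition at the region level; the member
fraction is a conservative, auditable proxy, and the 0.5 cutoff is
configurable.

**Region-class enrichment** compares a probe selection against the array
background per regulatory class (promoter, 5'UTR, exon/intron boundary,
1-5 kb upstream, other) or CpG-density class (island, shore, shelf, open
sea) with uncorrected 2×2 chi-square tests, optionally split by effect
direction.

## Meta-analysis

Fixed-effects inverse-variance-weighted pooling: w = 1/SE², pooled
b = Σwb/Σw, SE = 1/√Σw, two-sided normal p, with BH-FDR and Bonferroni
columns. Only ids present in every study are pooled; the rest are reported
unpooled rather than imputed. Cochran's Q is attached as heterogeneity
annotation only — no random-effects model is fit, matching the fixed-effects
design of the analysis this package implements. Direction concordance is
the fraction of shared probes whose coefficients agree in sign across all
studies (zeros counted as positive and logged). Set-overlap significance is
reported both as an uncorrected 2×2 chi-square and a hypergeometric upper
tail, because published overlap p-values in this literature are often not
reproducible from printed set sizes under either convention.

## Multi-OMICs integration

**eQTM**: Pearson correlation between a CpG's beta and a gene's log2
expression across shared samples, t-reference p on n−2 df, BH across pairs;
zero-variance inputs yield flagged NA rows.

**Driver score**: per gene, four event counts — samples with |CNV call| ≥ 2;
samples with ≥ 1 mutation; UV-mutant samples whose log2 expression deviates
from the non-UV group mean by > 2; UV-mutant samples whose gene-averaged
beta deviates from the non-UV group mean by > 0.1 — each normalized by the
maximum count over the analysed gene set, summed into a total in [0, 4].
Two open details were resolved as follows: expression deviations are
measured per UV-mutant sample against the non-UV group mean (the most
literal per-case reading of "relative to non-UV patients"), on the log2
scale (configurable threshold); gene-level methylation is the unweighted
mean over the gene's CpGs from the cpg→gene map.

**MAD filtering** keeps the k rows with the largest unscaled median absolute
deviation (ties broken lexicographically by row id; default k = 100).

**PLS-DA** is NIPALS partial least squares of the standardized feature
matrix against centered one-hot class labels, with X-deflation, so score
vectors are mutually orthogonal (verified to 1e-8). Classification assigns
a sample to the nearest class centroid (Euclidean) in latent space; new
samples are projected through the rotation W(PᵀW)⁻¹. The sparse variant
soft-thresholds each component's weight vector at the (k+1)-th largest
magnitude so exactly k features stay non-zero, then renormalizes — the
standard deterministic realization of the LASSO-style "keepX" constraint.
Because training accuracy of a many-feature PLS-DA overfits far above
chance, discriminative performance is measured by leave-one-out
cross-validation (`cv_accuracy`), which sits at ~0.5 under permuted
two-class labels.

**Block integration** is a deliberately simplified substitute for
multi-block covariance optimization: sparse PLS-DA per block, concatenation
of the selected (standardized) features, then a plain PLS-DA on the
concatenation, reporting per-block selections. It is deterministic and
sufficient for the qualitative question it serves (does adding a second
block improve discrimination?).

**Hierarchical clustering** is agglomerative on Euclidean distance,
complete linkage by default (the linkage is exposed because no principled
default exists); samples are ordered by id before linkage so ties resolve
deterministically.

## Clinical statistics

Chi-square tests are Pearson's without Yates continuity correction — the
convention under which the packaged cohort-comparison tables reproduce
their published p-values — with Fisher's exact test for small samples.
Mann-Whitney uses exact enumeration for n₁+n₂ ≤ 16 without ties, otherwise
the tie- and continuity-corrected normal approximation. Survival uses the
Kaplan-Meier product-limit estimator with Greenwood variance and the
multi-group log-rank test (lifelines), with events processed before
censorings at tied times. Methylation-based survival grouping dichotomizes
at the sample mean (values equal to the mean are "high"). Power for the
two-sided two-sample t-test uses the noncentral t with df = 2n−2 and
noncentrality Δ/(σ√(2/n)); at n = 20/group, Δ = 0.10, σ = 0.11, α = 0.05
this gives 80.0% (0.79997), crossing strictly above 80% from n = 21.

Gene-set enrichment adjusts for the probe-count-per-gene bias of
methylation arrays (1 to ~1300 probes per gene on 450K-class designs) by
matched resampling instead of an analytic approximation: the observed count
of significant genes in a set is compared against B = 10,000 resampled sets
matched on probe-count decile, with the plus-one empirical p
(1 + #null ≥ obs)/(B + 1) and BH across sets. Its calibration under
probe-count-biased nulls is tested directly.

## Synthetic cohort generator

The generator emulates the statistical structure of a two-group melanoma
cohort; its defaults are the conditions under which the pipeline is
validated.

- **Methylation**: baseline per-probe beta from a two-mode mixture (modes
  0.10 / 0.85, equal weight) with Gaussian noise of SD 0.5 added on the M
  scale and back-transformed — this keeps values strictly inside (0, 1) and
  reproduces the bimodal marginal distribution of 450K arrays. Planted DMR
  probes are equally spaced, 1-based, per chromosome; their baselines are
  drawn uniform in [0.25, 0.60] so a ±0.2 shift never clips at the
  (0.001, 0.999) bounds — a planted effect at an extreme baseline would be
  unrecoverable by construction, which would test the generator rather than
  the pipeline. The Jensen bias of the M-scale noise on the realized group
  difference at these baselines is ≈ −0.004, negligible against the ±0.03
  recovery tolerance.
- **Mutations**: per-sample event counts are Poisson (defaults: mean 200 UV
  / 100 non-UV, a scaled-down stand-in for the high burden of cutaneous
  melanoma); UV samples draw channels from
  w·(UV profile) + (1−w)·flat with w = `uv_signature_weight` (default 0.8),
  plus CC>TT DNP events at rate 0.05·w; non-UV samples are flat. Half the
  records are emitted on the purine strand to exercise folding.
- **Expression**: negative-binomial counts (size 10) with per-gene log2
  baseline ~ N(6, 1); eQTM-coupled genes add slope × (linked CpG's beta) to
  the log2 mean. Matrices are log2(count+1). Unlinked specs attach to
  planted DMR probes in order, so couplings are detectable through the
  group contrast.
- **CNV / mutation presence**: sparse integer calls in [−2, 2]
  (P(±2) = 0.02) and Bernoulli(0.05) gene-level mutation presence. The
  presence matrix is generated independently of the SNV catalogs (which
  carry no gene annotation) — the two layers serve different pipeline
  stages.
- **Survival**: exponential with group hazards (defaults 0.02/month UV,
  0.05/month non-UV, encoding the better prognosis of UV-mutant disease)
  and independent uniform-thinning censoring at rate 0.3.
- **Annotation**: ~3% SNP-flagged, ~1% cross-reactive, ~2% sex-chromosome
  probes among the background (planted probes are never flagged).

One global seed drives independent substreams (layout, methylation,
mutation, expression, survival) via fixed offsets, so changing one layer's
parameters leaves the others bit-identical. Identical configs produce
bit-identical cohorts.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: array batch effects and cell-type composition
(surrogate variables are accepted as covariates but never needed on
synthetic data), spatial correlation of background probes beyond planted
regions, realistic copy-number segmentation, linkage between mutation
catalogs and gene identity, and non-exponential survival. Results on real
cohorts additionally depend on normalization and confounder control that
happen upstream of this package's inputs.

## Validation scenarios and problem sizes

`uvmeth.validation` fixes the simulation study designs used by both the
test suite and `scripts/acceptance.py`: 20 null cohorts of 20,000 probes at
n = 25/group for calibration (λ band [0.9, 1.1]; empirical DMR FDR as mean
per-seed false-discovery proportion); 10 cohorts × 6 planted DMRs
(Δβ = 0.15, 5 CpGs) for recovery; 50 seeds at 58 samples for eQTM detection
(slope −3); 50 seeds × 8 samples at signature weight 0.7 and burden ≥ 100
for the UV caller; and a methylome-only-signal cohort for the PLS-DA block
comparison. Replicate seeds are derived from one root seed via
`SeedSequence`, keeping layers and replicates independent.

## Known limitations

- The DMR combiner is a correlation-corrected Stouffer chain, not a kernel
  smoother; region boundaries are the extreme member positions.
- The region-level meta-analysis uses the equicorrelation SE approximation
  rather than the full member-level covariance.
- Sparse PLS-DA applies one thresholding pass per component rather than
  alternating penalized regressions; with strongly correlated features the
  selected sets can differ from iterative solvers.
- The rule-based UV call ignores burden uncertainty; calls near the 60%/5%
  thresholds at low burden (< 100 events) should not be trusted, and
  zero-burden samples are flagged rather than called.
- Fisher's two-sided p is the sum of point probabilities ≤ the observed one
  (with 1e-7 relative slack), which differs from doubled one-tail
  conventions used by some software.
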