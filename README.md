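# uvmeth

UV mutational-signature calling and differential DNA-methylome analysis for
melanoma multi-OMICs cohorts.

Ultraviolet exposure leaves two complementary molecular marks in cutaneous
melanoma: a characteristic somatic mutation pattern (C>T transitions at
dipyrimidine sites, tandem CC>TT substitutions — COSMIC signature 7) and,
downstream, alterations of the DNA methylome with consequences for immune
regulation and patient survival. `uvmeth` implements the full analysis chain
that connects them, for epigenomics researchers working with 450K-style
methylation arrays, somatic mutation catalogs, expression and copy-number
data:

- **UV status inference** from SBS96 mutation spectra: a sample is called
  UV-mutant when C>T at dipyrimidine sites exceeds 60% of the total mutation
  burden or CC>TT events exceed 5% of it, with seeded multiplicative-update
  NMF + cosine similarity to a reference signature as confirmation.
- **Differential methylome analysis**: per-CpG Huber robust regression of
  M-values (M = log2(β/(1−β))) on UV group, genomic-inflation QC (median-based
  λ), proximity-based DMR calling (±1000 bp chaining with a
  correlation-corrected Stouffer combination), and the prioritization cascade
  (≥3 CpGs, consistent direction, |Δβ| ≥ 0.10, no SNP enrichment).
- **Cross-cohort meta-analysis**: fixed-effects inverse-variance-weighted
  pooling with BH-FDR and Bonferroni adjustment, direction-concordance and
  overlap statistics.
- **Multi-OMICs integration**: eQTM Pearson correlations, a per-gene driver
  score summing max-normalized CNV / mutation / expression / methylation
  alteration counts, MAD feature filtering, (sparse) PLS-DA discrimination
  and a simplified multi-block integration, hierarchical clustering with
  cluster-enrichment tests.
- **Clinical statistics**: uncorrected chi-square and Fisher contingency
  tests, Mann-Whitney, Kaplan-Meier + log-rank survival, noncentral-t power,
  and probe-count-bias-adjusted gene-set enrichment by matched resampling.
- **A synthetic cohort generator** (`uvmeth.synthetic_cohort`) that emulates
  the bimodal beta-value structure of 450K arrays with planted DMRs, UV-like
  mutation catalogs, methylation-coupled negative-binomial expression,
  sparse CNV/mutation layers and exponential survival — with the planted
  truth shipped alongside, so every stage is testable end to end without any
  data download.

## Worked example

Simulate a 25+25 cohort with two planted DMRs and one planted eQTM, then run
the pipeline from the shell (`uvmeth --help` lists all subcommands):

```bash
uvmeth simulate --config demo.yaml --seed 7 --out demo
uvmeth uv-call demo/mutations.tsv --out demo/uv_calls.tsv
uvmeth dmp --beta demo/beta.tsv --annotation demo/probe_annotation.tsv \
           --clinical demo/clinical.tsv --out demo/dmp.tsv
uvmeth dmr --dmp demo/dmp.tsv --annotation demo/probe_annotation.tsv \
           --beta demo/beta.tsv --out demo/dmr.tsv
uvmeth prioritize --dmr demo/dmr.tsv --out demo/dmr_prioritized.tsv
uvmeth survival --clinical demo/clinical.tsv
```

which prints:

```
wrote 8 files to demo
25 / 50 samples called UV-mutant
lambda = 1.033; 9 DMPs at FDR<0.05
2 regions (2 at FDR<0.05)
input:2 -> min_cpgs:2 -> direction_consistent:2 -> effect_size:2 -> snp_fraction:2
log-rank chi2 = 7.477, df = 1, p = 0.00625
```

All 50 samples are correctly UV-classified (the UV group's C>T-dipyrimidine
fraction is ~0.72-0.78 against the 0.60 threshold); the genomic inflation
λ = 1.03 shows the per-CpG tests are well calibrated; and both planted
regions are recovered with accurate effect sizes — the chr1 region planted
at Δβ = −0.20 is called with mean Δβ = −0.193 (q = 2.9e−16), the chr7 region
planted at +0.15 with +0.157 (q = 1.5e−13). Both survive the prioritization
cascade, and the log-rank test picks up the better survival of the UV-mutant
group built into the generator's hazards.

The same steps are available as library calls (`uvmeth.generate_cohort`,
`uvmeth.fit_dmp`, `uvmeth.call_dmrs`, ...), returning pandas DataFrames.

### File formats

Matrices are TSV with the feature id in the first column and sample ids as
header (beta values at 6 decimals). Mutation catalogs are MAF-like TSV with
columns `sample, chrom, pos, ref, alt, context, class` (`class` is `SNV` or
`DNP`; `context` is the trinucleotide around an SNV, either strand).
Reference signature matrices are TSV with 96 rows in canonical lexicographic
SBS96 order — substitutions C>A, C>G, C>T, T>A, T>C, T>G, each crossed with
5'/3' flanks in A, C, G, T order (`A[C>A]A`, `A[C>A]C`, ...) — and one
column per signature. Gene sets are GMT. The probe annotation TSV carries
`probe, chrom, pos, gene, regulatory_class, density_class, snp_flag,
cross_reactive_flag, sex_chrom_flag`.

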