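# Published clinicopathological contingency tables for the two cutaneous
# melanoma discovery cohorts (BCH, TCGA) and the acral cohort.
# Rows/columns are ordered as listed.
tumor_type:
  # rows: cohort (BCH, TCGA); columns: primary, metastatic
  rows: [BCH, TCGA]
  columns: [primary, metastatic]
  counts: [[20, 34], [9, 49]]
molecular_group:
  # rows: molecular group; columns: cohort (BCH, TCGA)
  rows: [BRAF, RAS, NF1, TN]
  columns: [BCH, TCGA]
  counts: [[39, 23], [6, 20], [2, 6], [7, 9]]
uv_signature_cutaneous_vs_acral:
  # rows: cohort (BCH cutaneous, BCH acral); columns: UV yes, UV no
  rows: [BCH_cutaneous, BCH_acral]
  columns: [uv_yes, uv_no]
  counts: [[44, 10], [4, 17]]
uv_signature_bch_vs_tcga:
  rows: [BCH, TCGA]
  columns: [uv_yes, uv_no]
  counts: [[44, 10], [47, 11]]
skin_phenotype_cutaneous_vs_acral:
  # white vs pigmented; the published p-value for this comparison is not
  # recoverable from these counts by chi-square or Fisher tests.
  rows: [BCH_cutaneous, BCH_acral]
  columns: [white, pigmented]
  counts: [[51, 3], [15, 6]]
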