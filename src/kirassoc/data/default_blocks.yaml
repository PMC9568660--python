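# Default synthetic-cohort generator parameters.
#
# Haplotype-block pool: each KIR haplotype is one centromeric block plus one
# telomeric block (framework genes implicit on every haplotype).  Block
# frequencies were fitted by least squares through the closed-form carrier
# relation F = 1 - (1 - q)^2 against the healthy-control carrier frequencies
# of the calibration cohort (n = 448), jointly with its AA fraction and
# C4/T4 cluster rates.  All twelve fitted gene marginals land within 0.02 of
# the calibration values (largest residual: AA fraction, 0.024 low).
centromeric_blocks:
  - name: cen-A
    genes: [2DL3, 2DP1, 2DL1]
    frequency: 0.6711
  - name: cen-B-full          # complete C4 cluster
    genes: [2DS2, 2DL2, 2DS3, 2DL5, 2DP1, 2DL1]
    frequency: 0.1857
  - name: cen-B-no-2DS3
    genes: [2DS2, 2DL2, 2DL5, 2DP1, 2DL1]
    frequency: 0.0070
  - name: cen-B-short         # truncated cen-B lacking 2DP1/2DL1
    genes: [2DS2, 2DL2]
    frequency: 0.1362
telomeric_blocks:
  - name: tel-A
    genes: [3DL1, 2DS4]
    frequency: 0.7186
  - name: tel-B-full          # complete T4 cluster
    genes: [3DS1, 2DL5, 2DS5, 2DS1]
    frequency: 0.1978
  - name: tel-B-no-2DL5
    genes: [3DS1, 2DS5, 2DS1]
    frequency: 0.0162
  - name: tel-B-no-2DS5
    genes: [3DS1, 2DL5, 2DS1]
    frequency: 0.0067
  - name: tel-B-2DS3          # 2DS3 occupying the telomeric 2DS3/2DS5 slot
    genes: [3DS1, 2DL5, 2DS3, 2DS1]
    frequency: 0.0607

# Full-length (fl) allele frequency among 2DS4-bearing haplotypes; the
# remainder are the 22-bp deleted (del) variant.  Fitted to the control
# fl / del / fl+del category split (12.9 / 73.5 / 13.6 %).
ds4_fl_allele_frequency: 0.18

# HLA KIR-ligand epitope allele frequencies (per locus, Hardy-Weinberg
# equilibrium), fitted to control epitope carrier frequencies.
hla_epitope_allele_frequencies:
  c1: 0.503          # HLA-C Asn80; C2 (Lys80) = 1 - c1
  b_bw4_i80: 0.093   # HLA-B Bw4 Ile80
  b_bw4_t80: 0.275   # HLA-B Bw4 Thr80; Bw6 (no KIR epitope) is the remainder
  a3_a11: 0.220      # HLA-A3/A11
  a_bw4: 0.288       # HLA-A23/24/25/32; other A alleles are the remainder

# Fraction of individuals with HLA typing available (typed-subset design:
# 85/232 cases and 178/448 controls in the calibration cohort).
hla_typed_fraction: 0.39

# Case histological-subtype proportions (given case status).
subtype_probabilities:
  NSCLC_SCC: 0.621
  NSCLC_AD: 0.151
  SCLC: 0.228
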