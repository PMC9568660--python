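# Methods

## Data model

An individual is a row of presence/absence calls (`1`/`0`/`NA`) over 16 KIR
loci, a 2DS4 variant category, a case/control label, an optional histological
subtype and optional HLA typing.  Four framework genes (*3DL3*, *3DP1*,
*2DL4*, *3DL2*) must be present or untyped in a valid record, never absent;
a 2DS4 variant call (`fl`, `del`, `fl+del`) must be consistent with 2DS4
presence.  Validation rejects violating records by default; a lenient mode
logs and retains them, since 100% framework carriage is expected and a
violation almost always indicates a typing or data-entry error.

Gene-content keys are 16-character 0/1 bitmasks in a fixed, documented
marker order (physical order along the locus: 3DL3, 2DS2, 2DL2, 2DL3, 2DP1,
2DL1, 3DP1, 2DL4, 3DL1, 3DS1, 2DL5, 2DS3, 2DS5, 2DS1, 2DS4, 3DL2).
Genotype IDs come from a user-supplied catalog file
(`content_key,genotype_id`) when available; otherwise deterministic synthetic
IDs (`G001`, `G002`, …) are assigned in canonical bitmask order, so the
numbering never depends on cohort row order and requires no external
database.

## Classification rules

**AA/Bx.**  AA requires *2DL3, 2DL1, 2DP1, 3DL1, 2DS4* all present and all
seven B-specific genes (*2DL2, 2DL5, 2DS1, 2DS2, 2DS3, 2DS5, 3DS1*) absent;
anything else is Bx (AB and BB are indistinguishable from presence/absence
data).  In lenient mode a single observed B-specific gene decides Bx even
when other markers are untyped; a record is left unclassified only when the
call genuinely depends on an untyped marker.

**C4/T4 linkage groups.**  The centromeric C4 cluster is called when
*2DS2, 2DL2, 2DS3* and *2DL5* are all present; telomeric T4 when
*3DS1, 2DS1, 2DS5* and *2DL5* are all present.  The biological clusters
involve the paralogs 2DL5B (centromeric) and 2DL5A (telomeric), but generic
presence/absence typing cannot split them, so the default rule uses generic
*2DL5* on both sides; the required-gene lists are configurable for data sets
that do resolve the paralogs.  Bx genotypes partition into C4Tx, CxT4, C4T4
and CxTx by the two cluster calls, giving the counting identities

    count(C4) = n(C4Tx) + n(C4T4)        count(T4) = n(CxT4) + n(C4T4)

which the pipeline re-verifies on every report and which hold for the
reference control column (162 = 105 + 57, 159 = 102 + 57, 333 Bx =
102 + 105 + 57 + 69).

**iKIR/aKIR counts.**  Receptor-class membership is not standardized across
studies, so the map is explicit and configurable, and every report prints the
map used.  The default counts seven inhibitory genes (*2DL1, 2DL2, 2DL3,
2DL5, 3DL1, 3DL2, 3DL3*) and six activating genes (*2DS1–2DS5, 3DS1*),
excluding 2DL4 (a dual-signalling receptor) and the pseudogenes.  The flags
iKIR>aKIR / aKIR>iKIR use strict integer comparison; a tie sets neither, so
the two directional carrier frequencies need not sum to 100%.

## HLA epitope assignment

The bundled motif table maps common two-field (and first-field group) HLA
alleles to C1/C2 (HLA-C position-80 Asn/Lys), Bw4-Ile80/Bw4-Thr80 and Bw6
(no KIR epitope) at HLA-B, and A3/A11 and A-Bw4 (A23/24/25/32) at HLA-A.
Per-locus flags are the union over the (up to two) alleles; an allele absent
from the table leaves its locus untyped with a logged warning rather than
silently negative, and a positive epitope already established by the other
allele survives.  Known limitation: rare C1-bearing B alleles
(B*46:01-type, B*73:01) are deliberately out of the default table; studies of
populations where they are common should supply an extended map file.

Pair flags (gene present AND epitope carried) use strict typing: a pair is
evaluated only for individuals typed on both sides, which reproduces the
typed-subset denominators of KIR–HLA analyses.  Bw4 for the 3DL1/3DS1 pairs
means B-locus Bw4 by default; A-locus Bw4 is tracked as its own factor and a
switch can merge it in, since studies report the two separately.

## Statistics

**Fisher exact test.**  Two-tailed p by exact enumeration of the
hypergeometric distribution over all tables with the observed margins,
summing point probabilities ≤ the observed one with relative tolerance 1e-7
for float ties — the convention of mainstream statistical software.  A zero
row/column margin is degenerate: p = 1 with a warning.  The test suite
checks the implementation against an independent integer-arithmetic
enumerator for every table with N ≤ 30 and against `scipy.stats.fisher_exact`.

**Odds ratio.**  OR = ad/bc with the Woolf logit interval
exp(ln OR ± z·√(1/a+1/b+1/c+1/d)), z = 1.959964 at the 95% level (an
arbitrary level falls back to the exact normal quantile).  Any zero cell
triggers the Haldane–Anscombe +0.5 on all four cells and flags the result;
two opposing zero cells leave the OR undefined.

**Multiple comparisons.**  P_n = 1 − (1 − P)^n, clamped to [p, 1] against
float roundoff.  The comparison-family size n is supplied per family in the
analysis configuration (defaults: 4 for the iKIR/aKIR count-flag family, 9
for combined genotypes) rather than auto-derived, because family definitions
are a study-design choice.  Reports star significance at α = 0.05 on the
uncorrected p and print the corrected p alongside.

**Svejgaard–Ryder battery.**  For factors A and B, individuals typed for
both are cross-tabulated into A+B+, A+B−, A−B+, A−B− per group, and eight
case-vs-control comparisons are run: A within B+, A within B−, B within A+,
B within A−, A+B+ vs A−B−, A+B− vs A−B+, and the two marginals — plus the
naive combined-carrier test (A+B+ vs all others), which is what published
"combined genotype" rows usually report.  Both forms are emitted because the
published combined-genotype ORs of the reference study do not match either
form exactly and the study does not state which comparison produced them.

## Synthetic cohort generator

The generator exists so every pipeline stage is testable without any data
download; its defaults emulate the reference study design (232 cases,
448 controls, HLA typing on a ~39% subset).

Each individual draws two independent haplotypes; each haplotype is one
centromeric block plus one telomeric block (frameworks implicit).  The
default pool has four centromeric structures (cen-A; full C4; C4 without
2DS3; a truncated *2DS2-2DL2* block lacking 2DP1/2DL1) and five telomeric
structures (tel-A; full T4; T4 variants missing 2DL5 or 2DS5; a 2DS3-bearing
variant), covering the observed decoupling of single genes from complete
clusters.  Block frequencies were fitted by least squares through the
carrier relation F = 1 − (1−q)² to the control-column gene marginals and
genotype-class rates (`scripts/fit_block_frequencies.py`); the fitted values
live in `src/kirassoc/data/default_blocks.yaml`, and all twelve gene
marginals land within 0.02 of the calibration values.  2DS4-positive
haplotypes carry the fl allele with probability 0.18 (fitted to the
fl/del/fl+del split); HLA epitopes are drawn per locus under Hardy–Weinberg
equilibrium with fitted allele frequencies.

Effect injection is an outcome model: case status is Bernoulli with
logit = α + ln(OR)·X for carrier status X of the target factor, with α
solved (Brent's method on the empirical batch) so the expected case fraction
matches the configured group sizes; sampling continues in batches until both
groups are filled.  Because the effect enters as a log-odds shift, the
case-control odds ratio equals the configured value in expectation
regardless of outcome-based sampling.

What the generator does *not* emulate: population structure and inbreeding
(haplotypes are independent, HWE), allele-level KIR diversity and copy
number, recombination between blocks beyond the fixed structure list,
linkage between KIR and HLA (drawn independently), and ethnic-specific
haplotype catalogs.  Passing calibration tests therefore show that the
*analysis* is correct under the stated generative model, not that the model
reproduces every feature of real cohorts — in particular the number of
distinct genotypes in a simulated cohort (~27 at n = 680) is smaller than in
real data (65 in the reference study), because real gene-content diversity
exceeds a 4×5 block pool.

## Problem sizes and numerical choices

The test suite runs the exhaustive Fisher sweep over all ~46,000 tables with
N ≤ 30, 2,000 null binomial tables for CI coverage and type-I error, and 500
Monte-Carlo cohorts (448/232) per calibration scenario (null and OR = 2 at
carrier probability 0.5); the acceptance script uses the same sizes.  These
sizes give Monte-Carlo standard errors of about 0.01 on rejection/coverage
rates and about 0.008 on the recovered log-OR mean, comfortably inside the
asserted bands.  Ties in the Fisher two-sided sum use the 1e-7 relative
tolerance noted above; report formatting is percentages to 1 d.p., OR/CI to
2 d.p., p to 2 significant figures.

## Known limitations

- Carrier-frequency tests only: no logistic regression or covariate
  adjustment (age/sex/smoking), no haplotype-frequency EM, no
  Hardy–Weinberg testing of cases, no survival analysis.
- The Woolf interval for the reference 2DS2 table gives a lower bound of
  1.026 (prints 1.03), marginally above the published 1.02 — consistent with
  rounding differences in the original software; the published odds ratios
  themselves reproduce exactly at printed precision.
- Presence/absence typing cannot resolve 2DL5A/B or copy number, so the
  C4/T4 rules approximate the cluster definitions (see above).
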