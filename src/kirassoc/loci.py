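"""Constants describing the KIR locus and its gene-content structure.

The KIR gene cluster (chromosome 19q13.4) is typed here as presence/absence
calls for 16 loci.  Four *framework* genes flank and divide the locus and are
carried by essentially every haplotype; the remaining genes vary between the
mostly-inhibitory A haplotype (fixed content) and the variable B haplotypes.
Two tightly linked B-haplotype gene clusters are distinguished: the
centromeric C4 group (2DS2-2DL2-2DS3-2DL5) and the telomeric T4 group
(3DS1-2DL5-2DS5-2DS1).
"""

from __future__ import annotations

# Canonical marker order used for content keys (16-character 0/1 bitmask).
# Follows the physical gene order along the locus, centromeric to telomeric.
KIR_MARKERS: tuple[str, ...] = (
    "3DL3", "2DS2", "2DL2", "2DL3", "2DP1", "2DL1", "3DP1",
    "2DL4", "3DL1", "3DS1", "2DL5", "2DS3", "2DS5", "2DS1", "2DS4", "3DL2",
)

# Framework genes/pseudogenes: present on essentially all haplotypes.
FRAMEWORK_GENES = frozenset({"3DL3", "3DP1", "2DL4", "3DL2"})

# Fixed gene content of the A haplotype (besides frameworks).
A_CONTENT_GENES = frozenset({"2DL1", "2DL3", "3DL1", "2DS4", "2DP1"})

# Genes specific to B haplotypes; any one of these forces a Bx genotype.
B_SPECIFIC_GENES = frozenset({"2DL2", "2DL5", "2DS1", "2DS2", "2DS3", "2DS5", "3DS1"})

# Centromeric / telomeric B-haplotype linkage clusters.  The locus carries two
# 2DL5 copies (2DL5B centromeric, 2DL5A telomeric) but presence/absence typing
# resolves only a generic 2DL5, which both rules therefore reference.
C4_GENES: tuple[str, ...] = ("2DS2", "2DL2", "2DS3", "2DL5")
T4_GENES: tuple[str, ...] = ("3DS1", "2DS1", "2DS5", "2DL5")

# Group labels for the case-control design.
GROUP_CASE = "case"
GROUP_CONTROL = "control"
GROUPS = (GROUP_CASE, GROUP_CONTROL)

# Optional histological subtypes for the case arm.
SUBTYPES = ("NSCLC_SCC", "NSCLC_AD", "SCLC")

# 2DS4 variant categories (full-length, 22-bp deleted, both, gene-negative).
DS4_FL = "fl"
DS4_DEL = "del"
DS4_FL_DEL = "fl_del"
DS4_NEGATIVE = "negative"
DS4_CATEGORIES = (DS4_FL, DS4_DEL, DS4_FL_DEL, DS4_NEGATIVE)
# Spelling used in cohort CSV files <-> internal category.
DS4_CSV_VALUES = {"fl": DS4_FL, "del": DS4_DEL, "fl+del": DS4_FL_DEL, "neg": DS4_NEGATIVE}
DS4_TO_CSV = {v: k for k, v in DS4_CSV_VALUES.items()}

# Bx genotype subsets by C4/T4 cluster carriage.
BX_SUBSETS = ("C4Tx", "CxT4", "C4T4", "CxTx")
NOT_APPLICABLE = "not_applicable"


def validate_marker(name: str) -> str:
    if name not in KIR_MARKERS:
        raise ValueError(f"unknown KIR marker {name!r}; expected one of {KIR_MARKERS}")
    return name
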