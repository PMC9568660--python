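"""KIR gene-content genotype classification.

Implements the record-level rules of the analysis: AA/Bx haplotype-group
assignment, centromeric (C4) and telomeric (T4) linkage-group calls, the four
Bx subsets (C4Tx, CxT4, C4T4, CxTx), inhibitory/activating gene counting,
2DS4 variant validation and full genotype profiling against a catalog of
gene-content keys.

An individual is *AA* when it carries every fixed A-haplotype content gene
(2DL3-2DL1-2DP1-3DL1-2DS4) and none of the B-specific genes; every other
individual is *Bx* (AB heterozygous or BB homozygous — indistinguishable from
presence/absence typing).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .loci import (
    A_CONTENT_GENES,
    B_SPECIFIC_GENES,
    BX_SUBSETS,
    C4_GENES,
    DS4_CATEGORIES,
    DS4_FL,
    DS4_DEL,
    DS4_FL_DEL,
    DS4_NEGATIVE,
    FRAMEWORK_GENES,
    GROUPS,
    KIR_MARKERS,
    NOT_APPLICABLE,
    T4_GENES,
)


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


class UntypedMarkerError(ValueError):
    """A marker required by a classification rule is untyped (strict mode)."""


class ConfigurationError(ValueError):
    """An analysis configuration object is internally inconsistent."""


@dataclass(frozen=True)
class KirClassMap:
    """Which markers count as inhibitory (iKIR) vs activating (aKIR).

    The default counts seven inhibitory genes (2DL1, 2DL2, 2DL3, 2DL5, 3DL1,
    3DL2, 3DL3) and six activating genes (2DS1-2DS5, 3DS1).  2DL4, a receptor
    with both inhibitory and activating signalling motifs, and the pseudogenes
    2DP1/3DP1 are excluded from both counts.  Reports always print the map in
    use, since the count flags depend on it.
    """

    inhibitory_set: frozenset[str]
    activating_set: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.inhibitory_set & self.activating_set
        if overlap:
            raise ConfigurationError(f"markers in both iKIR and aKIR sets: {sorted(overlap)}")
        unknown = (self.inhibitory_set | self.activating_set) - set(KIR_MARKERS)
        if unknown:
            raise ConfigurationError(f"unknown markers in class map: {sorted(unknown)}")

    @property
    def excluded_set(self) -> frozenset[str]:
        return frozenset(KIR_MARKERS) - self.inhibitory_set - self.activating_set

    def describe(self) -> str:
        return (
            f"iKIR={{{', '.join(sorted(self.inhibitory_set))}}}; "
            f"aKIR={{{', '.join(sorted(self.activating_set))}}}; "
            f"excluded={{{', '.join(sorted(self.excluded_set))}}}"
        )


DEFAULT_CLASS_MAP = KirClassMap(
    inhibitory_set=frozenset({"2DL1", "2DL2", "2DL3", "2DL5", "3DL1", "3DL2", "3DL3"}),
    activating_set=frozenset({"2DS1", "2DS2", "2DS3", "2DS4", "2DS5", "3DS1"}),
)


@dataclass(frozen=True)
class LinkageRule:
    """Genes required to call the centromeric (C4) / telomeric (T4) clusters.

    Generic presence/absence typing cannot split 2DL5A from 2DL5B, so the
    default rule requires the three distinguishable genes of each cluster plus
    generic 2DL5 on both sides.
    """

    c4_required: tuple[str, ...] = C4_GENES
    t4_required: tuple[str, ...] = T4_GENES

    def __post_init__(self) -> None:
        unknown = (set(self.c4_required) | set(self.t4_required)) - set(KIR_MARKERS)
        if unknown:
            raise ConfigurationError(f"unknown markers in linkage rule: {sorted(unknown)}")

    def describe(self) -> str:
        return (
            f"C4 requires {{{', '.join(self.c4_required)}}}; "
            f"T4 requires {{{', '.join(self.t4_required)}}}"
        )


DEFAULT_LINKAGE_RULE = LinkageRule()


@dataclass
class KirTypingRecord:
    """One individual's presence/absence typing for the 16 KIR markers.

    ``presence`` maps each marker to ``True`` (present), ``False`` (absent) or
    ``None`` (untyped).  ``ds4_variant`` is one of ``fl``, ``del``, ``fl_del``,
    ``negative`` or ``None`` (untyped).
    """

    sample_id: str
    group: str | None = None
    subtype: str | None = None
    presence: dict[str, bool | None] = field(default_factory=dict)
    ds4_variant: str | None = None

    def __post_init__(self) -> None:
        if self.group is not None and self.group not in GROUPS:
            raise ValidationError(f"{self.sample_id}: group must be one of {GROUPS}, got {self.group!r}")
        unknown = set(self.presence) - set(KIR_MARKERS)
        if unknown:
            raise ValidationError(f"{self.sample_id}: unknown markers {sorted(unknown)}")
        for m in KIR_MARKERS:
            self.presence.setdefault(m, None)
        if self.ds4_variant is not None and self.ds4_variant not in DS4_CATEGORIES:
            raise ValidationError(
                f"{self.sample_id}: ds4_variant must be one of {DS4_CATEGORIES}, got {self.ds4_variant!r}"
            )

    def validate(self, lenient: bool = False) -> list[str]:
        """Check framework and 2DS4-variant invariants.

        Returns the list of violation messages in lenient mode; raises
        :class:`ValidationError` on the first violation otherwise.
        """
        problems: list[str] = []
        for m in sorted(FRAMEWORK_GENES):
            if self.presence[m] is False:
                problems.append(f"{self.sample_id}: framework gene {m} called absent")
        ds4 = self.presence["2DS4"]
        if self.ds4_variant in (DS4_FL, DS4_DEL, DS4_FL_DEL) and ds4 is False:
            problems.append(
                f"{self.sample_id}: ds4_variant={self.ds4_variant} but 2DS4 called absent"
            )
        if self.ds4_variant == DS4_NEGATIVE and ds4 is True:
            problems.append(f"{self.sample_id}: ds4_variant=negative but 2DS4 called present")
        if problems and not lenient:
            raise ValidationError("; ".join(problems))
        return problems


def _require_typed(record: KirTypingRecord, markers, strict: bool) -> bool:
    """True when all ``markers`` are typed; raises in strict mode otherwise."""
    untyped = [m for m in markers if record.presence[m] is None]
    if untyped and strict:
        raise UntypedMarkerError(
            f"{record.sample_id}: marker(s) {', '.join(sorted(untyped))} untyped"
        )
    return not untyped


def classify_haplotype_group(record: KirTypingRecord, strict: bool = True) -> str | None:
    """Classify an individual as ``AA`` or ``Bx``.

    AA requires every A-haplotype content gene present and every B-specific
    gene absent.  With ``strict=False`` an undecidable record (untyped marker
    that could flip the call) yields ``None``.
    """
    record.validate()
    relevant = sorted(A_CONTENT_GENES | B_SPECIFIC_GENES)
    # A single observed B-specific gene (or missing A gene) decides Bx even
    # with other markers untyped.
    if any(record.presence[m] is True for m in B_SPECIFIC_GENES):
        return "Bx"
    if any(record.presence[m] is False for m in A_CONTENT_GENES):
        return "Bx"
    if not _require_typed(record, relevant, strict):
        return None
    return "AA"


def call_linkage_groups(
    record: KirTypingRecord,
    rule: LinkageRule = DEFAULT_LINKAGE_RULE,
    strict: bool = True,
) -> tuple[bool | None, bool | None]:
    """Call carriage of the centromeric C4 and telomeric T4 linkage groups.

    A cluster is called present when every gene its rule requires is present.
    With ``strict=False`` an undecidable call yields ``None``.
    """
    record.validate()
    out: list[bool | None] = []
    for required in (rule.c4_required, rule.t4_required):
        if any(record.presence[m] is False for m in required):
            out.append(False)
        elif _require_typed(record, required, strict):
            out.append(True)
        else:
            out.append(None)
    return out[0], out[1]


def classify_bx_subset(
    record: KirTypingRecord,
    rule: LinkageRule = DEFAULT_LINKAGE_RULE,
    strict: bool = True,
) -> str | None:
    """Assign a Bx individual to C4Tx / CxT4 / C4T4 / CxTx.

    AA individuals get ``not_applicable``; an undecidable record (lenient
    mode) yields ``None``.
    """
    group = classify_haplotype_group(record, strict=strict)
    if group is None:
        return None
    if group == "AA":
        return NOT_APPLICABLE
    c4, t4 = call_linkage_groups(record, rule=rule, strict=strict)
    if c4 is None or t4 is None:
        return None
    return {
        (True, False): "C4Tx",
        (False, True): "CxT4",
        (True, True): "C4T4",
        (False, False): "CxTx",
    }[(c4, t4)]


@dataclass(frozen=True)
class KirClassCounts:
    n_inhibitory: int
    n_activating: int

    @property
    def ikir_gt_akir(self) -> bool:
        return self.n_inhibitory > self.n_activating

    @property
    def akir_gt_ikir(self) -> bool:
        return self.n_activating > self.n_inhibitory

    @property
    def ikir_gt_4(self) -> bool:
        return self.n_inhibitory > 4

    @property
    def akir_gt_4(self) -> bool:
        return self.n_activating > 4


def count_kir_classes(
    record: KirTypingRecord, class_map: KirClassMap = DEFAULT_CLASS_MAP
) -> KirClassCounts:
    """Count inhibitory and activating genes carried by an individual.

    Directional flags use strict integer comparison; a tie sets neither.
    All mapped markers must be typed.
    """
    record.validate()
    _require_typed(record, class_map.inhibitory_set | class_map.activating_set, strict=True)
    n_i = sum(1 for m in class_map.inhibitory_set if record.presence[m])
    n_a = sum(1 for m in class_map.activating_set if record.presence[m])
    return KirClassCounts(n_inhibitory=n_i, n_activating=n_a)


def classify_2ds4_variant(record: KirTypingRecord) -> str | None:
    """Return the validated 2DS4 variant category (``None`` when untyped)."""
    record.validate()
    return record.ds4_variant


def content_key(record: KirTypingRecord) -> str:
    """Canonical 16-character 0/1 gene-content bitmask in fixed marker order."""
    record.validate()
    _require_typed(record, KIR_MARKERS, strict=True)
    return "".join("1" if record.presence[m] else "0" for m in KIR_MARKERS)


class GenotypeCatalog:
    """Bijective map from gene-content keys to genotype ID labels.

    IDs normally come from an external catalog file (e.g. a published
    genotype-ID numbering).  Unknown keys are assigned deterministic synthetic
    IDs ``G001, G002, ...`` in canonical bitmask order via :meth:`assign`.
    """

    def __init__(self, entries: dict[str, str] | None = None) -> None:
        self.entries: dict[str, str] = {}
        for key, label in (entries or {}).items():
            self.add(key, label)

    def add(self, key: str, label: str) -> None:
        if len(key) != len(KIR_MARKERS) or set(key) - {"0", "1"}:
            raise ValidationError(f"malformed content key {key!r}")
        if key in self.entries and self.entries[key] != label:
            raise ValidationError(f"content key {key} already mapped to {self.entries[key]}")
        if label in set(self.entries.values()) and self.entries.get(key) != label:
            raise ValidationError(f"genotype ID {label} already used")
        self.entries[key] = label

    def assign(self, keys) -> dict[str, str]:
        """Ensure every key has an ID; new keys get sequential synthetic IDs.

        New keys are ordered by canonical bitmask so the numbering does not
        depend on cohort row order.
        """
        new = sorted(set(keys) - set(self.entries))
        counter = itertools.count(len(self.entries) + 1)
        for key in new:
            label = f"G{next(counter):03d}"
            while label in set(self.entries.values()):
                label = f"G{next(counter):03d}"
            self.entries[key] = label
        return {k: self.entries[k] for k in keys}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries


@dataclass(frozen=True)
class GenotypeProfile:
    """Complete gene-content classification of one individual."""

    content_key: str
    haplotype_class: str
    c4_present: bool
    t4_present: bool
    bx_subset: str
    n_inhibitory: int
    n_activating: int
    genotype_id: str | None = None


def profile_genotype(
    record: KirTypingRecord,
    catalog: GenotypeCatalog | None = None,
    class_map: KirClassMap = DEFAULT_CLASS_MAP,
    rule: LinkageRule = DEFAULT_LINKAGE_RULE,
) -> GenotypeProfile:
    """Profile a fully typed record; appends unknown keys to ``catalog``."""
    key = content_key(record)
    group = classify_haplotype_group(record)
    c4, t4 = call_linkage_groups(record, rule=rule)
    subset = classify_bx_subset(record, rule=rule)
    counts = count_kir_classes(record, class_map)
    genotype_id = None
    if catalog is not None:
        genotype_id = catalog.assign([key])[key]
    if group == "AA" and (c4 or t4):
        raise ValidationError(f"{record.sample_id}: AA genotype cannot carry a B cluster")
    assert subset in BX_SUBSETS or subset == NOT_APPLICABLE
    return GenotypeProfile(
        content_key=key,
        haplotype_class=group,
        c4_present=bool(c4),
        t4_present=bool(t4),
        bx_subset=subset,
        n_inhibitory=counts.n_inhibitory,
        n_activating=counts.n_activating,
        genotype_id=genotype_id,
    )
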