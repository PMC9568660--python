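"""HLA class-I KIR-ligand epitope assignment and KIR-HLA pairing.

HLA-A, -B and -C molecules carry four KIR-binding epitope classes: C1 and C2
(the Asn80/Lys80 dimorphism of HLA-C), Bw4 (HLA-B, subdivided by the Ile80 /
Thr80 dimorphism that modulates 3DL1 binding; also carried by HLA-A23/24/25/32)
and A3/A11 (the 3DL2 ligand).  This module maps two-field HLA allele names to
these epitopes via a bundled motif table, or passes through epitope-level
typing unchanged, and combines epitope profiles with KIR gene presence into
receptor-ligand pair flags.

By default, Bw4 for 3DL1/3DS1 pairing means B-locus Bw4 only; the A-locus Bw4
alleles are tracked as a separate flag and can optionally be merged in.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .genotype import KirTypingRecord

logger = logging.getLogger(__name__)

EPITOPE_LABELS = ("C1", "C2", "BW4_I80", "BW4_T80", "A3A11", "A_BW4")

#: epitope flag columns in a cohort DataFrame
EPITOPE_COLUMNS = ("hla_c1", "hla_c2", "hla_bw4_i80", "hla_bw4_t80", "hla_a3a11", "hla_a_bw4")
ALLELE_COLUMNS = ("hla_a_1", "hla_a_2", "hla_b_1", "hla_b_2", "hla_c_1", "hla_c_2")

#: the eight receptor-ligand combinations analysed (KIR gene, epitope attribute)
PAIR_DEFS: tuple[tuple[str, str, str], ...] = (
    ("3DL2+A3/A11", "3DL2", "a3_a11"),
    ("2DL1+C2", "2DL1", "c2"),
    ("2DL3+C1", "2DL3", "c1"),
    ("2DL2+C1", "2DL2", "c1"),
    ("3DL1+Bw4", "3DL1", "bw4"),
    ("2DS1+C2", "2DS1", "c2"),
    ("2DS2+C1", "2DS2", "c1"),
    ("3DS1+Bw4", "3DS1", "bw4"),
)


@dataclass(frozen=True)
class EpitopeProfile:
    """Per-individual KIR-ligand flags; ``None`` marks an untyped field."""

    c1: bool | None = None
    c2: bool | None = None
    bw4_i80: bool | None = None
    bw4_t80: bool | None = None
    a3_a11: bool | None = None
    a_bw4: bool | None = None

    @property
    def bw4(self) -> bool | None:
        """B-locus Bw4 carriage (either position-80 subtype)."""
        if self.bw4_i80 or self.bw4_t80:
            return True
        if self.bw4_i80 is None or self.bw4_t80 is None:
            return None
        return False


def normalize_allele(name: str) -> str:
    """Normalize an HLA allele name to upper-case two-field form.

    ``b*5101`` / ``B*51:01:02`` / ``HLA-B*51:01`` all normalize to ``B*51:01``;
    a bare first-field group (``C*04``) stays group-level.
    """
    s = str(name).strip().upper().replace("HLA-", "")
    s = re.sub(r"[NLSCAQ]$", "", s)  # expression-suffix letters
    m = re.match(r"^([ABC])\*?(\d+)(?::(\d+))?", s)
    if not m:
        raise ValueError(f"unparseable HLA allele name {name!r}")
    locus, f1, f2 = m.group(1), m.group(2), m.group(3)
    if f2 is None and len(f1) == 4:  # legacy 4-digit form, e.g. B*5101
        f1, f2 = f1[:2], f1[2:]
    out = f"{locus}*{int(f1):02d}"
    if f2 is not None:
        out += f":{int(f2):02d}"
    return out


def load_epitope_map(path=None) -> dict[str, frozenset[str]]:
    """Load an allele -> epitope-set map (bundled table when ``path`` is None).

    Keys are normalized allele names, either two-field (``B*27:02``) or
    first-field group (``B*51``); lookups fall back from the two-field name to
    its group.  An empty epitope set means "known allele, no KIR epitope"
    (e.g. Bw6), which is distinct from an absent (unknown -> untyped) allele.
    """
    if path is None:
        ref = resources.files("kirassoc").joinpath("data/hla_epitope_map.csv")
        with ref.open() as fh:
            return _parse_epitope_map(fh)
    with open(path) as fh:
        return _parse_epitope_map(fh)


def _parse_epitope_map(fh) -> dict[str, frozenset[str]]:
    table: dict[str, frozenset[str]] = {}
    for row in csv.DictReader(fh):
        allele = normalize_allele(f"{row['locus']}*{row['allele'].split('*')[-1]}")
        epitopes = frozenset(e for e in row["epitopes"].split(";") if e)
        bad = epitopes - set(EPITOPE_LABELS)
        if bad:
            raise ValueError(f"unknown epitope label(s) {sorted(bad)} for {allele}")
        table[allele] = epitopes
    return table


_DEFAULT_MAP: dict[str, frozenset[str]] | None = None


def default_epitope_map() -> dict[str, frozenset[str]]:
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = load_epitope_map()
    return _DEFAULT_MAP


def _lookup(allele: str, table: dict[str, frozenset[str]]) -> frozenset[str] | None:
    """Epitopes for an allele, falling back to its first-field group."""
    norm = normalize_allele(allele)
    if norm in table:
        return table[norm]
    group = norm.split(":")[0]
    if group in table:
        return table[group]
    return None


def assign_epitopes(
    a_alleles=(), b_alleles=(), c_alleles=(),
    allele_map: dict[str, frozenset[str]] | None = None,
) -> EpitopeProfile:
    """Assign KIR-ligand epitopes from up to two allele names per locus.

    Per-locus flags are the union over the typed alleles.  An allele missing
    from the map leaves the flags of its locus untyped (``None``) with a
    logged warning — never a silent False.  A locus with no alleles at all is
    untyped.
    """
    table = default_epitope_map() if allele_map is None else allele_map
    flags: dict[str, bool | None] = {}
    locus_flags = {
        "A": ("A3A11", "A_BW4"),
        "B": ("BW4_I80", "BW4_T80"),
        "C": ("C1", "C2"),
    }
    for locus, alleles in (("A", a_alleles), ("B", b_alleles), ("C", c_alleles)):
        alleles = [
            a for a in alleles
            if a is not None and str(a).strip() not in ("", "NA", "nan", "<NA>")
        ]
        if len(alleles) > 2:
            raise ValueError(f"more than two {locus}-locus alleles: {alleles}")
        hit: set[str] = set()
        known = bool(alleles)
        for allele in alleles:
            epis = _lookup(allele, table)
            if epis is None:
                logger.warning("HLA allele %s not in epitope map; locus %s left untyped",
                               allele, locus)
                known = False
            else:
                hit |= epis
        for label in locus_flags[locus]:
            flags[label] = (label in hit) if known else (True if label in hit else None)
    return EpitopeProfile(
        c1=flags["C1"], c2=flags["C2"],
        bw4_i80=flags["BW4_I80"], bw4_t80=flags["BW4_T80"],
        a3_a11=flags["A3A11"], a_bw4=flags["A_BW4"],
    )


def profile_from_flags(row: dict) -> EpitopeProfile:
    """Build a profile from epitope-level flags (pass-through, no allele map)."""
    def tri(v):
        if v is None or (isinstance(v, float) and pd.isna(v)) or v is pd.NA:
            return None
        return bool(int(v))
    return EpitopeProfile(
        c1=tri(row.get("hla_c1")), c2=tri(row.get("hla_c2")),
        bw4_i80=tri(row.get("hla_bw4_i80")), bw4_t80=tri(row.get("hla_bw4_t80")),
        a3_a11=tri(row.get("hla_a3a11")), a_bw4=tri(row.get("hla_a_bw4")),
    )


def pair_kir_hla(
    record: KirTypingRecord, epitopes: EpitopeProfile, merge_a_bw4: bool = False
) -> dict[str, bool | None]:
    """Receptor-ligand pair flags: gene present AND epitope carried.

    ``None`` on either side propagates to the pair flag (typed-subset
    denominators).  With ``merge_a_bw4`` the A-locus Bw4 alleles also satisfy
    the Bw4 side of the 3DL1/3DS1 pairs.
    """
    out: dict[str, bool | None] = {}
    for name, gene, attr in PAIR_DEFS:
        lig = getattr(epitopes, attr)
        if attr == "bw4" and merge_a_bw4:
            lig = _tri_or(lig, epitopes.a_bw4)
        out[name] = _tri_and(record.presence[gene], lig)
    return out


def _tri_and(x: bool | None, y: bool | None) -> bool | None:
    # strict propagation: a pair is typed only when both sides are typed
    if x is None or y is None:
        return None
    return bool(x) and bool(y)


def _tri_or(x: bool | None, y: bool | None) -> bool | None:
    if x is True or y is True:
        return True
    if x is None or y is None:
        return None
    return False


def assign_epitopes_cohort(
    df: pd.DataFrame,
    allele_map: dict[str, frozenset[str]] | None = None,
    merge_a_bw4: bool = False,
) -> pd.DataFrame:
    """Append epitope and KIR-HLA pair columns to a cohort DataFrame.

    Works from allele columns (``hla_a_1`` ... ``hla_c_2``) when present,
    otherwise from epitope flag columns (``hla_c1`` ...).  Adds
    nullable-boolean columns ``C1``, ``C2``, ``Bw4``, ``Bw4I80``, ``Bw4T80``,
    ``A3/A11``, ``A23/24/25/32`` and one column per pair in
    :data:`PAIR_DEFS`.
    """
    out = df.copy()
    has_alleles = any(c in df.columns for c in ALLELE_COLUMNS)
    profiles: list[EpitopeProfile] = []
    for _, row in df.iterrows():
        if has_alleles:
            profiles.append(
                assign_epitopes(
                    a_alleles=(row.get("hla_a_1"), row.get("hla_a_2")),
                    b_alleles=(row.get("hla_b_1"), row.get("hla_b_2")),
                    c_alleles=(row.get("hla_c_1"), row.get("hla_c_2")),
                    allele_map=allele_map,
                )
            )
        else:
            profiles.append(profile_from_flags(row))

    def col(vals):
        return pd.array([pd.NA if v is None else v for v in vals], dtype="boolean")

    out["C1"] = col([p.c1 for p in profiles])
    out["C2"] = col([p.c2 for p in profiles])
    out["Bw4I80"] = col([p.bw4_i80 for p in profiles])
    out["Bw4T80"] = col([p.bw4_t80 for p in profiles])
    out["Bw4"] = col([p.bw4 for p in profiles])
    out["A3/A11"] = col([p.a3_a11 for p in profiles])
    out["A23/24/25/32"] = col([p.a_bw4 for p in profiles])
    for name, gene, attr in PAIR_DEFS:
        lig_col = {"c1": "C1", "c2": "C2", "bw4": "Bw4", "a3_a11": "A3/A11"}[attr]
        lig = out[lig_col]
        if attr == "bw4" and merge_a_bw4:
            lig = lig | out["A23/24/25/32"]
        gene_flag = (df[gene] == 1).astype("boolean").where(~df[gene].isna(), pd.NA)
        pair = gene_flag & lig
        out[name] = pair.mask(gene_flag.isna() | lig.isna(), pd.NA)
    return out
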