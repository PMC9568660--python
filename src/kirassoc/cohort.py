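"""Cohort tables: CSV IO, vectorized classification and carrier frequencies.

A cohort is a pandas DataFrame with one row per individual: ``sample_id``,
``group`` (case|control), optional ``subtype``, one nullable-integer column
per KIR marker (1 present / 0 absent / NA untyped), ``kir2ds4_variant``
(fl|del|fl+del|neg|NA) and, when available, HLA columns (allele names or
epitope flags, see :mod:`kirassoc.hla`).

The vectorized classifiers here apply exactly the record-level rules of
:mod:`kirassoc.genotype` to whole cohorts; the test suite cross-checks the
two paths row by row.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import (
    DEFAULT_CLASS_MAP,
    DEFAULT_LINKAGE_RULE,
    GenotypeCatalog,
    KirClassMap,
    KirTypingRecord,
    LinkageRule,
    ValidationError,
)
from .loci import (
    A_CONTENT_GENES,
    B_SPECIFIC_GENES,
    DS4_CSV_VALUES,
    DS4_TO_CSV,
    KIR_MARKERS,
    NOT_APPLICABLE,
)

#: derived boolean columns added by :func:`classify_cohort`
DERIVED_FLAGS = (
    "AA", "Bx", "C4", "T4", "C4Tx", "CxT4", "C4T4", "CxTx",
    "iKIR>aKIR", "aKIR>iKIR", "iKIR>4", "aKIR>4",
    "2DS4fl", "2DS4del", "2DS4fl,del",
)


class CohortParseError(ValueError):
    """Raised when a cohort file cannot be parsed into the data model."""


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV/TSV into the canonical typed DataFrame."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in ("sample_id", "group") if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing required column(s) {missing}")
    return coerce_cohort(df, source=str(path))


def coerce_cohort(df: pd.DataFrame, source: str = "cohort") -> pd.DataFrame:
    """Coerce string-typed columns to the canonical dtypes, with row-level errors."""
    df = df.copy()
    errors: list[str] = []
    for marker in KIR_MARKERS:
        if marker not in df.columns:
            df[marker] = pd.array([pd.NA] * len(df), dtype="Int8")
            continue
        col = df[marker].astype("string").str.strip()
        col = col.replace({"NA": pd.NA, "": pd.NA, "nan": pd.NA})
        bad = col.dropna()[~col.dropna().isin(["0", "1"])]
        for idx, val in bad.items():
            errors.append(f"{source}: row {idx + 2}: {marker}={val!r} (expected 1/0/NA)")
        df[marker] = pd.to_numeric(col.where(col.isin(["0", "1"])), errors="coerce").astype("Int8")
    hla_flag_cols = ("hla_c1", "hla_c2", "hla_bw4_i80", "hla_bw4_t80", "hla_a3a11", "hla_a_bw4")
    for flag in hla_flag_cols:
        if flag not in df.columns:
            continue
        col = df[flag].astype("string").str.strip()
        col = col.replace({"NA": pd.NA, "": pd.NA, "nan": pd.NA})
        bad = col.dropna()[~col.dropna().isin(["0", "1"])]
        for idx, val in bad.items():
            errors.append(f"{source}: row {idx + 2}: {flag}={val!r} (expected 1/0/NA)")
        df[flag] = pd.to_numeric(col.where(col.isin(["0", "1"])), errors="coerce").astype("Int8")
    if "kir2ds4_variant" in df.columns:
        col = df["kir2ds4_variant"].astype("string").str.strip()
        col = col.replace({"NA": pd.NA, "": pd.NA, "nan": pd.NA})
        bad = col.dropna()[~col.dropna().isin(list(DS4_CSV_VALUES))]
        for idx, val in bad.items():
            errors.append(
                f"{source}: row {idx + 2}: kir2ds4_variant={val!r} "
                f"(expected {'/'.join(DS4_CSV_VALUES)}/NA)"
            )
        df["kir2ds4_variant"] = col.map(DS4_CSV_VALUES).astype("string")
    else:
        df["kir2ds4_variant"] = pd.array([pd.NA] * len(df), dtype="string")
    badg = df["group"].dropna()[~df["group"].dropna().isin(["case", "control"])]
    for idx, val in badg.items():
        errors.append(f"{source}: row {idx + 2}: group={val!r} (expected case/control)")
    if errors:
        raise CohortParseError("\n".join(errors))
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort DataFrame back to CSV with the external value spellings."""
    out = df.copy()
    if "kir2ds4_variant" in out.columns:
        out["kir2ds4_variant"] = out["kir2ds4_variant"].map(DS4_TO_CSV).astype("string")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    out.to_csv(path, sep=sep, index=False, na_rep="NA")


def records_from_frame(df: pd.DataFrame) -> list[KirTypingRecord]:
    """Materialize :class:`KirTypingRecord` objects from a cohort DataFrame."""
    records = []
    for _, row in df.iterrows():
        presence = {
            m: (None if pd.isna(row[m]) else bool(row[m])) for m in KIR_MARKERS
        }
        variant = row.get("kir2ds4_variant")
        subtype = row.get("subtype")
        records.append(
            KirTypingRecord(
                sample_id=str(row["sample_id"]),
                group=None if pd.isna(row.get("group")) else str(row["group"]),
                subtype=None if pd.isna(subtype) else str(subtype),
                presence=presence,
                ds4_variant=None if pd.isna(variant) else str(variant),
            )
        )
    return records


def _all_eq(df: pd.DataFrame, markers: Iterable[str], value: int) -> pd.Series:
    """Nullable-boolean Series: all listed markers equal ``value`` (Kleene).

    Definitely True when every marker is typed and equals ``value``;
    definitely False when any typed marker differs; NA otherwise.
    """
    sub = df[list(markers)]
    definite_false = ((sub != value) & ~sub.isna()).any(axis=1)
    definite_true = (sub == value).all(axis=1) & ~sub.isna().any(axis=1)
    out = pd.Series(pd.NA, index=df.index, dtype="boolean")
    out[definite_true] = True
    out[definite_false] = False
    return out


def classify_cohort(
    df: pd.DataFrame,
    class_map: KirClassMap = DEFAULT_CLASS_MAP,
    rule: LinkageRule = DEFAULT_LINKAGE_RULE,
    catalog: GenotypeCatalog | None = None,
    validate: bool = True,
) -> pd.DataFrame:
    """Append genotype-classification columns to a cohort DataFrame.

    Adds nullable-boolean factor columns (``AA``, ``Bx``, ``C4``, ``T4``, the
    four Bx subsets, count flags, 2DS4 variant categories), integer
    ``n_inhibitory``/``n_activating`` counts, and — for fully typed records —
    ``content_key`` and ``genotype_id`` (when a catalog is supplied, new keys
    are appended to it).  Untyped markers propagate NA into every factor whose
    value they could change; the record-level functions in
    :mod:`kirassoc.genotype` define the semantics.
    """
    if validate:
        report = validate_frame(df)
        if report:
            raise ValidationError("; ".join(report[:20]))
    out = df.copy()

    # AA iff every A-content gene present and every B-specific gene absent;
    # Kleene conjunction keeps undecidable records NA.
    aa = _all_eq(df, sorted(A_CONTENT_GENES), 1) & _all_eq(df, sorted(B_SPECIFIC_GENES), 0)
    out["AA"], out["Bx"] = aa, ~aa

    c4 = _all_eq(df, rule.c4_required, 1)
    t4 = _all_eq(df, rule.t4_required, 1)
    out["C4"], out["T4"] = c4, t4
    for name, (cv, tv) in {
        "C4Tx": (True, False), "CxT4": (False, True),
        "C4T4": (True, True), "CxTx": (False, False),
    }.items():
        # three-valued logic: a definitely-absent cluster falsifies the subset
        # even when the other call is NA; AA records are simply False.
        out[name] = (c4 if cv else ~c4) & (t4 if tv else ~t4) & out["Bx"]
    subset = pd.Series(pd.NA, index=df.index, dtype="string")
    for name in ("C4Tx", "CxT4", "C4T4", "CxTx"):
        subset = subset.mask(out[name].fillna(False), name)
    subset = subset.mask(aa.fillna(False), NOT_APPLICABLE)
    out["bx_subset"] = subset

    isub = df[sorted(class_map.inhibitory_set)]
    asub = df[sorted(class_map.activating_set)]
    n_i = (isub == 1).sum(axis=1).where(~isub.isna().any(axis=1), pd.NA).astype("Int64")
    n_a = (asub == 1).sum(axis=1).where(~asub.isna().any(axis=1), pd.NA).astype("Int64")
    out["n_inhibitory"], out["n_activating"] = n_i, n_a
    out["iKIR>aKIR"] = (n_i > n_a).astype("boolean")
    out["aKIR>iKIR"] = (n_a > n_i).astype("boolean")
    out["iKIR>4"] = (n_i > 4).astype("boolean")
    out["aKIR>4"] = (n_a > 4).astype("boolean")

    variant = df["kir2ds4_variant"]
    out["2DS4fl"] = (variant == "fl").astype("boolean").where(~variant.isna(), pd.NA)
    out["2DS4del"] = (variant == "del").astype("boolean").where(~variant.isna(), pd.NA)
    out["2DS4fl,del"] = (variant == "fl_del").astype("boolean").where(~variant.isna(), pd.NA)

    typed = ~df[list(KIR_MARKERS)].isna().any(axis=1)
    keys = pd.Series(pd.NA, index=df.index, dtype="string")
    if typed.any():
        mat = df.loc[typed, list(KIR_MARKERS)].to_numpy(dtype="int64")
        keys.loc[typed] = ["".join("1" if v else "0" for v in row) for row in mat]
    out["content_key"] = keys
    if catalog is not None:
        present_keys = keys.dropna().unique().tolist()
        mapping = catalog.assign(present_keys)
        out["genotype_id"] = keys.map(mapping).astype("string")
    return out


def validate_frame(df: pd.DataFrame) -> list[str]:
    """Framework/2DS4 invariant violations on a cohort DataFrame."""
    problems: list[str] = []
    for m in ("3DL3", "3DP1", "2DL4", "3DL2"):
        if m in df.columns:
            bad = df.index[df[m] == 0]
            problems += [f"{df.loc[i, 'sample_id']}: framework gene {m} called absent" for i in bad]
    if "kir2ds4_variant" in df.columns and "2DS4" in df.columns:
        v = df["kir2ds4_variant"]
        pos = v.isin(["fl", "del", "fl_del"])
        bad = df.index[pos & (df["2DS4"] == 0)]
        problems += [
            f"{df.loc[i, 'sample_id']}: ds4_variant={v[i]} but 2DS4 called absent" for i in bad
        ]
        bad = df.index[(v == "negative") & (df["2DS4"] == 1)]
        problems += [
            f"{df.loc[i, 'sample_id']}: ds4_variant=negative but 2DS4 called present" for i in bad
        ]
    return problems


Factor = str | Callable[[pd.DataFrame], pd.Series]


def evaluate_factor(df: pd.DataFrame, factor: Factor) -> pd.Series:
    """Evaluate a factor to a nullable-boolean carrier Series.

    A factor is a column name (marker or derived flag) or a callable mapping
    the DataFrame to a boolean/nullable-boolean Series.
    """
    if callable(factor):
        series = factor(df)
    elif factor in df.columns:
        series = df[factor]
    else:
        raise KeyError(
            f"factor {factor!r} is not a cohort column; classify the cohort first "
            "or pass a callable"
        )
    if str(series.dtype) in ("Int8", "Int64", "int64", "float64"):
        series = (series == 1).astype("boolean").where(~series.isna(), pd.NA)
    return series.astype("boolean")


@dataclass(frozen=True)
class CarrierFrequency:
    numerator: int
    denominator: int

    @property
    def percent(self) -> float:
        if self.denominator == 0:
            return float("nan")
        return 100.0 * self.numerator / self.denominator

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def carrier_frequency(
    df: pd.DataFrame, factor: Factor, group: str | None = None
) -> CarrierFrequency:
    """Carrier frequency of a factor: positives / typed individuals x 100.

    Untyped records (NA) are excluded from numerator and denominator, so the
    per-factor denominator varies, mirroring per-marker typed subsets.
    """
    sub = df if group is None else df[df["group"] == group]
    series = evaluate_factor(sub, factor)
    typed = series.dropna()
    return CarrierFrequency(numerator=int(typed.sum()), denominator=int(len(typed)))


def distinct_genotype_count(df: pd.DataFrame) -> int:
    """Number of distinct gene-content keys among fully typed individuals."""
    typed = ~df[list(KIR_MARKERS)].isna().any(axis=1)
    if not typed.any():
        return 0
    mat = df.loc[typed, list(KIR_MARKERS)].to_numpy(dtype="int64")
    return len({tuple(row) for row in mat})
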