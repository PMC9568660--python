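"""End-to-end analysis runs: classify, pair with HLA, test, report.

``run_analysis`` reads a cohort, classifies every individual, assigns HLA
epitopes when typing is available, computes the comparison families
(individual genes, KIR-HLA pairs and epitopes, genotype classes, count flags
and combined factors) and writes one TSV per family plus a gene-content
matrix over the distinct genotypes and a JSON run log.  Internal sum checks
(AA + Bx = N, Bx subsets partition Bx, C4/T4 identities) are re-verified at
emit time and abort the run on failure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    CarrierFrequency,
    carrier_frequency,
    classify_cohort,
    distinct_genotype_count,
    read_cohort,
    validate_frame,
)
from .genotype import (
    DEFAULT_CLASS_MAP,
    DEFAULT_LINKAGE_RULE,
    GenotypeCatalog,
    KirClassMap,
    LinkageRule,
    ValidationError,
)
from .hla import ALLELE_COLUMNS, EPITOPE_COLUMNS, PAIR_DEFS, assign_epitopes_cohort
from .loci import KIR_MARKERS
from .stats import AssociationResult, UndefinedAssociation, carrier_association, svejgaard_combined

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A consistency check failed while emitting reports."""


@dataclass
class AnalysisConfig:
    """Comparison families and classification settings for a full run."""

    gene_family: tuple[str, ...] = KIR_MARKERS + ("2DS4fl", "2DS4del", "2DS4fl,del")
    epitope_family: tuple[str, ...] = (
        "C1", "C2", "Bw4", "Bw4T80", "Bw4I80", "A3/A11", "A23/24/25/32",
    )
    pair_family: tuple[str, ...] = tuple(name for name, _, _ in PAIR_DEFS)
    genotype_family: tuple[str, ...] = (
        "AA", "Bx", "CxT4", "C4Tx", "C4T4", "CxTx", "C4", "T4",
    )
    count_flag_family: tuple[str, ...] = ("iKIR>aKIR", "aKIR>iKIR", "iKIR>4", "aKIR>4")
    combined_factors: tuple[tuple[str, str], ...] = (("CxTx", "2DS2"), ("CxTx", "2DL2"))
    subgroup_factors: tuple[tuple[str, str], ...] = (
        ("2DS2", "iKIR>aKIR"), ("2DL2", "iKIR>aKIR"),
    )
    #: correction factor n per family (count flags: 4; combined genotypes: 9)
    correction_n: dict = field(default_factory=lambda: {"count_flags": 4, "combined": 9})
    class_map: KirClassMap = DEFAULT_CLASS_MAP
    linkage_rule: LinkageRule = DEFAULT_LINKAGE_RULE
    alpha: float = 0.05
    merge_a_bw4: bool = False
    subtype_stratification: bool = True


def _fmt_pct(freq: CarrierFrequency) -> str:
    if not freq.defined:
        return "NA"
    return f"{freq.percent:.1f} ({freq.numerator}/{freq.denominator})"


def format_p(p: float) -> str:
    """p to 2 significant figures (table convention)."""
    if p != p:
        return "NA"
    return f"{p:.2g}"


def _result_row(res: AssociationResult | None, factor: str) -> dict:
    if res is None:
        return {"factor": factor, "p": "NA", "OR": "NA", "CI95": "NA"}
    t = res.table
    row = {
        "factor": factor,
        "case_freq": _fmt_pct(CarrierFrequency(t.a, t.a + t.b)),
        "control_freq": _fmt_pct(CarrierFrequency(t.c, t.c + t.d)),
        "p": format_p(res.p_value),
        "OR": f"{res.odds_ratio:.2f}",
        "CI95": f"{res.ci_low:.2f}-{res.ci_high:.2f}",
        "significant": "*" if res.significant else "",
    }
    if res.correction_n:
        row["p_corrected"] = format_p(res.p_corrected)
        row["correction_n"] = res.correction_n
    if res.haldane_corrected:
        row["note"] = "Haldane-Anscombe +0.5"
    return row


def _family_report(
    df: pd.DataFrame,
    factors,
    correction_n: int | None,
    alpha: float,
    strata: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, list[dict]]:
    rows, results = [], []
    for factor in factors:
        row = {"factor": factor}
        for label, sub in strata.items():
            try:
                res = carrier_association(sub, factor, correction_n=correction_n, alpha=alpha)
            except (UndefinedAssociation, KeyError):
                res = None
            prefix = "" if label == "all" else f"{label}_"
            if res is None:
                row[f"{prefix}case_freq"] = row[f"{prefix}p"] = "NA"
                continue
            r = _result_row(res, factor)
            for k, v in r.items():
                if k != "factor":
                    row[f"{prefix}{k}"] = v
            if label == "all":
                results.append({"factor": factor, **_json_result(res)})
        rows.append(row)
    return pd.DataFrame(rows), results


def _json_result(res: AssociationResult) -> dict:
    t = res.table
    return {
        "case_positive": t.a, "case_n": t.a + t.b,
        "control_positive": t.c, "control_n": t.c + t.d,
        "case_percent": round(res.case_frequency, 4),
        "control_percent": round(res.control_frequency, 4),
        "odds_ratio": res.odds_ratio, "ci_low": res.ci_low, "ci_high": res.ci_high,
        "p_value": res.p_value, "p_corrected": res.p_corrected,
        "correction_n": res.correction_n, "haldane": res.haldane_corrected,
        "significant_uncorrected": res.significant,
    }


def _check_partitions(classified: pd.DataFrame) -> None:
    """Re-verify the partition and linkage identities; abort on failure."""
    full = classified[~classified["AA"].isna()]
    n_aa = int((full["AA"] == True).sum())  # noqa: E712
    n_bx = int((full["Bx"] == True).sum())  # noqa: E712
    if n_aa + n_bx != len(full):
        raise PipelineError("sum check failed: AA + Bx != N on classified records")
    bx = full[full["Bx"] == True]  # noqa: E712
    decided = bx[~bx["bx_subset"].isna()]
    sizes = {s: int((decided["bx_subset"] == s).sum()) for s in ("C4Tx", "CxT4", "C4T4", "CxTx")}
    if sum(sizes.values()) != len(decided):
        raise PipelineError("sum check failed: Bx subsets do not partition Bx")
    n_c4 = int((decided["C4"] == True).sum())  # noqa: E712
    n_t4 = int((decided["T4"] == True).sum())  # noqa: E712
    if n_c4 != sizes["C4Tx"] + sizes["C4T4"] or n_t4 != sizes["CxT4"] + sizes["C4T4"]:
        raise PipelineError("sum check failed: C4/T4 linkage identities violated")


def genotype_matrix(classified: pd.DataFrame) -> pd.DataFrame:
    """Distinct genotypes x gene-presence matrix with per-group carrier counts."""
    typed = classified[~classified["content_key"].isna()]
    rows = []
    for key, sub in typed.groupby("content_key"):
        row = {"genotype_id": sub["genotype_id"].iloc[0] if "genotype_id" in sub else key,
               "content_key": key}
        row.update({g: int(key[i]) for i, g in enumerate(KIR_MARKERS)})
        row["n_case"] = int((sub["group"] == "case").sum())
        row["n_control"] = int((sub["group"] == "control").sum())
        rows.append(row)
    mat = pd.DataFrame(rows).sort_values("content_key", ignore_index=True)
    if len(mat) != distinct_genotype_count(classified):
        raise PipelineError("genotype matrix row count disagrees with distinct-key count")
    return mat


def run_analysis(
    cohort, config: AnalysisConfig | None = None, out_dir=None,
    catalog: GenotypeCatalog | None = None,
) -> dict:
    """Run the full association analysis; returns the report bundle.

    ``cohort`` is a DataFrame or a CSV/TSV path.  When ``out_dir`` is given,
    reports are written as TSV plus a machine-readable JSON mirror and a run
    log.  Returns a dict with the per-family DataFrames, the JSON-style
    results, the genotype matrix and the classified cohort.
    """
    config = config or AnalysisConfig()
    df = read_cohort(cohort) if not isinstance(cohort, pd.DataFrame) else cohort
    for grp in ("case", "control"):
        if not (df["group"] == grp).any():
            raise PipelineError(f"empty group: no {grp} records in cohort")

    catalog = catalog if catalog is not None else GenotypeCatalog()
    classified = classify_cohort(
        df, class_map=config.class_map, rule=config.linkage_rule, catalog=catalog
    )
    has_hla = any(c in df.columns for c in ALLELE_COLUMNS + EPITOPE_COLUMNS)
    if has_hla:
        classified = assign_epitopes_cohort(classified, merge_a_bw4=config.merge_a_bw4)
    _check_partitions(classified)

    strata: dict[str, pd.DataFrame] = {"all": classified}
    if config.subtype_stratification and "subtype" in classified.columns:
        subtypes = classified["subtype"].dropna().unique()
        if {"NSCLC_SCC", "NSCLC_AD", "SCLC"} & set(subtypes):
            controls = classified[classified["group"] == "control"]
            nsclc = classified[
                classified["subtype"].isin(["NSCLC_SCC", "NSCLC_AD"]).fillna(False)
            ]
            sclc = classified[(classified["subtype"] == "SCLC").fillna(False)]
            if len(nsclc):
                strata["NSCLC"] = pd.concat([nsclc, controls], ignore_index=True)
            if len(sclc):
                strata["SCLC"] = pd.concat([sclc, controls], ignore_index=True)

    bundle: dict = {"classified": classified, "catalog": catalog, "results": {}}
    reports: dict[str, pd.DataFrame] = {}

    fam_specs = [
        ("kir_genes", config.gene_family, None, strata),
        ("genotype_classes", config.genotype_family, None, strata),
        ("count_flags", config.count_flag_family, config.correction_n.get("count_flags"), {"all": classified}),
    ]
    if has_hla:
        fam_specs.insert(1, ("kir_hla", config.epitope_family + config.pair_family, None,
                             {"all": classified}))
    for name, factors, corr_n, fam_strata in fam_specs:
        table, results = _family_report(classified, factors, corr_n, config.alpha, fam_strata)
        reports[name] = table
        bundle["results"][name] = results

    # combined genotypes (naive carrier test, corrected) + Svejgaard batteries
    combined_rows, combined_json = [], []
    corr = config.correction_n.get("combined")
    for fa, fb in config.combined_factors:
        rep = svejgaard_combined(classified, fa, fb, correction_n=corr, alpha=config.alpha)
        res = rep.combined_carrier
        combined_rows.append(_result_row(res, f"{fa}/{fb}"))
        combined_json.append({"factor": f"{fa}/{fb}", **(_json_result(res) if res else {})})
        bundle["results"].setdefault("svejgaard", {})[f"{fa}/{fb}"] = {
            name: (_json_result(r) if r else None) for name, r in rep.battery.items()
        }
    for fa, fb in config.subgroup_factors:
        rep = svejgaard_combined(classified, fa, fb, correction_n=corr, alpha=config.alpha)
        res = rep.battery[f"{fa} within {fb}+"]
        combined_rows.append(_result_row(res, f"{fa} within {fb}+"))
        combined_json.append(
            {"factor": f"{fa} within {fb}+", **(_json_result(res) if res else {})}
        )
    reports["combined_factors"] = pd.DataFrame(combined_rows)
    bundle["results"]["combined_factors"] = combined_json

    mat = genotype_matrix(classified)
    reports["genotype_matrix"] = mat
    bundle["reports"] = reports

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in reports.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        with open(out / "results.json", "w") as fh:
            json.dump(bundle["results"], fh, indent=2, sort_keys=True)
        run_log = {
            "kirassoc_version": __version__,
            "n_records": len(df),
            "n_cases": int((df["group"] == "case").sum()),
            "n_controls": int((df["group"] == "control").sum()),
            "distinct_genotypes": int(len(mat)),
            "class_map": config.class_map.describe(),
            "linkage_rule": config.linkage_rule.describe(),
            "alpha": config.alpha,
            "correction_n": config.correction_n,
            "merge_a_bw4": config.merge_a_bw4,
            "deterministic": "reports depend only on the input cohort and configuration",
        }
        with open(out / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=2, sort_keys=True)
    return bundle


@dataclass
class ValidationReport:
    n_records: int
    framework_violations: int
    ds4_violations: int
    hla_violations: int
    untyped_framework: int
    messages: list[str]

    @property
    def ok(self) -> bool:
        return not (self.framework_violations or self.ds4_violations or self.hla_violations)


def validate_cohort(cohort) -> ValidationReport:
    """Check data-model invariants; untyped (NA) frameworks are allowed."""
    df = read_cohort(cohort) if not isinstance(cohort, pd.DataFrame) else cohort
    messages = validate_frame(df)
    framework = sum("framework" in m for m in messages)
    ds4 = sum("ds4_variant" in m for m in messages)
    hla = 0
    for i80, t80 in (("hla_bw4_i80", "hla_bw4_t80"),):
        if i80 in df.columns and t80 in df.columns:
            pass  # position-80 subtypes are independent carriage flags
    if {"hla_c1", "hla_c2"} <= set(df.columns):
        bad = df.index[(df["hla_c1"] == 0) & (df["hla_c2"] == 0)]
        for i in bad:
            messages.append(
                f"{df.loc[i, 'sample_id']}: HLA-C typed but carries neither C1 nor C2"
            )
            hla += 1
    untyped_fw = int(df[["3DL3", "3DP1", "2DL4", "3DL2"]].isna().any(axis=1).sum())
    return ValidationReport(
        n_records=len(df),
        framework_violations=framework,
        ds4_violations=ds4,
        hla_violations=hla,
        untyped_framework=untyped_fw,
        messages=messages,
    )
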