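"""Association statistics for carrier-frequency case-control comparisons.

The engine consists of: the two-tailed Fisher exact test (exact hypergeometric
enumeration with fixed margins; two-sided p sums the probabilities of all
tables no more likely than the observed one), the odds ratio with a
Woolf-logit 95% confidence interval (Haldane-Anscombe +0.5 on zero cells),
the Sidak-type multiple-comparison correction P_n = 1 - (1 - P)^n, and the
Svejgaard-Ryder battery dissecting the joint effect of two factors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm

from .cohort import Factor, carrier_frequency

#: z quantile used for 95% intervals (Phi^-1(0.975) to 6 decimals)
Z_95 = 1.959964

#: relative tolerance for point-probability ties in the two-sided Fisher sum
FISHER_TIE_RTOL = 1e-7


class DegenerateTableWarning(UserWarning):
    """A 2x2 table has an empty row or column margin."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = case positive, b = case negative, c/d = control pos/neg."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact p-value.

    Enumerates the hypergeometric distribution over all tables with the
    observed margins and sums the point probabilities that do not exceed the
    observed one (relative tolerance ``FISHER_TIE_RTOL`` for float ties) —
    the convention of mainstream statistical packages.  A zero row or column
    margin makes the table degenerate: p = 1 with a warning.
    """
    a, b, c, d = table.cells()
    row1, row2, col1 = a + b, c + d, a + c
    n = table.n
    if row1 == 0 or row2 == 0 or col1 == 0 or (b + d) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", DegenerateTableWarning,
                      stacklevel=2)
        return 1.0
    support = np.arange(max(0, col1 - row2), min(col1, row1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + FISHER_TIE_RTOL)].sum())
    return min(p, 1.0)


def odds_ratio_woolf(
    table: ContingencyTable2x2, confidence: float = 0.95, z: float | None = None
) -> tuple[float, float, float, bool]:
    """Odds ratio (ad/bc) with a Woolf-logit confidence interval.

    Returns ``(odds_ratio, ci_low, ci_high, haldane_corrected)``.  When any
    cell is zero, 0.5 is added to every cell (Haldane-Anscombe) and the flag
    is set.  Two zero cells in the same column/row of the ratio leave the OR
    undefined even after correction only for fully empty margins, which raise.
    ``z`` defaults to 1.959964 at the 95% level (the 0.975 normal quantile to
    six decimals) and to ``norm.ppf`` otherwise.
    """
    if z is None:
        z = Z_95 if math.isclose(confidence, 0.95) else float(norm.ppf((1 + confidence) / 2))
    a, b, c, d = (float(v) for v in table.cells())
    haldane = min(table.cells()) == 0
    if haldane:
        if (table.a == 0 and table.d == 0) or (table.b == 0 and table.c == 0):
            # both numerator or both denominator cells empty: direction unknowable
            raise ValueError("odds ratio undefined: two opposing zero cells")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0 or a * d == 0:
        raise ValueError("odds ratio undefined for empty margin")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - z * se)
    hi = math.exp(math.log(or_) + z * se)
    return or_, lo, hi, haldane


def correct_pvalue(p: float, n: int) -> float:
    """Multiple-comparison correction P_n = 1 - (1 - P)^n for n comparisons."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if n == 1:
        return float(p)
    # clamp against float roundoff so the correction never undercuts p
    return min(1.0, max(float(p), 1.0 - (1.0 - p) ** n))


@dataclass(frozen=True)
class AssociationResult:
    """One carrier-frequency comparison between cases and controls."""

    factor: str
    table: ContingencyTable2x2
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    p_corrected: float | None = None
    correction_n: int | None = None
    haldane_corrected: bool = False
    alpha: float = 0.05

    @property
    def case_frequency(self) -> float:
        return 100.0 * self.table.a / (self.table.a + self.table.b)

    @property
    def control_frequency(self) -> float:
        return 100.0 * self.table.c / (self.table.c + self.table.d)

    @property
    def significant(self) -> bool:
        """Significance at alpha on the uncorrected p (as reported in tables)."""
        return self.p_value < self.alpha

    @property
    def significant_corrected(self) -> bool | None:
        if self.p_corrected is None:
            return None
        return self.p_corrected < self.alpha


def association_from_counts(
    factor: str,
    case_pos: int, case_n: int,
    control_pos: int, control_n: int,
    correction_n: int | None = None,
    alpha: float = 0.05,
) -> AssociationResult:
    """Build the 2x2 table from carrier counts and run the full battery."""
    if case_pos > case_n or control_pos > control_n:
        raise ValueError("positive count exceeds typed count")
    table = ContingencyTable2x2(
        a=case_pos, b=case_n - case_pos, c=control_pos, d=control_n - control_pos
    )
    p = fisher_exact_two_tailed(table)
    or_, lo, hi, haldane = odds_ratio_woolf(table)
    pc = correct_pvalue(p, correction_n) if correction_n else None
    return AssociationResult(
        factor=factor, table=table, odds_ratio=or_, ci_low=lo, ci_high=hi,
        p_value=p, p_corrected=pc, correction_n=correction_n,
        haldane_corrected=haldane, alpha=alpha,
    )


class UndefinedAssociation(ValueError):
    """The factor is untyped everywhere in one of the groups."""


def carrier_association(
    df: pd.DataFrame,
    factor: Factor,
    label: str | None = None,
    correction_n: int | None = None,
    alpha: float = 0.05,
    case_group: str = "case",
    control_group: str = "control",
) -> AssociationResult:
    """Case-vs-control carrier association for one factor on a cohort.

    Untyped records are excluded per-factor from both numerator and
    denominator, so each factor carries its own typed-subset n.
    """
    case = carrier_frequency(df[df["group"] == case_group], factor)
    ctrl = carrier_frequency(df[df["group"] == control_group], factor)
    if not case.defined or not ctrl.defined:
        raise UndefinedAssociation(
            f"factor {factor!r} has no typed records in "
            f"{'cases' if not case.defined else 'controls'}"
        )
    name = label or (factor if isinstance(factor, str) else getattr(factor, "__name__", "factor"))
    return association_from_counts(
        name, case.numerator, case.denominator, ctrl.numerator, ctrl.denominator,
        correction_n=correction_n, alpha=alpha,
    )


@dataclass
class CombinedFactorReport:
    """Svejgaard-Ryder dissection of the joint effect of two factors.

    ``cross_tab`` counts the four joint-carriage classes (A+B+, A+B-, A-B+,
    A-B-) per group over records typed for both factors; ``battery`` holds
    the pairwise comparisons, each a case-vs-control 2x2 on a subgroup or
    margin; ``combined_carrier`` is the naive A+B+ vs all-others test.
    """

    factor_a: str
    factor_b: str
    cross_tab: pd.DataFrame = field(default_factory=pd.DataFrame)
    battery: dict[str, AssociationResult | None] = field(default_factory=dict)
    combined_carrier: AssociationResult | None = None


def svejgaard_combined(
    df: pd.DataFrame,
    factor_a: Factor,
    factor_b: Factor,
    label_a: str | None = None,
    label_b: str | None = None,
    correction_n: int | None = None,
    alpha: float = 0.05,
) -> CombinedFactorReport:
    """Run the Svejgaard-Ryder combined-factor battery for two factors.

    Comparisons (each case vs control): A within B-positives, A within
    B-negatives, B within A-positives, B within A-negatives, A+B+ vs A-B-,
    A+B- vs A-B+, marginal A, marginal B — plus the naive combined-carrier
    test (A+B+ vs all others).  A comparison whose classes are empty in both
    groups is reported as ``None`` and the battery continues.
    """
    from .cohort import evaluate_factor

    la = label_a or str(factor_a)
    lb = label_b or str(factor_b)
    va = evaluate_factor(df, factor_a)
    vb = evaluate_factor(df, factor_b)
    typed = ~(va.isna() | vb.isna())
    sub = df[typed].copy()
    a = va[typed].astype(bool)
    b = vb[typed].astype(bool)

    classes = pd.Series("A-B-", index=sub.index)
    classes[a & b] = "A+B+"
    classes[a & ~b] = "A+B-"
    classes[~a & b] = "A-B+"
    cross = (
        pd.crosstab(sub["group"], classes)
        .reindex(index=["case", "control"], columns=["A+B+", "A+B-", "A-B+", "A-B-"],
                 fill_value=0)
    )

    def counts(group: str, pos_mask, denom_mask) -> tuple[int, int]:
        g = sub["group"] == group
        return int((g & pos_mask & denom_mask).sum()), int((g & denom_mask).sum())

    def compare(name: str, pos_mask, denom_mask) -> AssociationResult | None:
        ca, na = counts("case", pos_mask, denom_mask)
        cc, nc = counts("control", pos_mask, denom_mask)
        if na == 0 and nc == 0:
            return None
        if na == 0 or nc == 0:
            return None
        return association_from_counts(name, ca, na, cc, nc,
                                       correction_n=correction_n, alpha=alpha)

    all_ = pd.Series(True, index=sub.index)
    report = CombinedFactorReport(factor_a=la, factor_b=lb, cross_tab=cross)
    report.battery = {
        f"{la} within {lb}+": compare(f"{la} within {lb}+", a, b),
        f"{la} within {lb}-": compare(f"{la} within {lb}-", a, ~b),
        f"{lb} within {la}+": compare(f"{lb} within {la}+", b, a),
        f"{lb} within {la}-": compare(f"{lb} within {la}-", b, ~a),
        f"{la}+{lb}+ vs {la}-{lb}-": compare(f"{la}+{lb}+ vs {la}-{lb}-",
                                             a & b, (a & b) | (~a & ~b)),
        f"{la}+{lb}- vs {la}-{lb}+": compare(f"{la}+{lb}- vs {la}-{lb}+",
                                             a & ~b, (a & ~b) | (~a & b)),
        f"{la} marginal": compare(f"{la} marginal", a, all_),
        f"{lb} marginal": compare(f"{lb} marginal", b, all_),
    }
    report.combined_carrier = compare(f"{la}/{lb} combined carrier", a & b, all_)
    return report
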