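"""Synthetic case-control cohort generator with KIR haplotype-block structure.

Each individual inherits two independent KIR haplotypes; each haplotype is
one centromeric and one telomeric gene block drawn from a pool, with the four
framework genes implicit on every haplotype.  Gene presence is the union over
the two haplotypes, which reproduces the closed-form carrier relation
F = 1 - (1 - q)^2 for a gene carried by haplotype fraction q, and builds the
C4/T4 cluster linkage into the data by construction.  HLA KIR-ligand epitopes
are drawn per locus under Hardy-Weinberg equilibrium.  A case-control effect
of configurable odds ratio can be injected on any factor through an
outcome-model (logistic) assignment, which yields the target odds ratio in
expectation under case-control sampling.

Default parameters (block frequencies, epitope allele frequencies, 2DS4
variant split, HLA-typed fraction) live in ``data/default_blocks.yaml`` and
were fitted to the healthy-control column of the calibration cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import Factor, evaluate_factor
from .genotype import ConfigurationError
from .loci import FRAMEWORK_GENES, KIR_MARKERS

_FREQ_TOL = 1e-6


@dataclass(frozen=True)
class Block:
    name: str
    genes: frozenset[str]
    frequency: float

    def __post_init__(self) -> None:
        unknown = self.genes - set(KIR_MARKERS)
        if unknown:
            raise ConfigurationError(f"block {self.name}: unknown genes {sorted(unknown)}")
        if not 0 <= self.frequency <= 1:
            raise ConfigurationError(f"block {self.name}: frequency {self.frequency} not in [0,1]")


@dataclass(frozen=True)
class HaplotypeBlockPool:
    centromeric: tuple[Block, ...]
    telomeric: tuple[Block, ...]

    def __post_init__(self) -> None:
        for side, blocks in (("centromeric", self.centromeric), ("telomeric", self.telomeric)):
            total = sum(b.frequency for b in blocks)
            if abs(total - 1.0) > 1e-6:
                raise ConfigurationError(f"{side} block frequencies sum to {total}, expected 1")


@dataclass(frozen=True)
class HlaEpitopeFreqs:
    """Per-locus epitope allele frequencies (HWE).  Remainders: C2, Bw6, other-A."""

    c1: float = 0.503
    b_bw4_i80: float = 0.093
    b_bw4_t80: float = 0.275
    a3_a11: float = 0.220
    a_bw4: float = 0.288

    def __post_init__(self) -> None:
        for name, v in (("c1", self.c1), ("b_bw4_i80 + b_bw4_t80", self.b_bw4_i80 + self.b_bw4_t80),
                        ("a3_a11 + a_bw4", self.a3_a11 + self.a_bw4)):
            if not -_FREQ_TOL <= v <= 1 + _FREQ_TOL:
                raise ConfigurationError(f"HLA frequency {name} = {v} not in [0, 1]")


@dataclass(frozen=True)
class EffectSpec:
    """Injected case-control effect: log-odds of case status shift by ln(OR)."""

    factor: Factor
    odds_ratio: float

    def __post_init__(self) -> None:
        if not self.odds_ratio > 0:
            raise ConfigurationError(f"odds ratio must be > 0, got {self.odds_ratio}")


@dataclass(frozen=True)
class SimConfig:
    n_cases: int = 232
    n_controls: int = 448
    pool: HaplotypeBlockPool | None = None
    ds4_fl_freq: float = 0.18
    hla: HlaEpitopeFreqs = field(default_factory=HlaEpitopeFreqs)
    hla_typed_fraction: float = 0.39
    missing_rate: float = 0.0
    subtype_probs: dict[str, float] | None = None
    effect: EffectSpec | None = None
    seed: int = 0

    def with_effect(self, factor: Factor, odds_ratio: float) -> "SimConfig":
        return replace(self, effect=EffectSpec(factor=factor, odds_ratio=odds_ratio))


def _load_defaults() -> dict:
    ref = resources.files("kirassoc").joinpath("data/default_blocks.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


_DEFAULTS: dict | None = None


def default_config(**overrides) -> SimConfig:
    """The packaged default configuration (control-column calibration)."""
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = _load_defaults()
    d = _DEFAULTS
    pool = HaplotypeBlockPool(
        centromeric=tuple(
            Block(b["name"], frozenset(b["genes"]), b["frequency"])
            for b in d["centromeric_blocks"]
        ),
        telomeric=tuple(
            Block(b["name"], frozenset(b["genes"]), b["frequency"])
            for b in d["telomeric_blocks"]
        ),
    )
    h = d["hla_epitope_allele_frequencies"]
    cfg = SimConfig(
        pool=pool,
        ds4_fl_freq=d["ds4_fl_allele_frequency"],
        hla=HlaEpitopeFreqs(
            c1=h["c1"], b_bw4_i80=h["b_bw4_i80"], b_bw4_t80=h["b_bw4_t80"],
            a3_a11=h["a3_a11"], a_bw4=h["a_bw4"],
        ),
        hla_typed_fraction=d["hla_typed_fraction"],
        subtype_probs=dict(d["subtype_probabilities"]),
    )
    return replace(cfg, **overrides) if overrides else cfg


def config_from_yaml(path) -> SimConfig:
    """Load a SimConfig from a YAML file with the default-file schema.

    Any omitted section falls back to the packaged defaults; scalar keys
    ``n_cases``, ``n_controls``, ``seed``, ``missing_rate`` and an ``effect``
    mapping (``factor``, ``odds_ratio``) are also recognized.
    """
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    cfg = default_config()
    if "centromeric_blocks" in d or "telomeric_blocks" in d:
        base = _load_defaults()
        cen = d.get("centromeric_blocks", base["centromeric_blocks"])
        tel = d.get("telomeric_blocks", base["telomeric_blocks"])
        cfg = replace(cfg, pool=HaplotypeBlockPool(
            centromeric=tuple(Block(b["name"], frozenset(b["genes"]), b["frequency"]) for b in cen),
            telomeric=tuple(Block(b["name"], frozenset(b["genes"]), b["frequency"]) for b in tel),
        ))
    if "hla_epitope_allele_frequencies" in d:
        h = d["hla_epitope_allele_frequencies"]
        cfg = replace(cfg, hla=HlaEpitopeFreqs(**h))
    for key in ("n_cases", "n_controls", "seed", "missing_rate", "hla_typed_fraction"):
        if key in d:
            cfg = replace(cfg, **{key: d[key]})
    if "ds4_fl_allele_frequency" in d:
        cfg = replace(cfg, ds4_fl_freq=d["ds4_fl_allele_frequency"])
    if "subtype_probabilities" in d:
        cfg = replace(cfg, subtype_probs=dict(d["subtype_probabilities"]))
    if d.get("effect"):
        cfg = cfg.with_effect(d["effect"]["factor"], float(d["effect"]["odds_ratio"]))
    return cfg


def _draw_individuals(config: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n individuals from the population model (no group labels yet)."""
    pool = config.pool or default_config().pool
    cen_masks = np.array(
        [[g in b.genes for g in KIR_MARKERS] for b in pool.centromeric], dtype=bool
    )
    tel_masks = np.array(
        [[g in b.genes for g in KIR_MARKERS] for b in pool.telomeric], dtype=bool
    )
    cen_f = np.array([b.frequency for b in pool.centromeric])
    tel_f = np.array([b.frequency for b in pool.telomeric])
    cen_f, tel_f = cen_f / cen_f.sum(), tel_f / tel_f.sum()

    c = rng.choice(len(cen_masks), size=(n, 2), p=cen_f)
    t = rng.choice(len(tel_masks), size=(n, 2), p=tel_f)
    presence = cen_masks[c[:, 0]] | cen_masks[c[:, 1]] | tel_masks[t[:, 0]] | tel_masks[t[:, 1]]
    framework = np.array([g in FRAMEWORK_GENES for g in KIR_MARKERS], dtype=bool)
    presence |= framework

    df = pd.DataFrame(
        {g: pd.array(presence[:, i].astype(int), dtype="Int8") for i, g in enumerate(KIR_MARKERS)}
    )

    # 2DS4 variant category from per-copy fl/del allele draws
    ds4_idx = KIR_MARKERS.index("2DS4")
    copy1 = tel_masks[t[:, 0]][:, ds4_idx]
    copy2 = tel_masks[t[:, 1]][:, ds4_idx]
    fl1 = rng.random(n) < config.ds4_fl_freq
    fl2 = rng.random(n) < config.ds4_fl_freq
    has_fl = (copy1 & fl1) | (copy2 & fl2)
    has_del = (copy1 & ~fl1) | (copy2 & ~fl2)
    variant = np.where(
        ~(copy1 | copy2), "negative",
        np.where(has_fl & has_del, "fl_del", np.where(has_fl, "fl", "del")),
    )
    df["kir2ds4_variant"] = pd.array(variant, dtype="string")

    # HLA epitope genotypes under HWE, with a typed subset per individual
    h = config.hla
    typed = rng.random(n) < config.hla_typed_fraction

    def hwe_flags(freqs: dict[str, float]) -> dict[str, np.ndarray]:
        labels = list(freqs)
        p = np.array([freqs[k] for k in labels])
        rest = 1.0 - p.sum()
        if rest < -_FREQ_TOL:
            raise ConfigurationError("locus allele frequencies sum above 1")
        p = np.append(p, max(rest, 0.0))
        alleles = rng.choice(len(p), size=(n, 2), p=p / p.sum())
        return {
            lab: (alleles == i).any(axis=1) for i, lab in enumerate(labels)
        }

    bflags = hwe_flags({"i80": h.b_bw4_i80, "t80": h.b_bw4_t80})
    aflags = hwe_flags({"a3a11": h.a3_a11, "abw4": h.a_bw4})

    def tri(col: np.ndarray) -> pd.Series:
        s = pd.array(col.astype(int), dtype="Int8")
        return pd.Series(s).where(pd.Series(typed), pd.NA)

    # C locus is biallelic C1/C2: a genotype carries C2 unless C1-homozygous
    calleles = rng.choice(2, size=(n, 2), p=[h.c1, 1 - h.c1])
    df["hla_c1"] = tri((calleles == 0).any(axis=1))
    df["hla_c2"] = tri((calleles == 1).any(axis=1))
    df["hla_bw4_i80"] = tri(bflags["i80"])
    df["hla_bw4_t80"] = tri(bflags["t80"])
    df["hla_a3a11"] = tri(aflags["a3a11"])
    df["hla_a_bw4"] = tri(aflags["abw4"])

    if config.missing_rate > 0:
        non_framework = [g for g in KIR_MARKERS if g not in FRAMEWORK_GENES]
        drop = rng.random((n, len(non_framework))) < config.missing_rate
        for j, g in enumerate(non_framework):
            col = df[g].copy()
            col[drop[:, j]] = pd.NA
            df[g] = col
        var = df["kir2ds4_variant"].copy()
        var[rng.random(n) < config.missing_rate] = pd.NA
        df["kir2ds4_variant"] = var
    return df


def sample_cohort(config: SimConfig) -> pd.DataFrame:
    """Sample a case-control cohort; fixed seed gives identical output.

    Without an effect, individuals are exchangeable and the first
    ``n_cases`` draws are labelled cases.  With an effect, case status is a
    Bernoulli whose log-odds shift on the target factor equals ln(OR), with
    the intercept solved so the expected case fraction matches the configured
    group sizes; draws continue in batches until both groups are filled.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_cases + config.n_controls
    if config.effect is None:
        df = _draw_individuals(config, n_total, rng)
        group = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    else:
        beta = float(np.log(config.effect.odds_ratio))
        target = config.n_cases / n_total
        cases, controls = [], []
        max_batches = 60
        for _ in range(max_batches):
            batch = _draw_individuals(config, n_total, rng)
            target_df = batch
            if isinstance(config.effect.factor, str) and config.effect.factor not in batch.columns:
                from .cohort import classify_cohort  # derived factors (e.g. CxTx)

                target_df = classify_cohort(batch, validate=False)
            x = evaluate_factor(target_df, config.effect.factor).fillna(False).to_numpy(dtype=bool)

            def prevalence(alpha: float) -> float:
                return float(np.mean(expit(alpha + beta * x))) - target

            lo, hi = -30.0, 30.0
            alpha = brentq(prevalence, lo, hi) if prevalence(lo) * prevalence(hi) < 0 else 0.0
            is_case = rng.random(len(batch)) < expit(alpha + beta * x)
            cases.append(batch[is_case])
            controls.append(batch[~is_case])
            if (sum(len(b) for b in cases) >= config.n_cases
                    and sum(len(b) for b in controls) >= config.n_controls):
                break
        else:
            raise ConfigurationError(
                "could not fill case/control groups; infeasible effect configuration"
            )
        df = pd.concat(
            [pd.concat(cases).head(config.n_cases), pd.concat(controls).head(config.n_controls)],
            ignore_index=True,
        )
        group = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)

    df.insert(0, "sample_id", [f"S{i + 1:05d}" for i in range(len(df))])
    df.insert(1, "group", group)
    subtype = pd.array([pd.NA] * len(df), dtype="string")
    if config.subtype_probs:
        labels = list(config.subtype_probs)
        p = np.array([config.subtype_probs[k] for k in labels], dtype=float)
        draws = rng.choice(len(labels), size=len(df), p=p / p.sum())
        is_case = group == "case"
        subtype[is_case] = np.array(labels)[draws[is_case]]
    df.insert(2, "subtype", subtype)
    return df.reset_index(drop=True)


def recover_effect(
    config: SimConfig,
    odds_ratio: float,
    factor: Factor,
    n_replicates: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Monte-Carlo check that the pipeline recovers a configured effect.

    Simulates ``n_replicates`` cohorts with the effect injected, runs the
    carrier association on each, and summarizes the log-OR estimates, 95% CI
    coverage of the true value and the rejection rate at ``alpha``.
    """
    from .stats import carrier_association

    rng = np.random.default_rng(seed)
    log_ors, covered, rejected = [], 0, 0
    base = config.with_effect(factor, odds_ratio) if odds_ratio != 1.0 else replace(
        config, effect=None
    )
    for _ in range(n_replicates):
        rep_cfg = replace(base, seed=int(rng.integers(0, 2**31 - 1)))
        cohort = sample_cohort(rep_cfg)
        if isinstance(factor, str) and factor not in cohort.columns:
            from .cohort import classify_cohort

            cohort = classify_cohort(cohort, validate=False)
        res = carrier_association(cohort, factor)
        log_ors.append(np.log(res.odds_ratio))
        if res.ci_low <= odds_ratio <= res.ci_high:
            covered += 1
        if res.p_value < alpha:
            rejected += 1
    mean_log = float(np.mean(log_ors))
    return {
        "n_replicates": n_replicates,
        "true_odds_ratio": odds_ratio,
        "mean_log_or": mean_log,
        "geometric_mean_or": float(np.exp(mean_log)),
        "ci_coverage": covered / n_replicates,
        "rejection_rate": rejected / n_replicates,
    }
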