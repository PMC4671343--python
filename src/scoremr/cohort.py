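"""Synthetic elderly-cohort generator with a known causal structure.

Emulates an individual-level cohort of the kind the observational arm
of a homocysteine–diabetes analysis is run on: ~1,000 subjects aged
around 70, five biallelic SNPs in Hardy–Weinberg equilibrium at the
published effect-allele frequencies, an SD-standardized ln-scale
exposure driven by the SNP panel, two continuous glycemic outcomes
(fasting glucose and ln fasting insulin) and a binary type 2 diabetes
outcome with a configurable baseline prevalence.

The structural model, per individual, is::

    g_j        ~ Binomial(2, eaf_j)                      (independent SNPs, HWE)
    C          ~ Normal(0, 1)                            (shared confounder)
    L_glu      =  gamma_y * C + eps_glu                  (glucose liability)
    X_raw      =  sum_j beta_j g_j + gamma_x * C
                  + rev * L_glu + eps_x
    X          =  (X_raw - mean) / sd                    (within-sample SD units)
    glucose    =  theta * X + L_glu
    ln_insulin =  theta * X + gamma_y * C + eps_ins
    t2d        ~ Bernoulli(expit(alpha + theta * X + gamma_y * C))

with unit-variance outcome residuals, ``alpha = logit(baseline
prevalence)`` (hit exactly at covariate means; the marginal prevalence
differs slightly through the logistic nonlinearity), and the residual
variance of ``X_raw`` chosen so its theoretical variance is 1.  The
reverse-causation path ``rev`` feeds the *glucose* liability back into
the exposure; it is not modelled for the binary trait.

Randomness comes from a single ``numpy.random.default_rng(seed)``; the
sub-streams are drawn in a fixed order (genotypes SNP by SNP, then
confounder, glucose residual, insulin residual, exposure residual, T2D
uniforms, age jitter, sex permutation) so reconfiguring one component
does not reshuffle the upstream ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy.special import expit, logit

from .summary_data import LINEAR, LNOR, SD, SnpAssociation

log = logging.getLogger(__name__)

#: the five published homocysteine SNPs (rsid, gene, effect allele, EAF, beta on lnHcy in SD units)
DEFAULT_PANEL = (
    ("rs12134663", "MTHFR", "C", 0.20, 0.10),
    ("rs1801133", "MTHFR", "A", 0.34, 0.16),
    ("rs2275565", "MTR", "G", 0.79, 0.05),
    ("rs234709", "CBS", "C", 0.55, 0.07),
    ("rs2851391", "CBS", "T", 0.47, 0.06),
)

CONTINUOUS_TRAITS = ("glucose", "ln_insulin")
BINARY_TRAIT = "t2d"
_META_COLUMNS = ("exposure", "confounder", "age", "sex")


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


class SmallSampleError(ValueError):
    """Too few cases to fit a per-SNP logistic regression."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: n = 1,016 subjects, the
    five published SNPs at their published frequencies and ln-exposure
    effects, 12% baseline diabetes prevalence, and no causal,
    confounding or reverse-causation paths.
    """

    n: int = 1016
    eafs: tuple[float, ...] = tuple(r[3] for r in DEFAULT_PANEL)
    snp_effects: tuple[float, ...] = tuple(r[4] for r in DEFAULT_PANEL)
    rsids: tuple[str, ...] = tuple(r[0] for r in DEFAULT_PANEL)
    genes: tuple[str, ...] = tuple(r[1] for r in DEFAULT_PANEL)
    effect_alleles: tuple[str, ...] = tuple(r[2] for r in DEFAULT_PANEL)
    causal_effect: float = 0.0
    confounder_effect: tuple[float, float] = (0.0, 0.0)
    reverse_effect: float = 0.0
    t2d_baseline_prev: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        self.eafs = tuple(float(v) for v in self.eafs)
        self.snp_effects = tuple(float(v) for v in self.snp_effects)
        self.rsids = tuple(self.rsids)
        self.genes = tuple(self.genes)
        self.effect_alleles = tuple(self.effect_alleles)
        self.confounder_effect = tuple(float(v) for v in self.confounder_effect)
        m = len(self.eafs)
        for name in ("snp_effects", "rsids", "genes", "effect_alleles"):
            if len(getattr(self, name)) != m:
                raise ConfigError(
                    f"{name} has length {len(getattr(self, name))}, expected {m} (as eafs)"
                )
        if len(self.confounder_effect) != 2:
            raise ConfigError("confounder_effect must be a (gamma_x, gamma_y) pair")
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if any(not (0 < f < 1) for f in self.eafs):
            raise ConfigError("all eafs must lie in (0, 1)")
        if not (0 < self.t2d_baseline_prev < 1):
            raise ConfigError("t2d_baseline_prev must lie in (0, 1)")
        if self.exposure_residual_variance() <= 0:
            raise ConfigError(
                "variance budget exceeded: genetic + confounder + reverse-causation "
                f"variance is {1 - self.exposure_residual_variance():.3f} >= 1, "
                "leaving no room for exposure noise"
            )

    def genetic_variance(self) -> float:
        """Variance of ln-exposure explained by the SNP panel (pre-standardization)."""
        return float(
            sum(b * b * 2 * f * (1 - f) for b, f in zip(self.snp_effects, self.eafs))
        )

    def exposure_residual_variance(self) -> float:
        """Residual variance giving the raw exposure unit theoretical variance."""
        gx, gy = self.confounder_effect
        rev = self.reverse_effect
        var_liability = gy * gy + 1.0
        explained = (
            self.genetic_variance()
            + gx * gx
            + rev * rev * var_liability
            + 2.0 * gx * rev * gy
        )
        return 1.0 - explained

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("eafs", "snp_effects", "rsids", "genes", "effect_alleles",
                    "confounder_effect"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Individual-level data for one simulated cohort."""

    rsids: list[str]
    genes: list[str]
    effect_alleles: list[str]
    genotypes: np.ndarray          # n x m effect-allele counts in {0, 1, 2}
    exposure: np.ndarray           # n, within-sample SD units
    outcomes: dict[str, np.ndarray]
    confounder: np.ndarray
    age: np.ndarray
    sex: np.ndarray                # 0/1, balanced

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def trait(self, name: str) -> np.ndarray:
        if name == "exposure":
            return self.exposure
        if name in self.outcomes:
            return self.outcomes[name]
        raise KeyError(f"unknown trait {name!r}")

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {
            r: self.genotypes[:, j] for j, r in enumerate(self.rsids)
        }
        cols["exposure"] = self.exposure
        cols["confounder"] = self.confounder
        cols["age"] = self.age
        cols["sex"] = self.sex
        for name, vals in self.outcomes.items():
            cols[name] = vals
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        """One row per individual; genotype columns first, then
        exposure/confounder/age/sex, then outcomes."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path, *, genes: list[str] | None = None,
        effect_alleles: list[str] | None = None,
    ) -> "SyntheticCohort":
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns)
        if "exposure" not in cols:
            raise ValueError(f"{path}: no 'exposure' column")
        split = cols.index("exposure")
        rsids = cols[:split]
        outcome_cols = [c for c in cols[split:] if c not in _META_COLUMNS]
        m = len(rsids)
        return cls(
            rsids=rsids,
            genes=list(genes) if genes is not None else ["?"] * m,
            effect_alleles=list(effect_alleles) if effect_alleles is not None else ["other"] * m,
            genotypes=df[rsids].to_numpy(dtype=np.int8),
            exposure=df["exposure"].to_numpy(dtype=float),
            outcomes={c: df[c].to_numpy(dtype=float) for c in outcome_cols},
            confounder=df["confounder"].to_numpy(dtype=float),
            age=df["age"].to_numpy(dtype=float),
            sex=df["sex"].to_numpy(dtype=int),
        )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort from the structural model (see module docstring).

    Deterministic given ``config.seed``: the same configuration and seed
    always yield a bit-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n, len(config.eafs)
    theta = config.causal_effect
    gx, gy = config.confounder_effect
    rev = config.reverse_effect

    genotypes = np.empty((n, m), dtype=np.int8)
    for j, f in enumerate(config.eafs):  # fixed order: one stream per SNP
        genotypes[:, j] = rng.binomial(2, f, size=n)

    confounder = rng.standard_normal(n)
    eps_glu = rng.standard_normal(n)
    eps_ins = rng.standard_normal(n)
    sd_x = math.sqrt(config.exposure_residual_variance())
    eps_x = rng.standard_normal(n) * sd_x

    liability_glu = gy * confounder + eps_glu
    x_raw = (
        genotypes @ np.asarray(config.snp_effects)
        + gx * confounder
        + rev * liability_glu
        + eps_x
    )
    exposure = (x_raw - x_raw.mean()) / x_raw.std()

    glucose = theta * exposure + liability_glu
    ln_insulin = theta * exposure + gy * confounder + eps_ins
    alpha = logit(config.t2d_baseline_prev)
    p_t2d = expit(alpha + theta * exposure + gy * confounder)
    t2d = (rng.uniform(size=n) < p_t2d).astype(np.int8)

    age = 70.0 + rng.uniform(-0.2, 0.4, size=n).round(1)
    sex = np.zeros(n, dtype=np.int8)
    sex[: n // 2] = 1
    sex = sex[rng.permutation(n)]

    return SyntheticCohort(
        rsids=list(config.rsids),
        genes=list(config.genes),
        effect_alleles=list(config.effect_alleles),
        genotypes=genotypes,
        exposure=exposure,
        outcomes={"glucose": glucose, "ln_insulin": ln_insulin, "t2d": t2d},
        confounder=confounder,
        age=age,
        sex=sex,
    )


def _is_binary(values: np.ndarray) -> bool:
    return set(np.unique(values)).issubset({0.0, 1.0})


def _clip_p(p: float) -> float:
    if not np.isfinite(p) or p <= 0.0:
        return 1e-320
    return min(float(p), 1.0)


def gwas_summarize(
    cohort: SyntheticCohort, trait: str, *, adjust: bool = False
) -> list[SnpAssociation]:
    """Per-SNP association scan of one trait, GWAS-style.

    Continuous traits are regressed on the allele count by ordinary
    least squares (optionally age/sex-adjusted); binary traits by
    logistic regression, returning lnOR and its SE.  Monomorphic SNPs
    cannot be tested and are excluded with a warning.
    """
    y = np.asarray(cohort.trait(trait), dtype=float)
    binary = _is_binary(y)
    if binary and int(y.sum()) < 10:
        raise SmallSampleError(
            f"binary trait {trait!r} has {int(y.sum())} cases; need >= 10"
        )
    if trait == "exposure":
        scale = SD
    elif binary:
        scale = LNOR
    else:
        scale = LINEAR

    covars = [cohort.age, cohort.sex] if adjust else []
    records: list[SnpAssociation] = []
    for j, rsid in enumerate(cohort.rsids):
        g = cohort.genotypes[:, j].astype(float)
        if g.min() == g.max():
            log.warning("%s: monomorphic in this cohort, excluded from the scan", rsid)
            continue
        design = sm.add_constant(np.column_stack([g] + covars))
        if binary:
            res = sm.Logit(y, design).fit(disp=0)
        else:
            res = sm.OLS(y, design).fit()
        eaf = float(g.mean() / 2.0)
        records.append(
            SnpAssociation(
                rsid=rsid,
                gene=cohort.genes[j],
                effect_allele=cohort.effect_alleles[j],
                eaf=min(max(eaf, 1e-12), 1 - 1e-12),
                beta=float(res.params[1]),
                se=float(res.bse[1]),
                p=_clip_p(res.pvalues[1]),
                scale=scale,
            )
        )
    return records


@dataclass(frozen=True)
class ObservationalEstimate:
    """Age/sex-adjusted regression of a trait on the measured exposure."""

    beta: float            # lnOR for binary traits
    se: float
    p: float
    scale: str
    or_: float | None = None  # per SD of exposure, binary traits only


def observational_estimates(
    cohort: SyntheticCohort, trait: str, *, adjust: bool = True
) -> ObservationalEstimate:
    """Conventional observational estimate of exposure on one outcome.

    Continuous traits: linear regression of trait on exposure (+ age and
    sex by default).  Binary traits: logistic regression, reported as an
    odds ratio per SD-unit of the exposure.
    """
    y = np.asarray(cohort.trait(trait), dtype=float)
    binary = _is_binary(y)
    if binary and y.sum() == 0:
        raise SmallSampleError(f"binary trait {trait!r} has no cases")
    covars = [cohort.age, cohort.sex] if adjust else []
    design = sm.add_constant(np.column_stack([cohort.exposure] + covars))
    if binary:
        res = sm.Logit(y, design).fit(disp=0)
        beta = float(res.params[1])
        return ObservationalEstimate(
            beta=beta,
            se=float(res.bse[1]),
            p=_clip_p(res.pvalues[1]),
            scale=LNOR,
            or_=math.exp(beta),
        )
    res = sm.OLS(y, design).fit()
    return ObservationalEstimate(
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        p=_clip_p(res.pvalues[1]),
        scale=LINEAR,
    )
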