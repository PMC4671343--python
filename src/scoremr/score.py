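"""Unweighted genetic-score effects from per-SNP summary statistics.

The per-allele effect of an unweighted allele-count score on a trait is
recovered from per-SNP summary statistics as the inverse-variance
weighted mean

    beta_score = sum(beta_i / se_i^2) / sum(1 / se_i^2),
    se_score   = sqrt(1 / sum(1 / se_i^2)),

valid when the SNPs are mutually independent (no LD).  Because a SNP's
summary se is inversely proportional to the SD of its allele count,
these weights coincide with the variance weights implicit in regressing
the trait directly on the allele-count sum, so the formula is the
fixed-weight, summary-level equivalent of that individual-level
regression.

Instrument strength is summarized by F = z^2 = (beta/se)^2; F > 10 is
the usual rule of thumb for a usable instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .summary_data import LINEAR, LNOR, SnpAssociation

#: normal quantile used verbatim for 95% confidence intervals
Z95 = 1.96


class ScaleError(ValueError):
    """An operation was applied to a trait on the wrong scale."""


def _z_p(beta: float, se: float) -> tuple[float, float]:
    """z statistic and two-sided normal p, robust to extreme z.

    ``scipy.stats.norm.sf`` is used directly down to its underflow
    limit; below that the log-survival function is exponentiated, so p
    only reports 0 below roughly 1e-300.
    """
    if se < 0:
        raise ValueError(f"se must be >= 0 (got {se})")
    if se == 0:
        if beta == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, beta), 0.0
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    if p == 0.0:
        p = 2.0 * math.exp(stats.norm.logsf(abs(z)))
    return z, min(p, 1.0)


@dataclass(frozen=True)
class ScoreEffect:
    """Combined per-allele effect of the unweighted score on a trait."""

    beta: float
    se: float
    z: float
    p: float
    f_stat: float
    n_snps: int
    scale: str = LINEAR

    @classmethod
    def from_beta_se(
        cls, beta: float, se: float, *, n_snps: int = 1, scale: str = LINEAR
    ) -> "ScoreEffect":
        z, p = _z_p(beta, se)
        return cls(beta=beta, se=se, z=z, p=p, f_stat=z * z, n_snps=n_snps, scale=scale)


@dataclass(frozen=True)
class OddsRatioView:
    """Exponentiated view of a lnOR-scale effect with its 95% CI."""

    or_: float
    ci_low: float
    ci_high: float


def combine_score(assocs: list[SnpAssociation]) -> ScoreEffect:
    """Inverse-variance combination of per-SNP effects into the score effect.

    All records must share a trait scale; SNPs are assumed independent.
    """
    if not assocs:
        raise ValueError("combine_score requires at least one SNP")
    scales = {a.scale for a in assocs}
    if len(scales) > 1:
        raise ScaleError(f"mixed trait scales in score combination: {sorted(scales)}")
    sum_w = 0.0
    sum_bw = 0.0
    for a in assocs:
        if a.se <= 0:
            raise ValueError(f"{a.rsid}: se must be > 0")
        w = 1.0 / (a.se * a.se)
        sum_w += w
        sum_bw += a.beta * w
    beta = sum_bw / sum_w
    se = math.sqrt(1.0 / sum_w)
    return ScoreEffect.from_beta_se(beta, se, n_snps=len(assocs), scale=assocs[0].scale)


def score_odds_ratio(effect: ScoreEffect) -> OddsRatioView:
    """Per-allele odds ratio and 95% CI for a lnOR-scale score effect."""
    if effect.scale != LNOR:
        raise ScaleError(
            f"odds-ratio view requires a lnOR-scale effect (got {effect.scale!r})"
        )
    return OddsRatioView(
        or_=math.exp(effect.beta),
        ci_low=math.exp(effect.beta - Z95 * effect.se),
        ci_high=math.exp(effect.beta + Z95 * effect.se),
    )
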