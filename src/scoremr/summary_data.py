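"""GWAS summary-statistic records, TSV I/O, and allele harmonization.

Two-sample Mendelian randomization starts from per-variant association
tables: for each SNP, an effect allele, a per-allele effect estimate
(beta), its standard error and ideally the effect-allele frequency and
p-value, reported once against the exposure and once against each
outcome.  Before any combining, the exposure and outcome tables must be
*harmonized* — re-expressed with respect to the same allele at every
SNP.  The convention used throughout this package is the
exposure-increasing allele: after :func:`harmonize`, every exposure beta
is non-negative and every outcome record refers to the same allele as
the matching exposure record.

The TSV dialect is ``rsid  gene  effect_allele  eaf  beta  se  p``,
tab-separated, header mandatory, ``.`` (or empty) for absent optional
values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: The allele on the unreported side of a flipped record.  Source tables
#: here carry only the effect allele, so a flip cannot name the new one.
OTHER_ALLELE = "other"

# trait-scale tags
LINEAR = "linear"  # additive effect on the measured (or ln-measured) scale
LNOR = "lnor"      # natural-log odds ratio (binary traits)
SD = "sd"          # standard-deviation units (the standardized exposure)

SCALES = (LINEAR, LNOR, SD)

_REQUIRED_COLUMNS = ("rsid", "effect_allele", "beta", "se")
_ALL_COLUMNS = ("rsid", "gene", "effect_allele", "eaf", "beta", "se", "p")


class SummaryFormatError(ValueError):
    """A summary-statistic table violates the expected TSV dialect."""


class HarmonizationError(ValueError):
    """Exposure and outcome records cannot be aligned to a shared allele."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait,
    on the scale named by ``scale`` (``"sd"`` for the SD-standardized
    ln-exposure, ``"lnor"`` for binary outcomes, ``"linear"`` otherwise).
    """

    rsid: str
    effect_allele: str
    beta: float
    se: float
    gene: str | None = None
    eaf: float | None = None
    p: float | None = None
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.effect_allele not in VALID_BASES and self.effect_allele != OTHER_ALLELE:
            raise ValueError(
                f"{self.rsid}: effect_allele must be one of A/C/G/T "
                f"(got {self.effect_allele!r})"
            )
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: beta must be finite")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"{self.rsid}: se must be > 0 (got {self.se})")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.rsid}: eaf must lie in (0, 1) (got {self.eaf})")
        if self.p is not None and not (0 < self.p <= 1):
            raise ValueError(f"{self.rsid}: p must lie in (0, 1] (got {self.p})")
        if self.scale not in SCALES:
            raise ValueError(f"{self.rsid}: unknown scale {self.scale!r}")

    def flipped(self, new_allele: str | None = None) -> "SnpAssociation":
        """Re-express the record with respect to the other allele.

        Negates beta and complements the allele frequency.  The new
        effect allele is ``new_allele`` when the caller knows it (e.g.
        when aligning an outcome to a known exposure allele) and
        ``"other"`` otherwise, since the source tables do not report the
        non-effect allele.
        """
        return replace(
            self,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            effect_allele=new_allele if new_allele is not None else OTHER_ALLELE,
        )


@dataclass
class InstrumentSet:
    """Harmonized exposure and outcome associations across a SNP panel.

    All records are aligned to the exposure-increasing allele: every
    exposure beta is >= 0 and, for each SNP, the outcome records refer
    to the same allele as the exposure record.
    """

    snps: list[str]
    exposure: dict[str, SnpAssociation]
    outcomes: dict[str, dict[str, SnpAssociation]]
    exposure_name: str = "exposure"
    scales: dict[str, str] = field(default_factory=dict)
    #: harmonization provenance: one human-readable line per flip/drop
    actions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.snps)) != len(self.snps):
            raise ValueError("duplicate rsids in instrument set")
        for rsid in self.snps:
            if rsid not in self.exposure:
                raise ValueError(f"{rsid} missing from exposure records")
            if self.exposure[rsid].beta < 0:
                raise ValueError(f"{rsid}: exposure beta negative after harmonization")
            for name, table in self.outcomes.items():
                if rsid not in table:
                    raise ValueError(f"{rsid} missing from outcome {name!r}")

    def exposure_assocs(self) -> list[SnpAssociation]:
        return [self.exposure[r] for r in self.snps]

    def outcome_assocs(self, name: str) -> list[SnpAssociation]:
        return [self.outcomes[name][r] for r in self.snps]


def _check_duplicates(assocs: list[SnpAssociation], label: str) -> None:
    seen: set[str] = set()
    for a in assocs:
        if a.rsid in seen:
            raise SummaryFormatError(f"duplicated rsid {a.rsid} in {label} table")
        seen.add(a.rsid)


def _align_outcome(
    exp: SnpAssociation, exp_h: SnpAssociation, out: SnpAssociation, actions: list[str]
) -> SnpAssociation:
    """Align one outcome record to the harmonized exposure allele.

    ``exp`` is the exposure record as reported, ``exp_h`` after any sign
    flip.  With only effect alleles on record, an outcome allele that
    differs from the exposure's reported allele is taken to be the other
    allele of the biallelic SNP; when it equals the strand complement
    this is ambiguous (strand flip vs allele swap) and is resolved by
    allele identity with a warning.
    """
    target = exp_h.effect_allele
    if out.effect_allele == target:
        return out
    if target == OTHER_ALLELE:
        # exposure was sign-flipped; its harmonized allele is the one
        # NOT reported in the exposure table
        if out.effect_allele == exp.effect_allele:
            actions.append(f"{out.rsid}: outcome flipped to the exposure-increasing allele")
            return out.flipped()
        if out.effect_allele == OTHER_ALLELE:
            return out
        if out.effect_allele == _COMPLEMENT.get(exp.effect_allele):
            log.warning(
                "%s: outcome allele %s is the strand complement of the exposure "
                "allele %s; treating it as the other allele (forward strand assumed)",
                out.rsid, out.effect_allele, exp.effect_allele,
            )
        return out
    if out.effect_allele == OTHER_ALLELE:
        raise HarmonizationError(
            f"{out.rsid}: outcome allele is unspecified and cannot be matched "
            f"to exposure allele {target}"
        )
    if out.effect_allele == _COMPLEMENT.get(target):
        log.warning(
            "%s: outcome allele %s is the strand complement of the exposure "
            "allele %s; treating it as the other allele (forward strand assumed)",
            out.rsid, out.effect_allele, target,
        )
    actions.append(f"{out.rsid}: outcome flipped from {out.effect_allele} to {target}")
    return out.flipped(new_allele=target)


def harmonize(
    exposure: list[SnpAssociation],
    outcome: list[SnpAssociation],
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> InstrumentSet:
    """Align exposure and outcome tables to the exposure-increasing allele.

    Takes the intersection of rsids (ordered as in the exposure list),
    flips any exposure record with a negative beta, and flips each
    outcome record whose effect allele disagrees with the harmonized
    exposure allele.  SNPs present in only one table are dropped with a
    logged warning.
    """
    _check_duplicates(exposure, exposure_name)
    _check_duplicates(outcome, outcome_name)
    out_by = {a.rsid: a for a in outcome}
    shared = [a for a in exposure if a.rsid in out_by]
    if not shared:
        raise HarmonizationError(
            f"no shared rsids between {exposure_name} and {outcome_name}"
        )

    actions: list[str] = []
    for a in exposure:
        if a.rsid not in out_by:
            log.warning("%s: absent from %s table, dropped", a.rsid, outcome_name)
            actions.append(f"{a.rsid}: dropped (absent from {outcome_name})")
    exp_rsids = {a.rsid for a in exposure}
    for a in outcome:
        if a.rsid not in exp_rsids:
            log.warning("%s: absent from %s table, dropped", a.rsid, exposure_name)
            actions.append(f"{a.rsid}: dropped (absent from {exposure_name})")

    exp_h: dict[str, SnpAssociation] = {}
    out_h: dict[str, SnpAssociation] = {}
    for exp in shared:
        if exp.beta < 0:
            actions.append(
                f"{exp.rsid}: exposure flipped to the exposure-increasing allele"
            )
            e = exp.flipped()
        else:
            e = exp
        exp_h[exp.rsid] = e
        out_h[exp.rsid] = _align_outcome(exp, e, out_by[exp.rsid], actions)

    return InstrumentSet(
        snps=[a.rsid for a in shared],
        exposure=exp_h,
        outcomes={outcome_name: out_h},
        exposure_name=exposure_name,
        scales={outcome_name: next(iter(out_h.values())).scale},
        actions=actions,
    )


def harmonize_exposure(
    exposure: list[SnpAssociation],
) -> tuple[list[SnpAssociation], list[str]]:
    """Flip exposure records so every beta is non-negative."""
    _check_duplicates(exposure, "exposure")
    actions: list[str] = []
    out: list[SnpAssociation] = []
    for a in exposure:
        if a.beta < 0:
            actions.append(f"{a.rsid}: exposure flipped to the exposure-increasing allele")
            out.append(a.flipped())
        else:
            out.append(a)
    return out, actions


def _parse_float(value, column: str, row: int, path) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "."):
        return None
    try:
        return float(s)
    except ValueError:
        raise SummaryFormatError(
            f"{path}: non-numeric {column} {s!r} on data row {row}"
        ) from None


def read_summary_table(
    path, scale: str = LINEAR, *, odds_ratio: bool = False
) -> list[SnpAssociation]:
    """Read a tab-separated summary-statistic table.

    Parameters
    ----------
    path
        TSV file with a header naming at least ``rsid``,
        ``effect_allele``, ``beta`` and ``se``; ``gene``, ``eaf`` and
        ``p`` are optional.  Row order is preserved.
    scale
        Trait-scale tag attached to every record.
    odds_ratio
        If true, the ``beta`` column holds odds ratios and is converted
        to the lnOR scale via the natural log at load time (the ``se``
        column must already be on the log scale).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SummaryFormatError(f"{path}: missing mandatory column {col!r}")

    records: list[SnpAssociation] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rowd = dict(zip(df.columns, row))
        rsid = str(rowd["rsid"]).strip()
        if rsid in seen:
            raise SummaryFormatError(f"{path}: duplicated rsid {rsid} (row {i})")
        seen.add(rsid)
        beta = _parse_float(rowd["beta"], "beta", i, path)
        se = _parse_float(rowd["se"], "se", i, path)
        if beta is None or se is None:
            raise SummaryFormatError(f"{path}: beta/se missing on data row {i}")
        if odds_ratio:
            if beta <= 0:
                raise SummaryFormatError(
                    f"{path}: odds ratio must be positive on data row {i}"
                )
            beta = math.log(beta)
        gene = rowd.get("gene")
        gene = None if gene is None or str(gene).strip() in ("", ".") else str(gene).strip()
        try:
            records.append(
                SnpAssociation(
                    rsid=rsid,
                    effect_allele=str(rowd["effect_allele"]).strip(),
                    beta=beta,
                    se=se,
                    gene=gene,
                    eaf=_parse_float(rowd.get("eaf"), "eaf", i, path),
                    p=_parse_float(rowd.get("p"), "p", i, path),
                    scale=LNOR if odds_ratio else scale,
                )
            )
        except ValueError as exc:
            raise SummaryFormatError(f"{path}: row {i}: {exc}") from exc
    return records


def _fmt(value) -> str:
    return "." if value is None else repr(float(value))


def write_summary_table(assocs: list[SnpAssociation], path) -> None:
    """Write records in the summary-statistic TSV dialect, full precision."""
    path = Path(path)
    lines = ["\t".join(_ALL_COLUMNS)]
    for a in assocs:
        lines.append(
            "\t".join(
                [
                    a.rsid,
                    a.gene if a.gene is not None else ".",
                    a.effect_allele,
                    _fmt(a.eaf),
                    _fmt(a.beta),
                    _fmt(a.se),
                    _fmt(a.p),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
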