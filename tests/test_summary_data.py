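"""Summary-table I/O and allele-harmonization behaviour."""

import dataclasses
import logging
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from scoremr.summary_data import (
    LINEAR,
    LNOR,
    SD,
    HarmonizationError,
    SnpAssociation,
    SummaryFormatError,
    harmonize,
    read_summary_table,
    write_summary_table,
)


def test_read_exposure_fixture(hcy_assocs):
    assert len(hcy_assocs) == 5
    assert [a.rsid for a in hcy_assocs] == [
        "rs12134663", "rs1801133", "rs2275565", "rs234709", "rs2851391",
    ]
    a = hcy_assocs[1]
    assert (a.rsid, a.effect_allele, a.gene) == ("rs1801133", "A", "MTHFR")
    assert a.beta == 0.16 and a.se == 0.01 and a.eaf == 0.34
    assert a.p == pytest.approx(4.3e-104)
    assert all(a.scale == SD for a in hcy_assocs)


def test_read_header_only_gives_empty_list(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("rsid\tgene\teffect_allele\teaf\tbeta\tse\tp\n")
    assert read_summary_table(path) == []


def test_missing_eaf_and_gene_are_carried_as_absent(tmp_path):
    path = tmp_path / "sparse.tsv"
    path.write_text("rsid\teffect_allele\tbeta\tse\nrs1\tA\t0.1\t0.01\n")
    (rec,) = read_summary_table(path)
    assert rec.eaf is None and rec.gene is None and rec.p is None


@pytest.mark.parametrize(
    "body, message",
    [
        ("rsid\teffect_allele\tbeta\nrs1\tA\t0.1\n", "se"),  # missing column
        ("rsid\teffect_allele\tbeta\tse\nrs1\tA\tx\t0.01\n", "row 2"),
        ("rsid\teffect_allele\tbeta\tse\nrs1\tA\t0.1\t0.01\nrs1\tA\t0.2\t0.01\n",
         "rs1"),  # duplicate rsid
        ("rsid\teffect_allele\tbeta\tse\nrs1\tA\t0.1\t-0.01\n", "se"),
    ],
)
def test_malformed_tables_raise_naming_the_problem(tmp_path, body, message):
    path = tmp_path / "bad.tsv"
    path.write_text(body)
    with pytest.raises(SummaryFormatError, match=message):
        read_summary_table(path)


def test_odds_ratio_inputs_are_log_converted(tmp_path):
    path = tmp_path / "or.tsv"
    path.write_text("rsid\teffect_allele\tbeta\tse\nrs1\tA\t1.05\t0.02\n")
    (rec,) = read_summary_table(path, odds_ratio=True)
    assert rec.beta == pytest.approx(math.log(1.05))
    assert rec.scale == LNOR


def test_roundtrip_preserves_full_precision(tmp_path, hcy_assocs):
    extra = SnpAssociation(
        rsid="rs999", effect_allele="T", beta=0.1234567890123, se=1 / 3,
        eaf=0.123456789, p=2.5e-201, scale=SD,
    )
    records = list(hcy_assocs) + [extra]
    path = tmp_path / "rt.tsv"
    write_summary_table(records, path)
    back = read_summary_table(path, scale=SD)
    assert back == records


def test_harmonize_already_aligned_is_identity(hcy_assocs, t2d_assocs):
    iset = harmonize(hcy_assocs, t2d_assocs, outcome_name="t2d")
    assert iset.snps == [a.rsid for a in hcy_assocs]
    assert iset.exposure_assocs() == list(hcy_assocs)
    assert iset.outcome_assocs("t2d") == list(t2d_assocs)
    assert iset.actions == []
    assert iset.scales["t2d"] == LNOR


def test_harmonize_flips_negative_exposure_snp(hcy_assocs, t2d_assocs):
    # rs1801133 re-reported for the other allele (G): beta -0.16, eaf 0.66
    recoded = [
        dataclasses.replace(a, effect_allele="G", beta=-0.16, eaf=0.66)
        if a.rsid == "rs1801133" else a
        for a in hcy_assocs
    ]
    iset = harmonize(recoded, t2d_assocs, outcome_name="t2d")
    rec = iset.exposure["rs1801133"]
    assert rec.beta == pytest.approx(0.16)
    assert rec.eaf == pytest.approx(0.34)
    assert rec.effect_allele == "other"  # the non-reported allele
    # the outcome record already refers to the exposure-increasing allele (A != G)
    assert iset.outcomes["t2d"]["rs1801133"] == t2d_assocs[1]


def test_harmonize_flips_misaligned_outcome(hcy_assocs, t2d_assocs):
    recoded = [
        dataclasses.replace(a, effect_allele="G", beta=-a.beta, eaf=1 - a.eaf)
        if a.rsid == "rs1801133" else a
        for a in t2d_assocs
    ]
    iset = harmonize(hcy_assocs, recoded, outcome_name="t2d")
    out = iset.outcomes["t2d"]["rs1801133"]
    assert out.beta == pytest.approx(0.02)
    assert out.eaf == pytest.approx(0.34)
    assert out.effect_allele == "A"
    assert any("rs1801133" in a and "flipped" in a for a in iset.actions)


def test_harmonize_drops_missing_snps_with_warning(hcy_assocs, t2d_assocs, caplog):
    trimmed = [a for a in t2d_assocs if a.rsid != "rs234709"]
    with caplog.at_level(logging.WARNING):
        iset = harmonize(hcy_assocs, trimmed, outcome_name="t2d")
    assert len(iset.snps) == 4
    assert "rs234709" not in iset.snps
    assert any("rs234709" in r.message for r in caplog.records)
    assert any("rs234709" in a and "dropped" in a for a in iset.actions)


def test_harmonize_empty_intersection_raises(hcy_assocs):
    other = [SnpAssociation(rsid="rs0", effect_allele="A", beta=0.1, se=0.1)]
    with pytest.raises(HarmonizationError):
        harmonize(hcy_assocs, other)


def test_harmonize_unresolvable_outcome_allele_raises(hcy_assocs, t2d_assocs):
    recoded = [
        dataclasses.replace(a, effect_allele="other")
        if a.rsid == "rs1801133" else a
        for a in t2d_assocs
    ]
    with pytest.raises(HarmonizationError, match="rs1801133"):
        harmonize(hcy_assocs, recoded)


def _numeric(iset):
    return [
        (r, iset.exposure[r].beta, iset.exposure[r].se, iset.exposure[r].eaf,
         iset.outcomes["t2d"][r].beta, iset.outcomes["t2d"][r].se,
         iset.outcomes["t2d"][r].eaf)
        for r in iset.snps
    ]


def test_harmonize_is_idempotent(hcy_assocs, t2d_assocs):
    recoded = [
        dataclasses.replace(a, effect_allele="G", beta=-0.16, eaf=0.66)
        if a.rsid == "rs1801133" else a
        for a in hcy_assocs
    ]
    once = harmonize(recoded, t2d_assocs, outcome_name="t2d")
    twice = harmonize(once.exposure_assocs(), once.outcome_assocs("t2d"),
                      outcome_name="t2d")
    assert _numeric(once) == _numeric(twice)


_OTHER_BASE = {"A": "G", "C": "A", "G": "C", "T": "C"}


@given(
    flip_exp=st.lists(st.booleans(), min_size=5, max_size=5),
    flip_out=st.lists(st.booleans(), min_size=5, max_size=5),
)
def test_allele_flips_before_harmonization_change_nothing(
    hcy_assocs, t2d_assocs, flip_exp, flip_out
):
    """Re-reporting any SNP against its other allele (beta -> -beta,
    eaf -> 1-eaf) must not change the harmonized numeric content."""

    def flip(a):
        return dataclasses.replace(
            a, beta=-a.beta, eaf=1 - a.eaf,
            effect_allele=_OTHER_BASE[a.effect_allele],
        )

    exp = [flip(a) if f else a for a, f in zip(hcy_assocs, flip_exp)]
    out = [flip(a) if f else a for a, f in zip(t2d_assocs, flip_out)]
    base = harmonize(hcy_assocs, t2d_assocs, outcome_name="t2d")
    flipped = harmonize(exp, out, outcome_name="t2d")
    for ref, got in zip(_numeric(base), _numeric(flipped)):
        assert got[0] == ref[0]
        for a, b in zip(ref[1:], got[1:]):
            assert a == pytest.approx(b, abs=1e-12)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"se": 0.0},
        {"se": -0.1},
        {"eaf": 1.2},
        {"p": 0.0},
        {"effect_allele": "N"},
    ],
)
def test_record_invariants_are_enforced(kwargs):
    base = dict(rsid="rs1", effect_allele="A", beta=0.1, se=0.01, eaf=0.3, p=0.5)
    base.update(kwargs)
    with pytest.raises(ValueError):
        SnpAssociation(**base)
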