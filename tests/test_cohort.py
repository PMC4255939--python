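"""Cohort data model: parsing, validation, recoding, flags, VCF ingestion."""

import math
import textwrap

import numpy as np
import pandas as pd
import pytest

from gxescreen.cohort import (
    CohortTable,
    SnpInfo,
    derive_clinical_flags,
    normalize_genotype,
    read_cohort_table,
    read_genotypes_vcf,
    write_cohort_table,
)
from gxescreen.errors import (
    ConfigurationError,
    SchemaError,
    ValidationError,
)

from conftest import RS10757274, RS6903956


@pytest.mark.parametrize("raw", ["AG", "A/G", "A|G", "GA", "G/A", "G|A", "ag"])
def test_genotype_dialects_normalise_to_unordered_pair(raw):
    assert normalize_genotype(raw, RS10757274) == "AG"


@pytest.mark.parametrize("raw", [None, "", "NA", ".", "./.", "AT", "A", "AGG"])
def test_unparseable_or_missing_genotypes_become_missing(raw):
    assert normalize_genotype(raw, RS10757274) is None


def test_snp_catalog_rejects_identical_alleles():
    with pytest.raises(ConfigurationError):
        SnpInfo("rs0", "G", "G")


def _write_cohort_file(tmp_path, text, name="cohort.tsv"):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


def test_read_cohort_table_counts_and_normalisation(tmp_path):
    path = _write_cohort_file(
        tmp_path,
        """\
        subject_id\tstatus\trs10757274\tage
        a\t1\tG/A\t60
        b\t0\tAA\t55
        c\t1\tXX\t70
        """,
    )
    table = read_cohort_table(path, [RS10757274])
    assert table.n_cases == 2 and table.n_controls == 1
    assert table.data["rs10757274"].tolist()[:2] == ["AG", "AA"]
    assert table.data["rs10757274"].isna().tolist() == [False, False, True]


def test_read_cohort_table_schema_mapping_and_errors(tmp_path):
    path = _write_cohort_file(
        tmp_path,
        """\
        ID,outcome,rs10757274
        a,1,AG
        """,
        name="cohort.csv",
    )
    table = read_cohort_table(
        path, [RS10757274], schema={"ID": "subject_id", "outcome": "status"}
    )
    assert table.n_cases == 1

    with pytest.raises(SchemaError, match="status"):
        read_cohort_table(path, [RS10757274], schema={"ID": "subject_id"})


def test_empty_file_with_header_gives_empty_table(tmp_path):
    path = _write_cohort_file(tmp_path, "subject_id\tstatus\trs10757274\n")
    table = read_cohort_table(path, [RS10757274])
    assert len(table) == 0 and table.n_cases == 0 and table.n_controls == 0


def test_duplicate_subject_ids_rejected():
    df = pd.DataFrame({"subject_id": ["a", "a"], "status": [0, 1]})
    with pytest.raises(ValidationError, match="duplicate"):
        CohortTable(df)


def test_round_trip_preserves_values_and_missingness(tmp_path, study_cohort):
    path = tmp_path / "cohort.tsv"
    write_cohort_table(study_cohort, path)
    back = read_cohort_table(path, list(study_cohort.snps.values()))
    orig = study_cohort.data
    again = back.data[orig.columns]
    for col in orig.columns:
        a, b = orig[col], again[col]
        assert a.isna().equals(b.isna()), col
        if pd.api.types.is_float_dtype(a):
            assert np.allclose(a.dropna(), b.dropna()), col
        else:
            assert (a.dropna() == b.dropna()).all(), col


def test_effective_n_and_call_rate(study_cohort):
    for snp in study_cohort.snps:
        eff = study_cohort.effective_n(snp)
        assert eff["cases"] <= study_cohort.n_cases
        assert eff["controls"] <= study_cohort.n_controls
        rates = study_cohort.call_rate(snp)
        assert all(0.9 < r <= 1.0 for r in rates.values())


class TestGenotypeCoding:
    def _table(self):
        df = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "status": [1, 0, 1, 0],
                "rs10757274": ["GG", "AG", "AA", None],
            }
        )
        return CohortTable(df, [RS10757274])

    def test_additive_counts_risk_alleles(self):
        counts = self._table().encode_genotype("rs10757274", "additive")
        assert counts.tolist()[:3] == [2.0, 1.0, 0.0]
        assert math.isnan(counts.iloc[3])

    def test_dominant_is_carrier_indicator(self):
        table = self._table()
        dom = table.encode_genotype("rs10757274", "dominant")
        add = table.encode_genotype("rs10757274", "additive")
        assert dom.tolist()[:3] == [1.0, 1.0, 0.0]
        assert math.isnan(dom.iloc[3])
        # dominant coding == (additive >= 1) wherever observed
        obs = add.notna()
        assert (dom[obs] == (add[obs] >= 1)).all()

    def test_codominant_reference_level_is_major_homozygote(self):
        cod = self._table().encode_genotype("rs10757274", "codominant")
        assert list(cod.cat.categories) == ["AA", "AG", "GG"]
        assert cod.tolist()[:3] == ["GG", "AG", "AA"]

    def test_unknown_scheme_and_unknown_snp_rejected(self):
        with pytest.raises(ConfigurationError):
            self._table().encode_genotype("rs10757274", "recessive")
        with pytest.raises(ConfigurationError):
            self._table().encode_genotype("rs999", "dominant")


class TestClinicalFlags:
    def _table(self, **cols):
        base = {"subject_id": ["a"], "status": [1]}
        base.update({k: [v] for k, v in cols.items()})
        return CohortTable(pd.DataFrame(base))

    def test_hypertension_threshold_on_systolic(self):
        out, _ = derive_clinical_flags(
            self._table(sbp=140.0, dbp=80.0, antihypertensive_treatment=0.0)
        )
        assert out.data["hypertension"].iloc[0] == 1

    def test_treatment_alone_implies_hypertension(self):
        out, _ = derive_clinical_flags(
            self._table(sbp=120.0, dbp=70.0, antihypertensive_treatment=1.0)
        )
        assert out.data["hypertension"].iloc[0] == 1

    def test_hyperlipidemia_unit_conversion_just_below_thresholds(self):
        # 5.17 mmol/L * 38.67 = 199.9 mg/dL < 200; LDL 3.0 -> 116 < 130
        out, _ = derive_clinical_flags(self._table(tc=5.17, ldl=3.0))
        assert out.data["hyperlipidemia"].iloc[0] == 0
        out, _ = derive_clinical_flags(self._table(tc=5.18, ldl=3.0))
        assert out.data["hyperlipidemia"].iloc[0] == 1

    def test_bmi_from_weight_and_height(self):
        out, report = derive_clinical_flags(self._table(weight=72.0, height=1.70))
        assert out.data["bmi"].iloc[0] == pytest.approx(72.0 / 1.70**2, abs=1e-9)
        assert report.derived["bmi"] == 1

    def test_explicit_flag_takes_precedence(self):
        out, _ = derive_clinical_flags(self._table(sbp=180.0, hypertension=0.0))
        assert out.data["hypertension"].iloc[0] == 0

    def test_underivable_flags_counted(self):
        out, report = derive_clinical_flags(self._table(age=50.0))
        assert math.isnan(out.data["hypertension"].iloc[0])
        assert report.underivable["hypertension"] == 1


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=9>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
9\t100\trs10757274\tA\tG\t.\tPASS\t.\tGT\t0/1\t./.\t1|0
9\t200\trs_multi\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/0\t0/2
"""


class TestVcfIngestion:
    def _vcf(self, tmp_path):
        path = tmp_path / "genotypes.vcf"
        path.write_text(VCF_TEXT)
        return path

    def test_gt_decoding_phase_and_missing(self, tmp_path):
        frame = read_genotypes_vcf(self._vcf(tmp_path), snp_ids=["rs10757274"])
        assert frame.loc["s1", "rs10757274"] == "AG"
        assert frame.loc["s3", "rs10757274"] == "AG"  # 1|0 same as 0/1
        assert frame.loc["s2", "rs10757274"] is None or pd.isna(
            frame.loc["s2", "rs10757274"]
        )

    def test_multiallelic_site_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError, match="multi-allelic"):
            read_genotypes_vcf(self._vcf(tmp_path), snp_ids=["rs_multi"])

    def test_absent_sample_listed(self, tmp_path):
        with pytest.raises(ValidationError, match="s9"):
            read_genotypes_vcf(self._vcf(tmp_path), sample_ids=["s1", "s9"])

    def test_merge_into_cohort(self, tmp_path):
        frame = read_genotypes_vcf(self._vcf(tmp_path), snp_ids=["rs10757274"])
        df = pd.DataFrame(
            {"subject_id": ["s1", "s2", "s3"], "status": [1, 0, 1]}
        )
        table = CohortTable(df).merge_genotypes(frame)
        merged = CohortTable(table.data, [RS10757274])
        assert merged.effective_n("rs10757274") == {"controls": 0, "cases": 2}
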