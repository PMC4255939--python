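"""Subject-level cohort data model for case-control genetic studies.

The central container is :class:`CohortTable`: one row per subject with a
binary case/control status, diploid genotypes at a small number of named
SNPs, binary exposures (type 2 diabetes, smoking, drinking, hypertension,
hyperlipidemia), and continuous covariates (age, BMI, blood pressure,
lipids).  Genotypes are stored as unordered allele pairs in a canonical
string form (``"AG"`` with alleles sorted), so ``A/G``, ``G|A`` and ``GA``
all denote the same heterozygote.

Reading, writing, genotype normalisation and recoding (codominant /
dominant / additive), VCF ingestion and clinical-flag derivation all live
here so that every downstream analysis sees one validated representation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ParameterError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: tokens treated as missing on input, in addition to empty fields
MISSING_TOKENS = ("", "NA", ".", "na", "NaN", "nan")

#: mg/dL per mmol/L for cholesterol species (TC, LDL, HDL)
CHOLESTEROL_MGDL_PER_MMOL = 38.67

#: covariates adjusted for throughout the study design
DEFAULT_COVARIATES = ("age", "sex", "ethnicity", "bmi", "smoking", "drinking")

BINARY_FLAGS = (
    "sex",
    "ethnicity",
    "t2dm",
    "smoking",
    "drinking",
    "hypertension",
    "hyperlipidemia",
    "antihypertensive_treatment",
)

CONTINUOUS_FIELDS = (
    "age",
    "height",
    "weight",
    "bmi",
    "sbp",
    "dbp",
    "tc",
    "ldl",
    "hdl",
    "tg",
)


@dataclass(frozen=True)
class SnpInfo:
    """Catalog entry for one biallelic SNP.

    ``risk_allele`` is the allele counted by the additive/dominant codings;
    ``reference_allele`` is the other declared allele (the major allele in
    this study design, whose homozygote is the model reference level).
    """

    name: str
    risk_allele: str
    reference_allele: str

    def __post_init__(self) -> None:
        if self.risk_allele == self.reference_allele:
            raise ConfigurationError(
                f"SNP {self.name}: risk and reference allele are both "
                f"{self.risk_allele!r}"
            )

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.risk_allele, self.reference_allele))

    def genotype_strings(self) -> tuple[str, str, str]:
        """Canonical genotype strings ordered (ref-hom, het, risk-hom)."""
        ref, risk = self.reference_allele, self.risk_allele
        return (
            normalize_genotype(ref + ref, self),
            normalize_genotype(ref + risk, self),
            normalize_genotype(risk + risk, self),
        )


@dataclass(frozen=True)
class GenotypeCoding:
    """How a genotype enters a model.

    scheme
        ``"codominant"`` (3-level categorical), ``"dominant"`` (carrier of
        >=1 risk allele vs non-carrier) or ``"additive"`` (0/1/2 risk
        alleles).
    """

    scheme: str = "dominant"

    _SCHEMES = ("codominant", "dominant", "additive")

    def __post_init__(self) -> None:
        if self.scheme not in self._SCHEMES:
            raise ConfigurationError(
                f"unknown genotype coding scheme {self.scheme!r}; "
                f"expected one of {self._SCHEMES}"
            )


def normalize_genotype(raw: object, snp: SnpInfo) -> str | None:
    """Normalise a textual genotype to a canonical sorted allele pair.

    Accepts ``"AG"``, ``"A/G"``, ``"A|G"`` dialects; allele order and phase
    are ignored.  Returns ``None`` for missing or unparseable input (the
    caller decides whether to warn).

    Raises
    ------
    ValueError
        Never: unparseable strings map to ``None`` so that a single bad
        record cannot abort a bulk read.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text in MISSING_TOKENS or text in ("./.", ".|."):
        return None
    for sep in ("/", "|"):
        if sep in text:
            parts = text.split(sep)
            break
    else:
        parts = list(text)
    if len(parts) != 2:
        return None
    a, b = parts[0].strip().upper(), parts[1].strip().upper()
    if a not in snp.alleles or b not in snp.alleles:
        return None
    return "".join(sorted((a, b)))


def risk_allele_count(genotype: str | None, snp: SnpInfo) -> float:
    """Count risk alleles in a canonical genotype (NaN when missing)."""
    if genotype is None or (isinstance(genotype, float) and math.isnan(genotype)):
        return float("nan")
    return float(sum(1 for allele in genotype if allele == snp.risk_allele))


class CohortTable:
    """Validated subject-level case-control cohort.

    Parameters
    ----------
    data
        One row per subject.  Must contain ``subject_id`` and ``status``
        (1 = case, 0 = control); genotype columns are named after the SNPs
        in ``snps`` and hold canonical genotype strings or NaN.
    snps
        Catalog of the SNPs present (may be empty for purely clinical
        tables).
    """

    def __init__(self, data: pd.DataFrame, snps: Sequence[SnpInfo] = ()) -> None:
        self.data = data.reset_index(drop=True)
        self.snps: dict[str, SnpInfo] = {s.name: s for s in snps}
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        df = self.data
        for col in ("subject_id", "status"):
            if col not in df.columns:
                raise SchemaError(f"mandatory column {col!r} missing")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicate subject_id values: {dupes[:5]}")
        if len(df) and not df["status"].isin([0, 1]).all():
            bad = sorted(set(df["status"]) - {0, 1})
            raise ValidationError(f"status must be 0/1; found {bad}")
        if "age" in df.columns:
            ages = df["age"].dropna()
            if (ages <= 0).any():
                raise ValidationError("age must be positive")
        if "bmi" in df.columns:
            bmis = df["bmi"].dropna()
            if (bmis <= 0).any():
                raise ValidationError("bmi must be positive")
        for name in self.snps:
            if name not in df.columns:
                raise SchemaError(f"genotype column for SNP {name!r} missing")

    # -- basic accessors --------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def status(self) -> pd.Series:
        return self.data["status"].astype(int)

    @property
    def n_cases(self) -> int:
        return int((self.data["status"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data["status"] == 0).sum())

    def effective_n(self, snp: str) -> dict[str, int]:
        """Non-missing genotype count per group for one SNP."""
        self._require_snp(snp)
        ok = self.data[snp].notna()
        return {
            "controls": int((ok & (self.data["status"] == 0)).sum()),
            "cases": int((ok & (self.data["status"] == 1)).sum()),
        }

    def call_rate(self, snp: str) -> dict[str, float]:
        """Per-group genotyping call rate (1 - missing fraction)."""
        eff = self.effective_n(snp)
        out = {}
        for group, n_group in (("controls", self.n_controls), ("cases", self.n_cases)):
            out[group] = eff[group] / n_group if n_group else float("nan")
        return out

    def _require_snp(self, snp: str) -> SnpInfo:
        if snp not in self.snps:
            raise ConfigurationError(
                f"SNP {snp!r} not in catalog; have {sorted(self.snps)}"
            )
        return self.snps[snp]

    # -- genotype recoding ------------------------------------------------

    def encode_genotype(
        self, snp: str, coding: GenotypeCoding | str = "dominant"
    ) -> pd.Series:
        """Code one SNP's genotypes for modelling.

        Returns a float Series (NaN where the genotype is missing):
        additive = number of risk alleles (0/1/2); dominant = 1 iff
        carrier of at least one risk allele; codominant = a pandas
        Categorical over the three genotype strings with the
        reference-homozygote first (the reference level for dummies).
        """
        info = self._require_snp(snp)
        if isinstance(coding, str):
            coding = GenotypeCoding(coding)
        counts = self.data[snp].map(lambda g: risk_allele_count(g, info))
        if coding.scheme == "additive":
            return counts.rename(f"{snp}_additive")
        if coding.scheme == "dominant":
            dominant = (counts >= 1).astype(float)
            dominant[counts.isna()] = np.nan
            return dominant.rename(f"{snp}_carrier")
        levels = info.genotype_strings()
        cat = pd.Categorical(self.data[snp], categories=list(levels))
        return pd.Series(cat, index=self.data.index, name=f"{snp}_genotype")

    # -- merging genotypes ------------------------------------------------

    def merge_genotypes(self, genotypes: pd.DataFrame) -> "CohortTable":
        """Return a new table with genotype columns merged in by subject_id.

        ``genotypes`` is indexed by subject id with one column per SNP in
        the catalog (canonical strings or NaN), as produced by
        :func:`read_genotypes_vcf`.
        """
        df = self.data.copy()
        absent = [s for s in df["subject_id"] if s not in genotypes.index]
        if absent:
            raise ValidationError(
                f"{len(absent)} subjects have no genotype record: {absent[:5]}"
            )
        aligned = genotypes.loc[df["subject_id"]].reset_index(drop=True)
        for col in genotypes.columns:
            df[col] = aligned[col]
        return CohortTable(df, list(self.snps.values()))


# -- reading and writing ---------------------------------------------------


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cohort_table(
    path: str | Path,
    snps: Sequence[SnpInfo] = (),
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> CohortTable:
    """Read a delimited subject-level table into a validated CohortTable.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    snps
        SNP catalog; each SNP's column (after renaming via ``schema``) is
        normalised to canonical genotype strings.  Unparseable genotype
        strings become missing, with one warning per SNP giving the count.
    schema
        Optional mapping from file column names to canonical field names
        (``{"ID": "subject_id", ...}``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        sep=_infer_delimiter(path, delimiter),
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        dtype={"subject_id": str},
    )
    if schema:
        df = df.rename(columns=dict(schema))
    for col in ("subject_id", "status"):
        if col not in df.columns:
            raise SchemaError(
                f"mandatory column {col!r} missing after schema mapping; "
                f"columns present: {list(df.columns)}"
            )
    if snps and not any(s.name in df.columns for s in snps):
        raise SchemaError(
            f"no genotype column found for any of {[s.name for s in snps]}"
        )
    if len(df):
        df["subject_id"] = df["subject_id"].astype(str)
        df["status"] = pd.to_numeric(df["status"])
    for col in CONTINUOUS_FIELDS + BINARY_FLAGS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for snp in snps:
        if snp.name not in df.columns:
            continue
        raw = df[snp.name]
        normalized = raw.map(lambda g: normalize_genotype(g, snp))
        n_bad = int((raw.notna() & normalized.isna()).sum())
        if n_bad:
            logger.warning(
                "%s: %d unparseable genotype(s) set to missing", snp.name, n_bad
            )
        df[snp.name] = normalized
    return CohortTable(df, snps)


def write_cohort_table(
    table: CohortTable, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a cohort table as delimited text (missing values as ``NA``)."""
    path = Path(path)
    table.data.to_csv(
        path, sep=_infer_delimiter(path, delimiter), index=False, na_rep="NA"
    )


# -- VCF ingestion ----------------------------------------------------------


def read_genotypes_vcf(
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
    snp_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Extract diploid GT genotypes from a VCF into a sample x SNP frame.

    Values are unordered allele-pair strings (phase ignored); ``./.``
    becomes NaN.  Multi-allelic records are rejected: with more than one
    ALT the carrier/additive codings are ambiguous.

    Returns a DataFrame indexed by sample id, one column per variant ID.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_ids is not None:
        absent = [s for s in sample_ids if s not in samples]
        if absent:
            raise ValidationError(f"samples absent from VCF: {absent}")
    wanted = set(snp_ids) if snp_ids is not None else None
    columns: dict[str, pd.Series] = {}
    seen: set[str] = set()
    for record in vcf:
        rid = record.ID
        if rid is None or (wanted is not None and rid not in wanted):
            continue
        if len(record.ALT) != 1:
            raise ConfigurationError(
                f"variant {rid} is multi-allelic (ALT={record.ALT}); "
                "split or restrict to biallelic sites first"
            )
        alleles = [record.REF] + list(record.ALT)
        values = []
        for gt in record.genotypes:  # [allele_idx, allele_idx, phased]
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                values.append(None)
            else:
                values.append("".join(sorted((alleles[a], alleles[b]))))
        columns[rid] = pd.Series(values, index=samples)
        seen.add(rid)
    if wanted is not None and wanted - seen:
        raise ValidationError(f"variants absent from VCF: {sorted(wanted - seen)}")
    frame = pd.DataFrame(columns)
    if sample_ids is not None:
        frame = frame.loc[list(sample_ids)]
    return frame


# -- clinical flag derivation -----------------------------------------------


@dataclass
class FlagReport:
    """Completeness accounting for derived clinical flags."""

    derived: dict[str, int] = field(default_factory=dict)
    underivable: dict[str, int] = field(default_factory=dict)


def derive_clinical_flags(
    table: CohortTable,
    tc_mgdl_per_mmol: float = CHOLESTEROL_MGDL_PER_MMOL,
    ldl_mgdl_per_mmol: float = CHOLESTEROL_MGDL_PER_MMOL,
) -> tuple[CohortTable, FlagReport]:
    """Fill BMI, hypertension and hyperlipidemia from raw measurements.

    Explicit flags take precedence; derivation only fills missing values.
    Definitions: hypertension = SBP >= 140 mmHg or DBP >= 90 mmHg or
    current antihypertensive treatment; hyperlipidemia = fasting total
    cholesterol >= 200 mg/dL or LDL cholesterol >= 130 mg/dL (lipids are
    measured in mmol/L and converted with the given factors);
    BMI = weight / height**2 (kg/m^2).

    Returns the updated table and a :class:`FlagReport` counting how many
    subjects had each flag derived and how many could not be derived.
    """
    if tc_mgdl_per_mmol <= 0 or ldl_mgdl_per_mmol <= 0:
        raise ParameterError("unit conversion factors must be positive")
    df = table.data.copy()
    report = FlagReport()

    def _col(name: str) -> pd.Series:
        return df[name] if name in df.columns else pd.Series(np.nan, index=df.index)

    # BMI from weight/height where absent
    if "bmi" not in df.columns:
        df["bmi"] = np.nan
    derivable = df["bmi"].isna() & _col("weight").notna() & _col("height").notna()
    if derivable.any():
        df.loc[derivable, "bmi"] = (
            df.loc[derivable, "weight"] / df.loc[derivable, "height"] ** 2
        )
    report.derived["bmi"] = int(derivable.sum())

    # hypertension
    sbp, dbp, trt = _col("sbp"), _col("dbp"), _col("antihypertensive_treatment")
    raw_any = sbp.notna() | dbp.notna() | trt.notna()
    htn = (
        (sbp >= 140).fillna(False)
        | (dbp >= 90).fillna(False)
        | (trt == 1).fillna(False)
    ).astype(float)
    htn[~raw_any] = np.nan
    if "hypertension" not in df.columns:
        df["hypertension"] = np.nan
    fillable = df["hypertension"].isna() & raw_any
    df.loc[fillable, "hypertension"] = htn[fillable]
    report.derived["hypertension"] = int(fillable.sum())
    report.underivable["hypertension"] = int((df["hypertension"].isna()).sum())

    # hyperlipidemia (thresholds in mg/dL, measurements in mmol/L)
    tc_mgdl = _col("tc") * tc_mgdl_per_mmol
    ldl_mgdl = _col("ldl") * ldl_mgdl_per_mmol
    raw_any = tc_mgdl.notna() | ldl_mgdl.notna()
    hld = ((tc_mgdl >= 200).fillna(False) | (ldl_mgdl >= 130).fillna(False)).astype(
        float
    )
    hld[~raw_any] = np.nan
    if "hyperlipidemia" not in df.columns:
        df["hyperlipidemia"] = np.nan
    fillable = df["hyperlipidemia"].isna() & raw_any
    df.loc[fillable, "hyperlipidemia"] = hld[fillable]
    report.derived["hyperlipidemia"] = int(fillable.sum())
    report.underivable["hyperlipidemia"] = int((df["hyperlipidemia"].isna()).sum())

    return CohortTable(df, list(table.snps.values())), report


def encode_genotype(
    table: CohortTable, snp: str, coding: GenotypeCoding | str = "dominant"
) -> pd.Series:
    """Module-level convenience wrapper for :meth:`CohortTable.encode_genotype`."""
    return table.encode_genotype(snp, coding)
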