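"""Synthetic case-control cohort generation with a known disease model.

The generator draws a latent population — genotypes in Hardy-Weinberg
proportions, independent binary exposures and covariates — assigns each
subject a disease probability from a configurable logistic model (main
effects plus named product terms, so a gene x environment interaction can
be planted at a known strength), realises case/control status, and then
samples the requested numbers of cases and controls without replacement,
mirroring fixed-size hospital-based recruitment.

:func:`study_config` packages defaults that emulate the marginal structure
of the myocardial-infarction study this package re-implements: 502 cases /
308 controls, two SNPs (rs10757274 with control risk-allele frequency near
0.42, rs6903956 near 0.08), type-2-diabetes prevalence near 24% in
controls, and planted conditional odds ratios (1.60, 1.68, 4.38) for the
carrier-only, exposure-only and joint categories of the headline
interaction.  All randomness flows through one explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, SnpInfo
from .errors import ConfigurationError, ParameterError


def _check_prob(value: float, what: str) -> None:
    if not (0.0 < value < 1.0):
        raise ParameterError(f"{what} must be in (0, 1); got {value}")


@dataclass
class SnpSpec:
    """Simulation parameters for one biallelic SNP."""

    name: str
    risk_allele: str
    reference_allele: str
    risk_allele_freq: float
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        _check_prob(self.risk_allele_freq, f"{self.name} risk_allele_freq")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterError("missing_rate must be in [0, 1)")

    @property
    def info(self) -> SnpInfo:
        return SnpInfo(self.name, self.risk_allele, self.reference_allele)


@dataclass
class CovariateSpec:
    """Marginal distributions for the standard covariates."""

    age_mean: float = 62.1
    age_sd: float = 11.0
    bmi_mean: float = 25.8
    bmi_sd: float = 3.3
    male_prevalence: float = 0.49
    minority_prevalence: float = 0.053
    smoking_prevalence: float = 0.37
    drinking_prevalence: float = 0.258


@dataclass
class DiseaseModel:
    """Logistic disease model: intercept plus named log-odds terms.

    Keys of ``terms`` are variable names (a SNP name refers to its coded
    genotype under ``genotype_coding``) or products ``"a:b"`` of two
    declared variables.
    """

    intercept: float
    terms: dict[str, float] = field(default_factory=dict)
    genotype_coding: str = "dominant"


@dataclass
class SimulationConfig:
    """Full specification of one synthetic case-control cohort."""

    seed: int
    n_cases: int = 502
    n_controls: int = 308
    snps: list[SnpSpec] = field(default_factory=list)
    exposures: dict[str, float] = field(default_factory=dict)
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    disease_model: DiseaseModel = field(
        default_factory=lambda: DiseaseModel(intercept=0.0)
    )
    population_multiplier: int = 16
    max_population_multiplier: int = 200

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ParameterError("n_cases and n_controls must be positive")
        for name, prev in self.exposures.items():
            _check_prob(prev, f"exposure {name} prevalence")
        self._validate_model()

    def variable_names(self) -> set[str]:
        names = {"age", "bmi", "sex", "ethnicity", "smoking", "drinking"}
        names |= set(self.exposures)
        names |= {s.name for s in self.snps}
        return names

    def _validate_model(self) -> None:
        declared = self.variable_names()
        for term in self.disease_model.terms:
            parts = term.split(":")
            if len(parts) > 2 or any(p not in declared for p in parts):
                raise ConfigurationError(
                    f"disease-model term {term!r} references undeclared "
                    f"variables; declared: {sorted(declared)}"
                )


# -- primitive draws --------------------------------------------------------


def simulate_genotypes_hwe(
    freq: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw risk-allele counts (0/1/2) under Hardy-Weinberg proportions.

    P(2) = freq^2, P(1) = 2 freq (1-freq), P(0) = (1-freq)^2 — i.e. two
    independent Bernoulli(freq) allele draws per subject.
    """
    _check_prob(freq, "risk allele frequency")
    if n < 1:
        raise ParameterError("n must be at least 1")
    return rng.binomial(2, freq, size=n)


def _genotype_strings(counts: np.ndarray, snp: SnpSpec) -> np.ndarray:
    lookup = np.array(snp.info.genotype_strings(), dtype=object)
    return lookup[counts]


# -- population and phenotype ----------------------------------------------


def generate_population(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw a latent population of size ``n`` (no disease status yet)."""
    cov = config.covariates
    df = pd.DataFrame(
        {
            "age": np.clip(rng.normal(cov.age_mean, cov.age_sd, n), 18.0, None),
            "bmi": np.clip(rng.normal(cov.bmi_mean, cov.bmi_sd, n), 12.0, None),
            "sex": rng.binomial(1, cov.male_prevalence, n).astype(float),
            "ethnicity": rng.binomial(1, cov.minority_prevalence, n).astype(float),
            "smoking": rng.binomial(1, cov.smoking_prevalence, n).astype(float),
            "drinking": rng.binomial(1, cov.drinking_prevalence, n).astype(float),
        }
    )
    for name, prev in config.exposures.items():
        df[name] = rng.binomial(1, prev, n).astype(float)
    for snp in config.snps:
        counts = simulate_genotypes_hwe(snp.risk_allele_freq, n, rng)
        df[snp.name] = _genotype_strings(counts, snp)
        df[f"_{snp.name}_count"] = counts.astype(float)
    return df


def _model_value(
    df: pd.DataFrame, variable: str, config: SimulationConfig
) -> np.ndarray:
    snp_names = {s.name for s in config.snps}
    if variable in snp_names:
        counts = df[f"_{variable}_count"].to_numpy()
        if config.disease_model.genotype_coding == "dominant":
            return (counts >= 1).astype(float)
        if config.disease_model.genotype_coding == "additive":
            return counts
        raise ConfigurationError(
            "generative genotype coding must be dominant or additive"
        )
    if variable not in df.columns:
        raise ConfigurationError(f"model variable {variable!r} not generated")
    return df[variable].to_numpy(dtype=float)


def simulate_phenotype_logistic(
    population: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Attach true disease probability and realised status to a population.

    ``P(case) = logistic(intercept + sum(coef * value) + sum(coef *
    product))``; status is drawn Bernoulli per subject.
    """
    model = config.disease_model
    eta = np.full(len(population), model.intercept, dtype=float)
    for term, coef in model.terms.items():
        parts = term.split(":")
        value = _model_value(population, parts[0], config)
        for part in parts[1:]:
            value = value * _model_value(population, part, config)
        eta += coef * value
    p = 1.0 / (1.0 + np.exp(-eta))
    out = population.copy()
    out["p_disease"] = p
    out["status"] = rng.binomial(1, p).astype(int)
    return out


def sample_case_control(
    population: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    snps: Sequence[SnpSpec] = (),
) -> CohortTable:
    """Sample exact case/control counts without replacement per stratum."""
    if n_cases <= 0 or n_controls <= 0:
        raise ParameterError("n_cases and n_controls must be positive")
    cases = population.index[population["status"] == 1].to_numpy()
    controls = population.index[population["status"] == 0].to_numpy()
    if len(cases) < n_cases or len(controls) < n_controls:
        raise ParameterError(
            f"population has {len(cases)} cases / {len(controls)} controls; "
            f"requested {n_cases}/{n_controls} — increase the population "
            "multiplier"
        )
    chosen = np.concatenate(
        [
            rng.choice(cases, size=n_cases, replace=False),
            rng.choice(controls, size=n_controls, replace=False),
        ]
    )
    df = population.loc[chosen].reset_index(drop=True)
    df = df.drop(columns=[c for c in df.columns if c.startswith("_")])
    df.insert(0, "subject_id", [f"S{i:06d}" for i in range(len(df))])
    # per-SNP genotyping missingness, mirroring imperfect call rates
    for snp in snps:
        if snp.missing_rate > 0:
            miss = rng.random(len(df)) < snp.missing_rate
            df.loc[miss, snp.name] = np.nan
    return CohortTable(df, [s.info for s in snps])


def generate_cohort(config: SimulationConfig) -> CohortTable:
    """End-to-end cohort generation from one config (seeded, deterministic)."""
    rng = np.random.default_rng(config.seed)
    multiplier = config.population_multiplier
    n_target = config.n_cases + config.n_controls
    while True:
        population = generate_population(config, multiplier * n_target, rng)
        population = simulate_phenotype_logistic(population, config, rng)
        n_case = int((population["status"] == 1).sum())
        n_ctrl = int((population["status"] == 0).sum())
        if n_case >= config.n_cases and n_ctrl >= config.n_controls:
            break
        if multiplier >= config.max_population_multiplier:
            raise ParameterError(
                f"population multiplier {multiplier} still yields only "
                f"{n_case} cases / {n_ctrl} controls; raise "
                "max_population_multiplier"
            )
        multiplier = min(2 * multiplier, config.max_population_multiplier)
    return sample_case_control(
        population, config.n_cases, config.n_controls, rng, config.snps
    )


# -- study-shaped defaults --------------------------------------------------

#: planted conditional odds ratios for the headline interaction
PLANTED_OR_CARRIER_ONLY = 1.60
PLANTED_OR_EXPOSURE_ONLY = 1.68
PLANTED_OR_JOINT = 4.38


def study_config(
    seed: int,
    n_cases: int = 502,
    n_controls: int = 308,
    null_effects: bool = False,
) -> SimulationConfig:
    """Defaults emulating the study cohort's marginal structure.

    The gene x environment effect is parameterised so the conditional
    odds ratios of the four carrier x T2DM categories are (1, 1.60, 1.68,
    4.38).  ``null_effects=True`` zeroes every association (intercept
    kept), for type-I-error and calibration studies.
    """
    snps = [
        SnpSpec("rs10757274", "G", "A", risk_allele_freq=0.405, missing_rate=0.018),
        SnpSpec("rs6903956", "A", "G", risk_allele_freq=0.081, missing_rate=0.045),
    ]
    exposures = {"t2dm": 0.258, "hypertension": 0.645, "hyperlipidemia": 0.398}
    terms = {
        "age": 0.016,
        "sex": np.log(3.4),
        "ethnicity": -0.45,
        "smoking": np.log(2.1),
        "drinking": np.log(1.5),
        "hypertension": np.log(1.15),
        "t2dm": np.log(PLANTED_OR_EXPOSURE_ONLY),
        "rs10757274": np.log(PLANTED_OR_CARRIER_ONLY),
        "rs10757274:t2dm": np.log(
            PLANTED_OR_JOINT / (PLANTED_OR_CARRIER_ONLY * PLANTED_OR_EXPOSURE_ONLY)
        ),
    }
    # rare-disease intercept: the latent population has ~6% prevalence, so
    # sampled controls approximate the source population (and stay in HWE)
    intercept = -5.3
    if null_effects:
        terms = {k: 0.0 for k in terms}
        intercept = 0.0  # balanced latent population; prevalence is
        # irrelevant to odds ratios under case-control sampling
    return SimulationConfig(
        seed=seed,
        n_cases=n_cases,
        n_controls=n_controls,
        snps=snps,
        exposures=exposures,
        covariates=CovariateSpec(),
        disease_model=DiseaseModel(intercept=intercept, terms=terms),
    )


def generate_study_fixture(seed: int) -> CohortTable:
    """One-call cohort with the study's marginal structure (502/308)."""
    return generate_cohort(study_config(seed))


# -- config serialisation ---------------------------------------------------


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(payload: Mapping) -> SimulationConfig:
    data = dict(payload)
    data["snps"] = [SnpSpec(**s) for s in data.get("snps", [])]
    if "covariates" in data:
        data["covariates"] = CovariateSpec(**data["covariates"])
    if "disease_model" in data:
        data["disease_model"] = DiseaseModel(**data["disease_model"])
    return SimulationConfig(**data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    payload = config_to_dict(config)
    payload["disease_model"]["terms"] = {
        k: float(v) for k, v in payload["disease_model"]["terms"].items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: str | Path) -> SimulationConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
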