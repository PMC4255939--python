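"""End-to-end orchestration of the case-control interaction analysis.

One :class:`RunConfig` drives the full stage order: baseline descriptives,
Hardy-Weinberg + per-SNP association, the GMDR interaction screen, and the
confirmatory multiplicative/additive interaction analysis of one SNP x
exposure pair (by default the GMDR best model's pair).  Each stage writes
a TSV report plus a JSON twin; ``run.json`` records parameters, the seed,
drop counts and completion state so a run is reproducible byte-for-byte
given the same config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import genotype_association
from .cohort import (
    DEFAULT_COVARIATES,
    CohortTable,
    SnpInfo,
    derive_clinical_flags,
    read_cohort_table,
)
from .descriptives import DEFAULT_TABLE1_VARIABLES, build_table1, format_p
from .errors import ConfigurationError, GxeError
from .gmdr import (
    assign_cv_folds,
    compute_score_residuals,
    factor_matrix,
    permutation_test,
    search_models,
)
from .interaction import (
    additive_interaction,
    fit_joint_exposure_model,
    multiplicative_interaction_test,
)

logger = logging.getLogger(__name__)

DEFAULT_ENV_FACTORS = ("t2dm", "hypertension", "hyperlipidemia")


@dataclass
class GmdrSettings:
    k_folds: int = 10
    k_min: int = 1
    k_max: int = 5
    permutations: int = 1000
    env_factors: tuple[str, ...] = DEFAULT_ENV_FACTORS
    sign_alpha: float = 0.05  # permutation run only for sign-significant models

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be at least 2")
        if self.permutations < 0:
            raise ConfigurationError("permutations must be non-negative")


@dataclass
class RunConfig:
    """Everything needed for one full analysis run."""

    input_path: str
    snps: list[SnpInfo]
    output_dir: str = "gxescreen_out"
    seed: int = 0
    schema: dict[str, str] = field(default_factory=dict)
    delimiter: str | None = None
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    gmdr: GmdrSettings = field(default_factory=GmdrSettings)
    interaction_snp: str | None = None
    interaction_exposure: str | None = None
    derive_flags: bool = True


def load_run_config(path: str | Path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text())
    payload["snps"] = [SnpInfo(**s) for s in payload.get("snps", [])]
    if "gmdr" in payload:
        gm = dict(payload["gmdr"])
        if "env_factors" in gm:
            gm["env_factors"] = tuple(gm["env_factors"])
        payload["gmdr"] = GmdrSettings(**gm)
    if "covariates" in payload:
        payload["covariates"] = tuple(payload["covariates"])
    return RunConfig(**payload)


def _write_pair(frame: pd.DataFrame, out_dir: Path, stem: str) -> None:
    frame.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False, na_rep="NA")
    (out_dir / f"{stem}.json").write_text(
        json.dumps(
            json.loads(frame.to_json(orient="records")), indent=2, sort_keys=True
        )
        + "\n"
    )


def _association_frame(table: CohortTable, snps, covariates) -> tuple[pd.DataFrame, pd.DataFrame]:
    hwe_rows, assoc_rows = [], []
    for snp in snps:
        result = genotype_association(table, snp.name, covariates)
        hwe = result.hwe_controls
        counts = result.counts["controls"]
        hwe_rows.append(
            {
                "snp": snp.name,
                "group": "controls",
                "n_hom_other": counts.n_hom_other,
                "n_het": counts.n_het,
                "n_hom_risk": counts.n_hom_risk,
                "chi2": hwe.statistic,
                "df": hwe.df,
                "p_value": hwe.p_value,
            }
        )
        for contrast in result.contrasts:
            assoc_rows.append(
                {
                    "snp": snp.name,
                    "comparison": contrast.comparison,
                    "adjusted": contrast.adjusted,
                    "or": contrast.or_point,
                    "ci_low": contrast.ci_low,
                    "ci_high": contrast.ci_high,
                    "p_value": contrast.p_value,
                    "p_formatted": format_p(contrast.p_value),
                }
            )
    return pd.DataFrame(hwe_rows), pd.DataFrame(assoc_rows)


def run_full_analysis(config: RunConfig, table: CohortTable | None = None) -> dict:
    """Run every stage in study order; returns the run manifest dict.

    Stage failures halt the run with a stage-named error, leaving the
    completed reports plus a MANIFEST marking the run incomplete.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "covariates": list(config.covariates),
        "stages_completed": [],
        "complete": False,
        "drop_counts": {},
    }
    stage = "read"
    try:
        if table is None:
            table = read_cohort_table(
                config.input_path, config.snps, config.schema, config.delimiter
            )
        if config.derive_flags:
            table, flag_report = derive_clinical_flags(table)
            manifest["flag_derivation"] = {
                "derived": flag_report.derived,
                "underivable": flag_report.underivable,
            }
        manifest["n_cases"] = table.n_cases
        manifest["n_controls"] = table.n_controls
        manifest["stages_completed"].append(stage)

        stage = "describe"
        variables = [
            (name, kind)
            for name, kind in DEFAULT_TABLE1_VARIABLES
            if name in table.data.columns
        ]
        table1 = build_table1(table, variables)
        _write_pair(table1, out_dir, "table1")
        manifest["drop_counts"]["table1"] = {
            r["variable"]: int(r["n_dropped"]) for _, r in table1.iterrows()
        }
        manifest["stages_completed"].append(stage)

        stage = "association"
        hwe_frame, assoc_frame = _association_frame(
            table, config.snps.__iter__(), config.covariates
        )
        _write_pair(hwe_frame, out_dir, "hwe")
        _write_pair(assoc_frame, out_dir, "association")
        manifest["stages_completed"].append(stage)

        stage = "gmdr"
        settings = config.gmdr
        rng = np.random.default_rng(config.seed)
        snp_names = [s.name for s in config.snps]
        env = [e for e in settings.env_factors if e in table.data.columns]
        factors = factor_matrix(table, snp_names, env)
        scores = compute_score_residuals(table, config.covariates)
        folds = assign_cv_folds(table.status.to_numpy(), settings.k_folds, rng)
        k_max = min(settings.k_max, factors.shape[1])
        search = search_models(factors, scores, folds, settings.k_min, k_max)
        if settings.permutations > 0:
            for size, model in search.best_per_size.items():
                if model.p_sign < settings.sign_alpha:
                    model.p_perm, _ = permutation_test(
                        table,
                        model.factors,
                        snp_names,
                        env,
                        config.covariates,
                        settings.k_folds,
                        settings.permutations,
                        rng,
                        observed_accuracy=model.mean_testing_accuracy,
                    )
        _write_pair(search.to_frame(), out_dir, "gmdr")
        best = search.best_model
        manifest["gmdr_best_model"] = list(best.factors)
        manifest["stages_completed"].append(stage)

        stage = "interaction"
        snp_name = config.interaction_snp
        exposure = config.interaction_exposure
        if snp_name is None or exposure is None:
            # default to the best two-factor model when it is a SNP x
            # exposure pair, else the overall best model's first such pair
            pool = []
            if 2 in search.best_per_size:
                pool.append(search.best_per_size[2].factors)
            pool.append(best.factors)
            for factors_ in pool:
                cand_snps = [f for f in factors_ if f in snp_names]
                cand_envs = [f for f in factors_ if f in env]
                if cand_snps and cand_envs:
                    if snp_name is None:
                        snp_name = cand_snps[0]
                    if exposure is None:
                        exposure = cand_envs[0]
                    break
        if snp_name is None or exposure is None:
            logger.warning("no SNP/exposure pair for interaction stage; skipping")
            manifest["interaction_pair"] = None
        else:
            model = fit_joint_exposure_model(
                table, snp_name, exposure, config.covariates
            )
            additive = additive_interaction(model)
            multiplicative = multiplicative_interaction_test(
                table, snp_name, exposure, config.covariates
            )
            rows = []
            for key, orr in model.odds_ratios().items():
                rows.append(
                    {
                        "term": key,
                        "comparison": orr.comparison,
                        "estimate": orr.or_point,
                        "ci_low": orr.ci_low,
                        "ci_high": orr.ci_high,
                        "p_value": orr.p_value,
                    }
                )
            mult = multiplicative.or_product_term
            rows.append(
                {
                    "term": "multiplicative",
                    "comparison": mult.comparison,
                    "estimate": mult.or_point,
                    "ci_low": mult.ci_low,
                    "ci_high": mult.ci_high,
                    "p_value": mult.p_value,
                }
            )
            for name, value, ci in (
                ("RERI", additive.reri, additive.reri_ci),
                ("API", additive.api, additive.api_ci),
                ("S", additive.s, additive.s_ci),
            ):
                rows.append(
                    {
                        "term": name,
                        "comparison": f"{snp_name} x {exposure}",
                        "estimate": value,
                        "ci_low": ci[0] if ci else np.nan,
                        "ci_high": ci[1] if ci else np.nan,
                        "p_value": np.nan,
                    }
                )
            _write_pair(pd.DataFrame(rows), out_dir, "interaction")
            manifest["interaction_pair"] = [snp_name, exposure]
            manifest["significant_additive"] = bool(additive.significant_additive)
        manifest["stages_completed"].append(stage)
        manifest["complete"] = True
    except GxeError as exc:
        manifest["error"] = f"stage {stage!r} failed: {exc}"
        raise
    finally:
        (out_dir / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        (out_dir / "run.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return manifest
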