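"""Two-factor multiplicative and additive interaction on the odds-ratio scale.

For a dominant-coded SNP G and a binary exposure E, the joint-exposure
logistic model codes the four (G, E) categories with indicator terms
against the double-negative reference:

    logit P(case) = b0 + b1*[G+, E-] + b2*[G-, E+] + b3*[G+, E+] + covariates

so OR10 = exp(b1), OR01 = exp(b2), OR11 = exp(b3).  Departure from
additivity of odds-ratio excesses is measured by

    RERI = OR11 - OR10 - OR01 + 1          (0 under additivity)
    API  = RERI / OR11                     (0 under additivity)
    S    = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1))   (1 under additivity)

with 95% confidence intervals from the delta method applied to the
coefficient covariance of (b1, b2, b3) from the single joint fit; the
synergy index S is handled on the log scale so its interval stays
positive.  Multiplicative interaction is the conventional product-term
Wald test in a main-effects-plus-product logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import LogisticFit, OddsRatioResult, Z_95, fit_logistic
from .cohort import DEFAULT_COVARIATES, CohortTable
from .errors import ConfigurationError, NonEstimableError

_TERMS = ("g_only", "e_only", "joint")


@dataclass
class JointExposureModel:
    """Joint four-category logistic fit for one SNP/exposure pair."""

    snp: str
    exposure: str
    fit: LogisticFit
    covariates: tuple[str, ...]
    category_counts: pd.DataFrame  # cases/controls per joint category

    @property
    def log_ors(self) -> np.ndarray:
        """(b1, b2, b3) for (G+E-), (G-E+), (G+E+)."""
        return self.fit.params[list(_TERMS)].to_numpy()

    @property
    def cov3(self) -> np.ndarray:
        """3x3 covariance of (b1, b2, b3)."""
        return self.fit.cov.loc[list(_TERMS), list(_TERMS)].to_numpy()

    def odds_ratios(self) -> dict[str, OddsRatioResult]:
        labels = {
            "g_only": f"{self.snp}+ / {self.exposure}-",
            "e_only": f"{self.snp}- / {self.exposure}+",
            "joint": f"{self.snp}+ / {self.exposure}+",
        }
        return {
            key: self.fit.odds_ratio(key, labels[key], self.covariates)
            for key in _TERMS
        }


@dataclass
class AdditiveInteractionResult:
    """RERI / API / synergy-index summary with 95% CIs.

    ``s`` may be NaN (with ``s_defined=False``) when the main-effect
    excesses cancel, in which case the synergy index is undefined and the
    additive-interaction decision rests on RERI and API alone.
    """

    or10: float
    or01: float
    or11: float
    reri: float
    api: float
    s: float
    reri_ci: tuple[float, float] | None = None
    api_ci: tuple[float, float] | None = None
    s_ci: tuple[float, float] | None = None
    s_defined: bool = True

    def __post_init__(self) -> None:
        assert abs(self.api - self.reri / self.or11) < 1e-9
        if self.s_defined:
            denom = (self.or10 - 1.0) + (self.or01 - 1.0)
            assert abs(self.s - (self.or11 - 1.0) / denom) < 1e-9

    @property
    def significant_additive(self) -> bool:
        return significance_rule(self)


@dataclass
class MultiplicativeInteractionResult:
    """Product-term odds ratio from the multiplicative interaction model."""

    or_product_term: OddsRatioResult
    fit: LogisticFit


def _joint_indicators(
    table: CohortTable, snp: str, exposure: str
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    g = table.encode_genotype(snp, "dominant")
    if exposure not in table.data.columns:
        raise ConfigurationError(f"exposure {exposure!r} not in cohort")
    e = table.data[exposure].astype(float)
    levels = set(e.dropna().unique())
    if not levels <= {0.0, 1.0}:
        raise ConfigurationError(f"exposure {exposure!r} must be binary 0/1")
    ok = g.notna() & e.notna()
    ind = pd.DataFrame(
        {
            "g_only": ((g == 1) & (e == 0)).astype(float),
            "e_only": ((g == 0) & (e == 1)).astype(float),
            "joint": ((g == 1) & (e == 1)).astype(float),
        },
        index=table.data.index,
    )
    ind[~ok] = np.nan
    return ind, g, e


def fit_joint_exposure_model(
    table: CohortTable,
    snp: str,
    exposure: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> JointExposureModel:
    """Fit the four-category joint SNP-carrier x exposure logistic model."""
    ind, g, e = _joint_indicators(table, snp, exposure)
    ok = ind.notna().all(axis=1)
    cells = pd.crosstab(
        [g[ok], e[ok]], table.data.loc[ok, "status"], dropna=False
    )
    for (gv, ev) in ((0, 0), (1, 0), (0, 1), (1, 1)):
        if (gv, ev) not in cells.index or (cells.loc[(gv, ev)] == 0).any():
            raise NonEstimableError(
                f"joint category (carrier={gv}, {exposure}={ev}) is empty "
                "in cases or controls"
            )
    covar_df = table.data[list(covariates)] if covariates else None
    design = pd.concat([ind, covar_df], axis=1) if covariates else ind
    fit = fit_logistic(table.status, design)
    counts = cells.rename(columns={0: "controls", 1: "cases"})
    return JointExposureModel(
        snp=snp,
        exposure=exposure,
        fit=fit,
        covariates=tuple(covariates) if covariates else (),
        category_counts=counts,
    )


def multiplicative_interaction_test(
    table: CohortTable,
    snp: str,
    exposure: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> MultiplicativeInteractionResult:
    """Wald test of the SNP-carrier x exposure product term."""
    _, g, e = _joint_indicators(table, snp, exposure)
    design = pd.DataFrame(
        {"carrier": g, "exposure": e, "carrier_x_exposure": g * e},
        index=table.data.index,
    )
    if covariates:
        design = pd.concat([design, table.data[list(covariates)]], axis=1)
    fit = fit_logistic(table.status, design)
    or_term = fit.odds_ratio(
        "carrier_x_exposure",
        f"{snp} x {exposure} product term",
        tuple(covariates) if covariates else (),
    )
    return MultiplicativeInteractionResult(or_product_term=or_term, fit=fit)


# -- additive interaction ---------------------------------------------------


def additive_interaction_from_log_ors(
    b: Sequence[float], cov: np.ndarray | None = None
) -> AdditiveInteractionResult:
    """RERI/API/S from log odds ratios (b1, b2, b3), CIs if ``cov`` given.

    Delta-method gradients: RERI has (-e^b1, -e^b2, e^b3); API is computed
    as 1 - (e^b1 + e^b2 - 1) e^{-b3}; ln S has
    (-e^b1/(e^b1+e^b2-2), -e^b2/(e^b1+e^b2-2), e^b3/(e^b3-1)).
    """
    b1, b2, b3 = (float(v) for v in b)
    o10, o01, o11 = np.exp([b1, b2, b3])
    reri = o11 - o10 - o01 + 1.0
    api = reri / o11
    s_denom = (o10 - 1.0) + (o01 - 1.0)
    s_defined = s_denom != 0.0
    s = (o11 - 1.0) / s_denom if s_denom != 0.0 else float("nan")

    reri_ci = api_ci = s_ci = None
    if cov is not None:
        cov = np.asarray(cov, dtype=float)
        grad_reri = np.array([-o10, -o01, o11])
        se_reri = float(np.sqrt(grad_reri @ cov @ grad_reri))
        reri_ci = (reri - Z_95 * se_reri, reri + Z_95 * se_reri)
        grad_api = np.array(
            [-o10 / o11, -o01 / o11, (o10 + o01 - 1.0) / o11]
        )
        se_api = float(np.sqrt(grad_api @ cov @ grad_api))
        api_ci = (api - Z_95 * se_api, api + Z_95 * se_api)
        if s_defined and s > 0:
            grad_ln_s = np.array(
                [-o10 / s_denom, -o01 / s_denom, o11 / (o11 - 1.0)]
            )
            se_ln_s = float(np.sqrt(grad_ln_s @ cov @ grad_ln_s))
            s_ci = (
                float(s * np.exp(-Z_95 * se_ln_s)),
                float(s * np.exp(Z_95 * se_ln_s)),
            )
    return AdditiveInteractionResult(
        or10=float(o10),
        or01=float(o01),
        or11=float(o11),
        reri=float(reri),
        api=float(api),
        s=float(s),
        reri_ci=reri_ci,
        api_ci=api_ci,
        s_ci=s_ci,
        s_defined=bool(s_defined),
    )


def additive_interaction_from_ors(
    or10: float, or01: float, or11: float
) -> AdditiveInteractionResult:
    """Point estimates of RERI/API/S from published odds ratios (no CIs)."""
    if min(or10, or01, or11) <= 0:
        raise ConfigurationError("odds ratios must be positive")
    return additive_interaction_from_log_ors(np.log([or10, or01, or11]))


def additive_interaction(model: JointExposureModel) -> AdditiveInteractionResult:
    """RERI/API/S with delta-method 95% CIs from a fitted joint model."""
    return additive_interaction_from_log_ors(model.log_ors, model.cov3)


def significance_rule(result: AdditiveInteractionResult) -> bool:
    """Additive interaction declared iff 0 is outside the RERI and API CIs
    and 1 is outside the S CI (closed-interval containment).

    When S is undefined the rule falls back to RERI and API alone.
    """
    if result.reri_ci is None or result.api_ci is None:
        raise ConfigurationError("confidence intervals required for the rule")

    def excludes(ci: tuple[float, float], value: float) -> bool:
        return not (ci[0] <= value <= ci[1])

    decision = excludes(result.reri_ci, 0.0) and excludes(result.api_ci, 0.0)
    if result.s_defined and result.s_ci is not None:
        decision = decision and excludes(result.s_ci, 1.0)
    return decision
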