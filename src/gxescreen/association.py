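"""Single-SNP association analysis for case-control cohorts.

Covers the genotype-level workflow of a candidate-gene study: the
Hardy-Weinberg equilibrium chi-square in controls (a genotyping-quality
check), crude 2x2 odds ratios with Woolf (log-OR Wald) confidence
intervals, and crude/covariate-adjusted unconditional logistic regression
under codominant and carrier (dominant) genotype codings.

Maximum-likelihood logistic fits are delegated to statsmodels behind
:func:`fit_logistic`, which adds rank and separation diagnostics and a
uniform result container used by the GMDR and interaction stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import DEFAULT_COVARIATES, CohortTable
from .descriptives import TestResult
from .errors import (
    CollinearityError,
    NonEstimableError,
    ParameterError,
    SeparationError,
    UndefinedStatisticError,
)

Z_95 = 1.959964  # two-sided 95% normal multiplier


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype count triple for one SNP in one group."""

    snp: str
    group: str  # "cases" or "controls"
    n_hom_risk: int
    n_het: int
    n_hom_other: int

    def __post_init__(self) -> None:
        if min(self.n_hom_risk, self.n_het, self.n_hom_other) < 0:
            raise ParameterError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_risk + self.n_het + self.n_hom_other

    @property
    def risk_allele_freq(self) -> float:
        if self.n == 0:
            raise UndefinedStatisticError("no genotyped subjects")
        return (2 * self.n_hom_risk + self.n_het) / (2 * self.n)


@dataclass(frozen=True)
class OddsRatioResult:
    """One odds-ratio contrast with its Wald CI and p-value."""

    comparison: str
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool = False
    covariates: tuple[str, ...] = ()
    zero_cell_corrected: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError(
                f"inconsistent OR/CI: {self.or_point} in "
                f"({self.ci_low}, {self.ci_high})"
            )
        if self.adjusted != bool(self.covariates):
            raise ValueError("adjusted flag must match covariate list")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit.

    ``params`` holds log-odds coefficients indexed by term name,
    ``cov`` the corresponding covariance (inverse observed information).
    """

    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    n_used: int
    iterations: int
    llf: float = float("nan")

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def odds_ratio(
        self, term: str, comparison: str | None = None,
        covariates: Sequence[str] = (),
    ) -> OddsRatioResult:
        """Exponentiated coefficient with Wald CI and two-sided p."""
        b = self.params[term]
        se = self.se()[term]
        z = b / se
        return OddsRatioResult(
            comparison=comparison or term,
            or_point=float(np.exp(b)),
            ci_low=float(np.exp(b - Z_95 * se)),
            ci_high=float(np.exp(b + Z_95 * se)),
            p_value=float(2 * stats.norm.sf(abs(z))),
            adjusted=bool(covariates),
            covariates=tuple(covariates),
        )


# -- Hardy-Weinberg ---------------------------------------------------------


def hwe_chi2_test(counts: GenotypeCounts) -> TestResult:
    """Pearson goodness-of-fit chi-square for Hardy-Weinberg equilibrium.

    The allele frequency is estimated from the observed counts; expected
    genotype counts are (n*p^2, 2*n*p*q, n*q^2); the statistic has one
    degree of freedom (three classes, one estimated parameter) and no
    continuity correction is applied.
    """
    n = counts.n
    if n == 0:
        raise UndefinedStatisticError("no genotyped subjects")
    p = counts.risk_allele_freq
    if p in (0.0, 1.0):
        raise UndefinedStatisticError(
            f"{counts.snp} is monomorphic in {counts.group}; HWE test undefined"
        )
    q = 1.0 - p
    observed = np.array([counts.n_hom_risk, counts.n_het, counts.n_hom_other], float)
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return TestResult(chi2, 1.0, float(stats.chi2.sf(chi2, 1)), "HWE chi-square (df=1)")


def genotype_counts(table: CohortTable, snp: str, group: str) -> GenotypeCounts:
    """Tally genotype counts for one SNP in cases or controls."""
    info = table._require_snp(snp)
    status = {"controls": 0, "cases": 1}[group]
    sub = table.data.loc[table.data["status"] == status, snp].dropna()
    ref_hom, het, risk_hom = info.genotype_strings()
    vc = sub.value_counts()
    return GenotypeCounts(
        snp=snp,
        group=group,
        n_hom_risk=int(vc.get(risk_hom, 0)),
        n_het=int(vc.get(het, 0)),
        n_hom_other=int(vc.get(ref_hom, 0)),
    )


# -- crude odds ratios ------------------------------------------------------


def crude_or_2x2(
    exposed_cases: float,
    unexposed_cases: float,
    exposed_controls: float,
    unexposed_controls: float,
    comparison: str = "exposed vs unexposed",
) -> OddsRatioResult:
    """Cross-product odds ratio with Woolf (log-OR Wald) 95% CI.

    If any cell is zero the Haldane-Anscombe correction (+0.5 to every
    cell) is applied and flagged in the result.  With both cells of a
    diagonal zero the OR is not estimable.
    """
    a, b, c, d = (
        float(exposed_cases),
        float(unexposed_cases),
        float(exposed_controls),
        float(unexposed_controls),
    )
    if min(a, b, c, d) < 0:
        raise ParameterError("cell counts must be non-negative")
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        raise NonEstimableError("both cells of a diagonal are zero")
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        comparison=comparison,
        or_point=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z_95 * se)),
        ci_high=float(np.exp(log_or + Z_95 * se)),
        p_value=float(2 * stats.norm.sf(abs(log_or / se))),
        zero_cell_corrected=corrected,
    )


# -- logistic regression ----------------------------------------------------


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank == X.shape[1]:
        return
    # name a minimal set of columns whose removal restores full rank
    suspects = []
    cols = list(X.columns)
    for i in range(len(cols)):
        reduced = np.delete(mat, i, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            suspects.append(cols[i])
    raise CollinearityError(
        f"design matrix rank {rank} < {X.shape[1]} columns; "
        f"collinear terms include {suspects or cols}"
    )


def fit_logistic(
    outcome: Sequence[int] | pd.Series,
    design: pd.DataFrame,
    add_intercept: bool = True,
) -> LogisticFit:
    """Fit a binary logistic regression by maximum likelihood.

    Rows with any missing value in the outcome or design are dropped
    (complete-case).  The fit uses Newton-Raphson iteratively reweighted
    least squares; the covariance is the inverse observed information.

    Raises
    ------
    SeparationError
        If the outcome is perfectly (or quasi-) separated so the MLE
        diverges.
    CollinearityError
        If the design is rank deficient, naming the collinear terms.
    NonEstimableError
        If the outcome has only one class after dropping incomplete rows.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), index=design.index)
    X = design.astype(float)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X.loc[keep]
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    if y.nunique() < 2:
        raise NonEstimableError("outcome has a single class after row dropping")
    _check_rank(X)
    model = sm.Logit(y, X)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=200, warn_convergence=False)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = pd.Series(res.params, index=X.columns)
    if not np.isfinite(params).all() or np.abs(params).max() > 30:
        raise SeparationError(
            "diverging coefficients suggest separation: "
            f"max |beta| = {np.abs(params).max():.1f}"
        )
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return LogisticFit(
        params=params,
        cov=cov,
        converged=bool(res.mle_retvals.get("converged", True)),
        n_used=int(len(y)),
        iterations=int(res.mle_retvals.get("iterations", -1)),
        llf=float(res.llf),
    )


# -- per-SNP association report --------------------------------------------


@dataclass
class SnpAssociation:
    """Crude and adjusted contrasts for one SNP, Table-2 style."""

    snp: str
    counts: dict[str, GenotypeCounts]
    hwe_controls: TestResult
    contrasts: list[OddsRatioResult] = field(default_factory=list)
    n_dropped: dict[str, int] = field(default_factory=dict)


def genotype_association(
    table: CohortTable,
    snp: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> SnpAssociation:
    """Full single-SNP association analysis.

    Emits the codominant contrasts (het vs reference homozygote, risk
    homozygote vs reference) from one three-level model and the carrier
    contrast (dominant coding) from a second model, each both crude and
    adjusted for ``covariates`` (pass an empty list to get crude-only
    semantics: adjusted output then equals the crude output).
    """
    info = table._require_snp(snp)
    counts = {g: genotype_counts(table, snp, g) for g in ("controls", "cases")}
    hwe = hwe_chi2_test(counts["controls"])

    additive = table.encode_genotype(snp, "additive")
    het = (additive == 1).astype(float).where(additive.notna())
    hom = (additive == 2).astype(float).where(additive.notna())
    carrier = table.encode_genotype(snp, "dominant")
    y = table.status

    ref_hom, het_gt, risk_hom = info.genotype_strings()
    labels = {
        "het": f"{het_gt} vs {ref_hom}",
        "hom": f"{risk_hom} vs {ref_hom}",
        "carrier": f"{risk_hom}/{het_gt} vs {ref_hom}",
    }
    covar_df = table.data[list(covariates)] if covariates else pd.DataFrame(
        index=table.data.index
    )

    result = SnpAssociation(snp=snp, counts=counts, hwe_controls=hwe)
    for adjusted in (False, True):
        extra = covar_df if adjusted else covar_df.iloc[:, :0]
        used = tuple(covariates) if adjusted and len(covariates) else ()
        codominant = pd.concat(
            [het.rename("het"), hom.rename("hom"), extra], axis=1
        )
        fit_cod = fit_logistic(y, codominant)
        result.contrasts.append(fit_cod.odds_ratio("het", labels["het"], used))
        result.contrasts.append(fit_cod.odds_ratio("hom", labels["hom"], used))
        dominant = pd.concat([carrier.rename("carrier"), extra], axis=1)
        fit_dom = fit_logistic(y, dominant)
        result.contrasts.append(
            fit_dom.odds_ratio("carrier", labels["carrier"], used)
        )
        key = "adjusted" if adjusted else "crude"
        result.n_dropped[key] = int(len(table) - fit_cod.n_used)
    return result
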