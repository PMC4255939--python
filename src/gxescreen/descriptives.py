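"""Group comparisons for the baseline-characteristics table.

Continuous variables are compared between cases and controls with the
unequal-variance (Welch/Satterthwaite) two-sample t-test, categorical
variables with Pearson's chi-square without continuity correction; both
choices reproduce the printed statistics of the study this package
re-implements (the pooled-variance t and the Yates correction are available
behind flags).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BINARY_FLAGS, CohortTable
from .errors import ConfigurationError, DegenerateTableError, UndefinedStatisticError


@dataclass(frozen=True)
class TestResult:
    """Generic statistic / degrees-of-freedom / p-value container."""

    statistic: float
    df: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def format_p(p: float, decimals: int = 4) -> str:
    """Format a p-value to fixed decimals, with ``<.0001``-style flooring."""
    floor = 10.0 ** (-decimals)
    if np.isnan(p):
        return "NA"
    if p < floor:
        return "<" + f"{floor:.{decimals}f}".lstrip("0")
    return f"{p:.{decimals}f}"


def welch_t_test_from_stats(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    pooled: bool = False,
) -> TestResult:
    """Two-sample t-test from summary moments.

    The default is the unequal-variance Welch statistic with Satterthwaite
    degrees of freedom; ``pooled=True`` gives the classical equal-variance
    form.  The statistic is signed as group1 minus group2.
    """
    if n1 < 2 or n2 < 2:
        raise UndefinedStatisticError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise UndefinedStatisticError("standard deviations must be non-negative")
    v1, v2 = sd1**2, sd2**2
    if v1 == 0 and v2 == 0:
        if mean1 == mean2:
            raise UndefinedStatisticError("zero variance in both groups")
        raise UndefinedStatisticError("zero variance with unequal means")
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
        method = "Student t (pooled)"
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        method = "Welch t (Satterthwaite df)"
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), method)


def welch_t_test(
    x: Sequence[float], y: Sequence[float], pooled: bool = False
) -> TestResult:
    """Two-sample t-test from raw value sequences (NaNs dropped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise UndefinedStatisticError("each group needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        raise UndefinedStatisticError("zero variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=pooled)
    method = "Student t (pooled)" if pooled else "Welch t (Satterthwaite df)"
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), method)


def pearson_chi2(table: Sequence[Sequence[float]], yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default; set ``yates=True`` for the Yates
    correction (2x2 only, as in scipy).
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise DegenerateTableError("need at least a 2x2 table")
    if (observed < 0).any():
        raise DegenerateTableError("counts must be non-negative")
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(observed, correction=yates)
    method = "Pearson chi-square" + (" (Yates)" if yates else "")
    return TestResult(float(chi2), float(dof), float(p), method)


# -- baseline characteristics table ----------------------------------------

#: (variable, kind) layout mirroring the study's baseline table
DEFAULT_TABLE1_VARIABLES: tuple[tuple[str, str], ...] = (
    ("age", "continuous"),
    ("bmi", "continuous"),
    ("sex", "categorical"),
    ("ethnicity", "categorical"),
    ("smoking", "categorical"),
    ("drinking", "categorical"),
    ("t2dm", "categorical"),
    ("hypertension", "categorical"),
    ("hyperlipidemia", "categorical"),
)


def build_table1(
    table: CohortTable,
    variables: Sequence[tuple[str, str]] = DEFAULT_TABLE1_VARIABLES,
) -> pd.DataFrame:
    """Per-variable case/control comparison (mean+-SD or %, test, p).

    Each variable is analysed complete-case; the number of subjects dropped
    for missingness is reported per row.  A variable that cannot be tested
    (all missing, or a constant) is flagged ``not computable`` and the rest
    of the table is still produced.
    """
    df = table.data
    if table.n_cases == 0 or table.n_controls == 0:
        raise DegenerateTableError("both cases and controls are required")
    rows = []
    for name, kind in variables:
        if name not in df.columns:
            raise ConfigurationError(
                f"variable {name!r} not in cohort; available: "
                f"{sorted(c for c in df.columns if c not in ('subject_id',))}"
            )
        values = df[name]
        ok = values.notna()
        dropped = int((~ok).sum())
        ctrl = values[ok & (df["status"] == 0)]
        case = values[ok & (df["status"] == 1)]
        row: dict[str, object] = {
            "variable": name,
            "kind": kind,
            "n_dropped": dropped,
        }
        try:
            if kind == "continuous":
                row["controls"] = f"{ctrl.mean():.2f} ± {ctrl.std(ddof=1):.2f}"
                row["cases"] = f"{case.mean():.2f} ± {case.std(ddof=1):.2f}"
                res = welch_t_test(ctrl.to_numpy(), case.to_numpy())
            elif kind == "categorical":
                counts = pd.crosstab(df.loc[ok, "status"], values[ok])
                if counts.shape[0] < 2 or counts.shape[1] < 2:
                    raise DegenerateTableError("fewer than two levels observed")
                pct = counts.div(counts.sum(axis=1), axis=0) * 100
                row["controls"] = " / ".join(
                    f"{level}: {pct.loc[0, level]:.2f}%" for level in counts.columns
                )
                row["cases"] = " / ".join(
                    f"{level}: {pct.loc[1, level]:.2f}%" for level in counts.columns
                )
                res = pearson_chi2(counts.to_numpy())
            else:
                raise ConfigurationError(f"unknown variable kind {kind!r}")
        except (DegenerateTableError, UndefinedStatisticError) as exc:
            row.update(
                statistic=np.nan, df=np.nan, p_value=np.nan,
                p_formatted="NA", note=f"not computable: {exc}",
            )
            rows.append(row)
            continue
        row.update(
            statistic=res.statistic,
            df=res.df,
            p_value=res.p_value,
            p_formatted=format_p(res.p_value),
            note="",
        )
        rows.append(row)
    return pd.DataFrame(rows)
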