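"""Two-group comparison tables for lesion cohorts.

Reproduces the reporting conventions of clinical baseline/lesion tables:
continuous variables as "mean ± SD" compared by a two-sample t-test when a
Shapiro–Wilk screen accepts normality in both groups, otherwise as
"median (IQR)" compared by the Mann–Whitney U-test; categorical variables
as "n (%)" compared by the Pearson chi-square test without continuity
correction; p-values printed to three decimals, "<0.001" below that.

The central objects follow the statsmodels idiom:
``TwoGroupComparison(frame_a, frame_b, variables).fit()`` returns a
:class:`ComparisonResults` whose ``summary()`` is a formatted table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonRow",
    "ComparisonResults",
    "TwoGroupComparison",
    "summary_t_test",
    "chi_square_2x2",
    "mann_whitney",
    "build_comparison_table",
    "format_p",
]

STUDENT_T, WELCH_T, MANN_WHITNEY, CHI_SQUARE = (
    "student_t",
    "welch_t",
    "mann_whitney",
    "chi_square",
)


def summary_t_test(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    variant: str = "student",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics: (t, df, two-sided p).

    ``student`` pools the variances (df = n_a + n_b - 2); ``welch`` uses the
    Welch–Satterthwaite degrees of freedom.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    equal_var = {"student": True, "welch": False}.get(variant)
    if equal_var is None:
        raise ValueError(f"unknown variant {variant!r}")
    t, p = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var
    )
    if equal_var:
        df = float(n_a + n_b - 2)
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(t), float(df), float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, WITHOUT continuity correction.

    Rows are groups, columns outcome: [[a, b], [c, d]].  df = 1, two-sided.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined for a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def mann_whitney(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U-test: exact for small untied samples,
    normal approximation with tie correction otherwise."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if np.array_equal(np.sort(a), np.sort(b)):
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def format_p(p: Optional[float]) -> str:
    if p is None or np.isnan(p):
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class ComparisonRow:
    """One table row: formatted summaries, the test used, and its p-value."""

    variable: str
    group_a_summary: str
    group_b_summary: str
    test_used: Optional[str]
    statistic: Optional[float]
    p_value: Optional[float]

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must be in [0, 1]")


def _fmt_mean_sd(x: np.ndarray, decimals: int) -> str:
    return f"{np.mean(x):.{decimals}f} ± {np.std(x, ddof=1):.{decimals}f}"


def _fmt_median_iqr(x: np.ndarray, decimals: int) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.{decimals}f} ({q1:.{decimals}f}–{q3:.{decimals}f})"


def _fmt_n_pct(x: np.ndarray) -> str:
    n = int(np.sum(x))
    return f"{n} ({100.0 * n / x.size:.1f})"


def _continuous_row(
    name: str, a: np.ndarray, b: np.ndarray, alpha: float, decimals: int
) -> ComparisonRow:
    normal = True
    for x in (a, b):
        if x.size >= 3 and np.ptp(x) > 0:
            if sps.shapiro(x).pvalue < alpha:
                normal = False
        elif np.ptp(x) == 0:
            normal = False
    if normal:
        t, p = sps.ttest_ind(a, b, equal_var=True)
        if np.isnan(t):
            t, p = 0.0, 1.0
        return ComparisonRow(
            name, _fmt_mean_sd(a, decimals), _fmt_mean_sd(b, decimals),
            STUDENT_T, float(t), float(p),
        )
    u, p = mann_whitney(a, b)
    return ComparisonRow(
        name, _fmt_median_iqr(a, decimals), _fmt_median_iqr(b, decimals),
        MANN_WHITNEY, u, p,
    )


def _categorical_row(name: str, a: np.ndarray, b: np.ndarray) -> ComparisonRow:
    row = ComparisonRow(name, _fmt_n_pct(a), _fmt_n_pct(b), CHI_SQUARE, None, None)
    try:
        chi2, p = chi_square_2x2(
            int(np.sum(a)), int(a.size - np.sum(a)),
            int(np.sum(b)), int(b.size - np.sum(b)),
        )
        row.statistic, row.p_value = chi2, p
    except ValueError:
        pass  # degenerate margin: summaries reported, p left missing
    return row


def build_comparison_table(
    frame_a: pd.DataFrame,
    frame_b: pd.DataFrame,
    variables: Sequence[tuple[str, str] | tuple[str, str, int]],
    alpha: float = 0.05,
) -> list[ComparisonRow]:
    """Comparison rows for the given variables.

    ``variables`` lists (column, kind[, decimals]) with kind "continuous"
    or "binary".  Continuous variables are screened for normality
    (Shapiro–Wilk at ``alpha`` in each group) to choose t-test vs
    Mann–Whitney; binary variables use the chi-square test.  Variables with
    no non-missing values in a group yield a row with a missing p-value.
    """
    rows: list[ComparisonRow] = []
    for spec in variables:
        name, kind = spec[0], spec[1]
        decimals = spec[2] if len(spec) > 2 else 2
        a = frame_a[name].dropna().to_numpy(dtype=float)
        b = frame_b[name].dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            rows.append(ComparisonRow(name, "", "", None, None, None))
        elif kind == "binary":
            rows.append(_categorical_row(name, a, b))
        elif kind == "continuous":
            rows.append(_continuous_row(name, a, b, alpha, decimals))
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
    return rows


class ComparisonResults:
    """Fitted two-group comparison; ``summary()`` renders the table."""

    def __init__(self, rows: list[ComparisonRow], labels: tuple[str, str]):
        self.rows = rows
        self.labels = labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": [r.variable for r in self.rows],
                self.labels[0]: [r.group_a_summary for r in self.rows],
                self.labels[1]: [r.group_b_summary for r in self.rows],
                "test": [r.test_used or "" for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
                "p": [format_p(r.p_value) for r in self.rows],
            }
        )

    def summary(self) -> str:
        df = self.to_frame().drop(columns=["p_value"])
        return df.to_string(index=False)

    def significant(self, alpha: float = 0.05) -> list[str]:
        return [
            r.variable
            for r in self.rows
            if r.p_value is not None and r.p_value < alpha
        ]


class TwoGroupComparison:
    """Model object for a two-cohort comparison table.

    Parameters
    ----------
    frame_a, frame_b : DataFrame
        One row per lesion/patient, one column per variable.
    variables : sequence of (name, kind[, decimals])
        Table layout; kind is "continuous" or "binary".
    labels : pair of str
        Column headers for the two groups.
    """

    def __init__(
        self,
        frame_a: pd.DataFrame,
        frame_b: pd.DataFrame,
        variables: Sequence[tuple] | None = None,
        labels: tuple[str, str] = ("group A", "group B"),
        alpha: float = 0.05,
    ):
        self.frame_a = frame_a
        self.frame_b = frame_b
        if variables is None:
            variables = [
                (c, "binary" if set(pd.concat([frame_a[c], frame_b[c]]).dropna().unique())
                 <= {0, 1, True, False} else "continuous")
                for c in frame_a.columns
                if c in frame_b.columns and pd.api.types.is_numeric_dtype(frame_a[c])
            ]
        self.variables = list(variables)
        self.labels = labels
        self.alpha = alpha

    def fit(self) -> ComparisonResults:
        rows = build_comparison_table(
            self.frame_a, self.frame_b, self.variables, self.alpha
        )
        return ComparisonResults(rows, self.labels)
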