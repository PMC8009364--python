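"""Linear models on yearly category proportions.

The study's descriptive questions ("is autumn higher than summer?", "does
Friday stand out?") are answered by ordinary least squares on the per-year
category proportions of a :class:`~chronocollide.classify.FrequencyTable`,
with one of two contrast codings:

* successive-difference coding — each coefficient estimates the difference
  between adjacent category means (summer-spring, autumn-summer, ...) and
  the intercept the grand mean of category means, which for proportions is
  exactly 1/k;
* treatment coding — the intercept is the reference category's mean and
  each coefficient a category-minus-reference difference.

Both codings span the same column space, so fitted values, residuals and
R^2 are identical; only the parameterization differs.  A Tukey HSD post hoc
(studentized-range family-wise adjustment) with a compact letter display,
and a Shapiro-Wilk residual normality check, complete the surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .classify import FrequencyTable

__all__ = [
    "CategoryContrastModel",
    "CategoryContrastResults",
    "TukeyResult",
    "tukey_hsd",
    "compact_letter_display",
    "normality_check",
]


def _as_proportions(freq) -> pd.DataFrame:
    if isinstance(freq, FrequencyTable):
        props = freq.proportions
    elif isinstance(freq, pd.DataFrame):
        props = freq
    else:
        raise TypeError("expected a FrequencyTable or a categories-by-years DataFrame")
    if props.isna().any().any():
        missing = [
            (cat, year)
            for cat in props.index
            for year in props.columns
            if pd.isna(props.loc[cat, year])
        ]
        raise ValueError(f"unbalanced table; missing cells: {missing}")
    if props.shape[0] < 2 or props.shape[1] < 2:
        raise ValueError("need at least 2 categories and 2 replicate years")
    return props


def _successive_contrast_matrix(k: int) -> np.ndarray:
    """Backward-difference coding: coefficient j = mean(j+1) - mean(j)."""
    mat = np.zeros((k, k - 1))
    for j in range(1, k):  # contrast j: level j+1 vs level j (1-based)
        mat[:j, j - 1] = -(k - j) / k
        mat[j:, j - 1] = j / k
    return mat


class CategoryContrastModel:
    """OLS of within-year proportions on a categorical temporal label.

    Parameters
    ----------
    freq : FrequencyTable or DataFrame
        Categories-by-years proportions; each year is one replicate.
    coding : {"successive", "treatment"}
    reference : str, optional
        Reference category (treatment coding only; defaults to the first).
    """

    def __init__(self, freq, coding: str = "successive", reference: str | None = None):
        self.proportions = _as_proportions(freq)
        self.categories = list(self.proportions.index)
        self.years = list(self.proportions.columns)
        if coding not in ("successive", "treatment"):
            raise ValueError(f"unknown coding {coding!r}")
        self.coding = coding
        if coding == "treatment":
            reference = reference if reference is not None else self.categories[0]
            if reference not in self.categories:
                raise ValueError(f"reference {reference!r} not among categories")
        self.reference = reference

    @classmethod
    def from_frequency_table(cls, freq: FrequencyTable, **kwargs) -> "CategoryContrastModel":
        return cls(freq, **kwargs)

    # -- design ----------------------------------------------------------
    def _design(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        k = len(self.categories)
        if self.coding == "successive":
            coding = _successive_contrast_matrix(k)
            names = [
                f"{self.categories[j + 1]}-{self.categories[j]}" for j in range(k - 1)
            ]
        else:
            ref = self.categories.index(self.reference)
            coding = np.zeros((k, k - 1))
            others = [i for i in range(k) if i != ref]
            for col, i in enumerate(others):
                coding[i, col] = 1.0
            names = [self.categories[i] for i in others]
        level_idx = np.repeat(np.arange(k), len(self.years))
        X = np.column_stack([np.ones(k * len(self.years)), coding[level_idx]])
        y = self.proportions.to_numpy().reshape(-1)  # category-major order
        return X, y, ["Intercept"] + names

    def fit(self) -> "CategoryContrastResults":
        X, y, names = self._design()
        ols = sm.OLS(y, X).fit()
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.asarray(ols.tvalues)
        return CategoryContrastResults(
            model=self,
            params=pd.Series(ols.params, index=names),
            bse=pd.Series(ols.bse, index=names),
            tvalues=pd.Series(tvals, index=names),
            pvalues=pd.Series(ols.pvalues, index=names),
            fittedvalues=np.asarray(ols.fittedvalues),
            resid=np.asarray(ols.resid),
            df_resid=int(ols.df_resid),
            rsquared=float(ols.rsquared),
            sigma2=float(ols.mse_resid),
        )


@dataclass
class CategoryContrastResults:
    """Estimates and diagnostics of a fitted :class:`CategoryContrastModel`."""

    model: CategoryContrastModel
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fittedvalues: np.ndarray
    resid: np.ndarray
    df_resid: int
    rsquared: float
    sigma2: float

    def normality(self) -> tuple[float, float]:
        """Shapiro-Wilk (W, p) of the residuals."""
        return normality_check(self.resid)

    def tukey_hsd(self, alpha: float = 0.05) -> "TukeyResult":
        """All-pairs Tukey HSD on the category means, with letters."""
        return tukey_hsd(self.model.proportions, alpha=alpha)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: Estimate, SE, t-value, p."""
        return pd.DataFrame(
            {
                "Estimate": self.params,
                "SE": self.bse,
                "t-value": self.tvalues,
                "p": self.pvalues,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        w, p = self.normality()
        return (
            f"<CategoryContrastResults coding={self.model.coding!r} "
            f"R2={self.rsquared:.3f} shapiro_p={p:.3f}>\n{self.summary().round(4)}"
        )


# ---------------------------------------------------------------------------
# Tukey HSD and compact letter display


@dataclass
class TukeyResult:
    """All-pairs comparisons with family-wise adjusted p and letters.

    Two groups share a letter iff their adjusted p >= alpha.
    """

    comparisons: pd.DataFrame  # group1, group2, diff, p_adj, significant
    letters: dict[str, str]
    alpha: float

    def summary(self) -> pd.DataFrame:
        return self.comparisons


def tukey_hsd(freq, alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD over category means of a proportions table.

    The standard error uses the one-way residual mean square (within-
    category, across-year variance) and the studentized-range distribution
    with k groups and n-k residual degrees of freedom.  With zero residual
    variance every non-identical pair is reported significant with p = 0.
    """
    props = _as_proportions(freq)
    cats = list(props.index)
    k, r = props.shape
    means = props.mean(axis=1)
    resid = props.sub(means, axis=0).to_numpy()
    df = k * (r - 1)
    mse = float((resid**2).sum()) / df
    se = np.sqrt(mse / r)
    rows = []
    sig_pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means.iloc[j] - means.iloc[i]
            if se > 0:
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df))
            else:
                p_adj = 0.0 if diff != 0 else 1.0
            significant = p_adj < alpha
            if significant:
                sig_pairs.append((cats[i], cats[j]))
            rows.append(
                {
                    "group1": cats[i],
                    "group2": cats[j],
                    "diff": diff,
                    "p_adj": p_adj,
                    "significant": significant,
                }
            )
    letters = compact_letter_display(cats, sig_pairs)
    return TukeyResult(comparisons=pd.DataFrame(rows), letters=letters, alpha=alpha)


def compact_letter_display(
    groups: list[str], significant_pairs: list[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    Starts from one letter covering all groups; each significant pair splits
    every letter containing both; letters that become subsets of others are
    absorbed.  Ties are broken by group order.
    """
    columns: list[set[str]] = [set(groups)]
    for a, b in significant_pairs:
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb duplicates/subsets, keeping first occurrence
        kept: list[set[str]] = []
        for col in columns:
            if not any(col <= other for other in kept):
                kept = [c for c in kept if not c < col] + [col]
        columns = kept
    # order letters by the first group they contain
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(order[g] for g in c) if c else len(order))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in groups:
            if g in col:
                out[g] += letter
    return out


def normality_check(residuals) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) for 3 <= n <= 5000 residuals."""
    resid = np.asarray(residuals, dtype=float)
    if not 3 <= resid.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3..5000 observations, got {resid.size}")
    if np.ptp(resid) == 0:
        raise ValueError("residuals are constant; normality test undefined")
    w, p = stats.shapiro(resid)
    return float(w), float(p)
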