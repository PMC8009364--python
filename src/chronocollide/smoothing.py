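"""Penalized cyclic cubic regression-spline smoothing.

The annual and lunar accident cycles are estimated with a Gaussian additive
model: counts per (year x cell) — cells are day-of-year 1..365 or moon day
1..29 — regressed on a smooth, periodic function of the cell position,

    min_{alpha, beta}  || y - alpha - B beta ||^2  +  lambda beta' S beta,

where B is a cyclic cubic regression-spline basis (value, first- and
second-derivative continuity across the period seam) parameterized by the
function values at k-1 distinct knots, S the integrated-squared-second-
derivative penalty, and lambda chosen by generalized cross-validation
(GCV) on a log-spaced grid with golden-section refinement.  A sum-to-zero
constraint over the observed covariate values identifies the smooth
against the intercept, leaving k-2 free smooth coefficients (so the
nominal basis dimension k = 10 gives a reference df of 8).

The effective degrees of freedom (edf) of the smooth is the trace of its
influence matrix; "deviance explained" is 1 - RSS/TSS.  Pointwise 95%
bands use the Bayesian posterior covariance of the penalized coefficients,
and the horizontal-line test asks whether any constant function fits
entirely inside the bands — if not, the smooth is non-flat at the 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cyclic_basis",
    "CyclicSmoother",
    "CyclicSmootherResults",
    "horizontal_line_test",
]


def cyclic_knots(k: int, period: float) -> np.ndarray:
    """Evenly spaced distinct knots for nominal basis dimension ``k``.

    ``k`` counts the wrapped knot sequence over one full period (both
    endpoints), so there are ``k - 1`` distinct knots and coefficients.
    """
    if k < 4:
        raise ValueError("need k >= 4 basis functions")
    return np.linspace(0.0, period, k)[:-1]


def cyclic_basis(
    x: np.ndarray, knots: np.ndarray, period: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic cubic regression-spline design and penalty matrices.

    Parameters
    ----------
    x : array
        Covariate values; wrapped into one period internally.
    knots : array
        Strictly increasing distinct knot positions within one period.
    period : float
        The cycle length; ``knots[0] + period`` is identified with
        ``knots[0]``.

    Returns
    -------
    X : (len(x), n) design matrix, n = len(knots); coefficient j is the
        spline's value at knot j.
    S : (n, n) penalty, the integrated squared second derivative; symmetric
        positive semidefinite with the constant function in its null space.

    The construction is the classical value/second-derivative
    parameterization of a periodic cubic spline: continuity conditions give
    a cyclic tridiagonal system ``B m = D g`` linking knot values ``g`` to
    knot second derivatives ``m``, whence ``S = D' B^{-1} D`` and piecewise
    cubic interpolation rows.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 3:
        raise ValueError("need at least 3 distinct knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing and distinct")
    if knots[-1] - knots[0] >= period:
        raise ValueError("knots must span less than one period")
    n = len(knots)
    h = np.empty(n)
    h[:-1] = np.diff(knots)
    h[-1] = knots[0] + period - knots[-1]

    B = np.zeros((n, n))
    D = np.zeros((n, n))
    for j in range(n):
        jm, jp = (j - 1) % n, (j + 1) % n
        B[j, j] = (h[jm] + h[j]) / 3.0
        B[j, jp] += h[j] / 6.0
        B[j, jm] += h[jm] / 6.0
        D[j, j] = -(1.0 / h[jm] + 1.0 / h[j])
        D[j, jp] += 1.0 / h[j]
        D[j, jm] += 1.0 / h[jm]
    F = np.linalg.solve(B, D)  # maps knot values to knot second derivatives
    S = D.T @ F
    S = 0.5 * (S + S.T)

    xw = knots[0] + np.mod(np.asarray(x, dtype=float) - knots[0], period)
    # interval index: largest j with knots[j] <= xw
    idx = np.searchsorted(knots, xw, side="right") - 1
    idx = np.clip(idx, 0, n - 1)
    upper = np.where(idx == n - 1, knots[0] + period, knots[(idx + 1) % n])
    hj = h[idx]
    d_lo = xw - knots[idx]
    d_hi = upper - xw
    a_lo = d_hi / hj
    a_hi = d_lo / hj
    c_lo = (d_hi**3 / hj - hj * d_hi) / 6.0
    c_hi = (d_lo**3 / hj - hj * d_lo) / 6.0

    X = np.zeros((len(xw), n))
    rows = np.arange(len(xw))
    np.add.at(X, (rows, idx), a_lo)
    np.add.at(X, (rows, (idx + 1) % n), a_hi)
    X += c_lo[:, None] * F[idx, :] + c_hi[:, None] * F[(idx + 1) % n, :]
    return X, S


class CyclicSmoother:
    """Gaussian cyclic-spline smoother of a periodic covariate.

    Parameters
    ----------
    x, y : arrays
        Covariate (any real values; wrapped modulo ``period``) and response.
    k : int
        Nominal basis dimension (default 10): k-1 distinct knots, k-2 free
        coefficients after the centering constraint.
    period : float
        Cycle length of the covariate.
    """

    def __init__(self, x, y, k: int = 10, period: float = 365.0):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        self.k = int(k)
        self.period = float(period)
        self.knots = cyclic_knots(self.k, self.period)
        if len(self.x) < len(self.knots):
            raise ValueError("need more observations than basis functions")
        self._X, self._S = cyclic_basis(self.x, self.knots, self.period)
        # sum-to-zero constraint over the data: c'beta = 0
        c = self._X.sum(axis=0)
        _, _, vt = np.linalg.svd(c[None, :])
        self._Z = vt[1:].T  # (n, n-1) null-space basis of c
        self._Xz = self._X @ self._Z
        Sz = self._Z.T @ self._S @ self._Z
        # penalty square root in the constrained space (Sz is PD there)
        svals, U = np.linalg.eigh(0.5 * (Sz + Sz.T))
        svals = np.maximum(svals, svals[-1] * 1e-12)
        self._T = U / np.sqrt(svals)  # reparameterization: penalty -> identity
        Xt = self._Xz @ self._T
        self._P, self._d, qt = np.linalg.svd(Xt, full_matrices=False)
        self._Q = qt.T

    @classmethod
    def from_counts(
        cls,
        annotated: pd.DataFrame,
        by: str,
        period: float | None = None,
        k: int = 10,
        year_col: str = "year",
    ) -> "CyclicSmoother":
        """Counts per (year x cell) from an annotated record table.

        Cells are the integers 1..period of column ``by`` (``day_of_year``
        with period 365, or ``moon_day`` with period 29 once day 30 is
        dropped); cells a year never hit contribute zero counts.
        """
        if period is None:
            period = {"day_of_year": 365.0, "moon_day": 29.0}.get(by)
            if period is None:
                raise ValueError(f"no default period for column {by!r}; pass period=")
        cells = np.arange(1, int(period) + 1)
        labels = annotated[by]
        valid = labels.notna()
        sub = annotated.loc[valid, [year_col, by]].astype({by: int})
        xs, ys = [], []
        for _, grp in sub.groupby(year_col):
            counts = grp[by].value_counts().reindex(cells, fill_value=0)
            xs.append(cells.astype(float))
            ys.append(counts.to_numpy(dtype=float))
        return cls(np.concatenate(xs), np.concatenate(ys), k=k, period=period)

    # -- fitting ---------------------------------------------------------
    def _rss_edf(self, lam: float, z: np.ndarray, yc2: float) -> tuple[float, float]:
        f = self._d**2 / (self._d**2 + lam) if np.isfinite(lam) else np.zeros_like(self._d)
        rss = yc2 - float((z**2 * (2 * f - f**2)).sum())
        return max(rss, 0.0), float(f.sum())

    def _gcv(self, lam: float, z: np.ndarray, yc2: float, n: int) -> float:
        rss, edf = self._rss_edf(lam, z, yc2)
        return n * rss / (n - (1.0 + edf)) ** 2

    def fit(self, lam: float | None = None) -> "CyclicSmootherResults":
        """Fit the penalized smoother; ``lam=None`` selects lambda by GCV."""
        n = len(self.y)
        alpha = float(self.y.mean())
        yc = self.y - alpha
        z = self._P.T @ yc
        yc2 = float(yc @ yc)
        if lam is None:
            d2max = float(self._d.max() ** 2) if self._d.size else 1.0
            grid = np.logspace(np.log10(d2max) - 12, np.log10(d2max) + 12, 121)
            scores = [self._gcv(g, z, yc2, n) for g in grid]
            i = int(np.argmin(scores))
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, len(grid) - 1)]
            lam = _golden_min(lambda L: self._gcv(np.exp(L), z, yc2, n),
                              np.log(lo), np.log(hi))
            lam = float(np.exp(lam))
        lam = float(lam)
        if lam < 0:
            raise ValueError("lambda must be nonnegative")

        rss, edf = self._rss_edf(lam, z, yc2)
        if np.isfinite(lam):
            shrink = self._d / (self._d**2 + lam)
            beta_t = self._Q @ (shrink * z)
        else:
            beta_t = np.zeros(self._Q.shape[0])
        beta = self._Z @ (self._T @ beta_t)
        edf_total = 1.0 + edf
        sigma2 = rss / max(n - edf_total, 1e-8)
        # Bayesian posterior covariance of the constrained coefficients
        if np.isfinite(lam):
            inv = self._Q @ ((1.0 / (self._d**2 + lam))[:, None] * self._Q.T)
        else:
            inv = np.zeros((self._Q.shape[0], self._Q.shape[0]))
        Vb = self._Z @ (self._T @ inv @ self._T.T) @ self._Z.T * sigma2

        tss = yc2
        dev_expl = 1.0 - rss / tss if tss > 0 else 0.0
        df2 = n - 1.0 - edf
        if edf > 1e-8 and rss > 0 and df2 > 0:
            fstat = ((tss - rss) / edf) / (rss / df2)
            pval = float(stats.f.sf(fstat, edf, df2))
        else:
            fstat, pval = np.nan, np.nan
        return CyclicSmootherResults(
            model=self,
            alpha=alpha,
            beta=beta,
            lambda_=lam,
            edf=edf,
            ref_df=self.k - 2,
            sigma2=sigma2,
            rss=rss,
            tss=tss,
            deviance_explained=dev_expl,
            f_statistic=fstat,
            p_value=pval,
            cov_beta=Vb,
        )


def _golden_min(fn, a: float, b: float, tol: float = 1e-4) -> float:
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = fn(c), fn(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = fn(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = fn(d)
    return 0.5 * (a + b)


@dataclass
class CyclicSmootherResults:
    """Fitted cyclic smoother: coefficients, smoothness, bands, tests."""

    model: CyclicSmoother
    alpha: float
    beta: np.ndarray
    lambda_: float
    edf: float
    ref_df: int
    sigma2: float
    rss: float
    tss: float
    deviance_explained: float
    f_statistic: float
    p_value: float
    cov_beta: np.ndarray = field(repr=False)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.alpha + self.model._X @ self.beta

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    def smooth(self, grid) -> np.ndarray:
        """Smooth-term contribution s(x) on arbitrary positions."""
        Xg, _ = cyclic_basis(np.asarray(grid, dtype=float), self.model.knots, self.model.period)
        return Xg @ self.beta

    def bands(self, grid, level: float = 0.95) -> pd.DataFrame:
        """Pointwise confidence bands of the smooth contribution."""
        grid = np.asarray(grid, dtype=float)
        Xg, _ = cyclic_basis(grid, self.model.knots, self.model.period)
        fit = Xg @ self.beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, self.cov_beta, Xg), 0.0))
        zq = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {"grid": grid, "fit": fit, "se": se,
             "lower": fit - zq * se, "upper": fit + zq * se}
        )

    def horizontal_line_test(self, n_grid: int = 200, level: float = 0.95) -> bool:
        """True iff no horizontal line fits inside the pointwise bands —
        a formal nonlinearity test at 1 - level."""
        return horizontal_line_test(self, n_grid=n_grid, level=level)

    def peak_location(self, n_grid: int = 2000) -> float:
        """Covariate position where the fitted smooth is maximal."""
        grid = np.linspace(0.0, self.model.period, n_grid, endpoint=False)
        return float(grid[np.argmax(self.smooth(grid))])

    def summary(self) -> dict:
        return {
            "k": self.model.k,
            "period": self.model.period,
            "lambda": self.lambda_,
            "edf": round(self.edf, 3),
            "ref_df": self.ref_df,
            "f_statistic": None if np.isnan(self.f_statistic) else round(self.f_statistic, 3),
            "p_value": None if np.isnan(self.p_value) else self.p_value,
            "deviance_explained": round(self.deviance_explained, 4),
            "horizontal_line_rejected": self.horizontal_line_test(),
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CyclicSmootherResults edf={self.edf:.3f} ref_df={self.ref_df} "
            f"lambda={self.lambda_:.3g} dev_expl={self.deviance_explained:.3f}>"
        )


def horizontal_line_test(
    result: CyclicSmootherResults, n_grid: int = 200, level: float = 0.95
) -> bool:
    """Whether every horizontal line escapes the pointwise bands somewhere.

    Evaluated on ``n_grid`` (>= 100) equally spaced positions: a constant c
    fits iff lower(x) <= c <= upper(x) for all x, which is possible iff
    max(lower) <= min(upper).
    """
    if n_grid < 100:
        raise ValueError("use a grid of at least 100 points")
    grid = np.linspace(0.0, result.model.period, n_grid, endpoint=False)
    b = result.bands(grid, level=level)
    return bool(b["lower"].max() > b["upper"].min())
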