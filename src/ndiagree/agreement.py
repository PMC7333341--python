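"""Pairwise method-agreement statistics for score comparisons.

Implements the classical Bland-Altman analysis (mean difference ``d``, SD
of differences, 95% limits of agreement ``d +/- 1.96*SD``), a one-sample t
test of the mean difference, the Wilcoxon signed-rank test, a
regression-based limits-of-agreement variant for proportional bias (OLS of
differences on averages, band ``b1*A + b0 +/- 1.96*SD_res``), and simple
normality diagnostics for the differences.

Sign convention: for a pair ``(a, b)`` the differences are ``D = a - b``
and the averages ``A = (a + b)/2``; the first-listed method is the
reference, so a negative ``d`` means method *b* scores systematically
higher.

:class:`BlandAltman` and :class:`RegressionLoA` are scikit-learn style
estimators (``fit`` + trailing-underscore attributes); the module-level
functions wrap them and return frozen result dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "PairedScores",
    "BAStats",
    "RegLoA",
    "WilcoxonResult",
    "NormalitySummary",
    "differences_and_means",
    "bland_altman",
    "one_sample_t",
    "wilcoxon_signed_rank",
    "exact_signed_rank_p",
    "regression_loa",
    "normality_summary",
    "apply_bias_transform",
    "BlandAltman",
    "RegressionLoA",
]

Z_DEFAULT = 1.96  # conventional 95% limits-of-agreement multiplier


@dataclass(frozen=True)
class PairedScores:
    """Two score sequences for the same subjects, pairing preserved by position."""

    method_a: str
    method_b: str
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or b.ndim != 1:
            raise ValueError("paired scores must be one-dimensional")
        if len(a) != len(b):
            raise ValueError(
                f"{self.method_a} vs {self.method_b}: length mismatch "
                f"({len(a)} vs {len(b)})"
            )
        if len(a) < 2:
            raise ValueError("paired comparison needs at least 2 subjects")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n(self) -> int:
        return len(self.a)

    @property
    def label(self) -> str:
        return f"{self.method_a} vs. {self.method_b}"

    def swapped(self) -> "PairedScores":
        return PairedScores(self.method_b, self.method_a, self.b, self.a)


def _as_pair(pair, b=None) -> PairedScores:
    if isinstance(pair, PairedScores):
        return pair
    return PairedScores("A", "B", np.asarray(pair, dtype=float),
                        np.asarray(b, dtype=float))


def differences_and_means(pair: PairedScores, b=None) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise differences ``D = a - b`` and averages ``A = (a + b)/2``."""
    p = _as_pair(pair, b)
    return p.a - p.b, (p.a + p.b) / 2.0


@dataclass(frozen=True)
class BAStats:
    """Bland-Altman summary for one method pair.

    ``loa_lower/loa_upper`` are the 95% limits of agreement
    ``d -/+ z*sd``; ``ci_low/ci_high`` bound the mean difference itself;
    ``t_stat/p_value`` test ``d = 0``.  ``degenerate`` flags sd == 0, in
    which case the t statistic is undefined (NaN).
    """

    comparison: str
    n: int
    df: int
    d: float
    sd: float
    se: float
    ci_low: float
    ci_high: float
    loa_lower: float
    loa_upper: float
    z: float
    t_stat: float
    p_value: float
    degenerate: bool = False

    @classmethod
    def from_summary(cls, d: float, sd: float, n: int, z: float = Z_DEFAULT,
                     comparison: str = "summary") -> "BAStats":
        """Reconstruct LoA, SE, CI and t from printed summary statistics.

        Useful for auditing a published agreement table when only ``d``,
        ``sd`` and ``n`` are reported.
        """
        if n < 2:
            raise ValueError("need n >= 2")
        se = sd / np.sqrt(n)
        degenerate = sd == 0
        if degenerate:
            t = float("nan")
            p = float("nan")
        else:
            t = d / se
            p = 2.0 * stats.t.sf(abs(t), n - 1)
        return cls(
            comparison=comparison, n=n, df=n - 1, d=d, sd=sd, se=se,
            ci_low=d - z * se, ci_high=d + z * se,
            loa_lower=d - z * sd, loa_upper=d + z * sd,
            z=z, t_stat=t, p_value=p, degenerate=degenerate,
        )


class BlandAltman(BaseEstimator):
    """Bland-Altman agreement estimator.

    Parameters
    ----------
    z : float, default 1.96
        Limits-of-agreement multiplier (``d +/- z*sd``).
    ci_method : {"z", "t"}, default "z"
        Quantile used for the 95% CI of the mean difference.  ``"z"`` uses
        the fixed 1.96 normal quantile; ``"t"`` uses the t(n-1) quantile
        (differences only matter at small n).

    Fitted attributes (all per the ``D = a - b`` convention): ``n_``,
    ``df_``, ``d_``, ``sd_``, ``se_``, ``ci_low_``, ``ci_high_``,
    ``loa_lower_``, ``loa_upper_``, ``t_stat_``, ``p_value_``,
    ``degenerate_``.
    """

    def __init__(self, z: float = Z_DEFAULT, ci_method: str = "z"):
        self.z = z
        self.ci_method = ci_method

    def fit(self, a, b) -> "BlandAltman":
        pair = _as_pair(a, b)
        if self.ci_method not in ("z", "t"):
            raise ValueError("ci_method must be 'z' or 't'")
        d = pair.a - pair.b
        n = pair.n
        self.n_ = n
        self.df_ = n - 1
        self.d_ = float(np.mean(d))
        self.sd_ = float(np.std(d, ddof=1))  # sample SD, n-1 denominator
        self.se_ = self.sd_ / np.sqrt(n)
        self.degenerate_ = self.sd_ == 0.0
        if self.degenerate_:
            self.t_stat_ = float("nan")
            self.p_value_ = float("nan")
        else:
            self.t_stat_ = self.d_ / self.se_
            self.p_value_ = float(2.0 * stats.t.sf(abs(self.t_stat_), self.df_))
        q = self.z if self.ci_method == "z" else float(stats.t.ppf(0.975, self.df_))
        self.ci_low_ = self.d_ - q * self.se_
        self.ci_high_ = self.d_ + q * self.se_
        self.loa_lower_ = self.d_ - self.z * self.sd_
        self.loa_upper_ = self.d_ + self.z * self.sd_
        self.comparison_ = pair.label
        return self

    def summary(self) -> BAStats:
        return BAStats(
            comparison=self.comparison_, n=self.n_, df=self.df_, d=self.d_,
            sd=self.sd_, se=self.se_, ci_low=self.ci_low_, ci_high=self.ci_high_,
            loa_lower=self.loa_lower_, loa_upper=self.loa_upper_, z=self.z,
            t_stat=self.t_stat_, p_value=self.p_value_, degenerate=self.degenerate_,
        )


def bland_altman(pair: PairedScores, b=None, z: float = Z_DEFAULT,
                 ci_method: str = "z") -> BAStats:
    """Full Bland-Altman summary (see :class:`BlandAltman`)."""
    return BlandAltman(z=z, ci_method=ci_method).fit(_as_pair(pair, b), None).summary()


def one_sample_t(D: Sequence[float], ci_method: str = "z"
                 ) -> tuple[float, int, float, tuple[float, float]]:
    """One-sample t test of ``mean(D) = 0``.

    Returns ``(t, df, p, (ci_low, ci_high))`` with a 95% CI of the mean
    built from the 1.96 normal quantile by default (``ci_method="t"``
    switches to the t quantile).
    """
    d = np.asarray(D, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need n >= 2")
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: zero variance")
    se = sd / np.sqrt(n)
    m = float(np.mean(d))
    t = m / se
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    q = Z_DEFAULT if ci_method == "z" else float(stats.t.ppf(0.975, df))
    return float(t), df, p, (m - q * se, m + q * se)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test result; ``w_statistic = min(W+, W-)``."""

    w_statistic: float
    n_effective: int
    p_value: float
    method: str  # "exact" | "normal-approximation" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ over all 2^n equiprobable sign assignments.

    Dynamic programme on the subset-sum distribution of the ranks.  Ranks
    are doubled so midranks (ties) become integers; exact with or without
    ties, feasible for n up to ~25.
    """
    r2 = np.rint(2 * np.asarray(ranks, dtype=float)).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r or None]
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    lower = counts[: w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def exact_signed_rank_p(D: Sequence[float]) -> float:
    """Exact two-sided signed-rank p for the nonzero differences in *D*."""
    d = np.asarray(D, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    return _signed_rank_exact_p(ranks, float(ranks[d > 0].sum()))


def wilcoxon_signed_rank(pair: PairedScores, b=None, *,
                         zero_method: str = "wilcox",
                         mode: str = "auto",
                         exact_threshold: int = 20) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped before ranking (Wilcoxon's original
    rule; ``zero_method="pratt"`` keeps them in the ranking and then
    discards their ranks).  Absolute differences are ranked with midranks
    for ties and ``W = min(W+, W-)``.

    ``mode="auto"`` uses the exact sign-flip distribution when the number
    of nonzero differences is at most ``exact_threshold`` and there are no
    ties, otherwise a normal approximation with tie correction and a 0.5
    continuity correction.  ``mode="exact"`` forces exact enumeration
    (valid with ties via doubled midranks); ``mode="approx"`` forces the
    approximation.
    """
    p = _as_pair(pair, b)
    d = p.a - p.b
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    if zero_method == "wilcox":
        nz = d[d != 0]
        ranks_all = stats.rankdata(np.abs(nz))
        ranks = ranks_all
        signs = np.sign(nz)
    else:
        ranks_all = stats.rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        signs = np.sign(d[keep])
    n_eff = int(len(ranks))
    if n_eff == 0:
        return WilcoxonResult(0.0, 0, 1.0, "degenerate")
    w_plus = float(ranks[signs > 0].sum())
    w_minus = float(ranks[signs < 0].sum())
    w = min(w_plus, w_minus)
    has_ties = len(np.unique(ranks_all)) < len(ranks_all)
    if mode == "auto":
        mode = "exact" if (n_eff <= exact_threshold and not has_ties) else "approx"
    if mode == "exact":
        p_value = _signed_rank_exact_p(ranks, w_plus)
        return WilcoxonResult(w, n_eff, p_value, "exact")
    # normal approximation with continuity correction; Var(W+) = sum(r^2)/4
    # under independent sign flips, which equals the textbook
    # n(n+1)(2n+1)/24 - tie-correction form when midranks are used
    mu = ranks.sum() / 2.0
    var = float((ranks ** 2).sum()) / 4.0
    if var == 0:
        return WilcoxonResult(w, n_eff, 1.0, "degenerate")
    num = w_plus - mu
    num -= 0.5 * np.sign(num)  # continuity correction
    z = num / np.sqrt(var)
    p_value = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(w, n_eff, p_value, "normal-approximation")


# ---------------------------------------------------------------------------
# Regression-based limits of agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegLoA:
    """OLS fit of differences on averages: ``D = b1*A + b0``, band ``+/- z*sd_res``."""

    b1: float
    b0: float
    sd_res: float
    model_p: float
    z: float = Z_DEFAULT

    def loa_band(self, A) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``(lower, center, upper)`` of the regression LoA band at averages *A*."""
        A = np.asarray(A, dtype=float)
        center = self.b1 * A + self.b0
        half = self.z * self.sd_res
        return center - half, center, center + half


class RegressionLoA(BaseEstimator):
    """Regression-based limits of agreement for magnitude-dependent bias.

    Ordinary least squares of the differences ``D = a - b`` on the
    averages ``A = (a + b)/2``; residual SD uses the n-2 denominator; the
    band is the fitted line ``+/- z*sd_res``.

    Fitted attributes: ``slope_`` (b1), ``intercept_`` (b0), ``sd_res_``,
    ``model_p_`` (overall F-test p), ``n_``.
    """

    def __init__(self, z: float = Z_DEFAULT):
        self.z = z

    def fit(self, a, b) -> "RegressionLoA":
        pair = _as_pair(a, b)
        D, A = differences_and_means(pair)
        if pair.n < 3:
            raise ValueError("regression LoA needs n >= 3")
        if np.ptp(A) == 0:
            raise ValueError("averages are constant: slope undefined")
        res = sm.OLS(D, sm.add_constant(A)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.sd_res_ = float(np.sqrt(res.ssr / (pair.n - 2)))
        self.model_p_ = float(res.f_pvalue)
        self.n_ = pair.n
        return self

    def summary(self) -> RegLoA:
        return RegLoA(b1=self.slope_, b0=self.intercept_, sd_res=self.sd_res_,
                      model_p=self.model_p_, z=self.z)


def regression_loa(pair: PairedScores, b=None, z: float = Z_DEFAULT) -> RegLoA:
    """Fit the regression-based limits of agreement (see :class:`RegressionLoA`)."""
    return RegressionLoA(z=z).fit(_as_pair(pair, b), None).summary()


# ---------------------------------------------------------------------------
# Normality diagnostics and bias transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalitySummary:
    """Histogram plus moment-based shape diagnostics of the differences."""

    bin_edges: np.ndarray
    counts: np.ndarray
    skewness: float
    excess_kurtosis: float
    zero_variance: bool = False


def normality_summary(D: Sequence[float], bins: int = 10) -> NormalitySummary:
    """Histogram, sample skewness and excess kurtosis of the differences."""
    d = np.asarray(D, dtype=float)
    if len(d) < 2:
        raise ValueError("need n >= 2")
    counts, edges = np.histogram(d, bins=bins)
    if np.std(d) == 0:
        return NormalitySummary(edges, counts, float("nan"), float("nan"),
                                zero_variance=True)
    return NormalitySummary(edges, counts,
                            float(stats.skew(d)),
                            float(stats.kurtosis(d)))


@dataclass(frozen=True)
class TransformedScores:
    """Transformed score copy with a label describing the transform for plots."""

    values: np.ndarray
    label: str


def apply_bias_transform(scores, kind: str = "log", *, offset: float = 1.0,
                         scale: float = 1.0) -> TransformedScores:
    """Apply a log or linear transform to scores (bias-normalisation attempt).

    ``kind="log"`` computes ``log(x + offset)`` (default offset 1 admits
    zero scores); ``kind="linear"`` computes ``(x + offset) * scale``.
    """
    x = np.asarray(scores, dtype=float)
    if kind == "log":
        shifted = x + offset
        if np.any(shifted <= 0):
            bad = float(x[shifted <= 0][0])
            raise ValueError(
                f"log transform undefined for score {bad} with offset {offset}"
            )
        return TransformedScores(np.log(shifted), f"log(x + {offset:g})")
    if kind == "linear":
        return TransformedScores((x + offset) * scale,
                                 f"(x + {offset:g}) * {scale:g}")
    raise ValueError("kind must be 'log' or 'linear'")
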