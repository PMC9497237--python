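"""Group comparison and reproducibility statistics.

Covers the statistical layer of a perfusion-reserve study: Welch's
unpaired t-test from group summaries, the Wilcoxon rank-sum test (exact by
enumeration for small samples, tie-corrected normal approximation
otherwise), Bland-Altman agreement with a within-subject coefficient of
variation, ICC(2,1) absolute-agreement reliability with an F-based 95% CI,
and percent-change summaries for hemodynamic response.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, ParameterError

EXACT_WILCOXON_MAX_N = 20


@dataclass
class GroupSummary:
    """Descriptive summary of one group of a continuous measure."""

    label: str
    n: int
    mean: float
    sd: float
    median: float
    iqr: tuple[float, float]

    @classmethod
    def from_samples(cls, x, label: str = "") -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        if x.size < 1:
            raise ParameterError("empty sample")
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return cls(
            label=label, n=int(x.size), mean=float(x.mean()),
            sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
            median=float(med), iqr=(float(q1), float(q3)),
        )


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


def welch_ttest(
    group1, group2, *, summaries: bool = False
) -> TTestResult:
    """Welch's unpaired two-sided t-test.

    ``group1``/``group2`` are raw samples, or ``(mean, sd, n)`` triples when
    ``summaries=True`` (raw samples are reduced to summaries first, so both
    entry points agree exactly).
    """
    if summaries:
        (m1, s1, n1), (m2, s2, n2) = group1, group2
    else:
        g1 = GroupSummary.from_samples(group1)
        g2 = GroupSummary.from_samples(group2)
        m1, s1, n1 = g1.mean, g1.sd, g1.n
        m2, s2, n2 = g2.mean, g2.sd, g2.n
    if n1 < 2 or n2 < 2:
        raise ParameterError("each group needs n >= 2")
    if s1 <= 0 and s2 <= 0:
        raise DegenerateDataError("both groups have zero variance")
    v1, v2 = s1 * s1 / n1, s2 * s2 / n2
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


@dataclass
class RankSumResult:
    w: float  # rank sum of the first sample (midranks)
    p: float
    method: str  # "exact" or "normal"


def wilcoxon_rank_sum(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    For total n <= 20 the p-value is exact: the rank-sum distribution is
    enumerated over all C(n, n_x) group assignments of the observed
    (mid)ranks, and p = min(1, 2*min(P(W <= w), P(W >= w))).  Larger
    samples use the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ParameterError("each sample needs n >= 1")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all values identical in both groups")
    nx, n = x.size, pooled.size
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[:nx].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        lo = hi = total = 0
        for comb in combinations(range(n), nx):
            w = ranks[list(comb)].sum()
            total += 1
            if w <= w_obs + 1e-9:
                lo += 1
            if w >= w_obs - 1e-9:
                hi += 1
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return RankSumResult(w=w_obs, p=float(p), method="exact")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankSumResult(w=w_obs, p=float(res.pvalue), method="normal")


@dataclass
class AgreementResult:
    """Bland-Altman agreement of paired measurements, optionally with ICC."""

    n: int
    bias: float
    sd_diff: float
    loa: tuple[float, float]  # bias +/- 1.96 * SD of differences
    cov_percent: float  # 100 * (SD(d)/sqrt(2)) / grand mean
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None


def bland_altman(x, y, with_icc: bool = True) -> AgreementResult:
    """Agreement between two raters/readings of the same subjects.

    Differences d = x - y give the bias (mean), the 95% limits of agreement
    (bias +/- 1.96 * sample SD of d), and a within-subject coefficient of
    variation COV = 100 * (SD(d)/sqrt(2)) / grand mean of all measurements.
    ICC(2,1) is attached when at least 5 pairs are available.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1D paired arrays")
    n = x.size
    if n < 2:
        raise ParameterError("need at least 2 complete pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    grand = float(np.concatenate([x, y]).mean())
    cov = 100.0 * (sd / math.sqrt(2.0)) / grand if grand != 0 else float("nan")
    icc = ci = None
    if with_icc and n >= 5:
        icc, ci = icc_absolute(np.column_stack([x, y]))
    return AgreementResult(
        n=n, bias=bias, sd_diff=sd,
        loa=(bias - 1.96 * sd, bias + 1.96 * sd),
        cov_percent=cov, icc=icc, icc_ci=ci,
    )


def icc_absolute(ratings: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a complete subjects x raters matrix.  The estimate comes
    from the mean squares of the two-way ANOVA (rows = subjects, columns =
    raters); the confidence interval is the standard F-based interval with
    a Satterthwaite denominator df.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 5 or m.shape[1] < 2:
        raise ParameterError("need a complete matrix with >= 5 subjects and >= 2 raters")
    if np.isnan(m).any():
        raise ParameterError("missing cells are not supported")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)  # between subjects
    msc = ss_cols / (k - 1)  # between raters
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= mse * 1e-12 or ss_rows <= 0:
        warnings.warn("zero between-subject variance; ICC set to 0", stacklevel=2)
        return 0.0, (0.0, 0.0)
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if 1.0 - icc < 1e-12:  # perfect agreement: CI collapses
        return float(icc), (float(icc), float(icc))

    # F-based CI (two-way random, absolute agreement, single measurement)
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_low = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return float(icc), (float(lower), float(upper))


def percent_change(baseline, peak):
    """Percent rise from baseline: 100 * (peak - baseline) / baseline."""
    baseline = np.asarray(baseline, dtype=float)
    peak = np.asarray(peak, dtype=float)
    if np.any(baseline <= 0):
        raise ParameterError("baseline values must be positive")
    out = 100.0 * (peak - baseline) / baseline
    return float(out) if out.ndim == 0 else out


def cohort_percent_change(baselines, peaks) -> tuple[float, float]:
    """Per-subject percent change summarized as cohort (mean, SD)."""
    pc = percent_change(baselines, peaks)
    pc = np.atleast_1d(pc)
    return float(pc.mean()), float(pc.std(ddof=1)) if pc.size > 1 else 0.0


def bland_altman_plot(x, y, path, title: str = "Bland-Altman"):
    """Write a Bland-Altman scatter (mean vs difference) with bias and LoA."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(x, y, with_icc=False)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2.0, x - y, s=18)
    ax.axhline(res.bias, color="k", lw=1, label=f"bias {res.bias:.3f}")
    for v in res.loa:
        ax.axhline(v, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    ax.set_title(f"{title} (COV {res.cov_percent:.1f}%)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res
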