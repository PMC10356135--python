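"""Downstream statistics: qPCR normalization, outlier screening, trends,
group comparisons, decay half-lives and the bespoke single-cell summaries.

Conventions: percentiles interpolate linearly between order statistics;
Grubbs' test is applied iteratively, two-sided, at alpha per round; the
Wilcoxon rank-sum test uses the exact null for small tie-free samples and
the tie/continuity-corrected normal approximation otherwise; half-lives
come from an ordinary least-squares fit of log level against time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "relative_expression",
    "grubbs_exclude",
    "timeseries_slope",
    "GroupTestReport",
    "group_tests",
    "HalfLifeFit",
    "fit_half_life",
    "off_fraction",
    "percentile_exceedance",
    "tail_histogram",
]

LN2 = float(np.log(2.0))


def relative_expression(target, pp2a, ubc):
    """Expression relative to the housekeeping index (geometric mean of PP2A and UBC)."""
    target, pp2a, ubc = (np.asarray(v, dtype=float) for v in (target, pp2a, ubc))
    if np.any(target <= 0) or np.any(pp2a <= 0) or np.any(ubc <= 0):
        raise ValueError("abundances must be positive")
    out = target / np.sqrt(pp2a * ubc)
    return float(out) if out.ndim == 0 else out


def _grubbs_critical(n: int, alpha: float) -> float:
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_exclude(values, alpha: float = 0.05) -> tuple[np.ndarray, list[int]]:
    """Iterated two-sided Grubbs outlier screen.

    Each round tests the point with the largest absolute deviation from the
    mean against the Grubbs critical value; exclusion repeats until the test
    is no longer significant or fewer than 3 points remain. Returns the
    retained values and the original indices of the excluded points.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        warnings.warn("Grubbs' test needs n >= 3; returning data unchanged", stacklevel=2)
        return values.copy(), []
    keep = np.arange(values.size)
    excluded: list[int] = []
    while keep.size >= 3:
        v = values[keep]
        sd = v.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(v - v.mean())
        i = int(np.argmax(dev))
        if dev[i] / sd > _grubbs_critical(keep.size, alpha):
            excluded.append(int(keep[i]))
            keep = np.delete(keep, i)
        else:
            break
    return values[keep], excluded


def timeseries_slope(time_d, y) -> tuple[float, float]:
    """OLS slope per day with its two-sided t-test p-value."""
    time_d = np.asarray(time_d, dtype=float)
    y = np.asarray(y, dtype=float)
    if time_d.size < 3 or np.unique(time_d).size < 2:
        raise ValueError("need >= 3 points at >= 2 distinct times")
    res = sps.linregress(time_d, y)
    return float(res.slope), float(res.pvalue)


@dataclass
class GroupTestReport:
    """Omnibus and pairwise comparisons across groups of per-cell values."""

    kruskal_h: float
    kruskal_p: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p_raw, p_bonferroni
    anova_f: float | None = None
    anova_p: float | None = None
    tukey: pd.DataFrame | None = None


def _ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if max(a.size, b.size) <= 20 and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def group_tests(groups: dict[str, np.ndarray], parametric: bool = True) -> GroupTestReport:
    """Kruskal-Wallis omnibus plus Bonferroni-adjusted pairwise rank-sum tests.

    With ``parametric=True`` (the qPCR use-case) a one-way ANOVA F test and
    Tukey HSD post-hoc comparisons are included as well. Bonferroni
    adjustment multiplies each raw p-value by the number of pairs, capped
    at 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {k!r} is empty")
    if all(np.array_equal(arrays[names[0]], arrays[k]) for k in names):
        h, p = 0.0, 1.0  # identical groups: scipy raises on all-tied input
    else:
        h, p = sps.kruskal(*arrays.values())
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        stat, praw = _ranksum(arrays[a], arrays[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": stat,
                "p_raw": praw,
                "p_bonferroni": min(1.0, praw * len(pairs)),
            }
        )
    report = GroupTestReport(kruskal_h=float(h), kruskal_p=float(p), pairwise=pd.DataFrame(rows))
    if parametric:
        f, ap = sps.f_oneway(*arrays.values())
        report.anova_f, report.anova_p = float(f), float(ap)
        tk = sps.tukey_hsd(*arrays.values())
        trows = []
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if j <= i:
                    continue
                trows.append(
                    {
                        "group_a": a,
                        "group_b": b,
                        "mean_diff": float(np.mean(arrays[a]) - np.mean(arrays[b])),
                        "p_adj": float(tk.pvalue[i, j]),
                    }
                )
        report.tukey = pd.DataFrame(trows)
    return report


@dataclass(frozen=True)
class HalfLifeFit:
    half_life_h: float
    slope_per_h: float
    p_value: float
    sign_violation: bool  # True when the fitted trend is non-decaying


def fit_half_life(time_h, level) -> HalfLifeFit:
    """Half-life from an OLS fit of ln(level) against time (hours)."""
    time_h = np.asarray(time_h, dtype=float)
    level = np.asarray(level, dtype=float)
    if np.any(level <= 0):
        raise ValueError("levels must be positive for a log-linear decay fit")
    if time_h.size < 3:
        raise ValueError("need >= 3 timepoints")
    res = sps.linregress(time_h, np.log(level))
    slope = float(res.slope)
    return HalfLifeFit(
        half_life_h=float(LN2 / abs(slope)) if slope != 0 else float("inf"),
        slope_per_h=slope,
        p_value=float(res.pvalue),
        sign_violation=slope >= 0,
    )


def off_fraction(counts, threshold: int = 3) -> float:
    """Fraction of cells without appreciable expression (counts <= threshold)."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty counts")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return float((counts <= threshold).mean())


def percentile_exceedance(a, b, q: float = 95.0) -> float:
    """Fraction of ``a`` strictly above the q-th percentile of ``b``.

    The percentile interpolates linearly between order statistics.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float((a > np.percentile(b, q)).mean())


def tail_histogram(
    intensities, cutoff: float = 1.0, bins: int | np.ndarray = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the ON-cell tail above an intensity cutoff.

    Only values strictly above ``cutoff`` enter; the histogram is normalized
    by the number of tail cells so masses sum to 1 and sub-cutoff mass is
    irrelevant. Returns ``(fractions, edges)``; an empty tail yields an
    empty histogram with a warning.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("empty intensity vector")
    tail = x[x > cutoff]
    if tail.size == 0:
        warnings.warn("no values above the tail cutoff; empty histogram", stacklevel=2)
        return np.empty(0), np.empty(0)
    counts, edges = np.histogram(tail, bins=bins)
    return counts / tail.size, edges
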