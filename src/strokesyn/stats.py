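"""Assumption-gated group comparisons.

Normality (Shapiro-Wilk, per sample) and homoscedasticity (Levene, across
samples) are tested at alpha = 0.05; only when every gate passes are
parametric tests (t-tests) used, otherwise rank tests (Mann-Whitney U,
Wilcoxon signed-rank).  Two-way comparisons under violated assumptions use
the Scheirer-Ray-Hare extension of Kruskal-Wallis, implemented here because
no mainstream Python stack ships it: a two-way ANOVA decomposition on
mid-ranks, with each effect's H = SS_effect / MS_total referred to a
chi-square at the effect's degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

ALPHA_GATE = 0.05


@dataclass
class GateRecord:
    shapiro_p: list
    levene_p: Optional[float]
    parametric: bool
    forced_nonparametric: bool = False


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    gate: Optional[GateRecord] = None
    df: Optional[int] = None
    note: str = ""


def assumption_gate(samples: Sequence[np.ndarray], alpha: float = ALPHA_GATE) -> GateRecord:
    """Decide parametric vs nonparametric for a set of samples.

    Parametric requires every sample to pass Shapiro-Wilk AND a single
    Levene test across samples, all at ``alpha``.  Samples smaller than 3
    cannot be tested for normality and force the nonparametric branch.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(s.size < 3 for s in samples):
        return GateRecord(shapiro_p=[], levene_p=None, parametric=False,
                          forced_nonparametric=True)
    shapiro_p = [float(stats.shapiro(s).pvalue) for s in samples]
    levene_p = float(stats.levene(*samples).pvalue) if len(samples) >= 2 else None
    parametric = all(p > alpha for p in shapiro_p) and (
        levene_p is None or levene_p > alpha
    )
    return GateRecord(shapiro_p=shapiro_p, levene_p=levene_p, parametric=parametric)


def compare_two_samples(a, b, paired: bool = False) -> ComparisonResult:
    """Two-tailed two-sample comparison dispatched on the assumption gate."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal-length samples")
    if paired and np.all(a == b):
        gate = GateRecord(shapiro_p=[], levene_p=None, parametric=False,
                          forced_nonparametric=True)
        return ComparisonResult("wilcoxon signed-rank", np.nan, 1.0, gate,
                                note="all paired differences zero")
    gate = assumption_gate([a - b] if paired else [a, b])
    if gate.parametric:
        if paired:
            res = stats.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = stats.ttest_ind(a, b)
            name = "independent t-test"
        return ComparisonResult(name, float(res.statistic), float(res.pvalue), gate)
    if paired:
        d = a - b
        if np.all(d == 0):
            return ComparisonResult("wilcoxon signed-rank", np.nan, 1.0, gate,
                                    note="all paired differences zero")
        res = stats.wilcoxon(a, b)
        name = "wilcoxon signed-rank"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney U"
    return ComparisonResult(name, float(res.statistic), float(res.pvalue), gate)


def scheirer_ray_hare(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> dict[str, ComparisonResult]:
    """Rank-based two-way test for two crossed factors plus interaction.

    All N observations are mid-ranked together; two-way ANOVA sums of
    squares are computed on the ranks and each effect's
    H = SS_effect / (SS_total / (N - 1)) is compared to a chi-square with
    the effect's df.  Mid-ranks already deflate SS_total under ties, so no
    extra tie correction is applied.  Returns results keyed 'factor_a',
    'factor_b', 'interaction'.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factors must have equal length")
    a_levels = np.unique(fa)
    b_levels = np.unique(fb)
    if a_levels.size < 2 or b_levels.size < 2:
        raise ValueError("each factor needs at least 2 levels")
    for al in a_levels:
        for bl in b_levels:
            if not np.any((fa == al) & (fb == bl)):
                raise ValueError(f"empty cell: {al!r} x {bl!r}")

    r = stats.rankdata(y)  # mid-ranks
    N = r.size
    grand = r.mean()
    ss_total = float(np.sum((r - grand) ** 2))
    ms_total = ss_total / (N - 1)

    def ss_for(levels, factor):
        return float(sum(
            np.sum(factor == lv) * (r[factor == lv].mean() - grand) ** 2
            for lv in levels
        ))

    ss_a = ss_for(a_levels, fa)
    ss_b = ss_for(b_levels, fb)
    ss_cells = float(sum(
        np.sum(m) * (r[m].mean() - grand) ** 2
        for al in a_levels for bl in b_levels
        for m in [(fa == al) & (fb == bl)]
    ))
    ss_ab = ss_cells - ss_a - ss_b

    dfs = {
        "factor_a": a_levels.size - 1,
        "factor_b": b_levels.size - 1,
        "interaction": (a_levels.size - 1) * (b_levels.size - 1),
    }
    sss = {"factor_a": ss_a, "factor_b": ss_b, "interaction": ss_ab}
    out = {}
    for key, ss in sss.items():
        if ms_total <= 0:  # all observations tied: no rank variation at all
            out[key] = ComparisonResult("scheirer-ray-hare", 0.0, 1.0, df=dfs[key],
                                        note="degenerate: all observations equal")
            continue
        h = ss / ms_total
        p = float(stats.chi2.sf(h, dfs[key]))
        out[key] = ComparisonResult("scheirer-ray-hare", float(h), p, df=dfs[key])
    return out
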