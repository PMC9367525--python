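"""Group statistics: one-way ANOVA with Tukey's all-pairs post-hoc test.

Two entry points cover the two forms assay data arrives in:

* :func:`anova_tukey` — raw per-sample values, backed by
  :func:`scipy.stats.f_oneway` and :func:`scipy.stats.tukey_hsd`;
* :func:`anova_tukey_from_summary` — per-group (mean, SD, n) only, computed
  from first principles via the studentized-range distribution.  Published
  figures usually survive only in this form.

For matching inputs the two paths agree to numerical precision (this is a
tested invariant, not an accident: the summary path reconstructs the exact
sums of squares that raw data with those summaries would produce).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "PairResult",
    "StatsResult",
    "anova_tukey",
    "anova_tukey_from_summary",
    "summaries_from_raw",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")


@dataclass(frozen=True)
class PairResult:
    a: str
    b: str
    diff: float        # mean(a) - mean(b)
    q: float           # studentized range statistic
    p_adj: float       # Tukey-adjusted p-value
    stars: str         # '**', '*' or 'ns'


@dataclass(frozen=True)
class StatsResult:
    f_statistic: float
    p_value: float
    pairs: tuple[PairResult, ...]
    alpha: float = ALPHA

    def pair(self, a: str, b: str) -> PairResult:
        for pr in self.pairs:
            if {pr.a, pr.b} == {a, b}:
                return pr
        raise KeyError(f"no pair ({a}, {b})")


def _stars(p: float, alpha: float = ALPHA) -> str:
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


def _coerce_groups(groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, Mapping):
        labels = [str(k) for k in groups]
        arrays = [np.asarray(v, dtype=np.float64).ravel() for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=np.float64).ravel() for v in groups]
        labels = [f"group{i}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for lab, a in zip(labels, arrays):
        if a.size < 2:
            raise ValueError(f"group {lab!r} has n < 2")
        if not np.isfinite(a).all():
            raise ValueError(f"group {lab!r} contains non-finite values")
    return labels, arrays


def anova_tukey(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = ALPHA,
) -> StatsResult:
    """Fixed-effects one-way ANOVA plus Tukey HSD on raw per-sample values.

    If every group is constant (pooled within-group variance exactly zero)
    the degenerate denominator is replaced by a tiny variance floor so the
    comparison still resolves, rather than returning NaNs.
    """
    labels, arrays = _coerce_groups(groups)
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (
        sum(a.size for a in arrays) - len(arrays)
    )
    if msw == 0.0:
        # epsilon-guard: delegate to the summary path with a variance floor
        scale = max(abs(a.mean()) for a in arrays) + 1.0
        summ = [
            GroupSummary(lab, float(a.mean()), scale * 1e-9, a.size)
            for lab, a in zip(labels, arrays)
        ]
        return anova_tukey_from_summary(summ, alpha=alpha)
    f_stat, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    k = len(arrays)
    df = sum(a.size for a in arrays) - k
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrays[i].mean() - arrays[j].mean())
            se = np.sqrt(msw / 2.0 * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
            q = abs(diff) / se if se > 0 else np.inf
            p_adj = float(hsd.pvalue[i, j])
            pairs.append(
                PairResult(labels[i], labels[j], diff, float(q), p_adj,
                           _stars(p_adj, alpha))
            )
    return StatsResult(float(f_stat), float(p), tuple(pairs), alpha)


def anova_tukey_from_summary(
    summaries: Sequence[GroupSummary], alpha: float = ALPHA
) -> StatsResult:
    """ANOVA + Tukey HSD reconstructed from per-group (mean, SD, n).

    Between-group sums of squares come from the means, within-group from
    ``(n - 1) * sd^2``; pairwise comparisons use the Tukey–Kramer standard
    error and the studentized-range distribution with the pooled error df.
    Agrees exactly with :func:`anova_tukey` on raw data sharing the same
    summaries.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two groups")
    k = len(summaries)
    ns = np.array([g.n for g in summaries], dtype=np.float64)
    means = np.array([g.mean for g in summaries], dtype=np.float64)
    sds = np.array([g.sd for g in summaries], dtype=np.float64)
    N = ns.sum()
    df_between = k - 1
    df_within = N - k
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1.0) * sds ** 2).sum()
    # variance floor keeps all-constant groups from dividing by zero
    floor = (np.abs(means).max() + 1.0) ** 2 * 1e-18
    msw = max(ssw / df_within, floor)
    msb = ssb / df_between
    f_stat = msb / msw
    p = float(sps.f.sf(f_stat, df_between, df_within))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p_adj = float(np.clip(sps.studentized_range.sf(q, k, df_within), 0.0, 1.0))
            pairs.append(
                PairResult(summaries[i].label, summaries[j].label, diff,
                           float(q), p_adj, _stars(p_adj, alpha))
            )
    return StatsResult(float(f_stat), p, tuple(pairs), alpha)


def summaries_from_raw(
    groups: Mapping[str, Sequence[float]]
) -> list[GroupSummary]:
    """Per-group (mean, sample SD, n) in input order."""
    labels, arrays = _coerce_groups(groups)
    return [
        GroupSummary(lab, float(a.mean()), float(a.std(ddof=1)), int(a.size))
        for lab, a in zip(labels, arrays)
    ]
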