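"""Spatial-population comparison procedures.

Nonparametric and parametric tests used to compare cell populations along
a chamber gradient: a proximal-vs-distal Wilcoxon rank-sum test on the cells
nearest and farthest from the opening, a one-way ANOVA on replicate half-max
positions, per-bin unpaired t-tests of positive fractions against the first
(best-nurtured) bin, and a high-expressor classifier defined relative to a
control population's median.

These are per-cell tests on spatially structured data; they do not correct
for spatial autocorrelation (a known limitation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .cytometry import CellTable
from .profiling import BinnedFractionProfile

__all__ = [
    "ComparisonResult",
    "proximal_distal_test",
    "compare_half_max",
    "bins_vs_first_bin",
    "classify_high",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one statistical comparison."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    groups: tuple[str, ...] = ()
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    def __repr__(self) -> str:  # compact, log-friendly
        ns = "/".join(map(str, self.n))
        return f"<{self.test}: stat={self.statistic:.4g}, p={self.p_value:.3g}, n={ns}>"


def proximal_distal_test(
    table: CellTable,
    value: str,
    n_each: int = 10_000,
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test of the cells nearest vs farthest
    from the opening.

    Cells are ordered by distance; the ``n_each`` smallest-distance cells form
    the proximal group and the ``n_each`` largest the distal group. When the
    table holds fewer than ``2 * n_each`` cells, ``n_each`` is clamped to
    ``floor(N / 2)`` with a warning so the groups stay disjoint. The exact
    null distribution is enumerated for groups of up to 10 tie-free values;
    otherwise the tie-corrected normal approximation is used.
    """
    df = table.df
    if "distance_um" not in df.columns:
        raise ValueError("distances not assigned; call assign_distance first")
    if "outside_chamber" in df.columns:
        df = df.loc[~df["outside_chamber"]]
    d = df["distance_um"].to_numpy(dtype=float)
    v = df[value].to_numpy(dtype=float)
    n = len(v)
    if n_each < 1:
        raise ValueError("n_each must be >= 1")
    if 2 * n_each > n:
        clamped = n // 2
        warnings.warn(
            f"table has {n} cells < 2*{n_each}; clamping groups to {clamped} each",
            stacklevel=2,
        )
        n_each = clamped
    if n_each < 2:
        raise ValueError("need at least 2 cells per group")
    order = np.argsort(d, kind="stable")
    proximal = v[order[:n_each]]
    distal = v[order[-n_each:]]

    exact = n_each <= 10 and len(np.unique(np.concatenate([proximal, distal]))) == 2 * n_each
    res = sps.mannwhitneyu(
        proximal, distal, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return ComparisonResult(
        test="rank-sum",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(n_each, n_each),
        groups=("proximal", "distal"),
    )


def compare_half_max(groups: Mapping[str, Sequence[float]]) -> ComparisonResult:
    """One-way fixed-effects ANOVA across groups of replicate half-max positions.

    Replicates whose half-max is undefined (NaN/inf — the no-gradient
    condition) are excluded; the number dropped is reported in ``extra``.
    Requires >= 2 groups with >= 2 finite replicates each. When every group
    mean is identical F = 0 and, by convention, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels, samples, n_excluded = [], [], 0
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        finite = arr[np.isfinite(arr)]
        n_excluded += len(arr) - len(finite)
        if len(finite) < 2:
            raise ValueError(f"group {name!r} has < 2 finite replicates")
        labels.append(str(name))
        samples.append(finite)

    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(samples) - 1
    df_w = sum(len(s) for s in samples) - len(samples)
    if ss_between <= 1e-12 * max(ss_within, 1e-300):
        f_stat, p = 0.0, 1.0
    elif ss_within == 0.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))
    return ComparisonResult(
        test="one-way ANOVA",
        statistic=float(f_stat),
        p_value=float(p),
        n=tuple(len(s) for s in samples),
        groups=tuple(labels),
        extra={"n_excluded": float(n_excluded)},
    )


def _ttest(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    if np.var(a) == 0 and np.var(b) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def bins_vs_first_bin(
    profile: BinnedFractionProfile,
    welch: bool = False,
    holm: bool = False,
) -> list[ComparisonResult]:
    """Unpaired t-test of each bin's replicate fractions against the first bin.

    Uses Student's (pooled-variance) t by default; ``welch=True`` switches to
    the unequal-variance form. The first bin compared with itself is reported
    as t = 0, p = 1. No multiple-testing correction is applied unless
    ``holm=True`` (Holm step-down across the non-first bins).
    """
    frac = profile.fractions
    if frac.shape[0] < 2:
        raise ValueError("need >= 2 replicates per bin")
    first = frac[:, 0]
    first = first[np.isfinite(first)]
    if len(first) < 2:
        raise ValueError("first bin populated in < 2 replicates")

    results: list[ComparisonResult] = []
    raw_p: list[float] = []
    for b in range(frac.shape[1]):
        vals = frac[:, b]
        vals = vals[np.isfinite(vals)]
        if b == 0:
            t, p = 0.0, 1.0
        elif len(vals) < 2:
            t, p = np.nan, np.nan
        else:
            t, p = _ttest(vals, first, welch)
        raw_p.append(p)
        results.append(
            ComparisonResult(
                test="t-test vs first bin" + (" (Welch)" if welch else ""),
                statistic=t,
                p_value=p,
                n=(len(vals), len(first)),
                groups=(f"bin_{b}", "bin_0"),
                extra={"bin_lo_um": float(profile.bin_edges[b]),
                       "bin_hi_um": float(profile.bin_edges[b + 1])},
            )
        )
    if holm:
        from statsmodels.stats.multitest import multipletests

        idx = [i for i in range(1, len(raw_p)) if np.isfinite(raw_p[i])]
        if idx:
            adj = multipletests([raw_p[i] for i in idx], method="holm")[1]
            for i, p_adj in zip(idx, adj):
                r = results[i]
                results[i] = ComparisonResult(
                    test=r.test + " (Holm)",
                    statistic=r.statistic,
                    p_value=float(p_adj),
                    n=r.n,
                    groups=r.groups,
                    extra=r.extra,
                )
    return results


def classify_high(
    values: Sequence[float],
    control: Sequence[float],
    k: float = 2.0,
) -> tuple[np.ndarray, float]:
    """Flag cells expressing "high" levels relative to a control population.

    A cell is high iff its value is strictly greater than ``k`` times the
    control median (default k = 2). Returns the per-cell boolean flags and
    the fraction of high cells. Invariant under any common positive rescaling
    of values and control.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    control = np.asarray(list(control), dtype=float)
    if control.size == 0:
        raise ValueError("control population must be nonempty")
    values = np.asarray(list(values), dtype=float)
    cutoff = k * np.median(control)
    flags = values > cutoff
    fraction = float(flags.mean()) if values.size else 0.0
    return flags, fraction
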