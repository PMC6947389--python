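"""Supporting cohort statistics: trend tests, group comparisons, post-hocs.

* :func:`trend_test` — Cochran–Armitage test for a monotone trend in event
  proportions across ordered exposure categories (equally spaced scores),
  the standard reading of a "continuity across categories" p-value.
* :func:`compare_continuous` — ANOVA with Tukey–Kramer post-hoc when the
  Shapiro–Wilk normality and Bartlett homoscedasticity gates pass (alpha
  0.05), otherwise Kruskal–Wallis with Dunn's rank post-hoc (Bonferroni).
* :func:`compare_categorical` — chi-squared (no continuity correction) when
  all expected counts are >= 5, Fisher's exact for sparse 2x2 tables, with
  the Marascuillo procedure for pairwise proportion contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TrendResult",
    "GroupComparisonResult",
    "trend_test",
    "compare_continuous",
    "compare_categorical",
    "marascuillo",
    "dunn_posthoc",
]

GATE_ALPHA = 0.05  # normality / homoscedasticity gate level


@dataclass(frozen=True)
class TrendResult:
    statistic: float
    p: float
    ordering: tuple[str, ...]
    test_name: str = "cochran-armitage"


def trend_test(
    events: Sequence[int],
    n: Sequence[int],
    labels: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> TrendResult:
    """Cochran–Armitage trend test over ordered groups.

    ``events[i]`` of ``n[i]`` subjects in group i experienced the event;
    groups are scored 0, 1, 2, ... unless ``scores`` is given.  The signed
    z statistic is positive for a rising trend; p is two-sided.
    """
    e = np.asarray(events, dtype=float)
    m = np.asarray(n, dtype=float)
    if e.shape != m.shape or e.ndim != 1 or len(e) < 3:
        raise ValueError("need >= 3 ordered groups of matching shape")
    if np.any(m <= 0):
        raise ValueError("all group sizes must be positive")
    if np.any(e < 0) or np.any(e > m):
        raise ValueError("events must lie in [0, n] per group")
    d = np.asarray(scores, dtype=float) if scores is not None else np.arange(len(e), dtype=float)
    N = m.sum()
    pbar = e.sum() / N
    num = float(np.sum(d * (e - m * pbar)))
    var = pbar * (1 - pbar) * (np.sum(m * d**2) - np.sum(m * d) ** 2 / N)
    if var <= 0:  # all events or none: no information about trend
        return TrendResult(0.0, 1.0, tuple(labels or map(str, range(len(e)))))
    z = num / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z)))
    return TrendResult(float(z), p, tuple(labels or map(str, range(len(e)))))


@dataclass
class GroupComparisonResult:
    """Omnibus comparison with the matching post-hoc table."""

    omnibus_test: str  # "anova" or "kruskal-wallis"
    omnibus_statistic: float
    omnibus_p: float
    normality_p: float  # min Shapiro–Wilk p across groups
    homoscedasticity_p: float  # Bartlett p (NaN if undefined)
    posthoc_method: str
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)
    flags: tuple[str, ...] = ()


def _shapiro_p(x: np.ndarray) -> float:
    if len(x) < 3 or np.ptp(x) == 0:
        return 0.0  # constant / tiny group: treat as failing normality
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def dunn_posthoc(groups: Sequence[np.ndarray], labels: Sequence[str]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test after Kruskal–Wallis (Bonferroni adjusted)."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_unit = N * (N + 1) / 12.0 - tie_term
    mean_ranks, start = [], 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            se = np.sqrt(var_unit * (1 / sizes[a] + 1 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = min(1.0, 2 * sps.norm.sf(abs(z)) * n_pairs)
            rows.append({"group_a": labels[a], "group_b": labels[b],
                         "z": float(z), "p_adj": float(p),
                         "significant": bool(p < 0.05)})
    return pd.DataFrame(rows)


def compare_continuous(
    groups: Sequence[Sequence[float]] | dict[str, Sequence[float]],
) -> GroupComparisonResult:
    """Compare a continuous variable across independent groups.

    ANOVA + Tukey–Kramer when every group passes Shapiro–Wilk and Bartlett
    passes at alpha 0.05; otherwise Kruskal–Wallis + Dunn.  A constant-valued
    group makes Bartlett undefined: the comparison falls through to the
    rank-based branch and is flagged.
    """
    if isinstance(groups, dict):
        labels = list(map(str, groups.keys()))
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
        labels = [str(i) for i in range(len(arrays))]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")

    flags: list[str] = []
    norm_p = min(_shapiro_p(a) for a in arrays)
    if any(np.ptp(a) == 0 for a in arrays):
        bart_p = float("nan")
        flags.append("constant_group")
    else:
        bart_p = float(sps.bartlett(*arrays).pvalue)
    parametric = norm_p > GATE_ALPHA and np.isfinite(bart_p) and bart_p > GATE_ALPHA

    if parametric:
        stat, p = sps.f_oneway(*arrays)
        values = np.concatenate(arrays)
        grp = np.concatenate([[lab] * len(a) for lab, a in zip(labels, arrays)])
        tk = pairwise_tukeyhsd(values, grp, alpha=0.05)
        post = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        post = post.rename(columns={"group1": "group_a", "group2": "group_b",
                                    "p-adj": "p_adj", "reject": "significant"})
        return GroupComparisonResult("anova", float(stat), float(p), norm_p, bart_p,
                                     "tukey-kramer", post, tuple(flags))
    stat, p = sps.kruskal(*arrays)
    post = dunn_posthoc(arrays, labels)
    return GroupComparisonResult("kruskal-wallis", float(stat), float(p), norm_p,
                                 bart_p, "dunn-bonferroni", post, tuple(flags))


def marascuillo(
    events: Sequence[int], n: Sequence[int], labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Marascuillo procedure: which pairs of proportions differ.

    A pair (i, j) is flagged when |p_i - p_j| exceeds the critical range
    sqrt(chi2_{k-1, 1-alpha}) * sqrt(p_i(1-p_i)/n_i + p_j(1-p_j)/n_j).
    """
    e = np.asarray(events, dtype=float)
    m = np.asarray(n, dtype=float)
    if np.any(m <= 0) or np.any(e < 0) or np.any(e > m):
        raise ValueError("invalid counts")
    k = len(e)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    phat = e / m
    crit_mult = np.sqrt(sps.chi2.ppf(1 - alpha, k - 1))
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            rng = crit_mult * np.sqrt(
                phat[a] * (1 - phat[a]) / m[a] + phat[b] * (1 - phat[b]) / m[b]
            )
            diff = abs(phat[a] - phat[b])
            rows.append({"group_a": labels[a], "group_b": labels[b],
                         "abs_diff": float(diff), "critical_range": float(rng),
                         "significant": bool(diff > rng)})
    return pd.DataFrame(rows)


def compare_categorical(table) -> dict:
    """Omnibus test of an r x k contingency table plus Marascuillo pairs.

    Chi-squared without continuity correction when all expected counts are
    >= 5; Fisher's exact for sparse 2x2 tables.  Sparse tables larger than
    2x2 fall back to chi-squared with a ``small_expected`` flag (no exact
    r x k test is attempted).  For 2 x k tables the Marascuillo pairwise
    report on the first-row proportions is included.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or np.any(tab < 0):
        raise ValueError("table must be a non-negative 2-D array")
    flags: list[str] = []
    chi2, chi_p, dof, expected = sps.chi2_contingency(tab, correction=False)
    if np.all(expected >= 5):
        test, stat, p = "chi-squared", float(chi2), float(chi_p)
    elif tab.shape == (2, 2):
        _, p = sps.fisher_exact(tab)
        test, stat, p = "fisher-exact", float("nan"), float(p)
    else:
        test, stat, p = "chi-squared", float(chi2), float(chi_p)
        flags.append("small_expected")
    result = {"test": test, "statistic": stat, "p": p, "dof": int(dof),
              "flags": tuple(flags)}
    if tab.shape[0] == 2 and tab.shape[1] >= 3:
        result["marascuillo"] = marascuillo(tab[0], tab.sum(axis=0))
    return result
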