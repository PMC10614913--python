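"""Statistical tests and report artifacts for the turnover and imaging data.

Conventions follow the study design: two groups are compared with a
Student's t-test (Welch optional), more than two with a one-way ANOVA,
ratio-of-means values are compared to a hypothetical value of 1 with a
one-sample t-test, and non-parametric multi-group comparisons use
Kruskal-Wallis with a post-hoc (Dunn by default; Tukey-on-ranks offered
because the figure legends pair Kruskal-Wallis with Tukey's test, which is
statistically unconventional). Dispersion is reported as SEM and p-values
map to the star convention * p<.05, ** p<.01, *** p<.001.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.cluster import hierarchy as _hier


@dataclass
class TestResult:
    """A single hypothesis-test outcome with per-group summaries."""

    name: str
    statistic: float
    pvalue: float
    df: float | tuple | None = None
    group_ns: tuple = ()
    group_means: tuple = ()
    group_sems: tuple = ()
    note: str = ""

    @property
    def stars(self) -> str:
        return significance_stars(self.pvalue)

    def summary(self) -> str:
        groups = ", ".join(
            f"{m:.3g} ± {s:.3g} (n={n})"
            for m, s, n in zip(self.group_means, self.group_sems, self.group_ns)
        )
        p = f"p={self.pvalue:.3g}{self.stars}"
        return f"{self.name}: statistic={self.statistic:.4g}, {p}; mean±SEM {groups}"


def significance_stars(p: float) -> str:
    """* p<.05, ** p<.01, *** p<.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def _summaries(groups: Sequence[np.ndarray]):
    return (
        tuple(len(g) for g in groups),
        tuple(float(np.mean(g)) for g in groups),
        tuple(_sem(np.asarray(g)) for g in groups),
    )


def two_group_test(a, b, kind: str = "student") -> TestResult:
    """Two-sample t-test; ``kind`` is "student" (default) or "welch"."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if kind not in ("student", "welch"):
        raise ValueError(f"unknown test kind {kind!r}")
    equal_var = kind == "student"
    note = ""
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        stat = 0.0
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        note = "zero variance in both groups"
        df = len(a) + len(b) - 2
    else:
        res = _stats.ttest_ind(a, b, equal_var=equal_var)
        stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    ns, means, sems = _summaries([a, b])
    return TestResult(f"{kind} t-test", stat, p, df, ns, means, sems, note)


def one_way_anova(groups: Sequence) -> TestResult:
    """One-way ANOVA across >= 2 groups (each n >= 2)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df = (k - 1, n_total - k)
    ns, means, sems = _summaries(groups)
    if all(np.std(g, ddof=1) == 0 for g in groups) and len(set(means)) == 1:
        warnings.warn("all groups are identical constants; F undefined, reported as 0")
        return TestResult("one-way ANOVA", 0.0, 1.0, df, ns, means, sems,
                          "zero variance everywhere")
    stat, p = _stats.f_oneway(*groups)
    return TestResult("one-way ANOVA", float(stat), float(p), df, ns, means, sems)


def one_sample_test(values, mu: float) -> TestResult:
    """Two-sided one-sample t-test of the mean against ``mu``."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("one-sample t-test needs n >= 2")
    ns, means, sems = (len(x),), (float(np.mean(x)),), (_sem(x),)
    if np.std(x, ddof=1) == 0:
        if np.mean(x) == mu:
            warnings.warn("zero variance with mean equal to mu; p = 1")
            return TestResult("one-sample t-test", 0.0, 1.0, len(x) - 1,
                              ns, means, sems, "zero variance")
        return TestResult("one-sample t-test", float("inf"), 0.0, len(x) - 1,
                          ns, means, sems, "zero variance, mean != mu")
    res = _stats.ttest_1samp(x, mu)
    return TestResult(
        "one-sample t-test", float(res.statistic), float(res.pvalue),
        len(x) - 1, ns, means, sems,
    )


def _dunn_posthoc(groups: list[np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based z-tests for all pairs, with tie correction."""
    from statsmodels.stats.multitest import multipletests

    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = _stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start : start + len(g)].mean()))
        sizes.append(len(g))
        start += len(g)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * _stats.norm.sf(abs(z))
        rows.append({"group_a": i, "group_b": j, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_raw"], method=adjust)[1]
    return df


def _tukey_on_ranks(groups: list[np.ndarray]) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    pooled = np.concatenate(groups)
    ranks = _stats.rankdata(pooled)
    labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    res = pairwise_tukeyhsd(ranks, labels)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return pd.DataFrame(
        {
            "group_a": frame["group1"].astype(int),
            "group_b": frame["group2"].astype(int),
            "p_adj": frame["p-adj"].astype(float),
        }
    )


def kw_with_posthoc(
    groups: Sequence, posthoc: str = "dunn"
) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis H test with pairwise post-hoc comparisons.

    ``posthoc`` is "dunn" (default) or "tukey" (Tukey's HSD on ranks).
    Returns ``(kw_result, posthoc_table)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis needs >= 3 groups; use two_group_test")
    ns, means, sems = _summaries(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        kw = TestResult("Kruskal-Wallis", 0.0, 1.0, len(groups) - 1,
                        ns, means, sems, "all values identical; H = 0")
        table = pd.DataFrame(
            [
                {"group_a": i, "group_b": j, "p_adj": 1.0}
                for i, j in itertools.combinations(range(len(groups)), 2)
            ]
        )
        return kw, table
    h, p = _stats.kruskal(*groups)
    kw = TestResult("Kruskal-Wallis", float(h), float(p), len(groups) - 1,
                    ns, means, sems)
    if posthoc == "dunn":
        table = _dunn_posthoc(list(groups))
    elif posthoc == "tukey":
        table = _tukey_on_ranks(list(groups))
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return kw, table


# ---------------------------------------------------------------------------
# hierarchical clustering of fractional abundance
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Agglomerative clustering of a protein x condition FA matrix."""

    linkage: np.ndarray
    leaf_order: np.ndarray
    labels: list[str]
    metric: str
    method: str

    @property
    def n_leaves(self) -> int:
        return self.linkage.shape[0] + 1


def cluster_fa(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Hierarchical clustering of FA rows (proteins).

    Missing values are imputed with the row mean before computing distances.
    Defaults: Euclidean distance, average linkage.
    """
    mat = matrix.to_numpy(dtype=float)
    labels = [str(i) for i in matrix.index]
    if mat.shape[0] == 1:
        return ClusterResult(np.empty((0, 4)), np.array([0]), labels, metric, method)
    row_means = np.nanmean(mat, axis=1)
    inds = np.where(np.isnan(mat))
    mat[inds] = np.take(row_means, inds[0])
    if np.isnan(mat).any():
        raise ValueError("rows with no observed values cannot be imputed")
    z = _hier.linkage(mat, method=method, metric=metric)
    order = np.asarray(_hier.leaves_list(z))
    return ClusterResult(z, order, labels, metric, method)


def fa_heatmap(
    matrix: pd.DataFrame,
    result: ClusterResult,
    path: str | Path | None = None,
    cmap: str = "viridis",
):
    """Clustered FA heat map; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = matrix.iloc[result.leaf_order]
    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(8, max(3, 0.25 * len(matrix))),
        gridspec_kw={"width_ratios": [1, 3]},
    )
    if result.linkage.shape[0]:
        _hier.dendrogram(result.linkage, orientation="left", ax=ax_d, no_labels=True)
    ax_d.set_axis_off()
    im = ax_h.imshow(ordered.to_numpy(), aspect="auto", cmap=cmap)
    ax_h.set_yticks(range(len(ordered)), [str(i) for i in ordered.index], fontsize=6)
    ax_h.set_xticks(range(ordered.shape[1]), [str(c) for c in ordered.columns])
    fig.colorbar(im, ax=ax_h, label="FA (% 15N remaining)")
    fig.suptitle(f"FA clustering ({result.metric}, {result.method} linkage)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def write_test_table(path: str | Path, results: Sequence[TestResult]) -> None:
    rows = [
        {
            "test": r.name,
            "statistic": r.statistic,
            "df": str(r.df),
            "pvalue": r.pvalue,
            "stars": r.stars,
            "group_ns": str(r.group_ns),
            "group_means": str(tuple(round(m, 6) for m in r.group_means)),
            "group_sems": str(tuple(round(s, 6) for s in r.group_sems)),
            "note": r.note,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_markdown_report(path: str | Path, title: str,
                          results: Sequence[TestResult]) -> None:
    """A small run report: one section per test, mean ± SEM per group."""
    lines = [f"# {title}", ""]
    for r in results:
        lines.append(f"## {r.name}")
        lines.append("")
        lines.append(r.summary())
        if r.note:
            lines.append(f"\n*Note: {r.note}*")
        lines.append("")
    Path(path).write_text("\n".join(lines))
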