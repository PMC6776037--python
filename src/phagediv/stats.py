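"""Prevalence and richness statistics for phage presence/absence data.

Covers the statistical toolkit used throughout the prevalence figures: two-sided
Fisher's exact tests on per-cluster 2x2 tables with Bonferroni correction, one-way
ANOVA with post hoc Tukey HSD on per-genome prophage counts, Wilson-interval
prevalence summaries, and individual-based rarefaction of phage-cluster richness
(sampling genomes without replacement, 10 replicates by default, t-based 95% CIs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PresenceTable",
    "TestResult",
    "RarefactionCurve",
    "fisher_exact_2x2",
    "bonferroni",
    "significance_stars",
    "group_association_tests",
    "anova_tukey",
    "rarefy",
    "expected_richness",
    "prevalence_summary",
]

DEFAULT_REPLICATES = 10


@dataclass
class PresenceTable:
    """Binary entity x phage-cluster matrix with a group label per entity.

    Rows are bacterial genomes (grouped by clade/serotype) or metagenome samples
    (grouped by body site); columns are phage clusters; cells are carriage.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.data = self.data.astype(bool)
        if not self.data.index.equals(self.groups.index):
            raise ValueError("groups index must match data index")
        if self.groups.isna().any() or (self.groups.astype(str) == "").any():
            raise ValueError("group labels must be non-empty")

    @property
    def n_entities(self) -> int:
        return self.data.shape[0]

    @property
    def clusters(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.astype(int).copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceTable":
        df = pd.read_csv(path, sep="\t", index_col="id")
        groups = df.pop("group").astype(str)
        return cls(data=df.astype(bool), groups=groups)


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test with its Bonferroni-adjusted p value."""

    comparison_id: str
    statistic_name: str
    p_value: float
    p_adjusted: float
    n_comparisons: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


@dataclass(frozen=True)
class RarefactionCurve:
    """Mean richness and 95% CI per number of genomes sampled."""

    n_sampled: np.ndarray
    mean_richness: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_replicates: int
    replicate_curves: np.ndarray  # (n_replicates, G), kept for diagnostics

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_sampled": self.n_sampled,
                "mean_richness": self.mean_richness,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Two-sided in the standard sense: the sum of hypergeometric probabilities of
    all tables with the observed margins whose point probability does not exceed
    that of the observed table.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("at least one count must be positive")
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return float(min(p, 1.0))


def bonferroni(p_values: Sequence[float], family_size: int) -> list[float]:
    """Bonferroni-adjust p values: ``min(1, p * family_size)``.

    ``family_size`` is explicit (all tests in one figure-panel analysis) and must
    be at least the number of p values supplied.
    """
    ps = list(p_values)
    if family_size < len(ps):
        raise ValueError("family_size must be >= number of p values")
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p value {p} outside [0, 1]")
    return [min(1.0, p * family_size) for p in ps]


def significance_stars(p: float) -> str:
    """Star codes at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_association_tests(
    table: PresenceTable, family_size: int | None = None
) -> list[TestResult]:
    """Per-(cluster, group) Fisher tests: carrier vs non-carrier, group vs rest.

    Decomposes the k-group presence table into 2x2 tables, one per bar of a
    prevalence panel, and Bonferroni-adjusts over the whole panel.
    """
    groups = table.groups.unique()
    comparisons: list[tuple[str, float]] = []
    for cluster in table.clusters:
        carrier = table.data[cluster]
        for g in groups:
            in_g = table.groups == g
            t = [
                [int((carrier & in_g).sum()), int((~carrier & in_g).sum())],
                [int((carrier & ~in_g).sum()), int((~carrier & ~in_g).sum())],
            ]
            comparisons.append((f"{cluster}|{g}", fisher_exact_2x2(t)))
    fam = family_size if family_size is not None else len(comparisons)
    adjusted = bonferroni([p for _, p in comparisons], fam)
    return [
        TestResult(cid, "fisher_exact_two_sided", p, padj, fam)
        for (cid, p), padj in zip(comparisons, adjusted)
    ]


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA across groups plus all pairwise Tukey HSD comparisons.

    Returns ``(anova_result, tukey_results)``.  Tukey p values are already
    family-adjusted by the HSD procedure, so ``p_adjusted == p_value`` there.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled.var(), 0.0):
        raise ValueError("all observations identical; ANOVA undefined")
    f_stat, p = sps.f_oneway(*arrays)
    anova = TestResult("anova", "one_way_F", float(p), float(p), 1)

    values = pooled
    labels = np.concatenate([[g] * a.size for g, a in zip(names, arrays)])
    hsd = pairwise_tukeyhsd(values, labels)
    tukey = []
    for row in hsd.summary().data[1:]:
        g1, g2, _meandiff, p_adj = row[0], row[1], row[2], float(row[3])
        tukey.append(
            TestResult(f"{g1}|{g2}", "tukey_hsd", p_adj, p_adj, len(tukey) + 1)
        )
    return anova, tukey


def rarefy(
    table: PresenceTable, replicates: int = DEFAULT_REPLICATES, seed: int = 0
) -> RarefactionCurve:
    """Rarefaction of phage-cluster richness over genomes.

    For each n = 1..G, genomes are drawn without replacement (each replicate is
    one random ordering, so each replicate's curve is non-decreasing by
    construction) and the number of distinct clusters present is recorded.  Mean
    and t-based 95% CI are taken across replicates.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    if table.n_entities == 0:
        raise ValueError("empty presence table")
    rng = np.random.default_rng(seed)
    mat = table.data.to_numpy(dtype=bool)
    G, C = mat.shape
    curves = np.zeros((replicates, G), dtype=np.int64)
    for rep in range(replicates):
        order = rng.permutation(G)
        seen = np.cumsum(mat[order], axis=0) > 0  # (G, C): cluster seen by step n
        curves[rep] = seen.sum(axis=1)
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1)
    tcrit = sps.t.ppf(0.975, df=replicates - 1)
    half = tcrit * sd / np.sqrt(replicates)
    return RarefactionCurve(
        n_sampled=np.arange(1, G + 1),
        mean_richness=mean,
        ci_lower=mean - half,
        ci_upper=mean + half,
        n_replicates=replicates,
        replicate_curves=curves,
    )


def expected_richness(table: PresenceTable) -> np.ndarray:
    """Analytic rarefaction expectation E[S_n] = sum_i [1 - C(G-g_i, n)/C(G, n)].

    ``g_i`` is the number of genomes carrying cluster i.  Computed with log
    binomial coefficients for numerical stability.
    """
    mat = table.data.to_numpy(dtype=bool)
    G = mat.shape[0]
    g = mat.sum(axis=0)
    ns = np.arange(1, G + 1)
    out = np.zeros(G, dtype=float)
    from scipy.special import gammaln

    def log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        k = np.asarray(k, dtype=float)
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    for idx, n in enumerate(ns):
        keep = g > 0
        gi = g[keep]
        frac = np.zeros(gi.size, dtype=float)
        ok = (G - gi) >= n
        frac[ok] = np.exp(log_comb(G - gi[ok], n) - log_comb(G, n))
        out[idx] = float(np.sum(1.0 - frac))
    return out


def prevalence_summary(table: PresenceTable) -> pd.DataFrame:
    """Per-group, per-cluster prevalence with Wilson 95% CIs."""
    rows = []
    for g in table.groups.unique():
        in_g = table.groups == g
        n = int(in_g.sum())
        for cluster in table.clusters:
            k = int(table.data.loc[in_g, cluster].sum())
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            rows.append(
                {
                    "group": g,
                    "cluster": cluster,
                    "n": n,
                    "carriers": k,
                    "prevalence": k / n,
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                }
            )
    return pd.DataFrame(rows)
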