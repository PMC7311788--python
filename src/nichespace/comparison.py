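"""Cross-biome comparison of niche scores with rank statistics.

The pooled niche space (all biomes ordinated together) yields per-species
PC1/PC2 scores; biome differences are tested with the Kruskal-Wallis rank
test (tie-corrected, chi-square approximation) and summarized as a compact
letter display built from Dunn-type pairwise rank comparisons with Holm
multiplicity control: biomes sharing no letter differ at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ordination import NicheSpace, niche_space
from .traits import DEFAULT_SCHEME, BIOMES, DimensionScheme, TraitTable

__all__ = [
    "ComparisonResult",
    "combined_space",
    "kruskal_wallis",
    "dunn_pairwise",
    "significance_letters",
    "compare_axes",
    "stars",
]


def combined_space(
    tables: dict[str, TraitTable], scheme: DimensionScheme = DEFAULT_SCHEME
) -> tuple[dict, NicheSpace]:
    """Pool per-biome trait tables and ordinate the total niche space.

    Rows are concatenated (a species measured at two sites keeps both rows)
    and the full log10 -> dimension PCA -> second PCA pipeline runs once on
    the pooled table; biome labels stay in the score index.
    """
    if len(tables) < 2:
        raise ValueError("combined space needs at least 2 biomes")
    columns = None
    for biome, table in tables.items():
        if columns is None:
            columns = list(table.data.columns)
        elif list(table.data.columns) != columns:
            raise ValueError(f"trait columns of biome {biome} do not match the others")
    pooled = TraitTable(pd.concat([t.data for t in tables.values()]))
    return niche_space(pooled, scheme)


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def kruskal_wallis(scores, groups) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (df = k-1).

    H = [12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)] / [1 - sum(t^3-t)/(N^3-N)].
    If every observation is tied H is 0 and p is 1.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    N = len(scores)
    ranks = stats.rankdata(scores)
    H = 0.0
    for g in labels:
        r = ranks[groups == g]
        if len(r) == 0:
            raise ValueError(f"group {g!r} has no observations")
        H += r.sum() ** 2 / len(r)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    correction = 1.0 - _tie_term(scores) / (N**3 - N)
    if correction == 0.0:  # all observations identical
        return 0.0, len(labels) - 1, 1.0
    H /= correction
    df = len(labels) - 1
    return float(H), df, float(stats.chi2.sf(H, df))


def dunn_pairwise(scores, groups, adjust: str = "holm") -> pd.DataFrame:
    """Dunn-type pairwise rank comparisons on the pooled ranks.

    z_ij = (rbar_i - rbar_j) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j))
    with T the tie term; two-sided normal p-values, adjusted with the given
    statsmodels ``multipletests`` method.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    N = len(scores)
    ranks = stats.rankdata(scores)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    n = {g: int((groups == g).sum()) for g in labels}
    variance = N * (N + 1) / 12.0 - _tie_term(scores) / (12.0 * (N - 1))
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = np.sqrt(variance * (1.0 / n[a] + 1.0 / n[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            rows.append({"group_a": a, "group_b": b, "z": z,
                         "p_raw": 2 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=adjust)[1]
    return out


@dataclass
class ComparisonResult:
    """One axis's biome comparison: test, per-group summaries and letters."""

    axis: str
    H: float
    df: int
    p_value: float
    alpha: float
    adjust: str
    group_letters: dict[str, str]
    group_medians: dict[str, float]
    group_mean_ranks: dict[str, float]
    group_n: dict[str, int]
    pairwise: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.group_letters:
            rows.append(
                {
                    "axis": self.axis,
                    "H": self.H,
                    "df": self.df,
                    "p": self.p_value,
                    "stars": stars(self.p_value),
                    "biome": g,
                    "n": self.group_n[g],
                    "median": self.group_medians[g],
                    "mean_rank": self.group_mean_ranks[g],
                    "letters": self.group_letters[g],
                }
            )
        return pd.DataFrame(rows)


def stars(p: float) -> str:
    """Figure-style significance marks ('***' below 0.001)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _letter_display(labels, nonsig_pairs, mean_rank) -> dict[str, str]:
    """Compact letter display from the non-significance graph.

    Each maximal clique of mutually non-different groups gets one letter, so
    two groups share a letter iff their pairwise comparison is
    non-significant.  Letters are ordered by the best mean rank in each
    clique ('a' = highest-ranked homogeneous set).
    """
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    graph.add_edges_from(nonsig_pairs)
    cliques = sorted(
        nx.find_cliques(graph),
        key=lambda c: (-max(mean_rank[g] for g in c), sorted(str(g) for g in c)),
    )
    letters: dict[str, list[str]] = {g: [] for g in labels}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for g in clique:
            letters[g].append(letter)
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def significance_letters(
    scores, groups, alpha: float = 0.05, adjust: str = "holm", axis: str = "PC1"
) -> ComparisonResult:
    """Kruskal-Wallis plus Dunn/Holm pairwise letters for one score axis."""
    H, df, p = kruskal_wallis(scores, groups)
    pairwise = dunn_pairwise(scores, groups, adjust=adjust)
    scores = np.asarray(scores, dtype=float)
    groups_arr = np.asarray(groups)
    labels = list(pd.unique(groups_arr))
    ranks = stats.rankdata(scores)
    mean_rank = {g: float(ranks[groups_arr == g].mean()) for g in labels}
    nonsig = [
        (row.group_a, row.group_b)
        for row in pairwise.itertuples()
        if row.p_adj > alpha
    ]
    letters = _letter_display(labels, nonsig, mean_rank)
    return ComparisonResult(
        axis=axis,
        H=H,
        df=df,
        p_value=p,
        alpha=alpha,
        adjust=adjust,
        group_letters=letters,
        group_medians={g: float(np.median(scores[groups_arr == g])) for g in labels},
        group_mean_ranks=mean_rank,
        group_n={g: int((groups_arr == g).sum()) for g in labels},
        pairwise=pairwise,
    )


def compare_axes(
    space: NicheSpace, alpha: float = 0.05, adjust: str = "holm"
) -> list[ComparisonResult]:
    """Biome comparison of PC1 and PC2 scores of a pooled niche space."""
    biome = space.scores.index.get_level_values(1)
    order = [b for b in BIOMES if b in set(biome)]
    results = []
    for axis in ("PC1", "PC2"):
        res = significance_letters(
            space.scores[axis].to_numpy(), biome.to_numpy(), alpha=alpha,
            adjust=adjust, axis=axis,
        )
        # present biomes in canonical latitudinal order
        res.group_letters = {b: res.group_letters[b] for b in order}
        res.group_medians = {b: res.group_medians[b] for b in order}
        res.group_mean_ranks = {b: res.group_mean_ranks[b] for b in order}
        res.group_n = {b: res.group_n[b] for b in order}
        results.append(res)
    return results
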