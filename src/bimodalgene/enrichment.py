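"""Multiple-testing adjustment and rank enrichment of prognostic genes.

The genome-wide question: are genes whose splits predict survival
overrepresented near the top of a bimodality-ranked gene list?  The gene
universe of size N is ranked by a score; the N1 "prognostic" genes are those
with the smallest permutation logrank p-values (the set differs per grouping
family).  Enrichment corresponds to the prognostic genes having small ranks,
tested three ways:

* a one-sided one-sample Kolmogorov-Smirnov test of the normalised ranks
  against the uniform distribution (D+ = max_j (j/n - r_(j)/m); stochastically
  small ranks push D+ up),
* hypergeometric (Fisher) tail tests of the overlap between the top-k of the
  ranked list and the prognostic set, and
* a running-sum trace walking the ranked list, adding N0 at prognostic genes
  and subtracting N1 elsewhere — it always returns to 0 and its maximal
  deviation visualises where the prognostic genes concentrate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st

from .scores import RANK_COLUMNS, SCORE_COLUMNS

__all__ = [
    "bh_qvalues",
    "holm_adjust",
    "ks_enrichment",
    "fisher_topk",
    "running_sum",
    "select_prognostic",
    "EnrichmentResult",
    "enrichment_for_list",
    "enrich_all",
    "ScoreComparison",
    "score_comparison",
]

#: above this set size the one-sided KS p-value uses the asymptotic formula
KS_EXACT_MAX_N = 40


def _validated_p(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg q-values (FDR-adjusted p-values), input order kept.

    Iteratively from the largest p downward: q_(m) = p_(m) and
    q_(i) = min(q_(i+1), m p_(i) / i).
    """
    arr = _validated_p(p)
    m = arr.size
    order = np.argsort(arr, kind="stable")
    q_sorted = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def holm_adjust(p) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (FWER control), input order kept."""
    arr = _validated_p(p)
    m = arr.size
    order = np.argsort(arr, kind="stable")
    adj_sorted = arr[order] * (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _check_ranks(ranks, m: int) -> np.ndarray:
    r = np.asarray(sorted(ranks), dtype=np.int64)
    if r.size == 0:
        raise ValueError("empty rank set")
    if np.unique(r).size != r.size:
        raise ValueError("duplicate ranks")
    if r[0] < 1 or r[-1] > m:
        raise ValueError(f"ranks must lie in 1..{m}")
    return r


def ks_enrichment(ranks, m: int) -> tuple[float, float]:
    """One-sided KS test for stochastically small ranks among 1..m.

    D+ = max_j (j/n - r_(j)/m) on the normalised ranks; the p-value is exact
    (Smirnov one-sided distribution) for n <= 40 and asymptotic,
    exp(-2 n D+^2), beyond.

    Returns
    -------
    (D_plus, p_value)
    """
    r = _check_ranks(ranks, m)
    n = r.size
    ecdf_steps = np.arange(1, n + 1) / n
    d_plus = float(np.max(ecdf_steps - r / m))
    if d_plus <= 0:
        return max(d_plus, 0.0), 1.0
    if n <= KS_EXACT_MAX_N:
        p = float(st.ksone.sf(d_plus, n))
    else:
        p = float(np.exp(-2.0 * n * d_plus * d_plus))
    return d_plus, min(max(p, 0.0), 1.0)


def fisher_topk(ranks, m: int, k: int) -> tuple[int, float]:
    """Overlap of the prognostic set with the top-k genes plus its tail p-value.

    One-sided hypergeometric: P(X >= overlap) drawing k from m with |ranks|
    successes in the urn.
    """
    if k > m:
        raise ValueError(f"k={k} exceeds list length m={m}")
    r = _check_ranks(ranks, m)
    overlap = int(np.sum(r <= k))
    p = float(st.hypergeom.sf(overlap - 1, m, r.size, k))
    return overlap, min(p, 1.0)


def running_sum(ranks, m: int) -> tuple[np.ndarray, int]:
    """Running-sum enrichment trace along the ranked list.

    Walking ranks 1..m, add N0 = m - N1 when the gene is prognostic and
    subtract N1 otherwise; the telescoping sum ends at exactly 0.  Returns the
    integer trace and its maximal absolute deviation.
    """
    r = _check_ranks(ranks, m)
    n1 = r.size
    n0 = m - n1
    steps = np.full(m, -n1, dtype=np.int64)
    steps[r - 1] = n0
    trace = np.cumsum(steps)
    return trace, int(np.max(np.abs(trace)))


def select_prognostic(p_values: pd.Series, top_n: int = 250) -> list:
    """Ids of the ``top_n`` genes with smallest p-values (ties broken by id)."""
    s = pd.Series(p_values)
    if top_n > s.size:
        raise ValueError(f"top_n={top_n} exceeds {s.size} genes")
    order = np.lexsort((s.index.astype(str).to_numpy(), s.to_numpy(dtype=float)))
    return list(s.index.to_numpy()[order][:top_n])


@dataclass
class EnrichmentResult:
    """Enrichment of prognostic genes in one bimodality-ranked list."""

    score: str
    n1: int
    n0: int
    ks_d: float
    ks_p: float
    fisher: dict[int, tuple[int, float]]
    running_sum: np.ndarray = field(repr=False)
    max_deviation: int = 0


def enrichment_for_list(
    score: str,
    prognostic_ranks,
    m: int,
    fisher_k: tuple[int, ...] = (200, 1000),
) -> EnrichmentResult:
    """KS, Fisher and running-sum enrichment for one ranked list."""
    d_plus, ks_p = ks_enrichment(prognostic_ranks, m)
    fisher = {int(k): fisher_topk(prognostic_ranks, m, k) for k in fisher_k if k <= m}
    trace, max_dev = running_sum(prognostic_ranks, m)
    n1 = len(set(prognostic_ranks))
    return EnrichmentResult(
        score=score,
        n1=n1,
        n0=m - n1,
        ks_d=d_plus,
        ks_p=ks_p,
        fisher=fisher,
        running_sum=trace,
        max_deviation=max_dev,
    )


def enrich_all(
    score_table: pd.DataFrame,
    scan_tables: dict[str, pd.DataFrame],
    top_n: int = 250,
    fisher_k: tuple[int, ...] = (200, 1000),
) -> dict[str, EnrichmentResult]:
    """Enrichment of every ranked list against its own prognostic gene set.

    Parameters
    ----------
    score_table:
        Output of :func:`bimodalgene.scores.score_all`.
    scan_tables:
        Per grouping family (``kmeans``, ``mixture``, ``outlier``) the output
        of :func:`bimodalgene.survival.prognostic_scan` — each ranked list is
        paired with the prognostic set selected under its own grouping rule,
        so the sets differ between score families.
    """
    from .survival import grouping_method_for_score

    m = score_table.shape[0]
    results: dict[str, EnrichmentResult] = {}
    for rank_col, (score_col, _asc) in RANK_COLUMNS.items():
        list_name = rank_col.removeprefix("rank_")
        method = grouping_method_for_score(
            "kurtosis" if list_name.startswith("kurtosis") else score_col
        )
        scan = scan_tables[method]
        prognostic = select_prognostic(scan["p_perm"], top_n=top_n)
        ranks = score_table.loc[prognostic, rank_col].to_numpy()
        results[list_name] = enrichment_for_list(
            list_name, ranks, m, fisher_k=fisher_k
        )
    return results


@dataclass
class ScoreComparison:
    """Correlation structure of the seven scores across genes."""

    pearson: pd.DataFrame
    spearman: pd.DataFrame
    linkage_pearson: np.ndarray
    linkage_spearman: np.ndarray
    newick_pearson: str
    newick_spearman: str


def _newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = sch.to_tree(linkage)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return rec(tree, tree.dist) + ";"


def score_comparison(score_table: pd.DataFrame) -> ScoreComparison:
    """Pearson/Spearman correlation matrices of the scores plus dendrograms.

    The likelihood ratio enters on the log scale (as stored).  Genes with any
    missing score are dropped; a score column that is constant across the
    remaining genes gets missing correlations (with a warning) and is left
    out of the clustering.  Average-linkage hierarchical clustering runs on
    the distance matrix 1 - C.
    """
    data = score_table[SCORE_COLUMNS].dropna()
    if data.shape[0] < 2:
        raise ValueError("need at least 2 genes with complete scores")
    constant = [c for c in SCORE_COLUMNS if data[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant score column(s) {constant}: correlations set missing",
            stacklevel=2,
        )
    pearson = data.corr(method="pearson")
    spearman = data.corr(method="spearman")
    for c in constant:
        pearson.loc[c, :] = pearson.loc[:, c] = np.nan
        spearman.loc[c, :] = spearman.loc[:, c] = np.nan
    np.fill_diagonal(pearson.values, 1.0)
    np.fill_diagonal(spearman.values, 1.0)

    usable = [c for c in SCORE_COLUMNS if c not in constant]
    out = {}
    for name, corr in (("pearson", pearson), ("spearman", spearman)):
        sub = corr.loc[usable, usable].to_numpy()
        dist = 1.0 - sub
        condensed = dist[np.triu_indices(len(usable), k=1)]
        link = sch.linkage(condensed, method="average")
        out[name] = (link, _newick(link, usable))
    return ScoreComparison(
        pearson=pearson,
        spearman=spearman,
        linkage_pearson=out["pearson"][0],
        linkage_spearman=out["spearman"][0],
        newick_pearson=out["pearson"][1],
        newick_spearman=out["spearman"][1],
    )
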