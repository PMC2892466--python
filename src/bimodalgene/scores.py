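"""The seven per-gene bimodality scores and the genome-wide score table.

Scores and their directions (which tail of the ranked list is "most bimodal"):

===================  =========================================  ==========
score                what it measures                           bimodal at
===================  =========================================  ==========
VRS                  WSS/TSS of the 2-means split               low values
WVRS                 mean within-cluster variance / variance    low values
dip                  sup-distance of ECDF from unimodality      high values
kurtosis             unbiased excess kurtosis                   both tails
log likelihood       log L2/L1, 2- vs 1-component normal fit    high values
ratio
bimodality index     sqrt(pi (1-pi)) * |mu1-mu2| / sigma        high values
outlier sum          sum of median/MAD-standardised values      high values
                     beyond the quartile fences (larger side)
===================  =========================================  ==========

Kurtosis separates two shapes: balanced two-group genes are platykurtic
(negative) while outlier-driven genes are leptokurtic (positive), so
:func:`score_all` ranks it in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dip as _dip
from .clustering import (
    GeneGrouping,
    fit_mixture,
    fit_mixture_equal_variance,
    kmeans_univariate,
)
from .exceptions import (
    DegenerateInputError,
    EmptyInputError,
    InsufficientDataError,
)

__all__ = [
    "vrs",
    "wvrs",
    "kurtosis",
    "likelihood_ratio",
    "bimodality_index",
    "outlier_sum",
    "OutlierSumResult",
    "grouping_from_outliers",
    "score_all",
    "SCORE_COLUMNS",
    "RANK_COLUMNS",
]

#: consistency factor making the MAD unbiased for the normal sigma
MAD_SCALE = 1.4826022185056018

SCORE_COLUMNS = [
    "vrs",
    "wvrs",
    "dip",
    "kurtosis",
    "log_lr",
    "bimodality_index",
    "outlier_sum",
]

#: rank list name -> (score column, ascending?)
RANK_COLUMNS = {
    "rank_vrs": ("vrs", True),
    "rank_wvrs": ("wvrs", True),
    "rank_dip": ("dip", False),
    "rank_kurtosis_pos": ("kurtosis", False),
    "rank_kurtosis_neg": ("kurtosis", True),
    "rank_log_lr": ("log_lr", False),
    "rank_bi": ("bimodality_index", False),
    "rank_outlier_sum": ("outlier_sum", False),
}


def vrs(values) -> float:
    """Variance reduction score: WSS/TSS of the two-cluster k-means split.

    Lies in [0, 1]; a low value means the split explains most of the gene's
    variance, i.e. two well separated groups.
    """
    part = kmeans_univariate(values)
    return part.wss / part.tss


def wvrs(values) -> float:
    """Weighted variance reduction score.

    Mean of the two within-cluster sample variances over the overall sample
    variance, so a tiny cluster carries the same weight as a large one.  A
    singleton cluster contributes variance 0, which makes genes with one
    extreme outlier score 0.  Can exceed 1.
    """
    x = np.asarray(values, dtype=float).ravel()
    part = kmeans_univariate(x)
    within = []
    for g in (1, 2):
        vals = x[part.labels == g]
        within.append(float(np.var(vals, ddof=1)) if vals.size > 1 else 0.0)
    total = float(np.var(x, ddof=1))
    return (within[0] + within[1]) / 2.0 / total


def kurtosis(values) -> float:
    """Unbiased excess kurtosis; 0 for a gaussian.

    K = [n(n+1) / ((n-1)(n-2)(n-3))] * sum(((x - mean)/s)^4)
        - 3 (n-1)^2 / ((n-2)(n-3)),

    with s the (n-1)-divisor sample standard deviation.  Negative for
    balanced two-group mixtures, positive for outlier-heavy distributions.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"kurtosis requires n >= 4, got {n}")
    s2 = float(np.var(x, ddof=1))
    if s2 == 0:
        raise DegenerateInputError("all values identical")
    z4 = float(np.sum(((x - x.mean()) ** 2 / s2) ** 2))
    return (
        n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * z4
        - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    )


def likelihood_ratio(values) -> float:
    """Log likelihood ratio of the two- versus one-component normal model.

    log(L2/L1) with the unequal-variance mixture; non-negative at the EM
    optimum because the models are nested.  Large values flag genes whose
    expression is better described by two normal components.
    """
    fit = fit_mixture(values)
    return fit.loglik2 - fit.loglik1


def bimodality_index(values) -> float:
    """Bimodality index sqrt(pi (1 - pi)) * delta of the equal-variance mixture.

    delta = |mu1 - mu2| / sigma is the standardised separation of the two
    components.  The conventional cutoff for calling a gene bimodal is 1.1
    (pi = 0.5, delta = 2.2).
    """
    fit = fit_mixture_equal_variance(values)
    sigma = np.sqrt(fit.var1)
    if sigma == 0:
        return 0.0
    delta = abs(fit.mu2 - fit.mu1) / sigma
    return float(np.sqrt(fit.pi * (1.0 - fit.pi)) * delta)


@dataclass
class OutlierSumResult:
    """Outlier-sum statistic of one gene.

    ``statistic`` is signed: positive when the high-expression outliers win,
    negative when the low-expression outliers do.  ``score`` (its absolute
    value) is what the ranked gene list uses.  ``outlier_mask`` flags the
    samples on the winning side only.
    """

    statistic: float
    outlier_mask: np.ndarray
    side: str
    standardized: np.ndarray

    @property
    def score(self) -> float:
        return abs(self.statistic)


def outlier_sum(values, fence: str = "standard", mad_scale: bool = True) -> OutlierSumResult:
    """Modified outlier-sum statistic for a single-cohort design.

    Values are standardised by median and MAD; quartiles q25, q75 and the IQR
    of the standardised values define the outlier fences.  W sums the
    standardised values above the upper fence, W' those below the lower fence;
    the statistic is whichever of W and W' is larger in absolute value.

    Parameters
    ----------
    fence:
        ``"standard"`` uses the usual fences ``q25 - IQR`` and ``q75 + IQR``.
        ``"literal"`` uses ``IQR - q25`` and ``IQR + q75`` instead (a variant
        occasionally seen in print; kept selectable for comparison).
    mad_scale:
        Scale the MAD by 1.4826 so it estimates a normal sigma (default);
        ``False`` uses the raw MAD.

    Raises
    ------
    DegenerateInputError
        If both the MAD and the fallback mean absolute deviation are zero.
    InsufficientDataError
        If fewer than 4 observations are supplied.
    """
    if fence not in ("standard", "literal"):
        raise ValueError(f"unknown fence convention: {fence!r}")
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise InsufficientDataError(f"outlier sum requires n >= 4, got {x.size}")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad_scale:
        mad *= MAD_SCALE
    if mad == 0:
        # fall back to the mean absolute deviation from the median
        mad = float(np.mean(np.abs(x - med)))
        if mad == 0:
            raise DegenerateInputError("no spread around the median")
    z = (x - med) / mad
    q25, q75 = np.percentile(z, [25, 75])
    iqr = q75 - q25
    if fence == "standard":
        lo_fence, hi_fence = q25 - iqr, q75 + iqr
    else:
        lo_fence, hi_fence = iqr - q25, iqr + q75
    pos_mask = z > hi_fence
    neg_mask = z < lo_fence
    w_pos = float(np.sum(z[pos_mask]))
    w_neg = float(np.sum(z[neg_mask]))
    if abs(w_pos) >= abs(w_neg):
        return OutlierSumResult(
            statistic=w_pos, outlier_mask=pos_mask, side="positive", standardized=z
        )
    return OutlierSumResult(
        statistic=w_neg, outlier_mask=neg_mask, side="negative", standardized=z
    )


def grouping_from_outliers(result: OutlierSumResult, gene_id: str | None = None) -> GeneGrouping:
    """Outliers on the winning side versus everyone else.

    Group 2 holds the high-expression outliers when the positive side won;
    for negative outliers the outlier group is the low-expression group 1.
    With no outliers all samples share one group and the survival layer
    reports p = 1.
    """
    mask = result.outlier_mask
    if result.side == "positive":
        labels = np.where(mask, 2, 1).astype(np.int8)
    else:
        labels = np.where(mask, 1, 2).astype(np.int8)
    return GeneGrouping(labels=labels, method="outlier", gene_id=gene_id)


def _rank(values: np.ndarray, gene_ids: np.ndarray, ascending: bool) -> np.ndarray:
    """Dense 1..G ranks; ties and missing values broken by gene identifier.

    Missing scores sort after every observed score ("worst" ranks), so a
    constant gene in a G-gene matrix gets a rank close to G on every list.
    """
    v = values.astype(float).copy()
    if not ascending:
        v = -v
    nan = np.isnan(v)
    v[nan] = np.inf
    order = np.lexsort((gene_ids, nan, v))
    ranks = np.empty(v.size, dtype=np.int64)
    ranks[order] = np.arange(1, v.size + 1)
    return ranks


def score_all(
    matrix: pd.DataFrame,
    fence: str = "standard",
    mad_scale: bool = True,
) -> pd.DataFrame:
    """All seven bimodality scores plus per-score ranks for every gene.

    Parameters
    ----------
    matrix:
        Genes x samples expression frame (log2-scale intensities); missing
        cells are dropped per gene.
    fence, mad_scale:
        Passed through to :func:`outlier_sum`.

    Returns
    -------
    DataFrame indexed by gene id with the seven score columns and one integer
    rank column per ranked list (1 = most bimodal; kurtosis appears twice,
    once per direction).  Genes whose scores cannot be computed (constant
    rows, too many missing cells) carry NaN scores and worst ranks.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise EmptyInputError("empty expression matrix")
    records = {col: np.full(matrix.shape[0], np.nan) for col in SCORE_COLUMNS}
    data = matrix.to_numpy(dtype=float)
    for i in range(data.shape[0]):
        row = data[i]
        row = row[~np.isnan(row)]
        if row.size < 4 or np.ptp(row) == 0:
            continue
        part = kmeans_univariate(row)
        records["vrs"][i] = part.wss / part.tss
        records["wvrs"][i] = wvrs(row)
        records["dip"][i] = _dip.dip_statistic(row)
        records["kurtosis"][i] = kurtosis(row)
        records["log_lr"][i] = likelihood_ratio(row)
        records["bimodality_index"][i] = bimodality_index(row)
        records["outlier_sum"][i] = outlier_sum(row, fence=fence, mad_scale=mad_scale).score
    table = pd.DataFrame(records, index=matrix.index)
    gene_ids = matrix.index.astype(str).to_numpy()
    for rank_col, (score_col, ascending) in RANK_COLUMNS.items():
        table[rank_col] = _rank(table[score_col].to_numpy(), gene_ids, ascending)
    return table
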