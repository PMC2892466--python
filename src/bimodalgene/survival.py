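"""Logrank statistic, permutation p-values, Kaplan-Meier curves, genome scan.

The two-group logrank statistic compares hazard rates up to the largest time
at which both groups still have a subject at risk:

    Z = sum_i (d_i1 - Y_i1 d_i / Y_i)
        / sqrt( sum_i (Y_i1/Y_i)(1 - Y_i1/Y_i)((Y_i - d_i)/(Y_i - 1)) d_i )

summing over distinct event times with at least two subjects at risk; group 1
is the lower-expression group.  Because the groups produced by bimodal splits
are often tiny (sometimes a single outlying patient) the normal approximation
for Z is unreliable, so significance always comes from a permutation test:
group labels are permuted over patients with fixed group sizes and

    p = (#{|Z_perm| >= |Z_obs|} + 1) / (n_perm + 1).

Degenerate splits (all patients in one group) are scored p = 1 without
permutation — such genes look unimodal and carry no split information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import (
    GeneGrouping,
    fit_mixture,
    grouping_from_mixture,
    kmeans_univariate,
)
from .exceptions import (
    AlignmentError,
    BimodalGeneError,
    ConfigError,
    DegenerateGroupError,
)
from .scores import grouping_from_outliers, outlier_sum

__all__ = [
    "LogrankResult",
    "logrank_z",
    "permutation_pvalue",
    "km_estimate",
    "prognostic_scan",
    "grouping_method_for_score",
    "make_grouping",
]

#: permutation count floor; a permutation p-value from fewer draws is noise
MIN_PERMUTATIONS = 100

#: which grouping family backs each ranked score list in the survival scan
_SCORE_TO_METHOD = {
    "vrs": "kmeans",
    "wvrs": "kmeans",
    "dip": "kmeans",
    "kurtosis": "mixture",
    "kurtosis_pos": "mixture",
    "kurtosis_neg": "mixture",
    "log_lr": "mixture",
    "bimodality_index": "mixture",
    "outlier_sum": "outlier",
}


@dataclass
class LogrankResult:
    """Observed logrank Z plus its permutation p-value."""

    z: float
    p_perm: float
    n_perm: int
    degenerate: bool = False


def grouping_method_for_score(score: str) -> str:
    """Grouping family used for a score's survival evaluation.

    k-means backs the cluster scores (VRS, WVRS) and the dip; the model-based
    mixture backs kurtosis, the likelihood ratio and the bimodality index; the
    outlier-sum list splits outliers versus the main group.
    """
    try:
        return _SCORE_TO_METHOD[score]
    except KeyError:
        raise ConfigError(f"unknown score {score!r}") from None


def make_grouping(values, method: str, gene_id: str | None = None) -> GeneGrouping:
    """Build the low/high grouping of one gene by the requested family."""
    if method == "kmeans":
        part = kmeans_univariate(values)
        return GeneGrouping(labels=part.labels, method="kmeans", gene_id=gene_id)
    if method == "mixture":
        g = grouping_from_mixture(fit_mixture(values), gene_id=gene_id)
        return g
    if method == "outlier":
        return grouping_from_outliers(outlier_sum(values), gene_id=gene_id)
    raise ConfigError(f"unknown grouping method {method!r}")


class _LogrankEngine:
    """Precomputed risk-set structure of one survival dataset.

    Holds, per distinct event time with Y_i >= 2, the at-risk and event
    indicator matrices so that Z can be evaluated for many candidate group
    assignments with two matrix products.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
        if time.size == 0:
            raise DegenerateGroupError("empty survival table")
        self.n = time.size
        if not event.any():
            raise DegenerateGroupError("no events observed")
        etimes = np.unique(time[event])
        at_risk = time[None, :] >= etimes[:, None]          # (D, n)
        ev_here = event[None, :] & (time[None, :] == etimes[:, None])
        y = at_risk.sum(axis=1)
        keep = y >= 2
        self.at_risk = at_risk[keep].astype(float)
        self.ev_here = ev_here[keep].astype(float)
        self.y = y[keep].astype(float)
        self.d = self.ev_here.sum(axis=1)

    def z(self, group1: np.ndarray) -> np.ndarray:
        """Z for each column of a boolean (n,) or (n, P) group-1 indicator."""
        g = np.asarray(group1, dtype=float)
        squeeze = g.ndim == 1
        if squeeze:
            g = g[:, None]
        y1 = self.at_risk @ g                                # (D, P)
        d1 = self.ev_here @ g
        frac = y1 / self.y[:, None]
        num = (d1 - frac * self.d[:, None]).sum(axis=0)
        var = (
            frac
            * (1.0 - frac)
            * ((self.y - self.d) / (self.y - 1.0))[:, None]
            * self.d[:, None]
        ).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var > 0, num / np.sqrt(var), 0.0)
        return z[0] if squeeze else z


def _extract(survival: pd.DataFrame):
    return (
        survival["time"].to_numpy(dtype=float),
        survival["event"].to_numpy(dtype=bool),
    )


def logrank_z(survival: pd.DataFrame, grouping: GeneGrouping) -> float:
    """Observed logrank Z; group 1 (lower expression) enters the numerator.

    Raises
    ------
    DegenerateGroupError
        If a group is empty or no events were observed.
    """
    labels = np.asarray(grouping.labels)
    if grouping.degenerate:
        raise DegenerateGroupError(f"empty group (sizes {grouping.sizes})")
    time, event = _extract(survival)
    if labels.size != time.size:
        raise AlignmentError(
            f"{labels.size} group labels vs {time.size} survival records"
        )
    engine = _LogrankEngine(time, event)
    z = float(engine.z(labels == 1))
    if z == 0.0 and not np.any(engine.d):
        warnings.warn("logrank variance is zero; returning Z = 0", stacklevel=2)
    return z


def permutation_pvalue(
    survival: pd.DataFrame,
    grouping: GeneGrouping,
    n_perm: int = 100_000,
    seed: int | None = None,
    _engine: _LogrankEngine | None = None,
) -> LogrankResult:
    """Two-sided permutation p-value of the logrank statistic.

    Group labels are permuted over patients (group sizes fixed); the p-value
    is the fraction of permutations at least as extreme as observed, with the
    +1 correction.  A degenerate grouping short-circuits to p = 1.

    Raises
    ------
    ConfigError
        If ``n_perm`` is below the floor of 100.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ConfigError(f"n_perm must be >= {MIN_PERMUTATIONS}, got {n_perm}")
    if grouping.degenerate:
        return LogrankResult(z=np.nan, p_perm=1.0, n_perm=0, degenerate=True)
    time, event = _extract(survival)
    engine = _engine if _engine is not None else _LogrankEngine(time, event)
    g = np.asarray(grouping.labels) == 1
    z_obs = float(engine.z(g))
    rng = np.random.default_rng(seed)
    gmat = rng.permuted(
        np.broadcast_to(g, (n_perm, g.size)).copy(), axis=1
    ).T.astype(float)
    z_perm = engine.z(gmat)
    hits = int(np.sum(np.abs(z_perm) >= abs(z_obs) - 1e-10))
    return LogrankResult(
        z=z_obs, p_perm=(hits + 1) / (n_perm + 1), n_perm=n_perm
    )


def km_estimate(survival: pd.DataFrame, grouping: GeneGrouping) -> dict[int, pd.DataFrame]:
    """Kaplan-Meier product-limit curves of the two groups.

    Returns one frame per non-empty group with columns ``time``,
    ``survival_prob`` (step values, starting at 1) and ``censored`` marking
    times at which censoring occurred.
    """
    from lifelines import KaplanMeierFitter

    time, event = _extract(survival)
    labels = np.asarray(grouping.labels)
    curves: dict[int, pd.DataFrame] = {}
    for g in (1, 2):
        mask = labels == g
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        sf = kmf.survival_function_
        frame = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival_prob": sf.iloc[:, 0].to_numpy(dtype=float),
            }
        )
        cens_times = np.unique(time[mask & ~event])
        frame["censored"] = frame["time"].isin(cens_times)
        curves[g] = frame
    return curves


def prognostic_scan(
    matrix: pd.DataFrame,
    survival: pd.DataFrame,
    method: str = "kmeans",
    n_perm: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation logrank p-value for every gene's two-group split.

    Parameters
    ----------
    matrix:
        Genes x samples expression frame; columns must match the survival
        table's sample ids (order-insensitive).
    method:
        Grouping family (``kmeans``, ``mixture`` or ``outlier``) or a score
        name, which is mapped to its family via
        :func:`grouping_method_for_score`.
    seed:
        Master seed; each gene's permutation stream is derived from
        ``(seed, gene_index)`` so results do not depend on scan order.

    Returns
    -------
    DataFrame indexed by gene id with columns ``n1``, ``n2``, ``z``,
    ``p_perm`` and ``degenerate``.  Genes with degenerate splits (or rows on
    which no grouping can be formed) get p = 1.
    """
    if method in _SCORE_TO_METHOD:
        method = _SCORE_TO_METHOD[method]
    if method not in ("kmeans", "mixture", "outlier"):
        raise ConfigError(f"unknown grouping method {method!r}")
    if n_perm < MIN_PERMUTATIONS:
        raise ConfigError(f"n_perm must be >= {MIN_PERMUTATIONS}, got {n_perm}")
    if set(matrix.columns) != set(survival.index):
        raise AlignmentError("expression samples and survival ids differ")
    surv = survival.loc[list(matrix.columns)]
    time, event = _extract(surv)
    engine = _LogrankEngine(time, event)

    out = {
        "n1": np.zeros(matrix.shape[0], dtype=int),
        "n2": np.zeros(matrix.shape[0], dtype=int),
        "z": np.full(matrix.shape[0], np.nan),
        "p_perm": np.ones(matrix.shape[0]),
        "degenerate": np.ones(matrix.shape[0], dtype=bool),
    }
    data = matrix.to_numpy(dtype=float)
    for i in range(data.shape[0]):
        row = data[i]
        ok = ~np.isnan(row)
        gene_seed = np.random.SeedSequence((seed, i))
        try:
            grouping = make_grouping(row[ok], method)
        except BimodalGeneError:
            continue  # untestable gene: keep p = 1, degenerate
        if grouping.degenerate:
            continue
        if ok.all():
            res = permutation_pvalue(
                surv, grouping, n_perm=n_perm, seed=gene_seed, _engine=engine
            )
        else:  # missing cells: test on the complete samples only
            res = permutation_pvalue(
                surv.loc[ok], grouping, n_perm=n_perm, seed=gene_seed
            )
        out["n1"][i], out["n2"][i] = grouping.sizes
        out["z"][i] = res.z
        out["p_perm"][i] = res.p_perm
        out["degenerate"][i] = res.degenerate
    return pd.DataFrame(out, index=matrix.index)
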