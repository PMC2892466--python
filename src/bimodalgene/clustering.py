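"""Univariate two-group clustering: k-means and Gaussian mixture models.

A gene with a bimodal expression distribution splits the cohort into a low and a
high expression group.  Two routes produce that split:

* :func:`kmeans_univariate` — k-means with k = 2, deterministically initialised
  at the minimum and maximum observed value, so the low/high structure of the
  gene decides the partition rather than a random start.
* :func:`fit_mixture` — maximum-likelihood fit of a two-component normal
  mixture by EM.  The unequal-variance model is fitted first; when a component
  collapses (variance under the floor, or a single supporting observation) the
  model is refitted with a shared variance, mirroring the behaviour needed for
  genes whose second "component" is a lone outlier.

The sum-of-squares decomposition TSS = BSS + WSS of the k-means partition is
exposed on :class:`Partition` because two of the bimodality scores (VRS, WVRS)
are ratios of those terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, InsufficientDataError

__all__ = [
    "Partition",
    "MixtureFit",
    "GeneGrouping",
    "kmeans_univariate",
    "fit_mixture",
    "fit_mixture_equal_variance",
    "grouping_from_mixture",
]

#: relative variance floor below which a mixture component counts as collapsed
VARIANCE_FLOOR_REL = 1e-6
#: EM convergence tolerance on the log-likelihood
EM_TOL = 1e-8
#: EM iteration cap
EM_MAX_ITER = 500


@dataclass
class Partition:
    """A two-group split of a univariate sample.

    ``labels`` are 1 (lower-mean cluster) or 2 (higher-mean cluster).
    ``tss = bss + wss`` holds to floating-point accuracy.
    """

    labels: np.ndarray
    centers: tuple[float, float]
    sizes: tuple[int, int]
    wss: float
    bss: float
    tss: float


@dataclass
class MixtureFit:
    """Converged parameters of a two-component univariate normal mixture.

    Component 1 is the lower-mean component.  ``pi`` is the mixing proportion
    of component 1, ``responsibilities`` the per-observation posterior
    probability of component 1.  ``loglik1`` is the closed-form log-likelihood
    of the single-normal MLE (variance divisor n) so that
    ``loglik2 - loglik1`` is a proper nested likelihood-ratio statistic.
    """

    mu1: float
    mu2: float
    var1: float
    var2: float
    pi: float
    loglik1: float
    loglik2: float
    equal_variance_used: bool
    responsibilities: np.ndarray


@dataclass
class GeneGrouping:
    """Hard assignment of samples to a low (1) / high (2) expression group.

    ``labels`` may contain only one distinct value; downstream survival code
    treats such groupings as degenerate (p-value 1).
    """

    labels: np.ndarray
    method: str
    gene_id: str | None = None

    @property
    def sizes(self) -> tuple[int, int]:
        labels = np.asarray(self.labels)
        return int(np.sum(labels == 1)), int(np.sum(labels == 2))

    @property
    def degenerate(self) -> bool:
        n1, n2 = self.sizes
        return n1 == 0 or n2 == 0


def _as_valid_values(values, min_n: int) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < min_n:
        raise InsufficientDataError(
            f"need at least {min_n} observations, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("all values identical")
    return x


def kmeans_univariate(values) -> Partition:
    """Two-cluster k-means of a univariate sample, initialised at min and max.

    The initialisation at the extremes makes the result deterministic and
    orients it along the expression axis.  Assignment and centre updates
    alternate until the labels stabilise.  Points equidistant from both
    centres join the lower centre.

    Raises
    ------
    DegenerateInputError
        If all values are identical.
    InsufficientDataError
        If fewer than two observations are supplied.
    """
    x = _as_valid_values(values, 2)
    c1, c2 = float(np.min(x)), float(np.max(x))

    def assign(a, b):
        # tie goes to the lower centre: strict inequality for cluster 2
        return np.where(np.abs(x - b) < np.abs(x - a), 2, 1).astype(np.int8)

    labels = assign(c1, c2)
    for _ in range(1000):
        m1, m2 = x[labels == 1], x[labels == 2]
        if m1.size == 0 or m2.size == 0:
            break
        c1, c2 = float(m1.mean()), float(m2.mean())
        new_labels = assign(c1, c2)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    # cluster means must match the final assignment exactly for TSS = BSS + WSS
    c1 = float(x[labels == 1].mean())
    c2 = float(x[labels == 2].mean())
    if c1 > c2:  # keep group 1 the lower-mean cluster
        labels = np.where(labels == 1, 2, 1).astype(np.int8)
        c1, c2 = c2, c1
    n1 = int(np.sum(labels == 1))
    n2 = x.size - n1
    mean = x.mean()
    tss = float(np.sum((x - mean) ** 2))
    wss = float(np.sum((x[labels == 1] - c1) ** 2) + np.sum((x[labels == 2] - c2) ** 2))
    bss = float(n1 * (c1 - mean) ** 2 + n2 * (c2 - mean) ** 2)
    return Partition(
        labels=labels,
        centers=(c1, c2),
        sizes=(n1, n2),
        wss=wss,
        bss=bss,
        tss=tss,
    )


def _njit(func):
    try:
        from numba import njit

        return njit(cache=True)(func)
    except ImportError:  # pragma: no cover - numba is a hard dependency
        return func


def _normal_loglik_one_component(x: np.ndarray) -> float:
    """Closed-form log-likelihood of the single-normal MLE (variance divisor n)."""
    n = x.size
    var = float(np.mean((x - x.mean()) ** 2))
    if var <= 0:
        raise DegenerateInputError("zero variance")
    return -0.5 * n * (np.log(2 * np.pi * var) + 1.0)


@_njit
def _em_core(x, resp, equal_variance, floor, tol, max_iter):
    """EM iterations from initial responsibilities (modified in place).

    Returns (ok, pi, mu1, var1, mu2, var2, loglik).  ok = False flags a
    collapsed unequal-variance fit: a component variance under the floor or
    an (essentially) empty component, the regimes where that likelihood is
    unbounded.
    """
    n = x.shape[0]
    log2pi = np.log(2.0 * np.pi)
    pi = 0.5
    mu1 = mu2 = 0.0
    var1 = var2 = 1.0
    loglik = -np.inf
    for _ in range(max_iter):
        # M step
        n1 = 0.0
        s1 = 0.0
        s2 = 0.0
        for i in range(n):
            n1 += resp[i]
            s1 += resp[i] * x[i]
            s2 += (1.0 - resp[i]) * x[i]
        n2 = n - n1
        if n1 < 1.0 or n2 < 1.0:
            return False, pi, mu1, var1, mu2, var2, loglik
        pi = n1 / n
        mu1 = s1 / n1
        mu2 = s2 / n2
        v1 = 0.0
        v2 = 0.0
        for i in range(n):
            v1 += resp[i] * (x[i] - mu1) ** 2
            v2 += (1.0 - resp[i]) * (x[i] - mu2) ** 2
        if equal_variance:
            var1 = var2 = max((v1 + v2) / n, floor)
        else:
            var1 = v1 / n1
            var2 = v2 / n2
            if var1 < floor or var2 < floor:
                return False, pi, mu1, var1, mu2, var2, loglik
        # E step
        p = min(max(pi, 1e-12), 1.0 - 1e-12)
        la = np.log(p) - 0.5 * np.log(var1)
        lb = np.log(1.0 - p) - 0.5 * np.log(var2)
        new_loglik = 0.0
        for i in range(n):
            lg1 = la - 0.5 * (x[i] - mu1) ** 2 / var1
            lg2 = lb - 0.5 * (x[i] - mu2) ** 2 / var2
            if lg1 > lg2:
                m = lg1
            else:
                m = lg2
            new_loglik += m + np.log(np.exp(lg1 - m) + np.exp(lg2 - m))
            diff = lg2 - lg1
            if diff > 35.0:
                resp[i] = 0.0
            elif diff < -35.0:
                resp[i] = 1.0
            else:
                resp[i] = 1.0 / (1.0 + np.exp(diff))
        new_loglik -= 0.5 * n * log2pi
        if abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            break
        loglik = new_loglik
    return True, pi, mu1, var1, mu2, var2, loglik


def _em(x: np.ndarray, resp0: np.ndarray, equal_variance: bool):
    """Run EM from initial responsibilities.  Returns params or None on collapse."""
    floor = VARIANCE_FLOOR_REL * float(np.var(x))
    resp = resp0.astype(float).copy()
    ok, pi, mu1, var1, mu2, var2, loglik = _em_core(
        np.ascontiguousarray(x, dtype=np.float64),
        resp,
        equal_variance,
        floor,
        EM_TOL,
        EM_MAX_ITER,
    )
    if not ok:
        return None
    return pi, mu1, var1, mu2, var2, loglik, resp


def _orient(pi, mu1, var1, mu2, var2, resp):
    """Ensure component 1 is the lower-mean component."""
    if mu1 > mu2:
        return 1 - pi, mu2, var2, mu1, var1, 1 - resp
    return pi, mu1, var1, mu2, var2, resp


def _singleton_fit(x: np.ndarray) -> MixtureFit | None:
    """Degenerate fallback placing both components on the pooled normal."""
    mu = float(x.mean())
    var = float(np.mean((x - mu) ** 2))
    ll1 = _normal_loglik_one_component(x)
    return MixtureFit(
        mu1=mu,
        mu2=mu,
        var1=var,
        var2=var,
        pi=0.5,
        loglik1=ll1,
        loglik2=ll1,
        equal_variance_used=True,
        responsibilities=np.full(x.size, 0.5),
    )


def _finish(x, fit_params, equal_variance_used) -> MixtureFit:
    pi, mu1, var1, mu2, var2, loglik2, resp = fit_params
    pi, mu1, var1, mu2, var2, resp = _orient(pi, mu1, var1, mu2, var2, resp)
    ll1 = _normal_loglik_one_component(x)
    if loglik2 < ll1:
        # EM reached a local optimum below the nested one-component model;
        # report the one-component point of the mixture family instead.
        return _singleton_fit(x)
    return MixtureFit(
        mu1=mu1,
        mu2=mu2,
        var1=var1,
        var2=var2,
        pi=pi,
        loglik1=ll1,
        loglik2=loglik2,
        equal_variance_used=equal_variance_used,
        responsibilities=np.clip(resp, 0.0, 1.0),
    )


def fit_mixture(values) -> MixtureFit:
    """Fit a two-component normal mixture, preferring unequal variances.

    EM is initialised from the deterministic k-means partition.  If the
    unequal-variance fit collapses (a component shrinks to a near-singleton or
    its variance hits the floor, as happens when a gene has one extreme
    outlier) the model is refitted with a shared variance and
    ``equal_variance_used`` is set.

    Raises
    ------
    DegenerateInputError
        If all values are identical.
    InsufficientDataError
        If fewer than three observations are supplied.
    """
    x = _as_valid_values(values, 3)
    resp0 = (kmeans_univariate(x).labels == 1).astype(float)
    result = _em(x, resp0, equal_variance=False)
    if result is not None:
        return _finish(x, result, equal_variance_used=False)
    result = _em(x, resp0, equal_variance=True)
    if result is None:
        return _singleton_fit(x)
    return _finish(x, result, equal_variance_used=True)


def fit_mixture_equal_variance(values) -> MixtureFit:
    """Fit the two-component mixture with a shared component variance.

    This is the model behind the bimodality index, whose standardised
    separation delta assumes a common sigma.
    """
    x = _as_valid_values(values, 3)
    resp0 = (kmeans_univariate(x).labels == 1).astype(float)
    result = _em(x, resp0, equal_variance=True)
    if result is None:
        return _singleton_fit(x)
    return _finish(x, result, equal_variance_used=True)


def grouping_from_mixture(fit: MixtureFit, gene_id: str | None = None) -> GeneGrouping:
    """Hard-assign each sample to the mixture component with larger posterior.

    Ties go to the lower-mean component (component 1).  The grouping may be
    degenerate (one empty group) when the mixture collapsed onto one component;
    the survival layer then reports p = 1.
    """
    labels = np.where(np.asarray(fit.responsibilities) >= 0.5, 1, 2).astype(np.int8)
    return GeneGrouping(labels=labels, method="mixture", gene_id=gene_id)
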