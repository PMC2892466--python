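"""Hartigan & Hartigan dip statistic, Monte-Carlo null table, and p-values.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and any unimodal distribution function (convex below the
mode, concave above it, an atom allowed at the mode).

Computation
-----------
The classic modal-interval iteration on the sorted sample: fit the greatest
convex minorant (GCM) of the empirical CDF (through the lower jump corners
``(x_j, (j-1)/n)``) and the least concave majorant (LCM, through the upper
corners ``(x_j, j/n)``) over the current candidate modal interval.  The
largest cross-distance between the two fits — measured at LCM touch points
against the GCM and at GCM touch points against the LCM — quantifies how much
slack a unimodal CDF needs to bridge from the convex to the concave branch
inside the interval.  If it exceeds the deviations accumulated so far, the
modal interval shrinks to the chord endpoints achieving that distance, the
one-sided hull deviations in the stripped-off flanks are folded into the
running maximum, and the iteration repeats; otherwise the dip is half the
running maximum.  Working in count units, the result is ``D / (2n)`` and never
below ``1/(2n)``.

The null distribution is estimated by Monte Carlo from uniform samples, the
calibration case in which the dip is asymptotically largest among unimodal
distributions; p-values use the (b+1)/(B+1) estimator.  A compact pre-built
table ships with the package; larger tables can be regenerated via
``bimodalgene simulate-dip-null``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _importlib_resources

import numpy as np

from .exceptions import ConfigError, ExtrapolationError, InsufficientDataError

__all__ = [
    "DipResult",
    "DipNullTable",
    "dip_statistic",
    "dip_test",
    "build_null_table",
    "dip_pvalue",
    "default_null_table",
]

#: sizes covered by the table shipped in ``resources/``
DEFAULT_NULL_SIZES = (50, 100, 200, 500, 1000)
#: replicates in the shipped table (kept compact; regenerate for more)
DEFAULT_NULL_REPS = 2000
#: seed used to build the shipped table
DEFAULT_NULL_SEED = 20100525


def _njit(func):
    try:
        from numba import njit

        return njit(cache=True)(func)
    except ImportError:  # pragma: no cover - numba is a hard dependency
        return func


@_njit
def _gcm_hull(x, lo, hi, verts):
    """Lower convex hull vertices of ``(x_j, j)`` for j in [lo, hi] (0-based).

    Writes vertex indices ascending into ``verts``; returns the count.  For
    tied x values only the first index of a run can be a vertex.
    """
    top = 0
    verts[0] = lo
    for j in range(lo + 1, hi + 1):
        if x[j] == x[verts[top]]:
            continue  # same abscissa, larger ordinate: never on the lower hull
        while top >= 1:
            a = verts[top - 1]
            b = verts[top]
            # pop b if it lies on or above the chord a -> j
            if (b - a) * (x[j] - x[a]) >= (j - a) * (x[b] - x[a]):
                top -= 1
            else:
                break
        top += 1
        verts[top] = j
    return top + 1


@_njit
def _lcm_hull(x, lo, hi, verts):
    """Upper concave hull vertices of ``(x_j, j)`` for j in [lo, hi] (0-based).

    For tied x values only the last index of a run can be a vertex.
    """
    top = 0
    verts[0] = lo
    for j in range(lo + 1, hi + 1):
        if x[j] == x[verts[top]]:
            verts[top] = j  # same abscissa, larger ordinate replaces it
            continue
        while top >= 1:
            a = verts[top - 1]
            b = verts[top]
            # pop b if it lies on or below the chord a -> j
            if (b - a) * (x[j] - x[a]) <= (j - a) * (x[b] - x[a]):
                top -= 1
            else:
                break
        top += 1
        verts[top] = j
    return top + 1


@_njit
def _max_dev_above_gcm(x, verts, nv, j_from, j_to):
    """max over j in [j_from, j_to] of  (j+1) - gcm(x_j)  in count units.

    The GCM interpolates the lower jump corners (x_v, v) at its vertices; the
    empirical CDF reaches (j+1) at x_j, so this is n * sup(F_n - gcm) on the
    range.  Equals 1 at vertices.
    """
    best = 0.0
    seg = 0
    for j in range(j_from, j_to + 1):
        while seg < nv - 2 and verts[seg + 1] < j:
            seg += 1
        a = verts[seg]
        b = verts[min(seg + 1, nv - 1)]
        if b == a or x[b] == x[a]:
            g = a
        else:
            g = a + (x[j] - x[a]) * (b - a) / (x[b] - x[a])
        dev = (j + 1) - g
        if dev > best:
            best = dev
    return best


@_njit
def _max_dev_below_lcm(x, verts, nv, j_from, j_to):
    """max over j in [j_from, j_to] of  lcm(x_j) - j  in count units.

    The LCM interpolates the upper jump corners (x_v, v+1); the empirical CDF
    left limit at x_j is j, so this is n * sup(lcm - F_n(.^-)).
    """
    best = 0.0
    seg = 0
    for j in range(j_from, j_to + 1):
        while seg < nv - 2 and verts[seg + 1] < j:
            seg += 1
        a = verts[seg]
        b = verts[min(seg + 1, nv - 1)]
        if b == a or x[b] == x[a]:
            lv = b + 1.0
        else:
            lv = (a + 1) + (x[j] - x[a]) * (b - a) / (x[b] - x[a])
        dev = lv - j
        if dev > best:
            best = dev
    return best


@_njit
def _dip_count(x):
    """Dip of a sorted sample in count units; the dip statistic is this / (2n)."""
    n = x.shape[0]
    if n < 2 or x[n - 1] == x[0]:
        return 1.0
    low = 0
    high = n - 1
    d_accum = 1.0
    gv = np.empty(n, dtype=np.int64)
    lv = np.empty(n, dtype=np.int64)
    for _ in range(n + 1):
        if x[low] == x[high]:
            # modal interval inside a tie run: an atom at the mode absorbs it
            break
        ng = _gcm_hull(x, low, high, gv)
        nl = _lcm_hull(x, low, high, lv)

        # largest cross-distance between the two fits inside [low, high]
        d = 0.0
        arg_lo = low
        arg_hi = high
        # at LCM touch points v: n*F_n(x_v) - gcm(x_v) = (v+1) - gcm(x_v)
        seg = 0
        for iv in range(nl):
            v = lv[iv]
            while seg < ng - 2 and gv[seg + 1] < v:
                seg += 1
            a = gv[seg]
            b = gv[min(seg + 1, ng - 1)]
            if b == a or x[b] == x[a]:
                g = float(a)
            else:
                g = a + (x[v] - x[a]) * (b - a) / (x[b] - x[a])
            dx = (v + 1) - g
            if dx > d:
                d = dx
                # if the GCM touches at the same x (tie run), narrow into the
                # run: an atom at the mode absorbs a purely vertical distance
                arg_lo = b if x[b] == x[v] else a
                arg_hi = v
        # at GCM touch points g: lcm(x_g) - n*F_n(x_g^-) = lcm(x_g) - g
        seg = 0
        for ig in range(ng):
            g = gv[ig]
            while seg < nl - 2 and lv[seg + 1] < g:
                seg += 1
            a = lv[seg]
            b = lv[min(seg + 1, nl - 1)]
            if b == a or x[b] == x[a]:
                lval = b + 1.0
            else:
                lval = (a + 1) + (x[g] - x[a]) * (b - a) / (x[b] - x[a])
            dx = lval - g
            if dx > d:
                d = dx
                arg_lo = g
                arg_hi = a if x[a] == x[g] else b

        if d <= d_accum:
            break
        # fold in the one-sided deviations on the stripped-off flanks
        dl = _max_dev_above_gcm(x, gv, ng, low, arg_lo)
        du = _max_dev_below_lcm(x, lv, nl, arg_hi, high)
        if dl > d_accum:
            d_accum = dl
        if du > d_accum:
            d_accum = du
        if arg_lo == low and arg_hi == high:
            # no progress possible; the cross-distance itself is the answer
            if d > d_accum:
                d_accum = d
            break
        low = arg_lo
        high = arg_hi
    return d_accum


def dip_statistic(values) -> float:
    """Exact dip statistic of a univariate sample.

    Invariant under permutation of the input (the statistic depends on the
    sorted sample only).  Lies in ``[1/(2n), 0.25]``; 0.25 is reached by two
    equally heavy point masses.

    Raises
    ------
    InsufficientDataError
        If fewer than 4 observations are supplied.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise InsufficientDataError(f"dip requires n >= 4, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    xs = np.sort(x)
    return float(_dip_count(xs)) / (2.0 * x.size)


@dataclass
class DipResult:
    """Dip statistic of a sample plus its Monte-Carlo p-value (if a table is given)."""

    dip: float
    n: int
    p_value: float | None = None


@dataclass
class DipNullTable:
    """Sorted Monte-Carlo dip values under the uniform null, per sample size."""

    dips: dict[int, np.ndarray]
    reps: int
    seed: int

    @property
    def sizes(self) -> list[int]:
        return sorted(self.dips)

    def percentile(self, n: int, q: float) -> float:
        """Empirical percentile (0-100) of the null dips for sample size n."""
        return float(np.percentile(self._lookup(n), q))

    def _lookup(self, n: int) -> np.ndarray:
        if n not in self.dips:
            raise ExtrapolationError(f"size {n} not tabulated")
        return self.dips[n]


def build_null_table(sizes, reps: int, seed: int) -> DipNullTable:
    """Simulate the dip null distribution for uniform samples of the given sizes.

    Reproducible for a fixed seed; the per-size vectors are sorted ascending so
    p-value lookup is a binary search.
    """
    if reps < 1000:
        raise ConfigError(f"null table needs reps >= 1000, got {reps}")
    rng = np.random.default_rng(seed)
    dips: dict[int, np.ndarray] = {}
    for n in sizes:
        sims = np.empty(reps)
        for r in range(reps):
            sims[r] = dip_statistic(rng.random(n))
        sims.sort()
        dips[int(n)] = sims
    return DipNullTable(dips=dips, reps=reps, seed=seed)


def _pvalue_at_tabulated(dip: float, null: np.ndarray) -> float:
    b = null.size - np.searchsorted(null, dip, side="left")
    return (b + 1) / (null.size + 1)


def dip_pvalue(dip: float, n: int, table: DipNullTable) -> float:
    """Monte-Carlo p-value of an observed dip for sample size n.

    Uses the (b+1)/(B+1) estimator at tabulated sizes; for an in-between n the
    p-value is interpolated linearly in 1/sqrt(n) between the bracketing sizes
    (the dip scales like n^(-1/2) under the null).

    Raises
    ------
    ExtrapolationError
        If n lies outside the tabulated range.
    """
    sizes = table.sizes
    if n < sizes[0] or n > sizes[-1]:
        raise ExtrapolationError(
            f"n={n} outside tabulated range [{sizes[0]}, {sizes[-1]}]"
        )
    if n in table.dips:
        return _pvalue_at_tabulated(dip, table.dips[n])
    idx = int(np.searchsorted(sizes, n))
    n_lo, n_hi = sizes[idx - 1], sizes[idx]
    p_lo = _pvalue_at_tabulated(dip, table.dips[n_lo])
    p_hi = _pvalue_at_tabulated(dip, table.dips[n_hi])
    t_lo, t_hi, t = 1 / np.sqrt(n_lo), 1 / np.sqrt(n_hi), 1 / np.sqrt(n)
    w = (t - t_hi) / (t_lo - t_hi)
    return float(w * p_lo + (1 - w) * p_hi)


def dip_test(values, table: DipNullTable | None = None) -> DipResult:
    """Dip statistic plus p-value against the supplied (or default) null table."""
    x = np.asarray(values, dtype=float).ravel()
    d = dip_statistic(x)
    if table is None:
        table = default_null_table()
    try:
        p = dip_pvalue(d, x.size, table)
    except ExtrapolationError:
        p = None
    return DipResult(dip=d, n=x.size, p_value=p)


_DEFAULT_TABLE: DipNullTable | None = None


def default_null_table() -> DipNullTable:
    """The compact null table shipped with the package (lazily loaded)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        dips: dict[int, np.ndarray] = {}
        pkg = _importlib_resources.files("bimodalgene") / "resources"
        for n in DEFAULT_NULL_SIZES:
            text = (pkg / f"dip_null_n{n}.tsv").read_text()
            vals = np.array(
                [float(line) for line in text.splitlines() if not line.startswith("#")]
            )
            dips[n] = np.sort(vals)
        _DEFAULT_TABLE = DipNullTable(
            dips=dips, reps=DEFAULT_NULL_REPS, seed=DEFAULT_NULL_SEED
        )
    return _DEFAULT_TABLE


def write_null_table(table: DipNullTable, out_dir) -> list[str]:
    """Persist a null table as one TSV per sample size (sorted dip values)."""
    import os

    paths = []
    os.makedirs(out_dir, exist_ok=True)
    for n, vals in sorted(table.dips.items()):
        path = os.path.join(out_dir, f"dip_null_n{n}.tsv")
        with open(path, "w") as fh:
            fh.write(f"# dip null table  n={n}  reps={table.reps}  seed={table.seed}\n")
            fh.write("\n".join(f"{v:.6f}" for v in vals))
            fh.write("\n")
        paths.append(path)
    return paths
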