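"""Synthetic expression cohorts with planted distributional shapes + survival.

The generator emulates a microarray breast-cancer cohort on the log2 scale:
most genes are unimodal gaussian; a planted minority carries the shapes the
bimodality scores are designed to find:

* ``balanced_bimodal``   — two components of roughly equal size, separation
  ``delta`` in units of the component sigma,
* ``unbalanced_bimodal`` — a small high-expression component (5-20 % of
  patients),
* ``single_outlier``     — one or two extreme values above an otherwise
  unimodal distribution,
* ``heavy_tail``         — t-distributed noise (df = 3), fat tails without a
  clean second component.

A latent high-risk patient subgroup links expression to survival: every
prognostic gene is an unbalanced-bimodal gene whose high component is exactly
that subgroup (several co-regulated genes marking one biological subgroup,
the way ESR1- or erbB2-driven groups behave), and subgroup members carry a
proportionally larger exponential hazard.  Censoring is independent uniform,
calibrated to the requested censoring fraction.  Everything is reproducible
from the cohort's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ConfigError

__all__ = ["CohortSpec", "CohortTruth", "simulate_expression", "simulate_survival", "simulate_cohort"]


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Class fractions must sum to at most 1; the remainder is unimodal.
    ``delta`` values are component separations in sigma units.  The
    ``n_prognostic`` prognostic genes are drawn from the unbalanced class and
    share the latent high-risk subgroup of fraction
    ``prognostic_subgroup_fraction``; its hazard is ``hazard_ratio`` times the
    baseline.
    """

    n_genes: int = 2000
    n_samples: int = 200
    frac_balanced: float = 0.025
    frac_unbalanced: float = 0.025
    frac_outlier: float = 0.025
    frac_heavy: float = 0.025
    delta_balanced: float = 6.0
    delta_unbalanced: float = 6.0
    balanced_pi_range: tuple[float, float] = (0.45, 0.55)
    unbalanced_pi_range: tuple[float, float] = (0.05, 0.2)
    outlier_bulk_mu_range: tuple[float, float] = (4.0, 6.0)
    outlier_bulk_sigma_range: tuple[float, float] = (0.1, 0.3)
    outlier_level_range: tuple[float, float] = (8.0, 12.0)
    heavy_tail_df: float = 3.0
    baseline_mu_range: tuple[float, float] = (4.0, 12.0)
    baseline_sigma_range: tuple[float, float] = (0.2, 0.8)
    n_prognostic: int = 20
    prognostic_subgroup_fraction: float = 0.15
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.5
    n_batches: int = 1
    batch_offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        total = (
            self.frac_balanced
            + self.frac_unbalanced
            + self.frac_outlier
            + self.frac_heavy
        )
        if total > 1.0 + 1e-12:
            raise ConfigError(f"shape-class fractions sum to {total} > 1")
        if min(self.frac_balanced, self.frac_unbalanced, self.frac_outlier, self.frac_heavy) < 0:
            raise ConfigError("negative class fraction")
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard ratio must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ConfigError("censoring rate must lie in [0, 1)")
        n_unbal = int(round(self.frac_unbalanced * self.n_genes))
        if self.n_prognostic > 0 and n_unbal < self.n_prognostic:
            raise ConfigError(
                f"{self.n_prognostic} prognostic genes requested but only "
                f"{n_unbal} unbalanced-bimodal genes available"
            )


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort.

    ``gene_class`` maps gene id to its shape class; ``high_member`` is a
    boolean genes x samples frame flagging membership in the high component
    (all False for unimodal and heavy-tail genes); ``prognostic_genes`` lists
    the genes tied to the latent risk subgroup, ``subgroup`` the per-sample
    membership of that subgroup.
    """

    gene_class: pd.Series
    high_member: pd.DataFrame = field(repr=False)
    prognostic_genes: list[str] = field(default_factory=list)
    subgroup: pd.Series | None = None


def _class_layout(spec: CohortSpec, rng: np.random.Generator):
    counts = {
        "balanced_bimodal": int(round(spec.frac_balanced * spec.n_genes)),
        "unbalanced_bimodal": int(round(spec.frac_unbalanced * spec.n_genes)),
        "single_outlier": int(round(spec.frac_outlier * spec.n_genes)),
        "heavy_tail": int(round(spec.frac_heavy * spec.n_genes)),
    }
    classes = np.array(["unimodal"] * spec.n_genes, dtype=object)
    planted = rng.permutation(spec.n_genes)
    pos = 0
    for cls, k in counts.items():
        classes[planted[pos : pos + k]] = cls
        pos += k
    return classes


def simulate_expression(spec: CohortSpec) -> tuple[pd.DataFrame, CohortTruth]:
    """Genes x samples log2-scale expression matrix with known planted truth."""
    rng = np.random.default_rng(spec.seed)
    n_g, n_s = spec.n_genes, spec.n_samples
    gene_ids = [f"g{i:05d}" for i in range(n_g)]
    sample_ids = [f"s{j:04d}" for j in range(n_s)]
    classes = _class_layout(spec, rng)

    # latent high-risk subgroup shared by all prognostic genes
    subgroup = rng.random(n_s) < spec.prognostic_subgroup_fraction
    unbal_idx = np.flatnonzero(classes == "unbalanced_bimodal")
    prognostic_idx = set(rng.choice(unbal_idx, size=spec.n_prognostic, replace=False)) if spec.n_prognostic else set()

    values = np.empty((n_g, n_s))
    high = np.zeros((n_g, n_s), dtype=bool)
    for i in range(n_g):
        mu = rng.uniform(*spec.baseline_mu_range)
        sigma = rng.uniform(*spec.baseline_sigma_range)
        cls = classes[i]
        x = mu + sigma * rng.standard_normal(n_s)
        if cls == "balanced_bimodal":
            pi_high = rng.uniform(*spec.balanced_pi_range)
            members = rng.random(n_s) < pi_high
            x[members] += spec.delta_balanced * sigma
            high[i] = members
        elif cls == "unbalanced_bimodal":
            if i in prognostic_idx:
                members = subgroup.copy()
            else:
                pi_high = rng.uniform(*spec.unbalanced_pi_range)
                members = rng.random(n_s) < pi_high
            x[members] += spec.delta_unbalanced * sigma
            high[i] = members
        elif cls == "single_outlier":
            # noise-floor bulk with one or two strongly overexpressed samples
            mu = rng.uniform(*spec.outlier_bulk_mu_range)
            sigma = rng.uniform(*spec.outlier_bulk_sigma_range)
            x = mu + sigma * rng.standard_normal(n_s)
            k = int(rng.integers(1, 3))
            members = np.zeros(n_s, dtype=bool)
            members[rng.choice(n_s, size=k, replace=False)] = True
            # one characteristic overexpression level per gene (recurrent
            # amplification), plus the gene's own measurement noise
            level = rng.uniform(*spec.outlier_level_range)
            x[members] = level + sigma * rng.standard_normal(k)
            high[i] = members
        elif cls == "heavy_tail":
            x = mu + sigma * rng.standard_t(spec.heavy_tail_df, size=n_s)
        values[i] = x

    if spec.n_batches > 1 and spec.batch_offset != 0.0:
        # deliberate pooling artifact: per-batch global shifts
        batch = np.repeat(np.arange(spec.n_batches), int(np.ceil(n_s / spec.n_batches)))[:n_s]
        values += spec.batch_offset * batch[None, :]

    matrix = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    truth = CohortTruth(
        gene_class=pd.Series(classes, index=gene_ids, name="gene_class"),
        high_member=pd.DataFrame(high, index=gene_ids, columns=sample_ids),
        prognostic_genes=[gene_ids[i] for i in sorted(prognostic_idx)],
        subgroup=pd.Series(subgroup, index=sample_ids, name="subgroup"),
    )
    return matrix, truth


def _censoring_upper_bound(hazards: np.ndarray, weights: np.ndarray, target_rate: float) -> float:
    """Upper bound of the uniform censoring window hitting the target rate.

    For T ~ Exp(h) and C ~ U(0, u), P(T > C) = (1 - exp(-h u)) / (h u);
    the marginal censoring fraction averages this over the hazard mixture.
    Solved for u by bisection.
    """
    if target_rate <= 0:
        return np.inf
    h = np.asarray(hazards, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    def gap(u):
        return float(np.sum(w * (1.0 - np.exp(-h * u)) / (h * u))) - target_rate

    lo = 1e-9 / h.max()
    hi = 1e4 / h.min()
    return brentq(gap, lo, hi)


def simulate_survival(truth: CohortTruth, spec: CohortSpec) -> pd.DataFrame:
    """Exponential survival with elevated hazard in the latent risk subgroup.

    Event times are exponential with hazard ``baseline_hazard`` times
    ``hazard_ratio`` for subgroup members; censoring is independent uniform,
    calibrated so the overall censoring fraction approximately matches
    ``censoring_rate``.  Uses its own stream (seed + 1) so expression and
    survival can be regenerated independently.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_s = spec.n_samples
    member = (
        truth.subgroup.to_numpy()
        if truth.subgroup is not None
        else np.zeros(n_s, dtype=bool)
    )
    hazard = spec.baseline_hazard * np.where(member, spec.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        frac = float(member.mean())
        u = _censoring_upper_bound(
            np.array([spec.baseline_hazard, spec.baseline_hazard * spec.hazard_ratio]),
            np.array([1.0 - frac, frac]),
            spec.censoring_rate,
        )
        t_cens = rng.uniform(0.0, u, size=n_s)
    else:
        t_cens = np.full(n_s, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(np.int8)
    time = np.maximum(time, 1e-9)  # strictly positive follow-up
    return pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index(truth.subgroup.index if truth.subgroup is not None else range(n_s), name="sample_id"),
    )


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Expression matrix, survival table and truth in one call."""
    matrix, truth = simulate_expression(spec)
    survival = simulate_survival(truth, spec)
    return matrix, survival, truth
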