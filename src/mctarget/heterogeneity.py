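"""Pairwise-discordance heterogeneity index with bootstrap BCa intervals.

The heterogeneity of a marker at a grouping level is the probability that
a random pair of binarized H-score calls drawn from the same grouping unit
disagrees (exactly one member at or above the cut).  Two levels are
defined:

* ``intra_tumoral`` — both members of a pair come from the same tumor
  block; a unit is a block with at least two scored samples.
* ``intra_patient_inter_tumoral`` — both members come from the same
  patient but from *different* blocks; a unit is a patient with scored
  samples in at least two blocks, and only cross-block pairs are eligible.

The point estimate follows the sampling scheme of the source analysis:
draw a unit uniformly at random, then an eligible pair uniformly within
it, with replacement across draws (1000 pairs by default).  Confidence
limits are bias-corrected and accelerated (BCa) bootstrap intervals in
which the resampling unit is the grouping unit (block or patient), not the
individual pair, so the clustering of samples is respected; the
acceleration constant comes from leave-one-unit-out jackknife values.

An exhaustive oracle (:func:`exhaustive_discordance`) computes the exact
within-unit pair-discordance probability by enumeration; the Monte-Carlo
estimator converges to it as the number of sampled pairs grows.

For a unit with ``p`` positive and ``n`` negative eligible samples (all
pairs eligible), the discordant fraction is ``p*n / C(p+n, 2)``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort
from .scoring import DEFAULT_THRESHOLD, score_cohort

__all__ = [
    "GroupingLevel",
    "Unit",
    "HeterogeneityEstimate",
    "enumerate_units",
    "exhaustive_discordance",
    "sample_pairs",
    "bootstrap_replicates",
    "jackknife_values",
    "bca_interval",
    "heterogeneity_report",
]


class GroupingLevel(enum.Enum):
    intra_tumoral = "intra_tumoral"
    intra_patient_inter_tumoral = "intra_patient_inter_tumoral"


@dataclass(frozen=True)
class Unit:
    """One grouping unit: binarized calls plus the block label of each sample.

    ``n_pairs`` counts eligible pairs (all pairs for intra-tumoral units;
    cross-block pairs only for inter-tumoral units) and ``n_discordant``
    those among them with exactly one positive member.
    """

    unit_id: tuple
    level: GroupingLevel
    calls: tuple[bool, ...]
    blocks: tuple[str, ...]
    n_pairs: int
    n_discordant: int

    @property
    def discordant_fraction(self) -> float:
        return self.n_discordant / self.n_pairs


def _pair_counts(
    calls: Sequence[bool], blocks: Sequence[str], cross_block_only: bool
) -> tuple[int, int]:
    calls = np.asarray(calls, dtype=bool)
    n = len(calls)
    p = int(calls.sum())
    total = n * (n - 1) // 2
    disc = p * (n - p)
    if cross_block_only:
        for b in set(blocks):
            mask = np.asarray([x == b for x in blocks])
            nb = int(mask.sum())
            pb = int(calls[mask].sum())
            total -= nb * (nb - 1) // 2
            disc -= pb * (nb - pb)
    return total, disc


def enumerate_units(
    cohort: Cohort | pd.DataFrame,
    level: GroupingLevel | str,
    marker: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[Unit]:
    """List grouping units with their binarized calls and eligible-pair counts.

    Units without at least one eligible pair are dropped (intra-tumoral:
    blocks with fewer than two scored samples; inter-tumoral: patients whose
    scored samples do not span two blocks).
    """
    level = GroupingLevel(level)
    df = score_cohort(cohort, threshold=threshold) if isinstance(cohort, Cohort) else cohort
    df = df[(df["marker"] == marker) & df["h_score"].notna()]
    units: list[Unit] = []
    if level is GroupingLevel.intra_tumoral:
        groups = df.groupby(["patient_id", "block_id"], sort=True)
        cross = False
    else:
        groups = df.groupby(["patient_id"], sort=True)
        cross = True
    for key, grp in groups:
        calls = tuple(bool(v) for v in (grp["h_score"] >= threshold))
        blocks = tuple(grp["block_id"])
        if len(calls) < 2:
            continue
        if cross and len(set(blocks)) < 2:
            continue
        n_pairs, n_disc = _pair_counts(calls, blocks, cross_block_only=cross)
        if n_pairs < 1:
            continue
        units.append(
            Unit(
                unit_id=key if isinstance(key, tuple) else (key,),
                level=level,
                calls=calls,
                blocks=blocks,
                n_pairs=n_pairs,
                n_discordant=n_disc,
            )
        )
    return units


def exhaustive_discordance(
    units: Sequence[Unit], weighting: str = "per_unit"
) -> float:
    """Exact discordance probability by within-unit pair enumeration.

    ``per_unit`` (default) weights units equally: the mean over units of the
    unit's discordant-pair fraction — the exact expectation of the two-stage
    unit-then-pair sampler.  ``pooled`` pools all eligible pairs:
    sum(discordant) / sum(eligible).
    """
    units = [u for u in units if u.n_pairs >= 1]
    if not units:
        raise ValueError("no unit with an eligible pair")
    if weighting == "per_unit":
        return float(np.mean([u.discordant_fraction for u in units]))
    if weighting == "pooled":
        return float(sum(u.n_discordant for u in units) / sum(u.n_pairs for u in units))
    raise ValueError(f"weighting must be 'per_unit' or 'pooled', got {weighting!r}")


def sample_pairs(
    units: Sequence[Unit],
    n_pairs: int = 1000,
    seed: int | np.random.Generator | None = None,
    weighting: str = "per_unit",
) -> np.ndarray:
    """Monte-Carlo pair sampling: boolean discordance outcomes, one per draw.

    Each draw selects a unit (uniformly for ``per_unit``; proportionally to
    its eligible-pair count for ``pooled``) and then an eligible pair
    uniformly within it, with replacement across draws.  The discordance
    indicator of a uniform eligible pair from unit *u* is Bernoulli with
    success probability equal to *u*'s discordant fraction, which is how the
    outcome is drawn; the identity of the pair is immaterial downstream.

    A seed (or Generator) is required: there is no implicit global RNG.
    """
    if seed is None:
        raise ValueError("a seed or numpy Generator is required for reproducibility")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    units = [u for u in units if u.n_pairs >= 1]
    if not units:
        raise ValueError("no unit with an eligible pair")
    d = np.array([u.discordant_fraction for u in units])
    if weighting == "per_unit":
        idx = rng.integers(len(units), size=n_pairs)
    elif weighting == "pooled":
        w = np.array([u.n_pairs for u in units], dtype=float)
        idx = rng.choice(len(units), size=n_pairs, p=w / w.sum())
    else:
        raise ValueError(f"weighting must be 'per_unit' or 'pooled', got {weighting!r}")
    return rng.random(n_pairs) < d[idx]


def bootstrap_replicates(
    units: Sequence[Unit],
    n_boot: int,
    rng: np.random.Generator,
    weighting: str = "per_unit",
) -> np.ndarray:
    """Cluster bootstrap: resample units with replacement, recompute the statistic.

    Returns ``n_boot`` replicate discordance values.  Each replicate
    resamples the grouping units (blocks or patients, not individual pairs)
    and recomputes the exact (exhaustive) discordance of the resampled
    collection, so the replicate spread quantifies cohort-level sampling
    uncertainty rather than the reducible Monte-Carlo noise of the pair
    sampler.
    """
    units = [u for u in units if u.n_pairs >= 1]
    n_units = len(units)
    d = np.array([u.discordant_fraction for u in units])
    idx = rng.integers(n_units, size=(n_boot, n_units))
    if weighting == "per_unit":
        return d[idx].mean(axis=1)
    if weighting == "pooled":
        disc = np.array([u.n_discordant for u in units], dtype=float)
        pairs = np.array([u.n_pairs for u in units], dtype=float)
        return disc[idx].sum(axis=1) / pairs[idx].sum(axis=1)
    raise ValueError(f"weighting must be 'per_unit' or 'pooled', got {weighting!r}")


def jackknife_values(
    units: Sequence[Unit], weighting: str = "per_unit"
) -> np.ndarray:
    """Leave-one-unit-out exhaustive discordance values (for BCa acceleration)."""
    units = [u for u in units if u.n_pairs >= 1]
    n = len(units)
    if n < 2:
        return np.array([])
    d = np.array([u.discordant_fraction for u in units])
    if weighting == "per_unit":
        total = d.sum()
        return (total - d) / (n - 1)
    disc = np.array([u.n_discordant for u in units], dtype=float)
    pairs = np.array([u.n_pairs for u in units], dtype=float)
    return (disc.sum() - disc) / (pairs.sum() - pairs)


def bca_interval(
    point_estimate: float,
    boot_stats: np.ndarray,
    jackknife_stats: np.ndarray,
    alpha: float = 0.05,
    clip: tuple[float, float] = (0.0, 1.0),
) -> tuple[float, float, bool]:
    """Bias-corrected and accelerated bootstrap confidence limits.

    The bias correction ``z0`` is the normal quantile of the fraction of
    bootstrap replicates below the point estimate (ties counted half); the
    acceleration ``a`` is the jackknife skewness of leave-one-out statistics.
    Endpoints are the adjusted percentiles of the bootstrap distribution,
    clipped to ``clip``.  Returns ``(lo, hi, degenerate)``; a degenerate
    bootstrap distribution (all replicates equal) collapses the interval to
    the point estimate, flagged True — this is how all-concordant and
    all-discordant data are reported.
    """
    boot = np.asarray(boot_stats, dtype=float)
    if boot.size == 0 or np.all(boot == boot[0]):
        return float(point_estimate), float(point_estimate), True

    below = np.mean(boot < point_estimate) + 0.5 * np.mean(boot == point_estimate)
    eps = 1.0 / (boot.size + 1.0)
    z0 = stats.norm.ppf(np.clip(below, eps, 1.0 - eps))

    jk = np.asarray(jackknife_stats, dtype=float)
    if jk.size >= 2 and np.ptp(jk) > 0:
        dev = jk.mean() - jk
        a = (dev**3).sum() / (6.0 * ((dev**2).sum()) ** 1.5)
    else:
        a = 0.0

    z_lo = stats.norm.ppf(alpha / 2.0)
    z_hi = stats.norm.ppf(1.0 - alpha / 2.0)
    alphas = []
    for z in (z_lo, z_hi):
        num = z0 + z
        adj = stats.norm.cdf(z0 + num / (1.0 - a * num))
        alphas.append(float(np.clip(adj, 0.0, 1.0)))
    lo, hi = np.percentile(boot, [100.0 * a_ for a_ in alphas])
    lo = float(np.clip(lo, *clip))
    hi = float(np.clip(hi, *clip))
    return lo, hi, False


@dataclass(frozen=True)
class HeterogeneityEstimate:
    """Discordance probability with cluster-aware BCa 95% limits."""

    marker: str
    level: GroupingLevel
    estimate: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_units: int
    seed: int
    degenerate: bool = False
    evaluable: bool = True


def heterogeneity_report(
    cohort: Cohort | pd.DataFrame,
    markers: Sequence[str],
    levels: Iterable[GroupingLevel | str] = GroupingLevel,
    threshold: float = DEFAULT_THRESHOLD,
    n_pairs: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    weighting: str = "per_unit",
) -> pd.DataFrame:
    """Heterogeneity estimates per (marker, level) as a tidy table.

    Markers with no eligible unit at a level produce a row flagged not
    evaluable.  All randomness derives from ``seed``; identical inputs give
    identical output.
    """
    if seed is None:
        raise ValueError("seed is required")
    scored = score_cohort(cohort, threshold=threshold) if isinstance(cohort, Cohort) else cohort
    rows = []
    ss = np.random.SeedSequence(seed)
    levels = [GroupingLevel(lv) for lv in levels]
    children = ss.spawn(len(markers) * len(levels))
    k = 0
    for marker in markers:
        for level in levels:
            rng = np.random.default_rng(children[k])
            k += 1
            units = enumerate_units(scored, level, marker, threshold=threshold)
            if not units:
                rows.append(
                    HeterogeneityEstimate(
                        marker=marker, level=level, estimate=np.nan,
                        ci_low=np.nan, ci_high=np.nan, n_pairs=0, n_units=0,
                        seed=seed, degenerate=False, evaluable=False,
                    )
                )
                continue
            outcomes = sample_pairs(units, n_pairs=n_pairs, seed=rng, weighting=weighting)
            est = float(outcomes.mean())
            exact = exhaustive_discordance(units, weighting=weighting)
            boot = bootstrap_replicates(units, n_boot, rng, weighting=weighting)
            jk = jackknife_values(units, weighting=weighting)
            lo, hi, degen = bca_interval(exact, boot, jk, alpha=alpha)
            # the interval must contain the Monte-Carlo point estimate
            lo, hi = min(lo, est), max(hi, est)
            rows.append(
                HeterogeneityEstimate(
                    marker=marker, level=level, estimate=est, ci_low=lo,
                    ci_high=hi, n_pairs=n_pairs, n_units=len(units),
                    seed=seed, degenerate=degen, evaluable=True,
                )
            )
    return pd.DataFrame(
        [
            {
                "marker": r.marker,
                "level": r.level.value,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_pairs": r.n_pairs,
                "n_units": r.n_units,
                "seed": r.seed,
                "degenerate": r.degenerate,
                "evaluable": r.evaluable,
            }
            for r in rows
        ]
    )
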