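"""Soil-to-phyllosphere reachability via pooled equal-depth subsampling.

The open-environment (outside) phyllosphere samples are pooled into one read
pool and the sealed-growth-chamber phyllosphere samples into another; because
the sealed microboxes admit colonists only from the soil, any ASV detected in
the chamber pool must be able to reach the phyllosphere from soil.  To make
pools of unequal size comparable, both are repeatedly subsampled without
replacement to the same depth, stepping the depth down in 100-read increments
from the size of the smaller pool, and the fraction of outside-detected ASVs
also detected inside is recorded at each depth (an :class:`OverlapCurve`).
The reported value is the mean over the deepest few points, where the curve
has converged.

Two follow-up views are provided: restricting a pool to its most abundant
taxa (top fraction of taxa, ranked by pooled reads), and the fraction of a
sample's reads carried by the soil-reachable ASV set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tables import CountTable


@dataclass(frozen=True)
class ReadPool:
    """Per-ASV read counts summed over a group of samples."""

    asv_ids: tuple[str, ...]
    pooled_counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.pooled_counts)
        if counts.shape != (len(self.asv_ids),):
            raise ValueError("pooled counts must align with ASV ids")
        if counts.size and counts.min() < 0:
            raise ValueError("pooled counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return int(np.asarray(self.pooled_counts).sum())

    def detected(self) -> set[str]:
        return {
            a for a, c in zip(self.asv_ids, self.pooled_counts) if c > 0
        }

    def series(self) -> pd.Series:
        return pd.Series(self.pooled_counts, index=list(self.asv_ids))


def pool_reads(table: CountTable, sample_ids: Iterable[str]) -> ReadPool:
    """Sum reads over a sample group into one pool."""
    ids = list(sample_ids)
    if not ids:
        raise ValueError("cannot pool an empty sample group")
    sub = table.select_samples(ids)  # raises on unknown ids
    return ReadPool(
        asv_ids=sub.asv_ids,
        pooled_counts=sub.counts.sum(axis=0).astype(np.int64),
    )


@dataclass(frozen=True)
class OverlapCurve:
    """Depth-indexed overlap proportions, deepest first.

    ``proportions[k]`` is the mean (over replicates) fraction of ASVs
    detected in the pool-A subsample at ``depths[k]`` that were also detected
    in the pool-B subsample at the same depth.
    """

    depths: tuple[int, ...]
    proportions: tuple[float, ...]
    sds: tuple[float, ...]
    step: int
    replicates_per_depth: int

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths)
        if len(depths) > 1 and not (np.diff(depths) == -self.step).all():
            raise ValueError("depths must descend by the step size")
        if depths.size and depths[-1] < self.step:
            raise ValueError("smallest depth must be >= step")
        props = np.asarray(self.proportions)
        if props.size and (props.min() < 0 or props.max() > 1):
            raise ValueError("overlap proportions must lie in [0, 1]")

    def converged(self, k: int = 5) -> float:
        """Mean proportion over the ``k`` deepest depths (the plateau)."""
        if k < 1:
            raise ValueError("convergence window must be >= 1")
        return float(np.mean(self.proportions[: min(k, len(self.proportions))]))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.depths,
                "mean_proportion": self.proportions,
                "sd_proportion": self.sds,
            }
        )


def _aligned_counts(
    pool_a: ReadPool, pool_b: ReadPool
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of both pools over the union ASV axis (order: A's ids then B-only)."""
    a = pool_a.series()
    b = pool_b.series()
    union = list(a.index) + [x for x in b.index if x not in set(a.index)]
    return (
        a.reindex(union, fill_value=0).to_numpy(dtype=np.int64),
        b.reindex(union, fill_value=0).to_numpy(dtype=np.int64),
    )


def incremental_overlap(
    pool_a: ReadPool,
    pool_b: ReadPool,
    step: int = 100,
    replicates: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> OverlapCurve:
    """Equal-depth detection overlap between two pools, stepping the depth down.

    For each depth ``d`` from ``min(total_a, total_b)`` down to ``step`` in
    ``step``-read decrements, both pools are subsampled to ``d`` reads
    without replacement (``replicates`` independent draws, averaged) and the
    proportion |detected in A and B| / |detected in A| is recorded.  The
    direction matters: A is the open-environment pool whose detected taxa are
    being attributed.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    total_a, total_b = pool_a.total_reads, pool_b.total_reads
    if total_a == 0 or total_b == 0:
        raise ValueError("both pools must contain reads")
    start = min(total_a, total_b)
    if start < step:
        raise ValueError(
            f"smallest pool has {start} reads, fewer than the step size {step}"
        )
    a, b = _aligned_counts(pool_a, pool_b)
    rng = np.random.default_rng(seed)
    depths = list(range(start, step - 1, -step))
    means, sds = [], []
    for depth in depths:
        vals = np.empty(replicates)
        for r in range(replicates):
            sub_a = rng.multivariate_hypergeometric(a, depth) > 0
            sub_b = rng.multivariate_hypergeometric(b, depth) > 0
            det_a = int(sub_a.sum())
            vals[r] = (sub_a & sub_b).sum() / det_a if det_a else 0.0
        means.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=1)) if replicates > 1 else 0.0)
    return OverlapCurve(
        depths=tuple(depths),
        proportions=tuple(means),
        sds=tuple(sds),
        step=step,
        replicates_per_depth=replicates,
    )


def restrict_to_top_fraction(
    pool: ReadPool, fraction: float
) -> tuple[ReadPool, float]:
    """Keep the most abundant ``ceil(fraction * n_detected)`` taxa of a pool.

    Ties at the cutoff are broken by ASV id ascending.  Returns the reduced
    pool (other ASVs zeroed) and the share of reads it retains.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    counts = np.asarray(pool.pooled_counts)
    detected = [
        (int(c), a) for a, c in zip(pool.asv_ids, counts) if c > 0
    ]
    if not detected:
        raise ValueError("cannot restrict an empty pool")
    n_keep = int(np.ceil(fraction * len(detected)))
    ranked = sorted(detected, key=lambda t: (-t[0], t[1]))
    keep = {a for _, a in ranked[:n_keep]}
    new_counts = np.array(
        [c if a in keep else 0 for a, c in zip(pool.asv_ids, counts)],
        dtype=np.int64,
    )
    share = float(new_counts.sum() / counts.sum())
    return ReadPool(pool.asv_ids, new_counts), share


def reachable_asv_set(
    growth_chamber_phyllosphere: CountTable, presence_threshold: int
) -> set[str]:
    """ASVs reaching the phyllosphere from soil in the sealed growth chamber.

    An ASV qualifies when it carries at least ``presence_threshold`` reads in
    at least one growth-chamber rosette/leaf/flower sample (the caller
    restricts the table to one soil treatment's phyllosphere samples).
    """
    if presence_threshold < 1:
        raise ValueError("presence threshold must be >= 1")
    if not growth_chamber_phyllosphere.sample_ids:
        raise ValueError("empty table: no growth-chamber phyllosphere samples")
    hits = (growth_chamber_phyllosphere.counts >= presence_threshold).any(axis=0)
    return {
        a for a, h in zip(growth_chamber_phyllosphere.asv_ids, hits) if h
    }


def reachable_read_fraction(
    sample_row: Mapping[str, int] | pd.Series, reachable: set[str]
) -> float:
    """Fraction of a sample's reads carried by soil-reachable ASVs."""
    row = pd.Series(sample_row)
    total = float(row.sum())
    if total <= 0:
        raise ValueError("sample has zero total reads")
    on_reachable = float(row[[a for a in row.index if a in reachable]].sum())
    return on_reachable / total
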