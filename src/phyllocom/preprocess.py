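"""Data-cleaning rules applied before any community analysis.

Order of operations in the standard pipeline:

1. drop ASVs detected in *every* negative control (reagent/library
   contamination signature), together with the control samples themselves;
2. drop samples with fewer than ``min_sample_reads`` total reads (default
   1,000);
3. optionally derive a read-count presence threshold from the mock-community
   sample (off-target "bleed" reads average ~2, so presence requires 3) and
   zero out sub-threshold cells on *unrarefied* counts;
4. rarefy every sample to a common depth without replacement.

The presence threshold is applied before rarefaction when both are requested
(`threshold-then-rarefy`), matching the sensitivity analysis this models;
the order is a parameter of :func:`threshold_then_rarefy` for users who want
the alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import CountTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdConfig:
    """Read-count thresholds: minimum sample size and the presence threshold."""

    min_sample_reads: int = 1000
    presence_threshold: int = 3

    def __post_init__(self) -> None:
        if self.min_sample_reads < 1:
            raise ValueError("min_sample_reads must be >= 1")
        if self.presence_threshold < 1:
            raise ValueError("presence_threshold must be >= 1")


@dataclass(frozen=True)
class RarefactionPlan:
    """Common depth, iteration count and base seed for serial rarefaction.

    Per-iteration seeds are derived deterministically from
    ``(base_seed, iteration)`` so any single iteration is reproducible in
    isolation (see :func:`iteration_seed`).
    """

    depth: int = 1084
    n_iterations: int = 1000
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("rarefaction depth must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def iteration_seed(base_seed: int, iteration: int) -> np.random.SeedSequence:
    """Deterministic per-iteration seed stream."""
    return np.random.SeedSequence(entropy=(int(base_seed), int(iteration)))


@dataclass(frozen=True)
class PreprocessReport:
    removed_asvs: tuple[str, ...]
    removed_samples: tuple[str, ...]

    def frame(self) -> pd.DataFrame:
        rows = [("asv", a) for a in self.removed_asvs] + [
            ("sample", s) for s in self.removed_samples
        ]
        return pd.DataFrame(rows, columns=["kind", "id"])


def remove_control_asvs(
    table: CountTable, negative_control_ids: Iterable[str]
) -> tuple[CountTable, tuple[str, ...]]:
    """Drop ASVs present (>=1 read) in every negative control, and the controls.

    Presence in *all* negative controls is a strong signature of DNA
    extraction / library reagent contamination; an ASV absent from even one
    control is retained.  Counts of surviving ASVs are never altered.

    Returns the cleaned table and the tuple of removed ASV ids.
    """
    controls = list(negative_control_ids)
    if not controls:
        raise ValueError(
            "control-ASV removal is undefined without negative controls"
        )
    control_table = table.select_samples(controls)  # raises on unknown ids
    present_in_all = (control_table.counts >= 1).all(axis=0)
    removed = tuple(
        a for a, flag in zip(control_table.asv_ids, present_in_all) if flag
    )
    out = table.drop_samples(controls).drop_asvs(removed)
    log.info(
        "removed %d contamination ASV(s) found in all %d negative controls",
        len(removed),
        len(controls),
    )
    return out, removed


def filter_small_samples(
    table: CountTable, min_reads: int
) -> tuple[CountTable, tuple[str, ...]]:
    """Drop samples with total reads strictly below ``min_reads``."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    totals = table.sample_totals()
    removed = tuple(totals.index[totals < min_reads])
    if removed and len(removed) == len(table.sample_ids):
        log.warning("all %d samples fall below %d reads", len(removed), min_reads)
    elif removed:
        log.info("discarded %d sample(s) with < %d reads", len(removed), min_reads)
    return table.drop_samples(removed), removed


def derive_presence_threshold(
    mock_row: Mapping[str, int] | pd.Series,
    expected_member_asvs: Iterable[str],
) -> int:
    """Presence threshold from mock-community bleed reads.

    Reads on ASVs that are *not* expected members of the mock community are
    cross-contamination / index-switching bleed.  The threshold is the
    smallest count strictly above their mean: ``floor(mean) + 1`` (a mean
    bleed of two reads yields a three-read threshold).
    """
    series = pd.Series(mock_row)
    expected = set(expected_member_asvs)
    unexpected = series[[a for a in series.index if a not in expected]]
    detected = unexpected[unexpected >= 1]
    if detected.empty:
        raise ValueError(
            "no unexpected ASVs detected in the mock sample; presence "
            "threshold cannot be derived (fall back to a configured value)"
        )
    mean_bleed = float(detected.mean())
    return int(math.floor(mean_bleed)) + 1


def apply_presence_threshold(table: CountTable, threshold: int) -> CountTable:
    """Zero every cell with fewer than ``threshold`` reads (unrarefied counts).

    Idempotent, and monotone in the threshold: raising it never resurrects a
    zeroed cell.  Samples left all-zero are retained here (dropping is a
    separate, explicit step).
    """
    if threshold < 1:
        raise ValueError("presence threshold must be >= 1")
    arr = table.counts.copy()
    arr[arr < threshold] = 0
    return table.with_counts(arr)


def rarefy(
    table: CountTable,
    depth: int,
    seed: int | np.random.SeedSequence | None = 0,
) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each row is drawn from the multivariate hypergeometric distribution over
    its own reads, independently across samples; sample and ASV ordering is
    preserved and a fixed seed gives a bit-identical result.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.sample_totals()
    low = totals[totals < depth]
    if not low.empty:
        raise ValueError(
            f"sample {low.index[0]!r} has {int(low.iloc[0])} reads, fewer than "
            f"the rarefaction depth {depth}; filter small samples first"
        )
    rng = np.random.default_rng(seed)
    arr = table.counts
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        out[i] = rng.multivariate_hypergeometric(arr[i], depth)
    return table.with_counts(out)


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample proportions; every row sums to 1. Zero-total samples are rejected."""
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if not zero.empty:
        raise ValueError(
            f"sample {zero.index[0]!r} has zero total reads; relative "
            "abundance is undefined"
        )
    return table.data.div(totals, axis=0)


def threshold_then_rarefy(
    table: CountTable,
    threshold: int,
    depth: int,
    seed: int | np.random.SeedSequence | None = 0,
    order: str = "threshold_first",
) -> CountTable:
    """Presence threshold and rarefaction combined, in a configurable order."""
    if order == "threshold_first":
        return rarefy(apply_presence_threshold(table, threshold), depth, seed)
    if order == "rarefy_first":
        return apply_presence_threshold(rarefy(table, depth, seed), threshold)
    raise ValueError(f"unknown order {order!r}")
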