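"""Indicator-value (IndVal) analysis for group-characteristic taxa.

For a taxon and a target sample group, the indicator value is the product of

* **A (specificity)** — the taxon's mean per-sample relative abundance in
  the target group divided by the sum of that mean over all groups, and
* **B (fidelity)** — the fraction of target-group samples in which the taxon
  is detected (>= 1 read).

Both components live in [0, 1]; a perfect indicator (present in every target
sample, absent elsewhere) scores 1.  Significance comes from a
label-randomisation test: group labels are shuffled across samples and the
p-value is the add-one estimate ``(#{permuted >= observed} + 1) /
(n_permutations + 1)``, computed separately for IndVal, A and B.  Family-wise
error is controlled by Bonferroni over the number of taxa tested; taxa enter
the test only if they carry at least ``min_relabund`` (default 0.1%) of the
pooled reads of at least one group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tables import CountTable


@dataclass(frozen=True)
class IndValConfig:
    min_relabund: float = 0.001
    n_permutations: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_relabund < 1:
            raise ValueError("min_relabund must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _group_layout(
    table: CountTable, groups: Mapping[str, str]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Relative abundances, group names, and per-sample group indices."""
    missing = [s for s in table.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"sample(s) without a group label: {missing[:5]}")
    names = sorted({groups[s] for s in table.sample_ids})
    idx = np.array([names.index(groups[s]) for s in table.sample_ids])
    for g, name in enumerate(names):
        if (idx == g).sum() == 0:
            raise ValueError(f"group {name!r} has no samples")
    totals = table.counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("zero-total sample in IndVal input")
    rel = table.counts / totals
    return rel, names, idx


def filter_by_group_relabund(
    table: CountTable,
    groups: Mapping[str, str],
    min_relabund: float = 0.001,
) -> set[str]:
    """ASVs carrying >= ``min_relabund`` of at least one group's pooled reads.

    "Community" here is the organ-level pool: all reads of all samples of a
    group combined.
    """
    if not 0 < min_relabund < 1:
        raise ValueError("min_relabund must be in (0, 1)")
    names = sorted(set(groups[s] for s in table.sample_ids if s in groups))
    missing = [s for s in table.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"sample(s) without a group label: {missing[:5]}")
    keep: set[str] = set()
    for name in names:
        members = [s for s in table.sample_ids if groups[s] == name]
        if not members:
            raise ValueError(f"group {name!r} has no samples")
        pooled = table.select_samples(members).counts.sum(axis=0)
        total = pooled.sum()
        if total == 0:
            raise ValueError(f"group {name!r} has no reads")
        share = pooled / total
        keep.update(
            a for a, s in zip(table.asv_ids, share) if s >= min_relabund
        )
    return keep


def _components(
    rel: np.ndarray,
    detected: np.ndarray,
    idx: np.ndarray,
    n_groups: int,
    target: int,
) -> tuple[np.ndarray, np.ndarray]:
    """A and B for every column given a group assignment."""
    p = rel.shape[1]
    group_means = np.empty((n_groups, p))
    for g in range(n_groups):
        group_means[g] = rel[idx == g].mean(axis=0)
    denom = group_means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = group_means[target] / denom
    a = np.where(denom == 0, 0.0, a)
    b = detected[idx == target].mean(axis=0)
    return a, b


def indval_statistic(
    table: CountTable,
    groups: Mapping[str, str],
    target_group: str,
) -> pd.DataFrame:
    """A, B and IndVal = A*B for every ASV, for the target group.

    Requires >= 2 groups with >= 2 samples each.  An ASV absent from all
    groups gets A = 0 (hence IndVal 0).
    """
    rel, names, idx = _group_layout(table, groups)
    if target_group not in names:
        raise ValueError(f"unknown target group {target_group!r}")
    if len(names) < 2:
        raise ValueError("IndVal needs at least 2 groups")
    for g, name in enumerate(names):
        if (idx == g).sum() < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    detected = table.counts >= 1
    a, b = _components(rel, detected, idx, len(names), names.index(target_group))
    return pd.DataFrame(
        {
            "asv_id": table.asv_ids,
            "A": a,
            "B": b,
            "indval": a * b,
        }
    )


def indval_permutation_test(
    table: CountTable,
    groups: Mapping[str, str],
    target_group: str,
    n_permutations: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Label-randomisation p-values for IndVal, A and B per ASV.

    Group labels are shuffled across samples each iteration; the p-value is
    the add-one estimator (never exactly zero), deterministic under a fixed
    seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rel, names, idx = _group_layout(table, groups)
    target = names.index(target_group)
    detected = table.counts >= 1
    a_obs, b_obs = _components(rel, detected, idx, len(names), target)
    iv_obs = a_obs * b_obs
    rng = np.random.default_rng(seed)
    n = rel.shape[0]
    eps = 1e-12  # float-equality cushion so exact ties count as >=
    exceed_iv = np.zeros(rel.shape[1], dtype=np.int64)
    exceed_a = np.zeros_like(exceed_iv)
    exceed_b = np.zeros_like(exceed_iv)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        a, b = _components(
            rel[perm], detected[perm], idx, len(names), target
        )
        exceed_iv += (a * b) >= iv_obs - eps
        exceed_a += a >= a_obs - eps
        exceed_b += b >= b_obs - eps
    denom = n_permutations + 1
    return pd.DataFrame(
        {
            "asv_id": table.asv_ids,
            "A": a_obs,
            "B": b_obs,
            "indval": iv_obs,
            "p_indval": (exceed_iv + 1) / denom,
            "p_A": (exceed_a + 1) / denom,
            "p_B": (exceed_b + 1) / denom,
        }
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def indval_analysis(
    rarefied: CountTable,
    groups: Mapping[str, str],
    target_group: str,
    config: IndValConfig = IndValConfig(),
) -> pd.DataFrame:
    """Filter, test, and flag significance in one pass.

    Returns one row per tested ASV with A, B, IndVal, the three permutation
    p-values, and a ``significant`` flag (p_indval below the Bonferroni
    threshold over the number of ASVs tested).  p_A and p_B are reported
    descriptively.
    """
    tested = filter_by_group_relabund(rarefied, groups, config.min_relabund)
    subset = rarefied.select_asvs([a for a in rarefied.asv_ids if a in tested])
    result = indval_permutation_test(
        subset,
        groups,
        target_group,
        n_permutations=config.n_permutations,
        seed=config.seed,
    )
    threshold = bonferroni_threshold(config.alpha, len(result))
    result = result.copy()
    result["significant"] = result["p_indval"] < threshold
    result["target_group"] = target_group
    return result.sort_values("asv_id", kind="mergesort").reset_index(drop=True)
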