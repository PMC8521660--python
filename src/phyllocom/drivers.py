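"""Screen for taxa that individually reproduce the floral community cluster.

For every rarefied replicate of the raw table, the abundance profile of each
taxon is clustered *alone* (one-feature Bray-Curtis, which reduces to
``d(i, j) = |x_i - x_j| / (x_i + x_j)``, with ``d = 0`` when both are zero)
and the taxon scores a recovery when some clade's leaf set equals the target
sample set exactly (or, with the ``max_extra`` relaxation, contains all of it
plus at most that many others).  A *candidate driver* must score in every
rarefied replicate - the conservative all-iterations rule, which suppresses
false positives from taxa at the detection limit and from rarefaction noise.

Candidates are then validated two ways: removing them must dissolve the
target clade (:func:`removal_test`), while removing the same number of
random non-candidate taxa must leave it standing
(:func:`random_removal_null`).

Speed note: the one-feature complete-linkage dendrogram has a closed-form
clade structure (see :func:`single_feature_clades`), so the screen does not
need a full linkage run per taxon.  The closed form is property-tested
against the generic :func:`~phyllocom.clustering.linkage_complete` path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import DissimilarityMatrix, clades, linkage_complete
from .preprocess import RarefactionPlan, iteration_seed, rarefy
from .tables import CountTable

log = logging.getLogger(__name__)


def single_feature_distance_matrix(
    values: Sequence[float], sample_ids: Sequence[str]
) -> DissimilarityMatrix:
    """Bray-Curtis over a single taxon: |x_i - x_j| / (x_i + x_j), 0 for 0/0."""
    x = np.asarray(values, dtype=float)
    denom = x[:, None] + x[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.abs(x[:, None] - x[None, :]) / denom
    mat[denom == 0] = 0.0
    np.fill_diagonal(mat, 0.0)
    return DissimilarityMatrix(tuple(sample_ids), mat, "bray_curtis")


def single_feature_clades(
    values: Sequence[float], sample_ids: Sequence[str]
) -> set[frozenset]:
    """All clades of the one-feature complete-linkage dendrogram, in closed form.

    Structure of that dendrogram (all of it follows from the metric):

    * samples sharing a value are at distance 0 and collapse first, in a
      lexicographic caterpillar, so each equal-value class contributes its
      id-ordered prefixes as clades;
    * a zero-valued sample is at distance exactly 1 from every positive one,
      while any two positive values are strictly closer than 1 - so the
      zero class and the positives only ever meet at the root, and no other
      clade mixes them;
    * across distinct positive values the matrix is strictly Robinson
      (distances grow monotonically away from the diagonal), so the
      remaining clades come from a complete-linkage run over the distinct
      values themselves, with each value standing for its whole class.

    Singletons and the full leaf set are excluded, as in
    :func:`~phyllocom.clustering.clades`.
    """
    x = np.asarray(values, dtype=float)
    ids = list(sample_ids)
    n = len(ids)
    full = frozenset(ids)
    out: set[frozenset] = set()
    classes: dict[float, list[str]] = {}
    for v, s in zip(x, ids):
        classes.setdefault(float(v), []).append(s)
    # caterpillar prefixes within each equal-value class
    for members in classes.values():
        ordered = sorted(members)
        for k in range(2, len(ordered) + 1):
            out.add(frozenset(ordered[:k]))
    # reduced linkage over distinct values (classes as super-leaves)
    if len(classes) > 1:
        class_values = sorted(classes)
        labels = [min(classes[v]) for v in class_values]
        vv = np.asarray(class_values, dtype=float)
        denom = vv[:, None] + vv[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.abs(vv[:, None] - vv[None, :]) / denom
        mat[denom == 0] = 0.0
        np.fill_diagonal(mat, 0.0)
        reduced = linkage_complete(
            DissimilarityMatrix(tuple(labels), mat, "bray_curtis")
        )
        label_to_members = {
            min(classes[v]): classes[v] for v in class_values
        }
        for clade in clades(reduced) | {frozenset(labels)}:
            expanded = frozenset(
                s for lbl in clade for s in label_to_members[lbl]
            )
            if 2 <= len(expanded) < n:
                out.add(expanded)
    out.discard(full)
    return {c for c in out if len(c) >= 2}


def _matches(clade: frozenset, target: frozenset, max_extra: int) -> bool:
    return target <= clade and len(clade - target) <= max_extra


def single_taxon_cluster_test(
    taxon_counts: Mapping[str, float] | pd.Series,
    target_set: Iterable[str],
    max_extra: int = 0,
    method: str = "fast",
) -> bool:
    """Does this taxon's profile alone reproduce the target clade?

    ``method="fast"`` uses the closed-form clade set; ``method="full"`` runs
    the generic linkage (kept for cross-checking).  A taxon absent from every
    sample yields False with a warning - a flat profile carries no structure.
    """
    series = pd.Series(taxon_counts)
    target = frozenset(target_set)
    if not 2 <= len(target) < len(series):
        raise ValueError(
            "target set must have >= 2 samples and be a proper subset"
        )
    missing = target - set(series.index)
    if missing:
        raise KeyError(f"target sample(s) not in profile: {sorted(missing)[:5]}")
    if (series <= 0).all():
        log.warning("taxon absent from all samples; no structure to cluster")
        return False
    if method == "fast":
        found = single_feature_clades(series.to_numpy(), list(series.index))
    elif method == "full":
        tree = linkage_complete(
            single_feature_distance_matrix(series.to_numpy(), list(series.index))
        )
        found = clades(tree)
    else:
        raise ValueError(f"unknown method {method!r}")
    return any(_matches(c, target, max_extra) for c in found)


# ---------------------------------------------------------------------------
# vectorised per-iteration screen
# ---------------------------------------------------------------------------


def _screen_exact_match(
    counts: np.ndarray,
    sample_ids: Sequence[str],
    target_mask: np.ndarray,
) -> np.ndarray:
    """Exact-match (max_extra=0) screen over all ASV columns at once.

    Vectorised necessary/sufficient conditions from the closed-form clade
    structure decide almost every column; the ambiguous remainder falls back
    to :func:`single_feature_clades`.
    """
    ids = np.asarray(sample_ids, dtype=object)
    t = counts[target_mask]  # (n_target, p)
    o = counts[~target_mask]  # (n_out, p)
    out_ids = ids[~target_mask]
    max_target_id = max(ids[target_mask])
    out_lt = np.array([s < max_target_id for s in out_ids])
    p = counts.shape[1]
    result = np.zeros(p, dtype=bool)

    t_min = t.min(axis=0)
    t_max = t.max(axis=0)
    absent_everywhere = counts.max(axis=0) == 0

    # T mixes zero and positive values -> impossible (root-only union)
    mixed = (t_min == 0) & (t_max > 0)

    # T constant: clade iff T is the id-ordered prefix of its value class,
    # i.e. no outsider shares the value with a smaller id than max(T)
    constant = (t_min == t_max) & ~absent_everywhere
    if constant.any():
        cols = np.nonzero(constant)[0]
        shares_small = (o[out_lt][:, cols] == t_min[cols]).any(axis=0)
        result[cols] = ~shares_small

    # T all positive, non-constant: necessary that no outsider value falls in
    # the closed interval [min(T), max(T)]
    varied = (t_min > 0) & (t_min < t_max)
    if varied.any():
        cols = np.nonzero(varied)[0]
        inside = (
            (o[:, cols] >= t_min[cols]) & (o[:, cols] <= t_max[cols])
        ).any(axis=0)
        open_cols = cols[~inside]
        if open_cols.size:
            # sufficient: strict separation, max within-T distance below the
            # closest cross distance (zero outsiders sit at distance 1,
            # which never undercuts a within-T distance)
            within = (t_max[open_cols] - t_min[open_cols]) / (
                t_max[open_cols] + t_min[open_cols]
            )
            oc = o[:, open_cols].astype(float)
            below = np.where(oc < t_min[open_cols], oc, -np.inf).max(axis=0)
            above = np.where(oc > t_max[open_cols], oc, np.inf).min(axis=0)
            pos_below = below > 0
            cross = np.full(open_cols.shape, np.inf)
            with np.errstate(invalid="ignore"):
                cb = (t_min[open_cols] - below) / (t_min[open_cols] + below)
                ca = (above - t_max[open_cols]) / (above + t_max[open_cols])
            cross = np.where(pos_below, np.minimum(cb, cross), cross)
            finite_above = np.isfinite(above)
            cross = np.where(finite_above, np.minimum(ca, cross), cross)
            zero_out = (oc == 0).any(axis=0)
            cross = np.where(zero_out, np.minimum(cross, 1.0), cross)
            clear = within < cross
            result[open_cols[clear]] = True
            ambiguous = open_cols[~clear]
            for j in ambiguous:
                found = single_feature_clades(counts[:, j], list(ids))
                result[j] = frozenset(ids[target_mask]) in found

    result[mixed] = False
    result[absent_everywhere] = False
    return result


def screen_iteration(
    rarefied: CountTable,
    target_set: Iterable[str],
    max_extra: int = 0,
) -> np.ndarray:
    """Boolean per-ASV outcome of the single-taxon test on one rarefied table."""
    target = frozenset(target_set)
    ids = rarefied.sample_ids
    if not target <= set(ids):
        raise KeyError(f"target sample(s) missing: {sorted(target - set(ids))[:5]}")
    if not 2 <= len(target) < len(ids):
        raise ValueError("target set must have >= 2 samples and be a proper subset")
    mask = np.array([s in target for s in ids])
    if max_extra == 0:
        return _screen_exact_match(rarefied.counts, ids, mask)
    out = np.zeros(rarefied.shape[1], dtype=bool)
    for j, asv in enumerate(rarefied.asv_ids):
        col = rarefied.counts[:, j]
        if col.max() == 0:
            continue
        found = single_feature_clades(col, list(ids))
        out[j] = any(_matches(c, target, max_extra) for c in found)
    return out


@dataclass(frozen=True)
class DriverScreenResult:
    """Outcome of the all-iterations single-taxon screen."""

    target_set: frozenset
    per_asv_recovery: dict  # asv_id -> number of rarefied datasets recovered in
    candidates: tuple[str, ...]  # recovery == n_iterations
    n_iterations: int

    def frame(self, taxonomy: Mapping[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for asv, rec in self.per_asv_recovery.items():
            row = {
                "asv_id": asv,
                "recovery_count": rec,
                "candidate": asv in set(self.candidates),
            }
            if taxonomy is not None:
                row["taxonomy"] = taxonomy.get(asv, "")
            rows.append(row)
        return pd.DataFrame(rows).sort_values("asv_id", kind="mergesort")


def identify_drivers(
    raw_table: CountTable,
    target_set: Iterable[str],
    plan: RarefactionPlan,
    max_extra: int = 0,
) -> DriverScreenResult:
    """All-iterations single-taxon screen over independently rarefied datasets.

    A taxon is a candidate only if its profile reproduces the target clade in
    *every* one of ``plan.n_iterations`` rarefied datasets (iteration seeds
    derive from ``plan.base_seed``, so the same seed stream shared with
    :func:`~phyllocom.clustering.rarefaction_support` reuses the same
    datasets across analyses).
    """
    target = frozenset(target_set)
    recovery = np.zeros(raw_table.shape[1], dtype=np.int64)
    for it in range(plan.n_iterations):
        sub = rarefy(raw_table, plan.depth, iteration_seed(plan.base_seed, it))
        recovery += screen_iteration(sub, target, max_extra)
    per_asv = {a: int(r) for a, r in zip(raw_table.asv_ids, recovery)}
    candidates = tuple(
        a for a, r in per_asv.items() if r == plan.n_iterations
    )
    return DriverScreenResult(
        target_set=target,
        per_asv_recovery=per_asv,
        candidates=candidates,
        n_iterations=plan.n_iterations,
    )


@dataclass(frozen=True)
class RemovalTestResult:
    """Two-sided validation of a candidate driver set."""

    targeted_removal_breaks_clade: bool
    targeted_support_fraction: float
    null_fraction_retaining_clade: float
    k_removed: int


def target_recovery_fraction(
    raw_table: CountTable,
    target_set: Iterable[str],
    plan: RarefactionPlan,
    metric: str = "bray_curtis",
    max_extra: int = 0,
    drop_after_rarefying: Iterable[str] = (),
) -> float:
    """Fraction of rarefied full-community clusterings recovering the target clade.

    ``drop_after_rarefying`` removes ASV columns from each rarefied dataset
    *after* subsampling — exclusions operate on the rarefied data, so the
    excluded taxa's reads are not silently replaced by deeper sampling of
    the remainder.
    """
    from .clustering import cluster_table  # local to avoid cycle at import time

    target = frozenset(target_set)
    drop = list(drop_after_rarefying)
    hits = 0
    for it in range(plan.n_iterations):
        sub = rarefy(raw_table, plan.depth, iteration_seed(plan.base_seed, it))
        if drop:
            sub = sub.drop_asvs(drop)
        tree = cluster_table(sub, metric)
        if any(_matches(c, target, max_extra) for c in clades(tree)):
            hits += 1
    return hits / plan.n_iterations


def removal_test(
    table: CountTable,
    candidates: Iterable[str],
    target_set: Iterable[str],
    plan: RarefactionPlan,
    metric: str = "bray_curtis",
    max_extra: int = 0,
    support_threshold: float = 0.5,
) -> tuple[bool, float]:
    """Does removing the candidate taxa dissolve the target clade?

    Re-runs the serial-rarefaction support analysis with the candidate
    columns excluded from every rarefied dataset; returns ``(clade no
    longer supported, support fraction after removal)``.
    """
    cand = list(candidates)
    if not cand:
        raise ValueError("candidate set must be non-empty")
    if set(cand) >= set(table.asv_ids):
        raise ValueError("cannot remove every ASV in the table")
    frac = target_recovery_fraction(
        table, target_set, plan, metric, max_extra, drop_after_rarefying=cand
    )
    return frac <= support_threshold, frac


def random_removal_null(
    table: CountTable,
    k: int,
    excluded: Iterable[str],
    n_draws: int,
    target_set: Iterable[str],
    plan: RarefactionPlan,
    metric: str = "bray_curtis",
    max_extra: int = 0,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Fraction of random ``k``-taxon exclusions that keep the target clade.

    Each draw rarefies once (draw-specific seed), removes ``k`` taxa sampled
    uniformly without replacement from the non-candidate pool of the
    rarefied dataset, reclusters the full community, and checks whether the
    target clade is present.
    """
    from .clustering import cluster_table

    if k < 1:
        raise ValueError("k must be >= 1")
    excluded = set(excluded)
    eligible = [a for a in table.asv_ids if a not in excluded]
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} non-candidate ASVs available, need {k}"
        )
    target = frozenset(target_set)
    rng = np.random.default_rng(seed)
    hits = 0
    for draw in range(n_draws):
        drop = rng.choice(len(eligible), size=k, replace=False)
        sub = rarefy(table, plan.depth, iteration_seed(plan.base_seed, draw))
        sub = sub.drop_asvs([eligible[i] for i in drop])
        tree = cluster_table(sub, metric)
        if any(_matches(c, target, max_extra) for c in clades(tree)):
            hits += 1
    return hits / n_draws


def validate_drivers(
    table: CountTable,
    candidates: Sequence[str],
    target_set: Iterable[str],
    plan: RarefactionPlan,
    n_null_draws: int = 1000,
    metric: str = "bray_curtis",
    max_extra: int = 0,
    seed: int | np.random.SeedSequence = 0,
) -> RemovalTestResult:
    """Targeted-removal and random-removal validation in one record."""
    breaks, frac_after = removal_test(
        table, candidates, target_set, plan, metric, max_extra
    )
    null_frac = random_removal_null(
        table,
        k=len(candidates),
        excluded=candidates,
        n_draws=n_null_draws,
        target_set=target_set,
        plan=plan,
        metric=metric,
        max_extra=max_extra,
        seed=seed,
    )
    return RemovalTestResult(
        targeted_removal_breaks_clade=breaks,
        targeted_support_fraction=frac_after,
        null_fraction_retaining_clade=null_frac,
        k_removed=len(candidates),
    )
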