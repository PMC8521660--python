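"""Bray-Curtis dissimilarity, complete-linkage clustering, and clade support.

Community profiles at a common read depth are compared with the Bray-Curtis
metric (optionally binary, i.e. presence/absence only) and clustered by
complete linkage.  Clade support is estimated on two independent resampling
axes:

* **bootstrap** — resample ASV columns with replacement from one reference
  rarefied table and recluster (feature bootstrap, the standard practice for
  cluster support on community matrices; a read-level bootstrap within
  samples is available behind ``unit="reads"``);
* **serial rarefaction** — independently re-rarefy the raw table and
  recluster, quantifying sensitivity to the randomness of rarefaction itself.

Each axis is summarised by a majority-rule consensus: clades recovered in
more than half of the analyses, annotated with their recovery fraction.  A
clade counts as *statistically supported* only when it clears the threshold
on both axes.

The linkage implementation is deterministic: among equally distant cluster
pairs it merges the pair whose sorted label pair (labels are the
lexicographically smallest member sample id) is smallest, so fixed seeds
give bit-identical dendrograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .preprocess import RarefactionPlan, iteration_seed, rarefy
from .tables import CountTable

METRICS = ("bray_curtis", "bray_curtis_binary")


def bray_curtis(x, y, binary: bool = False) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(x,y)) / (sum(x)+sum(y)).

    With ``binary=True`` counts are first mapped to presence/absence.  Two
    all-zero profiles are defined as identical (distance 0, with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if binary:
        x = (x > 0).astype(float)
        y = (y > 0).astype(float)
    denom = x.sum() + y.sum()
    if denom == 0:
        warnings.warn("Bray-Curtis of two empty profiles defined as 0")
        return 0.0
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric sample-by-sample dissimilarity in [0, 1] with zero diagonal."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.isfinite(v).all():
            raise ValueError("dissimilarity matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("dissimilarity matrix has a nonzero diagonal")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("dissimilarities must lie in [0, 1]")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.sample_ids
        )


def bray_curtis_matrix(table: CountTable, binary: bool = False) -> DissimilarityMatrix:
    """All pairwise Bray-Curtis dissimilarities of a count table."""
    arr = table.counts.astype(float)
    if binary:
        arr = (arr > 0).astype(float)
    totals = arr.sum(axis=1)
    if (totals == 0).any():
        warnings.warn(
            "table contains all-zero sample(s); their mutual distance is "
            "defined as 0"
        )
    with np.errstate(invalid="ignore"):
        condensed = pdist(arr, metric="braycurtis")
    condensed = np.nan_to_num(condensed, nan=0.0)  # zero-zero pairs
    mat = squareform(condensed)
    metric = "bray_curtis_binary" if binary else "bray_curtis"
    return DissimilarityMatrix(table.sample_ids, mat, metric)


def matrix_for(table: CountTable, metric: str) -> DissimilarityMatrix:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r} (allowed: {METRICS})")
    return bray_curtis_matrix(table, binary=metric == "bray_curtis_binary")


# ---------------------------------------------------------------------------
# dendrograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Node:
    members: frozenset
    height: float
    label: str  # lexicographically smallest member id
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass(frozen=True)
class Dendrogram:
    """Binary complete-linkage tree with non-decreasing merge heights."""

    root: Node
    leaves: tuple[str, ...]

    def internal_nodes(self) -> list[Node]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.append(node.left)
                stack.append(node.right)
        return out

    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """(left members, right members, height), ordered by merge height."""
        out = [
            (n.left.members, n.right.members, n.height)
            for n in self.internal_nodes()
        ]
        out.sort(key=lambda t: (t[2], sorted(t[0] | t[1])))
        return out


def linkage_complete(d: DissimilarityMatrix) -> Dendrogram:
    """Agglomerative complete-linkage clustering with deterministic ties.

    Inter-cluster distance is the maximum pairwise member distance.  Among
    pairs at the current minimum distance, the pair whose sorted label pair
    is lexicographically smallest merges first.  Merge heights are
    non-decreasing (complete linkage is monotone); this is asserted.
    """
    n = len(d.sample_ids)
    if n < 2:
        raise ValueError("clustering needs at least 2 samples")
    nodes: list[Node | None] = [
        Node(members=frozenset([s]), height=0.0, label=s) for s in d.sample_ids
    ]
    # upper triangle holds inter-cluster distances; everything else is +inf
    dist = np.full((n, n), np.inf)
    iu = np.triu_indices(n, k=1)
    dist[iu] = d.values[iu]
    last_height = 0.0
    n_active = n
    while n_active > 1:
        flat = int(np.argmin(dist))
        a, b = divmod(flat, n)
        height = float(dist[a, b])
        ties = np.argwhere(dist == height)
        if len(ties) > 1:
            # deterministic tie-break: smallest sorted label pair
            def key(pair):
                la, lb = nodes[pair[0]].label, nodes[pair[1]].label
                return (min(la, lb), max(la, lb))

            a, b = min((tuple(t) for t in ties), key=key)
        assert height >= last_height - 1e-12, "complete linkage must be monotone"
        last_height = max(last_height, height)
        left, right = nodes[a], nodes[b]
        if right.label < left.label:
            left, right = right, left
        nodes[a] = Node(
            members=left.members | right.members,
            height=height,
            label=left.label,
            left=left,
            right=right,
        )
        # complete-linkage update: distance to merged = max of the two rows,
        # stored in slot a; slot b is retired
        row_a = np.minimum(dist[a], dist[:, a])
        row_b = np.minimum(dist[b], dist[:, b])
        new_row = np.maximum(row_a, row_b)
        new_row[a] = new_row[b] = np.inf
        dist[a, :] = np.inf
        dist[:, a] = np.inf
        dist[b, :] = np.inf
        dist[:, b] = np.inf
        dist[a, a + 1 :] = new_row[a + 1 :]
        dist[: a, a] = new_row[:a]
        nodes[b] = None
        n_active -= 1
    root = next(node for node in nodes if node is not None)
    return Dendrogram(root=root, leaves=d.sample_ids)


def clades(t: Dendrogram) -> set[frozenset]:
    """All internal-node leaf sets, excluding singletons and the full leaf set."""
    full = frozenset(t.leaves)
    return {
        n.members
        for n in t.internal_nodes()
        if 2 <= len(n.members) < len(full)
    }


def cluster_table(table: CountTable, metric: str = "bray_curtis") -> Dendrogram:
    return linkage_complete(matrix_for(table, metric))


# ---------------------------------------------------------------------------
# support estimation
# ---------------------------------------------------------------------------


def bootstrap_support(
    rarefied_table: CountTable,
    n_boot: int,
    metric: str = "bray_curtis",
    seed: int | np.random.SeedSequence = 0,
    unit: str = "asvs",
) -> dict[frozenset, float]:
    """Clade recovery fractions over ``n_boot`` bootstrap replicates.

    The resampling unit is ASV columns with replacement (``unit="asvs"``,
    the default feature bootstrap) or reads within each sample
    (``unit="reads"``).  The input should already be rarefied to a common
    depth.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if unit not in ("asvs", "reads"):
        raise ValueError(f"unknown bootstrap unit {unit!r}")
    rng = np.random.default_rng(seed)
    arr = rarefied_table.counts
    n_samples, n_asvs = arr.shape
    counts: dict[frozenset, int] = {}
    for _ in range(n_boot):
        if unit == "asvs":
            cols = rng.integers(0, n_asvs, size=n_asvs)
            boot = arr[:, cols]
        else:
            boot = np.empty_like(arr)
            for i in range(n_samples):
                total = arr[i].sum()
                p = arr[i] / total if total else np.full(n_asvs, 1.0 / n_asvs)
                boot[i] = rng.multinomial(total, p)
        boot_table = CountTable.from_arrays(
            rarefied_table.sample_ids,
            [f"b{j}" for j in range(n_asvs)],
            boot,
        )
        tree = cluster_table(boot_table, metric)
        for clade in clades(tree):
            counts[clade] = counts.get(clade, 0) + 1
    return {clade: c / n_boot for clade, c in counts.items()}


def rarefaction_support(
    raw_table: CountTable,
    plan: RarefactionPlan,
    metric: str = "bray_curtis",
) -> dict[frozenset, float]:
    """Clade recovery fractions over ``plan.n_iterations`` independent rarefactions."""
    counts: dict[frozenset, int] = {}
    for it in range(plan.n_iterations):
        sub = rarefy(raw_table, plan.depth, iteration_seed(plan.base_seed, it))
        tree = cluster_table(sub, metric)
        for clade in clades(tree):
            counts[clade] = counts.get(clade, 0) + 1
    return {clade: c / plan.n_iterations for clade, c in counts.items()}


@dataclass(frozen=True)
class CladeSupport:
    """One clade with its recovery fraction on both resampling axes."""

    clade: frozenset
    bootstrap_fraction: float
    rarefaction_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap fraction outside [0, 1]")
        if not 0 <= self.rarefaction_fraction <= 1:
            raise ValueError("rarefaction fraction outside [0, 1]")


@dataclass(frozen=True)
class ConsensusDendrogram:
    """Majority-rule consensus: clades recovered in > 50% of analyses.

    The >0.5 rule guarantees retained clades are pairwise compatible (nested
    or disjoint); this is verified at construction.  A point-estimate
    dendrogram (from one reference rarefied dataset) is attached for display.
    """

    clades: dict  # frozenset -> recovery fraction (> 0.5)
    point_estimate: Dendrogram | None = None

    def __post_init__(self) -> None:
        items = list(self.clades.items())
        for k, (c1, _) in enumerate(items):
            for c2, _ in items[k + 1 :]:
                if not (c1 <= c2 or c2 <= c1 or not (c1 & c2)):
                    raise ValueError(
                        "incompatible clades in a majority-rule consensus: "
                        f"{sorted(c1)} vs {sorted(c2)}"
                    )


def majority_consensus(
    supports: Mapping[frozenset, float],
    point_estimate: Dendrogram | None = None,
) -> ConsensusDendrogram:
    """Keep clades with recovery fraction > 0.5; collapse the rest."""
    for clade, frac in supports.items():
        if not 0 <= frac <= 1:
            raise ValueError(f"support fraction {frac} outside [0, 1]")
    kept = {clade: frac for clade, frac in supports.items() if frac > 0.5}
    return ConsensusDendrogram(clades=kept, point_estimate=point_estimate)


def is_supported(
    clade: Iterable[str],
    boot: Mapping[frozenset, float],
    rare: Mapping[frozenset, float],
    threshold: float = 0.5,
) -> bool:
    """Statistically supported = clears the threshold on *both* axes."""
    if not 0 < threshold <= 1:
        raise ValueError("support threshold must be in (0, 1]")
    clade = frozenset(clade)
    return boot.get(clade, 0.0) > threshold and rare.get(clade, 0.0) > threshold


def support_table(
    boot: Mapping[frozenset, float],
    rare: Mapping[frozenset, float],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """One row per clade seen on either axis, with both fractions and the verdict."""
    all_clades = sorted(set(boot) | set(rare), key=lambda c: (len(c), sorted(c)))
    rows = []
    for clade in all_clades:
        b = boot.get(clade, 0.0)
        r = rare.get(clade, 0.0)
        rows.append(
            {
                "clade": ";".join(sorted(clade)),
                "size": len(clade),
                "bootstrap_fraction": b,
                "rarefaction_fraction": r,
                "supported": b > threshold and r > threshold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["clade", "size", "bootstrap_fraction", "rarefaction_fraction", "supported"],
    )


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------


def _newick_label(s: str) -> str:
    if any(c in s for c in " \t()[]:;,'"):
        return "'" + s.replace("'", "''") + "'"
    return s


def to_newick(
    t: Dendrogram,
    boot: Mapping[frozenset, float] | None = None,
    rare: Mapping[frozenset, float] | None = None,
) -> str:
    """Serialize with optional ``boot%/rare%`` node support labels."""

    def fmt(node: Node, parent_height: float) -> str:
        length = max(parent_height - node.height, 0.0)
        if node.is_leaf:
            return f"{_newick_label(node.label)}:{length:.6g}"
        inner = ",".join(
            fmt(child, node.height) for child in (node.left, node.right)
        )
        label = ""
        if boot is not None or rare is not None:
            parts = []
            if boot is not None:
                parts.append(f"{100 * boot.get(node.members, 0.0):.0f}")
            if rare is not None:
                parts.append(f"{100 * rare.get(node.members, 0.0):.0f}")
            label = _newick_label("/".join(parts))
        return f"({inner}){label}:{length:.6g}"

    root = t.root
    inner = ",".join(fmt(child, root.height) for child in (root.left, root.right))
    return f"({inner});"
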