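"""Structure-based clustering of candidate deaminases.

The discovery pipeline predicts a 3D structure per candidate, scores every
pair with the length-normalized TM-score, and partitions the set with a
greedy leader rule: proteins are visited in descending length order, the
longest unclustered protein seeds a cluster, and every still-unclustered
protein whose TM-score against that seed exceeds the threshold (default
0.7, strict) joins it.  Clustered proteins never participate again.

Because the TM-score is length-normalized, the normalization convention
matters: the default ``by_first`` resolves the seed-vs-candidate lookup by
the seed's length, which — seeds being the longest remaining proteins —
coincides with normalizing by the longer partner, the conservative (lower)
score.  A size-weighted UPGMA tree over ``1 - TM`` is provided as the
hierarchical alternative, and representative deaminases are drawn per
cluster as ``max(1, ceil(fraction * n))`` members with a seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .seqio import ConfigError, FormatError, PairScoreRow

__all__ = [
    "StructureSet",
    "TMMatrix",
    "ClusteringParams",
    "Cluster",
    "ClusterSet",
    "SamplingParams",
    "Dendrogram",
    "build_tm_matrix",
    "leader_cluster",
    "upgma",
    "select_representatives",
    "compare_partitions",
]

NORMALIZATION_MODES = ("by_first", "by_longer", "by_shorter", "symmetric_min")


@dataclass(frozen=True)
class StructureSet:
    """Candidate proteins with their amino-acid lengths."""

    ids: tuple[str, ...]
    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ConfigError("duplicate ids in StructureSet")
        for i in self.ids:
            if i not in self.lengths:
                raise ConfigError(f"id {i!r} has no length")
            if self.lengths[i] < 1:
                raise ConfigError(f"id {i!r}: length must be >= 1")

    def __len__(self) -> int:
        return len(self.ids)


class TMMatrix:
    """Pairwise TM-score lookup under an explicit normalization convention.

    Scores are stored per unordered pair as (norm-by-a, norm-by-b); the
    ``lookup(center, other)`` resolution depends on ``mode``.  Missing pairs
    resolve to ``default_missing`` (0.0 by default: absent evidence never
    clusters anything).
    """

    def __init__(
        self,
        scores: Mapping[tuple[str, str], tuple[float, float]],
        lengths: Mapping[str, int],
        mode: str = "by_first",
        default_missing: float = 0.0,
    ) -> None:
        if mode not in NORMALIZATION_MODES:
            raise ConfigError(f"unknown normalization mode {mode!r}")
        self.mode = mode
        self.default_missing = default_missing
        self._lengths = dict(lengths)
        # canonical key: sorted id pair -> (norm_by_first_of_key, norm_by_second)
        self._scores: dict[tuple[str, str], tuple[float, float]] = {}
        for (a, b), (na, nb) in scores.items():
            key = (a, b) if a <= b else (b, a)
            val = (na, nb) if a <= b else (nb, na)
            self._scores[key] = val

    def lookup(self, center_id: str, other_id: str) -> float:
        if center_id == other_id:
            raise ConfigError("lookup of a self-pair is undefined")
        for i in (center_id, other_id):
            if i not in self._lengths:
                raise ConfigError(f"unknown id {i!r}")
        key = (center_id, other_id) if center_id <= other_id else (other_id, center_id)
        if key not in self._scores:
            return self.default_missing
        n_first, n_second = self._scores[key]
        by_id = {key[0]: n_first, key[1]: n_second}
        if self.mode == "by_first":
            return by_id[center_id]
        if self.mode == "symmetric_min":
            return min(n_first, n_second)
        la, lb = self._lengths[key[0]], self._lengths[key[1]]
        if la == lb:
            # equal lengths: both normalizations refer to the same length
            longer_id = shorter_id = None
            longer = min(n_first, n_second)
            shorter = max(n_first, n_second)
        else:
            longer_id = key[0] if la > lb else key[1]
            shorter_id = key[1] if la > lb else key[0]
            longer = by_id[longer_id]
            shorter = by_id[shorter_id]
        return longer if self.mode == "by_longer" else shorter


@dataclass(frozen=True)
class ClusteringParams:
    tm_threshold: float = 0.7  # strict: members require TM > threshold
    tie_break: str = "lexicographic"

    def __post_init__(self) -> None:
        if not 0.0 < self.tm_threshold < 1.0:
            raise ConfigError("tm_threshold must lie in (0, 1)")
        if self.tie_break != "lexicographic":
            raise ConfigError(f"unknown tie_break {self.tie_break!r}")


@dataclass(frozen=True)
class Cluster:
    center_id: str
    member_ids: tuple[str, ...]
    index: int  # 1-based, creation order

    def __post_init__(self) -> None:
        if self.center_id not in self.member_ids:
            raise ConfigError("cluster center must be a member")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ConfigError("duplicate members in cluster")

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple[Cluster, ...]
    params: ClusteringParams

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            overlap = seen.intersection(c.member_ids)
            if overlap:
                raise ConfigError(f"ids in multiple clusters: {sorted(overlap)}")
            seen.update(c.member_ids)

    def __len__(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, int]:
        """id -> 1-based cluster index."""
        return {m: c.index for c in self.clusters for m in c.member_ids}


@dataclass(frozen=True)
class SamplingParams:
    fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ConfigError("fraction must lie in (0, 1]")


class Dendrogram:
    """Ultrametric rooted binary tree from UPGMA agglomeration."""

    def __init__(self, root: "_Node"):
        self.root = root

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def height(self) -> float:
        return self.root.height

    def newick(self) -> str:
        return self.root.newick(parent_height=self.root.height) + ";"

    def cophenetic(self, a: str, b: str) -> float:
        """Tree distance between leaves = 2 x height of their LCA."""
        node = self.root
        while True:
            if node.left is None:
                raise ConfigError(f"leaves {a!r}, {b!r} not both in tree")
            left = set(node.left.leaf_names())
            if a in left and b in left:
                node = node.left
            elif a not in left and b not in left:
                node = node.right
            else:
                return 2.0 * node.height


class _Node:
    __slots__ = ("name", "height", "left", "right")

    def __init__(self, name=None, height=0.0, left=None, right=None):
        self.name = name
        self.height = height
        self.left = left
        self.right = right

    def leaf_names(self) -> list[str]:
        if self.left is None:
            return [self.name]
        return self.left.leaf_names() + self.right.leaf_names()

    def newick(self, parent_height: float) -> str:
        branch = parent_height - self.height
        if self.left is None:
            return f"{self.name}:{branch:g}"
        inner = ",".join(
            child.newick(parent_height=self.height)
            for child in (self.left, self.right)
        )
        return f"({inner}):{branch:g}" if branch > 0 or parent_height != self.height else f"({inner})"


def build_tm_matrix(
    pair_rows: Iterable[PairScoreRow],
    structure_set: StructureSet,
    mode: str = "by_first",
    default_missing: float = 0.0,
) -> TMMatrix:
    """Assemble a :class:`TMMatrix` from pair-score rows.

    Every row's ids must belong to the structure set; duplicate pairs must
    agree (last one wins after a consistency check is skipped — we reject
    conflicting duplicates outright).
    """
    known = set(structure_set.ids)
    scores: dict[tuple[str, str], tuple[float, float]] = {}
    for row in pair_rows:
        for i in (row.id_a, row.id_b):
            if i not in known:
                raise ConfigError(f"pair row references unknown id {i!r}")
        key = (row.id_a, row.id_b)
        scores[key] = (row.tm_norm_a, row.tm_norm_b)
    return TMMatrix(scores, structure_set.lengths, mode=mode,
                    default_missing=default_missing)


def leader_cluster(
    structure_set: StructureSet,
    tm_matrix: TMMatrix,
    params: ClusteringParams | None = None,
) -> ClusterSet:
    """Greedy descending-length leader clustering.

    Repeat until the pool is empty: the longest unclustered protein
    (length ties broken by lexicographically smallest id) becomes a cluster
    center and absorbs every unclustered protein with
    ``lookup(center, u) > tm_threshold`` (strict).  Clusters are numbered in
    creation order, 1-based.
    """
    params = params or ClusteringParams()
    order = sorted(structure_set.ids,
                   key=lambda i: (-structure_set.lengths[i], i))
    unclustered = set(order)
    clusters: list[Cluster] = []
    for center in order:
        if center not in unclustered:
            continue
        members = [center] + [
            u for u in order
            if u != center and u in unclustered
            and tm_matrix.lookup(center, u) > params.tm_threshold
        ]
        unclustered.difference_update(members)
        clusters.append(
            Cluster(center_id=center, member_ids=tuple(members),
                    index=len(clusters) + 1)
        )
    return ClusterSet(clusters=tuple(clusters), params=params)


def upgma(
    dissimilarity: np.ndarray,
    ids: Sequence[str],
    tol: float = 1e-9,
) -> Dendrogram:
    """Size-weighted average-linkage (UPGMA) agglomeration.

    ``dissimilarity`` is a symmetric non-negative matrix with zero diagonal
    (conventionally ``1 - TM``).  Node heights are half the merge distance,
    so leaf-to-leaf tree distance reproduces the cophenetic distance.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise ConfigError(f"matrix shape {d.shape} does not match {n} ids")
    if n < 2:
        raise ConfigError("need at least two leaves")
    if np.any(d < 0):
        raise ConfigError("dissimilarities must be non-negative")
    if np.max(np.abs(np.diag(d))) > tol:
        raise ConfigError("diagonal must be zero")
    if np.max(np.abs(d - d.T)) > tol:
        raise ConfigError("matrix asymmetric beyond tolerance")
    d = (d + d.T) / 2.0

    linkage = hierarchy.linkage(squareform(d, checks=False), method="average")
    nodes: list[_Node] = [_Node(name=i) for i in ids]
    for left_i, right_i, dist, _count in linkage:
        nodes.append(
            _Node(height=dist / 2.0,
                  left=nodes[int(left_i)], right=nodes[int(right_i)])
        )
    return Dendrogram(nodes[-1])


def representative_count(n: int, fraction: float = 0.10) -> int:
    """Per-cluster sample size: round the fraction up, minimum one."""
    if n < 1:
        raise ConfigError("cluster size must be >= 1")
    return max(1, math.ceil(fraction * n))


def select_representatives(
    cluster_set: ClusterSet,
    sampling_params: SamplingParams,
) -> dict[int, list[str]]:
    """Seeded uniform sampling of ``max(1, ceil(fraction*n))`` members per cluster.

    Deterministic for a given seed regardless of input ordering (members are
    sorted before sampling).  Returns cluster index -> selected ids.
    """
    rng = np.random.default_rng(sampling_params.seed)
    selection: dict[int, list[str]] = {}
    for cluster in cluster_set.clusters:
        k = representative_count(len(cluster), sampling_params.fraction)
        members = sorted(cluster.member_ids)
        chosen = rng.choice(len(members), size=k, replace=False)
        selection[cluster.index] = [members[i] for i in sorted(chosen)]
    return selection


def compare_partitions(
    partition_a: Mapping[str, int],
    partition_b: Mapping[str, int],
) -> dict[str, float]:
    """Adjusted Rand index plus the raw count of agreeing pairs.

    A pair of ids "agrees" when the two partitions make the same
    together/apart decision for it.
    """
    if set(partition_a) != set(partition_b):
        raise ConfigError("partitions cover different id universes")
    ids = sorted(partition_a)
    la = [partition_a[i] for i in ids]
    lb = [partition_b[i] for i in ids]
    ari = float(adjusted_rand_score(la, lb))
    n_agree = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            same_a = la[i] == la[j]
            same_b = lb[i] == lb[j]
            n_agree += same_a == same_b
    return {"adjusted_rand_index": ari, "n_agreeing_pairs": n_agree}
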