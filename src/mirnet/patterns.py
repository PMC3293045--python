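"""Stage-trend pattern classification and hierarchical clustering.

Features (or samples) are clustered on centred-Pearson distance with average
or complete linkage; agglomeration is fully deterministic, breaking distance
ties by the lexicographically smaller cluster-index pair, so results are
reproducible across runs and input orderings.

Stage-mean trajectories over the ordered design (normal, I-II, III, IV, MET)
are reduced to a sign vector of successive differences under a flatness
tolerance and classified into six dynamic patterns:

1. gradual decrease across progression
2. early decrease then flat
3. decrease then recovery (down-then-up)
4. increase then decline (up-then-down)
5. gradual increase across progression
6. flat through the primary stages, sharp jump at metastasis

Patterns 1, 5 and 6 follow the published verbal definitions; 2-4 complete the
taxonomy symmetrically and are an interpretation (a reduced 1/5/6-only mode is
available). Pattern 6 takes precedence over 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DataError, ExpressionMatrix, StageDesign

FLATNESS_EPS = 0.25  # log2 units below which a stage-to-stage step counts as flat
SPIKE_DELTA = 1.0    # log2 units a metastasis jump must reach for pattern 6


@dataclass(frozen=True)
class StageTrajectory:
    feature_id: str
    stage_means: tuple[float, ...]
    trend: tuple[int, ...]  # signs of successive differences in {-1, 0, +1}


@dataclass(frozen=True)
class PatternAssignment:
    feature_id: str
    pattern_id: int | None  # 1..6, None = unclassified


def stage_trajectories(matrix: ExpressionMatrix, design: StageDesign,
                       eps: float = FLATNESS_EPS) -> list[StageTrajectory]:
    """Stage-mean trajectory per feature over the design's stage order."""
    out = []
    for fid in matrix.feature_ids:
        row = matrix.data.loc[fid]
        means = tuple(float(np.nanmean(row[design.samples_in(st)])) for st in design.stages)
        out.append(make_trajectory(fid, means, eps))
    return out


def make_trajectory(feature_id: str, stage_means, eps: float = FLATNESS_EPS) -> StageTrajectory:
    means = tuple(float(m) for m in stage_means)
    diffs = np.diff(means)
    trend = tuple(0 if abs(d) <= eps else (1 if d > 0 else -1) for d in diffs)
    return StageTrajectory(feature_id=feature_id, stage_means=means, trend=trend)


def classify_pattern(traj: StageTrajectory, eps: float = FLATNESS_EPS,
                     delta: float = SPIKE_DELTA, taxonomy: str = "full") -> PatternAssignment:
    """Assign a trajectory to one of the six dynamic patterns (or None)."""
    if taxonomy not in ("full", "reduced"):
        raise DataError(f"unknown taxonomy {taxonomy!r}")
    if len(traj.stage_means) != 5:
        raise DataError(
            f"{traj.feature_id}: need 5 stage means, got {len(traj.stage_means)}")
    t = traj.trend
    diffs = np.diff(traj.stage_means)

    # 6 first: flat through primary stages, sharp metastasis jump.
    if all(x == 0 for x in t[:-1]) and t[-1] == 1 and diffs[-1] >= delta:
        return PatternAssignment(traj.feature_id, 6)
    nonzero = [x for x in t if x != 0]
    if all(x <= 0 for x in t) and any(x < 0 for x in t):
        # early-down-then-flat is split out of the monotone-decrease class
        if taxonomy == "full" and t[0] == -1 and all(x == 0 for x in t[1:]):
            return PatternAssignment(traj.feature_id, 2)
        return PatternAssignment(traj.feature_id, 1)
    if all(x >= 0 for x in t) and any(x > 0 for x in t):
        return PatternAssignment(traj.feature_id, 5)
    if taxonomy == "full" and nonzero:
        first = nonzero[0]
        if first == -1 and 1 in t[list(t).index(-1):]:
            return PatternAssignment(traj.feature_id, 3)
        if first == 1 and -1 in t[list(t).index(1):]:
            return PatternAssignment(traj.feature_id, 4)
    return PatternAssignment(traj.feature_id, None)


def classify_patterns(matrix: ExpressionMatrix, design: StageDesign,
                      eps: float = FLATNESS_EPS, delta: float = SPIKE_DELTA,
                      taxonomy: str = "full") -> pd.DataFrame:
    rows = []
    for traj in stage_trajectories(matrix, design, eps):
        pa = classify_pattern(traj, eps, delta, taxonomy)
        rows.append((traj.feature_id, pa.pattern_id, *traj.stage_means))
    cols = ["feature_id", "pattern_id", *[f"mean_{st}" for st in design.stages]]
    return pd.DataFrame(rows, columns=cols).set_index("feature_id")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def correlation_distance_matrix(matrix: ExpressionMatrix, axis: str = "features") -> pd.DataFrame:
    """Centred-Pearson distance d = 1 - r between features (or samples)."""
    X = matrix.values if axis == "features" else matrix.values.T
    ids = matrix.feature_ids if axis == "features" else matrix.sample_ids
    if X.shape[0] < 2:
        raise DataError("need at least 2 items to compute distances")
    sd = X.std(axis=1)
    zero = [ids[i] for i in np.where(sd == 0)[0]]
    if zero:
        raise DataError(f"zero-variance items cannot be correlated: {zero}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class Dendrogram:
    """Agglomeration history: merge i joins clusters `left` and `right` at `height`."""

    ids: list[str]
    merges: list[tuple[int, int, float]]  # cluster indices as in scipy convention

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat partition with ``n_clusters`` clusters (labels are arbitrary ints)."""
        n = len(self.ids)
        if not 1 <= n_clusters <= n:
            raise DataError(f"cannot cut {n} items into {n_clusters} clusters")
        parent = list(range(n + len(self.merges)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for m, (a, b, _) in enumerate(self.merges[: n - n_clusters]):
            parent[find(a)] = n + m
            parent[find(b)] = n + m
        roots = {find(i) for i in range(n)}
        relabel = {r: j for j, r in enumerate(sorted(roots))}
        return {self.ids[i]: relabel[find(i)] for i in range(n)}

    def to_newick(self) -> str:
        n = len(self.ids)
        nodes: dict[int, str] = {i: self.ids[i] for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for m, (a, b, h) in enumerate(self.merges):
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            nodes[n + m] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + m] = h
        return nodes[n + len(self.merges) - 1] + ";" if self.merges else f"({','.join(self.ids)});"


def hierarchical_cluster(dist: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Deterministic agglomerative clustering on a precomputed distance matrix.

    Ties in the minimum inter-cluster distance are broken by the smaller
    (index_i, index_j) pair, making the result invariant to input row
    permutation up to relabelling.
    """
    if linkage not in ("average", "complete"):
        raise DataError(f"linkage must be 'average' or 'complete', got {linkage!r}")
    ids = list(dist.index)
    n = len(ids)
    D = dist.to_numpy(dtype=float).copy()
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise DataError("distance matrix must be square and symmetric")

    active: dict[int, set[int]] = {i: {i} for i in range(n)}  # cluster idx -> leaf members
    cur = {i: i for i in range(n)}  # active slot -> cluster index (scipy-style)
    merges: list[tuple[int, int, float]] = []
    dmat = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}

    next_idx = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                d = dmat[(min(i, j), max(i, j))]
                key = (d, cur[i], cur[j])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        merged = active[i] | active[j]
        merges.append((cur[i], cur[j], d))
        # linkage update against every other active cluster
        for kslot in active:
            if kslot in (i, j):
                continue
            dik = dmat[(min(i, kslot), max(i, kslot))]
            djk = dmat[(min(j, kslot), max(j, kslot))]
            if linkage == "average":
                ni, nj = len(active[i]), len(active[j])
                dnew = (ni * dik + nj * djk) / (ni + nj)
            else:
                dnew = max(dik, djk)
            dmat[(min(i, kslot), max(i, kslot))] = dnew  # slot i becomes the merged cluster
        del active[j]
        active[i] = merged
        cur[i] = next_idx
        next_idx += 1
    return Dendrogram(ids=ids, merges=merges)


def cluster_and_cut(dist: pd.DataFrame, n_clusters: int, linkage: str = "average") -> dict[str, int]:
    return hierarchical_cluster(dist, linkage).cut(n_clusters)


def stage_purity(labels: dict[str, int], design: StageDesign) -> float:
    """Fraction of clusters whose majority stage accounts for all their members."""
    from collections import Counter

    clusters: dict[int, list[str]] = {}
    for s, c in labels.items():
        clusters.setdefault(c, []).append(design.sample_to_stage[s])
    pure = sum(1 for members in clusters.values() if len(Counter(members)) == 1)
    return pure / len(clusters)
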