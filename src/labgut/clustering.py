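"""Species-level genome bins (SGBs): average-linkage clustering at 5%
genome distance, source classification, food/human overlap summaries, and
classical MDS ordination.

An SGB is an operational species unit: a cluster of genomes spanning at most
~5% whole-genome genetic diversity.  Clustering is agglomerative with
average (UPGMA) linkage on a Mash-style distance matrix; the flat partition
applies every merge whose average inter-cluster distance is <= the threshold
(inclusive) and none above it.

Deterministic tie-breaking: when two candidate merges share the same height,
the pair whose lexicographically smallest member id is smallest is merged
first (then the other cluster's smallest id).  This makes the partition
invariant to the input order of the genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .catalog import Genome
from .sketching import DistanceMatrix

__all__ = [
    "SGB",
    "Merge",
    "MergeTree",
    "average_linkage_cluster",
    "classify_sgbs",
    "overlap_summary",
    "classical_mds",
]


@dataclass
class SGB:
    """One species-level genome bin with source-composition flags."""

    sgb_id: str
    members: list[str]
    contains_reference: bool = False
    contains_human_mag: bool = False
    contains_food_mag: bool = False
    sgb_class: str = ""  # kSGB / fSGB / other, filled by classify_sgbs


@dataclass(frozen=True)
class Merge:
    left: frozenset[str]
    right: frozenset[str]
    height: float


@dataclass
class MergeTree:
    """Full agglomeration sequence; heights are average inter-cluster
    distances at each merge and are non-decreasing (UPGMA is monotone)."""

    merges: list[Merge] = field(default_factory=list)
    leaves: list[str] = field(default_factory=list)

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        node_height: dict[frozenset[str], float] = {frozenset([l]): 0.0 for l in self.leaves}
        node_newick: dict[frozenset[str], str] = {frozenset([l]): l for l in self.leaves}
        for m in self.merges:
            h = m.height
            parts = []
            for child in (m.left, m.right):
                bl = h - node_height[child]
                parts.append(f"{node_newick[child]}:{bl:.6g}")
            merged = m.left | m.right
            node_newick[merged] = "(" + ",".join(parts) + ")"
            node_height[merged] = h
            del node_newick[m.left], node_newick[m.right]
        # forest (threshold cuts) or single root
        roots = sorted(node_newick.values())
        if len(roots) == 1:
            return roots[0] + ";"
        return "(" + ",".join(f"{r}:0" for r in roots) + ");"


def _pair_key(members_a: list[str], members_b: list[str]) -> tuple[str, str]:
    a, b = min(members_a), min(members_b)
    return (a, b) if a <= b else (b, a)


def average_linkage_cluster(d: DistanceMatrix, threshold: float = 0.05
                            ) -> tuple[list[SGB], MergeTree]:
    """Cluster genomes into SGBs by average linkage at ``threshold``.

    Returns the flat partition (every merge with height <= threshold applied)
    and the complete merge tree.  SGB ids are assigned by descending member
    count, ties broken by the smallest member id.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    n = len(d.ids)
    if n == 0:
        raise ValueError("empty distance matrix")
    # active clusters: index -> member id list; Lance-Williams average update
    members: dict[int, list[str]] = {i: [d.ids[i]] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.values[i, j])
    merges: list[Merge] = []
    next_id = n
    while len(members) > 1:
        best = None
        for (i, j), val in dist.items():
            key = (val, _pair_key(members[i], members[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        (height, _), i, j = best
        merges.append(Merge(frozenset(members[i]), frozenset(members[j]), height))
        new = next_id
        next_id += 1
        ni, nj = sizes[i], sizes[j]
        new_members = sorted(members[i] + members[j])
        for k in list(members):
            if k in (i, j):
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(new, k), max(new, k))] = (ni * dik + nj * djk) / (ni + nj)
        del dist[(i, j)]
        del members[i], members[j], sizes[i], sizes[j]
        members[new] = new_members
        sizes[new] = ni + nj
    tree = MergeTree(merges=merges, leaves=list(d.ids))
    # flat partition: apply merges with height <= threshold (inclusive)
    parent = {gid: gid for gid in d.ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in merges:
        if m.height <= threshold:
            a = find(next(iter(m.left)))
            b = find(next(iter(m.right)))
            if a != b:
                parent[max(a, b)] = min(a, b)
    clusters: dict[str, list[str]] = {}
    for gid in d.ids:
        clusters.setdefault(find(gid), []).append(gid)
    groups = sorted(clusters.values(), key=lambda ms: (-len(ms), min(ms)))
    width = max(3, len(str(len(groups))))
    sgbs = [SGB(sgb_id=f"SGB{idx + 1:0{width}d}", members=sorted(ms))
            for idx, ms in enumerate(groups)]
    return sgbs, tree


def classify_sgbs(sgbs: list[SGB], catalogue: dict[str, Genome],
                  *, ksgb_requires_reference: bool = False) -> list[SGB]:
    """Fill source flags and assign each SGB its class.

    kSGB: contains at least one reference genome or (unless
    ``ksgb_requires_reference``) at least one human MAG.  fSGB: all members
    are food MAGs.  Everything else: ``other``.
    """
    for sgb in sgbs:
        missing = [m for m in sgb.members if m not in catalogue]
        if missing:
            raise KeyError(f"SGB {sgb.sgb_id}: unresolvable member id(s) {missing}")
        gs = [catalogue[m] for m in sgb.members]
        sgb.contains_reference = any(g.is_reference for g in gs)
        sgb.contains_human_mag = any(g.is_human_mag for g in gs)
        sgb.contains_food_mag = any(g.is_food_mag for g in gs)
        known = sgb.contains_reference or (
            sgb.contains_human_mag and not ksgb_requires_reference)
        if known:
            sgb.sgb_class = "kSGB"
        elif all(g.is_food_mag for g in gs):
            sgb.sgb_class = "fSGB"
        else:
            sgb.sgb_class = "other"
    return sgbs


def overlap_summary(sgbs: list[SGB], catalogue: dict[str, Genome]):
    """Food/human overlap table over classified SGBs.

    For food MAGs and for food-containing SGBs, counts and percentages
    (one decimal) falling in: SGBs that also contain human MAGs
    (``human_overlap``), kSGBs with no human MAG (``known_no_human``),
    food-only fSGBs (``food_only``), and any remainder (``other``).
    Percentages are over all food MAGs / all food-containing SGBs.
    """
    import pandas as pd

    rows = {c: {"n_food_mags": 0, "n_food_sgbs": 0}
            for c in ("human_overlap", "known_no_human", "food_only", "other")}
    total_mags = 0
    total_sgbs = 0
    for sgb in sgbs:
        if not sgb.sgb_class:
            raise ValueError("overlap_summary requires a classified partition")
        n_food = sum(1 for m in sgb.members if catalogue[m].is_food_mag)
        if n_food == 0:
            continue
        total_mags += n_food
        total_sgbs += 1
        if sgb.contains_human_mag:
            cat = "human_overlap"
        elif sgb.sgb_class == "kSGB":
            cat = "known_no_human"
        elif sgb.sgb_class == "fSGB":
            cat = "food_only"
        else:
            cat = "other"
        rows[cat]["n_food_mags"] += n_food
        rows[cat]["n_food_sgbs"] += 1
    out = pd.DataFrame(rows).T
    out["pct_food_mags"] = (
        (100.0 * out["n_food_mags"] / total_mags).round(1) if total_mags else 0.0)
    out["pct_food_sgbs"] = (
        (100.0 * out["n_food_sgbs"] / total_sgbs).round(1) if total_sgbs else 0.0)
    out.index.name = "category"
    return out


def classical_mds(d: DistanceMatrix, dims: int = 2):
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    ``dims`` leading coordinates scaled by the square roots of the positive
    eigenvalues.  Negative eigenvalues (non-Euclidean distances) are
    truncated; if fewer than ``dims`` positive eigenvalues exist the output
    is reduced with a warning.  Coordinates are reproducible up to sign.
    """
    import pandas as pd

    if dims < 1:
        raise ValueError(f"dims must be >= 1, got {dims}")
    n = len(d.ids)
    d2 = d.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-9 * abs(vals[0])) if n > 1 else vals > 0
    n_pos = int(np.count_nonzero(pos))
    use = min(dims, n_pos)
    if use < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {use} MDS dimensions")
    coords = vecs[:, :use] * np.sqrt(vals[:use])
    cols = [f"MDS{i + 1}" for i in range(use)]
    return pd.DataFrame(coords, index=d.ids, columns=cols)
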