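"""Distance dendrograms of accessions and their comparison.

Accessions are clustered from binary (locus presence) or genotype-coded
matrices with the simple-matching distance (fraction of disagreeing
positions over pairwise-complete positions) and Ward.D2 agglomeration —
the Lance-Williams update applied to squared distances, with a
deterministic smallest-label tie-break.  Two dendrograms over the same
leaves are compared by Baker's gamma (rank correlation of per-leaf-pair
fusion levels), by the entanglement of their leaf orders, and by a
label-permutation test of gamma.  Cluster robustness is assessed with an
ordinary character bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Dendrogram",
    "simple_matching_distance",
    "ward_clustering",
    "cophenetic_steps",
    "bakers_gamma",
    "entanglement",
    "permutation_test_gamma",
    "bootstrap_support",
    "to_newick",
]


@dataclass
class Dendrogram:
    """Rooted binary merge tree with heights.

    ``merges`` follows the scipy linkage convention: row t merges clusters
    ``a`` and ``b`` (ids 0..n-1 for leaves, n+t for the cluster created at
    step t) at height ``merges[t, 2]``; column 3 is the new cluster size.
    """

    labels: list[str]
    merges: np.ndarray
    leaf_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.merges.shape != (n - 1, 4):
            raise ValueError(f"expected {(n - 1, 4)} merge matrix, got {self.merges.shape}")
        if not self.leaf_order:
            self.leaf_order = [self.labels[i] for i in self._leaf_sequence()]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _members(self) -> list[list[int]]:
        """Leaf index sets per cluster id (leaves then internal, by step)."""
        n = self.n_leaves
        members: list[list[int]] = [[i] for i in range(n)]
        for a, b, _, _ in self.merges:
            members.append(members[int(a)] + members[int(b)])
        return members

    def _leaf_sequence(self) -> list[int]:
        members = self._members()
        return members[-1] if self.merges.size else [0]

    def clusters(self) -> list[frozenset[str]]:
        """Leaf-label sets of every internal node."""
        members = self._members()
        return [
            frozenset(self.labels[i] for i in m) for m in members[self.n_leaves :]
        ]

    def relabel(self, new_labels: list[str]) -> "Dendrogram":
        """Same topology/heights with leaves renamed positionally."""
        if len(new_labels) != self.n_leaves:
            raise ValueError("label count mismatch")
        mapping = dict(zip(self.labels, new_labels))
        return Dendrogram(
            labels=list(new_labels),
            merges=self.merges.copy(),
            leaf_order=[mapping[l] for l in self.leaf_order],
        )


def simple_matching_distance(matrix: pd.DataFrame, missing=None) -> pd.DataFrame:
    """Pairwise simple-matching distance between columns (accessions).

    d(i, j) = disagreeing positions / comparable positions, where a
    position is comparable when neither column is missing there.  Missing
    entries are NaN, or the value given as ``missing`` (e.g. -1 for
    genotype codes).  Raises if some pair shares no comparable position.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two accessions")
    x = matrix.to_numpy(dtype=float)
    if missing is not None:
        x = np.where(x == missing, np.nan, x)
    ok = ~np.isnan(x)
    accs = list(matrix.columns)
    n = len(accs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[:, i] & ok[:, j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no comparable positions for pair ({accs[i]}, {accs[j]})")
            mism = int((x[both, i] != x[both, j]).sum())
            d[i, j] = d[j, i] = mism / m
    return pd.DataFrame(d, index=accs, columns=accs)


def ward_clustering(distances: pd.DataFrame) -> Dendrogram:
    """Ward.D2 agglomeration of a distance matrix.

    Lance-Williams update on squared distances; the merge height is the
    (unsquared) updated distance, so heights are non-decreasing.  Ties are
    broken by the smallest (a, b) cluster-id pair, which makes the result
    deterministic and independent of floating-point dict ordering.
    """
    labels = list(distances.index)
    n = len(labels)
    d = distances.to_numpy(dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")
    if n < 2:
        raise ValueError("need at least two leaves")
    S = d.astype(float) ** 2  # squared distances, Lance-Williams operates here

    active: dict[int, int] = {i: i for i in range(n)}  # cluster id -> row index
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    merges = np.zeros((n - 1, 4))
    # grow S to hold new clusters
    S = np.pad(S, ((0, n - 1), (0, n - 1)), constant_values=np.inf)
    np.fill_diagonal(S, np.inf)

    for t in range(n - 1):
        ids = sorted(active)
        best = None
        for ii, a in enumerate(ids):
            for b in ids[ii + 1 :]:
                v = S[a, b]
                if best is None or v < best[0] - 1e-12:
                    best = (v, a, b)
        _, a, b = best
        h = float(np.sqrt(S[a, b]))
        new = n + t
        na, nb = sizes[a], sizes[b]
        for k in ids:
            if k in (a, b):
                continue
            nk = sizes[k]
            S[new, k] = S[k, new] = (
                (na + nk) * S[a, k] + (nb + nk) * S[b, k] - nk * S[a, b]
            ) / (na + nb + nk)
        del active[a], active[b]
        active[new] = new
        sizes[new] = na + nb
        merges[t] = (a, b, h, na + nb)
    return Dendrogram(labels=labels, merges=merges)


def cophenetic_steps(dend: Dendrogram) -> dict[tuple[str, str], int]:
    """Fusion level per leaf pair: clusters present just before the pair joins.

    If leaves i and j first co-cluster at merge step t (0-based), there
    were n - t clusters just beforehand; identical trees therefore yield
    identical level vectors, and the level decreases the later a pair
    fuses.
    """
    n = dend.n_leaves
    members: list[list[int]] = [[i] for i in range(n)]
    out: dict[tuple[str, str], int] = {}
    for t, (a, b, _, _) in enumerate(dend.merges):
        left, right = members[int(a)], members[int(b)]
        for i in left:
            for j in right:
                la, lb = dend.labels[i], dend.labels[j]
                key = (la, lb) if la <= lb else (lb, la)
                out[key] = n - t
        members.append(left + right)
    return out


def bakers_gamma(d1: Dendrogram, d2: Dendrogram) -> float:
    """Baker's gamma: rank correlation of the two pair fusion-level vectors.

    1 for identical hierarchies (any dendrogram against itself), around 0
    for unrelated ones, -1 for perfectly anti-ranked hierarchies.
    """
    if set(d1.labels) != set(d2.labels):
        raise ValueError("leaf sets differ")
    s1 = cophenetic_steps(d1)
    s2 = cophenetic_steps(d2)
    pairs = sorted(s1)
    v1 = np.array([s1[p] for p in pairs], dtype=float)
    v2 = np.array([s2[p] for p in pairs], dtype=float)
    if np.array_equal(v1, v2):
        return 1.0
    rho = stats.spearmanr(v1, v2).statistic
    return float(rho)


def entanglement(d1: Dendrogram, d2: Dendrogram, norm_power: float = 1.5) -> float:
    """Alignment quality of two leaf orders in [0, 1]; 0 = identical orders.

    The L-``norm_power`` norm of the rank differences between the two leaf
    orderings, divided by its worst-case value (one order reversed).
    """
    if set(d1.leaf_order) != set(d2.leaf_order):
        raise ValueError("leaf sets differ")
    n = d1.n_leaves
    pos2 = {l: i for i, l in enumerate(d2.leaf_order)}
    r1 = np.arange(n, dtype=float)
    r2 = np.array([pos2[l] for l in d1.leaf_order], dtype=float)
    num = float(np.sum(np.abs(r1 - r2) ** norm_power))
    worst = float(np.sum(np.abs(r1 - r1[::-1]) ** norm_power))
    if worst == 0:
        return 0.0
    return num / worst


def permutation_test_gamma(
    d1: Dendrogram,
    d2: Dendrogram,
    n_iter: int = 100,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Label-shuffling null for Baker's gamma.

    Returns (observed gamma, mean gamma under the null, empirical p) with
    p = (1 + #{null >= observed}) / (1 + n_iter).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    observed = bakers_gamma(d1, d2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    labels = np.array(d1.labels)
    for it in range(n_iter):
        perm = rng.permutation(len(labels))
        null[it] = bakers_gamma(d1.relabel(list(labels[perm])), d2)
    p = (1 + int((null >= observed).sum())) / (1 + n_iter)
    return observed, float(null.mean()), p


def bootstrap_support(
    matrix: pd.DataFrame,
    n_boot: int,
    seed: int = 0,
    missing=None,
) -> dict[frozenset[str], float]:
    """Character-bootstrap support for every cluster of the full-data tree.

    Rows (characters) are resampled with replacement, the tree is rebuilt
    with the same distance/clustering, and support is the fraction of
    replicates whose tree contains the cluster (as a leaf set).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    base = ward_clustering(simple_matching_distance(matrix, missing=missing))
    targets = {c for c in base.clusters() if 1 < len(c) < base.n_leaves}
    hits = {c: 0 for c in targets}
    rng = np.random.default_rng(seed)
    n_rows = matrix.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_rows, size=n_rows)
        boot = matrix.iloc[idx]
        tree = ward_clustering(simple_matching_distance(boot, missing=missing))
        found = set(tree.clusters())
        for c in targets:
            if c in found:
                hits[c] += 1
    return {c: hits[c] / n_boot for c in targets}


def to_newick(dend: Dendrogram) -> str:
    """Newick string with branch lengths derived from merge heights."""
    n = dend.n_leaves
    height = {i: 0.0 for i in range(n)}
    node = {i: dend.labels[i] for i in range(n)}
    for t, (a, b, h, _) in enumerate(dend.merges):
        a, b = int(a), int(b)
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node[n + t] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
        height[n + t] = h
    return node[2 * n - 2] + ";"
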