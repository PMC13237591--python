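"""Correlation-to-distance conversion, Ward clustering, rubric cuts, neighbours.

The similarity matrix is turned into a dissimilarity matrix with the standard
correlation distance d = 1 − ρ (mapping [−1, 1] monotonically onto [0, 2])
and joined agglomeratively under the Ward criterion. Because the input is a
precomputed, generally non-Euclidean distance matrix, Ward is applied through
the Lance–Williams recurrence on the squared distances as given, with no
Euclidean embedding:

    d²(k, i∪j) = [(nᵢ+nₖ) d²(k,i) + (nⱼ+nₖ) d²(k,j) − nₖ d²(i,j)] / (nᵢ+nⱼ+nₖ)

Merge heights are the square roots of the merged d² values; with
non-Euclidean input, inversions (non-monotone heights) are possible and are
not treated as errors. Ties in the merge criterion are broken toward the
lexicographically smallest pair of cluster indices, so the merge sequence is
a deterministic function of the input label order — which is exactly what
makes order-shuffling a meaningful perturbation in the robustness protocol.

Cutting the dendrogram at k = 13 and k = 5 yields the two-level rubric:
13 low-level categories nested inside 5 broad categories (nesting is
guaranteed because both cuts come from the same merge tree). PTs excluded
from clustering (by default Scientific Integrity Review, which is too rare
to estimate correlations for reliably) are merged back in via explicit
manual placements and flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vocab_io import MatrixValueError, PTVocabulary, SimilarityMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "RubricAssignment",
    "to_distance",
    "ward_dendrogram",
    "cut",
    "cluster_labels",
    "build_rubric",
    "nearest_neighbour",
    "to_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric PT × PT dissimilarity matrix with zero diagonal, entries in [0, 2]."""

    values: pd.DataFrame
    vocab: PTVocabulary = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise MatrixValueError("distance matrix not square")
        if np.isnan(arr).any():
            raise MatrixValueError("distance matrix contains NaN")
        if (arr < -1e-12).any() or (arr > 2 + 1e-9).any():
            raise MatrixValueError("distance entries outside [0, 2]")
        if np.abs(arr - arr.T).max() > 1e-8:
            raise MatrixValueError("distance matrix not symmetric")
        if np.abs(np.diag(arr)).max() > 1e-12:
            raise MatrixValueError("distance matrix diagonal not zero")
        if self.vocab is None:
            self.vocab = PTVocabulary(tuple(str(c) for c in self.values.columns))

    @property
    def d(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, keep: list[str]) -> "DistanceMatrix":
        df = self.values.loc[keep, keep]
        return DistanceMatrix(df.copy())

    def __len__(self) -> int:
        return len(self.vocab)


@dataclass
class Dendrogram:
    """Agglomerative merge tree.

    ``merges`` is an (n−1) × 4 array in the usual linkage layout: columns are
    left node, right node, merge height, merged size. Nodes 0..n−1 are leaves
    in input label order; node n+t is the cluster formed at step t.
    """

    merges: np.ndarray
    labels: PTVocabulary

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


@dataclass
class RubricAssignment:
    """PT → (low-level category id, broad category id), with manual placements flagged.

    Category ids are ``low-01``… and ``broad-1``…, numbered by order of first
    member in the clustered label order; manual categories created for
    excluded PTs get ids of the form ``manual:<name>``.
    """

    low: dict[str, str]
    broad: dict[str, str]
    manual: frozenset[str] = frozenset()
    k_low: int = 0
    k_broad: int = 0

    def __post_init__(self) -> None:
        if set(self.low) != set(self.broad):
            raise ValueError("low-level and broad assignments cover different PT sets")
        missing = self.manual - set(self.low)
        if missing:
            raise ValueError(f"manually placed PTs missing an assignment: {sorted(missing)}")

    def low_categories(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pt, cat in self.low.items():
            out.setdefault(cat, []).append(pt)
        return out

    def broad_categories(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pt, cat in self.broad.items():
            out.setdefault(cat, []).append(pt)
        return out

    def to_frame(self) -> pd.DataFrame:
        pts = list(self.low)
        return pd.DataFrame(
            {
                "publication_type": pts,
                "low_level_category": [self.low[p] for p in pts],
                "broad_category": [self.broad[p] for p in pts],
                "manual": [p in self.manual for p in pts],
            }
        )


def to_distance(S: SimilarityMatrix) -> DistanceMatrix:
    """Correlation distance d = 1 − ρ, entrywise; diagonal exactly 0."""
    d = 1.0 - S.rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    df = pd.DataFrame(d, index=S.values.index, columns=S.values.columns)
    return DistanceMatrix(df, S.vocab)


def ward_dendrogram(D: DistanceMatrix) -> Dendrogram:
    """Ward merge tree on a precomputed distance matrix via Lance–Williams.

    Deterministic given the input label order; criterion ties are broken
    toward the smallest (left-most) pair of cluster indices.
    """
    n = len(D)
    if n < 2:
        raise ValueError("need at least 2 labels to cluster")
    total = 2 * n - 1
    # squared distances between active clusters; inf marks self/inactive pairs
    M = np.full((total, total), np.inf)
    M[:n, :n] = D.d ** 2
    np.fill_diagonal(M, np.inf)
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    merges = np.zeros((n - 1, 4))
    for t in range(n - 1):
        idx = np.flatnonzero(active)
        sub = M[np.ix_(idx, idx)]
        # row-major argmin over the upper triangle == lexicographically
        # smallest (i, j) among tied minima
        iu = np.triu_indices(len(idx), k=1)
        flat = sub[iu]
        best = int(np.argmin(flat))
        i, j = int(idx[iu[0][best]]), int(idx[iu[1][best]])
        d2 = M[i, j]
        m = n + t
        si, sj = sizes[i], sizes[j]
        sizes[m] = si + sj
        others = idx[(idx != i) & (idx != j)]
        sk = sizes[others]
        M[m, others] = ((si + sk) * M[i, others] + (sj + sk) * M[j, others] - sk * d2) / (
            si + sj + sk
        )
        M[others, m] = M[m, others]
        active[i] = active[j] = False
        active[m] = True
        merges[t] = (i, j, float(np.sqrt(d2)), si + sj)
    return Dendrogram(merges, D.vocab)


def cut(dendro: Dendrogram, k: int) -> np.ndarray:
    """Flat cluster labels obtained by undoing the last k−1 merges.

    Returns an integer label per leaf (input label order); cluster ids
    0..k−1 are numbered by order of each cluster's first leaf.
    """
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for t in range(n - k):
        i, j = int(dendro.merges[t, 0]), int(dendro.merges[t, 1])
        m = n + t
        parent[find(i)] = m
        parent[find(j)] = m
    roots = [find(leaf) for leaf in range(n)]
    relabel: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for leaf, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = len(relabel)
        out[leaf] = relabel[r]
    assert len(relabel) == k
    return out


def cluster_labels(S: SimilarityMatrix, k: int) -> np.ndarray:
    """Convenience: Ward-cluster a similarity matrix and cut at ``k``."""
    return cut(ward_dendrogram(to_distance(S)), k)


def build_rubric(
    D: DistanceMatrix,
    k_low: int = 13,
    k_broad: int = 5,
    manual: dict[str, str] | None = None,
    exclude: tuple[str, ...] = (),
) -> RubricAssignment:
    """Two-level rubric from one dendrogram, with manual placements merged in.

    PTs listed in ``exclude`` are dropped before clustering and must appear in
    ``manual``. A manual placement value is either an existing category id
    (``low-03``), ``with:<PT name>`` (join the low-level and broad category of
    that clustered PT), or ``new:<name>`` (create a fresh manual category,
    which also becomes its own broad category). Anything else is an unknown
    category and an error.
    """
    manual = dict(manual or {})
    if k_broad > k_low:
        raise ValueError("k_broad must not exceed k_low (broad cut is coarser)")
    keep = [t for t in D.vocab.terms if t not in exclude]
    missing_manual = [t for t in exclude if t not in manual]
    if missing_manual:
        raise ValueError(f"excluded PTs need a manual placement: {missing_manual}")
    unknown_manual = [t for t in manual if t in keep]
    if unknown_manual:
        raise ValueError(
            f"manual placements must name PTs excluded from clustering: {unknown_manual}"
        )
    sub = D.subset(keep) if exclude else D
    dendro = ward_dendrogram(sub)
    low_lab = cut(dendro, k_low)
    broad_lab = cut(dendro, k_broad)
    low = {t: f"low-{low_lab[i] + 1:02d}" for i, t in enumerate(sub.vocab.terms)}
    broad = {t: f"broad-{broad_lab[i] + 1}" for i, t in enumerate(sub.vocab.terms)}
    for pt, spec_ in manual.items():
        if spec_.startswith("with:"):
            anchor = spec_[5:]
            if anchor not in low:
                raise ValueError(f"manual placement for {pt!r}: unknown anchor PT {anchor!r}")
            low[pt], broad[pt] = low[anchor], broad[anchor]
        elif spec_.startswith("new:"):
            low[pt] = f"manual:{spec_[4:]}"
            broad[pt] = f"manual:{spec_[4:]}"
        elif spec_ in set(low.values()):
            low[pt] = spec_
            anchor = next(t for t, c in low.items() if c == spec_ and t != pt)
            broad[pt] = broad[anchor]
        else:
            raise ValueError(f"manual placement for {pt!r} names unknown category {spec_!r}")
    return RubricAssignment(
        low=low, broad=broad, manual=frozenset(manual), k_low=k_low, k_broad=k_broad
    )


def nearest_neighbour(S: SimilarityMatrix, pt: str) -> str:
    """The other PT with maximal ρ against ``pt``; ties broken lexicographically."""
    if pt not in S.vocab:
        raise KeyError(f"unknown PT {pt!r}")
    if len(S) < 2:
        raise ValueError("need at least 2 PTs")
    row = S.values.loc[pt].drop(pt)
    best = row.max()
    return min(str(name) for name, v in row.items() if v == best)


def all_nearest_neighbours(S: SimilarityMatrix) -> dict[str, str]:
    """Nearest neighbour of every PT (same tie rule as :func:`nearest_neighbour`)."""
    rho = S.rho.copy()
    np.fill_diagonal(rho, -np.inf)
    names = np.asarray(S.vocab.terms)
    lexrank = np.argsort(np.argsort(names))
    out: dict[str, str] = {}
    for i, pt in enumerate(names):
        row = rho[i]
        mask = row == row.max()
        j = int(np.flatnonzero(mask)[np.argmin(lexrank[mask])])
        out[str(pt)] = str(names[j])
    return out


def _quote(name: str) -> str:
    if any(c in name for c in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(dendro: Dendrogram) -> str:
    """Newick rendering of the merge tree, branch lengths from merge heights.

    Heights may invert on non-Euclidean input; negative branch lengths are
    clipped to zero for viewer compatibility.
    """
    n = dendro.n_leaves
    heights = {i: 0.0 for i in range(n)}
    node_str: dict[int, str] = {i: _quote(dendro.labels.terms[i]) for i in range(n)}
    for t in range(n - 1):
        i, j, h, _ = dendro.merges[t]
        i, j, m = int(i), int(j), n + t
        heights[m] = float(h)
        bi = max(heights[m] - heights[i], 0.0)
        bj = max(heights[m] - heights[j], 0.0)
        node_str[m] = f"({node_str[i]}:{bi:.6g},{node_str[j]}:{bj:.6g})"
    return node_str[2 * n - 2] + ";"
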