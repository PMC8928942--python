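"""Unsupervised 2-D classification and class averaging of aligned particles.

The stages: pairwise joint alignment builds a Pearson similarity matrix S;
S is converted to a k-nearest-neighbor / shared-nearest-neighbor (SNN) graph
with an adaptively chosen k; the thresholded binary adjacency feeds the
normalized spectral clustering algorithm; each class is re-aligned onto its
medoid and averaged with similarity weights, which cancels independent
background noise while reinforcing the common view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .align import Aligner
from .imageops import as_square

__all__ = [
    "ClusterAssignment",
    "ClassAverage",
    "PipelineResult",
    "similarity",
    "build_similarity_matrix",
    "adaptive_k",
    "snn_counts",
    "binarize_adjacency",
    "spectral_partition",
    "class_average",
    "run_pipeline",
]


def similarity(Mi, Mj) -> float:
    """2-D Pearson correlation coefficient between two images, in [-1, 1]."""
    a = as_square(Mi)
    b = as_square(Mj)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    na = float(np.sqrt(np.sum(da * da)))
    nb = float(np.sqrt(np.sum(db * db)))
    if na == 0.0 or nb == 0.0:
        raise ValueError("correlation is undefined for a constant image")
    return float(np.clip(np.sum(da * db) / (na * nb), -1.0, 1.0))


def build_similarity_matrix(stack, interpolate: bool = True,
                            max_iter: int = 10) -> np.ndarray:
    """Post-alignment similarity matrix over all image pairs.

    For each pair (i, j), i < j, image j is jointly aligned onto image i and
    the Pearson correlation of the aligned pair is recorded symmetrically.
    """
    images = [as_square(im) for im in stack]
    n = len(images)
    if n == 0:
        raise ValueError("empty stack")
    if len({im.shape for im in images}) > 1:
        raise ValueError("stack images have mixed dimensions")
    s = np.eye(n)
    for i in range(n - 1):
        aligner = Aligner(images[i], interpolate=interpolate)
        for j in range(i + 1, n):
            _, aligned = aligner.align(images[j], max_iter=max_iter)
            s[i, j] = s[j, i] = similarity(images[i], aligned)
    return s


def adaptive_k(n: int, ns: int = 5) -> int:
    """Neighborhood size for the kNN graph: ``floor(sqrt(N)) + NS``, capped at N-1."""
    if n < 2:
        raise ValueError("need at least two images")
    return min(int(np.floor(np.sqrt(n))) + int(ns), n - 1)


def _knn_membership(s: np.ndarray, k: int) -> np.ndarray:
    """Boolean (N, N) matrix: row i marks the k most similar images to i.

    Self-similarity is excluded; ties broken toward the lower index.
    """
    n = s.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    work = s.astype(float).copy()
    np.fill_diagonal(work, -np.inf)
    member = np.zeros((n, n), dtype=bool)
    for i in range(n):
        # stable sort on descending similarity keeps lower indices first on ties
        order = np.argsort(-work[i], kind="stable")[:k]
        member[i, order] = True
    return member


def snn_counts(s: np.ndarray, k: int) -> np.ndarray:
    """Shared-nearest-neighbor counts ``|KNN(i) & KNN(j)|`` (symmetric ints)."""
    member = _knn_membership(np.asarray(s, dtype=float), k)
    counts = member.astype(int) @ member.astype(int).T
    np.fill_diagonal(counts, k)
    return counts


def binarize_adjacency(counts: np.ndarray, ns: int = 5) -> np.ndarray:
    """Binary graph: edge where strictly more than ``ns`` shared neighbors."""
    counts = np.asarray(counts)
    am = (counts > ns).astype(int)
    np.fill_diagonal(am, 0)
    return am


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of the stack into classes (labels are 0-based)."""

    labels: np.ndarray
    n_classes: int
    medoids: np.ndarray | None = None  # per-class image index, -1 for empty

    def members(self, cls: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cls)


def _medoids(labels: np.ndarray, n_classes: int, s: np.ndarray) -> np.ndarray:
    """Per-class member maximizing total within-class similarity."""
    med = np.full(n_classes, -1, dtype=int)
    for c in range(n_classes):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        sub = s[np.ix_(idx, idx)]
        med[c] = int(idx[np.argmax(sub.sum(axis=1))])
    return med


def spectral_partition(am: np.ndarray, n_classes: int, seed: int = 0,
                       similarity_matrix: np.ndarray | None = None,
                       ) -> ClusterAssignment:
    """Normalized spectral clustering of the binary adjacency graph.

    The symmetric-normalized affinity ``D^-1/2 A D^-1/2`` of the non-isolated
    subgraph is eigen-decomposed, the eigenvectors of the ``n_classes``
    largest eigenvalues are row-normalized and clustered with seeded k-means.
    Isolated vertices (zero degree, for which the normalized Laplacian is
    undefined) are attached afterward to the class of their most similar
    non-isolated image, which requires ``similarity_matrix``.
    """
    am = np.asarray(am)
    n = am.shape[0]
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if am.shape != (n, n) or not np.array_equal(am, am.T):
        raise ValueError("adjacency must be a symmetric square matrix")

    deg = am.sum(axis=1)
    active = np.flatnonzero(deg > 0)
    isolated = np.flatnonzero(deg == 0)
    if n_classes > active.size:
        raise ValueError(
            f"n_classes={n_classes} exceeds the {active.size} connected images"
        )
    if isolated.size and similarity_matrix is None:
        raise ValueError(
            "isolated vertices present: a similarity matrix is needed to attach them"
        )

    a = am[np.ix_(active, active)].astype(float)
    d_inv_sqrt = 1.0 / np.sqrt(a.sum(axis=1))
    affinity = a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    nsub = active.size
    _, vecs = eigh(affinity, subset_by_index=[nsub - n_classes, nsub - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    embedding = vecs / norms
    km = KMeans(n_clusters=n_classes, n_init=10, random_state=seed)
    sub_labels = km.fit_predict(embedding)

    labels = np.full(n, -1, dtype=int)
    labels[active] = sub_labels
    for i in isolated:
        row = np.asarray(similarity_matrix)[i].copy()
        row[isolated] = -np.inf  # only attach to clustered vertices
        row[i] = -np.inf
        labels[i] = labels[int(np.argmax(row))]

    medoids = None
    if similarity_matrix is not None:
        medoids = _medoids(labels, n_classes, np.asarray(similarity_matrix))
    return ClusterAssignment(labels=labels, n_classes=n_classes, medoids=medoids)


@dataclass(frozen=True)
class ClassAverage:
    """Similarity-weighted mean of one class, anchored at its medoid."""

    image: np.ndarray
    n_members: int
    member_weights: np.ndarray  # effective convex weights, sum to 1


def class_average(members, medoid_index: int, s_row,
                  eq9_literal: bool = False) -> ClassAverage:
    """Weighted average of an aligned class.

    ``members`` must already be aligned onto the medoid; ``s_row`` holds the
    post-alignment similarity of each member to the medoid (the medoid's own
    entry is ignored). The medoid enters with weight 1 and every other member
    with weight ``S(i, medoid)``; by default the sum is normalized by
    ``1 + sum(S)`` so the weights are convex (``eq9_literal=True`` keeps the
    printed ``sum(S)`` denominator instead).
    """
    images = [as_square(im) for im in members]
    nj = len(images)
    if nj == 0:
        raise ValueError("empty class")
    if not 0 <= medoid_index < nj:
        raise ValueError("medoid index out of range")
    s_row = np.asarray(s_row, dtype=float)
    if s_row.shape != (nj,):
        raise ValueError("similarity row length must match the class size")

    weights = s_row.copy()
    weights[medoid_index] = 1.0
    others = np.sum(np.delete(s_row, medoid_index))
    denom = others if eq9_literal else 1.0 + others
    if denom <= 0:
        raise ValueError("non-positive weight normalization")
    avg = sum(w * im for w, im in zip(weights, images)) / denom
    return ClassAverage(image=avg, n_members=nj, member_weights=weights / denom)


@dataclass
class PipelineResult:
    """All artifacts of one classification run."""

    assignment: ClusterAssignment
    averages: list
    similarity_matrix: np.ndarray
    k: int
    params: pd.DataFrame = field(default_factory=pd.DataFrame)
    aligned_members: dict = field(default_factory=dict)  # class -> (N_j, m, m)


def run_pipeline(stack, n_classes: int, ns: int = 5, seed: int = 0,
                 interpolate: bool = True, k_override: int | None = None,
                 eq9_literal: bool = False, max_iter: int = 10,
                 ) -> PipelineResult:
    """Full classification chain: similarity -> SNN graph -> spectral -> averages.

    Also records, per image, its alignment parameters onto its class medoid
    and the post-alignment similarity used as its averaging weight.
    """
    images = [as_square(im) for im in stack]
    n = len(images)
    s = build_similarity_matrix(images, interpolate=interpolate, max_iter=max_iter)
    k = adaptive_k(n, ns) if k_override is None else int(k_override)
    counts = snn_counts(s, k)
    am = binarize_adjacency(counts, ns)
    assignment = spectral_partition(am, n_classes, seed=seed, similarity_matrix=s)

    averages = []
    aligned_members = {}
    rows = [None] * n
    for c in range(n_classes):
        idx = assignment.members(c)
        if idx.size == 0:
            averages.append(None)
            continue
        medoid = int(assignment.medoids[c])
        aligner = Aligner(images[medoid], interpolate=interpolate)
        aligned = []
        s_row = np.zeros(idx.size)
        for pos, i in enumerate(idx):
            if i == medoid:
                aligned.append(images[i])
                s_row[pos] = 1.0
                rows[i] = {"index": i, "label": c, "theta": 0.0, "dx": 0.0,
                           "dy": 0.0, "n_iter": 0, "similarity": 1.0}
                continue
            params, ima = aligner.align(images[i], max_iter=max_iter)
            aligned.append(ima)
            s_row[pos] = similarity(images[medoid], ima)
            rows[i] = {"index": i, "label": c, "theta": params.theta,
                       "dx": params.dx, "dy": params.dy,
                       "n_iter": params.n_iter, "similarity": s_row[pos]}
        medoid_pos = int(np.flatnonzero(idx == medoid)[0])
        averages.append(class_average(aligned, medoid_pos, s_row,
                                      eq9_literal=eq9_literal))
        aligned_members[c] = np.array(aligned)

    return PipelineResult(
        assignment=assignment,
        averages=averages,
        similarity_matrix=s,
        k=k,
        params=pd.DataFrame([r for r in rows if r is not None]),
        aligned_members=aligned_members,
    )
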