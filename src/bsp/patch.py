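"""Radius-neighborhood ("patch") construction and local-mean statistics.

A patch around spot *i* at radius D is the set of spots at Euclidean distance
strictly less than D. The local mean of a gene over each patch smooths the
expression surface at granularity D; the per-gene variance of those local
means is the building block of the big-small-patch score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = ["PatchIndex", "build_patch_index", "local_means", "local_mean_variance"]


@dataclass
class PatchIndex:
    """Neighbor sets within a fixed radius, as a binary sparse adjacency.

    ``adjacency[i, l] == 1`` iff ``l`` is in spot *i*'s patch. With
    ``include_center=False`` (the strict definition) the diagonal is zero and
    the structure is symmetric; with ``include_center=True`` each spot also
    belongs to its own patch, so no patch is ever empty.
    """

    radius: float
    adjacency: sparse.csr_matrix
    include_center: bool = False

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]

    @property
    def patch_sizes(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def neighbor_sets(self) -> list[np.ndarray]:
        """Per-spot sorted arrays of member indices (center included per flag)."""
        a = self.adjacency
        return [a.indices[a.indptr[i]: a.indptr[i + 1]] for i in range(self.n_spots)]


def build_patch_index(coords: np.ndarray, radius: float, include_center: bool = False) -> PatchIndex:
    """Exact strict-inequality radius neighborhoods via a KD-tree.

    Results are identical to an all-pairs O(M^2) scan: the KD-tree query uses a
    closed ball, and pairs at distance exactly ``radius`` are removed to honor
    the strict ``dist < D`` definition.
    """
    coords = np.asarray(coords, dtype=float)
    if radius <= 0:
        raise ValueError("radius must be positive")
    m = coords.shape[0]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < radius]
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else np.empty(0, dtype=np.int64)
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else np.empty(0, dtype=np.int64)
    if include_center:
        eye = np.arange(m)
        rows = np.concatenate([rows, eye])
        cols = np.concatenate([cols, eye])
    data = np.ones(len(rows), dtype=float)
    adj = sparse.csr_matrix((data, (rows, cols)), shape=(m, m))
    adj.sort_indices()
    return PatchIndex(radius=float(radius), adjacency=adj, include_center=include_center)


def local_means(expr: np.ndarray, index: PatchIndex) -> np.ndarray:
    """Per-spot, per-gene average expression over the patch.

    For a spot whose patch is empty (isolated spot under the strict
    definition) the local mean falls back to the spot's own expression — the
    limit of a patch shrinking onto its center.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape[0] != index.n_spots:
        raise ValueError("expression rows do not match the patch index")
    sizes = index.patch_sizes
    sums = index.adjacency @ expr
    out = np.empty_like(sums)
    nonempty = sizes > 0
    out[nonempty] = sums[nonempty] / sizes[nonempty, None]
    out[~nonempty] = expr[~nonempty]
    return out


def local_mean_variance(lm: np.ndarray) -> np.ndarray:
    """Population variance of the local means, per gene (length-N vector).

    Uses the shifted-data form (each gene shifted by its first local mean
    before the moment computation); variance is shift-invariant, and the
    shift makes the degenerate case — identical local means, e.g. a patch
    radius covering the whole sample — come out exactly zero instead of
    accumulating rounding noise.
    """
    lm = np.asarray(lm, dtype=float)
    return np.var(lm - lm[0], axis=0)
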