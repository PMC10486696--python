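"""Trajectory embedding of a single-channel series and its exact inverse.

A length-``l`` series is cut into ``L = floor(l / i)`` consecutive
non-overlapping windows of ``i`` samples, giving the embedding matrix
``M`` (``L x i``).  Stacking ``w`` consecutive rows of ``M`` per slab
yields an order-3 trajectory tensor ``T`` of shape
``(L - w + 1, w, i)`` that is Hankel in its first two modes:
``T[k, a, b] = M[k + a, b]``.  The inverse map averages every tensor
entry over the pre-image of its original sample index
``t = (k + a) * i + b`` (diagonal averaging), so
``tensor_to_series(matrix_to_tensor(embed_series(s)))`` returns ``s``
truncated to ``L * i`` samples exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmbeddingMatrix",
    "TrajectoryTensor",
    "GroupingScheme",
    "embed_series",
    "matrix_to_tensor",
    "tensor_to_series",
    "reconstruct_groups",
    "overlap_counts",
]


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Non-overlapping windowed view of a series.

    Attributes
    ----------
    M : ndarray, shape (L, window)
        Row ``r`` holds samples ``s[r*window : (r+1)*window]``.
    window : int
        Window length ``i`` in samples.
    source_length : int
        Length ``l`` of the series the matrix was built from; the
        trailing ``l mod i`` samples are not represented in ``M``.
    """

    M: np.ndarray
    window: int
    source_length: int

    @property
    def L(self) -> int:
        return self.M.shape[0]


@dataclass(frozen=True)
class TrajectoryTensor:
    """Order-3 Hankel trajectory tensor built from an embedding matrix."""

    T: np.ndarray  # (L - w + 1, w, i)
    depth: int
    window: int
    source_length: int

    @property
    def L(self) -> int:
        return self.T.shape[0] + self.depth - 1


@dataclass(frozen=True)
class GroupingScheme:
    """Assignment of decomposition components to reconstruction groups.

    ``assignment[j]`` is the group (``0 .. n_groups-1``) of flat
    component index ``j``; every component belongs to exactly one group.
    """

    n_groups: int
    assignment: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=int)
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if a.size and (a.min() < 0 or a.max() >= self.n_groups):
            raise ValueError("group labels must lie in [0, n_groups)")
        object.__setattr__(self, "assignment", a)

    def members(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == group)


def embed_series(s: np.ndarray, window: int) -> EmbeddingMatrix:
    """Segment ``s`` into non-overlapping windows of ``window`` samples.

    The trailing ``len(s) mod window`` samples are dropped (and
    zero-padded back by :func:`tensor_to_series`).
    """
    s = np.asarray(s, dtype=float).ravel()
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    L = len(s) // window
    if L < 2:
        raise ValueError(
            f"series of length {len(s)} gives only {L} window(s) of size "
            f"{window}; need at least 2"
        )
    M = s[: L * window].reshape(L, window).copy()
    return EmbeddingMatrix(M=M, window=window, source_length=len(s))


def matrix_to_tensor(em: EmbeddingMatrix, depth: int | None = None) -> TrajectoryTensor:
    """Stack ``depth`` consecutive rows of ``M`` per slab.

    ``T[k, a, :] = M[k + a, :]`` for ``k = 0 .. L-depth``; default
    ``depth = floor(L / 2)`` balances the first two mode sizes.
    ``depth = L`` is the degenerate single-slab case.
    """
    L = em.L
    if depth is None:
        depth = max(2, L // 2)
    if not 1 <= depth <= L:
        raise ValueError(f"depth must be in [1, {L}], got {depth}")
    K = L - depth + 1
    # sliding_window_view over rows, then reorder to (slab, lag, within-window)
    T = np.lib.stride_tricks.sliding_window_view(em.M, (depth, em.window))[:, 0]
    assert T.shape == (K, depth, em.window)
    return TrajectoryTensor(
        T=T.copy(), depth=depth, window=em.window, source_length=em.source_length
    )


def overlap_counts(n_slabs: int, depth: int) -> np.ndarray:
    """Number of (k, a) pairs with k + a = m, for m = 0 .. L-1.

    This is the multiplicity of each embedding-matrix row inside the
    trajectory tensor (the anti-diagonal lengths of the first two modes).
    """
    L = n_slabs + depth - 1
    m = np.arange(L)
    return np.minimum.reduce([m + 1, np.full(L, min(n_slabs, depth)), L - m])


def tensor_to_series(
    arr: np.ndarray | TrajectoryTensor,
    window: int | None = None,
    source_length: int | None = None,
) -> np.ndarray:
    """Invert the double Hankel structure by diagonal averaging.

    Every entry ``(k, a, b)`` maps to sample ``t = (k + a) * window + b``;
    all entries sharing ``t`` are averaged.  Output has length
    ``L * window``, zero-padded to ``source_length`` if given.
    """
    if isinstance(arr, TrajectoryTensor):
        window = arr.window
        source_length = arr.source_length if source_length is None else source_length
        arr = arr.T
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected an order-3 tensor, got ndim={arr.ndim}")
    K, w, i = arr.shape
    if window is not None and window != i:
        raise ValueError(f"tensor last mode {i} inconsistent with window {window}")
    L = K + w - 1
    # sum anti-diagonals of the first two modes -> (L, i) row-averaged matrix
    rows = np.zeros((L, i))
    idx = (np.arange(K)[:, None] + np.arange(w)[None, :]).ravel()
    np.add.at(rows, idx, arr.reshape(K * w, i))
    rows /= overlap_counts(K, w)[:, None]
    out = rows.ravel()
    if source_length is not None:
        if source_length < out.size:
            raise ValueError("source_length shorter than reconstructed series")
        out = np.pad(out, (0, source_length - out.size))
    return out


def rank1_series(
    u: np.ndarray, v: np.ndarray, wv: np.ndarray, source_length: int | None = None
) -> np.ndarray:
    """Diagonal-averaged series of the rank-1 tensor ``u ∘ v ∘ wv``.

    Because ``t = (k + a) * i + b`` splits as ``m = t // i = k + a`` and
    ``b = t mod i``, the average over the pre-image factorises into a
    1-D convolution over the first two modes times the third-mode
    vector: ``series[m*i + b] = (conv(u, v)[m] / c[m]) * wv[b]`` where
    ``c`` are the overlap counts.  Identical to running
    :func:`tensor_to_series` on the explicit outer product.
    """
    c = overlap_counts(len(u), len(v))
    rows = (np.convolve(u, v) / c)[:, None] * wv[None, :]
    out = rows.ravel()
    if source_length is not None:
        out = np.pad(out, (0, source_length - out.size))
    return out


def reconstruct_groups(
    components: list[np.ndarray],
    grouping: GroupingScheme,
    window: int,
    source_length: int | None = None,
) -> list[np.ndarray]:
    """Sum member component tensors per group, then diagonal-average.

    ``components[j]`` are order-3 tensors from one decomposition of one
    series (all the same shape).  Returns one subseries per group.
    """
    if len(components) != len(grouping.assignment):
        raise ValueError("grouping assignment length != number of components")
    out = []
    for z in range(grouping.n_groups):
        members = grouping.members(z)
        if members.size == 0:
            raise ValueError(f"group {z} is empty")
        total = sum(components[j] for j in members)
        out.append(tensor_to_series(total, window, source_length))
    return out
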