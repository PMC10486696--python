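"""Higher-order (multilinear) SVD and its rank-truncated variant.

The factor matrix of mode ``m`` collects the left singular vectors of
the mode-``m`` unfolding; the core tensor is the input contracted with
every factor transposed.  Truncation keeps the leading ``ranks[m]``
singular vectors per mode, with the classical quasi-optimality bound
``err^2 <= sum_m sum_{k > ranks[m]} sigma(m)_k^2``.

Unfolding convention: mode ``m`` is moved to the front and the
remaining modes are flattened in their original order (row-major), so
``unfold(T, m) = moveaxis(T, m, 0).reshape(shape[m], -1)``.  ``fold``
inverts it; all pairs in this module share the convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HOSVDResult",
    "unfold",
    "fold",
    "multi_mode_dot",
    "hosvd",
    "truncated_hosvd",
    "ranks_by_energy",
    "truncation_error_bound",
]


def unfold(T: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding: fibers of that mode become columns."""
    T = np.asarray(T)
    if not 0 <= mode < T.ndim:
        raise ValueError(f"mode {mode} invalid for order-{T.ndim} tensor")
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


def fold(mat: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given full shape."""
    if not 0 <= mode < len(shape):
        raise ValueError(f"mode {mode} invalid for order-{len(shape)} shape")
    moved = [shape[mode]] + [s for j, s in enumerate(shape) if j != mode]
    return np.moveaxis(np.asarray(mat).reshape(moved), 0, mode)


def mode_dot(T: np.ndarray, mat: np.ndarray, mode: int) -> np.ndarray:
    """Contract ``mat`` (new_dim x shape[mode]) along ``mode`` of ``T``."""
    res = mat @ unfold(T, mode)
    shape = list(T.shape)
    shape[mode] = mat.shape[0]
    return fold(res, mode, tuple(shape))


def multi_mode_dot(
    T: np.ndarray, mats: list[np.ndarray], transpose: bool = False
) -> np.ndarray:
    out = T
    for m, mat in enumerate(mats):
        out = mode_dot(out, mat.T if transpose else mat, m)
    return out


@dataclass(frozen=True)
class HOSVDResult:
    """Core tensor, per-mode factors and singular spectra.

    ``factors[m]`` has orthonormal columns (the kept left singular
    vectors of the mode-``m`` unfolding); ``mode_singular_values[m]``
    is the *full* singular spectrum of that unfolding, so truncation
    error bounds can be formed from the discarded tail.
    """

    core: np.ndarray
    factors: list[np.ndarray]
    mode_singular_values: list[np.ndarray]
    kept_ranks: tuple[int, ...]

    def reconstruct(self) -> np.ndarray:
        """Multilinear product of the core with every factor."""
        return multi_mode_dot(self.core, self.factors)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(f.shape[0] for f in self.factors)


def hosvd(T: np.ndarray) -> HOSVDResult:
    """Full multilinear SVD of ``T``.

    Reconstruction is exact (to round-off) and the core inherits the
    Frobenius norm of ``T`` by orthogonality of the factors.
    """
    return truncated_hosvd(T, None)


def truncated_hosvd(T: np.ndarray, ranks: tuple[int, ...] | None) -> HOSVDResult:
    """HOSVD keeping the dominant ``ranks[m]`` singular vectors per mode.

    ``ranks=None`` keeps everything (full decomposition).
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("tensor contains non-finite entries")
    order = T.ndim
    max_ranks = tuple(min(T.shape[m], unfold(T, m).shape[1]) for m in range(order))
    if ranks is None:
        ranks = max_ranks
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != order:
        raise ValueError(f"need {order} ranks, got {len(ranks)}")
    for m, r in enumerate(ranks):
        if not 1 <= r <= max_ranks[m]:
            raise ValueError(
                f"rank {r} for mode {m} outside [1, {max_ranks[m]}]"
            )
    factors, spectra = [], []
    for m in range(order):
        U, s, _ = np.linalg.svd(unfold(T, m), full_matrices=False)
        factors.append(U[:, : ranks[m]])
        spectra.append(s)
    core = multi_mode_dot(T, factors, transpose=True)
    return HOSVDResult(
        core=core, factors=factors, mode_singular_values=spectra, kept_ranks=ranks
    )


def ranks_by_energy(
    T: np.ndarray, energy: float = 0.99, max_rank: int | None = None
) -> tuple[int, ...]:
    """Smallest per-mode ranks capturing ``energy`` of each mode spectrum.

    ``max_rank`` caps every mode (keeps downstream per-component work
    bounded on noisy data).
    """
    if not 0 < energy <= 1:
        raise ValueError("energy must be in (0, 1]")
    ranks = []
    for m in range(T.ndim):
        s = np.linalg.svd(unfold(T, m), compute_uv=False)
        cum = np.cumsum(s**2)
        r = int(np.searchsorted(cum, energy * cum[-1]) + 1)
        if max_rank is not None:
            r = min(r, max_rank)
        ranks.append(min(r, len(s)))
    return tuple(ranks)


def truncation_error_bound(result: HOSVDResult) -> float:
    """Quasi-optimality bound sqrt(sum over modes of discarded sigma^2)."""
    tail = 0.0
    for m, s in enumerate(result.mode_singular_values):
        tail += float(np.sum(s[result.kept_ranks[m]:] ** 2))
    return float(np.sqrt(tail))
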