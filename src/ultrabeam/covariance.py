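"""Covariance estimation (subarray + temporal averaging, diagonal loading)
and the forward-backward (Toeplitz/persymmetric) correction.

The forward-backward step returns ``F + K conj(F) K`` with ``K`` the
anti-diagonal exchange matrix, with no 1/2 normalisation: Capon-family
weights are invariant to a positive rescaling of the covariance, so the
missing factor cannot change any beamformer output (asserted by test).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CovarianceEstimate",
    "estimate_covariance",
    "forward_backward_correct",
    "exchange_matrix",
]

_HERM_TOL = 1e-12


@dataclass(frozen=True)
class CovarianceEstimate:
    """Hermitian interference-plus-noise covariance with provenance."""

    matrix: np.ndarray
    subarray_length: int
    temporal_halfwidth: int
    loading_factor: float
    corrected: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        scale = max(float(np.abs(m).max()), 1.0)
        if np.abs(m - m.conj().T).max() > 1e-10 * scale:
            raise ValueError("covariance matrix must be Hermitian")
        object.__setattr__(self, "matrix", m)

    @property
    def size(self) -> int:
        return int(self.matrix.shape[0])


def _as_snapshot_matrix(snapshots) -> np.ndarray:
    """Stack snapshots into (M, n_t); accepts Snapshot objects or vectors."""
    cols = []
    for s in snapshots:
        v = getattr(s, "values", s)
        cols.append(np.asarray(v).ravel())
    if not cols:
        raise ValueError("at least one snapshot is required")
    return np.column_stack(cols)


def estimate_covariance(
    snapshots,
    subarray_length: int,
    temporal_halfwidth: int = 0,
    loading_factor: float = 0.0,
) -> CovarianceEstimate:
    """Spatially-smoothed, temporally-averaged sample covariance.

    ``F`` is the average over subarray offsets ``g = 0 .. M-L`` and over the
    snapshots within ``temporal_halfwidth`` of the middle of the stream, of
    the outer products of length-``L`` snapshot windows; diagonal loading
    ``loading_factor * (trace(F)/L) * I`` is added at the end.

    Parameters
    ----------
    snapshots
        Sequence of aligned snapshot vectors (or :class:`Snapshot`), all of
        length ``M``, ordered in time; or an ``(M, n_t)`` array.
    subarray_length
        ``L`` with ``1 <= L <= M``.
    temporal_halfwidth
        Snapshots with time offset ``|k| <= halfwidth`` from the central one
        enter the average.
    loading_factor
        Relative diagonal loading (0 disables).
    """
    x = (
        np.asarray(snapshots)
        if isinstance(snapshots, np.ndarray)
        else _as_snapshot_matrix(snapshots)
    )
    if x.ndim == 1:
        x = x[:, None]
    m, n_t = x.shape
    L = int(subarray_length)
    if not 1 <= L <= m:
        raise ValueError(f"subarray_length must be in [1, {m}], got {L}")
    if temporal_halfwidth < 0:
        raise ValueError("temporal_halfwidth must be >= 0")
    if loading_factor < 0:
        raise ValueError("loading_factor must be >= 0")

    center = (n_t - 1) // 2
    k0 = max(0, center - temporal_halfwidth)
    k1 = min(n_t, center + temporal_halfwidth + 1)
    xs = x[:, k0:k1]
    if not np.any(np.abs(xs) > 0):
        raise ValueError("all-zero snapshots: covariance would be degenerate")

    n_sub = m - L + 1
    # windows: (n_sub, L, n_used)
    windows = np.lib.stride_tricks.sliding_window_view(xs, L, axis=0)
    windows = np.ascontiguousarray(np.moveaxis(windows, 2, 1))
    flat = windows.transpose(1, 0, 2).reshape(L, -1)  # (L, n_sub * n_used)
    f = flat @ flat.conj().T / flat.shape[1]
    f = 0.5 * (f + f.conj().T)  # kill round-off asymmetry
    if loading_factor > 0:
        f = f + loading_factor * (np.trace(f).real / L) * np.eye(L, dtype=f.dtype)
    return CovarianceEstimate(
        matrix=f,
        subarray_length=L,
        temporal_halfwidth=int(temporal_halfwidth),
        loading_factor=float(loading_factor),
        corrected=False,
    )


def exchange_matrix(n: int) -> np.ndarray:
    """Anti-diagonal exchange matrix ``K`` (ones on the anti-diagonal)."""
    return np.eye(n)[::-1].copy()


def forward_backward_correct(
    f: CovarianceEstimate | np.ndarray,
) -> CovarianceEstimate | np.ndarray:
    """Forward-backward correction ``F + K conj(F) K``.

    The output is Hermitian and persymmetric (``K conj(F') K = F'``).  Passing
    a :class:`CovarianceEstimate` returns one with ``corrected=True``; a bare
    array returns a bare array.
    """
    is_estimate = isinstance(f, CovarianceEstimate)
    mat = f.matrix if is_estimate else np.asarray(f)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("forward_backward_correct requires a square matrix")
    k = exchange_matrix(mat.shape[0])
    out = mat + k @ mat.conj() @ k
    if is_estimate:
        return replace(f, matrix=out, corrected=True)
    return out
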