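"""Per-window linear operator estimation by regularized dynamic mode decomposition.

Each 250 ms window of preprocessed SEEG is modeled as a discrete-time linear
network ``x(t+1) = A x(t) + eps(t)``.  The operator is the Tikhonov-
regularized least squares solution

    A = argmin ||X2 - A X1||_F^2 + reg * ||A||_F^2
      = X2 V diag(sigma / (sigma^2 + reg)) U^T,

where ``X1 = U diag(sigma) V^T`` is the (economy) SVD of the first m-1
snapshots and ``X2`` holds the last m-1.  Rank is capped at
``min(N, m - 1)``; the operator lives in the observed channel basis, so each
row/column maps to a named channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import SeegRecording
from .preprocess import WindowPlan

#: relative singular-value cutoff distinguishing rank deficiency from noise
_RANK_RTOL = 1e-12


@dataclass
class StateMatrixSeries:
    """Estimated window operators with per-window conditioning diagnostics."""

    matrices: np.ndarray  # (n_windows, N, N)
    window_plan: WindowPlan
    reg: float
    rank_used: np.ndarray  # (n_windows,)
    channel_names: list[str]
    residual_norms: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be (n_windows, N, N)")
        if self.matrices.shape[0] != self.window_plan.n_windows:
            raise ValueError("one operator per planned window required")
        if self.matrices.shape[1] != len(self.channel_names):
            raise ValueError("operator size must equal retained channel count")
        if not np.isfinite(self.matrices).all():
            raise ValueError("non-finite operator entries")

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]


def fit_window_operator(Xw: np.ndarray, reg: float = 0.05) -> np.ndarray:
    """Estimate the window operator from one snapshot matrix ``Xw`` (N x m).

    With snapshot pairs ``X1 = Xw[:, :-1]``, ``X2 = Xw[:, 1:]``, returns the
    Tikhonov-regularized DMD operator.  ``reg = 0`` reduces to the plain
    pseudo-inverse and recovers the generating operator exactly on noise-free
    identifiable data.
    """
    Xw = np.asarray(Xw, dtype=float)
    if Xw.ndim != 2:
        raise ValueError("snapshot matrix must be 2-D")
    if Xw.shape[1] < 2:
        raise ValueError("need at least 2 snapshots (m >= 2)")
    if not np.isfinite(Xw).all():
        raise ValueError("non-finite snapshot values")
    if reg < 0:
        raise ValueError("reg must be >= 0")
    X1, X2 = Xw[:, :-1], Xw[:, 1:]
    A, _ = _regularized_lstsq(X1, X2, reg)
    return A


def _regularized_lstsq(X1: np.ndarray, X2: np.ndarray, reg: float) -> tuple[np.ndarray, int]:
    """Solve min ||X2 - A X1||_F^2 + reg ||A||_F^2; returns (A, rank)."""
    U, s, Vt = np.linalg.svd(X1, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros((X2.shape[0], X1.shape[0])), 0
    keep = s > _RANK_RTOL * s[0]
    rank = int(keep.sum())
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    inv_s = s / (s * s + reg)
    A = (X2 @ Vt.T) @ (inv_s[:, None] * U.T)
    return A, rank


def fit_operator_series(rec: SeegRecording, plan: WindowPlan, reg: float = 0.05) -> StateMatrixSeries:
    """One operator per planned window of a preprocessed recording.

    Per-window rank and residual norm are recorded for audit; failures carry
    the window index.
    """
    n_w = plan.n_windows
    N = rec.n_channels
    mats = np.empty((n_w, N, N))
    ranks = np.empty(n_w, dtype=int)
    resid = np.empty(n_w)
    for w, start in enumerate(plan.starts):
        Xw = rec.data[:, start : start + plan.win_len]
        try:
            X1, X2 = Xw[:, :-1], Xw[:, 1:]
            A, rank = _regularized_lstsq(X1, X2, reg)
        except Exception as exc:  # pragma: no cover - defensive context wrap
            raise RuntimeError(f"operator fit failed in window {w} (start={start})") from exc
        mats[w] = A
        ranks[w] = rank
        resid[w] = np.linalg.norm(X2 - A @ X1)
    return StateMatrixSeries(
        matrices=mats,
        window_plan=plan,
        reg=reg,
        rank_used=ranks,
        channel_names=list(rec.channel_names),
        residual_norms=resid,
    )


def spectral_radius(A: np.ndarray) -> float:
    """Largest eigenvalue magnitude of a square matrix."""
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("spectral radius needs a square matrix")
    return float(np.abs(np.linalg.eigvals(A)).max())
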