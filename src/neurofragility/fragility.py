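"""Neural fragility: minimum structured perturbations that destabilize a network operator.

For a stable window operator ``A`` (spectral radius < 1), the fragility of
node ``k`` is the smallest 2-norm single-column (default) or single-row
perturbation ``Delta`` such that ``A + Delta`` has an eigenvalue ``lam`` on
the unit circle — i.e. the least interference at that node that tips the
network into instability.  Small raw fragility therefore means a *fragile*
node; the per-window normalization below inverts the orientation so that
high normalized values mark fragile (seizure-predisposed) channels, matching
the heatmap convention.

Closed form (column mode, ``Delta = gamma e_k^T``): by the matrix
determinant lemma, ``lam`` is an eigenvalue of ``A + gamma e_k^T`` iff
``w^T gamma = -1`` with ``w^T = e_k^T (A - lam I)^{-1}``.  Over real
``gamma`` this is the stacked linear system ``[Im w^T; Re w^T] gamma =
(0, -1)``, whose minimum-norm solution is returned.  Row mode is the
transpose construction with ``w = (A - lam I)^{-1} e_k``.  Conjugate
symmetry makes the half-circle ``omega in [0, pi]`` sufficient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import StateMatrixSeries, spectral_radius
from .preprocess import WindowPlan

logger = logging.getLogger(__name__)

#: relative threshold below which Im(w) is treated as exactly zero
_REAL_TOL = 1e-12


class InfeasiblePerturbationError(ValueError):
    """No structured perturbation at this node can place this eigenvalue."""


@dataclass
class FragilityMap:
    """Channels x windows fragility matrices.

    ``raw`` holds the minimum perturbation norms (>= 0; smaller = more
    fragile).  ``normalized`` is the per-window-column rescaling
    ``(col_max - raw) / col_max`` in [0, 1] (larger = more fragile); it is
    ``None`` until :func:`normalize_map` fills it.
    """

    raw: np.ndarray
    channel_names: list[str]
    window_plan: WindowPlan
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2:
            raise ValueError("raw must be channels x windows")
        if self.raw.shape[0] != len(self.channel_names):
            raise ValueError("one row per channel required")
        finite = self.raw[np.isfinite(self.raw)]
        if (finite < 0).any():
            raise ValueError("raw fragility norms must be non-negative")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.raw.shape:
                raise ValueError("normalized shape must match raw")

    @property
    def n_channels(self) -> int:
        return self.raw.shape[0]

    @property
    def n_windows(self) -> int:
        return self.raw.shape[1]


def default_omega_grid(n_points: int = 51) -> np.ndarray:
    """Uniform grid on [0, pi] including both endpoints."""
    if n_points < 2:
        raise ValueError("need at least the two endpoint frequencies")
    return np.linspace(0.0, np.pi, n_points)


def min_structured_perturbation(
    A: np.ndarray, k: int, lam: complex, mode: str = "column"
) -> tuple[float, np.ndarray]:
    """Minimum 2-norm single-column/row perturbation placing eigenvalue ``lam``.

    Parameters
    ----------
    A
        Stable square operator (``lam`` must not already be an eigenvalue).
    k
        Node (channel) index whose column (or row) is perturbed.
    lam
        Target eigenvalue, on the unit circle for destabilization.
    mode
        ``"column"`` perturbs node ``k``'s outgoing couplings
        (``Delta = gamma e_k^T``); ``"row"`` its incoming ones.

    Returns
    -------
    norm, gamma
        ``norm = ||gamma||_2`` and the real perturbation vector itself.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.ndim != 2 or A.shape[1] != n:
        raise ValueError("A must be square")
    if not 0 <= k < n:
        raise ValueError(f"node index {k} out of range for N={n}")
    if mode not in ("column", "row"):
        raise ValueError("mode must be 'column' or 'row'")
    M = A - complex(lam) * np.eye(n)
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise InfeasiblePerturbationError(
            f"lam={lam} is (numerically) an eigenvalue of A; perturbation norm is 0"
        ) from exc
    w = Minv[k, :] if mode == "column" else Minv[:, k]
    return _min_norm_solution(w)


def _min_norm_solution(w: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum-norm real gamma with Im(w)^T gamma = 0 and Re(w)^T gamma = -1."""
    re, im = w.real, w.imag
    d = float(re @ re)
    a = float(im @ im)
    scale = a + d
    if scale == 0:
        raise InfeasiblePerturbationError("w vanishes; constraint -1 = w^T gamma unsatisfiable")
    if a <= _REAL_TOL * scale:  # effectively real lam / real w
        if d == 0:
            raise InfeasiblePerturbationError("real part of w vanishes")
        gamma = -re / d
        return float(np.linalg.norm(gamma)), gamma
    c = float(im @ re)
    det = a * d - c * c
    if det <= _REAL_TOL * scale * scale:
        raise InfeasiblePerturbationError("Im(w) parallel to Re(w); stacked constraints inconsistent")
    # gamma = C^T (C C^T)^{-1} (0, -1)  with C = [Im w^T; Re w^T]
    gamma = (im * c - re * a) / det
    return float(np.sqrt(a / det)), gamma


def _node_fragility_all(A: np.ndarray, omega_grid: np.ndarray, mode: str = "column") -> np.ndarray:
    """Per-node fragility for every node at once (vectorized over the grid).

    For each grid eigenvalue the resolvent ``(A - lam I)^{-1}`` is formed
    once; its rows (column mode) or columns (row mode) supply every node's
    constraint vector simultaneously.
    """
    n = A.shape[0]
    if spectral_radius(A) >= 1.0:
        return np.zeros(n)
    best = np.full(n, np.inf)
    eye = np.eye(n)
    for om in np.asarray(omega_grid, dtype=float):
        lam = np.exp(1j * om)
        try:
            Minv = np.linalg.inv(A - lam * eye)
        except np.linalg.LinAlgError:  # grid point is an eigenvalue: skip
            continue
        W = Minv if mode == "column" else Minv.T  # rows are the w vectors
        re, im = W.real, W.imag
        d = np.einsum("ij,ij->i", re, re)
        a = np.einsum("ij,ij->i", im, im)
        c = np.einsum("ij,ij->i", im, re)
        scale = a + d
        norms = np.full(n, np.inf)
        real_case = a <= _REAL_TOL * scale
        ok = real_case & (d > 0)
        norms[ok] = 1.0 / np.sqrt(d[ok])
        det = a * d - c * c
        ok = ~real_case & (det > _REAL_TOL * scale * scale)
        norms[ok] = np.sqrt(a[ok] / det[ok])
        best = np.minimum(best, norms)
    return best


def node_fragility(A: np.ndarray, k: int, omega_grid: np.ndarray, mode: str = "column") -> float:
    """Fragility of node ``k``: min over unit-circle grid of the perturbation norm.

    An already-unstable operator (spectral radius >= 1) has fragility 0 for
    every node: the zero perturbation suffices.
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    if omega_grid.size == 0:
        raise ValueError("empty frequency grid")
    A = np.asarray(A, dtype=float)
    if spectral_radius(A) >= 1.0:
        return 0.0
    best = np.inf
    for om in omega_grid:
        try:
            norm, _ = min_structured_perturbation(A, k, np.exp(1j * om), mode)
        except InfeasiblePerturbationError:
            continue
        best = min(best, norm)
    if not np.isfinite(best):
        raise InfeasiblePerturbationError(f"no feasible destabilizing perturbation found for node {k}")
    return float(best)


def compute_fragility_map(
    series: StateMatrixSeries,
    mode: str = "column",
    omega_grid: np.ndarray | None = None,
) -> FragilityMap:
    """Raw fragility for every (channel, window) of an operator series."""
    if omega_grid is None:
        omega_grid = default_omega_grid()
    omega_grid = np.asarray(omega_grid, dtype=float)
    if omega_grid.size == 0:
        raise ValueError("empty frequency grid")
    raw = np.empty((series.n_channels, series.n_windows))
    for w in range(series.n_windows):
        try:
            raw[:, w] = _node_fragility_all(series.matrices[w], omega_grid, mode)
        except Exception as exc:  # pragma: no cover - context wrap
            raise RuntimeError(f"fragility computation failed in window {w}") from exc
    return FragilityMap(raw=raw, channel_names=list(series.channel_names), window_plan=series.window_plan)


def normalize_map(fmap: FragilityMap) -> FragilityMap:
    """Fill the per-window normalization ``(col_max - raw) / col_max``.

    The most fragile channel of a window (minimal raw norm) attains the
    column's maximum normalized value; the least fragile gets 0.  An all-zero
    column (window already unstable for every node) normalizes to 0 with a
    warning.
    """
    raw = fmap.raw
    col_max = raw.max(axis=0)
    zero_cols = col_max <= 0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} window(s) have an all-zero fragility column; normalized set to 0",
            stacklevel=2,
        )
    safe = np.where(zero_cols, 1.0, col_max)
    normalized = np.where(zero_cols[None, :], 0.0, (col_max[None, :] - raw) / safe[None, :])
    return FragilityMap(
        raw=raw.copy(),
        channel_names=list(fmap.channel_names),
        window_plan=fmap.window_plan,
        normalized=normalized,
    )


def plot_fragility_heatmap(fmap: FragilityMap, path, use_normalized: bool = True) -> None:
    """Render the heatmap (channels on y, time on x) to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    values = fmap.normalized if (use_normalized and fmap.normalized is not None) else fmap.raw
    times = fmap.window_plan.times
    fig, ax = plt.subplots(figsize=(8, 0.3 * fmap.n_channels + 2))
    im = ax.imshow(
        values,
        aspect="auto",
        origin="upper",
        cmap="inferno",
        extent=(times[0], times[-1], fmap.n_channels - 0.5, -0.5),
        vmin=0.0,
        vmax=1.0 if use_normalized else None,
    )
    ax.set_yticks(range(fmap.n_channels))
    ax.set_yticklabels(fmap.channel_names, fontsize=6)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("channel")
    fig.colorbar(im, ax=ax, label="normalized fragility" if use_normalized else "raw fragility")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
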