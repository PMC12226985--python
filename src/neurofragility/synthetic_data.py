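"""Verified synthetic SEEG: stochastic linear network recordings and cohorts.

Real interictal SEEG is clinical data and is not redistributable; this
module generates ground-truth-labeled stand-ins with the statistical
structure the analysis assumes: an N-channel discrete-time linear network
``x(t+1) = A_true x(t) + eps(t)`` sampled at clinical rates (2 kHz default)
whose designated *fragile* node subset sits near instability, plus cohort
tables whose SOZ-fragility effect differs by outcome group.

Fragility is planted by adding near-critical rank-one column structure on
the fragile set and then *verified* with the fragility module's own math —
every emitted network carries a verification report, and construction
redraws (new sub-seed) until the planted nodes are strictly the most
fragile.  Closed-form planting of exact fragility values is intractable;
verified construction is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import spectral_radius
from .fragility import _node_fragility_all, default_omega_grid
from .io_formats import ChannelAnnotation, CohortTable, SeegRecording


@dataclass
class CohortConfig:
    """Cohort-level block: outcome mix and label-placement behavior.

    Success-profile patients have ``fragile_set ⊆ SOZE ⊆ SOZC`` and
    Engel 1; failure-profile patients have ``mislocalization_fraction`` of
    their fragile nodes placed *outside* SOZC (emulating a missed target)
    and Engel drawn from {2, 3, 4}.  Treatment-flag probabilities default to
    the 30-patient study mix (27 RFTC, 5 LITT, 11 resections, 2 RNS).
    """

    n_patients: int = 30
    success_fraction: float = 22 / 30
    n_sozc_extra: int = 1
    mislocalization_fraction: float = 0.5
    p_rftc: float = 27 / 30
    p_litt: float = 5 / 30
    p_surgery: float = 11 / 30
    p_rns: float = 2 / 30
    p_mri_lesional: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.success_fraction <= 1.0:
            raise ValueError("success_fraction must lie in [0, 1]")
        if not 0.0 <= self.mislocalization_fraction <= 1.0:
            raise ValueError("mislocalization_fraction must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Generator settings for one synthetic patient (plus optional cohort block).

    ``fs`` defaults to 2 kHz and ``duration_s`` to 600 s, emulating the
    clinical acquisition (2-4 kHz sampling, ~10 min interictal snapshots);
    the pipeline later downsamples to 500 Hz.  ``target_radius`` is the
    spectral radius of the generating operator (near-critical), and
    ``base_radius`` that of the stable random base network.
    """

    n_channels: int = 8
    fs: float = 2000.0
    duration_s: float = 600.0
    fragile_set: tuple[int, ...] = (0, 1)
    target_radius: float = 0.95
    base_radius: float = 0.7
    noise_sd: float = 1.0
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if not set(self.fragile_set) <= set(range(self.n_channels)):
            raise ValueError("fragile_set must be a subset of channel indices")
        if len(self.fragile_set) == 0:
            raise ValueError("fragile_set must be non-empty")
        if not 0 < self.base_radius < self.target_radius < 1:
            raise ValueError("need 0 < base_radius < target_radius < 1")
        if self.noise_sd < 0:  # 0 is the degenerate noise-free control
            raise ValueError("noise_sd must be non-negative")

    @property
    def channel_names(self) -> list[str]:
        return [f"CH{i + 1:02d}" for i in range(self.n_channels)]


def build_fragile_network(
    cfg: SimulationConfig, rng: np.random.Generator | None = None, max_attempts: int = 20
) -> tuple[np.ndarray, dict]:
    """Construct and verify a stable operator whose fragile set is planted.

    ``A_true = B + c * u_F u_F^T``: a random stable base ``B`` (spectral
    radius rescaled to ``base_radius``) plus rank-one column loadings on the
    fragile set ``F`` (``u_F`` = normalized indicator of F), with ``c``
    chosen by bisection so ``rho(A_true) = target_radius ± 1e-6``.  The
    construction is *verified* by direct computation: every node in F must
    have strictly smaller fragility than every node outside F, else a new
    sub-seed is drawn (up to ``max_attempts``).

    Returns the operator and a verification report (spectral radius,
    attempts used, per-node fragility, verified flag).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_channels
    F = np.array(sorted(cfg.fragile_set), dtype=int)
    others = np.setdiff1d(np.arange(n), F)
    u = np.zeros(n)
    u[F] = 1.0
    u /= np.linalg.norm(u)
    R = np.outer(u, u)
    grid = default_omega_grid()
    last_report: dict = {}
    for attempt in range(1, max_attempts + 1):
        B = rng.standard_normal((n, n))
        rho_b = spectral_radius(B)
        if rho_b == 0:
            continue
        B *= cfg.base_radius / rho_b
        c = _bisect_loading(B, R, cfg.target_radius)
        A = B + c * R
        rho = spectral_radius(A)
        frag = _node_fragility_all(A, grid)
        verified = bool(
            abs(rho - cfg.target_radius) <= 1e-6
            and frag[F].max() < (frag[others].min() if others.size else np.inf)
        )
        last_report = {
            "spectral_radius": float(rho),
            "attempts": attempt,
            "node_fragility": frag,
            "fragile_set": F.tolist(),
            "verified": verified,
        }
        if verified:
            return A, last_report
    raise RuntimeError(
        f"fragile-network verification failed {max_attempts} times for config {cfg!r}; "
        "ground truth would be unusable"
    )


def _bisect_loading(B: np.ndarray, R: np.ndarray, target: float) -> float:
    """Loading c with spectral_radius(B + c R) = target to within 1e-8."""
    lo, hi = 0.0, 1.0
    while spectral_radius(B + hi * R) < target:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("bisection bracket blew up; rank-one loading cannot reach target")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if spectral_radius(B + mid * R) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


def simulate_recording(
    cfg: SimulationConfig,
    A_true: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    soze: np.ndarray | None = None,
    sozc: np.ndarray | None = None,
) -> tuple[SeegRecording, ChannelAnnotation]:
    """Simulate one interictal snapshot driven by a verified fragile network.

    Gaussian innovations (SD = ``noise_sd`` microvolts) drive the linear
    network; a 2 s burn-in is discarded so the emitted snapshot is
    stationary.  By default the annotation marks the fragile set as SOZE and
    a configurable superset as SOZC; explicit ``soze``/``sozc`` index arrays
    override that (used by the cohort generator's failure profile).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if A_true is None:
        A_true, _ = build_fragile_network(cfg, rng)
    n = cfg.n_channels
    burn = int(round(2.0 * cfg.fs))
    total = burn + int(round(cfg.duration_s * cfg.fs))
    noise = rng.normal(0.0, cfg.noise_sd, size=(total, n))
    X = np.empty((n, total))
    x = np.zeros(n)
    limit = 1e6 * max(cfg.noise_sd, 1e-30)
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(total):
            x = A_true @ x + noise[t]
            X[:, t] = x
    if not np.isfinite(X).all() or np.abs(X).max() > limit:
        raise RuntimeError("trajectory diverged; generating operator is not stable as required")
    rec = SeegRecording(X[:, burn:], cfg.fs, cfg.channel_names)

    if soze is None:
        soze = np.array(sorted(cfg.fragile_set), dtype=int)
    if sozc is None:
        non_f = np.setdiff1d(np.arange(n), soze)
        extra = rng.choice(non_f, size=min(cfg.cohort.n_sozc_extra, non_f.size), replace=False)
        sozc = np.union1d(soze, extra)
    ann = ChannelAnnotation.empty(cfg.channel_names)
    ann.is_soze[np.asarray(soze, dtype=int)] = True
    ann.is_sozc[np.asarray(sozc, dtype=int)] = True
    return rec, ann


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[CohortTable, dict[str, tuple[SeegRecording, ChannelAnnotation]]]:
    """Generate a labeled cohort of synthetic patients.

    Success-profile patients (``engel = 1``): SOZE = fragile set, SOZC adds
    ``n_sozc_extra`` channels.  Failure-profile patients: a
    ``mislocalization_fraction`` of fragile nodes is excluded from SOZE/SOZC
    and replaced by non-fragile channels; ``engel`` is drawn from {2, 3, 4}.
    All draws descend from ``cfg.seed`` via spawned sub-streams, so the
    whole cohort is byte-reproducible.
    """
    cc = cfg.cohort
    if cc.n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    n_success = int(round(cc.n_patients * cc.success_fraction))
    n_failure = cc.n_patients - n_success
    if n_success == 0 and n_failure == 0:
        raise ValueError("both outcome profiles empty")
    master = np.random.SeedSequence(cfg.seed)
    streams = master.spawn(cc.n_patients + 1)
    meta_rng = np.random.default_rng(streams[-1])

    rows = []
    patients: dict[str, tuple[SeegRecording, ChannelAnnotation]] = {}
    n = cfg.n_channels
    F = np.array(sorted(cfg.fragile_set), dtype=int)
    for i in range(cc.n_patients):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(streams[i])
        success = i < n_success
        A_true, _ = build_fragile_network(cfg, rng)
        missed = np.array([], dtype=int)
        if success:
            soze = F.copy()
        else:
            n_miss = int(round(cc.mislocalization_fraction * F.size))
            missed = rng.choice(F, size=n_miss, replace=False) if n_miss else np.array([], dtype=int)
            kept = np.setdiff1d(F, missed)
            pool = np.setdiff1d(np.arange(n), F)
            repl = rng.choice(pool, size=min(n_miss, pool.size), replace=False)
            soze = np.sort(np.concatenate([kept, repl]).astype(int))
            if soze.size == 0:  # degenerate: keep at least one labeled channel
                soze = np.array([int(pool[0])])
        # mislocalized fragile nodes must stay outside SOZC too
        pool_c = np.setdiff1d(np.arange(n), np.union1d(soze, missed))
        extra = rng.choice(pool_c, size=min(cc.n_sozc_extra, pool_c.size), replace=False)
        sozc = np.union1d(soze, extra)
        rec, ann = simulate_recording(cfg, A_true=A_true, rng=rng, soze=soze, sozc=sozc)
        patients[pid] = (rec, ann)
        engel = 1 if success else int(meta_rng.choice([2, 3, 4]))
        rows.append(
            {
                "patient_id": pid,
                "engel": engel,
                "rftc": int(meta_rng.random() < cc.p_rftc),
                "litt": int(meta_rng.random() < cc.p_litt),
                "surgery": int(meta_rng.random() < cc.p_surgery),
                "rns": int(meta_rng.random() < cc.p_rns),
                "mri_lesional": int(meta_rng.random() < cc.p_mri_lesional),
                "cc_class": int(meta_rng.integers(1, 5)),
            }
        )
    return CohortTable(pd.DataFrame(rows)), patients
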