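"""Preprocessing: resampling, bandpass filtering, bad-channel handling, window planning.

The analysis operates on SEEG downsampled to 500 Hz and bandpass-filtered
0.1-30 Hz, cut into 250 ms windows with 125 ms overlap.  Windows are
half-open sample intervals ``[start, start + win_len)`` with 0-based indexing;
at 500 Hz the 125 ms overlap is 62.5 samples and the hop is fixed at
``win_len - floor(62.5) = 63`` samples so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .io_formats import ChannelAnnotation, SeegRecording


@dataclass
class WindowPlan:
    """A sliding-window schedule over a recording."""

    win_len: int
    hop: int
    starts: list[int]
    fs: float

    def __post_init__(self) -> None:
        if self.win_len <= 0:
            raise ValueError("win_len must be positive")
        if not 0 < self.hop <= self.win_len:
            raise ValueError("hop must be in (0, win_len]")
        if list(self.starts) != sorted(set(int(s) for s in self.starts)):
            raise ValueError("window starts must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def times(self) -> np.ndarray:
        """Window-center times in seconds."""
        return (np.asarray(self.starts) + self.win_len / 2) / self.fs


def resample_to(rec: SeegRecording, target_fs: float) -> SeegRecording:
    """Anti-aliased polyphase downsampling to ``target_fs``.

    Upsampling is not part of this pipeline; ``target_fs > rec.fs`` is an
    error.  The rate ratio must be rational (it always is for the clinical
    2-4 kHz -> 500 Hz case).
    """
    if target_fs > rec.fs:
        raise ValueError(f"no upsampling: target {target_fs} Hz > recording {rec.fs} Hz")
    if target_fs == rec.fs:
        return SeegRecording(rec.data.copy(), rec.fs, list(rec.channel_names), rec.t0)
    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data, up, down, axis=1)
    return SeegRecording(data, target_fs, list(rec.channel_names), rec.t0)


def bandpass_filter(rec: SeegRecording, lo: float = 0.1, hi: float = 30.0) -> SeegRecording:
    """Zero-phase 4th-order Butterworth bandpass (default 0.1-30 Hz).

    Applied forward-backward per channel (``sosfiltfilt``), so the passband is
    flat, the phase is zero and DC is removed.  Shape is unchanged.
    """
    nyq = rec.fs / 2
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"high cutoff {hi} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return SeegRecording(data, rec.fs, list(rec.channel_names), rec.t0)


def detect_bad_channels(
    rec: SeegRecording,
    ann: ChannelAnnotation | None = None,
    *,
    k: float = 5.0,
    flat_eps: float = 1e-12,
) -> ChannelAnnotation:
    """Union of manual bad flags and two automatic rules.

    Automatic flags: flatline (sample variance < ``flat_eps``, in uV^2) and
    amplitude outlier (channel robust SD > ``k`` x the median robust SD across
    channels; robust SD = 1.4826 * MAD).  Raises if every channel ends up
    flagged — there would be nothing left to analyze.
    """
    if ann is None:
        ann = ChannelAnnotation.empty(rec.channel_names)
    if list(ann.channel_names) != list(rec.channel_names):
        raise ValueError("annotation channels do not match recording channels")
    var = rec.data.var(axis=1)
    flat = var < flat_eps
    med = np.median(rec.data, axis=1, keepdims=True)
    robust_sd = 1.4826 * np.median(np.abs(rec.data - med), axis=1)
    ref = np.median(robust_sd)
    outlier = robust_sd > k * ref if ref > 0 else np.zeros_like(flat)
    bad = ann.is_bad | flat | outlier
    if bad.all():
        raise ValueError("all channels flagged bad; nothing to analyze")
    return ChannelAnnotation(list(ann.channel_names), ann.is_soze.copy(), ann.is_sozc.copy(), bad)


def drop_bad_channels(rec: SeegRecording, ann: ChannelAnnotation) -> tuple[SeegRecording, ChannelAnnotation]:
    """Remove flagged channels from recording and annotation alike."""
    good = ann.good_channels
    return rec.pick(good), ann.subset(good)


def plan_windows(n_samples: int, fs: float, win_ms: float = 250.0, overlap_ms: float = 125.0) -> WindowPlan:
    """Plan half-open sliding windows of ``win_ms`` with ``overlap_ms`` overlap.

    ``win_len = round(win_ms * fs / 1000)``;
    ``hop = win_len - floor(overlap_ms * fs / 1000)``; starts run from 0 in
    steps of ``hop`` while the window fits, and a trailing partial window is
    discarded.
    """
    win_len = int(round(win_ms * fs / 1000))
    hop = win_len - int(np.floor(overlap_ms * fs / 1000))
    if hop <= 0:
        raise ValueError("overlap too large: hop would be non-positive")
    if n_samples < win_len:
        raise ValueError(f"recording has {n_samples} samples < one window ({win_len})")
    starts = list(range(0, n_samples - win_len + 1, hop))
    return WindowPlan(win_len=win_len, hop=hop, starts=starts, fs=fs)
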