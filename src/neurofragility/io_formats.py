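"""Readers and writers for SEEG recordings, annotations, fragility maps and cohort tables.

EDF/EDF+ is the recording interchange format (the clinical standard); EDF is
read through :mod:`mne`. Because EDF quantizes to 16 bits, fragility maps use
a lossless internal container (``.npz`` plus a JSON sidecar) instead.
Channel identity is by *name* everywhere downstream: bad-channel removal
changes indices, never names.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, type checking only
    from .fragility import FragilityMap
    from .preprocess import WindowPlan

logger = logging.getLogger(__name__)

FRAGILITY_CONTAINER_VERSION = 1

#: labels accepted in annotation CSVs
_ANNOTATION_LABELS = {"soze", "sozc", "bad", "none"}

_COHORT_REQUIRED = ["patient_id", "engel", "rftc", "litt", "surgery", "rns", "mri_lesional", "cc_class"]
_METRIC_COLUMNS = ["precision_soze", "recall_soze", "precision_sozc", "recall_sozc"]


class FormatError(ValueError):
    """An input file violates its documented schema."""


@dataclass
class SeegRecording:
    """A multichannel SEEG snapshot.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array of potentials in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        Unique channel labels, one per row of ``data``.
    t0
        Recording-relative start time of the first sample, seconds.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = [str(c) for c in self.channel_names]
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.n_channels < 2:
            raise ValueError("a recording needs at least 2 channels")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )
        dupes = _duplicates(self.channel_names)
        if dupes:
            raise ValueError(f"duplicate channel names: {sorted(dupes)}")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def pick(self, names: list[str]) -> "SeegRecording":
        """Return a copy restricted to ``names``, preserving their order."""
        idx = [self.channel_names.index(n) for n in names]
        return SeegRecording(self.data[idx].copy(), self.fs, list(names), self.t0)


@dataclass
class ChannelAnnotation:
    """Per-channel clinical flags aligned to a recording's channel names.

    ``is_soze`` marks channels with the earliest electrographic seizure-onset
    changes (clinician-read SOZ); ``is_sozc`` marks the treatment-target set
    (ablated/disconnected channels, including early propagation); the two may
    overlap.  ``is_bad`` channels are excluded from all downstream analysis.
    """

    channel_names: list[str]
    is_soze: np.ndarray
    is_sozc: np.ndarray
    is_bad: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.channel_names)
        for name in ("is_soze", "is_sozc", "is_bad"):
            v = np.asarray(getattr(self, name), dtype=bool)
            if v.shape != (n,):
                raise ValueError(f"{name} must have one flag per channel")
            setattr(self, name, v)
        dupes = _duplicates(self.channel_names)
        if dupes:
            raise ValueError(f"duplicate channel names: {sorted(dupes)}")

    @classmethod
    def empty(cls, channel_names: list[str]) -> "ChannelAnnotation":
        z = np.zeros(len(channel_names), dtype=bool)
        return cls(list(channel_names), z.copy(), z.copy(), z.copy())

    def subset(self, names: list[str]) -> "ChannelAnnotation":
        idx = [self.channel_names.index(n) for n in names]
        return ChannelAnnotation(
            list(names), self.is_soze[idx], self.is_sozc[idx], self.is_bad[idx]
        )

    @property
    def good_channels(self) -> list[str]:
        return [c for c, b in zip(self.channel_names, self.is_bad) if not b]


@dataclass
class CohortTable:
    """Patient-level cohort table: outcomes, treatments, covariates, metrics.

    ``engel`` is the ordinal surgical outcome 1-4 (1 = free of disabling
    seizures for >= 12 months = success); ``cc_class`` is the 4-level
    clinical-complexity stratification (1 = single MRI-visible lesion ...
    4 = multifocal abnormalities).  Concordance metrics
    (precision/recall vs SOZE and SOZC) may be absent before prediction.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"cohort table missing columns: {missing}")
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
            raise FormatError(f"duplicated patient id(s): {dup}")
        for col, lo, hi in (("engel", 1, 4), ("cc_class", 1, 4)):
            vals = df[col].astype(int)
            bad = df.loc[(vals < lo) | (vals > hi), "patient_id"].tolist()
            if bad:
                raise FormatError(f"{col} outside {lo}-{hi} for patients {bad}")
            df[col] = vals
        for col in ("rftc", "litt", "surgery", "rns", "mri_lesional"):
            df[col] = df[col].astype(int).astype(bool)
        df = df.reset_index(drop=True)
        object.__setattr__(self, "table", df)

    @property
    def success(self) -> pd.Series:
        """Boolean success flag: Engel class I."""
        return self.table["engel"] == 1

    @property
    def n_patients(self) -> int:
        return len(self.table)

    @property
    def has_metrics(self) -> bool:
        return all(c in self.table.columns for c in _METRIC_COLUMNS)

    def with_metrics(self, metrics: pd.DataFrame) -> "CohortTable":
        """Join per-patient concordance metrics (indexed by patient_id)."""
        df = self.table.drop(columns=[c for c in _METRIC_COLUMNS if c in self.table], errors="ignore")
        merged = df.merge(metrics, on="patient_id", how="left", validate="one_to_one")
        return CohortTable(merged)


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _peek_edf_header(path: Path) -> tuple[list[str], list[int]]:
    """Read channel labels and samples-per-record from a raw EDF header.

    A light pre-check only: full parsing is delegated to mne.  Needed because
    mne silently renames duplicate labels and resamples mixed-rate files,
    whereas this pipeline's contract is to reject both.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: unreadable EDF header") from exc
        if ns <= 0:
            raise FormatError(f"{path}: EDF header reports {ns} signals")
        rest = fh.read(ns * 256)
        if len(rest) < ns * 256:
            raise FormatError(f"{path}: truncated EDF signal header")
    labels = [rest[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip() for i in range(ns)]
    spr_off = ns * 216
    spr = []
    for i in range(ns):
        fieldb = rest[spr_off + i * 8 : spr_off + (i + 1) * 8]
        try:
            spr.append(int(fieldb.decode("ascii").strip()))
        except ValueError as exc:
            raise FormatError(f"{path}: bad samples-per-record for {labels[i]!r}") from exc
    return labels, spr


def read_edf(path: str | Path) -> SeegRecording:
    """Read an EDF/EDF+ file into a :class:`SeegRecording` (microvolts).

    Raises
    ------
    FormatError
        If the header is unreadable, channel labels are duplicated, or
        channels have mixed sampling rates (the offenders are named).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels, spr = _peek_edf_header(path)
    dupes = _duplicates(labels)
    if dupes:
        raise FormatError(f"{path}: duplicate channel labels: {sorted(dupes)}")
    annot_like = [l for l in labels if l.upper().startswith("EDF ANNOTATION")]
    sig = [(l, s) for l, s in zip(labels, spr) if l not in annot_like]
    rates = {s for _, s in sig}
    if len(rates) > 1:
        common = max(rates, key=lambda r: sum(1 for _, s in sig if s == r))
        off = [l for l, s in sig if s != common]
        raise FormatError(f"{path}: mixed sampling rates across channels; offending: {off}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return SeegRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def write_edf(rec: SeegRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF.

    The physical range per file is the symmetric max absolute amplitude, so
    round-tripping quantizes each sample by at most half of one digital step,
    ``(phys_max - phys_min) / (2^16 - 1) / 2``.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n = rec.n_channels
    if rec.n_samples % fs == 0:
        spr, rec_dur, n_rec = fs, 1.0, rec.n_samples // fs
    else:  # one big record; valid EDF, keeps exact sample count
        spr, rec_dur, n_rec = rec.n_samples, rec.n_samples / fs, 1

    # integer physical bound: exactly representable in the 8-char header field
    phys = _edf_physical_bound(rec)
    phys_min, phys_max = -phys, phys
    dig_min, dig_max = -32767, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((rec.data - phys_min) * scale + dig_min).astype("<i2")

    def f(x: object, w: int) -> bytes:
        s = str(x)[:w]
        return s.ljust(w).encode("ascii")

    def num(x: float, w: int) -> bytes:
        s = f"{x:.10g}"[:w]
        return s.ljust(w).encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),  # patient id (anonymous)
            f("Startdate X X X X", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (1 + n)), 8),
            f("", 44),
            f(str(n_rec), 8),
            num(rec_dur, 8),
            f(str(n), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(f(c, 16) for c in rec.channel_names),
            b"".join(f("", 80) for _ in range(n)),
            b"".join(f("uV", 8) for _ in range(n)),
            b"".join(num(phys_min, 8) for _ in range(n)),
            b"".join(num(phys_max, 8) for _ in range(n)),
            b"".join(f(str(dig_min), 8) for _ in range(n)),
            b"".join(f(str(dig_max), 8) for _ in range(n)),
            b"".join(f("", 80) for _ in range(n)),
            b"".join(f(str(spr), 8) for _ in range(n)),
            b"".join(f("", 32) for _ in range(n)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def _edf_physical_bound(rec: SeegRecording) -> float:
    """Symmetric physical range: the smallest integer >= max |amplitude|."""
    return float(max(1.0, np.ceil(np.abs(rec.data).max())))


def edf_quantization_step(rec: SeegRecording) -> float:
    """Worst-case per-sample round-trip error of :func:`write_edf`."""
    phys = _edf_physical_bound(rec)
    return 2 * phys / (2 * 32767) / 2 + 1e-12


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_channel_annotation(path: str | Path, channel_names: list[str]) -> ChannelAnnotation:
    """Read a channel,label CSV (multi-row multi-label) aligned to ``channel_names``.

    Labels are drawn from {soze, sozc, bad, none}.  Channels absent from the
    file default to all-false with a logged warning; a file channel not in
    ``channel_names`` is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty and list(df.columns) in ([], ["channel"], ["channel", "label"]):
        logger.warning("%s: empty annotation file; all channels unflagged", path)
        return ChannelAnnotation.empty(channel_names)
    for col in ("channel", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation CSV needs columns channel,label")
    ann = ChannelAnnotation.empty(channel_names)
    index = {c: i for i, c in enumerate(channel_names)}
    for _, row in df.iterrows():
        ch, label = str(row["channel"]).strip(), str(row["label"]).strip().lower()
        if ch not in index:
            raise FormatError(f"{path}: annotation references unknown channel {ch!r}")
        if label not in _ANNOTATION_LABELS:
            raise FormatError(f"{path}: unknown label {label!r} (allowed: {sorted(_ANNOTATION_LABELS)})")
        if label == "soze":
            ann.is_soze[index[ch]] = True
        elif label == "sozc":
            ann.is_sozc[index[ch]] = True
        elif label == "bad":
            ann.is_bad[index[ch]] = True
    unseen = set(channel_names) - set(df["channel"].astype(str).str.strip())
    if unseen:
        logger.warning("%s: %d channel(s) absent from annotation, defaulting to unflagged", path, len(unseen))
    return ann


def write_channel_annotation(ann: ChannelAnnotation, path: str | Path) -> None:
    rows = []
    for i, ch in enumerate(ann.channel_names):
        labels = [
            lab
            for lab, flag in (("soze", ann.is_soze[i]), ("sozc", ann.is_sozc[i]), ("bad", ann.is_bad[i]))
            if flag
        ] or ["none"]
        rows.extend({"channel": ch, "label": lab} for lab in labels)
    pd.DataFrame(rows, columns=["channel", "label"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fragility container (.npz + JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_fragility_map(fmap: "FragilityMap", path: str | Path) -> None:
    """Write a fragility map as a versioned ``.npz`` with a JSON metadata sidecar."""
    path = Path(path)
    arrays = {"raw": fmap.raw}
    if fmap.normalized is not None:
        arrays["normalized"] = fmap.normalized
    np.savez(path, **arrays)
    plan = fmap.window_plan
    meta = {
        "container_version": FRAGILITY_CONTAINER_VERSION,
        "channel_names": list(fmap.channel_names),
        "window_plan": {
            "win_len": int(plan.win_len),
            "hop": int(plan.hop),
            "starts": [int(s) for s in plan.starts],
            "fs": float(plan.fs),
        },
    }
    with open(_sidecar(path if path.suffix == ".npz" else path.with_suffix(".npz")), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_fragility_map(path: str | Path) -> "FragilityMap":
    """Read a fragility container; bit-exact inverse of :func:`write_fragility_map`."""
    from .fragility import FragilityMap
    from .preprocess import WindowPlan

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    try:
        with open(_sidecar(path)) as fh:
            meta = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: missing or corrupt sidecar metadata") from exc
    version = meta.get("container_version")
    if version != FRAGILITY_CONTAINER_VERSION:
        raise FormatError(
            f"{path}: container version {version!r} != supported {FRAGILITY_CONTAINER_VERSION}"
        )
    try:
        with np.load(path) as npz:
            raw = npz["raw"]
            normalized = npz["normalized"] if "normalized" in npz else None
    except Exception as exc:
        raise FormatError(f"{path}: unreadable or truncated container") from exc
    wp = meta["window_plan"]
    plan = WindowPlan(win_len=wp["win_len"], hop=wp["hop"], starts=list(wp["starts"]), fs=wp["fs"])
    return FragilityMap(
        raw=raw, normalized=normalized, channel_names=list(meta["channel_names"]), window_plan=plan
    )


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

def read_cohort_table(path: str | Path) -> CohortTable:
    """Read and validate a cohort CSV (one row per patient; header required)."""
    df = pd.read_csv(path)
    return CohortTable(df)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    out = cohort.table.copy()
    for col in ("rftc", "litt", "surgery", "rns", "mri_lesional"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
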