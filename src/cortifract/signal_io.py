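"""Multichannel recording I/O and preprocessing.

A :class:`Recording` is a time x channels matrix with a sampling rate and
subject/condition metadata.  On disk it is a plain CSV (header row of
channel ids, one time sample per row) accompanied by a YAML sidecar
holding the sampling rate and metadata; EDF files are supported read-only
through :mod:`mne` when that package is available.

Preprocessing mirrors a standard ECoG pipeline: zero-phase band-pass at
the acquisition rate (0.5-100 Hz by default), rational-ratio downsampling
to the analysis rate (1000 Hz -> 256 Hz), edge-transient trimming, then a
split into one whole-session epoch per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .errors import ConfigurationError, IngestError, ParameterError

#: Recognized experimental conditions.  "pd" covers both the chronic
#: lesioned group at baseline and the acute drug-induced parkinsonian
#: state; "*_treated" marks the intervention session (DBS or agonist).
CONDITIONS = ("control", "pd", "pd_treated", "control_treated")


@dataclass
class Recording:
    """Uniformly sampled multichannel recording.

    Attributes
    ----------
    samples:
        2-D float array, shape ``(n_samples, n_channels)``, microvolt-like
        arbitrary units.
    fs:
        Sampling rate in Hz.
    channel_ids:
        One label per column, order preserved from the source file.
    subject_id:
        Subject/animal identifier.
    condition:
        One of :data:`CONDITIONS`.
    """

    samples: np.ndarray
    fs: float
    channel_ids: list[str] = field(default_factory=list)
    subject_id: str = "unknown"
    condition: str = "control"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2 or self.samples.shape[0] < 2:
            raise ParameterError("samples must be 2-D with at least 2 time points")
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            bad = np.argwhere(~np.isfinite(self.samples))[0]
            ch = self._channel_label(int(bad[1]))
            raise IngestError(
                f"non-finite sample at row {int(bad[0])}, channel {ch!r}"
            )
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.samples.shape[1])]
        if len(self.channel_ids) != self.samples.shape[1]:
            raise ParameterError("channel_ids length must match channel count")
        if self.condition not in CONDITIONS:
            raise ParameterError(
                f"condition {self.condition!r} not one of {CONDITIONS}"
            )

    def _channel_label(self, col: int) -> str:
        if self.channel_ids and col < len(self.channel_ids):
            return self.channel_ids[col]
        return f"ch{col}"

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SignalEpoch:
    """One channel's time series, the unit on which HFD is computed."""

    x: np.ndarray
    fs: float
    channel_id: str = "ch0"
    subject_id: str = "unknown"
    condition: str = "control"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        if self.x.size < 2:
            raise ParameterError("epoch must contain at least 2 samples")
        if not np.all(np.isfinite(self.x)):
            raise IngestError(f"non-finite value in epoch for channel {self.channel_id!r}")
        if not self.fs > 0:
            raise ParameterError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.x.size


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def read_recording(path: str | Path, format: str = "matrix_csv") -> Recording:
    """Read a recording from disk.

    ``matrix_csv`` expects a CSV with a header row of channel ids and a
    YAML sidecar (same stem, ``.yaml``) providing at least ``fs``; ``edf``
    reads a European Data Format file via :mod:`mne`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"recording file not found: {path}")
    if format == "matrix_csv":
        return _read_matrix_csv(path)
    if format == "edf":
        return _read_edf(path)
    raise ParameterError(f"unknown recording format {format!r}")


def _read_matrix_csv(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ConfigurationError(
            f"sidecar {sidecar} not found; sampling rate unavailable"
        )
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh) or {}
    if "fs" not in meta:
        raise ConfigurationError(f"sidecar {sidecar} does not define 'fs'")
    frame = pd.read_csv(path)
    channel_ids = [str(c) for c in frame.columns]
    values = frame.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for col in frame.columns:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.index[coerced.isna() & frame[col].notna()]
            if len(bad):
                raise IngestError(
                    f"non-numeric cell at row {int(bad[0])}, channel {col!r}"
                )
        values = frame.apply(pd.to_numeric).to_numpy()
    nan_rows, nan_cols = np.nonzero(~np.isfinite(values))
    if nan_rows.size:
        raise IngestError(
            f"non-finite value at row {int(nan_rows[0])}, "
            f"channel {channel_ids[int(nan_cols[0])]!r}"
        )
    return Recording(
        samples=values.astype(float),
        fs=float(meta["fs"]),
        channel_ids=list(meta.get("channel_ids", channel_ids)),
        subject_id=str(meta.get("subject_id", path.stem)),
        condition=str(meta.get("condition", "control")),
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ConfigurationError(
            "EDF support requires the 'mne' package (install cortifract[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T  # mne returns channels x time
    return Recording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_ids=[str(c) for c in raw.ch_names],
        subject_id=path.stem,
        condition="control",
    )


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as matrix CSV plus YAML sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(rec.samples, columns=rec.channel_ids)
    frame.to_csv(path, index=False)
    meta = {
        "fs": float(rec.fs),
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "channel_ids": list(rec.channel_ids),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def bandpass(rec: Recording, low_hz: float, high_hz: float) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass.

    Applied forward-backward (``sosfiltfilt``) so the waveform shape --
    which the fractal-dimension estimator is sensitive to -- is not
    distorted by group delay.
    """
    nyq = rec.fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ParameterError(f"need 0 < low ({low_hz}) < high ({high_hz})")
    if high_hz >= nyq:
        raise ParameterError(
            f"high cutoff {high_hz} Hz must be below Nyquist ({nyq} Hz)"
        )
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=0)
    return replace(rec, samples=np.ascontiguousarray(filtered))


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase rational downsampling with built-in anti-alias filtering.

    Upsampling is out of scope and rejected.
    """
    if target_fs > rec.fs:
        raise ParameterError(
            f"upsampling ({rec.fs} -> {target_fs} Hz) is not supported"
        )
    if target_fs == rec.fs:
        return replace(rec, samples=rec.samples.copy())
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = sps.resample_poly(rec.samples, ratio.numerator, ratio.denominator, axis=0)
    return replace(rec, samples=np.ascontiguousarray(out), fs=float(target_fs))


def trim_edges(rec: Recording, seconds: float = 1.0) -> Recording:
    """Drop ``seconds`` from each end (filter edge transients)."""
    n_trim = int(round(seconds * rec.fs))
    if rec.n_samples <= 2 * n_trim + 2:
        raise ParameterError(
            f"recording too short ({rec.n_samples} samples) to trim "
            f"{seconds} s per edge at {rec.fs} Hz"
        )
    return replace(rec, samples=rec.samples[n_trim : rec.n_samples - n_trim].copy())


def split_epochs(rec: Recording) -> list[SignalEpoch]:
    """One whole-session epoch per channel, carrying subject metadata."""
    return [
        SignalEpoch(
            x=rec.samples[:, j].copy(),
            fs=rec.fs,
            channel_id=rec.channel_ids[j],
            subject_id=rec.subject_id,
            condition=rec.condition,
        )
        for j in range(rec.n_channels)
    ]


def preprocess(
    rec: Recording,
    low_hz: float = 0.5,
    high_hz: float = 100.0,
    target_fs: float | None = 256.0,
    edge_trim_s: float = 1.0,
) -> Recording:
    """Band-pass at the acquisition rate, trim edges, then downsample.

    ``target_fs=None`` skips the downsampling stage (useful when the
    analysis should run at the acquisition rate).
    """
    out = bandpass(rec, low_hz, high_hz)
    if edge_trim_s > 0:
        out = trim_edges(out, edge_trim_s)
    if target_fs is not None and target_fs != out.fs:
        out = resample(out, target_fs)
    return out
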