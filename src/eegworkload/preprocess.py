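"""Offline preprocessing chain: resample, filter, reject, re-reference, epoch.

The default chain order is resample -> band/notch filter -> epoch ->
amplitude rejection -> common average reference, matching standard
offline EEG practice.  All filters are zero-phase (forward-backward
Butterworth) so microstate timing is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import signal as sps

from .layout import ChannelLayout

__all__ = [
    "Recording",
    "EpochSet",
    "resample",
    "filter_band_notch",
    "rereference_average",
    "epoch",
    "reject_amplitude",
    "preprocess_chain",
]


@dataclass
class Recording:
    """One multichannel EEG recording in microvolts.

    data is (n_samples, n_channels); meta carries subject/condition/block
    tags and anything else a pipeline wants to thread through.
    """

    data: np.ndarray
    fs: float
    layout: ChannelLayout
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples, channels)")
        if self.data.shape[1] != self.layout.n_channels:
            raise ValueError(
                f"channel count {self.data.shape[1]} does not match layout "
                f"({self.layout.n_channels})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length consecutive epochs cut from one recording.

    epochs is (n_epochs, n_samples_per_epoch, n_channels); kept_mask
    records which of the originally cut epochs survived rejection.
    """

    epochs: np.ndarray
    fs: float
    epoch_length_s: float
    layout: ChannelLayout
    kept_mask: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D")
        expected = int(round(self.fs * self.epoch_length_s))
        if self.epochs.shape[1] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[1]} != fs*epoch_length_s "
                f"({expected})"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def concatenate(self) -> np.ndarray:
        """Stitch epochs back into a continuous (samples, channels) array."""
        return self.epochs.reshape(-1, self.epochs.shape[2])


def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling to ``target_fs`` (downsampling only)."""
    if target_fs > rec.fs:
        raise ValueError(f"no upsampling: target {target_fs} > fs {rec.fs}")
    if target_fs == rec.fs:
        return replace(rec, data=rec.data.copy())
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(rec.data, up, down, axis=0)
    n_out = int(round(rec.n_samples * target_fs / rec.fs))
    out = out[:n_out]
    return replace(rec, data=out, fs=float(target_fs))


def filter_band_notch(
    rec: Recording, lo: float = 1.0, hi: float = 40.0, notch: float | None = 50.0
) -> Recording:
    """Zero-phase Butterworth band-pass (order 4) plus notch (order 2 band-stop)."""
    nyq = rec.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"invalid band ({lo}, {hi}) for fs={rec.fs}")
    sos_bp = sps.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos_bp, rec.data, axis=0)
    if notch is not None and notch < nyq:
        sos_notch = sps.butter(
            2, [notch - 2.0, notch + 2.0], btype="bandstop", fs=rec.fs, output="sos"
        )
        out = sps.sosfiltfilt(sos_notch, out, axis=0)
    return replace(rec, data=out)


def rereference_average(rec: Recording) -> Recording:
    """Common average reference: subtract the per-sample channel mean. Idempotent."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = rec.data - rec.data.mean(axis=1, keepdims=True)
    return replace(rec, data=out)


def epoch(rec: Recording, length_s: float = 2.0) -> EpochSet:
    """Cut consecutive non-overlapping epochs; a trailing partial window is dropped."""
    n_per = int(round(length_s * rec.fs))
    if rec.n_samples < n_per:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than one epoch ({n_per})"
        )
    n_epochs = rec.n_samples // n_per
    cut = rec.data[: n_epochs * n_per].reshape(n_epochs, n_per, rec.n_channels)
    return EpochSet(
        epochs=cut,
        fs=rec.fs,
        epoch_length_s=length_s,
        layout=rec.layout,
        kept_mask=np.ones(n_epochs, dtype=bool),
        meta=dict(rec.meta),
    )


def reject_amplitude(epochs: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Drop epochs whose peak absolute amplitude on any channel exceeds the threshold."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.epochs).max(axis=(1, 2))
    keep = peak <= threshold_uv
    if not keep.any():
        raise ValueError(
            f"all {epochs.n_epochs} epochs rejected at {threshold_uv} uV"
        )
    mask = epochs.kept_mask.copy()
    mask[np.flatnonzero(mask)] = keep
    return EpochSet(
        epochs=epochs.epochs[keep],
        fs=epochs.fs,
        epoch_length_s=epochs.epoch_length_s,
        layout=epochs.layout,
        kept_mask=mask,
        meta=dict(epochs.meta),
    )


def preprocess_chain(
    rec: Recording,
    target_fs: float = 250.0,
    lo: float = 1.0,
    hi: float = 40.0,
    notch: float | None = 50.0,
    epoch_length_s: float = 2.0,
    reject_uv: float | None = 100.0,
) -> EpochSet:
    """Full default chain on a raw recording."""
    out = resample(rec, target_fs) if target_fs < rec.fs else rec
    out = filter_band_notch(out, lo=lo, hi=hi, notch=notch)
    out = rereference_average(out)
    eps = epoch(out, epoch_length_s)
    if reject_uv is not None:
        eps = reject_amplitude(eps, reject_uv)
    return eps
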