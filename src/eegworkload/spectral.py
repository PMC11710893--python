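"""Periodogram band power.

Per-epoch, per-channel power spectrum P(k) = |X(k)|^2 / N with X the
unwindowed DFT of the N-sample epoch, then arithmetic band averages over
the DFT bins whose frequency falls inside each band (both edges
inclusive, non-negative frequencies only).  Powers stay linear (uV^2);
no windowing, overlap or log transform.

Note the default delta band starts at 0.5 Hz while the standard analysis
band-pass starts at 1 Hz, so delta content below 1 Hz is attenuated by
preprocessing; the band definition is kept as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochSet

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "SpectralEstimate",
    "periodogram",
    "band_average",
    "total_average_power",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: f_lo must be < f_hi")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
)


@dataclass
class SpectralEstimate:
    """One-sided periodogram per epoch and channel.

    P has shape (n_epochs, n_channels, n_freqs) over the non-negative
    DFT frequencies; values are |X(k)|^2 / N without one-sided doubling,
    so mirrored negative-frequency bins carry the same power implicitly.
    """

    P: np.ndarray
    freqs: np.ndarray
    N: int
    fs: float
    channel_names: tuple[str, ...]

    @property
    def resolution(self) -> float:
        return self.fs / self.N


def periodogram(epochs: EpochSet) -> SpectralEstimate:
    """Unwindowed per-epoch periodogram.

    Parseval holds on the full (two-sided) spectrum:
    (1/N) * sum_k P(k) equals the mean square of the epoch.
    """
    if epochs.n_epochs == 0:
        raise ValueError("no epochs")
    x = epochs.epochs  # (epoch, sample, channel)
    N = x.shape[1]
    X = np.fft.rfft(x, axis=1)
    P = (np.abs(X) ** 2) / N  # (epoch, freq, channel)
    P = np.moveaxis(P, 1, 2)
    freqs = np.fft.rfftfreq(N, d=1.0 / epochs.fs)
    return SpectralEstimate(
        P=P,
        freqs=freqs,
        N=N,
        fs=epochs.fs,
        channel_names=tuple(epochs.layout.names),
    )


def band_average(
    spec: SpectralEstimate,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    meta: dict | None = None,
) -> pd.DataFrame:
    """Mean P(k) over each band's bins, then averaged across epochs.

    Returns a tidy table with one row per (channel, band); any meta keys
    (subject, condition, block, ...) are added as constant columns.
    """
    rows = []
    for band in bands:
        sel = (spec.freqs >= band.f_lo) & (spec.freqs <= band.f_hi)
        if not sel.any():
            raise ValueError(
                f"band {band.name!r} ({band.f_lo}-{band.f_hi} Hz) contains no "
                f"DFT bins at resolution {spec.resolution} Hz"
            )
        power = spec.P[:, :, sel].mean(axis=2).mean(axis=0)  # per channel
        for ch, p in zip(spec.channel_names, power):
            rows.append({"channel": ch, "band": band.name, "power": float(p)})
    table = pd.DataFrame(rows)
    for key, value in (meta or {}).items():
        table[key] = value
    return table


def total_average_power(table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean power across channels (and blocks, if present).

    Grouped by every identifying column except channel/block/power, which
    in the full pipeline means one row per (subject, condition, band).
    """
    drop = {"channel", "block", "power"}
    keys = [c for c in table.columns if c not in drop]
    out = table.groupby(keys, as_index=False, sort=True)["power"].mean()
    return out.rename(columns={"power": "total_power"})
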