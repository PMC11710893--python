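"""Synthetic multichannel EEG with planted microstate and spectral structure.

The generator is a stand-in for real recordings: nothing in it is fitted
to data.  A semi-Markov class sequence (geometric dwell times, explicit
transition matrix) switches between four dipolar template topographies;
the active template is modulated by a band-limited noise carrier and
spatially white sensor noise is added at a controlled SNR.  Everything
is deterministic given the config seed, and the planted ground truth is
returned alongside each recording so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .layout import ChannelLayout, make_layout
from .microstate import MicrostateTemplateSet
from .preprocess import Recording

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SubjectPair",
    "make_canonical_templates",
    "sample_state_sequence",
    "synthesize_recording",
    "make_workload_scenario",
    "stationary_coverage",
    "LOW_CONDITION",
    "HIGH_CONDITION",
]

_CLASS_LABELS = ("A", "B", "C", "D")

#: Carrier sub-bands available to the generator (Hz).
CARRIER_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
}


def make_canonical_templates(layout: ChannelLayout) -> MicrostateTemplateSet:
    """Analytic dipolar stand-ins for the four canonical map classes.

    Each map is the cosine of the angle between the electrode position and
    a class-specific dipole axis, re-referenced to zero mean and normalized:
    A right-frontal / left-posterior, B left-frontal / right-posterior,
    C symmetric anterior-posterior, D frontocentral maximum.
    """
    axes = {
        "A": np.array([1.0, 0.8, 0.2]),
        "B": np.array([-1.0, 0.8, 0.2]),
        "C": np.array([0.0, 1.0, -0.6]),
        "D": np.array([0.0, 0.35, 1.0]),
    }
    maps = []
    for lab in _CLASS_LABELS:
        axis = axes[lab] / np.linalg.norm(axes[lab])
        maps.append(layout.positions @ axis)
    return MicrostateTemplateSet(
        templates=np.stack(maps), labels=_CLASS_LABELS, level="canonical"
    )


@dataclass
class SyntheticConfig:
    """Everything needed to synthesize one recording deterministically."""

    layout: ChannelLayout
    templates: MicrostateTemplateSet
    mean_durations_ms: np.ndarray  # per class, > 0
    transition_matrix: np.ndarray  # row-stochastic, zero diagonal
    fs: float = 250.0
    duration_s: float = 120.0
    seed: int = 0
    snr_db: float = 20.0
    amplitude_uv: float = 10.0  # RMS scale of the template-signal part
    carrier_band: tuple[float, float] = (8.0, 13.0)
    band_gain: dict[str, float] | None = None  # per-band power multipliers

    def __post_init__(self) -> None:
        self.mean_durations_ms = np.asarray(self.mean_durations_ms, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = self.templates.k
        if self.mean_durations_ms.shape != (k,):
            raise ValueError("one mean duration per class required")
        if np.any(self.mean_durations_ms <= 0):
            raise ValueError("mean durations must be positive")
        P = self.transition_matrix
        if P.shape != (k, k):
            raise ValueError("transition matrix shape mismatch")
        if np.any(np.abs(np.diag(P)) > 0):
            raise ValueError("transition matrix must have zero diagonal")
        rows = P.sum(axis=1)
        if np.any(rows == 0):
            raise ValueError("degenerate transition row (all zero)")
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        f_hi = max(
            [self.carrier_band[1]]
            + [CARRIER_BANDS[b][1] for b in (self.band_gain or {})]
        )
        if self.fs <= 2 * f_hi:
            raise ValueError("fs must exceed twice the highest carrier frequency")
        if self.snr_db < -40:
            raise ValueError("snr below -40 dB is unusable")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass
class GroundTruth:
    """Planted structure of one synthetic recording."""

    label_sequence: np.ndarray
    templates: MicrostateTemplateSet
    transition_matrix: np.ndarray
    mean_durations_ms: np.ndarray
    coverage: np.ndarray  # stationary occupancy implied by dwell + transitions
    band_gain: dict[str, float]


def stationary_coverage(
    transition_matrix: np.ndarray, mean_durations_ms: np.ndarray
) -> np.ndarray:
    """Time-stationary class occupancy of the semi-Markov chain.

    The embedded chain's stationary vector, weighted by mean dwell time.
    """
    P = np.asarray(transition_matrix, dtype=float)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    cov = pi * np.asarray(mean_durations_ms, dtype=float)
    return cov / cov.sum()


def sample_state_sequence(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-sample class indices of a semi-Markov sequence.

    Dwell lengths are geometric with mean ``fs * mean_duration_ms / 1000``
    samples (support >= 1); the successor class follows the transition
    matrix row.  The initial class is drawn from the time-stationary
    occupancy so short sequences are unbiased.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    k = cfg.templates.k
    mean_samples = cfg.fs * cfg.mean_durations_ms / 1000.0
    p_geo = np.minimum(1.0, 1.0 / mean_samples)
    coverage = stationary_coverage(cfg.transition_matrix, cfg.mean_durations_ms)

    n = cfg.n_samples
    labels = np.empty(n, dtype=int)
    pos = 0
    state = int(rng.choice(k, p=coverage))
    while pos < n:
        dwell = int(rng.geometric(p_geo[state]))
        end = min(pos + dwell, n)
        labels[pos:end] = state
        pos = end
        state = int(rng.choice(k, p=cfg.transition_matrix[state]))
    return labels


def _band_limited_noise(
    n: int, band: tuple[float, float], fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to ``band``."""
    lo, hi = band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _carrier(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.band_gain is None:
        return _band_limited_noise(cfg.n_samples, cfg.carrier_band, cfg.fs, rng)
    parts = []
    for name, gain in cfg.band_gain.items():
        if name not in CARRIER_BANDS:
            raise ValueError(f"unknown carrier band {name!r}")
        comp = _band_limited_noise(cfg.n_samples, CARRIER_BANDS[name], cfg.fs, rng)
        parts.append(np.sqrt(gain) * comp)
    return np.sum(parts, axis=0)


def synthesize_recording(
    cfg: SyntheticConfig, meta: dict | None = None
) -> tuple[Recording, GroundTruth]:
    """Template-switching signal plus white sensor noise at the configured SNR.

    signal(t) = amplitude * template[label(t)] * carrier(t); noise is
    spatially white Gaussian with RMS set so that
    SNR_dB = 20 log10(RMS(signal) / RMS(noise)).  The output is
    average-referenced.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = sample_state_sequence(cfg, rng)
    carrier = _carrier(cfg, rng)

    signal = cfg.amplitude_uv * cfg.templates.templates[labels] * carrier[:, None]
    sig_rms = np.sqrt(np.mean(signal**2))
    noise_rms = sig_rms / (10.0 ** (cfg.snr_db / 20.0))
    noise = noise_rms * rng.standard_normal(signal.shape)
    data = signal + noise
    data = data - data.mean(axis=1, keepdims=True)

    rec = Recording(data=data, fs=cfg.fs, layout=cfg.layout, meta=dict(meta or {}))
    gt = GroundTruth(
        label_sequence=labels,
        templates=cfg.templates,
        transition_matrix=cfg.transition_matrix,
        mean_durations_ms=cfg.mean_durations_ms,
        coverage=stationary_coverage(cfg.transition_matrix, cfg.mean_durations_ms),
        band_gain=dict(cfg.band_gain or {}),
    )
    return rec, gt


# ---------------------------------------------------------------------------
# Two-condition workload scenario with planted effect directions

#: Planted low-workload dynamics: mean dwell (ms) per class A-D and the
#: segment-level transition matrix.
LOW_CONDITION = {
    "mean_durations_ms": np.array([80.0, 80.0, 80.0, 70.0]),
    "transition_matrix": np.array(
        [
            [0.00, 0.40, 0.30, 0.30],
            [0.40, 0.00, 0.30, 0.30],
            [0.30, 0.35, 0.00, 0.35],
            [0.30, 0.35, 0.35, 0.00],
        ]
    ),
    "band_gain": {"delta": 1.0, "theta": 1.0, "alpha": 1.2, "beta": 1.0},
}

#: High workload plants: theta/beta power up, class-B dwell down, traffic
#: into D up, A<->B transitions down, C<->D up.
HIGH_CONDITION = {
    "mean_durations_ms": np.array([80.0, 60.0, 80.0, 70.0]),
    "transition_matrix": np.array(
        [
            [0.00, 0.25, 0.30, 0.45],
            [0.25, 0.00, 0.30, 0.45],
            [0.25, 0.25, 0.00, 0.50],
            [0.25, 0.25, 0.50, 0.00],
        ]
    ),
    "band_gain": {"delta": 1.0, "theta": 1.5, "alpha": 1.2, "beta": 1.4},
}


@dataclass
class SubjectPair:
    """One synthetic subject: per-condition recording blocks + ground truth."""

    subject: int
    recordings: dict[str, list[Recording]]  # condition -> blocks
    truths: dict[str, list[GroundTruth]]


def make_workload_scenario(
    n_subjects: int,
    seed: int,
    block_duration_s: float = 180.0,
    n_blocks: int = 2,
    fs: float = 250.0,
    snr_db: float = 10.0,
    layout: ChannelLayout | None = None,
) -> list[SubjectPair]:
    """Paired low/high workload recordings for ``n_subjects`` subjects.

    Each subject gets ``n_blocks`` blocks per condition.  Subject-specific
    multiplicative jitter (same in both conditions) preserves the paired
    design while keeping between-subject variance realistic.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    layout = layout or make_layout()
    templates = make_canonical_templates(layout)
    top_rng = np.random.default_rng(seed)
    subject_seeds = np.random.SeedSequence(seed).spawn(n_subjects)

    subjects: list[SubjectPair] = []
    for si in range(n_subjects):
        child = np.random.default_rng(subject_seeds[si])
        dur_jit = top_rng.lognormal(0.0, 0.05, size=4)
        gain_jit = top_rng.lognormal(0.0, 0.08)
        amp = 10.0 * top_rng.lognormal(0.0, 0.1)
        recs: dict[str, list[Recording]] = {}
        gts: dict[str, list[GroundTruth]] = {}
        for cond, planted in (("low", LOW_CONDITION), ("high", HIGH_CONDITION)):
            recs[cond], gts[cond] = [], []
            for block in range(n_blocks):
                block_seed = int(child.integers(0, 2**31 - 1))
                cfg = SyntheticConfig(
                    layout=layout,
                    templates=templates,
                    mean_durations_ms=planted["mean_durations_ms"] * dur_jit,
                    transition_matrix=planted["transition_matrix"],
                    fs=fs,
                    duration_s=block_duration_s,
                    seed=block_seed,
                    snr_db=snr_db,
                    amplitude_uv=amp,
                    band_gain={
                        b: g * gain_jit for b, g in planted["band_gain"].items()
                    },
                )
                rec, gt = synthesize_recording(
                    cfg,
                    meta={"subject": si, "condition": cond, "block": block},
                )
                recs[cond].append(rec)
                gts[cond].append(gt)
        subjects.append(SubjectPair(subject=si, recordings=recs, truths=gts))
    return subjects
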