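"""Four-class EEG microstate analysis.

Implements the classic GFP-peak / polarity-invariant modified k-means
workflow: global field power, peak-map extraction, clustering of peak
topographies, two-level (subject -> grand mean) template aggregation,
canonical A-D labeling, whole-signal back-fitting, temporal parameters
(duration / occurrence / coverage), global explained variance, and
segment-level transition probabilities.

Polarity is ignored throughout: a map and its negation belong to the
same class, so all similarities are absolute (or squared) spatial
correlations.  Spatial correlation between average-referenced maps is
the normalized dot product of the mean-removed channel vectors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import Recording

__all__ = [
    "TopographySet",
    "MicrostateTemplateSet",
    "SegmentationResult",
    "MicrostateParams",
    "TransitionMatrix",
    "compute_gfp",
    "find_gfp_peaks",
    "extract_gfp_peak_maps",
    "spatial_correlation",
    "modified_kmeans",
    "aggregate_grand_mean",
    "label_canonical",
    "backfit",
    "temporal_parameters",
    "compute_gev",
    "transition_probabilities",
]

_EPS = 1e-15


@dataclass
class TopographySet:
    """Instantaneous scalp maps (rows) with their GFP values."""

    maps: np.ndarray  # (n_maps, n_channels), average-referenced, microvolts
    gfp_values: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.gfp_values = np.asarray(self.gfp_values, dtype=float)
        if self.maps.shape[0] != self.gfp_values.shape[0]:
            raise ValueError("maps and gfp_values disagree in length")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]


@dataclass
class MicrostateTemplateSet:
    """k unit-norm, zero-mean template topographies with class labels."""

    templates: np.ndarray  # (k, n_channels)
    labels: tuple[str, ...]
    level: str = "subject"  # subject | grand_mean | canonical

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.templates, dtype=float))
        # normalize defensively; inputs are meant to be zero-mean already
        t = t - t.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(t, axis=1)
        if np.any(norms < _EPS):
            raise ValueError("degenerate (zero) template")
        self.templates = t / norms[:, None]
        self.labels = tuple(self.labels)
        if len(self.labels) != self.templates.shape[0]:
            raise ValueError("one label per template required")

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


@dataclass
class SegmentationResult:
    """Per-sample microstate class labels with fit quality."""

    labels: np.ndarray  # (n_samples,) int class indices
    abs_corr: np.ndarray  # (n_samples,) |spatial corr| to winning template
    gfp: np.ndarray
    fs: float
    n_classes: int = 4
    # start indices of independent chunks (e.g. concatenated blocks); runs
    # and transitions never straddle a chunk boundary
    boundaries: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.abs_corr = np.asarray(self.abs_corr, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if not (len(self.labels) == len(self.abs_corr) == len(self.gfp)):
            raise ValueError("labels/abs_corr/gfp must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.labels)


@dataclass
class MicrostateParams:
    """Per-class temporal parameters of a segmentation."""

    duration_ms: np.ndarray
    occurrence_per_s: np.ndarray
    coverage: np.ndarray
    present: np.ndarray  # False where a class never occurs (duration reported 0)
    total_gev: float | None = None


@dataclass
class TransitionMatrix:
    """Segment-level transition probabilities, zero diagonal."""

    probs: np.ndarray  # (k, k); rows of undefined sources are NaN
    counts: np.ndarray
    undefined_rows: np.ndarray  # True where a class has no outgoing transitions


# ---------------------------------------------------------------------------
# GFP and peak maps


def compute_gfp(data: Recording | np.ndarray) -> np.ndarray:
    """Global field power: population std across channels at each sample."""
    x = data.data if isinstance(data, Recording) else np.asarray(data, dtype=float)
    return x.std(axis=1, ddof=0)


def find_gfp_peaks(gfp: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (endpoints excluded)."""
    g = np.asarray(gfp, dtype=float)
    if g.size < 3:
        return np.array([], dtype=int)
    interior = (g[1:-1] > g[:-2]) & (g[1:-1] > g[2:])
    return np.flatnonzero(interior) + 1


def extract_gfp_peak_maps(
    rec: Recording, boundaries: Sequence[int] | None = None
) -> TopographySet:
    """Average-referenced maps at GFP peaks, pooled across chunks."""
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    bounds = list(boundaries) if boundaries else [0]
    bounds = sorted(set(bounds)) + [rec.n_samples]
    maps, gfps = [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = data[lo:hi]
        g = compute_gfp(seg)
        idx = find_gfp_peaks(g)
        maps.append(seg[idx])
        gfps.append(g[idx])
    return TopographySet(
        maps=np.concatenate(maps) if maps else np.empty((0, rec.n_channels)),
        gfp_values=np.concatenate(gfps) if gfps else np.empty(0),
        source=dict(rec.meta),
    )


# ---------------------------------------------------------------------------
# Similarity


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms < _EPS] = 1.0
    return x / norms


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between rows of ``a`` and rows of ``b``.

    Returns an (n_a, n_b) signed correlation matrix.
    """
    ua = _normalize_rows(np.atleast_2d(np.asarray(a, dtype=float)))
    ub = _normalize_rows(np.atleast_2d(np.asarray(b, dtype=float)))
    return ua @ ub.T


# ---------------------------------------------------------------------------
# Modified (polarity-invariant) k-means


def _gev_of_assignment(
    norm_maps: np.ndarray,
    gfp: np.ndarray,
    templates: np.ndarray,
    assign: np.ndarray,
) -> float:
    corr = np.abs(np.einsum("ij,ij->i", norm_maps, templates[assign]))
    denom = float(np.sum(gfp**2))
    if denom < _EPS:
        return 0.0
    return float(np.sum((gfp * corr) ** 2) / denom)


def _dominant_eigvec(u: np.ndarray) -> np.ndarray:
    """Dominant right singular vector of stacked (already normalized) maps."""
    # eigenvector of sum_i u_i u_i^T == first right singular vector of U
    _, _, vt = np.linalg.svd(u, full_matrices=False)
    return vt[0]


def modified_kmeans(
    maps: TopographySet,
    k: int = 4,
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[MicrostateTemplateSet, np.ndarray, float]:
    """Polarity-invariant k-means on topographic maps.

    Assignment: each map goes to the template with maximal squared spatial
    correlation.  Update: each template becomes the dominant eigenvector of
    the scatter of its assigned normalized maps.  The best of ``n_restarts``
    runs by global explained variance (GEV) wins; everything is
    deterministic given ``seed``.

    Returns (templates, per-map assignments, gev).
    """
    if maps.n_maps < k:
        raise ValueError(f"need at least k={k} maps, got {maps.n_maps}")
    u = _normalize_rows(maps.maps)
    gfp = maps.gfp_values
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        init_idx = rng.choice(maps.n_maps, size=k, replace=False)
        templates = u[init_idx].copy()
        prev_gev = -np.inf
        assign = np.zeros(maps.n_maps, dtype=int)
        for _it in range(max_iter):
            corr = u @ templates.T  # (n, k)
            assign = np.argmax(corr**2, axis=1)
            # refill empty clusters from the worst-fitting map
            best_abs = np.abs(corr[np.arange(maps.n_maps), assign])
            for c in range(k):
                if not np.any(assign == c):
                    worst = int(np.argmin(best_abs))
                    assign[worst] = c
                    best_abs[worst] = 1.0
            for c in range(k):
                templates[c] = _dominant_eigvec(u[assign == c])
            gev = _gev_of_assignment(u, gfp, templates, assign)
            if abs(gev - prev_gev) < tol:
                prev_gev = gev
                break
            prev_gev = gev
        if best is None or prev_gev > best[0]:
            best = (prev_gev, templates.copy(), assign.copy())

    gev, templates, assign = best  # type: ignore[misc]
    tset = MicrostateTemplateSet(
        templates=templates,
        labels=tuple(str(i) for i in range(k)),
        level="subject",
    )
    return tset, assign, float(gev)


# ---------------------------------------------------------------------------
# Two-level aggregation and canonical labeling


def _best_permutation(
    subject: np.ndarray, reference: np.ndarray
) -> tuple[tuple[int, ...], np.ndarray]:
    """Permutation of subject maps maximizing total |corr| to reference rows."""
    corr = spatial_correlation(reference, subject)  # (k_ref, k_subj)
    k = corr.shape[0]
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(abs(corr[i, perm[i]]) for i in range(k))
        if score > best_score:
            best_score, best_perm = score, perm
    signs = np.array([np.sign(corr[i, best_perm[i]]) or 1.0 for i in range(k)])
    return best_perm, signs


def aggregate_grand_mean(
    subject_sets: Sequence[MicrostateTemplateSet],
    seed: int = 0,
    max_iter: int = 50,
) -> MicrostateTemplateSet:
    """Cluster subject template sets into grand-mean templates.

    Subjects' maps are permutation- and polarity-aligned to an evolving
    mean (exhaustive search over k! label orders per subject), iterated
    until the alignment stabilizes; the grand templates are the normalized
    means of the aligned maps.
    """
    if not subject_sets:
        raise ValueError("no subject sets")
    k = subject_sets[0].k
    nch = subject_sets[0].n_channels
    for s in subject_sets:
        if s.k != k or s.n_channels != nch:
            raise ValueError("all subject sets must share k and channel count")

    reference = subject_sets[0].templates.copy()
    prev_perms: list[tuple[int, ...]] | None = None
    for _ in range(max_iter):
        aligned = np.zeros((len(subject_sets), k, nch))
        perms: list[tuple[int, ...]] = []
        for si, s in enumerate(subject_sets):
            perm, signs = _best_permutation(s.templates, reference)
            aligned[si] = signs[:, None] * s.templates[list(perm)]
            perms.append(perm)
        mean_maps = aligned.mean(axis=0)
        reference = _normalize_rows(mean_maps)
        if perms == prev_perms:
            break
        prev_perms = perms
    return MicrostateTemplateSet(
        templates=reference,
        labels=tuple(str(i) for i in range(k)),
        level="grand_mean",
    )


def label_canonical(
    templates: MicrostateTemplateSet, canon: MicrostateTemplateSet
) -> tuple[MicrostateTemplateSet, dict[str, float]]:
    """Assign canonical labels by the best one-to-one |corr| matching.

    Exhaustive over the k! assignments; returns the relabeled set (rows
    reordered to the canonical label order, polarity aligned) and the
    per-class match quality.
    """
    if templates.n_channels != canon.n_channels:
        raise ValueError("channel spaces differ")
    if templates.k != canon.k:
        raise ValueError("template counts differ")
    perm, signs = _best_permutation(templates.templates, canon.templates)
    maps = signs[:, None] * templates.templates[list(perm)]
    corr = spatial_correlation(maps, canon.templates)
    quality = {canon.labels[i]: float(abs(corr[i, i])) for i in range(canon.k)}
    out = MicrostateTemplateSet(
        templates=maps, labels=canon.labels, level=templates.level
    )
    return out, quality


# ---------------------------------------------------------------------------
# Back-fitting and derived parameters


def backfit(
    rec: Recording,
    templates: MicrostateTemplateSet,
    boundaries: Sequence[int] | None = None,
    fit_at: str = "all",
) -> SegmentationResult:
    """Label every sample with the template of highest |spatial correlation|.

    ``fit_at="peaks"`` labels GFP peaks only and extends each peak's label
    to the midpoints between neighbouring peaks.  Zero-variance samples
    carry the previous sample's label (ties in the argmax go to the lowest
    class index).
    """
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    gfp = compute_gfp(data)
    norms = np.linalg.norm(data, axis=1)
    valid = norms > _EPS

    corr = np.zeros((rec.n_samples, templates.k))
    if valid.any():
        u = data[valid] / norms[valid, None]
        corr[valid] = np.abs(u @ templates.templates.T)
    labels = np.argmax(corr, axis=1)
    abs_corr = corr[np.arange(rec.n_samples), labels]

    if fit_at == "peaks":
        bounds = sorted(set(boundaries)) if boundaries else [0]
        bounds = bounds + [rec.n_samples]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            peaks = find_gfp_peaks(gfp[lo:hi]) + lo
            if peaks.size == 0:
                continue
            mids = ((peaks[:-1] + peaks[1:]) // 2) + 1
            edges = np.concatenate(([lo], mids, [hi]))
            for p, a, b in zip(peaks, edges[:-1], edges[1:]):
                labels[a:b] = labels[p]
    elif fit_at != "all":
        raise ValueError("fit_at must be 'all' or 'peaks'")

    # propagate through zero-variance samples
    if not valid.all():
        idx = np.flatnonzero(valid)
        if idx.size == 0:
            raise ValueError("recording has no non-degenerate samples")
        filled = labels.copy()
        last = labels[idx[0]]
        for i in range(rec.n_samples):
            if valid[i]:
                last = labels[i]
            else:
                filled[i] = last
        # leading invalid samples take the first valid label
        filled[: idx[0]] = labels[idx[0]]
        labels = filled
        abs_corr[~valid] = 0.0

    return SegmentationResult(
        labels=labels,
        abs_corr=abs_corr,
        gfp=gfp,
        fs=rec.fs,
        n_classes=templates.k,
        boundaries=tuple(sorted(set(boundaries))) if boundaries else (0,),
    )


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(run_labels, run_lengths) of maximal constant runs."""
    if labels.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return labels[starts], ends - starts


def _chunks(seg: SegmentationResult) -> list[np.ndarray]:
    bounds = list(seg.boundaries) + [seg.n_samples]
    return [seg.labels[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def temporal_parameters(seg: SegmentationResult) -> MicrostateParams:
    """Duration (ms), occurrence (1/s) and coverage per class.

    Maximal runs of one label are segments; runs never straddle chunk
    boundaries.  Absent classes get duration 0 (flagged via ``present``),
    occurrence 0 and coverage 0.
    """
    if seg.n_samples == 0:
        raise ValueError("empty segmentation")
    k = seg.n_classes
    seg_counts = np.zeros(k)
    seg_samples = np.zeros(k)
    for chunk in _chunks(seg):
        run_labels, run_lengths = _runs(chunk)
        for c in range(k):
            m = run_labels == c
            seg_counts[c] += m.sum()
            seg_samples[c] += run_lengths[m].sum()
    total_s = seg.n_samples / seg.fs
    present = seg_counts > 0
    duration_ms = np.zeros(k)
    duration_ms[present] = (
        seg_samples[present] / seg_counts[present] / seg.fs * 1000.0
    )
    occurrence = seg_counts / total_s
    coverage = seg_samples / seg.n_samples
    return MicrostateParams(
        duration_ms=duration_ms,
        occurrence_per_s=occurrence,
        coverage=coverage,
        present=present,
    )


def compute_gev(
    seg: SegmentationResult,
    rec: Recording,
    templates: MicrostateTemplateSet,
) -> float:
    """GFP-weighted global explained variance of the labeled segmentation.

    GEV = sum_t (GFP_t * |corr(map_t, template_{label_t})|)^2 / sum_t GFP_t^2.
    """
    if rec.n_samples != seg.n_samples:
        raise ValueError("recording and segmentation lengths differ")
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    gfp = compute_gfp(data)
    norms = np.linalg.norm(data, axis=1)
    safe = np.where(norms < _EPS, 1.0, norms)
    u = data / safe[:, None]
    corr = np.abs(np.einsum("ij,ij->i", u, templates.templates[seg.labels]))
    corr[norms < _EPS] = 0.0
    denom = float(np.sum(gfp**2))
    if denom < _EPS:
        return 0.0
    return float(np.sum((gfp * corr) ** 2) / denom)


def transition_probabilities(seg: SegmentationResult) -> TransitionMatrix:
    """Segment-level transition probabilities (self-transitions impossible)."""
    k = seg.n_classes
    counts = np.zeros((k, k))
    n_segments = 0
    for chunk in _chunks(seg):
        run_labels, _ = _runs(chunk)
        n_segments += run_labels.size
        for a, b in zip(run_labels[:-1], run_labels[1:]):
            counts[a, b] += 1
    if n_segments < 2:
        raise ValueError("need at least 2 segments for transitions")
    row_sums = counts.sum(axis=1)
    undefined = row_sums == 0
    probs = np.full((k, k), np.nan)
    ok = ~undefined
    probs[ok] = counts[ok] / row_sums[ok, None]
    return TransitionMatrix(probs=probs, counts=counts, undefined_rows=undefined)
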