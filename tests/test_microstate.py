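import itertools

import numpy as np
import pytest

from conftest import random_zero_mean_maps
from eegworkload.microstate import (
    MicrostateTemplateSet,
    SegmentationResult,
    TopographySet,
    aggregate_grand_mean,
    backfit,
    compute_gev,
    compute_gfp,
    extract_gfp_peak_maps,
    find_gfp_peaks,
    label_canonical,
    modified_kmeans,
    spatial_correlation,
    temporal_parameters,
    transition_probabilities,
)
from eegworkload.preprocess import Recording
from eegworkload.synth import LOW_CONDITION, SyntheticConfig, synthesize_recording


# ---------------------------------------------------------------------------
# independent oracles


def _normalize(maps):
    maps = maps - maps.mean(axis=1, keepdims=True)
    return maps / np.linalg.norm(maps, axis=1, keepdims=True)


def _gev(u, gfp, templates, assign):
    corr = np.abs(np.einsum("ij,ij->i", u, templates[assign]))
    return np.sum((gfp * corr) ** 2) / np.sum(gfp**2)


def _dominant(u):
    _, _, vt = np.linalg.svd(u, full_matrices=False)
    return vt[0]


def brute_force_kmeans_optimum(maps, gfp, k):
    """Exhaustive max over surjective polarity-invariant assignments."""
    u = _normalize(maps)
    n = len(u)
    best = -np.inf
    for assign in itertools.product(range(k), repeat=n):
        assign = np.array(assign)
        if len(np.unique(assign)) < k:
            continue
        templates = np.stack([_dominant(u[assign == c]) for c in range(k)])
        best = max(best, _gev(u, gfp, templates, assign))
    return best


class TestGFP:
    def test_two_channel(self):
        assert compute_gfp(np.array([[1.0, -1.0]]))[0] == pytest.approx(1.0)

    def test_zero_sample(self):
        assert compute_gfp(np.zeros((1, 5)))[0] == 0.0

    def test_three_channel_hand_computed(self):
        assert compute_gfp(np.array([[1.0, 0.0, -1.0]]))[0] == pytest.approx(
            np.sqrt(2.0 / 3.0)
        )


class TestGFPPeaks:
    def test_simple(self):
        assert list(find_gfp_peaks(np.array([0, 1, 0, 2, 0.0]))) == [1, 3]

    def test_monotone(self):
        assert find_gfp_peaks(np.arange(10.0)).size == 0

    def test_rectified_sinusoid_two_peaks_per_cycle(self):
        fs = 250.0
        t = np.arange(0, 1, 1 / fs)
        gfp = np.abs(np.sin(2 * np.pi * 10.0 * t))
        peaks = find_gfp_peaks(gfp)
        # brute-force count
        brute = [
            i
            for i in range(1, len(gfp) - 1)
            if gfp[i - 1] < gfp[i] > gfp[i + 1]
        ]
        assert list(peaks) == brute
        assert abs(len(peaks) - 20) <= 1


class TestModifiedKmeans:
    def test_zero_noise_fixed_point(self, rng):
        # 4 orthogonal zero-mean templates repeated with random signs
        base = _normalize(random_zero_mean_maps(rng, 4, 31))
        q, _ = np.linalg.qr(base.T)
        planted = q[:, :4].T
        planted = _normalize(planted)
        signs = rng.choice([-1.0, 1.0], size=40)
        maps = planted[np.repeat(np.arange(4), 10)] * signs[:, None]
        tset, assign, gev = modified_kmeans(
            TopographySet(maps=maps, gfp_values=np.ones(40)), k=4, n_restarts=20, seed=0
        )
        corr = np.abs(spatial_correlation(tset.templates, planted))
        assert np.allclose(corr.max(axis=1), 1.0, atol=1e-9)
        assert gev == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_optimum_8_maps(self, rng):
        maps = random_zero_mean_maps(rng, 8, 4)
        gfp = np.ones(8)
        oracle = brute_force_kmeans_optimum(maps, gfp, k=2)
        _, _, gev = modified_kmeans(
            TopographySet(maps=maps, gfp_values=gfp), k=2, n_restarts=50, seed=1
        )
        assert gev == pytest.approx(oracle, abs=1e-9)

    def test_k1_equals_dominant_eigenvector(self, rng):
        maps = random_zero_mean_maps(rng, 20, 10)
        tset, _, _ = modified_kmeans(
            TopographySet(maps=maps, gfp_values=np.ones(20)), k=1, n_restarts=1, seed=0
        )
        u = _normalize(maps)
        evals, evecs = np.linalg.eigh(u.T @ u)
        dom = evecs[:, -1]
        assert abs(abs(tset.templates[0] @ dom) - 1.0) < 1e-9

    def test_k_larger_than_maps(self, rng):
        maps = random_zero_mean_maps(rng, 3, 8)
        with pytest.raises(ValueError):
            modified_kmeans(TopographySet(maps=maps, gfp_values=np.ones(3)), k=4)

    def test_deterministic(self, rng):
        maps = random_zero_mean_maps(rng, 30, 12)
        ts = TopographySet(maps=maps, gfp_values=np.ones(30))
        a = modified_kmeans(ts, k=3, n_restarts=5, seed=42)
        b = modified_kmeans(ts, k=3, n_restarts=5, seed=42)
        assert np.array_equal(a[0].templates, b[0].templates)
        assert a[2] == b[2]


class TestGrandMean:
    def test_identical_sets_shuffled_labels(self, rng):
        maps = _normalize(random_zero_mean_maps(rng, 4, 31))
        sets = []
        for perm in ([0, 1, 2, 3], [3, 2, 1, 0], [1, 0, 3, 2]):
            sets.append(
                MicrostateTemplateSet(
                    templates=maps[perm], labels=("0", "1", "2", "3")
                )
            )
        grand = aggregate_grand_mean(sets)
        corr = np.abs(spatial_correlation(grand.templates, maps))
        assert np.allclose(corr.max(axis=1), 1.0, atol=1e-9)

    def test_polarity_invariance(self, rng):
        maps = _normalize(random_zero_mean_maps(rng, 4, 31))
        s1 = MicrostateTemplateSet(templates=maps, labels=("0", "1", "2", "3"))
        s2 = MicrostateTemplateSet(templates=-maps, labels=("0", "1", "2", "3"))
        grand = aggregate_grand_mean([s1, s2, s1])
        corr = np.abs(spatial_correlation(grand.templates, maps))
        assert np.allclose(corr.max(axis=1), 1.0, atol=1e-9)

    def test_exhaustive_alignment_oracle_3_subjects_k2(self, rng):
        # noisy copies of common base maps, randomly permuted/sign-flipped,
        # so the optimal alignment is well defined
        base = _normalize(random_zero_mean_maps(rng, 2, 6))
        subject_maps = []
        for _ in range(3):
            perm = rng.permutation(2)
            signs = rng.choice([-1.0, 1.0], size=2)
            noisy = base[perm] * signs[:, None]
            noisy = noisy + 0.3 * random_zero_mean_maps(rng, 2, 6)
            subject_maps.append(_normalize(noisy))
        best_score, best_mean = -np.inf, None
        for perms in itertools.product(itertools.permutations(range(2)), repeat=3):
            for signs in itertools.product([-1.0, 1.0], repeat=6):
                aligned = np.stack(
                    [
                        np.array(signs[2 * s : 2 * s + 2])[:, None]
                        * subject_maps[s][list(perms[s])]
                        for s in range(3)
                    ]
                )
                mean = _normalize(aligned.mean(axis=0))
                score = sum(
                    abs(aligned[s, c] @ mean[c]) for s in range(3) for c in range(2)
                )
                if score > best_score:
                    best_score, best_mean = score, mean
        sets = [
            MicrostateTemplateSet(templates=m, labels=("0", "1"))
            for m in subject_maps
        ]
        grand = aggregate_grand_mean(sets)
        corr = np.abs(spatial_correlation(grand.templates, best_mean))
        assert np.allclose(corr.max(axis=1), 1.0, atol=1e-6)


class TestLabelCanonical:
    def test_identity(self, canon):
        out, quality = label_canonical(canon, canon)
        assert out.labels == canon.labels
        assert np.allclose(list(quality.values()), 1.0)
        assert np.allclose(np.abs(np.sum(out.templates * canon.templates, axis=1)), 1.0)

    def test_permutation_recovered(self, canon):
        perm = [2, 0, 3, 1]
        shuffled = MicrostateTemplateSet(
            templates=canon.templates[perm], labels=("0", "1", "2", "3")
        )
        out, _ = label_canonical(shuffled, canon)
        corr = np.abs(spatial_correlation(out.templates, canon.templates))
        assert np.allclose(np.diag(corr), 1.0, atol=1e-9)

    def test_noisy_templates_mostly_correct(self, canon, rng):
        correct = 0
        n_trials = 200
        for _ in range(n_trials):
            noise = rng.standard_normal(canon.templates.shape)
            noise = _normalize(noise) * 10 ** (-10 / 20)  # snr 10 dB
            noisy = MicrostateTemplateSet(
                templates=canon.templates + noise, labels=("0", "1", "2", "3")
            )
            out, _ = label_canonical(noisy, canon)
            corr = np.abs(spatial_correlation(out.templates, canon.templates))
            if np.all(np.argmax(corr, axis=1) == np.arange(4)):
                correct += 1
        assert correct / n_trials >= 0.95


class TestBackfit:
    def test_exact_template_gets_labeled(self, layout, canon):
        rec = Recording(data=5.0 * canon.templates[[1]], fs=250.0, layout=layout)
        seg = backfit(rec, canon)
        assert seg.labels[0] == 1
        assert seg.abs_corr[0] == pytest.approx(1.0)

    def test_polarity_ignored(self, layout, canon):
        rec = Recording(data=-3.0 * canon.templates[[2]], fs=250.0, layout=layout)
        assert backfit(rec, canon).labels[0] == 2

    def test_winner_matches_brute_force(self, layout, canon, rng):
        data = random_zero_mean_maps(rng, 50, 31)
        rec = Recording(data=data, fs=250.0, layout=layout)
        seg = backfit(rec, canon)
        for i in range(50):
            v = data[i] - data[i].mean()
            corrs = [
                abs(np.corrcoef(v, tmpl)[0, 1]) for tmpl in canon.templates
            ]
            assert seg.labels[i] == int(np.argmax(corrs))
            assert seg.abs_corr[i] == pytest.approx(max(corrs))

    def test_zero_variance_sample_carries_forward(self, layout, canon):
        data = np.vstack([canon.templates[[3]], np.zeros((2, 31)), canon.templates[[0]]])
        seg = backfit(Recording(data=data, fs=250.0, layout=layout), canon)
        assert list(seg.labels) == [3, 3, 3, 0]
        assert seg.abs_corr[1] == 0.0


class TestTemporalParameters:
    def _seg(self, labels, fs=4.0, boundaries=(0,)):
        labels = np.asarray(labels)
        return SegmentationResult(
            labels=labels,
            abs_corr=np.ones(len(labels)),
            gfp=np.ones(len(labels)),
            fs=fs,
            boundaries=boundaries,
        )

    def test_hand_counted_example(self):
        params = temporal_parameters(self._seg([0, 0, 1, 1, 1, 1, 0, 0]))
        assert params.duration_ms[0] == pytest.approx(500.0)
        assert params.duration_ms[1] == pytest.approx(1000.0)
        assert params.coverage[0] == pytest.approx(0.5)
        assert params.coverage[1] == pytest.approx(0.5)
        assert params.occurrence_per_s[0] == pytest.approx(1.0)
        assert params.occurrence_per_s[1] == pytest.approx(0.5)

    def test_all_one_class(self):
        params = temporal_parameters(self._seg([2] * 8))
        assert params.coverage[2] == pytest.approx(1.0)
        assert params.occurrence_per_s[2] == pytest.approx(0.5)
        assert not params.present[0] and params.duration_ms[0] == 0.0

    def test_duration_times_occurrence_equals_coverage(self, rng):
        labels = rng.integers(0, 4, size=1000)
        params = temporal_parameters(self._seg(labels, fs=250.0))
        lhs = params.duration_ms / 1000.0 * params.occurrence_per_s
        assert np.allclose(lhs, params.coverage, atol=1e-12)
        assert params.coverage.sum() == pytest.approx(1.0)

    def test_boundaries_break_runs(self):
        # one long run split by a chunk boundary counts as two segments
        params = temporal_parameters(self._seg([0] * 8, boundaries=(0, 4)))
        assert params.occurrence_per_s[0] == pytest.approx(1.0)
        assert params.duration_ms[0] == pytest.approx(1000.0)


class TestGEV:
    def test_pure_template_recording(self, layout, canon, rng):
        amp = rng.uniform(1, 5, size=100)
        labels = rng.integers(0, 4, size=100)
        data = canon.templates[labels] * amp[:, None]
        rec = Recording(data=data, fs=250.0, layout=layout)
        seg = backfit(rec, canon)
        assert compute_gev(seg, rec, canon) == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_templates(self, layout, rng):
        # templates drawn from the orthogonal complement of the sample maps
        data = random_zero_mean_maps(rng, 20, 31)
        q, _ = np.linalg.qr(np.vstack([data, np.ones((1, 31))]).T, mode="complete")
        ortho = q[:, 21:25].T
        templates = MicrostateTemplateSet(
            templates=ortho, labels=("0", "1", "2", "3")
        )
        rec = Recording(data=data, fs=250.0, layout=layout)
        seg = backfit(rec, templates)
        assert compute_gev(seg, rec, templates) == pytest.approx(0.0, abs=1e-12)

    def test_five_sample_hand_computed(self, layout, canon, rng):
        data = random_zero_mean_maps(rng, 5, 31)
        rec = Recording(data=data, fs=250.0, layout=layout)
        seg = backfit(rec, canon)
        num = 0.0
        den = 0.0
        for i in range(5):
            v = data[i]
            g = v.std()
            c = abs(np.corrcoef(v, canon.templates[seg.labels[i]])[0, 1])
            num += (g * c) ** 2
            den += g**2
        assert compute_gev(seg, rec, canon) == pytest.approx(num / den, rel=1e-9)


class TestTransitions:
    def _seg(self, labels):
        labels = np.asarray(labels)
        return SegmentationResult(
            labels=labels,
            abs_corr=np.ones(len(labels)),
            gfp=np.ones(len(labels)),
            fs=250.0,
        )

    def test_alternating(self):
        tm = transition_probabilities(self._seg([0, 1, 0, 1]))
        assert tm.probs[0, 1] == pytest.approx(1.0)
        assert tm.probs[1, 0] == pytest.approx(1.0)

    def test_cycle(self):
        tm = transition_probabilities(self._seg([0, 1, 2, 0]))
        assert tm.probs[0, 1] == pytest.approx(1.0)
        assert tm.probs[1, 2] == pytest.approx(1.0)
        assert tm.probs[2, 0] == pytest.approx(1.0)

    def test_rows_sum_to_one_or_undefined(self, rng):
        labels = rng.integers(0, 4, size=500)
        tm = transition_probabilities(self._seg(labels))
        sums = np.nansum(tm.probs, axis=1)
        assert np.allclose(sums[~tm.undefined_rows], 1.0, atol=1e-9)
        assert np.allclose(np.diag(tm.counts), 0.0)


@pytest.fixture(scope="module")
def recording(layout, canon):
    cfg = SyntheticConfig(
        layout=layout,
        templates=canon,
        mean_durations_ms=np.array([80.0, 80.0, 80.0, 70.0]),
        transition_matrix=LOW_CONDITION["transition_matrix"],
        duration_s=20.0,
        seed=21,
        snr_db=10.0,
    )
    return synthesize_recording(cfg)[0]


class TestSegmentationInvariances:
    def test_polarity_invariance(self, layout, canon, recording):
        neg = Recording(data=-recording.data, fs=recording.fs, layout=layout)
        a = backfit(recording, canon)
        b = backfit(neg, canon)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.abs_corr, b.abs_corr)
        assert compute_gev(a, recording, canon) == pytest.approx(
            compute_gev(b, neg, canon)
        )

    def test_scale_invariance(self, layout, canon, recording):
        scaled = Recording(data=3.5 * recording.data, fs=recording.fs, layout=layout)
        a = backfit(recording, canon)
        b = backfit(scaled, canon)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(b.gfp, 3.5 * a.gfp)
        assert compute_gev(a, recording, canon) == pytest.approx(
            compute_gev(b, scaled, canon), rel=1e-9
        )

    def test_gev_nondecreasing_in_k(self, layout, recording):
        peaks = extract_gfp_peak_maps(recording)
        gevs = []
        for k in range(1, 7):
            tset, _, _ = modified_kmeans(peaks, k=k, n_restarts=40, seed=3)
            seg = backfit(recording, tset)
            gevs.append(compute_gev(seg, recording, tset))
        assert all(0.0 <= g <= 1.0 for g in gevs)
        assert all(b >= a - 1e-6 for a, b in zip(gevs, gevs[1:]))
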