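import numpy as np
import pytest

from microstate_lab import (
    EpochSet,
    backfit,
    extract_peak_maps,
    find_gfp_peaks,
    gfp,
    group_templates,
    sort_to_normative,
    spatial_correlation,
    taahc,
)
from microstate_lab.preprocess import average_reference
from microstate_lab.templates import TemplateSet

from oracles import sort_by_exhaustive_search


class TestGfp:
    def test_two_channel_frame(self):
        assert gfp(np.array([1.0, -1.0])) == pytest.approx(1.0)

    def test_constant_frame_is_zero(self):
        assert gfp(np.full(8, 3.7)) == pytest.approx(0.0)

    def test_hand_computed_four_channels(self):
        assert gfp(np.array([2.0, 0.0, -2.0, 0.0])) == pytest.approx(np.sqrt(2.0))

    def test_offset_invariance_and_linearity(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(size=16)
        assert gfp(frame + 5.0) == pytest.approx(gfp(frame))
        assert gfp(3.0 * frame) == pytest.approx(3.0 * gfp(frame))

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            gfp(np.array([1.0]))


class TestFindGfpPeaks:
    def test_hand_case(self):
        assert list(find_gfp_peaks([1, 3, 1, 2, 5, 2])) == [1, 4]

    def test_monotone_curve_has_no_peaks(self):
        assert len(find_gfp_peaks(np.arange(10.0))) == 0

    def test_plateau_counted_once_at_first_sample(self):
        assert list(find_gfp_peaks([1, 2, 2, 1])) == [1]
        assert list(find_gfp_peaks([1, 2, 2, 3, 1])) == [3]

    def test_edges_excluded(self):
        assert list(find_gfp_peaks([5, 1, 2, 1, 5])) == [2]

    def test_min_sep_keeps_larger(self):
        peaks = find_gfp_peaks([0, 3, 0, 4, 0, 1, 0], min_sep=3)
        assert list(peaks) == [3]


class TestSpatialCorrelation:
    def test_self_and_flip(self):
        u = np.array([1.0, 2.0, -3.0, 0.5])
        assert spatial_correlation(u, u) == pytest.approx(1.0)
        assert spatial_correlation(u, -u) == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        r = spatial_correlation(np.array([1.0, 0.0, -1.0]), np.array([0.0, 1.0, -1.0]))
        assert r == pytest.approx(0.5)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spatial_correlation(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))


def orthogonal_generators(montage, k=4, seed=0):
    """k mutually orthogonal zero-mean unit maps via QR."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(montage.n_channels, k))
    a -= a.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(a)
    maps = q.T - q.T.mean(axis=1, keepdims=True)
    return maps / np.linalg.norm(maps, axis=1, keepdims=True)


class TestTaahc:
    def test_noise_free_recovery(self, montage32):
        gens = orthogonal_generators(montage32)
        rng = np.random.default_rng(1)
        which = np.repeat(np.arange(4), 10)
        signs = rng.choice([-1.0, 1.0], size=40)
        scales = rng.uniform(0.5, 2.0, size=40)
        maps = gens[which] * (signs * scales)[:, None]
        templates, assign = taahc(maps, scales, 4, montage=montage32)
        # each centroid matches exactly one generator, partition is exact
        match = np.array(
            [
                [abs(spatial_correlation(c, g)) for g in gens]
                for c in templates.maps
            ]
        )
        best = match.argmax(axis=1)
        assert sorted(best) == [0, 1, 2, 3]
        assert np.all(match.max(axis=1) >= 0.999)
        for slot in range(4):
            assert len(set(which[assign == slot])) == 1

    def test_k_equals_n_maps(self, montage32):
        gens = orthogonal_generators(montage32)
        templates, assign = taahc(gens, np.ones(4), 4, montage=montage32)
        assert sorted(assign) == [0, 1, 2, 3]
        for c in templates.maps:
            assert max(abs(spatial_correlation(c, g)) for g in gens) >= 1 - 1e-9

    def test_polarity_invariance(self, montage32):
        gens = orthogonal_generators(montage32)
        rng = np.random.default_rng(2)
        which = np.repeat(np.arange(4), 8)
        maps = gens[which] + 0.05 * rng.normal(size=(32, 32))
        w = rng.uniform(0.5, 2.0, size=32)
        t1, a1 = taahc(maps, w, 4, montage=montage32)
        t2, a2 = taahc(-maps, w, 4, montage=montage32)
        assert np.array_equal(a1, a2)
        for m1, m2 in zip(t1.maps, t2.maps):
            assert abs(spatial_correlation(m1, m2)) >= 1 - 1e-9

    def test_too_few_maps_rejected(self, montage32):
        gens = orthogonal_generators(montage32)
        with pytest.raises(ValueError):
            taahc(gens[:3], np.ones(3), 4, montage=montage32)

    def test_total_gev_nondecreasing_in_k(self, montage32):
        rng = np.random.default_rng(3)
        gens = orthogonal_generators(montage32)
        which = np.repeat(np.arange(4), 15)
        maps = gens[which] + 0.3 * rng.normal(size=(60, 32)) / np.sqrt(32)
        w = rng.uniform(0.5, 2.0, size=60)
        z = maps - maps.mean(axis=1, keepdims=True)
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        gevs = []
        for k in (2, 3, 4, 5):
            cents, assign = taahc(maps, w, k)
            r = np.einsum("ij,ij->i", z, cents[assign])
            gevs.append(np.sum((w * r) ** 2) / np.sum(w**2))
        assert all(b >= a - 1e-12 for a, b in zip(gevs, gevs[1:]))


class TestGroupTemplates:
    def test_identical_pool_recovered(self, canon32):
        group = group_templates([canon32] * 5, 4)
        for m in group.maps:
            assert max(
                abs(spatial_correlation(m, c)) for c in canon32.maps
            ) >= 1 - 1e-6

    def test_sign_flipped_participants_agree(self, canon32, montage32):
        flipped = TemplateSet(canon32.labels, -canon32.maps, montage32)
        g1 = group_templates([canon32, canon32], 4)
        g2 = group_templates([canon32, flipped], 4)
        for m1 in g1.maps:
            assert max(
                abs(spatial_correlation(m1, m2)) for m2 in g2.maps
            ) >= 1 - 1e-6

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            group_templates([], 4)


class TestSortToNormative:
    def test_recovers_shuffled_order(self, canon32, montage32):
        perm = [2, 0, 3, 1]
        shuffled = TemplateSet(("w", "x", "y", "z"), canon32.maps[perm], montage32)
        out = sort_to_normative(shuffled, canon32)
        assert out.labels == canon32.labels
        assert np.allclose(out.maps, canon32.maps)

    def test_corrects_flipped_polarity(self, canon32, montage32):
        flipped = TemplateSet(canon32.labels, -canon32.maps, montage32)
        out = sort_to_normative(flipped, canon32)
        for i in range(4):
            assert spatial_correlation(out.maps[i], canon32.maps[i]) >= 0.999

    def test_matches_exhaustive_search_oracle(self, montage32, canon32):
        rng = np.random.default_rng(4)
        for trial in range(10):
            maps = rng.normal(size=(4, 32))
            maps -= maps.mean(axis=1, keepdims=True)
            cand = TemplateSet(("1", "2", "3", "4"), maps, montage32)
            out = sort_to_normative(cand, canon32)
            perm, score = sort_by_exhaustive_search(maps, canon32.maps)
            assert np.allclose(np.abs(out.maps), np.abs(maps[list(perm)]))
            achieved = sum(
                abs(spatial_correlation(out.maps[j], canon32.maps[j]))
                for j in range(4)
            )
            assert achieved == pytest.approx(score, abs=1e-9)

    def test_montage_mismatch_rejected(self, canon32):
        from microstate_lab import make_canonical_templates, make_montage

        other = make_canonical_templates(make_montage(16))
        with pytest.raises(ValueError, match="montage"):
            sort_to_normative(other, canon32)


class TestBackfit:
    def test_noise_free_labels_match_truth(self, canon32, noisefree_recording):
        ep, gt = noisefree_recording
        seg = backfit(average_reference(ep), canon32)
        assert (seg.labels == gt.labels).mean() >= 0.99
        assert seg.labels.size == 2500  # 10 epochs x 2 s x 125 Hz

    def test_sign_flip_leaves_labels_unchanged(self, canon32, noisefree_recording):
        ep, _ = noisefree_recording
        seg = backfit(ep, canon32)
        flipped = EpochSet(-ep.data, ep.fs, ep.epoch_s, ep.montage)
        seg2 = backfit(flipped, canon32)
        assert np.array_equal(seg.labels, seg2.labels)

    def test_constant_frames_inherit_previous_label(self, canon32, montage32):
        data = np.zeros((1, 32, 4))
        data[0, :, 1] = canon32.maps[2] * 10
        ep = EpochSet(data, 125.0, 4 / 125.0, montage32)
        seg = backfit(ep, canon32)
        assert seg.labels[0, 0] == 0  # epoch start fallback
        assert seg.labels[0, 2] == seg.labels[0, 1]
        assert seg.n_degenerate == 3

    def test_reproduces_clustering_partition_on_peak_maps(self, montage32):
        # backfitting the clustering's own input maps with its centroids
        # must reproduce the T-AAHC partition when clusters are separated
        gens = orthogonal_generators(montage32, seed=7)
        rng = np.random.default_rng(8)
        which = np.repeat(np.arange(4), 12)
        maps = gens[which] + 0.1 * rng.normal(size=(48, 32)) / np.sqrt(32)
        cents, assign = taahc(maps, np.ones(48), 4)
        sep = np.abs(np.corrcoef(cents))
        np.fill_diagonal(sep, 0)
        assert sep.max() < 0.5
        z = maps - maps.mean(axis=1, keepdims=True)
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        relabel = np.abs(z @ cents.T).argmax(axis=1)
        assert np.array_equal(relabel, assign)


class TestExtractPeakMaps:
    def test_maps_are_centered_and_indexed(self, canon32, noisefree_recording):
        ep, _ = noisefree_recording
        peaks = extract_peak_maps(ep)
        assert peaks.n_maps > 10
        assert np.max(np.abs(peaks.maps.mean(axis=1))) < 1e-9
        for idx in peaks.peak_indices:
            assert list(idx) == sorted(idx)
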