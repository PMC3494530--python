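import numpy as np
import pytest

from seldiflow import (SpecError, Spectrum, cluster_peaks, combine_surfaces,
                       detect_peaks, estimate_noise, extract_intensity_matrix,
                       make_mz_grid)
from seldiflow.peaks import (PeakCandidate, PeakCluster, PeakDetectionParams,
                             detect_and_cluster)
from conftest import make_matrix


def spectrum_from(intensity, lo=1500.0, hi=20000.0, sample_id="s"):
    intensity = np.asarray(intensity, dtype=float)
    mz = np.linspace(lo, hi, len(intensity))
    return Spectrum(sample_id, mz=mz, intensity=intensity)


class TestEstimateNoise:
    def test_gaussian_noise_recovered(self, rng):
        sigma = 2.5
        s = spectrum_from(rng.normal(0, sigma, size=10000))
        est = estimate_noise(s)
        assert np.median(est) == pytest.approx(sigma, rel=0.15)

    def test_all_zero_signal_floors(self):
        est = estimate_noise(spectrum_from(np.zeros(500)))
        np.testing.assert_array_equal(est, 1e-12)

    def test_robust_to_isolated_spike(self, rng):
        base = rng.normal(0, 1.0, size=10000)
        spiked = base.copy()
        spiked[5000] += 500.0
        e0 = estimate_noise(spectrum_from(base))
        e1 = estimate_noise(spectrum_from(spiked))
        assert abs(np.median(e1) - np.median(e0)) / np.median(e0) < 0.05


class TestDetectPeaks:
    def test_flat_spectrum_yields_nothing(self):
        assert detect_peaks(spectrum_from(np.zeros(500)), 5.0) == []

    def test_three_planted_gaussians_found(self, rng):
        mz = make_mz_grid((1500, 20000), 8000)
        sigma_noise = 0.5
        intensity = rng.normal(0, sigma_noise, size=len(mz))
        truth = [3000.0, 7000.0, 15000.0]
        for c in truth:
            w = (c / 400.0) / 2.355
            intensity += 20 * sigma_noise * np.exp(-0.5 * ((mz - c) / w) ** 2)
        cands = detect_peaks(Spectrum("s", mz=mz, intensity=intensity), 5.0)
        strong = [c for c in cands if c.snr >= 5.0]
        assert len(strong) == 3
        for c, t in zip(sorted(x.mz for x in strong), truth):
            assert abs(c - t) / t < 0.001

    def test_threshold_boundary_excludes(self, rng):
        """A candidate whose measured S/N sits just below the threshold is
        dropped; just above, kept."""
        mz = make_mz_grid((1500, 20000), 4000)
        intensity = rng.normal(0, 1.0, size=len(mz))
        w = (5000.0 / 400.0) / 2.355
        intensity += 8.0 * np.exp(-0.5 * ((mz - 5000.0) / w) ** 2)
        s = Spectrum("s", mz=mz, intensity=intensity)
        hits = [c for c in detect_peaks(s, 2.0)
                if abs(c.mz - 5000.0) / 5000.0 < 0.001]
        assert hits, "planted peak not detected at permissive threshold"
        snr = max(h.snr for h in hits)
        above = [c for c in detect_peaks(s, snr + 0.1)
                 if abs(c.mz - 5000.0) / 5000.0 < 0.001]
        below = [c for c in detect_peaks(s, snr - 0.1)
                 if abs(c.mz - 5000.0) / 5000.0 < 0.001]
        assert not above and below


def _cands(mzs):
    return [PeakCandidate(mz=m, height=1.0, snr=10.0) for m in np.atleast_1d(mzs)]


class TestClusterPeaks:
    def test_single_candidate_single_cluster(self):
        params = PeakDetectionParams()
        out = cluster_peaks([_cands(3000.0)], params)
        assert len(out) == 1
        assert out[0].support == 1.0

    def test_separated_candidates_make_two_clusters(self):
        """3000 vs 3012: relative gap 0.4% exceeds the 0.3% window."""
        params = PeakDetectionParams()
        lists = [_cands([3000.0, 3012.0]) for _ in range(10)]
        out = cluster_peaks(lists, params)
        assert len(out) == 2

    def test_support_threshold_discards_rare_clusters(self):
        params = PeakDetectionParams(min_peak_threshold_pct=25.0)
        lists = [_cands(3000.0) for _ in range(10)]
        lists[0] = _cands([3000.0, 8000.0])   # 8000 seen in 10% of spectra
        out = cluster_peaks(lists, params)
        assert [round(c.center_mz) for c in out] == [3000]

    def test_second_pass_updates_support_but_adds_no_clusters(self):
        params = PeakDetectionParams(min_peak_threshold_pct=25.0)
        first = [_cands(3000.0), _cands(3000.0), _cands([]), _cands([])]
        second = [_cands([]), _cands([]), _cands(3001.0), _cands([9000.0])]
        out = cluster_peaks(first, params, second_pass_lists=second)
        assert len(out) == 1
        assert out[0].support == pytest.approx(0.75)

    def test_empty_input_empty_output(self):
        assert cluster_peaks([], PeakDetectionParams()) == []

    def test_cluster_separation_invariant(self, small_cohort):
        from seldiflow import subtract_baseline, tic_normalize
        _, spectra, _, _ = small_cohort
        norm = tic_normalize([subtract_baseline(s, 200.0)[0] for s in spectra],
                             (2000, 20000))
        params = PeakDetectionParams()
        clusters = detect_and_cluster(norm.spectra, params)
        centers = [c.center_mz for c in clusters]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                rel = abs(centers[i] - centers[j]) / np.mean([centers[i],
                                                              centers[j]])
                assert rel > params.cluster_mass_window_pct / 100.0

    def test_raising_first_pass_snr_never_adds_clusters(self, small_cohort):
        from seldiflow import subtract_baseline, tic_normalize
        _, spectra, _, _ = small_cohort
        norm = tic_normalize([subtract_baseline(s, 200.0)[0] for s in spectra],
                             (2000, 20000))
        counts = []
        for snr in (3.0, 5.0, 8.0, 12.0, 20.0):
            params = PeakDetectionParams(first_pass_snr=snr, second_pass_snr=2.0)
            counts.append(len(detect_and_cluster(norm.spectra, params)))
        assert counts == sorted(counts, reverse=True)


class TestExtractMatrix:
    def test_half_min_substitution_rule(self):
        """Raw values (-0.5, 0, 1, 4) become (0.5, 0.5, 1, 4) then log2."""
        n = 101
        spectra = []
        for i, h in enumerate((-0.5, 0.0, 1.0, 4.0)):
            x = np.zeros(n)
            x[50] = h
            spectra.append(spectrum_from(x, lo=2900, hi=3100,
                                         sample_id=f"s{i}"))
        cl = PeakCluster(id="M3000", center_mz=3000.0,
                         window=(2991.0, 3009.0), support=1.0)
        matrix, subs = extract_intensity_matrix(spectra, [cl])
        np.testing.assert_allclose(matrix.values["M3000"],
                                   [-1.0, -1.0, 0.0, 2.0])
        assert subs["M3000"] == pytest.approx(0.5)

    def test_all_positive_no_substitution(self):
        spectra = [spectrum_from(np.full(101, h), lo=2900, hi=3100,
                                 sample_id=f"s{i}")
                   for i, h in enumerate((2.0, 8.0))]
        cl = PeakCluster(id="M3000", center_mz=3000.0,
                         window=(2991.0, 3009.0), support=1.0)
        matrix, _ = extract_intensity_matrix(spectra, [cl])
        np.testing.assert_allclose(matrix.values["M3000"], [1.0, 3.0])

    def test_noiseless_planted_height_is_exact(self):
        x = np.zeros(101)
        x[50] = 8.0
        s = spectrum_from(x, lo=2900, hi=3100)
        cl = PeakCluster(id="M3000", center_mz=3000.0,
                         window=(2991.0, 3009.0), support=1.0)
        matrix, _ = extract_intensity_matrix([s], [cl])
        assert matrix.values["M3000"].iloc[0] == 3.0

    def test_all_nonpositive_cluster_dropped_with_warning(self):
        spectra = [spectrum_from(np.zeros(101), lo=2900, hi=3100,
                                 sample_id=f"s{i}") for i in range(2)]
        for s in spectra:
            s.intensity[10] = 5.0   # keeps a second cluster alive
        clusters = [
            PeakCluster(id="M2920", center_mz=2920.0, window=(2915, 2925),
                        support=1.0),
            PeakCluster(id="M3000", center_mz=3000.0, window=(2991, 3009),
                        support=1.0)]
        with pytest.warns(UserWarning, match="M3000"):
            matrix, _ = extract_intensity_matrix(spectra, clusters)
        assert matrix.cluster_ids == ["M2920"]

    def test_permutation_equivariance(self, rng):
        spectra = [spectrum_from(rng.gamma(2.0, 2.0, size=301), lo=2000,
                                 hi=4000, sample_id=f"s{i}") for i in range(6)]
        cl = PeakCluster(id="M3000", center_mz=3000.0,
                         window=(2991.0, 3009.0), support=1.0)
        m1, _ = extract_intensity_matrix(spectra, [cl])
        perm = [3, 1, 5, 0, 4, 2]
        m2, _ = extract_intensity_matrix([spectra[i] for i in perm], [cl])
        np.testing.assert_array_equal(
            m1.values.to_numpy()[perm], m2.values.to_numpy())


class TestCombineSurfaces:
    def test_column_counts_add(self, rng):
        a = make_matrix(rng.normal(size=(10, 5)), ["cancer"] * 10,
                        surface="CM10")
        b = make_matrix(rng.normal(size=(10, 7)), ["cancer"] * 10,
                        surface="Q10", centers=3000 + 100 * np.arange(7))
        u = combine_surfaces(a, b)
        assert u.values.shape == (10, 12)
        assert u.cluster_ids[0].startswith("CM10:")
        assert u.cluster_ids[-1].startswith("Q10:")

    def test_one_surface_only_sample_dropped(self, rng):
        a = make_matrix(rng.normal(size=(3, 2)), ["cancer"] * 3,
                        sample_ids=["S0", "S1", "S2"], surface="CM10")
        b = make_matrix(rng.normal(size=(2, 2)), ["cancer"] * 2,
                        sample_ids=["S0", "S1"], surface="Q10",
                        centers=[5000, 6000])
        with pytest.warns(UserWarning, match="dropped 1"):
            u = combine_surfaces(a, b)
        assert u.samples["sample_id"].tolist() == ["S0", "S1"]

    def test_values_identical_to_sources(self, rng):
        va, vb = rng.normal(size=(4, 3)), rng.normal(size=(4, 2))
        a = make_matrix(va, ["cancer"] * 4, surface="CM10")
        b = make_matrix(vb, ["cancer"] * 4, surface="Q10",
                        centers=[7000, 8000])
        u = combine_surfaces(a, b)
        np.testing.assert_array_equal(u.values.to_numpy()[:, :3], va)
        np.testing.assert_array_equal(u.values.to_numpy()[:, 3:], vb)

    def test_disjoint_sample_sets_rejected(self, rng):
        a = make_matrix(rng.normal(size=(2, 2)), ["cancer"] * 2,
                        sample_ids=["A0", "A1"], surface="CM10")
        b = make_matrix(rng.normal(size=(2, 2)), ["cancer"] * 2,
                        sample_ids=["B0", "B1"], surface="Q10")
        with pytest.raises(SpecError):
            combine_surfaces(a, b)
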