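"""Cross-spectra, Wilson factorization, conditional GC, permutation
thresholds, dGC rules and pair pooling."""

import numpy as np
import pandas as pd
import pytest

from ecognet.connectivity import (GC_BANDS, conditional_gc, dgc_by_band,
                                  estimate_csd, gc_all_pairs,
                                  permutation_threshold, pool_pairs,
                                  wilson_factorize)
from ecognet.epochs import TrialEpochs
from ecognet.grid import GridSet, make_grid
from ecognet.preprocess import bipolar_derive
from ecognet.synth import VARSpec, analytic_var_gc, simulate_var, \
    var_spectral_matrix, var_transfer


def _resonant3(fs=500.0):
    """X: 40 Hz resonance driving Y; Z independent AR(1)."""
    r, th = 0.85, 2 * np.pi * 40 / fs
    coeffs = np.zeros((2, 3, 3))
    coeffs[0] = [[2 * r * np.cos(th), 0, 0], [0.25, 0.5, 0], [0, 0, 0.5]]
    coeffs[1][0, 0] = -r ** 2
    return VARSpec(channels=[0, 1, 2], coeffs=coeffs, sigma=np.eye(3))


def _chain3():
    coeffs = np.zeros((1, 3, 3))
    coeffs[0] = [[0.5, 0, 0], [0.6, 0.5, 0], [0, 0.6, 0.5]]
    return VARSpec(channels=[0, 1, 2], coeffs=coeffs, sigma=np.eye(3))


def _var_epochs(spec, n_total, n_per_epoch, seed):
    x = simulate_var(spec, n_total, np.random.default_rng(seed))
    k = spec.k
    return x.reshape(k, n_total // n_per_epoch, n_per_epoch).transpose(1, 0, 2)


class TestEstimateCsd:
    def test_independent_noise_has_low_coherence(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((80, 2, 250))
        csd = estimate_csd(data, fs=500.0, n_tapers=5, nw=3)
        coh = csd.coherence()[:, 0, 1]
        # expected null coherence level ~ 1/(epochs*tapers)
        assert np.mean(coh) < 3.0 / (80 * 5) * 2

    def test_identical_signals_fully_coherent(self):
        rng = np.random.default_rng(1)
        sig = rng.standard_normal((40, 1, 250))
        data = np.repeat(sig, 2, axis=1)
        csd = estimate_csd(data, fs=500.0, n_tapers=5, nw=3)
        assert np.all(csd.coherence()[1:-1, 0, 1] > 0.999)

    def test_matches_analytic_var_spectrum(self):
        spec = _resonant3()
        data = _var_epochs(spec, 200_000, 500, seed=2)
        csd = estimate_csd(data, fs=500.0, n_tapers=5, nw=3)
        s_true = var_spectral_matrix(spec.coeffs, spec.sigma, csd.freqs, 500.0)
        # compare autospectra of the resonant channel away from the sharp peak
        p_est, p_true = np.real(csd.s[:, 0, 0]), np.real(s_true[:, 0, 0])
        smooth = np.abs(csd.freqs - 40) > 12
        rel = np.abs(p_est[smooth] - p_true[smooth]) / p_true[smooth]
        assert np.median(rel) < 0.1

    def test_hermitian_psd_structure(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((30, 3, 200))
        csd = estimate_csd(data, fs=500.0, n_tapers=5, nw=3)
        assert np.allclose(csd.s, np.conj(np.swapaxes(csd.s, 1, 2)))
        assert np.linalg.eigvalsh(csd.s).min() > -1e-12

    def test_single_site_rejected(self):
        with pytest.raises(ValueError, match="2 sites"):
            estimate_csd(np.zeros((10, 1, 100)), fs=500.0)


class TestWilsonFactorize:
    def test_identity_spectrum_factorizes_trivially(self):
        s = np.broadcast_to(np.eye(3), (33, 3, 3)).copy().astype(complex)
        fact = wilson_factorize(s)
        assert np.allclose(fact.sigma, np.eye(3), atol=1e-8)
        assert np.allclose(fact.h, np.broadcast_to(np.eye(3), (33, 3, 3)),
                           atol=1e-8)

    def test_recovers_var_innovation_covariance_and_transfer(self):
        spec = _resonant3()
        freqs = np.linspace(0, 250, 257)
        s = var_spectral_matrix(spec.coeffs, spec.sigma, freqs, 500.0)
        fact = wilson_factorize(s)
        assert np.max(np.abs(fact.sigma - np.eye(3))) < 0.01
        h_true = var_transfer(spec.coeffs, freqs, 500.0)
        assert np.max(np.abs(fact.h - h_true)) < 1e-6

    def test_reconstruction_residual_below_1e6(self):
        spec = _chain3()
        freqs = np.linspace(0, 250, 129)
        s = var_spectral_matrix(spec.coeffs, spec.sigma, freqs, 500.0)
        fact = wilson_factorize(s)
        assert fact.residual < 1e-6

    def test_non_psd_input_rejected(self):
        s = np.broadcast_to(-np.eye(2), (17, 2, 2)).copy().astype(complex)
        with pytest.raises((ValueError, RuntimeError)):
            wilson_factorize(s)


class TestConditionalGC:
    def test_independent_sites_near_zero(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((100, 3, 250))
        csd = estimate_csd(data, fs=500.0, n_tapers=5, nw=3)
        for src, tgt in ((0, 1), (2, 0)):
            spec = conditional_gc(csd, src, tgt,
                                  [i for i in range(3) if i not in (src, tgt)])
            assert spec.max() < 0.03

    def test_chain_mediation_suppressed_by_conditioning(self):
        data = _var_epochs(_chain3(), 100_000, 500, seed=5)
        csd = estimate_csd(data, fs=500.0, n_tapers=5, nw=3)
        pw = conditional_gc(csd, 0, 2)
        cond = conditional_gc(csd, 0, 2, conditioning=(1,))
        assert pw.max() > 0.3
        assert cond.max() < 0.1 * pw.max()

    def test_direct_coupling_unaffected_by_independent_conditioning(self):
        data = _var_epochs(_resonant3(), 100_000, 500, seed=6)
        csd = estimate_csd(data, fs=500.0, n_tapers=5, nw=3)
        pw = conditional_gc(csd, 0, 1)
        cond = conditional_gc(csd, 0, 1, conditioning=(2,))
        pk = np.argmax(pw)
        assert cond[pk] == pytest.approx(pw[pk], rel=0.1)

    def test_estimate_matches_analytic_oracle_at_peak(self):
        spec = _resonant3()
        ga = analytic_var_gc(spec, fs=500.0, n_freqs=257)
        pk = int(np.argmax(ga.conditional[(0, 1)]))
        data = _var_epochs(spec, 100_000, 500, seed=7)
        csd = estimate_csd(data, fs=500.0, n_tapers=5, nw=3)
        est = conditional_gc(csd, 0, 1, conditioning=(2,))
        fi = int(np.argmin(np.abs(csd.freqs - ga.freqs[pk])))
        assert est[fi] == pytest.approx(ga.conditional[(0, 1)][pk], rel=0.10)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((60, 3, 200))
        csd = estimate_csd(data, fs=500.0, n_tapers=5, nw=3)
        gcs = gc_all_pairs(csd, conditional=True)
        for spec in gcs.spectra.values():
            assert np.all(spec >= 0)

    def test_gc_vanishes_with_more_epochs(self):
        """Independent channels: GC shrinks toward 0 as epochs grow."""
        rng = np.random.default_rng(9)
        maxima = []
        for n_ep in (25, 100, 400):
            data = rng.standard_normal((n_ep, 2, 200))
            csd = estimate_csd(data, fs=500.0, n_tapers=5, nw=3)
            maxima.append(conditional_gc(csd, 0, 1).max())
        assert maxima[2] < maxima[0]
        assert maxima[2] < 0.02

    def test_source_equals_target_rejected(self):
        rng = np.random.default_rng(10)
        csd = estimate_csd(rng.standard_normal((30, 2, 100)), fs=500.0,
                           n_tapers=5, nw=3)
        with pytest.raises(ValueError):
            conditional_gc(csd, 1, 1)

    def test_bipolar_invariance_to_common_mode(self, small_grid):
        """Adding a common-mode signal to all channels before bipolar
        derivation leaves GC spectra unchanged."""
        rng = np.random.default_rng(11)
        n_tr, n = 60, 300
        data = rng.standard_normal((n_tr, 16, n))
        labels = np.array(["animate", "inanimate"] * (n_tr // 2))
        times = np.arange(n) / 500.0
        ep = TrialEpochs(data=data, fs=500.0, times=times, labels=labels,
                         grid=small_grid)
        common = rng.standard_normal((n_tr, 1, n)) * 3.0
        ep_cm = TrialEpochs(data=data + common, fs=500.0, times=times,
                            labels=labels, grid=small_grid)
        sites = [5, 10]
        a = bipolar_derive(ep, sites).data
        b = bipolar_derive(ep_cm, sites).data
        assert np.allclose(a, b)
        csd_a = estimate_csd(a, fs=500.0, n_tapers=5, nw=3)
        csd_b = estimate_csd(b, fs=500.0, n_tapers=5, nw=3)
        assert np.allclose(conditional_gc(csd_a, 0, 1),
                           conditional_gc(csd_b, 0, 1), atol=1e-10)


class TestPermutationThreshold:
    def test_coupled_direction_exceeds_threshold_only(self):
        coeffs = np.zeros((1, 2, 2))
        coeffs[0] = [[0.5, 0], [0.5, 0.5]]
        spec = VARSpec([0, 1], coeffs, np.eye(2))
        data = _var_epochs(spec, 60 * 250, 250, seed=12)
        csd = estimate_csd(data, fs=500.0, n_tapers=5, nw=3)
        fwd = conditional_gc(csd, 0, 1)
        rev = conditional_gc(csd, 1, 0)
        out = permutation_threshold(data, fs=500.0, n_perm=200, n_tapers=5,
                                    nw=3, seed=0, n_tests=1)
        fmask = csd.freqs <= 150.0
        assert fwd[fmask].max() > out["threshold"][(0, 1)]
        assert rev[fmask].max() < out["threshold"][(1, 0)] * 2.5

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(13)
        data = rng.standard_normal((60, 2, 100))
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_threshold(data, fs=200.0, n_perm=50, n_tapers=3, nw=2,
                                  seed=0)

    def test_bonferroni_threshold_at_least_uncorrected(self):
        rng = np.random.default_rng(14)
        data = rng.standard_normal((60, 2, 100))
        out = permutation_threshold(data, fs=200.0, n_perm=200, n_tapers=3,
                                    nw=2, seed=0, alpha=0.05, n_tests=24)
        for pair in out["threshold"]:
            assert out["threshold"][pair] >= out["threshold_99"][pair]


class TestDgcByBand:
    def _freqs(self):
        return np.linspace(0, 100, 101)

    def test_symmetric_spectra_give_zero_dgc(self):
        f = self._freqs()
        spec = 0.2 * np.exp(-0.5 * ((f - 10) / 3.0) ** 2)
        table = dgc_by_band(spec, spec.copy(), f, 0.01, 0.01)
        alpha = table[table["band"] == "alpha"].iloc[0]
        assert alpha["dgc"] == pytest.approx(0.0, abs=1e-12)

    def test_single_significant_direction_takes_own_value(self):
        f = self._freqs()
        fwd = 0.2 * np.exp(-0.5 * ((f - 11) / 2.0) ** 2)
        rev = np.full_like(f, 0.001)
        table = dgc_by_band(fwd, rev, f, thr_fwd=0.05, thr_rev=0.05,
                            labels=("A", "B"))
        alpha = table[table["band"] == "alpha"].iloc[0]
        assert alpha["direction"] == "A->B"
        # own value at its in-band peak
        assert alpha["dgc"] == pytest.approx(fwd[11], rel=0.05)

    def test_known_peak_asymmetry_equals_hand_computed_difference(self):
        f = self._freqs()
        fwd = 0.3 * np.exp(-0.5 * ((f - 11) / 2.0) ** 2)
        rev = 0.1 * np.exp(-0.5 * ((f - 11) / 2.0) ** 2)
        table = dgc_by_band(fwd, rev, f, 0.01, 0.01, labels=("A", "B"))
        alpha = table[table["band"] == "alpha"].iloc[0]
        assert alpha["direction"] == "A->B"
        # hand-computed: smoothed peak lands on the true peak bin (11 Hz)
        assert alpha["dgc"] == pytest.approx(fwd[11] - rev[11], rel=0.05)

    def test_no_significant_direction_marked_none(self):
        f = self._freqs()
        flat = np.full_like(f, 0.001)
        table = dgc_by_band(flat, flat, f, 0.05, 0.05)
        assert table["direction"].isna().all()

    def test_flat_band_uses_band_average(self):
        f = self._freqs()
        fwd = np.full_like(f, 0.30)
        rev = np.full_like(f, 0.10)
        table = dgc_by_band(fwd, rev, f, 0.01, 0.01)
        beta = table[table["band"] == "beta"].iloc[0]
        assert beta["dgc"] == pytest.approx(0.20)


class TestPoolPairs:
    def test_four_sites_three_subregions(self):
        pools = pool_pairs(["ITC", "STSv", "STSf", "STSf"])
        assert pools.n_inter == 5
        assert pools.n_intra == 1
        assert pools.n_connections == 6
        assert pools.n_band_tests(4) == 24

    def test_pooling_averages_over_doubled_subregion(self):
        pools = pool_pairs(["ITC", "STSv", "STSf", "STSf"])
        f = np.linspace(0, 50, 11)
        spectra = {(i, j): np.full(11, 10 * i + j, dtype=float)
                   for i in range(4) for j in range(4) if i != j}
        pooled = pool_pairs(["ITC", "STSv", "STSf", "STSf"]).pool(spectra)
        # ITC(0) -> STSf(2,3): mean of spectra (0,2) and (0,3)
        assert np.allclose(pooled[("ITC", "STSf")], (2 + 3) / 2)
        assert np.allclose(pooled[("STSf", "ITC")], (20 + 30) / 2)
        assert len(pooled) == 6

    def test_degenerate_labelings_rejected(self):
        with pytest.raises(ValueError):
            pool_pairs(["A", "A", "A", "A"])
        with pytest.raises(ValueError):
            pool_pairs(["A", "B", "C", "D"])
        with pytest.raises(ValueError):
            pool_pairs(["A", "B", "B"])
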