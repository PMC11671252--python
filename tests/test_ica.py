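"""ICA decomposition, component scoring and subnetwork site selection."""

import numpy as np
import pytest

from ecognet.grid import GridSet, make_grid
from ecognet.ica import (amari_index, fit_ica, fit_ica_epochs, score_components,
                         select_sites, source_epochs, topography)
from ecognet.synth import EffectSpec, SynthConfig, simulate_session


def _mixture(seed=0, n=20000):
    """Known 4-source mixture with super- and sub-Gaussian sources."""
    rng = np.random.default_rng(seed)
    s = np.vstack([
        rng.laplace(size=n),
        rng.laplace(size=n),
        rng.uniform(-np.sqrt(3), np.sqrt(3), size=n),
        np.sign(np.sin(2 * np.pi * 13 * np.arange(n) / 500)),   # sub-Gaussian
    ])
    a = rng.standard_normal((4, 4))
    return a @ s, a, s


class TestFitICA:
    def test_known_mixture_recovered(self):
        x, a_true, _ = _mixture()
        d = fit_ica(x, seed=1)
        assert amari_index(d.unmixing, a_true) < 0.1

    def test_square_decomposition_and_inverse_consistency(self):
        x, _, _ = _mixture(seed=2)
        d = fit_ica(x, seed=0)
        assert d.n_components == 4
        assert np.max(np.abs(d.mixing @ d.unmixing - np.eye(4))) < 1e-6
        assert np.max(np.abs(d.reconstruct() - x)) < 1e-8

    def test_sources_mutually_uncorrelated(self):
        x, _, _ = _mixture(seed=3)
        d = fit_ica(x, seed=0)
        cc = np.corrcoef(d.sources)
        assert np.max(np.abs(cc - np.eye(4))) < 0.05

    def test_rank_deficient_input_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 500))
        x = np.vstack([x, x[0] + x[1]])
        with pytest.raises(ValueError, match="rank"):
            fit_ica(x, seed=0)

    def test_more_channels_than_samples_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            fit_ica(np.zeros((10, 5)), seed=0)

    def test_deterministic_given_seed(self):
        x, _, _ = _mixture(seed=4, n=5000)
        d1 = fit_ica(x, seed=9)
        d2 = fit_ica(x, seed=9)
        assert np.array_equal(d1.unmixing, d2.unmixing)


class TestTopography:
    def test_single_channel_source_gives_indicator_map(self):
        rng = np.random.default_rng(5)
        n = 8000
        x = rng.standard_normal((3, n)) * 0.01
        x[2] += rng.laplace(size=n) * 5          # one strong source, one channel
        d = fit_ica(x, seed=0)
        comp = int(np.argmax([topography(d, j)[2] for j in range(3)]))
        topo = topography(d, comp)
        assert np.argmax(topo) == 2
        assert topo[2] > 5 * np.sort(topo)[-2]

    def test_sign_flip_leaves_topography_unchanged(self):
        x, _, _ = _mixture(seed=6, n=5000)
        d = fit_ica(x, seed=0)
        topo = topography(d, 1)
        d.mixing[:, 1] *= -1
        assert np.allclose(np.abs(d.mixing[:, 1]), topo)

    def test_unit_norm_with_positive_max(self):
        x, _, _ = _mixture(seed=7, n=5000)
        d = fit_ica(x, seed=0)
        for j in range(4):
            col = d.mixing[:, j]
            assert np.linalg.norm(col) == pytest.approx(1.0)
            assert col[np.argmax(np.abs(col))] > 0

    def test_invalid_component_rejected(self):
        x, _, _ = _mixture(seed=8, n=4000)
        d = fit_ica(x, seed=0)
        with pytest.raises(IndexError):
            topography(d, 4)


@pytest.fixture(scope="module")
def subnetwork_session():
    """Planted coherent band-limited source on channels 5, 6, 9, 10 with
    category-dependent power, overlapping the low-resolution target
    frequencies (12 and 16 Hz)."""
    grid = GridSet([make_grid(4, 4, 2.5, "A")])
    eff = EffectSpec(channels=[5, 6, 9, 10], band=(10, 20), window=(0.1, 1.6),
                     amplitude=3.0,
                     category_gain={"animate": 2.5, "inanimate": 1.0},
                     shared=True)
    cfg = SynthConfig(grid=grid, n_trials=80, epoch_window=(-0.7, 2.4),
                      effects=[eff], seed=31)
    ep = simulate_session(cfg)
    return ep, grid, fit_ica_epochs(ep, seed=0)


class TestScoring:
    def test_planted_component_ranked_first_and_localized(self, subnetwork_session):
        ep, grid, d = subnetwork_session
        scores = score_components(d, ep, n_perm=0, seed=0)
        best = max(scores, key=lambda s: s.decoding_value)
        assert best.decoding_value > 0.65
        others = sorted(s.decoding_value for s in scores)[:-1]
        assert best.decoding_value > max(others) + 0.05
        topo = topography(d, best.component)
        top4 = set(np.argsort(topo)[-4:])
        jac = len(top4 & {5, 6, 9, 10}) / len(top4 | {5, 6, 9, 10})
        assert jac >= 0.5

    def test_permutation_flags_effect_not_noise(self):
        """On a 4-channel session, the planted component is informative
        after Bonferroni while pure-noise components get adjusted p ~ 1."""
        grid = GridSet([make_grid(2, 2, 2.5, "A")])
        eff = EffectSpec(channels=[0, 1], band=(10, 20), window=(0.1, 1.6),
                         amplitude=3.0,
                         category_gain={"animate": 2.5, "inanimate": 1.0},
                         shared=True)
        cfg = SynthConfig(grid=grid, n_trials=40, epoch_window=(-0.7, 2.4),
                          effects=[eff], seed=33)
        ep = simulate_session(cfg)
        d = fit_ica_epochs(ep, seed=0)
        scores = score_components(d, ep, n_perm=100, seed=0)
        best = max(scores, key=lambda s: s.decoding_value)
        assert best.informative
        worst = min(scores, key=lambda s: s.decoding_value)
        assert worst.p_adjusted > 0.5

    def test_source_epochs_shape(self, subnetwork_session):
        ep, _, d = subnetwork_session
        src = source_epochs(d, ep)
        assert src.data.shape == ep.data.shape


class TestSelectSites:
    def test_order_statistics_bound(self):
        grid = GridSet([make_grid(8, 16, 2.5, "TC"), make_grid(8, 8, 2.5, "dmPFC")])
        rng = np.random.default_rng(0)
        topo = rng.uniform(size=192)
        thr = np.percentile(topo, 95)
        assert np.sum(topo > thr) <= int(np.ceil(0.05 * 192))

    def test_planted_subnetwork_channels_selected(self, subnetwork_session):
        ep, grid, d = subnetwork_session
        scores = score_components(d, ep, n_perm=0, seed=0)
        best = max(scores, key=lambda s: s.decoding_value)
        sites = select_sites(topography(d, best.component), grid, n_sites=2)
        assert set(sites) <= {5, 6, 9, 10}

    def test_uniform_topography_yields_empty_set(self, small_grid):
        with pytest.warns(UserWarning, match="percentile"):
            sites = select_sites(np.ones(16), small_grid)
        assert sites == []

    def test_fewer_candidates_than_requested_warns(self, small_grid):
        topo = np.zeros(16)
        topo[5] = 1.0
        with pytest.warns(UserWarning, match="candidate"):
            sites = select_sites(topo, small_grid, n_sites=4)
        assert sites == [5]
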