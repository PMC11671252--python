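"""ICA decomposition of concatenated epochs and subnetwork site selection.

Trials are concatenated into a continuous channels x time matrix and
decomposed into as many statistically independent sources as channels via
a square unmixing matrix U (sources S = U X); the mixing matrix M = U^-1
back-projects each component onto the electrodes, and the absolute values
of a component's column of M form its topography.  Components are scored
by category decoding of their low-resolution time-frequency power, with a
label-permutation null and Bonferroni (default) or FDR correction across
components; the most informative component's topography selects the sites
entering the connectivity analysis (channels above the 95th percentile of
all channels jointly, thinned to grid-local maxima).

Component sign and scale are fixed by giving each topography unit norm
with a positive maximal element, so decompositions are reproducible given
the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import kurtosis
from sklearn.decomposition import FastICA

from .decoding import decode_point
from .epochs import TrialEpochs
from .grid import GridSet
from .spectral import LOW_RES, multitaper_tfr

__all__ = ["ICDecomposition", "ICScore", "fit_ica", "fit_ica_epochs",
           "topography", "source_epochs", "score_components", "select_sites",
           "flag_noise_components", "amari_index"]


@dataclass
class ICDecomposition:
    """Square ICA decomposition X(t) = M S(t) + mean.

    ``unmixing`` (U) maps centered channels to sources; ``mixing`` (M) is
    its inverse; ``sources`` is components x time.
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    sources: np.ndarray
    mean: np.ndarray
    n_channels: int

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.mixing @ self.sources + self.mean[:, None]


@dataclass
class ICScore:
    """Decoding-based informativeness of one component."""

    component: int
    decoding_value: float
    p_raw: float | None = None
    p_adjusted: float | None = None
    informative: bool = False


def fit_ica(continuous: np.ndarray, seed: int | None = 0,
            max_iter: int = 500, tol: float = 1e-4) -> ICDecomposition:
    """Square ICA of a channels x time matrix.

    The data are centered and whitened internally and decomposed into as
    many components as channels.  Rank-deficient input is rejected (the
    mixing matrix must be invertible).  The decomposition is deterministic
    given ``seed``; the contrast function handles both sub- and
    super-Gaussian sources.
    """
    x = np.asarray(continuous, dtype=float)
    if x.ndim != 2:
        raise ValueError("continuous data must be channels x time")
    n_ch, n_t = x.shape
    if n_ch > n_t:
        raise ValueError(f"more channels ({n_ch}) than samples ({n_t})")
    sv = np.linalg.svd(x - x.mean(axis=1, keepdims=True), compute_uv=False)
    rank = int(np.sum(sv > sv[0] * max(n_ch, n_t) * np.finfo(float).eps))
    if rank < n_ch:
        raise ValueError(f"rank-deficient input: rank {rank} < {n_ch} channels")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings handled via diagnostics
        ica = FastICA(n_components=n_ch, whiten="unit-variance",
                      random_state=seed, max_iter=max_iter, tol=tol)
        sources = ica.fit_transform(x.T).T          # (components, time)
    unmixing = ica.components_                       # centered X -> S
    mixing = np.linalg.inv(unmixing)

    # canonical sign/scale: unit-norm topography, positive maximal element
    for j in range(n_ch):
        col = mixing[:, j]
        scale = np.linalg.norm(col)
        sign = np.sign(col[np.argmax(np.abs(col))]) or 1.0
        mixing[:, j] = col / (scale * sign)
        unmixing[j, :] *= scale * sign
        sources[j, :] *= scale * sign

    return ICDecomposition(unmixing=unmixing, mixing=mixing, sources=sources,
                           mean=ica.mean_, n_channels=n_ch)


def fit_ica_epochs(epochs: TrialEpochs, seed: int | None = 0,
                   max_iter: int = 500) -> ICDecomposition:
    """Concatenate trials along time and fit the square ICA."""
    x = np.transpose(epochs.data, (1, 0, 2)).reshape(epochs.n_channels, -1)
    return fit_ica(x, seed=seed, max_iter=max_iter)


def topography(decomp: ICDecomposition, component: int) -> np.ndarray:
    """Per-channel absolute back-projection weight of one component (the
    absolute values of its column of the mixing matrix)."""
    if not (0 <= component < decomp.n_components):
        raise IndexError(f"component {component} out of range")
    return np.abs(decomp.mixing[:, component])


def source_epochs(decomp: ICDecomposition, epochs: TrialEpochs) -> TrialEpochs:
    """Re-epoch continuous sources on the trial structure of ``epochs``."""
    s = decomp.sources.reshape(decomp.n_components, epochs.n_trials,
                               epochs.n_samples)
    data = np.transpose(s, (1, 0, 2))
    return epochs.copy_with(data, keep_grid=False,
                            note=f"source_epochs: {decomp.n_components} components")


def _component_features(src_epochs: TrialEpochs,
                        value_window: tuple[float, float]) -> list[list[np.ndarray]]:
    """Per-component, per-target-frequency power feature matrices over the
    value window (computed once; label permutations reuse them)."""
    tfr = multitaper_tfr(src_epochs, LOW_RES)
    tmask = (tfr.times >= value_window[0]) & (tfr.times <= value_window[1])
    if not tmask.any():
        raise ValueError(f"value window {value_window} outside TFR grid")
    return [[tfr.power[:, c, fi, :][:, tmask] for fi in range(tfr.n_freqs)]
            for c in range(src_epochs.n_channels)]


def _decoding_values(features: list[list[np.ndarray]], labels: np.ndarray,
                     n_folds: int, seed: int | None) -> np.ndarray:
    """Mean low-resolution decoding accuracy per component across the six
    target frequencies."""
    values = np.empty(len(features))
    for c, per_freq in enumerate(features):
        accs = [decode_point(x, labels, n_folds=n_folds, seed=seed).accuracy
                for x in per_freq]
        values[c] = np.mean(accs)
    return values


def score_components(decomp: ICDecomposition, epochs: TrialEpochs,
                     labels: np.ndarray | None = None, n_perm: int = 1000,
                     value_window: tuple[float, float] = (0.300, 2.050),
                     n_folds: int = 5, seed: int | None = 0,
                     correction: str = "bonferroni", alpha: float = 0.05
                     ) -> list[ICScore]:
    """Score every component by category decoding with a permutation null.

    The decoding value is the mean low-resolution accuracy over the value
    window across the six target frequencies.  With ``n_perm > 0`` labels
    are shuffled before training to build a per-component null; p-values
    are Bonferroni-corrected across components by default
    (``correction="fdr"`` switches to Benjamini-Hochberg).  With
    ``n_perm=0`` only the decoding values are returned (ranking use).
    """
    y = np.asarray(labels) if labels is not None else epochs.labels
    src = source_epochs(decomp, epochs)
    features = _component_features(src, value_window)
    values = _decoding_values(features, y, n_folds, seed)
    n_comp = values.size

    scores = [ICScore(component=c, decoding_value=float(values[c]))
              for c in range(n_comp)]
    if n_perm <= 0:
        return scores

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_comp)
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        perm_vals = _decoding_values(features, y_perm, n_folds, seed)
        exceed += perm_vals >= values
    p_raw = (1.0 + exceed) / (1.0 + n_perm)

    if correction == "bonferroni":
        p_adj = np.minimum(p_raw * n_comp, 1.0)
    elif correction == "fdr":
        from .decoding import fdr_bh
        _, p_adj = fdr_bh(p_raw, q=alpha)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    for c, sc in enumerate(scores):
        sc.p_raw = float(p_raw[c])
        sc.p_adjusted = float(p_adj[c])
        sc.informative = bool(p_adj[c] < alpha)
    return scores


def select_sites(topo: np.ndarray, grid: GridSet, percentile: float = 95.0,
                 n_sites: int = 4) -> list[int]:
    """Connectivity sites from a topography.

    Channels whose weight strictly exceeds the given percentile of all
    channels (both arrays jointly) are candidates; these are thinned to
    4-neighbor local maxima on their grid, and the ``n_sites`` strongest
    are returned (all candidates, with a warning, if fewer remain).  A
    uniform topography yields an empty list.
    """
    grid = GridSet.coerce(grid)
    topo = np.asarray(topo, dtype=float)
    if topo.size != grid.n_channels:
        raise ValueError("topography length must equal channel count")
    thr = np.percentile(topo, percentile)
    candidates = np.flatnonzero(topo > thr)
    if candidates.size == 0:
        warnings.warn("no channel strictly exceeds the percentile "
                      "(degenerate/uniform topography)", stacklevel=2)
        return []

    peaks = []
    for ch in candidates:
        array_id, r, c = grid.position(ch)
        g = grid.grid(array_id)
        is_peak = True
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < g.rows and 0 <= cc < g.cols:
                if topo[grid.global_channel(array_id, rr, cc)] > topo[ch]:
                    is_peak = False
                    break
        if is_peak:
            peaks.append(int(ch))
    if not peaks:
        peaks = [int(ch) for ch in candidates]
    peaks.sort(key=lambda ch: -topo[ch])
    if len(peaks) < n_sites:
        warnings.warn(f"only {len(peaks)} candidate sites (requested {n_sites})",
                      stacklevel=2)
        return peaks
    return peaks[:n_sites]


def flag_noise_components(decomp: ICDecomposition, epochs: TrialEpochs,
                          kurtosis_threshold: float = 15.0,
                          dominance_threshold: float = 0.5,
                          manual: Sequence[int] = ()) -> np.ndarray:
    """Automated artifact-component screen.

    Flags components whose source activity has extreme excess kurtosis
    (irregular high-voltage events) or whose variance is dominated by a
    single trial (trial artifacts); ``manual`` adds explicit overrides.
    Returns a boolean mask over components.
    """
    src = source_epochs(decomp, epochs)
    n_comp = decomp.n_components
    mask = np.zeros(n_comp, dtype=bool)
    for c in range(n_comp):
        k = kurtosis(decomp.sources[c])
        trial_var = src.data[:, c, :].var(axis=1)
        dominance = trial_var.max() / max(trial_var.sum(), np.finfo(float).tiny)
        mask[c] = (k > kurtosis_threshold) or (dominance > dominance_threshold)
    mask[list(manual)] = True
    return mask


def amari_index(w: np.ndarray, a_true: np.ndarray) -> float:
    """Amari permutation-invariant separation error of an unmixing matrix
    ``w`` against the true mixing matrix ``a_true`` (0 = perfect, normalized
    to [0, 1] by ``2 n (n - 1)``)."""
    p = np.abs(w @ a_true)
    n = p.shape[0]
    rows = np.sum(p / p.max(axis=1, keepdims=True), axis=1) - 1
    cols = np.sum(p / p.max(axis=0, keepdims=True), axis=0) - 1
    return float((rows.sum() + cols.sum()) / (2 * n * (n - 1)))
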