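"""Frequency-resolved conditional Granger causality between selected sites.

The estimation chain is fully nonparametric: a multitaper cross-spectral
density (CSD) matrix is estimated from trial epochs, factorized into a
minimum-phase transfer function and innovation covariance by Wilson's
iterative algorithm, and Geweke's spectral Granger-causality (GC) measures
are evaluated from the factors.  Conditional GC uses the two-factorization
construction (full site set versus the set without the source), which
distinguishes direct influences from ones mediated by the conditioning
sites.  Significance comes from a permutation scheme that shuffles epoch
indices independently per site, destroying cross-site alignment while
preserving each site's marginal spectrum; the band-wise directionality
statistic (dGC) summarizes each significant connection.

Conventions
-----------
* CSDs live on a uniform frequency grid from 0 to Nyquist inclusive (the
  factorization requires the full half-circle even when only a sub-range,
  e.g. 0--150 Hz, is reported).
* GC spectra are nonnegative; tiny negative values from finite-precision
  factorization are clipped to zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import windows

from .epochs import TrialEpochs

__all__ = [
    "CrossSpectralDensity",
    "SpectralFactorization",
    "GCSpectra",
    "GC_BANDS",
    "estimate_csd",
    "wilson_factorize",
    "conditional_gc",
    "gc_all_pairs",
    "permutation_threshold",
    "dgc_by_band",
    "pool_pairs",
    "PooledPairs",
]

#: Frequency bands for the band-wise directionality table (Hz).
GC_BANDS: dict[str, tuple[float, float]] = {
    "theta": (5.0, 8.0),
    "alpha": (9.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (31.0, 70.0),
}


@dataclass
class CrossSpectralDensity:
    """Taper- and epoch-averaged cross-spectral matrix per frequency.

    ``s`` has shape ``(n_freqs, n_sites, n_sites)``; each slice is Hermitian
    with real nonnegative diagonal.  The grid spans 0..Nyquist uniformly.
    """

    s: np.ndarray
    freqs: np.ndarray
    fs: float
    n_tapers: int
    n_epochs: int
    window: tuple[float, float] | None = None
    site_labels: list[str] | None = None

    @property
    def n_sites(self) -> int:
        return self.s.shape[1]

    def coherence(self) -> np.ndarray:
        """Magnitude-squared coherence, same shape as ``s`` (diagnostic)."""
        p = np.real(np.einsum("fii->fi", self.s))
        denom = p[:, :, None] * p[:, None, :]
        return np.abs(self.s) ** 2 / np.maximum(denom, np.finfo(float).tiny)


@dataclass
class SpectralFactorization:
    """Minimum-phase factorization S(f) = H(f) Sigma H(f)*."""

    h: np.ndarray          # (n_freqs, m, m) complex, H(0 lag) normalized to I
    sigma: np.ndarray      # (m, m) real symmetric positive definite
    n_iter: int
    residual: float        # max relative reconstruction error over frequencies
    converged: bool


@dataclass
class GCSpectra:
    """GC spectra per ordered site pair with significance metadata."""

    freqs: np.ndarray
    spectra: dict[tuple[int, int], np.ndarray]
    site_labels: list[str] | None = None
    thresholds: dict[tuple[int, int], float] = field(default_factory=dict)
    band_table: pd.DataFrame | None = None


def _dpss_tapers(n: int, n_tapers: int, nw: float | None) -> np.ndarray:
    if nw is None:
        nw = (n_tapers + 1) / 2.0  # K = 2NW - 1 convention
    if n_tapers > 2 * nw - 1 + 1e-9:
        raise ValueError(f"{n_tapers} tapers exceed 2*NW-1 for NW={nw}")
    return windows.dpss(n, nw, Kmax=n_tapers)


def estimate_csd(epochs: TrialEpochs | np.ndarray, *, sites: Sequence[int] | None = None,
                 window: tuple[float, float] = (0.0, 1.0), n_tapers: int = 15,
                 nw: float | None = None, fs: float | None = None,
                 site_labels: list[str] | None = None) -> CrossSpectralDensity:
    """Multitaper cross-spectral density of selected sites.

    Parameters
    ----------
    epochs:
        :class:`TrialEpochs`, or a raw ``(n_epochs, n_sites, n_samples)``
        array (then ``fs`` is required and ``window`` ignored).
    sites:
        Channel indices to include (defaults to all).
    window:
        Analysis window in seconds (default 0--1 s after stimulus onset).
    n_tapers:
        Number of Slepian tapers (default 15, i.e. NW = 8).
    """
    if isinstance(epochs, TrialEpochs):
        idx = epochs.time_indices(window, inclusive=False)
        if idx.size == 0:
            raise ValueError(f"window {window} outside epoch")
        data = epochs.data[:, :, idx]
        fs = epochs.fs
    else:
        data = np.asarray(epochs)
        if fs is None:
            raise ValueError("fs required for raw-array input")
    if sites is not None:
        data = data[:, np.asarray(sites, dtype=int), :]
    n_ep, m, n = data.shape
    if m < 2:
        raise ValueError("need at least 2 sites for cross-spectra")

    tapers = _dpss_tapers(n, n_tapers, nw)               # (K, n)
    x = np.fft.rfft(data[:, None, :, :] * tapers[None, :, None, :], axis=-1)
    # x: (epochs, tapers, sites, F); average outer products over epochs+tapers
    s = np.einsum("ekif,ekjf->fij", x, np.conj(x)) / (n_ep * tapers.shape[0])
    s = 0.5 * (s + np.conj(np.swapaxes(s, 1, 2)))        # enforce Hermitian
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return CrossSpectralDensity(s=s, freqs=freqs, fs=fs, n_tapers=tapers.shape[0],
                                n_epochs=n_ep, window=window, site_labels=site_labels)


# ---------------------------------------------------------------------------
# Wilson's spectral matrix factorization
# ---------------------------------------------------------------------------

def _plus_operator(g: np.ndarray, n_half: int) -> np.ndarray:
    """Causal ('plus') part of a spectral matrix function on the full circle:
    keep nonnegative lags, halve the zero lag keeping its upper triangle."""
    gam = np.fft.ifft(g, axis=0)
    beta0 = 0.5 * gam[0]
    m = beta0.shape[0]
    beta0[np.tril_indices(m, k=-1)] = 0.0
    gam[0] = beta0
    gam[n_half:] = 0.0
    return np.fft.fft(gam, axis=0)


def wilson_factorize(csd: CrossSpectralDensity | np.ndarray, *, tol: float = 1e-9,
                     max_iter: int = 1000, ridge: float = 0.0,
                     residual_tol: float = 1e-2) -> SpectralFactorization:
    """Wilson's iterative minimum-phase factorization of a CSD.

    The input spectrum must cover a uniform grid from 0 to Nyquist
    inclusive.  Iteration stops when the maximum change of the spectral
    factor falls below ``tol`` relative to its magnitude, or when the
    change stalls (spectra with sharp peaks admit only grid-limited
    accuracy, because the exact factor's impulse response outruns the
    half-circle lag support; analytic/smooth spectra reach ``tol``).  A
    ``RuntimeError`` is raised if the relative reconstruction error still
    exceeds ``residual_tol`` when iteration ends.  Near-singular spectra
    can be regularized by adding ``ridge * mean(diag)`` to the diagonal.
    """
    s_half = csd.s if isinstance(csd, CrossSpectralDensity) else np.asarray(csd)
    f_count, m, _ = s_half.shape
    if f_count < 2:
        raise ValueError("need at least 2 frequencies")
    s_half = s_half.astype(complex)
    if ridge > 0:
        lam = ridge * float(np.mean(np.real(np.einsum("fii->fi", s_half))))
        s_half = s_half + lam * np.eye(m)[None, :, :]

    n_full = 2 * (f_count - 1)
    s_full = np.empty((n_full, m, m), dtype=complex)
    s_full[:f_count] = s_half
    s_full[f_count:] = np.conj(s_half[-2:0:-1])

    gam = np.real(np.fft.ifft(s_full, axis=0))
    gam0 = gam[0]
    # initialize with the (upper) Cholesky factor of the lag-0 covariance
    scale = np.mean(np.diag(gam0))
    try:
        chol = np.linalg.cholesky(gam0 + 1e-12 * scale * np.eye(m))
    except np.linalg.LinAlgError as err:
        raise ValueError("CSD is not positive semidefinite; cannot factorize") from err
    psi = np.broadcast_to(chol.T.astype(complex), (n_full, m, m)).copy()

    eye = np.eye(m)
    converged = False
    n_iter = 0
    best_delta = np.inf
    stall = 0
    for n_iter in range(1, max_iter + 1):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ s_full @ np.conj(np.swapaxes(psi_inv, 1, 2)) + eye
        g_plus = _plus_operator(g, f_count)
        psi_new = psi @ g_plus
        delta = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-300)
        psi = psi_new
        if delta < tol:
            converged = True
            break
        if delta < 0.99 * best_delta:
            best_delta, stall = delta, 0
        else:
            stall += 1
            if stall >= 20:   # grid-limited accuracy floor reached
                break

    a0 = np.real(np.fft.ifft(psi, axis=0)[0])
    sigma = a0 @ a0.T
    h = psi[:f_count] @ np.linalg.inv(a0)

    recon = psi[:f_count] @ np.conj(np.swapaxes(psi[:f_count], 1, 2))
    denom = max(np.max(np.abs(s_half)), np.finfo(float).tiny)
    residual = float(np.max(np.abs(recon - s_half)) / denom)
    if residual > residual_tol:
        raise RuntimeError(
            f"Wilson factorization failed after {n_iter} iterations "
            f"(relative reconstruction residual {residual:.2e})"
        )
    return SpectralFactorization(h=h, sigma=sigma, n_iter=n_iter,
                                 residual=residual, converged=converged)


def _wilson_batch(s_half: np.ndarray, *, tol: float = 1e-8, max_iter: int = 200
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Factorize a batch of CSDs ``(B, F, m, m)`` simultaneously.

    Same iteration as :func:`wilson_factorize` vectorized over the batch
    axis (used for permutation nulls); returns ``(h, sigma)`` with shapes
    ``(B, F, m, m)`` and ``(B, m, m)``.  Convergence is tracked by the
    worst batch member, with the same stall handling.
    """
    b, f_count, m, _ = s_half.shape
    n_full = 2 * (f_count - 1)
    s_full = np.empty((b, n_full, m, m), dtype=complex)
    s_full[:, :f_count] = s_half
    s_full[:, f_count:] = np.conj(s_half[:, -2:0:-1])

    gam0 = np.real(np.fft.ifft(s_full, axis=1))[:, 0]
    scale = np.mean(np.einsum("bii->bi", gam0), axis=1)
    chol = np.linalg.cholesky(gam0 + (1e-12 * scale)[:, None, None] * np.eye(m))
    psi = np.broadcast_to(np.conj(np.swapaxes(chol, 1, 2))[:, None].astype(complex),
                          (b, n_full, m, m)).copy()

    eye = np.eye(m)
    best_delta, stall = np.inf, 0
    for _ in range(max_iter):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ s_full @ np.conj(np.swapaxes(psi_inv, 2, 3)) + eye
        gam = np.fft.ifft(g, axis=1)
        beta0 = 0.5 * gam[:, 0]
        beta0[:, np.tril_indices(m, k=-1)[0], np.tril_indices(m, k=-1)[1]] = 0.0
        gam[:, 0] = beta0
        gam[:, f_count:] = 0.0
        psi_new = psi @ np.fft.fft(gam, axis=1)
        delta = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-300)
        psi = psi_new
        if delta < tol:
            break
        if delta < 0.99 * best_delta:
            best_delta, stall = delta, 0
        else:
            stall += 1
            if stall >= 20:
                break

    a0 = np.real(np.fft.ifft(psi, axis=1)[:, 0])
    sigma = a0 @ np.swapaxes(a0, 1, 2)
    h = psi[:, :f_count] @ np.linalg.inv(a0)[:, None]
    return h, sigma


def _csd_batch(x0: np.ndarray, perm_idx: np.ndarray) -> np.ndarray:
    """CSDs of per-site epoch-permuted data from precomputed tapered FFTs.

    The tapered FFT of each epoch is permutation-invariant; only the
    cross-site epoch pairing changes, so ``x0`` ``(n_ep, K, m, F)`` is
    computed once and gathered here.  ``perm_idx`` is ``(B, m, n_ep)``
    epoch orderings per site; returns ``(B, F, m, m)``.
    """
    b, m, n_ep = perm_idx.shape
    k, f_count = x0.shape[1], x0.shape[3]
    norm = n_ep * k
    s = np.empty((b, f_count, m, m), dtype=complex)
    xs = [x0[perm_idx[:, j, :], :, j, :] for j in range(m)]   # each (B, ep, K, F)
    for i in range(m):
        for j in range(i, m):
            sij = np.einsum("bekf,bekf->bf", xs[i], np.conj(xs[j])) / norm
            s[:, :, i, j] = sij
            if i != j:
                s[:, :, j, i] = np.conj(sij)
            else:
                s[:, :, i, i] = np.real(sij)
    return s


# ---------------------------------------------------------------------------
# Geweke spectral GC from factorizations
# ---------------------------------------------------------------------------

def _pairwise_gc(s_pair: np.ndarray, fact: SpectralFactorization) -> np.ndarray:
    """Unconditional GC 0 -> 1 for a two-site CSD and its factorization."""
    h, sigma = fact.h, fact.sigma
    s_tt = np.real(s_pair[:, 1, 1])
    sig_cond = sigma[0, 0] - sigma[0, 1] ** 2 / sigma[1, 1]
    intrinsic = s_tt - sig_cond * np.abs(h[:, 1, 0]) ** 2
    intrinsic = np.maximum(intrinsic, np.finfo(float).tiny)
    return np.maximum(np.log(np.maximum(s_tt, np.finfo(float).tiny) / intrinsic), 0.0)


def _conditional_gc_from_factors(full_fact: SpectralFactorization,
                                 red_fact: SpectralFactorization,
                                 red_positions: np.ndarray,
                                 src_pos: int, tgt_pos: int) -> np.ndarray:
    """Conditional GC src -> tgt given the factorizations of the full site
    set and of the reduced set (full minus source).

    ``red_positions`` gives, for each variable of the reduced factorization,
    its position in the full ordering.  The whitening filter of the reduced
    system is embedded (identity at the source position), the full transfer
    is passed through it (Q = G~^{-1} H), and the source's innovation --
    partialized against all other innovations -- yields the causal term.
    """
    h, sigma = full_fact.h, full_fact.sigma
    g = red_fact.h
    f_count, m, _ = h.shape

    # embed the reduced minimum-phase transfer at the reduced positions,
    # identity at the source position; G^{-1} V is the reduced-model residual
    g_full_form = np.zeros((f_count, m, m), dtype=complex)
    g_full_form[:, np.arange(m), np.arange(m)] = 1.0
    g_full_form[np.ix_(np.arange(f_count), red_positions, red_positions)] = g

    q = np.linalg.solve(g_full_form, h)
    qsq = np.real(np.einsum("fij,jk,fik->fi", q, sigma, np.conj(q)))
    total = qsq[:, tgt_pos]

    others = [i for i in range(m) if i != src_pos]
    sig_oo = sigma[np.ix_(others, others)]
    sig_so = sigma[src_pos, others]
    sig_cond = sigma[src_pos, src_pos] - sig_so @ np.linalg.solve(sig_oo, sig_so)
    causal = np.abs(q[:, tgt_pos, src_pos]) ** 2 * sig_cond
    intrinsic = np.maximum(total - causal, np.finfo(float).tiny)
    return np.maximum(np.log(np.maximum(total, np.finfo(float).tiny) / intrinsic), 0.0)


def _gc_from_csd_matrix(s: np.ndarray, freqs: np.ndarray, src: int, tgt: int,
                        conditioning: Sequence[int] = (), *, tol: float = 1e-9,
                        max_iter: int = 1000) -> np.ndarray:
    """GC spectrum src -> tgt from a raw CSD array ``(F, m, m)``.

    With an empty conditioning set this is the unconditional (pairwise)
    Geweke measure on the 2 x 2 sub-spectrum; otherwise the conditional
    measure from nested factorizations.
    """
    if src == tgt:
        raise ValueError("source and target must differ")
    conditioning = tuple(conditioning)
    if src in conditioning or tgt in conditioning:
        raise ValueError("conditioning set must exclude source and target")
    if not conditioning:
        idx = np.array([src, tgt])
        s_pair = s[np.ix_(np.arange(s.shape[0]), idx, idx)]
        fact = wilson_factorize(s_pair, tol=tol, max_iter=max_iter)
        return _pairwise_gc(s_pair, fact)

    full_idx = np.array([tgt, *conditioning, src])
    s_full = s[np.ix_(np.arange(s.shape[0]), full_idx, full_idx)]
    full_fact = wilson_factorize(s_full, tol=tol, max_iter=max_iter)
    red_idx_local = np.arange(len(full_idx) - 1)          # all but the source
    s_red = s_full[np.ix_(np.arange(s.shape[0]), red_idx_local, red_idx_local)]
    red_fact = wilson_factorize(s_red, tol=tol, max_iter=max_iter)
    return _conditional_gc_from_factors(full_fact, red_fact, red_idx_local,
                                        src_pos=len(full_idx) - 1, tgt_pos=0)


def conditional_gc(csd: CrossSpectralDensity, source: int, target: int,
                   conditioning: Sequence[int] = (), *, tol: float = 1e-9,
                   max_iter: int = 1000) -> np.ndarray:
    """Geweke spectral GC from ``source`` to ``target`` site, optionally
    conditional on further sites.  Returns a nonnegative spectrum on
    ``csd.freqs``."""
    return _gc_from_csd_matrix(csd.s, csd.freqs, source, target, conditioning,
                               tol=tol, max_iter=max_iter)


def gc_all_pairs(csd: CrossSpectralDensity, *, conditional: bool = True,
                 tol: float = 1e-9, max_iter: int = 1000) -> GCSpectra:
    """GC spectra for every ordered site pair (conditional on the remaining
    sites by default).  Factorizations are shared across pairs."""
    m = csd.n_sites
    spectra: dict[tuple[int, int], np.ndarray] = {}
    if not conditional or m == 2:
        for src, tgt in itertools.permutations(range(m), 2):
            spectra[(src, tgt)] = _gc_from_csd_matrix(csd.s, csd.freqs, src, tgt,
                                                      tol=tol, max_iter=max_iter)
        return GCSpectra(freqs=csd.freqs, spectra=spectra, site_labels=csd.site_labels)

    # one full factorization plus one reduced factorization per excluded
    # source, shared across all ordered pairs (the minimum-phase factor is
    # equivariant under channel permutation, so the natural order suffices)
    full_fact = wilson_factorize(csd.s, tol=tol, max_iter=max_iter)
    f_idx = np.arange(csd.s.shape[0])
    reduced: dict[int, tuple[SpectralFactorization, np.ndarray]] = {}
    for src in range(m):
        keep = np.array([i for i in range(m) if i != src])
        fact = wilson_factorize(csd.s[np.ix_(f_idx, keep, keep)],
                                tol=tol, max_iter=max_iter)
        reduced[src] = (fact, keep)
    for src, tgt in itertools.permutations(range(m), 2):
        red_fact, keep = reduced[src]
        spectra[(src, tgt)] = _conditional_gc_from_factors(
            full_fact, red_fact, keep, src_pos=src, tgt_pos=tgt)
    return GCSpectra(freqs=csd.freqs, spectra=spectra, site_labels=csd.site_labels)


# ---------------------------------------------------------------------------
# Permutation significance and band-wise directionality
# ---------------------------------------------------------------------------

def permutation_threshold(data: np.ndarray, *, fs: float,
                          pairs: Sequence[tuple[int, int]] | None = None,
                          conditional: bool = False,
                          n_perm: int = 1000, alpha: float = 0.05, n_tests: int = 24,
                          n_tapers: int = 15, nw: float | None = None,
                          freq_max: float | None = 150.0,
                          seed: int | None = None,
                          tol: float = 1e-9, max_iter: int = 1000) -> dict:
    """Permutation null for GC spectra with per-pair max-statistic thresholds.

    Each permutation shuffles epoch indices independently per site (which
    preserves every site's marginal spectrum while destroying cross-site
    alignment), recomputes the CSD and the GC spectrum of every requested
    ordered pair, and records the maximum GC across frequencies.  The
    uncorrected threshold is the 99th percentile of these null maxima; the
    corrected threshold applies a Bonferroni adjustment for ``n_tests``
    band-wise connections, i.e. the ``1 - alpha/n_tests`` quantile.

    Parameters
    ----------
    data:
        ``(n_epochs, n_sites, n_samples)`` site signals (already windowed).
    pairs:
        Ordered (source, target) pairs; all ordered pairs by default.

    Returns
    -------
    dict with keys ``"threshold"`` (corrected, per pair), ``"threshold_99"``
    (uncorrected 99th percentile, per pair), and ``"null_max"`` (the null
    distributions).
    """
    data = np.asarray(data)
    n_ep, m, _ = data.shape
    if n_perm < 100:
        import warnings
        warnings.warn(f"n_perm={n_perm} < 100 gives an unstable null tail",
                      stacklevel=2)
    if n_ep < 50:
        import warnings
        warnings.warn(f"only {n_ep} epochs; permutation null may be unstable",
                      stacklevel=2)
    if pairs is None:
        pairs = list(itertools.permutations(range(m), 2))
    rng = np.random.default_rng(seed)

    freqs = np.fft.rfftfreq(data.shape[2], 1.0 / fs)
    fmask = np.ones(freqs.size, dtype=bool)
    if freq_max is not None:
        fmask = freqs <= freq_max
    null_max: dict[tuple[int, int], np.ndarray] = {p: np.empty(n_perm) for p in pairs}

    if not conditional:
        # batched pairwise path: factorize all permutations of an unordered
        # pair at once, read both directions from the same factors
        tapers = _dpss_tapers(data.shape[2], n_tapers, nw)
        x0 = np.fft.rfft(data[:, None, :, :] * tapers[None, :, None, :], axis=-1)
        unordered = sorted({tuple(sorted(p)) for p in pairs})
        # chunk permutations to bound the gather working set
        chunk = max(1, int(4e6 // (n_ep * n_tapers * freqs.size)))
        perm_all = np.stack([
            np.stack([rng.permutation(n_ep) for _ in range(m)])
            for _ in range(n_perm)])                      # (n_perm, m, n_ep)
        for a, b_ in unordered:
            x0_pair = x0[:, :, [a, b_], :]
            for lo in range(0, n_perm, chunk):
                idx = perm_all[lo:lo + chunk][:, [a, b_], :]
                s_b = _csd_batch(x0_pair, idx)
                h, sigma = _wilson_batch(s_b, tol=max(tol, 1e-8))
                for local_src, local_tgt, key in ((0, 1, (a, b_)), (1, 0, (b_, a))):
                    if key not in null_max:
                        continue
                    s_tt = np.real(s_b[:, :, local_tgt, local_tgt])
                    sig_cond = (sigma[:, local_src, local_src]
                                - sigma[:, local_src, local_tgt] ** 2
                                / sigma[:, local_tgt, local_tgt])
                    intrinsic = s_tt - sig_cond[:, None] * np.abs(
                        h[:, :, local_tgt, local_src]) ** 2
                    intrinsic = np.maximum(intrinsic, np.finfo(float).tiny)
                    gc = np.maximum(np.log(np.maximum(s_tt, np.finfo(float).tiny)
                                           / intrinsic), 0.0)
                    null_max[key][lo:lo + idx.shape[0]] = gc[:, fmask].max(axis=1)
    else:
        for it in range(n_perm):
            shuffled = np.empty_like(data)
            for j in range(m):
                shuffled[:, j, :] = data[rng.permutation(n_ep), j, :]
            csd = estimate_csd(shuffled, fs=fs, n_tapers=n_tapers, nw=nw)
            for src, tgt in pairs:
                cond = tuple(i for i in range(m) if i not in (src, tgt))
                spec = _gc_from_csd_matrix(csd.s, csd.freqs, src, tgt, cond,
                                           tol=tol, max_iter=max_iter)
                null_max[(src, tgt)][it] = float(np.max(spec[fmask]))

    q_corr = 100.0 * (1.0 - alpha / n_tests)
    thresholds = {p: float(np.percentile(v, q_corr)) for p, v in null_max.items()}
    thresholds_99 = {p: float(np.percentile(v, 99.0)) for p, v in null_max.items()}
    return {"threshold": thresholds, "threshold_99": thresholds_99,
            "null_max": null_max}


def _band_peak(spec: np.ndarray, mask: np.ndarray) -> int | None:
    """Index of a local maximum of the 3-bin-smoothed spectrum inside the
    band (strictly above both smoothed neighbors), or None."""
    sm = np.convolve(spec, np.ones(3) / 3.0, mode="same")
    idx = np.flatnonzero(mask)
    best: int | None = None
    for i in idx:
        if 0 < i < spec.size - 1 and sm[i] > sm[i - 1] and sm[i] > sm[i + 1]:
            if best is None or sm[i] > sm[best]:
                best = i
    return best


def dgc_by_band(gc_fwd: np.ndarray, gc_rev: np.ndarray, freqs: np.ndarray,
                thr_fwd: float, thr_rev: float,
                bands: Mapping[str, tuple[float, float]] = GC_BANDS,
                labels: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Band-wise directionality statistic for one site/subregion pair.

    Per band: a direction is significant if its spectrum exceeds its
    threshold anywhere in the band.  If both directions are significant, the
    dominant one (larger band value) is compared to the other at the
    dominant spectrum's peak frequency in the band, or -- when no peak
    exists -- via band-averaged values.  If only one direction is
    significant its own band value is taken.  ``dGC`` is nonnegative; a
    band with no significant direction is marked ``direction=None``.
    """
    rows = []
    for band, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs <= hi)
        if not mask.any():
            raise ValueError(f"band {band} {lo}-{hi} Hz has no frequency points")
        sig_f = bool(np.any(gc_fwd[mask] > thr_fwd))
        sig_r = bool(np.any(gc_rev[mask] > thr_rev))

        def band_value(spec: np.ndarray) -> tuple[float, int | None]:
            peak = _band_peak(spec, mask)
            if peak is not None:
                return float(spec[peak]), peak
            return float(np.mean(spec[mask])), None

        if not sig_f and not sig_r:
            rows.append({"band": band, "direction": None, "dgc": np.nan,
                         "sig_forward": False, "sig_reverse": False})
            continue
        if sig_f and not sig_r:
            val, _ = band_value(gc_fwd)
            rows.append({"band": band, "direction": f"{labels[0]}->{labels[1]}",
                         "dgc": val, "sig_forward": True, "sig_reverse": False})
            continue
        if sig_r and not sig_f:
            val, _ = band_value(gc_rev)
            rows.append({"band": band, "direction": f"{labels[1]}->{labels[0]}",
                         "dgc": val, "sig_forward": False, "sig_reverse": True})
            continue

        val_f, peak_f = band_value(gc_fwd)
        val_r, peak_r = band_value(gc_rev)
        if val_f >= val_r:
            dom, opp, peak = gc_fwd, gc_rev, peak_f
            direction = f"{labels[0]}->{labels[1]}"
        else:
            dom, opp, peak = gc_rev, gc_fwd, peak_r
            direction = f"{labels[1]}->{labels[0]}"
        if peak is not None:
            dgc = float(dom[peak] - opp[peak])
        else:
            dgc = float(np.mean(dom[mask]) - np.mean(opp[mask]))
        rows.append({"band": band, "direction": direction, "dgc": max(dgc, 0.0),
                     "sig_forward": sig_f, "sig_reverse": sig_r})
    return pd.DataFrame(rows)


@dataclass
class PooledPairs:
    """Site-pair bookkeeping for the 4-site / 3-subregion connectivity design."""

    site_subregions: list[str]
    inter_site_pairs: list[tuple[int, int]]
    intra_site_pairs: list[tuple[int, int]]
    subregion_pairs: list[tuple[str, str]]            # unordered, 3 expected
    directed_map: dict[tuple[str, str], list[tuple[int, int]]]

    @property
    def n_inter(self) -> int:
        return len(self.inter_site_pairs)

    @property
    def n_intra(self) -> int:
        return len(self.intra_site_pairs)

    @property
    def n_connections(self) -> int:
        """Pooled inter-subregional connections (unordered pairs counted in
        both directions)."""
        return 2 * len(self.subregion_pairs)

    def n_band_tests(self, n_bands: int = 4) -> int:
        """Corrected family size: one member per (connection, band)."""
        return self.n_connections * n_bands

    def pool(self, spectra: Mapping[tuple[int, int], np.ndarray]
             ) -> dict[tuple[str, str], np.ndarray]:
        """Average ordered-site-pair GC spectra into directed subregion-level
        connections (pairs sharing the doubled subregion are averaged)."""
        out: dict[tuple[str, str], np.ndarray] = {}
        for key, site_pairs in self.directed_map.items():
            out[key] = np.mean([spectra[p] for p in site_pairs], axis=0)
        return out


def pool_pairs(site_subregions: Sequence[str]) -> PooledPairs:
    """Classify the C(4,2)=6 site pairs of the 4-site design and build the
    pooling map onto 3 subregions.

    Requires exactly 4 sites carrying 3 distinct subregion labels with
    exactly one label doubled, which yields 5 inter-subregional and 1
    intra-subregional site pair and, after averaging over the doubled
    subregion, 6 directed subregion-level connections (3 unordered pairs x
    2 directions).
    """
    labels = list(site_subregions)
    if len(labels) != 4:
        raise ValueError(f"expected 4 sites, got {len(labels)}")
    uniq = sorted(set(labels))
    counts = {u: labels.count(u) for u in uniq}
    if len(uniq) != 3 or sorted(counts.values()) != [1, 1, 2]:
        raise ValueError(
            "site labeling must cover 3 subregions with exactly one doubled, "
            f"got counts {counts}"
        )
    inter, intra = [], []
    for i, j in itertools.combinations(range(4), 2):
        (intra if labels[i] == labels[j] else inter).append((i, j))

    sub_pairs = list(itertools.combinations(uniq, 2))
    directed: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for a, b in sub_pairs:
        for src_lab, tgt_lab in ((a, b), (b, a)):
            members = [(i, j) for i in range(4) for j in range(4)
                       if i != j and labels[i] == src_lab and labels[j] == tgt_lab]
            directed[(src_lab, tgt_lab)] = members
    return PooledPairs(site_subregions=labels, inter_site_pairs=inter,
                       intra_site_pairs=intra, subregion_pairs=sub_pairs,
                       directed_map=directed)
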