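"""Complex Morlet wavelet decomposition of segmented trials.

The analyzing wavelet at frequency f is a complex exponential under a
Gaussian envelope with sigma_t = n_cycles / (2 pi f), L1-normalized so that a
unit-amplitude cosine at f yields |coefficient| ~= 0.5 (half of the tone's
energy lies at the negative frequency).  Convolution is done by FFT; when a
decimation factor is requested the inverse FFT is taken on the alias-folded
spectrum, which is exactly equivalent to slicing the full convolution but
``decim`` times cheaper.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import TFCoefficients, TrialSet


def morlet_kernel(freq: float, fs: float, n_cycles: float) -> tuple[np.ndarray, int]:
    """Discrete complex Morlet kernel and its half-width in samples.

    Support is +-5 sigma_t; the kernel integrates (in the continuous-time
    sense, i.e. sum * dt) to a unit-gain Gaussian low-pass around ``freq``.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-0.5 * (t / sigma_t) ** 2) / (sigma_t * np.sqrt(2.0 * np.pi))
    k = envelope * np.exp(2j * np.pi * freq * t) / fs
    return k, half


def analytic_tone_response(grid_freq: float, tone_freq: float,
                           n_cycles: float) -> float:
    """Closed-form |coefficient| for a unit cosine probed at ``grid_freq``.

    The Gaussian kernel's transfer function is exp(-2 pi^2 sigma_t^2 df^2);
    a cosine splits into two complex exponentials of amplitude 1/2 at +-f.
    """
    sigma_t = n_cycles / (2.0 * np.pi * grid_freq)
    pos = 0.5 * np.exp(-2.0 * np.pi**2 * sigma_t**2 * (tone_freq - grid_freq) ** 2)
    neg = 0.5 * np.exp(-2.0 * np.pi**2 * sigma_t**2 * (tone_freq + grid_freq) ** 2)
    return pos + neg


def morlet_transform(ts: TrialSet | np.ndarray, freqs_hz: np.ndarray,
                     n_cycles: float | np.ndarray = 7.0,
                     fs: float | None = None, decim: int = 1,
                     max_chunk_elems: int = 2_000_000) -> TFCoefficients:
    """Per-trial/channel complex Morlet coefficients on a frequency grid.

    ``decim`` keeps every decim-th output sample (it must divide round(fs));
    edge samples within one wavelet half-width of either trial edge are
    flagged invalid in the returned mask, never zeroed.
    """
    if isinstance(ts, TrialSet):
        data, fs_, time0 = ts.data, ts.fs, float(ts.time_s[0])
    else:
        if fs is None:
            raise ValueError("fs required when passing a bare array")
        data, fs_, time0 = np.asarray(ts, dtype=float), float(fs), 0.0
    if data.ndim != 3:
        raise ValueError("expected (n_trials, n_locations, n_samples)")
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if np.any(freqs_hz >= fs_ / 2.0):
        raise ValueError("frequency at or above Nyquist")
    cycles = np.broadcast_to(np.asarray(n_cycles, dtype=float), freqs_hz.shape)
    if np.any(cycles < 3):
        raise ValueError("n_cycles must be >= 3")
    decim = int(decim)
    if decim < 1 or round(fs_) % decim != 0:
        raise ValueError("decim must be a positive divisor of the sampling rate")

    n_tr, n_loc, n_samp = data.shape
    kernels = [morlet_kernel(f, fs_, c) for f, c in zip(freqs_hz, cycles)]
    max_half = max(h for _, h in kernels)
    # nfft must be a multiple of decim for spectrum folding; choosing the
    # folded length as a fast FFT size keeps nfft = decim * m fast too
    min_n = n_samp + 2 * max_half + 1
    nfft = decim * next_fast_len(-(-min_n // decim))

    n_out = int(np.ceil(n_samp / decim))
    out = np.empty((n_tr, n_loc, freqs_hz.size, n_out), dtype=complex)
    flat = data.reshape(n_tr * n_loc, n_samp)
    chunk = max(1, int(max_chunk_elems // nfft))
    m = nfft // decim
    idx = np.arange(nfft)
    for start in range(0, flat.shape[0], chunk):
        block = flat[start:start + chunk]
        spec = fft(block, n=nfft, axis=-1)
        for fi, (k, half) in enumerate(kernels):
            ks = fft(k, n=nfft)
            prod = spec * ks
            if decim == 1:
                y = ifft(prod, axis=-1)[..., half:half + n_samp]
            else:
                # shift so output sample 0 aligns with trial sample 0, then
                # alias-fold the spectrum: ifft of the folded spectrum equals
                # the decimated full convolution
                shifted = prod * np.exp(2j * np.pi * idx * half / nfft)
                folded = shifted.reshape(block.shape[0], decim, m).sum(axis=1)
                y = ifft(folded, axis=-1)[..., :n_out] / decim
            out.reshape(n_tr * n_loc, freqs_hz.size, n_out)[start:start + chunk, fi] = y

    sample_idx = np.arange(0, n_samp, decim)
    valid = np.empty((freqs_hz.size, n_out), dtype=bool)
    for fi, (_, half) in enumerate(kernels):
        valid[fi] = (sample_idx >= half) & (sample_idx <= n_samp - 1 - half)
    time_s = time0 + sample_idx / fs_
    return TFCoefficients(out, freqs_hz, time_s, valid, domain="channel", fs=fs_ / decim)


class MorletTransformer(TransformerMixin, BaseEstimator):
    """Stateless sklearn wrapper around :func:`morlet_transform`."""

    def __init__(self, freqs_hz=None, n_cycles: float = 7.0,
                 decim: int = 1, fs: float | None = None):
        self.freqs_hz = freqs_hz
        self.n_cycles = n_cycles
        self.decim = decim
        self.fs = fs

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: TrialSet | np.ndarray) -> TFCoefficients:
        freqs = self.freqs_hz if self.freqs_hz is not None else np.arange(70.0, 101.0)
        return morlet_transform(X, freqs, n_cycles=self.n_cycles,
                                fs=self.fs, decim=self.decim)
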