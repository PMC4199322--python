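"""LCMV beamformer source mapping and baseline Z-scoring.

The beamformer weight row for source v is w_v = C_r^-1 l_v / (l_v' C_r^-1 l_v)
with C_r the (regularized) broadband channel covariance and l_v the leadfield
column — the linearly constrained minimum-variance filter with unit gain on
its own source.  Stacked rows form a transfer matrix T; because the wavelet
transform is linear, channel-domain coefficients map to source space as
j_i(t, f) = T d_i(t, f).  Trial-summed magnitudes give the amplitude map
a(t, f) = sum_i |j_i(t, f)| (amplitudes rather than powers, for robustness to
outlier trials), which is then normalized per (source, frequency) to Z-scores
against the mean and standard deviation over a pre-cue baseline interval.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .containers import Leadfield, SourceTFMap, TFCoefficients, TransferMatrix, TrialSet


def broadband_covariance(ts: TrialSet) -> np.ndarray:
    """Sample covariance pooled over retained trials and the full trial window.

    Each trial is mean-removed per channel before pooling; the result is
    symmetric PSD and invariant to trial order.
    """
    keep = ts.retained()
    if keep.size == 0:
        raise ValueError("all trials are artifact-flagged")
    x = ts.data[keep]                                # (i, c, t)
    x = x - x.mean(axis=2, keepdims=True)
    n_tot = keep.size * ts.n_samples
    if n_tot < ts.n_channels:
        warnings.warn("fewer samples than channels: covariance is rank-deficient, "
                      "regularization is mandatory", stacklevel=2)
    if n_tot < 10 * ts.n_channels:
        warnings.warn("fewer than 10 samples per channel; covariance estimate is noisy",
                      stacklevel=2)
    c = np.einsum("ict,idt->cd", x, x) / max(n_tot - 1, 1)
    return 0.5 * (c + c.T)


def lcmv_transfer(lf: Leadfield, C: np.ndarray,
                  reg_lambda: float = 0.05) -> TransferMatrix:
    """Unit-gain LCMV rows for every source; ``reg_lambda`` scales mean(diag C)."""
    if reg_lambda < 0:
        raise ValueError("reg_lambda must be >= 0")
    C = np.asarray(C, dtype=float)
    if C.shape != (lf.n_channels, lf.n_channels):
        raise ValueError("covariance does not match the leadfield")
    c_r = C + reg_lambda * float(np.mean(np.diag(C))) * np.eye(lf.n_channels)
    try:
        w = np.linalg.solve(c_r, lf.gain)            # C_r^-1 L, (channels, sources)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance is singular; increase reg_lambda") from err
    denom = np.einsum("cv,cv->v", lf.gain, w)
    if np.any(denom <= 0):
        raise ValueError("numerically broken covariance: l' C^-1 l <= 0")
    t = (w / denom).T
    return TransferMatrix(t, reg_lambda=reg_lambda,
                          source_vertex_ids=np.array(lf.source_vertex_ids))


def map_coefficients(T: TransferMatrix | np.ndarray,
                     d: TFCoefficients) -> TFCoefficients:
    """Apply the transfer matrix per trial/frequency/time: j = T d."""
    t_mat = T.T if isinstance(T, TransferMatrix) else np.asarray(T)
    if t_mat.shape[1] != d.n_locations:
        raise ValueError("transfer matrix and coefficients disagree on channels")
    i, c, nf, nt = d.coef.shape
    j = (t_mat.astype(d.coef.dtype) @ d.coef.reshape(i, c, nf * nt)
         ).reshape(i, t_mat.shape[0], nf, nt)
    return TFCoefficients(j, d.freqs_hz, d.time_s, d.valid, domain="source", fs=d.fs)


def average_amplitude(j: TFCoefficients,
                      artifact_flags: np.ndarray | None = None,
                      with_power: bool = False) -> SourceTFMap:
    """Trial sums a = sum_i |j_i| (and optionally p = sum_i |j_i|^2).

    The sums are literal — no 1/N — so duplicating every trial doubles both;
    the later Z-scoring cancels the overall scale.
    """
    if artifact_flags is not None:
        keep = np.flatnonzero(~np.asarray(artifact_flags, dtype=bool))
        if keep.size == 0:
            raise ValueError("all trials are artifact-flagged")
        mag = np.abs(j.coef[keep])
    else:
        if j.n_trials == 0:
            raise ValueError("need at least one retained trial")
        mag = np.abs(j.coef)
    a = mag.sum(axis=0)
    p = (mag**2).sum(axis=0) if with_power else None
    return SourceTFMap(a=a, freqs_hz=j.freqs_hz, time_s=j.time_s,
                       n_trials=mag.shape[0], valid=j.valid, p=p, domain=j.domain)


def zscore_baseline(m: SourceTFMap,
                    baseline_s: tuple[float, float] | None = None,
                    ddof: int = 1) -> SourceTFMap:
    """Z-score the amplitude map against its baseline interval.

    z(v, f, t) = (a(v, f, t) - mu_b(v, f)) / sd_b(v, f) with mu/sd taken over
    baseline time points; locations with zero baseline SD are marked invalid
    in ``z_valid`` (their z is NaN).  Invariant to positive rescaling of a.
    """
    b0, b1 = baseline_s if baseline_s is not None else m.baseline_s
    in_b = (m.time_s >= b0) & (m.time_s < b1)
    if not in_b.any():
        raise ValueError("baseline window contains no time points")
    b_idx = np.flatnonzero(in_b)
    if not m.valid[:, b_idx].all():
        raise ValueError("baseline window overlaps wavelet edge-invalid samples")
    base = m.a[:, :, b_idx]
    mu = base.mean(axis=2)
    sd = base.std(axis=2, ddof=ddof)
    z_valid = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m.a - mu[:, :, None]) / sd[:, :, None]
    z[~z_valid] = np.nan
    return SourceTFMap(a=m.a, freqs_hz=m.freqs_hz, time_s=m.time_s,
                       n_trials=m.n_trials, valid=m.valid, p=m.p, z=z,
                       z_valid=z_valid, baseline_s=(b0, b1),
                       signal_s=m.signal_s, domain=m.domain)


class LCMVBeamformer(BaseEstimator):
    """Sklearn-style LCMV spatial filter.

    ``fit`` estimates the broadband covariance from a :class:`TrialSet`
    (artifact-flagged trials excluded) and solves the unit-gain weights for
    every leadfield column; ``transform`` maps channel-domain wavelet
    coefficients (or raw channel data) into source space.

    Attributes
    ----------
    covariance_ : (channels, channels) pooled broadband covariance
    transfer_ : :class:`TransferMatrix` with rows w_v
    """

    def __init__(self, leadfield: Leadfield | None = None,
                 reg_lambda: float = 0.05):
        self.leadfield = leadfield
        self.reg_lambda = reg_lambda

    def fit(self, X: TrialSet | np.ndarray, y=None):
        if self.leadfield is None:
            raise ValueError("LCMVBeamformer requires a leadfield")
        if isinstance(X, TrialSet):
            self.covariance_ = broadband_covariance(X)
        else:
            C = np.asarray(X, dtype=float)
            if C.ndim != 2 or C.shape[0] != C.shape[1]:
                raise ValueError("expected a TrialSet or a square covariance")
            self.covariance_ = C
        self.transfer_ = lcmv_transfer(self.leadfield, self.covariance_,
                                       self.reg_lambda)
        return self

    def transform(self, X: TFCoefficients | np.ndarray):
        if isinstance(X, TFCoefficients):
            return map_coefficients(self.transfer_, X)
        return np.einsum("vc,...ct->...vt", self.transfer_.T, np.asarray(X))
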