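"""Trial segmentation, artifact-trial rejection, and HG envelopes.

Muscle and ocular activity overlap the high-gamma band and can exceed
cortical HG by orders of magnitude, and because trial averaging is over
amplitudes these errors do not cancel — contaminated trials are therefore
removed outright, never repaired.  Three configurable spectral rules flag
trials: extreme pooled-percentile HG power, excessive 100-150 Hz power, and
synchronous threshold crossings on many channels at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d
from scipy.signal import buttord, butter, hilbert, sosfiltfilt
from sklearn.base import BaseEstimator

from .containers import TrialSet

logger = logging.getLogger(__name__)

HG_BAND = (70.0, 100.0)


@dataclass
class ArtifactRule:
    """One rejection rule; ``rule_id`` in {hg_extreme, hf_power, sync_multi}."""

    rule_id: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rule_id not in ("hg_extreme", "hf_power", "sync_multi"):
            raise ValueError(f"unknown rule {self.rule_id!r}")
        for k, val in self.params.items():
            if isinstance(val, (int, float)) and val <= 0:
                raise ValueError(f"rule parameter {k} must be positive")


def default_rules(n_channels: int) -> list[ArtifactRule]:
    return [
        ArtifactRule("hg_extreme", {"factor": 1.0}),
        ArtifactRule("hf_power", {"k": 5.0, "band": (100.0, 150.0)}),
        ArtifactRule("sync_multi", {"m": int(np.ceil(n_channels / 4)),
                                    "window_s": 0.05, "n_mad": 6.0}),
    ]


def segment_trials(raw: np.ndarray, fs: float, cue_samples: np.ndarray,
                   cue_labels: np.ndarray,
                   pre_s: float = 2.0, post_s: float = 3.0) -> TrialSet:
    """Cut a continuous (channels, samples) recording into cue-locked trials.

    Each trial covers [cue - pre_s, cue + post_s); cues whose window would
    cross a recording edge are dropped and logged.  Windows are copied
    verbatim — segmentation is lossless within each window.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.size == 0:
        raise ValueError("raw must be a non-empty (channels, samples) array")
    if fs <= 0:
        raise ValueError("fs must be positive")
    cue_samples = np.asarray(cue_samples, dtype=np.int64)
    cue_labels = np.asarray(cue_labels)
    if cue_samples.size and np.any(np.diff(cue_samples) < 0):
        raise ValueError("cues must be sorted")
    if cue_samples.shape != cue_labels.shape:
        raise ValueError("cue_samples and cue_labels must align")

    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    n_len = n_pre + n_post
    n_total = raw.shape[1]
    kept, dropped = [], []
    for c in cue_samples:
        if c - n_pre < 0 or c + n_post > n_total:
            dropped.append(int(c))
        else:
            kept.append(int(c))
    for c in dropped:
        logger.warning("cue at sample %d dropped: window crosses recording edge", c)
    keep_mask = np.isin(cue_samples, kept)
    trials = np.stack([raw[:, c - n_pre:c + n_post] for c in kept], axis=0) \
        if kept else np.empty((0, raw.shape[0], n_len))
    time_s = (np.arange(n_len) - n_pre) / fs
    return TrialSet(trials, fs, time_s, cue_labels[keep_mask],
                    meta={"dropped_cue_samples": dropped})


def _bandpass_sos(fs: float, lo: float, hi: float,
                  stop_lo: float, stop_hi: float):
    """Butterworth band-pass meeting >= 40 dB stop-band at the stop edges."""
    n, wn = buttord([lo, hi], [stop_lo, stop_hi], gpass=1.0, gstop=40.0, fs=fs)
    return butter(n, wn, btype="bandpass", output="sos", fs=fs)


def hg_envelope(x: np.ndarray, fs: float,
                band: tuple[float, float] = HG_BAND) -> np.ndarray:
    """Amplitude envelope of the 70-100 Hz band: zero-phase band-pass then
    analytic-signal magnitude.  Length-preserving; works on the last axis."""
    if fs <= 200.0:
        raise ValueError("fs must exceed 200 Hz for the HG band")
    x = np.asarray(x, dtype=float)
    lo, hi = band
    sos = _bandpass_sos(fs, lo, hi, lo - 20.0, hi + 20.0)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= padlen:
        raise ValueError("signal shorter than the filter transient")
    y = sosfiltfilt(sos, x, axis=-1)
    return np.abs(hilbert(y, axis=-1))


class ArtifactDetector(BaseEstimator):
    """Flags artifact-contaminated trials by spectral rules.

    Parameters mirror :func:`default_rules`; ``fit`` computes per-trial
    statistics, ``predict``/``fit_predict`` return the boolean flags, and the
    per-rule evidence is exposed as ``report_`` (a DataFrame with one row per
    flagged trial and rule: trial_id, rule_id, statistic, threshold).
    """

    def __init__(self, rules: list[ArtifactRule] | None = None):
        self.rules = rules

    def fit(self, ts: TrialSet, y=None):
        if ts.n_trials < 2:
            raise ValueError("need at least 2 trials (percentile rules pool across trials)")
        rules = self.rules if self.rules is not None else default_rules(ts.n_channels)
        env = hg_envelope(ts.data, ts.fs)          # (i, c, t)
        flags = np.zeros(ts.n_trials, dtype=bool)
        rows = []
        for rule in rules:
            if rule.rule_id == "hg_extreme":
                stat, thr = self._hg_extreme(env, rule.params)
            elif rule.rule_id == "hf_power":
                stat, thr = self._hf_power(ts, rule.params)
            else:
                stat, thr = self._sync_multi(env, ts.fs, rule.params)
            thr = np.broadcast_to(np.asarray(thr, dtype=float), stat.shape)
            hit = stat > thr
            flags |= hit
            for i in np.flatnonzero(hit):
                rows.append({"trial_id": int(i), "rule_id": rule.rule_id,
                             "statistic": float(stat[i]), "threshold": float(thr[i])})
        self.flags_ = flags
        self.report_ = pd.DataFrame(rows, columns=["trial_id", "rule_id",
                                                   "statistic", "threshold"])
        return self

    @staticmethod
    def _hg_extreme(env: np.ndarray, params: dict) -> tuple[np.ndarray, np.ndarray]:
        """Channel-mean HG power exceeding the pooled 99th percentile by the factor.

        The percentile for trial i pools the other trials' power samples
        (leave-one-out): a single grossly contaminated trial must not lift
        its own threshold out of reach.
        """
        factor = params.get("factor", 1.0)
        power = (env**2).mean(axis=1)[:, ::5]      # (i, t), decimated (smooth env)
        n = power.shape[0]
        thr = np.empty(n)
        for i in range(n):
            others = np.delete(power, i, axis=0)
            thr[i] = (1.0 + factor) * np.percentile(others, 99.0)
        stat = power.max(axis=1)
        return stat, thr

    @staticmethod
    def _hf_power(ts: TrialSet, params: dict) -> tuple[np.ndarray, float]:
        """Mean 100-150 Hz power above k times the across-trial median."""
        lo, hi = params.get("band", (100.0, 150.0))
        k = params.get("k", 5.0)
        if ts.fs <= 2 * hi:
            raise ValueError("sampling rate too low for the 100-150 Hz band")
        sos = _bandpass_sos(ts.fs, lo, hi, lo - 20.0, hi + 25.0)
        y = sosfiltfilt(sos, ts.data, axis=-1)
        stat = (y**2).mean(axis=(1, 2))
        return stat, k * float(np.median(stat))

    @staticmethod
    def _sync_multi(env: np.ndarray, fs: float, params: dict) -> tuple[np.ndarray, float]:
        """>= m channels over their own robust threshold within one short window."""
        m = params.get("m", int(np.ceil(env.shape[1] / 4)))
        win = max(1, int(round(params.get("window_s", 0.05) * fs)))
        n_mad = params.get("n_mad", 6.0)
        med = np.median(env, axis=(0, 2), keepdims=True)
        mad = np.median(np.abs(env - med), axis=(0, 2), keepdims=True)
        thr_c = med + n_mad * 1.4826 * mad
        exceed = (env > thr_c).astype(np.int8)
        # a channel counts if it crosses anywhere inside the sliding window
        any_in_win = maximum_filter1d(exceed, size=win, axis=-1)
        stat = any_in_win.sum(axis=1).max(axis=1).astype(float)
        return stat, float(m) - 0.5   # integer count, strict >= m

    def predict(self, ts: TrialSet | None = None) -> np.ndarray:
        return self.flags_

    def fit_predict(self, ts: TrialSet, y=None) -> np.ndarray:
        return self.fit(ts).flags_


def detect_artifact_trials(ts: TrialSet,
                           rules: list[ArtifactRule] | None = None,
                           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the rejection rules; returns (updated flags, report).

    Flags are monotone: the result is OR-ed with any pre-existing flags.
    """
    det = ArtifactDetector(rules=rules).fit(ts)
    return ts.artifact_flags | det.flags_, det.report_
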