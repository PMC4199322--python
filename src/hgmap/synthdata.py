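"""Synthetic motor-imagery EEG sessions with known ground truth.

Emulates the study protocol the pipeline targets: 54-channel EEG sampled at
1200 Hz, 100 cue-locked trials per hand on a [-2, 3) s window, a focal
narrowband high-gamma (HG) burst at a contralateral cortical source between
0.3 and 1.0 s post-cue, beta-band desynchronization, spatially mixed 1/f
background noise, occasional broadband muscle artifacts, bipolar EMG/EOG
channels, and matched per-vertex fMRI Z maps.

The forward model is an analytic current-dipole potential in an infinite
homogeneous conductor; sources sit on a jittered spherical cortex mesh inside
a spherical sensor shell.  This keeps the desk-scale geometry realistic in
structure (focal gain columns, distance fall-off, mixed topographies) while
remaining a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.spatial import ConvexHull

from .containers import Leadfield, TriangleMesh, TrialSet

HAND_ORDER = ("left", "right")

#: conductivity of the homogeneous medium, S/m (brain-tissue ballpark)
SIGMA_S_PER_M = 0.33


@dataclass
class SimConfig:
    """Simulation parameters; defaults state the emulated protocol."""

    n_trials_per_hand: int = 100
    n_channels: int = 54
    fs: float = 1200.0
    trial_window: tuple[float, float] = (-2.0, 3.0)
    hg_center_range: tuple[float, float] = (70.0, 96.0)  # Hz, per-source draw
    hg_bandwidth: float = 5.0          # Hz FWHM of the burst's spectral profile
    burst_window: tuple[float, float] = (0.3, 1.0)
    hg_snr: float = 2.0                # burst/noise amplitude ratio in-band at best channel
    beta_freq: float = 21.0            # Hz carrier of the ongoing beta rhythm
    beta_erd_depth: float = 0.5        # fractional post-cue beta attenuation
    beta_snr: float = 1.0              # beta/noise amplitude ratio in-band at best channel
    noise_exponent: float = 1.0        # 1/f^alpha background slope
    artifact_rate: float = 0.05        # fraction of trials with a muscle burst
    artifact_gain: float = 10.0        # artifact amplitude in channel-std units
    emg_task_locked: bool = False      # inject systematic task-locked EMG contamination
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.trial_window
        if abs((hi - lo) - 5.0) > 1e-9:
            raise ValueError("trial_window must span exactly 5 s")
        b0, b1 = self.burst_window
        if not (0.0 <= b0 < b1 < hi):
            raise ValueError("burst_window must lie inside [0, trial end)")
        if not (0.0 <= self.artifact_rate < 1.0):
            raise ValueError("artifact_rate must be in [0, 1)")
        c0, c1 = self.hg_center_range
        if not (70.0 <= c0 <= c1 <= 100.0):
            raise ValueError("hg_center_range must lie within [70, 100] Hz")

    @property
    def n_samples(self) -> int:
        return int(round((self.trial_window[1] - self.trial_window[0]) * self.fs))

    def time_axis(self) -> np.ndarray:
        return self.trial_window[0] + np.arange(self.n_samples) / self.fs


@dataclass
class GroundTruth:
    """What the simulator actually injected, for downstream validation."""

    source_vertex_ids: np.ndarray      # per hand, ordered like HAND_ORDER
    source_centers_hz: np.ndarray      # HG center per hand
    burst_onset_s: float
    burst_offset_s: float
    artifact_trial_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def dipole_potential(dip_pos_mm: np.ndarray, moment: np.ndarray,
                     sensor_pos_mm: np.ndarray,
                     sigma: float = SIGMA_S_PER_M) -> np.ndarray:
    """Potential of a current dipole in an infinite homogeneous conductor.

    V = p . (r - r0) / (4 pi sigma |r - r0|^3), positions in mm (converted to
    meters internally), moment in A*m; returns volts.
    """
    r = (np.atleast_2d(sensor_pos_mm) - np.asarray(dip_pos_mm)) * 1e-3
    dist = np.linalg.norm(r, axis=-1)
    if np.any(dist < 1e-6):
        raise ValueError("sensor coincides with the dipole")
    return (r @ np.asarray(moment)) / (4.0 * np.pi * sigma * dist**3)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere point set."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.c_[np.sin(phi) * np.cos(theta),
                 np.sin(phi) * np.sin(theta),
                 np.cos(phi)]


def make_mesh_and_leadfield(n_vertices: int, n_channels: int,
                            seed: int = 0,
                            cortex_radius_mm: float = 70.0,
                            sensor_radius_mm: float = 100.0,
                            ) -> tuple[TriangleMesh, Leadfield]:
    """Spherical cortex mesh inside a sensor shell, with an analytic leadfield.

    Dipoles are oriented along the (outward) vertex normal; the gain is the
    infinite-homogeneous-medium dipole potential per unit moment.
    """
    if n_vertices < 20:
        raise ValueError("need at least 20 vertices")
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    rng = default_rng(seed)
    unit = _fibonacci_sphere(n_vertices)
    # triangulate the unit sphere (every point is extreme there), then jitter
    # radii — keeps all vertices referenced even where jitter breaks convexity
    faces = ConvexHull(unit).simplices.copy()
    radius = cortex_radius_mm * (1.0 + 0.02 * rng.standard_normal(n_vertices))
    vertices = unit * radius[:, None]
    # consistent outward winding
    fn = np.cross(vertices[faces[:, 1]] - vertices[faces[:, 0]],
                  vertices[faces[:, 2]] - vertices[faces[:, 0]])
    centers = vertices[faces].mean(axis=1)
    flip = np.einsum("ij,ij->i", fn, centers) < 0
    faces[flip] = faces[flip][:, ::-1]
    mesh = TriangleMesh(vertices, faces)

    sensors = _fibonacci_sphere(n_channels) * sensor_radius_mm
    dmin = np.min(np.linalg.norm(sensors[:, None, :] - vertices[None, :, :], axis=-1))
    if dmin < 5.0:
        raise ValueError("degenerate geometry: sensor within 5 mm of a source")

    normals = mesh.vertex_normals
    gain = np.empty((n_channels, n_vertices))
    for v in range(n_vertices):
        gain[:, v] = dipole_potential(vertices[v], normals[v], sensors)
    lf = Leadfield(gain, channel_names=[f"E{c:02d}" for c in range(n_channels)],
                   source_vertex_ids=np.arange(n_vertices))
    return mesh, lf


def _one_over_f_noise(rng: np.random.Generator, n_series: int, n_samples: int,
                      fs: float, alpha: float) -> np.ndarray:
    """Unit-variance rows with power spectral density proportional to 1/f^alpha."""
    n_f = n_samples // 2 + 1
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.empty(n_f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    shape[0] = 0.0  # no DC
    spec = (rng.standard_normal((n_series, n_f))
            + 1j * rng.standard_normal((n_series, n_f))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _band_fraction(fs: float, n_samples: int, alpha: float,
                   lo: float, hi: float) -> float:
    """Fraction of 1/f^alpha noise variance falling in [lo, hi) Hz."""
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)[1:]
    pwr = f ** (-alpha)
    band = (f >= lo) & (f < hi)
    return float(pwr[band].sum() / pwr.sum())


def _narrowband_noise(rng: np.random.Generator, n_samples: int, fs: float,
                      center: float, fwhm: float) -> np.ndarray:
    """Gaussian noise spectrally shaped to a Gaussian band around ``center``."""
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    sigma_f = max(fwhm, 1e-3) / 2.355
    shape = np.exp(-0.5 * ((f - center) / sigma_f) ** 2)
    spec = (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)) * shape
    x = np.fft.irfft(spec, n=n_samples)
    return x


def _erd_envelope(t: np.ndarray, depth: float,
                  span: tuple[float, float] = (0.0, 1.5),
                  ramp: float = 0.2) -> np.ndarray:
    """Multiplicative beta envelope: 1 pre-cue, (1-depth) during the ERD span."""
    env = np.ones_like(t)
    t0, t1 = span
    core = (t >= t0 + ramp) & (t < t1 - ramp)
    env[core] = 1.0 - depth
    up = (t >= t0) & (t < t0 + ramp)
    env[up] = 1.0 - depth * 0.5 * (1 - np.cos(np.pi * (t[up] - t0) / ramp))
    dn = (t >= t1 - ramp) & (t < t1)
    env[dn] = 1.0 - depth * 0.5 * (1 + np.cos(np.pi * (t[dn] - (t1 - ramp)) / ramp))
    return env


def _pick_sources(mesh: TriangleMesh, rng: np.random.Generator) -> np.ndarray:
    """One source vertex per hand, in the contralateral (opposite-x) hemisphere."""
    x = mesh.vertices[:, 0]
    picks = []
    for hand in HAND_ORDER:
        # left-hand imagery activates the right hemisphere (x > 0) and vice versa
        side = x > 0.3 * np.abs(x).max() if hand == "left" else x < -0.3 * np.abs(x).max()
        cand = np.flatnonzero(side)
        picks.append(int(rng.choice(cand)))
    return np.asarray(picks, dtype=np.int64)


def render_clean_trial(cfg: SimConfig, lf: Leadfield, source_vertex: int,
                       hg_center: float, rng: np.random.Generator,
                       hg_amp: float = 1.0, beta_amp: float = 0.0,
                       ) -> np.ndarray:
    """Noiseless channel-space trial: leadfield-projected HG burst (+ beta).

    The HG burst is Hann-windowed narrowband Gaussian noise on
    ``cfg.burst_window`` with unit RMS over the window before scaling by
    ``hg_amp``; beta is a sinusoid attenuated post-cue by ``beta_erd_depth``.
    """
    t = cfg.time_axis()
    n = t.size
    src = np.zeros(n)
    b0, b1 = cfg.burst_window
    in_burst = (t >= b0) & (t < b1)
    nb = int(in_burst.sum())
    burst = _narrowband_noise(rng, nb, cfg.fs, hg_center, cfg.hg_bandwidth)
    burst *= np.hanning(nb)
    rms = np.sqrt(np.mean(burst**2))
    if rms > 0:
        burst /= rms
    src[in_burst] = hg_amp * burst
    if beta_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        beta = np.sin(2 * np.pi * cfg.beta_freq * t + phase)
        beta *= _erd_envelope(t, cfg.beta_erd_depth)
        src = src + beta_amp * beta
    return np.outer(lf.gain[:, source_vertex], src)


def simulate_session(cfg: SimConfig, mesh: TriangleMesh, lf: Leadfield,
                     ) -> tuple[TrialSet, np.ndarray, np.ndarray, GroundTruth]:
    """Full synthetic session.

    Returns ``(trials, emg, eog, truth)`` where ``emg``/``eog`` are
    (n_trials, 2, n_samples) bipolar channel stacks sharing the trial time
    axis.  Deterministic in ``cfg.seed``; per-trial noise comes from spawned
    substreams of one master seed.
    """
    if lf.n_channels != cfg.n_channels:
        raise ValueError("leadfield channel count does not match config")
    c_hi = cfg.hg_center_range[1]
    if c_hi + cfg.hg_bandwidth / 2.0 > cfg.fs / 2.0:
        raise ValueError("HG band exceeds Nyquist for this sampling rate")

    master = SeedSequence(cfg.seed)
    s_global, s_trials = master.spawn(2)
    rng = default_rng(s_global)
    t = cfg.time_axis()
    n_samples = cfg.n_samples
    n_trials = 2 * cfg.n_trials_per_hand

    sources = _pick_sources(mesh, rng)
    lo, hi = cfg.hg_center_range
    centers = rng.uniform(lo, hi, size=2)

    labels = np.array([HAND_ORDER[i % 2] for i in range(n_trials)])
    rng.shuffle(labels)

    n_art = int(round(cfg.artifact_rate * n_trials))
    artifact_ids = (np.sort(rng.choice(n_trials, size=n_art, replace=False))
                    if n_art else np.empty(0, dtype=np.int64))
    art_set = set(int(i) for i in artifact_ids)

    # smooth random mixing of latent 1/f noise sources onto channels (unit rows)
    mix = rng.standard_normal((cfg.n_channels, cfg.n_channels))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)

    # analytic in-band noise RMS: channels have unit variance, the 1/f shape
    # puts a fixed fraction of it into each band
    hg_band_rms = np.sqrt(_band_fraction(cfg.fs, n_samples, cfg.noise_exponent, 70.0, 100.0))
    beta_band_rms = np.sqrt(_band_fraction(cfg.fs, n_samples, cfg.noise_exponent, 15.0, 35.0))

    amp_by_hand = {}
    beta_by_hand = {}
    for h, hand in enumerate(HAND_ORDER):
        gmax = np.abs(lf.gain[:, sources[h]]).max()
        amp_by_hand[hand] = cfg.hg_snr * hg_band_rms / gmax
        # sine RMS is 1/sqrt(2): scale so in-band channel RMS matches beta_snr
        beta_by_hand[hand] = cfg.beta_snr * beta_band_rms / gmax * np.sqrt(2.0)

    data = np.empty((n_trials, cfg.n_channels, n_samples))
    emg = np.empty((n_trials, 2, n_samples))
    eog = np.empty((n_trials, 2, n_samples))
    hand_index = {"left": 0, "right": 1}
    trial_seeds = s_trials.spawn(n_trials)
    for i in range(n_trials):
        trng = default_rng(trial_seeds[i])
        latent = _one_over_f_noise(trng, cfg.n_channels, n_samples,
                                   cfg.fs, cfg.noise_exponent)
        x = mix @ latent
        hand = str(labels[i])
        h = hand_index[hand]
        clean = render_clean_trial(cfg, lf, int(sources[h]), float(centers[h]),
                                   trng,
                                   hg_amp=amp_by_hand[hand] if cfg.hg_snr > 0 else 0.0,
                                   beta_amp=beta_by_hand[hand] if cfg.beta_snr > 0 else 0.0)
        x = x + clean
        if i in art_set:
            x = x + _muscle_burst(trng, cfg, n_samples, t)
        data[i] = x
        emg[i] = _one_over_f_noise(trng, 2, n_samples, cfg.fs, cfg.noise_exponent)
        eog[i] = _one_over_f_noise(trng, 2, n_samples, cfg.fs, 1.5)
        if cfg.emg_task_locked:
            # systematic contamination of the imagined hand's EMG channel
            post = (t >= 0.0) & (t < 2.0)
            burst = _narrowband_noise(trng, int(post.sum()), cfg.fs, 85.0, 30.0)
            burst /= max(burst.std(), 1e-12)
            emg[i, h, post] += 3.0 * burst

    ts = TrialSet(data, cfg.fs, t, labels,
                  channel_names=list(lf.channel_names),
                  meta={"protocol": "cued motor imagery", "seed": int(cfg.seed)})
    truth = GroundTruth(source_vertex_ids=sources, source_centers_hz=centers,
                        burst_onset_s=cfg.burst_window[0],
                        burst_offset_s=cfg.burst_window[1],
                        artifact_trial_ids=artifact_ids)
    return ts, emg, eog, truth


def _muscle_burst(rng: np.random.Generator, cfg: SimConfig,
                  n_samples: int, t: np.ndarray) -> np.ndarray:
    """Broadband 20-300 Hz burst on a random channel subset, ~0.5 s long."""
    out = np.zeros((cfg.n_channels, n_samples))
    n_hit = max(2, cfg.n_channels // 3)
    chans = rng.choice(cfg.n_channels, size=n_hit, replace=False)
    dur = 0.5
    t0 = rng.uniform(t[0] + 0.2, t[-1] - 0.2 - dur)
    win = (t >= t0) & (t < t0 + dur)
    nw = int(win.sum())
    f = np.fft.rfftfreq(nw, 1.0 / cfg.fs)
    shape = ((f >= 20.0) & (f < 300.0)).astype(float)
    for c in chans:
        spec = (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)) * shape
        b = np.fft.irfft(spec, n=nw)
        b *= np.hanning(nw) / max(b.std(), 1e-12)
        out[c, win] = cfg.artifact_gain * b   # channels have unit std by construction
    return out


def simulate_fmri_map(mesh: TriangleMesh, truth: GroundTruth,
                      extra_clusters: int = 0, noise_sd: float = 0.0,
                      seed: int = 0, peak_z: float = 5.0,
                      blob_sigma_mm: float = 8.0,
                      threshold: float = 2.3) -> np.ndarray:
    """Per-vertex fMRI Z map: Gaussian blobs at the true sources plus distractors.

    With ``noise_sd = 0`` and no distractors, thresholding at Z > ``threshold``
    yields exactly one contiguous cluster per true source; distractor blobs are
    placed pairwise far enough apart (and from the sources) that each adds one
    cluster at the default threshold.
    """
    src = np.asarray(truth.source_vertex_ids, dtype=np.int64)
    if src.size and (src.min() < 0 or src.max() >= mesh.n_vertices):
        raise ValueError("ground-truth vertices outside the mesh")
    rng = default_rng(seed)
    v = mesh.vertices
    # supra-threshold blob radius; keep blob centers > 3x apart so clusters stay distinct
    r_star = blob_sigma_mm * np.sqrt(2.0 * np.log(peak_z / threshold))
    min_sep = 3.2 * r_star
    centers = [v[s] for s in src]
    for _ in range(extra_clusters):
        for _try in range(2000):
            cand = v[rng.integers(mesh.n_vertices)]
            if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                centers.append(cand)
                break
        else:
            raise ValueError("mesh too small to place distractor clusters")
    zmap = np.zeros(mesh.n_vertices)
    for c in centers:
        d2 = np.sum((v - c) ** 2, axis=1)
        zmap += peak_z * np.exp(-d2 / (2.0 * blob_sigma_mm**2))
    if noise_sd > 0:
        zmap += rng.normal(0.0, noise_sd, size=mesh.n_vertices)
    return zmap
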