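"""Shared data containers for the high-gamma EEG mapping pipeline.

Everything downstream operates on a small set of plain dataclasses wrapping
numpy arrays: segmented trials, a triangulated cortical source space with its
forward model, time-frequency coefficient stacks, source-space amplitude/Z
maps, and result records for the permutation and proximity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path


@dataclass
class TriangleMesh:
    """Triangulated cortical surface; vertex coordinates in mm."""

    vertices: np.ndarray  # (n_vertices, 3) float, mm
    faces: np.ndarray     # (n_faces, 3) int vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates must be finite")
        n = self.n_vertices
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face indices out of range")
        referenced = np.zeros(n, dtype=bool)
        referenced[self.faces.ravel()] = True
        if not referenced.all():
            raise ValueError("every vertex must be referenced by at least one face")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @cached_property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric vertex adjacency: two vertices adjacent iff they share a face edge."""
        i = self.faces[:, [0, 1, 2]].ravel()
        j = self.faces[:, [1, 2, 0]].ravel()
        n = self.n_vertices
        a = sp.coo_matrix((np.ones_like(i, dtype=np.int8), (i, j)), shape=(n, n))
        a = ((a + a.T) > 0).astype(np.int8)
        return a.tocsr()

    @cached_property
    def neighbor_lists(self) -> list[np.ndarray]:
        a = self.adjacency
        return [a.indices[a.indptr[v]:a.indptr[v + 1]] for v in range(self.n_vertices)]

    @cached_property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        v = self.vertices
        f = self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        normals = np.zeros_like(v)
        for k in range(3):
            np.add.at(normals, f[:, k], fn)
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        normals = normals / norm
        # orient outward relative to the mesh centroid
        center = v.mean(axis=0)
        flip = np.einsum("ij,ij->i", normals, v - center) < 0
        normals[flip] *= -1.0
        return normals

    def edge_distance(self, source: int) -> np.ndarray:
        """Graph (hop) distance from ``source`` to every vertex."""
        d = shortest_path(self.adjacency, method="D", unweighted=True,
                          indices=source)
        return d

    def components(self) -> np.ndarray:
        return connected_components(self.adjacency, directed=False)[1]


@dataclass
class Leadfield:
    """Forward model: scalp potential per unit dipole moment, (channels, sources)."""

    gain: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    source_vertex_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("gain must be (channels, sources)")
        if not np.isfinite(self.gain).all():
            raise ValueError("gain must be finite")
        if np.any(np.all(self.gain == 0, axis=0)):
            raise ValueError("leadfield has an all-zero source column")
        if self.source_vertex_ids is None:
            self.source_vertex_ids = np.arange(self.gain.shape[1])
        else:
            self.source_vertex_ids = np.asarray(self.source_vertex_ids, dtype=np.int64)
        if not self.channel_names:
            self.channel_names = [f"ch{c:03d}" for c in range(self.gain.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class TrialSet:
    """Cue-locked segmented trials, (n_trials, n_channels, n_samples) in volts.

    ``time_s`` is the within-trial time axis relative to the cue; the standard
    protocol uses a 5 s window spanning [-2, 3) s.
    """

    data: np.ndarray
    fs: float
    time_s: np.ndarray
    labels: np.ndarray                  # per-trial condition, e.g. 'left'/'right'
    artifact_flags: np.ndarray | None = None
    channel_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.time_s.shape != (self.data.shape[2],):
            raise ValueError("time_s must match the sample axis")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels must match the trial axis")
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.data.shape[0], dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if self.artifact_flags.shape != (self.data.shape[0],):
            raise ValueError("artifact_flags must match the trial axis")
        if not self.channel_names:
            self.channel_names = [f"ch{c:03d}" for c in range((self.data.shape[1]))]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def retained(self) -> np.ndarray:
        """Indices of trials not flagged as artifact-contaminated."""
        return np.flatnonzero(~self.artifact_flags)


@dataclass
class TFCoefficients:
    """Complex Morlet coefficients, (n_trials, n_locations, n_freqs, n_times).

    ``domain`` says whether the location axis is EEG channels or cortical
    sources.  ``valid`` masks (freq, time) cells closer to the trial edge than
    one wavelet half-width; those cells are carried, never zeroed.
    """

    coef: np.ndarray
    freqs_hz: np.ndarray
    time_s: np.ndarray
    valid: np.ndarray
    domain: str = "channel"
    fs: float | None = None

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.coef.shape[2:] != (self.freqs_hz.size, self.time_s.size):
            raise ValueError("coef shape inconsistent with freq/time axes")
        if self.valid.shape != (self.freqs_hz.size, self.time_s.size):
            raise ValueError("valid mask must be (n_freqs, n_times)")
        if self.domain not in ("channel", "source"):
            raise ValueError("domain must be 'channel' or 'source'")

    @property
    def n_trials(self) -> int:
        return self.coef.shape[0]

    @property
    def n_locations(self) -> int:
        return self.coef.shape[1]

    def crop_time(self, t_min: float, t_max: float) -> "TFCoefficients":
        idx = np.flatnonzero((self.time_s >= t_min) & (self.time_s < t_max))
        sl = slice(idx[0], idx[-1] + 1) if idx.size else slice(0, 0)
        return TFCoefficients(self.coef[..., sl], self.freqs_hz,
                              self.time_s[sl], self.valid[:, sl],
                              domain=self.domain, fs=self.fs)


@dataclass
class TransferMatrix:
    """LCMV beamformer rows mapping channel data to source waveforms, (sources, channels)."""

    T: np.ndarray
    reg_lambda: float = 0.0
    source_vertex_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.T.ndim != 2:
            raise ValueError("T must be (sources, channels)")
        if self.source_vertex_ids is None:
            self.source_vertex_ids = np.arange(self.T.shape[0])


@dataclass
class SourceTFMap:
    """Trial-summed amplitude map a(v, f, t) and its baseline Z-scores.

    ``a`` is the plain sum of coefficient magnitudes over retained trials
    (no 1/N); ``z`` expresses each (v, f, t) in units of the standard
    deviation of ``a`` over the baseline window at that (v, f).
    """

    a: np.ndarray                     # (n_locations, n_freqs, n_times), >= 0
    freqs_hz: np.ndarray
    time_s: np.ndarray
    n_trials: int
    valid: np.ndarray                 # (n_freqs, n_times)
    p: np.ndarray | None = None       # optional power twin, sum |j|^2
    z: np.ndarray | None = None
    z_valid: np.ndarray | None = None  # (n_locations, n_freqs): False where baseline SD == 0
    baseline_s: tuple[float, float] = (-1.0, 0.0)
    signal_s: tuple[float, float] = (0.0, 1.0)
    domain: str = "source"


@dataclass
class PermutationResult:
    """Max-statistic permutation test outcome."""

    observed_max: float
    argmax: tuple[int, float, float]   # (location index, freq Hz, time s)
    null_max: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        loc, f, t = self.argmax
        return {
            "observed": float(self.observed_max),
            "argmax": {"location": int(loc), "freq_hz": float(f), "time_s": float(t)},
            "p": float(self.p_value),
            "n_perm": int(self.n_perm),
            "seed": int(self.seed),
        }


@dataclass
class SurfaceCluster:
    """Contiguous supra-threshold vertex set with centroid and mean spherical radius."""

    vertex_ids: np.ndarray
    centroid: np.ndarray      # (3,) mm
    mean_radius: float        # mm

    @property
    def size(self) -> int:
        return self.vertex_ids.size


@dataclass
class ProximityResult:
    """EEG-fMRI cluster goodness-of-match: per-pair distances and median compound."""

    pair_distances: np.ndarray | None   # mm, one per selected fMRI cluster
    compound: float | None              # mm, median of selected minimal distances
    p_value: float | None = None
    n_resamples: int | None = None
    seed: int | None = None
    reason: str | None = None           # set when the result is NA

    @property
    def is_na(self) -> bool:
        return self.compound is None

    def to_dict(self) -> dict:
        return {
            "pair_distances_mm": None if self.pair_distances is None
            else [float(d) for d in self.pair_distances],
            "compound_mm": None if self.compound is None else float(self.compound),
            "p": None if self.p_value is None else float(self.p_value),
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "reason": self.reason,
        }
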