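"""EEG-fMRI co-localization on the cortical surface.

Significant activity from each modality is grouped into contiguous
supra-threshold clusters under mesh edge adjacency.  Each cluster is reduced
to a centroid and a mean spherical radius (mean member-to-centroid Euclidean
distance); the distance between an EEG and an fMRI cluster is the centroid
separation minus both radii, floored at zero when the spheres overlap.  For
every fMRI cluster the nearest EEG cluster is selected (keeping only the
#EEG smallest distances when fMRI clusters outnumber EEG clusters), and the
median of the kept distances is the compound goodness-of-match in mm.
Plain 3-D distances stand in for geodesics: the measure is meant to flag
gross (multi-centimeter) mismatches, not millimeter geodesy.

Significance comes from relocating the fMRI clusters to random mesh
positions — preserving cluster count and exact vertex counts by growing
breadth-first patches — and comparing the observed compound against the
resampled histogram (smaller distance = better match).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numpy.random import default_rng
from scipy.sparse.csgraph import connected_components
from scipy.stats import norm

from .containers import ProximityResult, SurfaceCluster, TriangleMesh


def centroid_radius(vertex_ids: np.ndarray, mesh: TriangleMesh) -> SurfaceCluster:
    """Centroid (coordinate mean) and mean spherical radius of a vertex set."""
    vertex_ids = np.asarray(vertex_ids, dtype=np.int64)
    if vertex_ids.size == 0:
        raise ValueError("cluster must be non-empty")
    coords = mesh.vertices[vertex_ids]
    centroid = coords.mean(axis=0)
    radius = float(np.linalg.norm(coords - centroid, axis=1).mean())
    return SurfaceCluster(vertex_ids=vertex_ids, centroid=centroid,
                          mean_radius=radius)


def extract_clusters(vmap: np.ndarray, mesh: TriangleMesh, threshold: float,
                     mode: str = "z") -> list[SurfaceCluster]:
    """Connected components of supra-threshold vertices.

    ``mode='z'`` keeps vertices with value >= threshold; ``mode='p'`` keeps
    value <= threshold.  Returns clusters sorted by (descending size,
    ascending first vertex id); an empty supra-threshold set gives [].
    """
    vmap = np.asarray(vmap, dtype=float)
    if vmap.shape != (mesh.n_vertices,):
        raise ValueError("map length must equal the vertex count")
    if mode == "z":
        keep = vmap >= threshold
    elif mode == "p":
        keep = vmap <= threshold
    else:
        raise ValueError("mode must be 'z' or 'p'")
    ids = np.flatnonzero(keep)
    if ids.size == 0:
        return []
    sub = mesh.adjacency[np.ix_(ids, ids)]
    n_comp, labels = connected_components(sub, directed=False)
    clusters = [centroid_radius(ids[labels == k], mesh) for k in range(n_comp)]
    clusters.sort(key=lambda c: (-c.size, int(c.vertex_ids.min())))
    return clusters


def cluster_table(clusters: list[SurfaceCluster]):
    """Summary rows (cluster_id, size, centroid_xyz_mm, radius_mm)."""
    import pandas as pd

    return pd.DataFrame([
        {"cluster_id": k, "size": c.size,
         "centroid_x_mm": c.centroid[0], "centroid_y_mm": c.centroid[1],
         "centroid_z_mm": c.centroid[2], "radius_mm": c.mean_radius}
        for k, c in enumerate(clusters)])


def cluster_pair_distance(c1: SurfaceCluster, c2: SurfaceCluster) -> float:
    """max(0, ||centroid1 - centroid2|| - r1 - r2); overlap floors at zero."""
    d = float(np.linalg.norm(c1.centroid - c2.centroid))
    return max(0.0, d - c1.mean_radius - c2.mean_radius)


def proximity(eeg: list[SurfaceCluster], fmri: list[SurfaceCluster]
              ) -> ProximityResult:
    """Compound EEG-fMRI proximity (without significance).

    For each fMRI cluster, the distance to the nearest EEG cluster; if fMRI
    clusters outnumber EEG clusters only the #EEG smallest distances are
    kept; the compound is their median.  Either side empty gives an NA
    result (no match exists).
    """
    if not eeg or not fmri:
        side = "EEG" if not eeg else "fMRI"
        return ProximityResult(pair_distances=None, compound=None,
                               reason=f"no {side} clusters: no match exists")
    dmat = np.array([[cluster_pair_distance(f, e) for e in eeg] for f in fmri])
    nearest = dmat.min(axis=1)
    if len(fmri) > len(eeg):
        nearest = np.sort(nearest)[:len(eeg)]
    return ProximityResult(pair_distances=np.sort(nearest),
                           compound=float(np.median(nearest)))


def grow_patch(mesh: TriangleMesh, seed_vertex: int, size: int,
               rng: np.random.Generator,
               forbidden: set[int] | None = None) -> np.ndarray | None:
    """Connected vertex patch of exactly ``size``, grown breadth-first with a
    randomly ordered frontier; returns None if growth stalls (component too
    small or hemmed in by forbidden vertices)."""
    forbidden = forbidden or set()
    if seed_vertex in forbidden:
        return None
    members = [seed_vertex]
    in_patch = {seed_vertex}
    frontier = [seed_vertex]
    nbrs = mesh.neighbor_lists
    while len(members) < size:
        candidates = []
        for v in frontier:
            for u in nbrs[v]:
                u = int(u)
                if u not in in_patch and u not in forbidden:
                    candidates.append(u)
        candidates = sorted(set(candidates))
        if not candidates:
            return None
        rng.shuffle(candidates)
        take = candidates[:size - len(members)]
        members.extend(take)
        in_patch.update(take)
        frontier = take
    return np.asarray(members, dtype=np.int64)


def resample_clusters(fmri: list[SurfaceCluster], mesh: TriangleMesh,
                      rng: np.random.Generator,
                      max_tries: int = 200) -> list[SurfaceCluster]:
    """Relocate every fMRI cluster to a random position, preserving the
    cluster count and each cluster's exact vertex count; clusters within one
    resample stay disjoint."""
    used: set[int] = set()
    out = []
    for c in fmri:
        patch = None
        for _ in range(max_tries):
            seed_v = int(rng.integers(mesh.n_vertices))
            patch = grow_patch(mesh, seed_v, c.size, rng, forbidden=used)
            if patch is not None:
                break
        if patch is None:
            raise ValueError("cannot place a resampled cluster of size "
                             f"{c.size} on this mesh")
        used.update(int(v) for v in patch)
        out.append(centroid_radius(patch, mesh))
    return out


def resample_significance(fmri: list[SurfaceCluster],
                          eeg: list[SurfaceCluster],
                          mesh: TriangleMesh,
                          n_resamples: int = 1000,
                          seed: int = 0) -> ProximityResult:
    """Observed compound proximity with its resampling p-value.

    p = (1 + #{null compound <= observed}) / (1 + n_resamples): a smaller
    distance is a better match, and ties count against rejection.
    """
    obs = proximity(eeg, fmri)
    if obs.is_na:
        return ProximityResult(pair_distances=None, compound=None,
                               n_resamples=n_resamples, seed=seed,
                               reason=obs.reason)
    rng = default_rng(seed)
    null = np.empty(n_resamples)
    for r in range(n_resamples):
        surrogate = resample_clusters(fmri, mesh, rng)
        null[r] = proximity(eeg, surrogate).compound
    p = float((1 + np.sum(null <= obs.compound)) / (1 + n_resamples))
    return ProximityResult(pair_distances=obs.pair_distances,
                           compound=obs.compound, p_value=p,
                           n_resamples=n_resamples, seed=seed)


def group_average(zmaps: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Vertex-wise mean of per-subject maps sharing one mesh."""
    maps = np.asarray(zmaps, dtype=float)
    if maps.ndim != 2:
        raise ValueError("expected (n_subjects, n_vertices)")
    return maps.mean(axis=0)


def equivalent_group_threshold(z_single: float, n_subjects: int) -> float:
    """Group-map threshold matching a single-subject threshold.

    The mean of n independent standard-normal maps has SD 1/sqrt(n), so the
    threshold with the same tail level as ``z_single`` on one map is
    z_single / sqrt(n).
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    return float(z_single / np.sqrt(n_subjects))


def normal_confidence_level(z: float) -> float:
    """One-sided standard-normal confidence level Phi(z)."""
    return float(norm.cdf(z))
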