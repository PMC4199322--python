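"""HDF5 session container.

One file carries everything a session needs: /trials, /time_s, /labels,
/artifact_flags, /emg, /eog, the mesh as vertex/face arrays, the leadfield
gain, the simulation ground truth (when synthetic), the fMRI vertex map, and
any results written by later stages (/zmap, /permtest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from .containers import Leadfield, PermutationResult, TriangleMesh, TrialSet
from .synthdata import GroundTruth


@dataclass
class Session:
    trials: TrialSet
    mesh: TriangleMesh | None = None
    leadfield: Leadfield | None = None
    emg: np.ndarray | None = None
    eog: np.ndarray | None = None
    truth: GroundTruth | None = None
    fmri_zmap: np.ndarray | None = None


def save_session(path: str, s: Session) -> None:
    with h5py.File(path, "w") as h:
        ts = s.trials
        h.create_dataset("trials", data=ts.data, compression="gzip", compression_opts=1)
        h["time_s"] = ts.time_s
        h.attrs["fs"] = ts.fs
        h["labels"] = np.asarray(ts.labels, dtype="S")
        h["artifact_flags"] = ts.artifact_flags
        h["channel_names"] = np.asarray(ts.channel_names, dtype="S")
        if s.emg is not None:
            h.create_dataset("emg", data=s.emg, compression="gzip", compression_opts=1)
        if s.eog is not None:
            h.create_dataset("eog", data=s.eog, compression="gzip", compression_opts=1)
        if s.mesh is not None:
            h["mesh/vertices"] = s.mesh.vertices
            h["mesh/faces"] = s.mesh.faces
        if s.leadfield is not None:
            h["leadfield/gain"] = s.leadfield.gain
            h["leadfield/source_vertex_ids"] = s.leadfield.source_vertex_ids
        if s.truth is not None:
            g = h.create_group("truth")
            g["source_vertex_ids"] = s.truth.source_vertex_ids
            g["source_centers_hz"] = s.truth.source_centers_hz
            g.attrs["burst_onset_s"] = s.truth.burst_onset_s
            g.attrs["burst_offset_s"] = s.truth.burst_offset_s
            g["artifact_trial_ids"] = s.truth.artifact_trial_ids
        if s.fmri_zmap is not None:
            h["fmri/zmap"] = s.fmri_zmap


def load_session(path: str) -> Session:
    with h5py.File(path, "r") as h:
        ts = TrialSet(
            data=h["trials"][()], fs=float(h.attrs["fs"]),
            time_s=h["time_s"][()],
            labels=h["labels"][()].astype("U"),
            artifact_flags=h["artifact_flags"][()].astype(bool),
            channel_names=list(h["channel_names"][()].astype("U")))
        mesh = lf = truth = None
        if "mesh" in h:
            mesh = TriangleMesh(h["mesh/vertices"][()], h["mesh/faces"][()])
        if "leadfield" in h:
            lf = Leadfield(h["leadfield/gain"][()],
                           channel_names=list(ts.channel_names),
                           source_vertex_ids=h["leadfield/source_vertex_ids"][()])
        if "truth" in h:
            g = h["truth"]
            truth = GroundTruth(
                source_vertex_ids=g["source_vertex_ids"][()],
                source_centers_hz=g["source_centers_hz"][()],
                burst_onset_s=float(g.attrs["burst_onset_s"]),
                burst_offset_s=float(g.attrs["burst_offset_s"]),
                artifact_trial_ids=g["artifact_trial_ids"][()])
        emg = h["emg"][()] if "emg" in h else None
        eog = h["eog"][()] if "eog" in h else None
        fmri = h["fmri/zmap"][()] if "fmri" in h else None
    return Session(trials=ts, mesh=mesh, leadfield=lf, emg=emg, eog=eog,
                   truth=truth, fmri_zmap=fmri)


def update_flags(path: str, flags: np.ndarray) -> None:
    with h5py.File(path, "a") as h:
        h["artifact_flags"][...] = np.asarray(flags, dtype=bool)


def save_zmap(path: str, band: str, zmap: np.ndarray,
              freqs_hz: np.ndarray, time_s: np.ndarray) -> None:
    """Store a (sources, freqs, times) Z array under /zmap/<band>."""
    with h5py.File(path, "a") as h:
        g = h.require_group(f"zmap/{band}")
        for name in ("z", "freqs_hz", "time_s"):
            if name in g:
                del g[name]
        g.create_dataset("z", data=zmap, compression="gzip", compression_opts=1)
        g["freqs_hz"] = freqs_hz
        g["time_s"] = time_s


def save_tf(path: str, band: str, tf) -> None:
    """Store complex TF coefficients under /tf/<band>."""
    with h5py.File(path, "a") as h:
        g = h.require_group(f"tf/{band}")
        for name in ("coef", "freqs_hz", "time_s", "valid"):
            if name in g:
                del g[name]
        g.create_dataset("coef", data=tf.coef, compression="gzip",
                         compression_opts=1)
        g["freqs_hz"] = tf.freqs_hz
        g["time_s"] = tf.time_s
        g["valid"] = tf.valid
        g.attrs["domain"] = tf.domain


def load_tf(path: str, band: str):
    from .containers import TFCoefficients

    with h5py.File(path, "r") as h:
        g = h[f"tf/{band}"]
        return TFCoefficients(g["coef"][()], g["freqs_hz"][()], g["time_s"][()],
                              g["valid"][()].astype(bool),
                              domain=str(g.attrs["domain"]))


def save_permutation_result(path_json: str, result: PermutationResult) -> None:
    with open(path_json, "w") as f:
        json.dump(result.to_dict(), f, indent=2)
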