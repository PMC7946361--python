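"""Dipole forward projection from cortical sources to SEEG contacts.

Each vertex of the triangulated cortex acts as a current dipole oriented
along the outward surface normal (the pyramidal-cell population geometry).
The local field potential at a point contact ``x_s`` is the discretized
surface integral

    phi(x_s, t) = sum_v A_v * [n_v . (x_s - x_v) / |x_s - x_v|] /
                  (|x_s - x_v| + eps)^2 * s_v(t),

with ``eps`` (default 1 mm) regularizing the singularity at the surface.
The direction term at zero source-sensor distance is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .geometry import TriSurface

EPSILON_MM = 1.0
CONTACT_SPACING_MM = 1.5
GROUP_SIZE = 5
GROUP_GAP_MM = 9.0


@dataclass
class ElectrodeArray:
    """Point contacts organized along electrode shafts.

    ``table`` columns: name, electrode, shaft_index (0 = deepest contact),
    x, y, z (mm).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["name", "electrode", "shaft_index", "x", "y", "z"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"contact table missing columns {missing}")
        if self.table["name"].duplicated().any():
            raise ValueError("contact names must be unique")
        pos = self.positions
        if not np.all(np.isfinite(pos)):
            raise ValueError("contact positions must be finite")
        for label, sub in self.table.groupby("electrode"):
            idx = np.sort(sub["shaft_index"].to_numpy())
            if not np.array_equal(idx, np.arange(len(idx))):
                raise ValueError(f"shaft indices of electrode {label!r} not contiguous")

    @property
    def n_contacts(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def electrode_rows(self, label: str) -> pd.DataFrame:
        sub = self.table[self.table["electrode"] == label]
        return sub.sort_values("shaft_index")

    @classmethod
    def from_tsv(cls, path) -> "ElectrodeArray":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SensorRecording:
    """Multichannel monopolar sensor time-series."""

    data: np.ndarray                   # (n_channels, n_samples)
    fs: float
    electrodes: ElectrodeArray
    onset: float                       # seizure onset marker, s

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != self.electrodes.n_contacts:
            raise ValueError("channel count does not match contact count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("data", data=self.data)
            h5.create_dataset("fs", data=self.fs)
            h5.create_dataset("onset_marker", data=self.onset)
            tab = self.electrodes.table
            grp = h5.create_group("contacts")
            for col in ["name", "electrode"]:
                grp.create_dataset(col, data=np.array(tab[col], dtype="S"))
            for col in ["shaft_index", "x", "y", "z"]:
                grp.create_dataset(col, data=tab[col].to_numpy())

    @classmethod
    def from_hdf5(cls, path) -> "SensorRecording":
        with h5py.File(path, "r") as h5:
            data = h5["data"][()]
            fs = float(h5["fs"][()])
            onset = float(h5["onset_marker"][()])
            grp = h5["contacts"]
            tab = pd.DataFrame({
                "name": [s.decode() for s in grp["name"][()]],
                "electrode": [s.decode() for s in grp["electrode"][()]],
                "shaft_index": grp["shaft_index"][()],
                "x": grp["x"][()], "y": grp["y"][()], "z": grp["z"][()],
            })
        return cls(data, fs, ElectrodeArray(tab), onset)


def gain_matrix(surface: TriSurface, contact_positions: np.ndarray,
                eps: float = EPSILON_MM) -> np.ndarray:
    """(n_contacts, n_vertices) dipole gains.

    ``gain[c, v] = A_v * (n_v . u) / (r + eps)^2`` where ``u`` is the unit
    vector from vertex to contact and ``r`` their distance. Negating the
    vertex normals negates the gain (dipole antisymmetry).
    """
    if surface.vertex_area is None or surface.vertex_normal is None:
        raise ValueError("surface geometry not computed")
    if eps <= 0:
        raise ValueError("eps must be positive")
    contacts = np.atleast_2d(np.asarray(contact_positions, dtype=float))
    diff = contacts[:, None, :] - surface.vertices[None, :, :]   # (c, v, 3)
    r = np.linalg.norm(diff, axis=2)
    ndot = np.einsum("cvk,vk->cv", diff, surface.vertex_normal)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(r > 0.0, ndot / np.where(r > 0.0, r, 1.0), 0.0)
    return surface.vertex_area[None, :] * direction / (r + eps) ** 2


def project(gain: np.ndarray, activity) -> np.ndarray:
    """Project source activity to the sensors: ``phi = gain @ s``.

    ``activity`` is either a single (n_vertices, n_times) array or an
    iterable of such chunks; chunked evaluation concatenates along time and
    is identical to a single pass (pure linear map).
    """
    gain = np.asarray(gain)
    if isinstance(activity, np.ndarray):
        if activity.shape[0] != gain.shape[1]:
            raise ValueError("gain and activity disagree on vertex count")
        return gain @ activity
    chunks = [project(gain, np.asarray(c)) for c in activity]
    return np.concatenate(chunks, axis=1)


def calibrate_q(lp_traces: list[np.ndarray], p_rec: float, q_hat: float = 10.0,
                k_s: float = 30.0) -> float:
    """Calibrate the amplitude scaling from a batch of trial simulations.

    ``lp_traces`` holds one baseline-normalized log10 band-power trace per
    channel per calibration simulation (post-onset samples). ``p_sim`` is the
    95th percentile, across channels and simulations, of each channel's 80th
    percentile over time; the scaling is updated as
    ``q = 10 ** ((p_rec - p_sim) / 2) * q_hat`` (amplitude scales power by
    q^2, i.e. 2*log10 q). ``p_rec`` comes from the recorded seizures and is a
    required input. Raises if no channel in the batch reaches the seizing
    threshold ``log10(k_s)``.
    """
    if q_hat <= 0:
        raise ValueError("q_hat must be positive")
    if not lp_traces:
        raise ValueError("calibration batch is empty")
    per_channel = np.array([np.percentile(lp, 80) for lp in lp_traces])
    p90s = np.array([np.percentile(lp, 90) for lp in lp_traces])
    if not np.any(p90s >= np.log10(k_s)):
        raise ValueError("no seizing channels in the calibration batch")
    p_sim = float(np.percentile(per_channel, 95))
    return float(10.0 ** ((p_rec - p_sim) / 2.0) * q_hat)
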