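"""Synthetic geometry, electrodes and signals for exercising the pipeline.

No patient surfaces, implantations or recordings ship with this package;
everything the pipeline consumes is generated here: triangulated sheets with
a controlled edge length, depth-electrode shafts with the clinical contact
layouts (1.5 mm uniform spacing, or groups of five separated by 9 mm),
single-channel detector fixtures with machine-readable ground truth, and a
stand-in "recordings" fingerprint sample for the comparison stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import signal as sps

from .geometry import TriSurface, compute_vertex_geometry
from .forward import (ElectrodeArray, CONTACT_SPACING_MM, GROUP_SIZE,
                      GROUP_GAP_MM)
from .sources import pink_noise, triangle_wave

DEFAULT_FS = 256.0


# ---------------------------------------------------------------------------
# Surfaces

def make_flat_sheet(extent: tuple[float, float] = (60.0, 60.0),
                    edge_length: float = 1.0) -> TriSurface:
    """Regular triangulated sheet in the z=0 plane, normals +z.

    Rows are offset by half an edge and spaced by edge*sqrt(3)/2, giving a
    near-equilateral triangulation whose mean edge length is within a few
    percent of the target.
    """
    if edge_length <= 0 or min(extent) <= 0:
        raise ValueError("extent and edge length must be positive")
    lx, ly = extent
    nx = int(round(lx / edge_length)) + 1
    dy = edge_length * np.sqrt(3.0) / 2.0
    ny = int(round(ly / dy)) + 1
    verts = []
    for j in range(ny):
        xoff = 0.5 * edge_length if j % 2 else 0.0
        for i in range(nx):
            verts.append((i * edge_length + xoff, j * dy, 0.0))
    verts = np.array(verts)

    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            b = a + 1
            c = a + nx
            d = c + 1
            if j % 2 == 0:
                tris.append((a, b, c))
                tris.append((b, d, c))
            else:
                tris.append((a, b, d))
                tris.append((a, d, c))
    surface = TriSurface(verts, np.array(tris, dtype=np.int64))
    return compute_vertex_geometry(surface)


def make_folded_sheet(extent: tuple[float, float] = (60.0, 60.0),
                      edge_length: float = 1.0, amplitude: float = 5.0,
                      fold_wavelength: float = 30.0) -> TriSurface:
    """Flat sheet displaced by z = A sin(2 pi x / lambda) (a gyral fold)."""
    sheet = make_flat_sheet(extent, edge_length)
    verts = sheet.vertices.copy()
    verts[:, 2] = amplitude * np.sin(2.0 * np.pi * verts[:, 0] / fold_wavelength)
    return compute_vertex_geometry(TriSurface(verts, sheet.triangles))


def make_icosphere(radius: float = 10.0, subdivisions: int = 3) -> TriSurface:
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return compute_vertex_geometry(
        TriSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces)))


def mean_edge_length(surface: TriSurface) -> float:
    g = surface.edge_graph()
    return float(g.data.mean()) if g.nnz else 0.0


# ---------------------------------------------------------------------------
# Electrodes

@dataclass
class ShaftSpec:
    label: str
    start: tuple[float, float, float]
    direction: tuple[float, float, float]
    n_contacts: int = 10
    layout: str = "uniform"            # uniform | grouped
    spacing: float = CONTACT_SPACING_MM
    group_size: int = GROUP_SIZE
    group_gap: float = GROUP_GAP_MM


def contact_offsets(spec: ShaftSpec) -> np.ndarray:
    """Distance of each contact from the shaft tip, per the layout."""
    i = np.arange(spec.n_contacts)
    if spec.layout == "uniform":
        return i * spec.spacing
    if spec.layout == "grouped":
        within = (i % spec.group_size) * spec.spacing
        group = (i // spec.group_size) * ((spec.group_size - 1) * spec.spacing
                                          + spec.group_gap)
        return within + group
    raise ValueError(f"unknown layout {spec.layout!r}")


def make_electrodes(specs: list[ShaftSpec]) -> ElectrodeArray:
    """Place point contacts along straight shaft lines."""
    rows = []
    for spec in specs:
        direction = np.asarray(spec.direction, dtype=float)
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise ValueError("shaft direction must be non-zero")
        direction = direction / norm
        start = np.asarray(spec.start, dtype=float)
        for i, off in enumerate(contact_offsets(spec)):
            x, y, z = start + off * direction
            rows.append({"name": f"{spec.label}{i + 1}", "electrode": spec.label,
                         "shaft_index": i, "x": x, "y": y, "z": z})
    return ElectrodeArray(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Default end-to-end scenario

@dataclass
class Scenario:
    """Default synthetic implantation: a flat sheet with two shafts.

    One shaft runs parallel to the sheet's x axis (the axis along which a
    spreading seizure crossing the sheet center propagates past the
    contacts), the other perpendicular to it; both hover 2 mm above the
    surface so the contacts see positive-normal dipole gains.
    """

    extent: tuple[float, float] = (60.0, 60.0)
    edge_length: float = 1.0
    shaft_height: float = 2.0
    n_contacts: int = 10
    t_pre: float = 60.0                # s of preictal baseline
    t_post: float = 60.0               # s of ictal signal
    fs: float = DEFAULT_FS

    surface: TriSurface = field(init=False, repr=False)
    electrodes: ElectrodeArray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.surface = make_flat_sheet(self.extent, self.edge_length)
        cx, cy = self.extent[0] / 2.0, self.extent[1] / 2.0
        span = (self.n_contacts - 1) * CONTACT_SPACING_MM
        self.electrodes = make_electrodes([
            ShaftSpec("PAR", (cx - span / 2.0, cy, self.shaft_height), (1, 0, 0),
                      n_contacts=self.n_contacts),
            ShaftSpec("PERP", (cx, cy - span / 2.0 - 6.0, self.shaft_height), (0, 1, 0),
                      n_contacts=self.n_contacts),
        ])

    @property
    def onset(self) -> float:
        return self.t_pre

    @property
    def duration(self) -> float:
        return self.t_pre + self.t_post

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


# ---------------------------------------------------------------------------
# Detector fixtures

FIXTURE_KINDS = ("taa_clean", "taa_noisy", "lvfa_like", "flat_noise", "slow_spikes")


def _band_variance(x: np.ndarray, fs: float, band=(4.0, 13.0)) -> float:
    """Band-limited variance via a Butterworth bandpass (detector-independent)."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return float(sps.sosfiltfilt(sos, x).var())


def make_detector_fixture(kind: str, fs: float = DEFAULT_FS, seed: int = 0,
                          t_pre: float = 60.0, t_post: float = 70.0) -> dict:
    """Single-channel signal with programmed detection ground truth.

    Returns a dict with ``signal``, ``fs``, ``onset`` and the expected
    outcome: ``expected_class`` always; for the taa kinds also ``t_o``,
    ``t_t`` (the programmed threshold-crossing times) and ``f0``.

    The taa fixtures ramp the theta-alpha log10 band power linearly from 0
    to a plateau level L over a programmed window, by shaping the carrier
    amplitude as a(t) = sqrt(P_base*(10^(L*u(t)) - 1)/P_unit); the detector
    thresholds k1*P90 and k2*P90 with P90 ~= L then cross at the programmed
    fractions of the ramp.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    rng = np.random.default_rng(seed)
    n = int(round((t_pre + t_post) * fs))
    t = np.arange(n) / fs
    onset = t_pre
    noise_amp = 1.0
    noise = noise_amp * pink_noise(n, fs, rng)
    out = {"fs": fs, "onset": onset}

    if kind == "flat_noise":
        out.update(signal=noise, expected_class="non_seizing")
        return out

    if kind == "lvfa_like":
        # abrupt-onset broadband burst: seizing by band power, but the
        # flattened spectrum peaks well above the theta-alpha range
        sos = sps.butter(4, (4.0, 45.0), btype="bandpass", fs=fs, output="sos")
        burst = sps.sosfilt(sos, rng.standard_normal(n))
        burst /= burst.std()
        gate = t >= onset + 5.0
        out.update(signal=noise + 60.0 * gate * burst, expected_class="seizing")
        return out

    if kind == "slow_spikes":
        # periodic sharp transients at 1.5 Hz: harmonics of a fundamental
        # below the theta-alpha band, so the peak pattern fails the check
        period = 1.0 / 1.5
        phase = np.mod(t - onset - 5.0, period)
        spikes = np.exp(-0.5 * (np.minimum(phase, period - phase) / 0.02) ** 2)
        gate = t >= onset + 5.0
        out.update(signal=noise + 80.0 * gate * spikes, expected_class="seizing")
        return out

    # taa_clean / taa_noisy: 8 Hz triangle carrier, log-power ramp
    f0 = 8.0
    level = 4.0
    ramp_start, ramp_len = onset + 3.0, 8.0
    if kind == "taa_noisy":
        noise = 1.6 * pink_noise(n, fs, rng)
        level = 5.0
    carrier = triangle_wave(t - ramp_start, f0)
    p_base = _band_variance(noise, fs)
    p_unit = _band_variance(carrier, fs)
    u = np.clip((t - ramp_start) / ramp_len, 0.0, 1.0)
    amp = np.sqrt(p_base * (10.0 ** (level * u) - 1.0) / p_unit)
    signal = noise + amp * carrier
    # programmed crossings assuming P90 ~= plateau level
    out.update(signal=signal, expected_class="taa", f0=f0,
               t_o=ramp_start + 0.15 * ramp_len,
               t_t=ramp_start + 0.85 * ramp_len)
    return out


# ---------------------------------------------------------------------------
# Stand-in recordings fingerprints

def make_pseudo_recordings_features(n: int = 32, seed: int = 0) -> np.ndarray:
    """Synthetic stand-in for an observed TAA-group fingerprint sample.

    Draws n five-dimensional fingerprints (slope s/mm, onset R^2, duration
    s, PCA VE1, VE2) from a fixed mixture whose marginals respect the
    feature-space semantics: slope >= 0 and mostly small, R^2 in [0, 1],
    duration skewed to 3-7 s, VE1 skewed high with VE1 <= VE2 <= 1. This is
    synthetic plumbing for tests and demonstrations, not observed data.
    """
    if n < 4:
        raise ValueError("need at least four fingerprints")
    rng = np.random.default_rng(seed)
    slope = rng.exponential(0.25, size=n)
    r2 = rng.beta(1.2, 1.2, size=n)
    duration = rng.lognormal(mean=np.log(4.5), sigma=0.45, size=n)
    ve1 = rng.beta(5.0, 1.5, size=n)
    ve2 = ve1 + (1.0 - ve1) * rng.beta(4.0, 1.2, size=n)
    return np.column_stack([slope, r2, duration, ve1, ve2])
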