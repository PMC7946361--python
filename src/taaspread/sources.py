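"""Seizure source activity on the cortical surface.

Three generative models share a common structure: a small excitable patch of
cortex carries seizure oscillations while the rest of the surface emits
background noise.

* ``one_source`` — the whole patch switches on at ``t0`` and oscillates as a
  triangle wave whose amplitude ramps up linearly over the onset duration
  ``delta``. The gradual amplitude growth is present at the source level.
* ``two_sources`` — two disjoint patches, the second switching on with a
  delay ``Delta``; each has its own onset duration.
* ``spreading`` — a slow ictal wavefront expands geodesically from a random
  origin at ``u_spread`` mm/s; each recruited vertex starts a pulse-wave
  oscillation instantly, phase-delayed by ``d/u_wave`` to emulate fast
  traveling waves inside the recruited territory. Here the gradual amplitude
  growth only appears at the sensor level, through spatial averaging.

Waveforms are normalized to unit variance over whole periods: the triangle
wave has peak amplitude sqrt(3), the duty-cycle-0.25 pulse wave has high
level sqrt(16/3). Background noise is pink (1/f), unit variance, shared
within ~100 mm^2 surface patches; seizure noise is pink in time and
spatially correlated with kernel exp(-d/l), l = 10 mm geodesic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .geometry import (TriSurface, SurfacePatch, SurfacePartition,
                       geodesic_distances, grow_patch,
                       grow_patches_simultaneous, partition_surface)

TRIANGLE_AMP = np.sqrt(3.0)           # unit-variance triangle wave peak
DUTY_CYCLE = 0.25
MAX_CONTACT_DISTANCE = 15.0           # mm, patch center to nearest contact
TWO_SOURCE_CENTER_DISTANCE = 10.0     # mm, between the two patch centers
NOISE_CORRELATION_LENGTH = 10.0       # mm, seizure-noise kernel length
BACKGROUND_PATCH_AREA = 100.0         # mm^2, background-noise patch size

#: Uniform sampling ranges for the model parameters.
PARAM_RANGES = {
    "patch_size": (400.0, 2500.0),   # mm^2
    "f": (4.0, 13.0),                # Hz
    "delta": (1.0, 30.0),            # s, one/two-source onset duration
    "Delta": (0.0, 10.0),            # s, two-source onset delay
    "u_spread": (0.5, 4.0),          # mm/s, wavefront velocity
    "u_wave": (100.0, 500.0),        # mm/s, fast-wave velocity
}

#: Amplitude scaling q per (model kind, noisy flag), calibrated against
#: recorded log-power levels.
Q_DEFAULTS = {
    ("one_source", False): 8.16, ("one_source", True): 7.87,
    ("two_sources", False): 9.96, ("two_sources", True): 9.85,
    ("spreading", False): 16.28, ("spreading", True): 15.34,
}

MODEL_KINDS = ("one_source", "two_sources", "spreading")


def pulse_amplitude(duty: float) -> float:
    """High level of a zero-offset-free pulse wave with unit variance."""
    return 1.0 / np.sqrt(duty * (1.0 - duty))


def triangle_wave(t, f: float) -> np.ndarray:
    """Unit-variance triangle wave: +sqrt(3) at phase 0, -sqrt(3) at phase 1/2."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    frac = np.mod(np.asarray(t, dtype=float) * f, 1.0)
    return TRIANGLE_AMP * np.where(frac < 0.5, 1.0 - 4.0 * frac, 4.0 * frac - 3.0)


def pulse_wave(t, f: float, duty: float = DUTY_CYCLE) -> np.ndarray:
    """Unit-variance pulse wave: high for the first ``duty`` of each period."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    if not 0.0 < duty < 1.0:
        raise ValueError("duty cycle must lie in (0, 1)")
    frac = np.mod(np.asarray(t, dtype=float) * f, 1.0)
    return np.where(frac < duty, pulse_amplitude(duty), 0.0)


@dataclass
class SourceParams:
    """One sampled model configuration."""

    model_kind: str
    patch_size: float
    f: float
    q: float
    noisy: bool
    t0: float = 60.0
    delta: float | None = None        # one-source onset duration
    delta2: float | None = None       # two-source: second patch onset duration
    Delta: float | None = None        # two-source onset delay
    u_spread: float | None = None
    u_wave: float | None = None
    duty: float = DUTY_CYCLE
    seed: int | None = None

    @property
    def alpha(self) -> int:
        return int(self.noisy)


def sample_params(model_kind: str, rng: np.random.Generator, *,
                  noisy: bool = False, ranges: dict | None = None,
                  q: float | None = None, t0: float = 60.0,
                  shared_delta: bool = False, seed: int | None = None) -> SourceParams:
    """Draw one parameter set uniformly from the prescribed ranges."""
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    r = dict(PARAM_RANGES)
    if ranges:
        r.update(ranges)
    for lo, hi in r.values():
        if hi < lo:
            raise ValueError("empty parameter range")

    def draw(name):
        lo, hi = r[name]
        return float(rng.uniform(lo, hi))

    p = SourceParams(
        model_kind=model_kind,
        patch_size=draw("patch_size"),
        f=draw("f"),
        q=Q_DEFAULTS[(model_kind, noisy)] if q is None else q,
        noisy=noisy, t0=t0, seed=seed,
    )
    if model_kind in ("one_source", "two_sources"):
        p.delta = draw("delta")
    if model_kind == "two_sources":
        p.delta2 = p.delta if shared_delta else draw("delta")
        p.Delta = draw("Delta")
    if model_kind == "spreading":
        p.u_spread = draw("u_spread")
        p.u_wave = draw("u_wave")
    return p


@dataclass
class SourceConfiguration:
    """Placement of the excitable patch(es) on a surface.

    For the spreading model, ``origin`` is the seizure origin vertex and
    ``origin_distance`` the geodesic distance from it to every patch member
    (same order as ``patches[0].members``).
    """

    patches: list
    origin: int | None = None
    origin_distance: np.ndarray | None = None

    @property
    def member_index(self) -> np.ndarray:
        return np.concatenate([p.members for p in self.patches])


def place_patches(surface: TriSurface, contact_positions: np.ndarray,
                  params: SourceParams, rng: np.random.Generator,
                  max_contact_distance: float = MAX_CONTACT_DISTANCE,
                  center_distance: float = TWO_SOURCE_CENTER_DISTANCE,
                  ) -> SourceConfiguration:
    """Place the excitable patch(es) near the implanted contacts.

    Patch centers are drawn uniformly from vertices closer than
    ``max_contact_distance`` (Euclidean) to any contact. For the two-source
    model the second center must additionally lie within ``center_distance``
    of the first, and the second patch is grown excluding the vertices of the
    first so the patches stay disjoint. For the spreading model the seizure
    origin is drawn uniformly from the patch vertices.
    """
    contact_positions = np.asarray(contact_positions, dtype=float)
    d2 = ((surface.vertices[:, None, :] - contact_positions[None, :, :]) ** 2).sum(-1)
    near = np.sqrt(d2.min(axis=1)) < max_contact_distance
    admissible = np.flatnonzero(near)
    if admissible.size == 0:
        raise ValueError(
            f"no surface vertex lies within {max_contact_distance} mm of a contact")

    if params.model_kind == "two_sources":
        c1 = int(rng.choice(admissible))
        close = np.linalg.norm(surface.vertices[admissible] - surface.vertices[c1],
                               axis=1) < center_distance
        cand2 = admissible[close]
        cand2 = cand2[cand2 != c1]
        if cand2.size == 0:
            raise ValueError(
                f"no admissible second center within {center_distance} mm of the first")
        c2 = int(rng.choice(cand2))
        # the centers lie within each other's patch radius, so the two
        # disjoint patches are grown simultaneously from both centers
        p1, p2 = grow_patches_simultaneous(surface, [c1, c2],
                                           [params.patch_size / 2.0] * 2)
        return SourceConfiguration(patches=[p1, p2])

    center = int(rng.choice(admissible))
    patch = grow_patch(surface, center, params.patch_size)
    if params.model_kind == "spreading":
        origin = int(rng.choice(patch.members))
        dist = geodesic_distances(surface, origin)[patch.members]
        return SourceConfiguration(patches=[patch], origin=origin, origin_distance=dist)
    return SourceConfiguration(patches=[patch])


# ---------------------------------------------------------------------------
# Noise

def pink_noise(n_samples: int, fs: float, rng: np.random.Generator,
               size: int | None = None) -> np.ndarray:
    """Unit-variance pink (1/f) noise, spectrally shaped white noise.

    The white series is shaped with a 1/sqrt(f) amplitude profile in the
    rFFT domain (DC bin zeroed) and rescaled to exactly unit sample variance.
    Returns shape (n_samples,) or (size, n_samples).
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    shape = (n_samples,) if size is None else (size, n_samples)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    k = np.arange(spec.shape[-1], dtype=float)
    scale = np.zeros_like(k)
    scale[1:] = 1.0 / np.sqrt(k[1:])
    series = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    series -= series.mean(axis=-1, keepdims=True)
    series /= series.std(axis=-1, keepdims=True)
    return series


@dataclass
class BackgroundNoise:
    """Pink background noise shared within ~100 mm^2 surface patches."""

    partition: SurfacePartition
    series: np.ndarray                 # (n_patches, n_samples)
    scale: float = 1.0

    def vertex_series(self, vertices, t_slice=slice(None)) -> np.ndarray:
        labels = self.partition.labels[np.asarray(vertices, dtype=np.int64)]
        return self.scale * self.series[:, t_slice][labels]


def background_noise(surface: TriSurface, n_samples: int, fs: float,
                     rng: np.random.Generator,
                     mean_patch_area: float = BACKGROUND_PATCH_AREA,
                     scale: float = 1.0) -> BackgroundNoise:
    partition = partition_surface(surface, mean_patch_area, rng)
    series = pink_noise(n_samples, fs, rng, size=partition.n_patches)
    return BackgroundNoise(partition, series, scale)


@dataclass
class CorrelatedNoise:
    """Lazy per-vertex seizure noise ``nu = factor @ modes``.

    ``factor`` rows are unit-norm, so every vertex series is a fixed mixture
    of independent unit-variance pink modes — itself pink with unit variance
    in expectation — and the inter-vertex correlation approximates the
    geodesic kernel exp(-d/l).
    """

    vertices: np.ndarray               # patch member indices, factor row order
    factor: np.ndarray                 # (n_vertices, n_modes)
    modes: np.ndarray                  # (n_modes, n_samples)

    def chunk(self, t_slice) -> np.ndarray:
        return self.factor @ self.modes[:, t_slice]

    def full(self) -> np.ndarray:
        return self.chunk(slice(None))


def _farthest_point_anchors(points: np.ndarray, n_anchors: int) -> np.ndarray:
    """Deterministic farthest-point sampling (Euclidean) starting at index 0."""
    n = len(points)
    chosen = [0]
    dist = np.linalg.norm(points - points[0], axis=1)
    for _ in range(1, min(n_anchors, n)):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(chosen, dtype=np.int64)


def correlated_seizure_noise(surface: TriSurface, patch: SurfacePatch,
                             n_samples: int, fs: float, rng: np.random.Generator,
                             l: float = NOISE_CORRELATION_LENGTH,
                             dense_threshold: int = 512,
                             n_anchors: int = 160) -> CorrelatedNoise:
    """Spatially correlated pink noise on the patch vertices.

    Small patches use the exact dense route: the geodesic kernel matrix is
    eigendecomposed (negative eigenvalues from symmetrization clipped to
    zero, i.e. projection to the nearest PSD matrix). Larger patches use a
    Nystrom low-rank factor built from geodesic distances to
    farthest-point-sampled anchor vertices. In both routes the factor rows
    are renormalized to unit norm so each vertex has unit variance.
    """
    members = patch.members
    n = len(members)
    if n == 0:
        raise ValueError("patch is empty")
    graph = surface.edge_graph()
    limit = 15.0 * l    # kernel below ~3e-7 past this distance

    if n <= dense_threshold:
        d = dijkstra(graph, directed=False, indices=members, limit=limit)[:, members]
        d = np.minimum(d, limit)
        kernel = np.exp(-0.5 * (d + d.T) / l)
        eigval, eigvec = np.linalg.eigh(kernel)
        eigval = np.clip(eigval, 0.0, None)
        factor = eigvec * np.sqrt(eigval)
    else:
        anchors_local = _farthest_point_anchors(surface.vertices[members], n_anchors)
        anchors = members[anchors_local]
        d_am = dijkstra(graph, directed=False, indices=anchors, limit=limit)[:, members]
        d_am = np.minimum(d_am, limit)
        k_am = np.exp(-d_am / l)                       # (r, n)
        k_aa = 0.5 * (k_am[:, anchors_local] + k_am[:, anchors_local].T)
        eigval, eigvec = np.linalg.eigh(k_aa)
        keep = eigval > 1e-10 * eigval.max()
        inv_sqrt = eigvec[:, keep] / np.sqrt(eigval[keep])
        factor = k_am.T @ inv_sqrt                     # (n, r')

    norms = np.linalg.norm(factor, axis=1)
    norms[norms == 0.0] = 1.0
    factor = factor / norms[:, None]
    modes = pink_noise(n_samples, fs, rng, size=factor.shape[1])
    return CorrelatedNoise(members.copy(), factor, modes)


# ---------------------------------------------------------------------------
# Source activity

def recruitment_times(config: SourceConfiguration, params: SourceParams) -> np.ndarray:
    """Per-member seizure onset time (same order as config.member_index)."""
    if params.model_kind == "one_source":
        return np.full(len(config.patches[0].members), params.t0)
    if params.model_kind == "two_sources":
        n1, n2 = (len(p.members) for p in config.patches)
        return np.concatenate([np.full(n1, params.t0),
                               np.full(n2, params.t0 + params.Delta)])
    return params.t0 + config.origin_distance / params.u_spread


def seizure_activity(config: SourceConfiguration, params: SourceParams,
                     t: np.ndarray,
                     seizure_noise: CorrelatedNoise | None = None,
                     noise_slice=slice(None)) -> tuple[np.ndarray, np.ndarray]:
    """Seizure-driven activity on the patch members for times ``t``.

    Returns ``(activity, recruited_mask)`` of shape (n_members, len(t)).
    Unrecruited entries are zero in ``activity``; the caller substitutes the
    background noise there. ``noise_slice`` selects the matching time window
    of the precomputed seizure-noise modes so chunked evaluation is bitwise
    identical to a single pass.
    """
    t = np.asarray(t, dtype=float)
    members = config.member_index
    nu = 0.0
    if params.alpha and seizure_noise is not None:
        nu = seizure_noise.chunk(noise_slice)

    if params.model_kind == "spreading":
        d = config.origin_distance
        recruited = d[:, None] < (t[None, :] - params.t0) * params.u_spread
        phase_t = t[None, :] - params.t0 - d[:, None] / params.u_wave
        wave = pulse_wave(phase_t, params.f, params.duty)
        act = params.q * (wave + (params.alpha * nu if params.alpha else 0.0))
        return np.where(recruited, act, 0.0), recruited

    # one or two homogeneous sources: amplitude ramps over the onset duration
    onsets, deltas, sizes = [], [], []
    if params.model_kind == "one_source":
        onsets, deltas = [params.t0], [params.delta]
        sizes = [len(config.patches[0].members)]
    else:
        onsets = [params.t0, params.t0 + params.Delta]
        deltas = [params.delta, params.delta2]
        sizes = [len(p.members) for p in config.patches]

    act = np.zeros((len(members), len(t)))
    recruited = np.zeros((len(members), len(t)), dtype=bool)
    row = 0
    for t0i, di, ni in zip(onsets, deltas, sizes):
        rows = slice(row, row + ni)
        mask = t >= t0i
        env = np.minimum(1.0, (t - t0i) / di)
        wave = triangle_wave(t - t0i, params.f)
        common = env * wave
        block = np.broadcast_to(common, (ni, len(t))).copy()
        if params.alpha and seizure_noise is not None:
            block = common[None, :] + env[None, :] * nu[rows]
        # Eq structure: q * min(1,(t-t0)/delta) * (y_s + alpha*nu)
        act[rows] = params.q * np.where(mask[None, :], block, 0.0)
        recruited[rows] = mask[None, :]
        row += ni
    return act, recruited


def source_activity(surface: TriSurface, config: SourceConfiguration,
                    params: SourceParams, background: BackgroundNoise,
                    t: np.ndarray, t_slice,
                    seizure_noise: CorrelatedNoise | None = None) -> np.ndarray:
    """Full per-vertex activity s(x, t) over a time window.

    ``t`` is the time stamp array of the window and ``t_slice`` the matching
    index window into the full simulation timeline (used to slice the
    precomputed noise series so chunked evaluation reproduces a single pass
    exactly). Vertices outside the recruited territory carry background
    noise only.
    """
    t = np.asarray(t, dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9):
            raise ValueError("time array must be sorted and uniform")
    act = background.vertex_series(np.arange(surface.n_vertices), t_slice).copy()
    seiz, recruited = seizure_activity(config, params, t, seizure_noise, t_slice)
    members = config.member_index
    act[members] = np.where(recruited, seiz, act[members])
    return act
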