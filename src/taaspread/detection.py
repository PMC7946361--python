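"""Two-step theta-alpha-activity (TAA) detection and group fingerprinting.

Step 1 locates, per channel, a tentative interval of band-power growth: the
4-13 Hz multitaper log10 power (normalized so that its preictal mean is 0)
must reach ``k_s = 30`` times the baseline at its post-onset 90th percentile
(``P90 >= log10 30``, the *seizing* criterion); the terminal time ``t_t`` is
the first upward crossing of ``k2 * P90`` after the onset marker and the
onset ``t_o`` is the last time before ``t_t`` at which the trace was below
``k1 * P90``.

Step 2 confirms the TAA morphology: the log-power growth over [t_o, t_t]
must be close to linear (R^2 > 0.75), and the frequency-flattened,
max-normalized power spectrum of the raw signal in that interval must have
its largest peak ``f0`` inside 4-13 Hz with every other peak a harmonic of
``f0`` within 0.15*f0.

TAA patterns on >= 4 consecutive contacts of one electrode form a *TAA
group*, fingerprinted by five features: |slope| and R^2 of the regression of
onset times on contact position along the shaft, mean TAA duration, and the
variance explained by the first one and two principal components of the
member signals over [min t_o, max t_t].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .forward import ElectrodeArray, SensorRecording

FEATURE_NAMES = ["slope", "r2", "duration", "ve1", "ve2"]


@dataclass
class DetectorConfig:
    band: tuple[float, float] = (4.0, 13.0)
    time_bandwidth: float = 2.0
    n_cycles: float = 8.0
    baseline_duration: float = 60.0      # s before the onset marker
    k_s: float = 30.0                    # seizing power ratio threshold
    k_1: float = 0.15                    # lower interval threshold coefficient
    k_2: float = 0.85                    # upper interval threshold coefficient
    r2_min: float = 0.75
    psd_range: tuple[float, float] = (1.0, 100.0)
    peak_min_height: float = 0.25
    peak_min_distance: float = 2.0       # Hz
    harmonic_tolerance: float = 0.15     # fraction of f0
    group_min_contacts: int = 4
    lp_time_step: float = 0.25           # s, log-power grid resolution

    def __post_init__(self) -> None:
        if not 0.0 < self.k_1 < self.k_2 <= 1.0:
            raise ValueError("need 0 < k_1 < k_2 <= 1")


@dataclass
class ChannelResult:
    cls: str                             # non_seizing | seizing | taa
    p90: float = np.nan
    t_o: float = np.nan
    t_t: float = np.nan
    f0: float = np.nan
    r2_growth: float = np.nan
    onset_delay: float = np.nan

    @property
    def is_taa(self) -> bool:
        return self.cls == "taa"


@dataclass
class TAAGroup:
    electrode: str
    channel_indices: np.ndarray          # recording channel indices, deep-first
    features: dict = field(default_factory=dict)


def band_logpower(data: np.ndarray, fs: float, onset: float,
                  config: DetectorConfig = DetectorConfig()
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-normalized log10 band power on a coarse time grid.

    Multitaper power is evaluated on a 1-Hz grid across the band, averaged
    over frequencies, log10-transformed and shifted so that the mean over
    the ``baseline_duration`` preceding the onset marker is exactly zero.
    Returns ``(times, lp)`` with ``lp`` of shape (n_channels, n_times).
    """
    from mne.time_frequency import tfr_array_multitaper

    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_times = data.shape[1]
    if onset < config.baseline_duration - 1e-9:
        raise ValueError("recording too short before the onset marker for a baseline")
    decim = max(1, int(round(fs * config.lp_time_step)))
    freqs = np.arange(config.band[0], config.band[1] + 0.5)
    power = tfr_array_multitaper(
        data[None, :, :], sfreq=fs, freqs=freqs, n_cycles=config.n_cycles,
        time_bandwidth=config.time_bandwidth, output="power", decim=decim,
        zero_mean=True, verbose="error")[0]
    times = np.arange(n_times)[::decim] / fs
    band_power = power.mean(axis=1)
    tiny = np.finfo(float).tiny
    lp = np.log10(np.maximum(band_power, tiny))
    baseline = (times >= onset - config.baseline_duration) & (times < onset)
    if not baseline.any():
        raise ValueError("no baseline samples before the onset marker")
    lp -= lp[:, baseline].mean(axis=1, keepdims=True)
    return times, lp


def _interp_crossing(times: np.ndarray, lp: np.ndarray, i0: int, i1: int,
                     level: float) -> float:
    """Linear interpolation of the crossing time between two grid points."""
    y0, y1 = lp[i0], lp[i1]
    if y1 == y0:
        return float(times[i1])
    w = (level - y0) / (y1 - y0)
    return float(times[i0] + w * (times[i1] - times[i0]))


def classify_channel(lp: np.ndarray, times: np.ndarray, raw: np.ndarray,
                     fs: float, onset: float,
                     config: DetectorConfig = DetectorConfig()) -> ChannelResult:
    """Classify one channel as non_seizing / seizing / taa."""
    post = times >= onset
    p90 = float(np.percentile(lp[post], 90))
    if p90 < np.log10(config.k_s):
        return ChannelResult("non_seizing", p90=p90)

    hi, lo = config.k_2 * p90, config.k_1 * p90
    post_idx = np.flatnonzero(post)
    above = np.flatnonzero(lp[post_idx] >= hi)
    if above.size == 0:
        return ChannelResult("seizing", p90=p90)
    it = post_idx[above[0]]
    t_t = times[it] if it == 0 else _interp_crossing(times, lp, it - 1, it, hi)

    below = np.flatnonzero((np.arange(len(times)) < it) & (lp <= lo))
    if below.size == 0:
        return ChannelResult("seizing", p90=p90)
    io = below[-1]
    t_o = times[io] if io + 1 >= len(times) else _interp_crossing(times, lp, io, io + 1, lo)
    t_o = min(t_o, t_t)

    res = ChannelResult("seizing", p90=p90, t_o=float(t_o), t_t=float(t_t),
                        onset_delay=float(t_o - onset))

    in_interval = (times >= t_o) & (times <= t_t)
    if in_interval.sum() < 3:
        return res
    fit = stats.linregress(times[in_interval], lp[in_interval])
    res.r2_growth = float(fit.rvalue ** 2)
    if res.r2_growth <= config.r2_min:
        return res

    f0, ok = _spectral_check(raw, fs, t_o, t_t, config)
    res.f0 = f0
    if ok:
        res.cls = "taa"
    return res


def _spectral_check(raw: np.ndarray, fs: float, t_o: float, t_t: float,
                    config: DetectorConfig) -> tuple[float, bool]:
    """Largest flattened-PSD peak in band, all other peaks its harmonics."""
    seg = raw[int(round(t_o * fs)):int(round(t_t * fs))]
    if len(seg) < 8:
        return np.nan, False
    nperseg = min(len(seg), int(round(2.0 * fs)))
    freqs, psd = sps.welch(seg, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    mask = (freqs >= config.psd_range[0]) & (freqs <= config.psd_range[1])
    freqs, psd = freqs[mask], psd[mask]
    flat = psd * freqs
    if flat.max() <= 0:
        return np.nan, False
    flat = flat / flat.max()
    df = freqs[1] - freqs[0]
    distance = max(1, int(round(config.peak_min_distance / df)))
    peaks, _ = sps.find_peaks(flat, height=config.peak_min_height, distance=distance)
    if peaks.size == 0:
        # a maximum at the very edge of the range is not returned by the
        # peak finder; treat the global maximum as the dominant peak then
        peaks = np.array([int(np.argmax(flat))])
    peak_freqs = freqs[peaks]
    f0 = float(peak_freqs[np.argmax(flat[peaks])])
    if not config.band[0] <= f0 <= config.band[1]:
        return f0, False
    tol = config.harmonic_tolerance * f0
    for fi in peak_freqs:
        k = max(1, int(round(fi / f0)))
        if abs(fi - k * f0) >= tol:
            return f0, False
    return f0, True


def classify_recording(recording: SensorRecording,
                       config: DetectorConfig = DetectorConfig()
                       ) -> list[ChannelResult]:
    times, lp = band_logpower(recording.data, recording.fs, recording.onset, config)
    return [classify_channel(lp[c], times, recording.data[c], recording.fs,
                             recording.onset, config)
            for c in range(recording.n_channels)]


def form_groups(results: list[ChannelResult], electrodes: ElectrodeArray,
                config: DetectorConfig = DetectorConfig()) -> list[TAAGroup]:
    """Maximal runs of >=4 consecutive TAA contacts on one electrode."""
    groups = []
    for label in electrodes.table["electrode"].unique():
        rows = electrodes.electrode_rows(label)
        chan_idx = rows.index.to_numpy()
        flags = np.array([results[c].is_taa for c in chan_idx])
        start = None
        for i in range(len(flags) + 1):
            if i < len(flags) and flags[i]:
                if start is None:
                    start = i
            else:
                if start is not None and i - start >= config.group_min_contacts:
                    groups.append(TAAGroup(str(label), chan_idx[start:i]))
                start = None
    return groups


def group_features(group: TAAGroup, results: list[ChannelResult],
                   recording: SensorRecording) -> dict:
    """Five-feature fingerprint of a TAA group.

    slope, R^2: linear regression of onset times t_o on contact position
    (mm along the shaft, measured from the deepest contact; the absolute
    slope is used because shaft orientation is arbitrary). duration: mean
    t_t - t_o. ve1, ve2: cumulative explained-variance ratios of the first
    principal components of the mean-centered member signals over
    [min t_o, max t_t].
    """
    chans = group.channel_indices
    t_o = np.array([results[c].t_o for c in chans])
    t_t = np.array([results[c].t_t for c in chans])
    if np.any(~np.isfinite(t_o)) or np.any(~np.isfinite(t_t)):
        raise ValueError("group member without a detected TAA interval")

    tab = recording.electrodes.table
    pos_all = recording.electrodes.positions
    elec_rows = recording.electrodes.electrode_rows(group.electrode)
    deepest = elec_rows.index[elec_rows["shaft_index"].to_numpy().argmin()]
    positions = np.linalg.norm(pos_all[chans] - pos_all[deepest], axis=1)

    fit = stats.linregress(positions, t_o)
    slope = float(abs(fit.slope))
    r2 = float(fit.rvalue ** 2)
    duration = float(np.mean(t_t - t_o))

    fs = recording.fs
    sl = slice(int(round(t_o.min() * fs)), int(round(t_t.max() * fs)))
    X = recording.data[chans, sl]
    X = X - X.mean(axis=1, keepdims=True)
    cov = X @ X.T / X.shape[1]
    total = np.trace(cov)
    if total <= 0:
        raise ValueError("zero-variance signals in the group interval")
    eigval = np.sort(np.linalg.eigvalsh(cov))[::-1]
    ve1 = float(eigval[0] / total)
    ve2 = float((eigval[0] + eigval[1]) / total)
    feats = {"slope": slope, "r2": r2, "duration": duration, "ve1": ve1, "ve2": ve2}
    group.features = feats
    return feats


def detect_taa_groups(recording: SensorRecording,
                      config: DetectorConfig = DetectorConfig()
                      ) -> tuple[list[ChannelResult], list[TAAGroup]]:
    """Full per-recording pipeline: classify channels, form and fingerprint groups."""
    results = classify_recording(recording, config)
    groups = form_groups(results, recording.electrodes, config)
    for g in groups:
        group_features(g, results, recording)
    return results, groups


def results_table(results: list[ChannelResult], electrodes: ElectrodeArray) -> pd.DataFrame:
    return pd.DataFrame({
        "name": electrodes.names,
        "electrode": electrodes.table["electrode"],
        "shaft_index": electrodes.table["shaft_index"],
        "class": [r.cls for r in results],
        "p90": [r.p90 for r in results],
        "t_o": [r.t_o for r in results],
        "t_t": [r.t_t for r in results],
        "f0": [r.f0 for r in results],
        "onset_delay": [r.onset_delay for r in results],
    })


def groups_table(groups: list[TAAGroup]) -> pd.DataFrame:
    rows = []
    for g in groups:
        row = {"electrode": g.electrode,
               "contacts": ",".join(str(c) for c in g.channel_indices)}
        row.update(g.features)
        rows.append(row)
    return pd.DataFrame(rows, columns=["electrode", "contacts", *FEATURE_NAMES])
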