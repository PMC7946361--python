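"""Orchestration: simulate -> project -> detect -> fingerprint -> compare.

Seeding is hierarchical: a master seed spawns one independent substream per
simulation index (so adding simulations never perturbs earlier ones), and
each simulation draws its parameters, patch placement and noise from its own
substream. If a simulated seizure is not detected on any contact, a new
parameter set is drawn from the same substream and the simulation repeated,
up to a retry cap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

import yaml

from .forward import SensorRecording, gain_matrix, project
from .sources import (SourceParams, SourceConfiguration, sample_params,
                      place_patches, background_noise, correlated_seizure_noise,
                      seizure_activity, PARAM_RANGES)
from .detection import (DetectorConfig, detect_taa_groups, FEATURE_NAMES)
from .comparison import bootstrap_measures, sensitivity
from .synthetic import Scenario

logger = logging.getLogger("taaspread")

MAX_RETRIES = 50
CHUNK_SECONDS = 8.0


@dataclass
class SimulationResult:
    recording: SensorRecording
    params: SourceParams
    config: SourceConfiguration
    channel_results: list
    groups: list
    manifest: dict


def simulate_recording(scenario: Scenario, params: SourceParams,
                       rng: np.random.Generator,
                       config: SourceConfiguration | None = None,
                       background_scale: float = 1.0,
                       chunk_seconds: float = CHUNK_SECONDS) -> tuple[SensorRecording, SourceConfiguration]:
    """Simulate one seizure and project it onto the scenario's contacts.

    The projection exploits linearity: background noise is shared within
    partition patches, so its sensor contribution is the label-summed gain
    times the per-patch series; the seizure patch is projected chunk-wise.
    Patch members carry background noise until recruited.
    """
    surface = scenario.surface
    contacts = scenario.electrodes.positions
    fs = scenario.fs
    n_samples = scenario.n_samples
    t = np.arange(n_samples) / fs

    if config is None:
        config = place_patches(surface, contacts, params, rng)
    members = config.member_index

    bg = background_noise(surface, n_samples, fs, rng, scale=background_scale)
    seiz_noise = None
    if params.alpha:
        seiz_noise = correlated_seizure_noise(surface, config.patches[0], n_samples,
                                              fs, rng)
        if len(config.patches) > 1:
            # two-source: one correlated field spanning both patches, built on
            # the concatenated member list
            from .geometry import SurfacePatch
            both = SurfacePatch(surface, members, int(members[0]), 0.0)
            seiz_noise = correlated_seizure_noise(surface, both, n_samples, fs, rng)

    gain = gain_matrix(surface, contacts)
    labels = bg.partition.labels
    n_ch = len(contacts)
    # label-summed gains excluding seizure-patch members (their background
    # contribution is handled inside the member block)
    non_member = np.ones(surface.n_vertices, dtype=bool)
    non_member[members] = False
    bg_gain = np.zeros((n_ch, bg.partition.n_patches))
    np.add.at(bg_gain.T, labels[non_member], gain[:, non_member].T)
    gain_members = gain[:, members]
    member_labels = labels[members]

    sensor = np.empty((n_ch, n_samples))
    chunk = max(1, int(round(chunk_seconds * fs)))
    for start in range(0, n_samples, chunk):
        sl = slice(start, min(start + chunk, n_samples))
        seiz, recruited = seizure_activity(config, params, t[sl], seiz_noise, sl)
        eta = bg.scale * bg.series[:, sl][member_labels]
        member_act = np.where(recruited, seiz, eta)
        sensor[:, sl] = bg_gain @ (bg.scale * bg.series[:, sl]) \
            + project(gain_members, member_act)
    rec = SensorRecording(sensor, fs, scenario.electrodes, scenario.onset)
    return rec, config


def run_one_simulation(scenario: Scenario, model_kind: str, seed_seq,
                       noisy: bool = False, overrides: dict | None = None,
                       detector: DetectorConfig = DetectorConfig(),
                       background_scale: float = 1.0,
                       max_retries: int = MAX_RETRIES) -> SimulationResult:
    """Sample parameters, simulate and detect; redraw until a seizure shows.

    ``overrides`` maps parameter names to degenerate (fixed) ranges, e.g.
    ``{"u_spread": (2.0, 2.0)}`` for controlled experiments.
    """
    rng = np.random.default_rng(seed_seq)
    ranges = dict(PARAM_RANGES)
    if overrides:
        ranges.update({k: (v, v) if np.isscalar(v) else tuple(v)
                       for k, v in overrides.items()})
    for attempt in range(max_retries):
        params = sample_params(model_kind, rng, noisy=noisy, ranges=ranges,
                               t0=scenario.onset)
        recording, config = simulate_recording(scenario, params, rng,
                                               background_scale=background_scale)
        results, groups = detect_taa_groups(recording, detector)
        if any(r.cls != "non_seizing" for r in results):
            manifest = {"model": model_kind, "noisy": noisy, "retries": attempt,
                        "params": {k: v for k, v in asdict(params).items()
                                   if v is not None},
                        "patch_centers": [int(p.center) for p in config.patches],
                        "origin": config.origin,
                        "n_groups": len(groups)}
            return SimulationResult(recording, params, config, results, groups,
                                    manifest)
        logger.warning("no seizing channel (attempt %d), redrawing parameters",
                       attempt + 1)
    raise RuntimeError(f"no seizing channel after {max_retries} retries")


def run_model_batch(scenario: Scenario, model_kind: str, n_simulations: int,
                    master_seed: int, noisy: bool = False,
                    overrides: dict | None = None,
                    detector: DetectorConfig = DetectorConfig(),
                    ) -> tuple[pd.DataFrame, list[SimulationResult]]:
    """Run a batch of simulations; one feature row per detected TAA group."""
    children = np.random.SeedSequence(master_seed).spawn(n_simulations)
    rows, sims = [], []
    for i, child in enumerate(children):
        try:
            sim = run_one_simulation(scenario, model_kind, child, noisy=noisy,
                                     overrides=overrides, detector=detector)
        except RuntimeError as err:
            logger.warning("simulation %d failed: %s", i, err)
            continue
        sims.append(sim)
        for g in sim.groups:
            row = {"simulation": i, "model": model_kind, "electrode": g.electrode}
            row.update(g.features)
            for key in ("patch_size", "f", "delta", "Delta", "u_spread", "u_wave"):
                val = getattr(sim.params, key)
                if val is not None:
                    row[key] = val
            rows.append(row)
    return pd.DataFrame(rows), sims


def run_compare(recordings_features: np.ndarray,
                model_features: dict[str, np.ndarray],
                master_seed: int, reference: str,
                n_resamples: dict | None = None,
                measures: tuple[str, ...] | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrap goodness-of-fit of every model against the observed sample."""
    from .comparison import MEASURES
    for name, X in model_features.items():
        if len(X) == 0:
            raise ValueError(f"empty feature sample for model {name!r}")
    if len(recordings_features) == 0:
        raise ValueError("empty feature sample for provenance 'recordings'")
    rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    return bootstrap_measures(recordings_features, model_features, rng,
                              reference=reference, n_resamples=n_resamples,
                              measures=MEASURES if measures is None else measures)


def run_sensitivity(features_df: pd.DataFrame,
                    parameters: tuple[str, ...] = ("patch_size", "f", "u_spread",
                                                   "u_wave"),
                    ranges: dict | None = None):
    """Parameter-feature sensitivity for a (spreading-model) feature table."""
    ranges = dict(PARAM_RANGES) | (ranges or {})
    params_table = features_df[list(parameters)]
    feats_table = features_df[list(FEATURE_NAMES)]
    return sensitivity(params_table, feats_table,
                       {p: ranges[p] for p in parameters})


def calibration_lp_traces(scenario: Scenario, model_kind: str, n_calib: int,
                          master_seed: int, noisy: bool = False,
                          q_hat: float = 10.0, ranges: dict | None = None,
                          detector: DetectorConfig = DetectorConfig()
                          ) -> list[np.ndarray]:
    """Post-onset log-power traces of a fixed-q calibration batch.

    Runs ``n_calib`` simulations with the amplitude scaling pinned at
    ``q_hat`` and returns one baseline-normalized log10 band-power trace per
    channel per simulation, the input ``forward.calibrate_q`` needs to
    compute p_sim and update q.
    """
    from .detection import band_logpower

    traces = []
    for child in np.random.SeedSequence(master_seed).spawn(n_calib):
        rng = np.random.default_rng(child)
        params = sample_params(model_kind, rng, noisy=noisy, q=q_hat,
                               ranges=ranges, t0=scenario.onset)
        recording, _ = simulate_recording(scenario, params, rng)
        times, lp = band_logpower(recording.data, recording.fs,
                                  recording.onset, detector)
        post = times >= recording.onset
        traces.extend(lp[c, post] for c in range(recording.n_channels))
    return traces


def save_manifest(sims: list[SimulationResult], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.manifest for s in sims], fh, indent=1, default=str)


@dataclass
class RunConfig:
    """Configuration of a full study run, loadable from YAML or JSON."""

    models: list = field(default_factory=lambda: ["one_source", "two_sources",
                                                  "spreading"])
    noisy: bool = True
    n_simulations: int = 20
    master_seed: int = 0
    reference: str = "spreading"
    overrides: dict = field(default_factory=dict)      # parameter range overrides
    scenario: dict = field(default_factory=dict)       # Scenario(...) kwargs
    detector: dict = field(default_factory=dict)       # DetectorConfig(...) kwargs

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be at least 1")
        if self.reference not in self.models:
            raise ValueError("reference model must be in the model list")


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from a .yaml/.yml or .json file."""
    path = str(path)
    with open(path) as fh:
        if path.endswith((".yaml", ".yml")):
            raw = yaml.safe_load(fh)
        elif path.endswith(".json"):
            raw = json.load(fh)
        else:
            raise ValueError("config must be YAML or JSON: " + path)
    return RunConfig(**(raw or {}))


def run_study(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the configured simulation batches; one feature table per model."""
    scenario = Scenario(**config.scenario)
    detector = DetectorConfig(**config.detector)
    tables = {}
    for i, model in enumerate(config.models):
        feats, _ = run_model_batch(scenario, model, config.n_simulations,
                                   master_seed=config.master_seed * 1000 + i,
                                   noisy=config.noisy,
                                   overrides=config.overrides or None,
                                   detector=detector)
        tables[model] = feats
    return tables
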