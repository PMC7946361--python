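# taaspread

Forward modelling of the **theta-alpha activity (TAA)** electrographic
pattern: seizure-source simulation on triangulated cortical sheets, dipole
projection to stereo-EEG (SEEG) depth-electrode contacts, two-step TAA
detection and fingerprinting, and statistical comparison of candidate
source models.

TAA — sustained 4–13 Hz oscillations whose amplitude grows gradually — is
among the most common early ictal patterns in regions of seizure spread.
This package implements, as a tested and reusable pipeline, the analysis
needed to ask whether a *spreading seizure* (a slow ictal wavefront at
u_spread = 0.5–4 mm/s, internally organized by fast traveling waves at
u_wave = 100–500 mm/s) explains the TAA fingerprints better than reference
models in which the gradual onset already exists at the source (one or two
homogeneous sources). Everything runs on synthetic geometry and signals; no
patient data are required or included.

## The model in brief

Source activity s(x, t) lives on the vertices of a triangulated cortical
patch Ω_e. For the spreading model,

    Ω_r(t) = { x ∈ Ω_e : d(x, x₀) < (t − t₀) · u_spread }
    s(x, t) = q · ( y_p(t − t₀ − d(x, x₀)/u_wave) + α·ν(x, t) ) ,  x ∈ Ω_r(t)

with d the geodesic distance from the seizure origin x₀, y_p a unit-variance
pulse wave (duty cycle 0.25), ν spatially correlated pink noise
(kernel e^{−d/l}, l = 10 mm), and background pink noise η elsewhere. A
contact at x_s sees the dipole sum

    φ(x_s, t) = Σ_v A_v · n_v·(x_s−x_v)/|x_s−x_v| / (|x_s−x_v| + ε)² · s_v(t),  ε = 1 mm.

Channels whose 4–13 Hz multitaper log-power exceeds 30× baseline are
*seizing*; a near-linear growth interval (R² > 0.75) whose spectrum is
dominated by a single 4–13 Hz peak and its harmonics is a *TAA*; ≥ 4
consecutive TAA contacts on one electrode form a *TAA group*, fingerprinted
by (slope, R², duration, PCA VE1, PCA VE2). Fingerprint samples are
compared by k-nearest-neighbor log-likelihood (k = 10, 50), Bhattacharyya
and Earth Mover's distances on 4⁵ = 1024 bins, with paired bootstrap
confidence intervals. See `docs/methods.md` for the full account.

## Worked example

The `analysis/` scripts run the study end to end on the default synthetic
scenario (60×60 mm sheet, two 10-contact shafts, 60 s baseline + 60 s ictal
at 256 Hz):

```sh
python analysis/01_simulate_models.py --n-sims 12 --seed 3
python analysis/02_compare_models.py --seed 3
python analysis/03_parameter_sensitivity.py
python analysis/04_mesh_refinement.py --n-sims 6 --seed 2
```

which printed:

```
one_source: 12/12 simulations seized, 24 TAA groups -> results/features_one_source.csv
two_sources: 12/12 simulations seized, 21 TAA groups -> results/features_two_sources.csv
spreading: 12/12 simulations seized, 23 TAA groups -> results/features_spreading.csv

median goodness-of-fit (reference = held-out spreading sample):
  ll10: best -> worst: spreading, two_sources, one_source
  db: best -> worst: spreading, one_source, two_sources
  emd: best -> worst: spreading, two_sources, one_source

normalized regression slopes s_pf * w_p / sigma_f:
feature     duration    r2  slope   ve1   ve2
parameter
f               0.62 -0.10   0.78 -0.13 -0.70
patch_size     -0.61 -1.05  -1.42 -0.53 -0.27
u_spread       -3.29  0.01  -2.24  0.13  0.50
u_wave         -0.82 -0.68  -1.11 -0.25 -0.40

mean agreement: refined 0.967, background redraw 0.967
```

Reading the numbers: every simulation produced seizing channels and most
produced TAA groups on both shafts. With the reference sample held out of
the spreading model's own output, the spreading model ranks best on all
computed measures (a self-recovery check of the comparison machinery). The
sensitivity matrix shows the model's strongest causal relations: faster
wavefronts (u_spread) sharply shorten the TAA and flatten the onset slope
(−3.29 and −2.24), exactly the physics of a wavefront crossing the
electrode faster. Refining the mesh 1→4 changes per-channel classifications
no more than redrawing the background noise does (0.967 vs 0.967), so the
default triangulation density is sufficient.

## Layout

    src/taaspread/      library: geometry, sources, forward, detection,
                        comparison, synthetic, pipeline
    analysis/           numbered study drivers (simulate → compare →
                        sensitivity → mesh robustness)
    scripts/acceptance.py
    tests/              pytest suite incl. end-to-end acceptance checks
    docs/methods.md     model, assumptions, numerical choices, limitations
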