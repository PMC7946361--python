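# Methods

`taaspread` implements a forward-modelling pipeline for one question: can a
seizure that spreads slowly across the cortical sheet explain the
*theta-alpha activity* (TAA) pattern — sustained 4–13 Hz oscillations with
gradually growing amplitude — seen on stereo-EEG (SEEG) contacts during
seizure propagation? The pipeline simulates candidate source models on a
triangulated cortical surface, projects them to depth-electrode contacts
through a dipole forward model, detects and fingerprints TAA patterns in the
projected signals, and compares the fingerprint distributions of the
candidate models against a reference sample.

## Source models

All models place seizure activity on a small excitable patch Ω_e of the
surface Ω and treat the rest of the cortex as a noise source. Activity is
defined per vertex; time is continuous and sampled at `fs` (default 256 Hz)
over a 60 s preictal baseline plus 60 s of ictal signal, with the onset
marker `t0` at 60 s.

* **One homogeneous source.** Every vertex of the patch follows
  `s = q · min(1, (t−t0)/δ) · (y_s(t−t0) + α·ν)` for t ≥ t0 — a triangle
  wave `y_s` whose amplitude ramps linearly over the onset duration δ. The
  hallmark TAA feature (gradual growth) exists at the source level.
* **Two homogeneous sources.** Two disjoint patches, each of area |Ω_s|/2,
  recruited at `t0` and `t0 + Δ`, each with its own onset duration. The
  patch centers are drawn within 15 mm of a contact and within 10 mm of
  each other; because each patch's radius exceeds that separation, the two
  patches are grown simultaneously from both centers by a shared FIFO
  queue, which keeps them disjoint while guaranteeing each contains its
  center.
* **Spreading seizure.** A wavefront expands geodesically from a random
  origin x₀ on the patch at `u_spread` (0.5–4 mm/s): vertex x is recruited
  once `d(x, x₀) < (t−t0)·u_spread`. Each recruited vertex instantly starts
  a duty-cycle-0.25 pulse wave phase-shifted by `d(x, x₀)/u_wave`,
  emulating fast traveling waves (100–500 mm/s) inside the recruited
  territory. Gradual amplitude growth appears only at the sensor level,
  through the spatial averaging of the dipole projection.

Waveforms are normalized to unit variance over whole periods (triangle peak
√3; pulse high level √(16/3)), so the scaling coefficient `q` alone sets
the source amplitude. `q` defaults per model and noise variant
(8.16/7.87, 9.96/9.85, 16.28/15.34) and can be recalibrated with
`forward.calibrate_q`, which implements `q = 10^((p_rec − p_sim)/2) · q̂`
on normalized log₁₀ band-power percentiles (the 95th percentile across
channels and simulations of each channel's 80th percentile over time);
`p_rec` must be supplied, since it summarizes recordings this package does
not ship.

Parameter ranges (uniform priors): patch area 400–2500 mm², frequency
4–13 Hz, onset duration 1–30 s, two-source delay 0–10 s, `u_spread`
0.5–4 mm/s, `u_wave` 100–500 mm/s. The two-source onset durations are
sampled independently (a config flag shares them); the "centers closer than
10 mm" constraint is implemented literally.

## Noise

Background noise η is pink (1/f), unit variance, shared within surface
patches of ~100 mm² mean area obtained by simultaneous queue expansion from
random seeds. Seizure noise ν (noisy variants only, α = 1) is pink in time
and spatially correlated with kernel `exp(−d/l)`, l = 10 mm geodesic.
Pink series are spectrally shaped white noise (1/√f amplitude, DC zeroed)
rescaled to exactly unit sample variance.

The correlated field is realized as `ν = F · m` with independent pink modes
`m` and a factor `F` whose rows are renormalized to unit norm (unit
per-vertex variance). For patches up to 512 vertices `F` comes from a dense
eigendecomposition of the geodesic kernel matrix (negative eigenvalues from
symmetrization clipped to zero — projection to the nearest PSD matrix);
larger patches use a Nyström factor built from up to 160 farthest-point
anchor vertices. The Nyström route reproduces the kernel correlation to a
few percent at the default patch sizes (verified in the test suite) at a
fraction of the dense cost; the 512-vertex threshold is a deliberate
speed/accuracy trade-off so a full simulation stays at a few seconds on one
CPU.

## Forward model

Each vertex is a current dipole along the outward normal; a point contact
at x_s sees `φ(x_s) = Σ_v A_v · (n_v·(x_s−x_v)/|x_s−x_v|) /
(|x_s−x_v| + ε)² · s_v(t)` with ε = 1 mm regularizing the surface
singularity, vertex area A_v = one third of the incident triangle areas,
and n_v the area-weighted average of incident triangle normals. The
direction term at zero source–sensor distance is defined as 0. Projection
is chunked in time (default 8 s) and, by linearity, background noise is
projected per partition patch (label-summed gains) rather than per vertex.

## TAA detection

Per channel, monopolar: multitaper power (time-bandwidth 2.0, 8 cycles) on
a 1 Hz grid over 4–13 Hz, averaged over the band, log₁₀-transformed, and
shifted so the mean over the 60 s preceding the onset marker is zero; the
trace is evaluated on a 0.25 s grid. A channel is *seizing* when the
post-onset 90th percentile P₉₀ reaches log₁₀(30). The tentative TAA
interval is `t_t` = first upward crossing of 0.85·P₉₀ after the marker and
`t_o` = last time before `t_t` below 0.15·P₉₀ (crossings linearly
interpolated between grid points). The crossing directions are chosen so
the interval spans the growth from baseline to full seizure activity: an
upward crossing of the upper threshold ends the growth, and the last
sub-lower-threshold sample before it starts it. The interval is confirmed
as TAA when (a) the log-power growth
is near-linear (R² > 0.75 over at least three grid points) and (b) the
Welch spectrum of the raw interval (2 s segments, 50% overlap, 1–100 Hz),
flattened by multiplying by frequency and max-normalized, has its largest
peak f₀ in 4–13 Hz with every other peak (height ≥ 0.25, separation ≥
2 Hz) a harmonic of f₀ within 0.15·f₀.

TAA on ≥ 4 consecutive contacts of one electrode forms a *group* with a
5-dimensional fingerprint: |slope| and R² of the regression of t_o on
contact position along the shaft (mm from the deepest contact; absolute
slope because shaft orientation is arbitrary), mean duration t_t − t_o,
and the variance explained by the first one and two principal components
of the mean-centered member signals over [min t_o, max t_t].
Consecutiveness is defined on shaft index, not physical distance, so a
grouped-layout run may span the 9 mm inter-group gap. P₉₀ uses the window
from the onset marker to the end of the recording, and the band statistic
is power-then-log (both switchable).

## Goodness of fit

Fingerprint samples are compared with four measures: k-nearest-neighbor
log-likelihood estimates (k = 10 and 50) — per observed point,
`log[k·Γ(d/2+1)/(m·π^{d/2}·s_k^d)]` with s_k the Euclidean distance to the
k-th nearest model sample — and Bhattacharyya and Earth Mover's distances
between histograms on 4 uniform bins per dimension (4⁵ = 1024 bins; default
limits are the per-dimension min/max of the pooled samples). Distances for
the EMD (and, by the same convention, the kNN coordinates) are standardized
by the reference sample's per-dimension standard deviation. The EMD is
solved as the exact transportation LP restricted to occupied bins (HiGHS);
the tests cross-check it against an integer-scaled network-simplex solver
and, in one dimension, against the closed-form Wasserstein distance.
Bhattacharyya distance is +∞ for disjoint supports and infinities propagate
uncapped into bootstrap summaries; in paired differences, a resample
disjoint from *both* models yields the indeterminate ∞−∞ and is defined as
0, the conservative choice (it pulls paired intervals toward zero).

Uncertainty: the observed sample is bootstrap-resampled (1000 resamples;
100 for the EMD, which dominates the cost) and the identical resamples are
evaluated under every model, so paired per-resample differences to a
reference model control the between-resample variance. Zero k-NN distances
from duplicated resample points are floored at machine-epsilon scale with a
warning.

Parameter sensitivity reports, per parameter–feature pair, the OLS slope
normalized as `s_pf · w_p / σ_f` (w_p = prior range width, σ_f = feature
standard deviation), and per parameter the density shift
`(μ_TAA − μ_prior)/w_p` of detected-TAA parameter values against the
uniform prior; constant parameter columns are flagged and reported as 0.

## Synthetic study conditions

No patient data ship with the package; the synthetic module generates what
the pipeline needs:

* **Surfaces** — regular triangulated flat sheets (default 60×60 mm at
  1 mm target edge length, matching the ~0.9 mm mean edge of
  surface-reconstruction meshes), an analytic sinusoidal fold, and
  icospheres. Refinement splits every triangle into four with shared edge
  midpoints and original vertex indices preserved.
* **Electrodes** — point contacts along straight shafts, 1.5 mm uniform
  spacing or groups of five separated by 9 mm. The default implantation is
  two 10-contact shafts 2 mm above the sheet, one parallel and one
  perpendicular to the x axis. Contacts are points; the physical 2 mm
  contact extent is ignored, consistent with the point-sensor forward
  model.
* **Detector fixtures** — single channels with machine-readable ground
  truth. The TAA fixtures shape the carrier amplitude so the band log-power
  rises *linearly* from 0 to a plateau L over a programmed window
  (`a(t) = sqrt(P_base·(10^{L·u(t)} − 1)/P_unit)`, with the band powers
  estimated by a detector-independent Butterworth bandpass), so the k₁/k₂
  threshold crossings sit at known fractions of the ramp. Steeper ramps
  pin the crossings more tightly against baseline log-power fluctuations;
  the defaults keep the detected crossings within ±0.5 s of the programmed
  ones. Counter-fixtures (abrupt broadband burst, 1.5 Hz spike train,
  stationary noise) must not be classified TAA.
* **Pseudo-recordings fingerprints** — a fixed mixture over the 5-D feature
  space respecting its semantics (slope ≥ 0, R² and VEs in [0,1],
  VE1 ≤ VE2, duration skewed to 3–7 s). Synthetic plumbing for tests and
  demos only.

What passing tests do *not* show about real data: the flat sheet has no
folding geometry (no gain sign changes from opposing sulcal walls), the
implantation is two idealized shafts rather than ~12 clinical electrodes,
and the reference sample in the self-recovery comparison is model-generated
— so the tests validate the machinery and the model's qualitative physics,
not clinical claims.

## Numerical choices and degenerate inputs

* Geodesics are Dijkstra shortest paths on the edge graph with Euclidean
  weights. On the regular sheet the measured overshoot over the Euclidean
  distance stays below 1.4 (asserted in the tests); refinement can only
  shorten graph paths. Exact polyhedral geodesics were not needed at the
  model's granularity.
* Queue expansions enqueue neighbors in ascending vertex index, making
  patch growth and partitioning deterministic given the RNG draws.
* Degenerate zero-area triangles contribute nothing and raise a warning;
  isolated vertices are an error. Patch growth stops at the first patch
  whose vertex-area sum reaches the target (overshoot ≤ one vertex area).
* Simulations are chunk-evaluated in time; noise series are precomputed
  full-length, so chunked evaluation is bitwise identical to a single pass.
* Seeding is hierarchical (`SeedSequence(master).spawn(n)`), one substream
  per simulation, so growing a batch never perturbs earlier simulations.
  If no channel is seizing, parameters are redrawn from the same substream
  (cap: 50 retries, then the simulation is recorded as failed).
* The rank-one check (noise-free one-source ⇒ VE1 = 1) cannot run the
  detector on fully noise-free signals (the baseline log-power of an
  all-zero baseline is undefined), so groups are detected on the normal
  simulation and the fingerprint recomputed on an identical-seed
  re-simulation with the background amplitude set to 0; VE1 is then exactly
  1 by linearity of the projection.

## Problem sizes

The default scenario (≈4300 vertices, 20 channels, 120 s at 256 Hz) runs
one noisy spreading simulation in ≈4–8 s on one CPU. The acceptance-style
experiments use 10 seeds per spread velocity, 40 wavelength-controlled
runs, 10 runs per band-edge frequency, 55 + 30 simulations for the
self-recovery comparison, and 10 paired triples for the mesh-refinement
check — sizes chosen so the entire suite completes comfortably on a single
CPU while leaving every qualitative effect far from its decision threshold.

## Known limitations

Flat-sheet geometry understates the gain cancellation real cortical folding
produces; the spreading model has no seizure offset and sources oscillate
until the end of the simulation; the wavefront is isotropic in geodesic
distance; the EMD at 4 bins/dimension is coarse by construction; and the
kNN log-likelihood is biased at small model sample sizes (both models in a
comparison share the same m, which is what the paired design relies on).
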