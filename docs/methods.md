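# Methods

This note documents the models behind `ctdyn`, the parameter
conventions, what the synthetic-data generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Single-molecule FRET

**Per-frame efficiency.** For an immobilized molecule imaged at
100 ms/frame, `E_t = I_A/(I_A + I_D)` on the raw (background-subtracted
upstream) channel intensities, clamped to [0, 1]. Frames with
non-positive total intensity are marked invalid (NaN) and excluded —
they carry no ratio information. Whether out-of-range efficiencies
should be clamped or discarded is an open convention in the field; we
clamp per-frame values and treat bursts separately (below).

**Photobleach truncation.** Donor photobleaching appears as a sustained
drop of total intensity. The detector is a single least-squares
change-point: the split minimizing the within-segment sum of squares is
accepted only if the post-drop mean falls below `drop_fraction` (default
0.5) of the pre-drop mean, persists for ≥ 5 frames, and no post-drop
frame recovers toward the pre-drop level. Manual/visual truncation is
common practice; an explicit change-point rule makes the step
reproducible. A trace already dark from frame 0 can only be recognized
against an expected level, hence the optional `reference_level`.

**Histograms.** Exactly 100 bins of width 0.01 on [0, 1], half-open
`[lo, hi)` with the final bin closed, heights normalized by the total
number of valid frames. Heights therefore always sum to 1 and are
invariant to how frames are distributed across traces.

**Bursts.** A confocal burst enters the analysis only if its raw photon
sum (both channels) is ≥ 40. Efficiency is computed on background-
corrected counts; if exactly one corrected channel is negative the
efficiency is clamped to the nearest boundary (0 or 1), and bursts with
both corrected channels ≤ 0 are discarded as background-only events.

## State kinetics

**HMM.** `FretHmm` fits a Gaussian-emission HMM to pooled efficiency
traces with hmmlearn's Baum–Welch, k-means initialization of the
emission means, and seed-controlled restarts (default 5; best likelihood
kept). Convergence: relative log-likelihood change < 1e-6 within 500
iterations; non-convergence is flagged, never silent. States are
relabeled by ascending emission mean so state 0 is always the low-FRET
state. A fit is flagged *degenerate* when neighbouring means are closer
than max(0.05, 2× their pooled emission sd) — the resolvability limit at
which a two-state interpretation stops being meaningful. The number of
states defaults to 2 (the observed two-state exchange); a free
state-count search is out of scope.

**Dwell times.** Viterbi paths are cut into maximal constant runs; each
run's duration is `n_frames × frame_time`. The first and last run of
every trace are censored — the observation window truncates them — and
mean dwells are computed over uncensored runs only. For geometric dwell
lengths this censoring convention is unbiased (memorylessness), with a
small downward truncation effect when dwells approach the trace length.

**Occupancy fits.** Histograms are fitted with one or two Gaussians by
weighted nonlinear least squares on bin centers; the model height is
`Σ aᵢ·N(x; cᵢ, sᵢ)·binwidth` and occupancies are the area fractions
`aᵢ/Σa` — probability masses, not peak amplitudes. Residual weights are
`1/√max(h, 1/N)` (Poisson-motivated; stabilizes empty bins). The low
component's center can be held exactly at a supplied value (0.38 is the
convention for weakly populated low-FRET states at low G-protein
concentration). FWHM = 2√(2 ln 2)·σ per component. `occupancy_curve`
classifies components into low/high by a configurable center boundary
(default 0.55, between the ~0.40 and ~0.72 populations) rather than by
rank, so a condition whose mass is entirely in one population reports
occupancy (1, 0) even when the two-component fit splits that single
peak.

## Dose-response

The 4PL `R(c) = bottom + (top−bottom)/(1+(EC50/c)^h)` is fitted on the
log₁₀-concentration axis by trust-region least squares with bounds; the
free Hill slope is bounded to [0.3, 5], EC50 to one decade beyond the
measured grid. Initialization: plateaus from the extreme-concentration
means, EC50 from the half-maximal crossing. Replicates are fitted
jointly (pooled), preserving the error structure. Flat data (variance
below tolerance) raise a no-signal error. Standard errors come from the
Jacobian at the solution.

For the smFRET occupancy titrations — 1:1 binding equilibria of a
nanobody or G protein to a single receptor — the recovery protocols fix
the Hill slope at 1, the mechanistically expected value for single-site
binding; cell-based concentration-response data keep the free slope
(signal amplification makes effective slopes ≠ 1 common). ΔpEC50 is the
difference of pEC50s; relative Emax is the ratio of fitted spans.

## NMR profiles

CSP: `Δδ_av = √((Δδ_H)² + (Δδ_N/5)²)` per residue shared between two
peak lists; the 1/5 nitrogen scaling reflects the relative shift
dispersion of ¹⁵N vs ¹H. Peaks are matched by assigned residue number;
residues absent from either list (prolines, unassigned) propagate as
explicit NaN gaps, never as zeros. Intensity ratios are computed per
replicate pair then averaged (mean ± s.e.m.); a merged-intensity mode is
the PRE convention, where the ratio uses replicate-mean intensities with
first-order error propagation of each side's s.e.m. Replicate counts
are configurable (the two profile types ship with 2 and 3 sequential
measurements respectively).

## Adaptive sampling

Frames accumulated over all previous epochs are scored

    P(frame_i) ∝ W₁·(1 − |D_norm(target) − D_norm(frame_i)|) + W₂/P_obs

with defaults W₁ = W₂ = 1 (equal balance of exploit and explore) and
D_target = 44 Å, the inter-label distance consistent with the high-FRET
state. Numerical conventions, each chosen where the scheme is
dimensionally underdetermined:

* the exploit term `1 − |ΔD|` is only meaningful on a normalized axis,
  so D (and the target) are min-max rescaled to [0, 1] over the
  accumulated pool (bounds refreshed every epoch, or fixed via
  `distance_bounds`); both terms are then commensurate;
* `P_obs` is the normalized count of the frame's conformation-descriptor
  bin on a fixed grid (default width 2 Å on the toy scalar descriptor);
  a frame counts its own bin, so P_obs ≥ 1/total and 1/P_obs is finite;
* raw scores are clipped at zero (rescaling precludes negatives up to
  rounding) and normalized to sum to 1;
* seeds are drawn *without* replacement, so one dominant frame cannot
  seed a whole epoch.

A campaign runs epochs of trajectories on a pluggable engine
(`engine(x0, n_steps, seed) → trajectory`); epoch 1 starts all
trajectories from the initial conformation, later epochs from the
selected seed frames. The production geometry is 5 epochs × 10
trajectories. The naive control (`adaptive=False`) restarts every epoch
from the initial conformation at equal budget.

Campaign analysis descriptors: minimum pairwise distance between two
labelled atom sets, RMSD vs the trajectory's first frame and vs its
average structure (no superposition — inputs are assumed pre-aligned),
centered running averages (50 ns windows at production strides), and
per-residue-pair contact frequencies at a 3.5 Å minimum-distance cutoff
("in contact distance of at least 3.5 Å" is read as *within* 3.5 Å).

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed).

**Traces.** Two-state exchange is simulated per frame with switching
probability `p = k·frame_time` (capped at 1), so dwell lengths are
*exactly* geometric with mean `1/(k·frame_time)` frames — the discrete
analogue of exponential kinetics, chosen over `1 − exp(−k·dt)` so the
generator matches the geometric-dwell oracle identically. Channel noise
is additive Gaussian (EMCCD readout-dominated regime); donor
photobleaching is an absorbing exponential event after which both
channels emit background. `simulate_efficiency_traces` specifies noise
directly in efficiency units (E ~ N(μ_state, σ) at constant total
intensity), matching how per-frame efficiency widths are reported.
No blinking, spectral crosstalk, or gamma correction is modeled, and
TIRF camera-frame processing (spot fitting, registration) is upstream of
these inputs.

**Bursts.** Exponential durations (rounded up to whole 1000 μs bins),
Poisson photons per channel at state-dependent rates plus background.

**Titrations.** 4PL plus i.i.d. Gaussian noise per replicate point.
The experimental grids are half-log series over 316 pM–100 nM
(nanobody) and 3.16 nM–10 μM (G protein).

**Peak lists.** Base shifts plus localized perturbations and intensity
scalings per residue over CT residues 347–413, with missing residues
absent from both lists; optional Gaussian noise on shifts/intensities.

**Toy dynamics.** Overdamped Langevin (Euler–Maruyama) on a 1-D
free-energy landscape of Gaussian wells:
`x⁺ = x + (D₀/kT)·F(x)·dt + √(2D₀dt)·ξ`. The default landscape is a
double well with minima at 40 and 60 Å (spanning the ~30–70 Å sampled
range of the all-atom system), widths 5 Å, depths 7 kT, D₀ = 50 Å²/ns,
kT = 1. The 7 kT depth puts spontaneous barrier crossings well beyond a
single short (15 ns) trajectory — the regime adaptive seeding addresses,
where unbiased MD is far shorter than conformational exchange. The
descriptor is the scalar position itself. This engine reproduces the
*logic* of the sampling problem (metastability, seeding, enrichment),
not atomistic forces, membranes, or real CT conformations; passing
campaign tests demonstrates the controller's behavior, not all-atom
realism.

## Recovery protocols and problem sizes

The acceptance script and tests recover reported values from synthetic
data at desk scale, chosen to keep every run in seconds while leaving
statistical error well inside each tolerance:

* apo peaks: 300 traces × 200 frames (60 000 frames); center within
  ±0.01, FWHM within ±0.02;
* titration EC50s: 3 replicates on the experimental half-log grids,
  noise sd 0.03 occupancy units; within ±25%;
* dwell plateau: 200 traces × 600 frames, emission means 0.40/0.72,
  sd 0.05; mean uncensored high-FRET dwell within ±20% of the 2 s
  ground truth;
* mixture low center: 100 000 frames, 85/15 mixture, σ = 0.06; within
  ±0.02;
* enrichment: 5 epochs × 10 trajectories × 300 steps per campaign,
  adaptive vs naive at equal budget over 10 seeded repeats.

## Known limitations

* The HMM assumes Gaussian emissions and frame-discretized kinetics;
  sub-frame transitions alias into apparent intermediate efficiencies.
* Dwell censoring leaves a small truncation bias when mean dwells are
  not ≪ the trace length.
* The double-Gaussian occupancy model is unidentifiable when components
  overlap within their widths; such fits are flagged, not repaired.
* The toy engine is 1-D: descriptor binning for P_obs is trivially
  well-behaved there, whereas real conformational descriptors require a
  clustering choice the controller deliberately leaves pluggable.
* PRE ratios are reported as attenuation profiles only; no
  distance-to-ratio conversion is attempted.
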