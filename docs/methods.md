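# Methods notes

## Scope and assumptions

`refkin` quantifies dynamic PET against a reference region assumed devoid
of specific binding (cerebellar grey matter in the amyloid/tau setting).
All inputs are assumed decay-corrected, motion-corrected and atlas-aligned;
the package performs no registration, reconstruction, attenuation/scatter
correction or grey-matter probability weighting. Regional TACs are
unweighted voxel means within an integer atlas label. Frame intervals are
half-open `[start, end)` in minutes post-injection; frame values are
time-averages over the frame, matching how scanners bin counts, not
midpoint samples.

## Estimators

**SRTM (basis functions).** For a fixed apparent efflux rate θ ≡
k2/(1+BP_ND), the model C_T = R1·C_R + φ·(C_R ⊗ e^(−θt)) is linear in
(R1, φ). The fit solves this weighted linear problem on a grid of 100
log-spaced θ values spanning 1/600–1 min⁻¹ (clearance half-times ~0.7 to
~7000 min), then refines θ by bounded scalar minimisation between the two
grid neighbours of the grid optimum. The refinement matters: the grid
spacing alone (~6.7% between points) would leave a comparable quantisation
error in k2 and BP_ND, while the refined noiseless fit recovers parameters
to ~10⁻⁵ relative. Parameters follow from k2 = R1·θ + φ and
BP_ND = k2/θ − 1. Ties in the θ search break toward smaller θ (smoother
kinetics); fits whose optimum sits on the grid edge are flagged
`on_boundary`; a vanishing φ (target proportional to the reference) leaves
θ and the k2/BP split unidentifiable and is flagged `degenerate`. Default
weights are uniform; duration-based weights are available but the studies
this package emulates do not state a weighting. Negative BP_ND estimates
are reported and flagged, never clipped — clipping would bias the
stability sweeps.

Convolutions run on a uniform fine grid (default 0.01 min) with the exact
piecewise-linear solution of y' = f − k·y implemented as a first-order IIR
recursion; this is what keeps the forward model and the basis functions
accurate enough for sub-0.1% oracle comparisons. Discontinuous inputs
(e.g. a boxcar test input) carry an O(dt/2) sampling error at the step and
need a finer grid in tests that compare against closed forms. When a TAC
carries the simulator's fine-grid curve, fits use it exactly; measured
TACs are interpolated linearly through (0, 0) and the frame midpoints.

**Direct NLLS cross-check.** `fit_srtm_nlls` fits (R1, k2, BP_ND) jointly
with a bounded trust-region solver and a small multistart. It shares only
the convolution primitive with the basis-function route and serves as the
independent optimiser in validation; agreement on noiseless draws is at
the 10⁻⁶ relative level.

**Reference Logan.** Cumulative integrals are trapezoidal over frame
midpoints with an implicit (0, 0) anchor (activity is zero at injection);
OLS runs over frames with midpoint > t*. The method's well-known
transient-equilibrium property — BP_ND approaches truth from below as t*
grows — is reproduced and tested. The simplified operational equation
(no C_R/C_T correction term) leaves a residual noiseless bias at finite t*
that shrinks with the apparent efflux rate k2a: about −0.9% at k2a = 0.10
min⁻¹ and t* = 20 min, −2.8% at k2a = 0.067. The fast-tracer single-TAC
checks therefore use R1 = 1.0, k2 = 0.30 min⁻¹, BP_ND = 2.0 (k2a = 0.10):
a tracer for which t* = 20 min is already adequate — consistent with
fast-kinetics amyloid tracers, for which ~20-min equilibrium times are
standard practice.

**SUVR.** Duration-weighted mean target over reference activity in the
window; frames partially inside contribute their overlapping duration, so
SUVR is exactly additive under frame merging. At secular equilibrium
SUVR = 1 + BP_ND; on bolus data it overshoots, which is precisely why the
window sweeps and the SUVR-on-BP_ND agreement regression exist.

**Parametric maps.** The regional estimators applied per voxel, sharing
one precomputed basis set per image; per-voxel failures become NaN plus a
failure count, never an exception. Identical voxel time series (noiseless
phantoms) are cached.

## The synthetic cohort generator

The simulator emulates a two-arm dual-tracer design: a fast-kinetics
60-min tracer ("amyloid", AV45-like) and a slow-kinetics 120-min tracer
("tau", AV1451-like), each with a cerebellar reference region.

* **Input function** — an internal device only (reference-tissue methods
  never see it): a gamma-variate bolus peaking at 0.8 min plus a
  bi-exponential recirculation tail, zero at t = 0 and non-negative. An
  "infusion" variant (saturating ramp) drives regions to secular
  equilibrium for the SUVR identity checks.
* **Reference kinetics** — one-tissue: K1_ref = 0.5 mL/min/mL with
  k2_ref = 0.17 min⁻¹ (fast arm) or 0.06 min⁻¹ (slow arm).
* **Schedules** — fast arm: 26 frames, 6×10 s, 3×20 s, 3×30 s, 4×60 s,
  10×315 s, exactly 0–60 min; slow arm: the same early pattern plus
  5×150 s and 20×300 s to 120 min. Both are configuration, not constants.
* **Regional truths** — seven target regions per arm with plausible
  AD-pattern values: fast arm k2 ≈ 0.2 min⁻¹, BP_ND 0.6–1.6 (high
  cortical amyloid); slow arm k2 ≈ 0.05 min⁻¹, BP_ND 0.3–0.9 (low
  cortical tau, higher thalamus/hippocampus/amygdala).
* **Between-subject spread** — parameters are sampled log-normally and
  mean-preserving with CVs of 10% (R1), 15% (k2) and 25% (BP_ND); BP_ND
  is sampled as (1 + BP_ND) log-normal to respect BP_ND > −1. The
  across-subject correlation of BP_ND between (tracer, region) pairs is
  imposed by a Gaussian copula on the log-normal draws; at these CVs the
  realized Pearson correlation is within ~0.001 of the requested copula
  value. The default structure links fast-arm thalamus to slow-arm
  thalamus, hippocampus and amygdala (0.72–0.85), mirroring the
  thalamo-hippocampal dual-pathology hypothesis the correlation analysis
  is designed to probe.
* **Noise** — zero-mean Gaussian per frame with the count-based variance
  surrogate σᵢ = scale·√(Cᵢ·e^(λ·tᵢ)/Δtᵢ), λ fixed to ¹⁸F decay
  (half-life 109.77 min); default scale 0.05 (~1–2% on well-counted
  frames, worst on short late frames). Default cohort size: 12 subjects.

**What the generator does not emulate:** partial-volume effects, motion,
scatter/randoms/attenuation residuals, off-target binding, reference-region
specific binding, or SRTM model violations (the target truly follows
one-tissue kinetics). Consequently noiseless synthetic data are
model-exact: truncated scans refit perfectly at any duration, so the
scan-duration instability seen in real cohorts appears here only under
measurement noise — the duration-stability analyses therefore run on noisy
cohorts, while the Logan t* and SUVR window sweeps show genuine
deterministic time-dependence even noiselessly. Passing tests demonstrate
estimator correctness and protocol-ordering logic, not robustness to model
misspecification.

## Stability and correlation conventions

"Stable" is operationalised as the earliest sweep value from which the
across-subject regional mean enters and stays within ±5% of its
longest-sweep value (band configurable). Frames straddling a truncation
boundary are dropped, not clipped; truncations leaving fewer than 5 frames
are skipped with a warning. The static-vs-dynamic agreement regression
pools all (subject, region) pairs jointly. The signed-R² matrix uses
Pearson correlation (Spearman switchable), masks |sign(r)·r²| ≤ 0.3 as
missing while always retaining the raw values and per-cell p-values, and
applies no multiple-testing correction by default (Benjamini–Hochberg
optional).

Under the default noisy conditions (8-subject cohorts in the test-sized
runs) the onsets come out at ~20–30 min (duration), ~15 min (t*) and
~25 min (window start) for the fast arm versus ~30–40, ~65–75 and
~80–85 min for the slow arm — the fast arm is strictly earlier on every
sweep, reproducing the core protocol-design ordering for 60- vs 120-min
dual-tracer studies.

## Problem sizes

Tests and the acceptance script are sized for a single CPU: 50-draw
recovery sweeps, 200-replicate noise studies, 8-subject stability cohorts,
200-subject correlation cohorts and ~100-voxel phantoms; the full test
suite runs in under a minute, the acceptance script in under half a
minute. The pipeline scales to larger cohorts/images linearly.

## Known limitations

* SRTM assumptions (one-tissue target, binding-free reference) are taken
  as true in simulation; violations seen with real tracers (off-target
  binding, choroid-plexus spillover) are out of scope.
* The reference Logan implementation omits the C_R/C_T correction term of
  the full operational equation (standard practice when k2' is unknown),
  hence the small finite-t* bias quantified above.
* Voxelwise SRTM on large 4-D volumes is loop-based; it is fast for
  phantom-scale images but not optimised for whole-brain clinical grids.
* The CSV cohort format stores frame averages only; the simulator's exact
  fine-grid curves do not survive a round-trip to disk, so fits on re-read
  cohorts use midpoint interpolation like any measured data.
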