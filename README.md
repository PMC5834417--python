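# refkin

Reference-tissue kinetic quantification of dynamic brain PET, built for
dual-tracer amyloid/tau studies: the simplified reference tissue model
(SRTM), reference Logan graphical analysis and static SUVR, together with
the study-design analyses that decide between them — time-stability of the
outcome versus scan duration / equilibrium time / static window, agreement
of static SUVR with dynamic BP_ND, and cross-tracer regional correlation.
A built-in synthetic cohort and phantom generator with known ground truth
drives every analysis, so the whole pipeline is testable without clinical
scans; user data can be supplied as 4-D NIfTI + integer-label atlas + frame
timing.

Intended users: PET methodologists and trialists choosing acquisition
protocols (dynamic vs short static scans) and analysts validating
reference-tissue pipelines.

## The models

With C_T(t) the target-region and C_R(t) the reference-region (cerebellar
grey) activity concentration:

**SRTM** — one-tissue target kinetics driven by the reference region:

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·C_R(t) ⊗ e^(−k2a·t),   k2a = k2/(1+BP_ND)

with R1 the target/reference delivery ratio, k2 (1/min) the target efflux
rate and BP_ND the non-displaceable binding potential. Fitted by the
basis-function method: for fixed k2a the model is linear in (R1, φ), so a
1-D search over a log-spaced k2a grid (with local refinement) replaces a
3-parameter nonlinear fit. An independent direct nonlinear least-squares
fit is included as a cross-check.

**Reference Logan** — for t > t*,

    ∫₀ᵗC_T/C_T(t) = (1 + BP_ND)·∫₀ᵗC_R/C_T(t) + int

estimated by OLS over frame midpoints beyond t*; slope − 1 = BP_ND.

**SUVR** — duration-weighted mean target over reference activity in a
static window; approaches 1 + BP_ND at secular equilibrium.

## Worked example

```python
from refkin import (RegionTruth, RegionalTACSet, fit_srtm,
                    fit_reference_logan, compute_suvr)
from refkin.synthetic_data import (InputFunction, default_schedule_av45,
                                   generate_reference_tac, generate_target_tac)

ref = generate_reference_tac(InputFunction(), K1_ref=0.5, k2_ref=0.17,
                             schedule=default_schedule_av45())
truth = RegionTruth("precuneus", R1=0.95, k2=0.20, BP_ND=1.6)
target = generate_target_tac(ref, truth)

srtm = fit_srtm(target, ref)
logan = fit_reference_logan(target, ref, t_star=20.0)
print(f"SRTM : R1={srtm.R1:.3f}  k2={srtm.k2:.3f}/min  BP_ND={srtm.BP_ND:.3f}")
print(f"Logan: BP_ND={logan.BP_ND:.3f}  int={logan.intercept:.2f} min  R2={logan.r_squared:.4f}")

ts = RegionalTACSet("sub-01", "amyloid",
                    {"cerebellum-grey": ref, "precuneus": target}, "cerebellum-grey")
print(f"SUVR (40-60 min): {compute_suvr(ts, (40.0, 60.0)).suvr['precuneus']:.3f}")
```

prints

```
SRTM : R1=0.950  k2=0.200/min  BP_ND=1.600
Logan: BP_ND=1.567  int=-8.38 min  R2=0.9999
SUVR (40-60 min): 3.130
```

SRTM recovers the generating parameters exactly on noiseless data. The
Logan estimate sits ~2% low at t* = 20 min — the transient-equilibrium
underestimate of the graphical method, which shrinks as t* grows. The
40–60-min SUVR of 3.13 exceeds 1 + BP_ND = 2.6 because a bolus scan is
still washing out (the identity SUVR = 1 + BP_ND holds only at true
equilibrium, e.g. under constant infusion).

A full simulated study — cohort simulation, all three fits, stability
sweeps, agreement regression, signed-R² correlation matrices, plots and a
manifest — runs from the command line:

```bash
refkin run --seed 1 --out runs/demo          # or: refkin run --config cfg.yaml
refkin simulate --out cohort/ --seed 1       # individual stages
refkin fit --tacs cohort/tacs.csv --method srtm --out fits.csv
```

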