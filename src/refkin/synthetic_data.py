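"""Dual-tracer synthetic cohort generator with known ground truth.

Emulates the acquisition design of a dual-tracer amyloid/tau dynamic PET
study: a fast-kinetics 60-min tracer (AV45-like) and a slow-kinetics
120-min tracer (AV1451-like), each quantified against a cerebellar
grey-matter reference region, in a small cohort with between-subject
parameter spread, frame-dependent noise, and a configurable cross-tracer
correlation structure on the binding potentials.

The forward model is the simplified reference tissue model (SRTM): the
reference region follows one-tissue kinetics driven by an analytic input
function, and each target region is

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·C_R(t) ⊗ exp(−k2a·t),
    k2a = k2 / (1 + BP_ND),

where R1 is the target/reference delivery ratio, k2 (1/min) the target
efflux rate, and BP_ND the non-displaceable binding potential. Curves are
integrated on a 0.01-min grid and binned to frame time-averages.

No arterial input function is measured in reference-tissue studies; the
generator's input function is an internal device to obtain bolus-shaped
reference curves, not a quantity any fit sees.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .convolve import DEFAULT_DT, exp_conv, fine_times, frame_average
from .tac_io import (
    FineCurve,
    FrameSchedule,
    RegionalTACSet,
    TimeActivityCurve,
    write_tac_table,
)

__all__ = [
    "F18_DECAY_CONSTANT",
    "InputFunction",
    "RegionTruth",
    "TracerSpec",
    "CohortSpec",
    "CohortDataset",
    "default_schedule_av45",
    "default_schedule_av1451",
    "generate_reference_tac",
    "generate_target_tac",
    "add_noise",
    "generate_cohort",
    "generate_phantom",
    "default_cohort_spec",
    "write_cohort",
]

#: 18F decay constant, ln2 / 109.77 min half-life (1/min)
F18_DECAY_CONSTANT = math.log(2.0) / 109.77


def default_schedule_av45() -> FrameSchedule:
    """Fast-tracer schedule: 26 frames, 0–60 min (short early frames)."""
    return FrameSchedule.from_durations(
        [10] * 6 + [20] * 3 + [30] * 3 + [60] * 4 + [315] * 10
    )

def default_schedule_av1451() -> FrameSchedule:
    """Slow-tracer schedule: 0–120 min, 5-min late frames."""
    return FrameSchedule.from_durations(
        [10] * 6 + [20] * 3 + [30] * 3 + [60] * 4 + [150] * 5 + [300] * 20
    )


@dataclass(frozen=True)
class InputFunction:
    """Analytic tracer input function, in arbitrary concentration units.

    ``kind="bolus"`` is a gamma-variate peak (peak time ``peak_time`` min,
    unit peak height before scaling by ``amplitude``) plus a bi-exponential
    recirculation tail; ``kind="infusion"`` is a saturating ramp
    ``amplitude·(1 − e^{−t/peak_time})`` used to drive regions to secular
    equilibrium. Both are 0 at t = 0 and non-negative for t ≥ 0.
    """

    kind: str = "bolus"
    amplitude: float = 100.0     # peak scale, nominally kBq/mL
    peak_time: float = 0.8       # min
    sharpness: float = 4.0       # gamma-variate exponent
    tail_fractions: tuple[float, float] = (0.25, 0.10)
    tail_rates: tuple[float, float] = (0.08, 0.008)  # 1/min
    tail_onset_rate: float = 2.0  # 1/min, pulls the tail to 0 at t=0

    def __post_init__(self) -> None:
        if self.kind not in ("bolus", "infusion"):
            raise ValueError(f"unknown input-function kind {self.kind!r}")
        if self.amplitude < 0 or self.peak_time <= 0:
            raise ValueError("amplitude must be >= 0 and peak_time > 0")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "infusion":
            return self.amplitude * -np.expm1(-np.maximum(t, 0.0) / self.peak_time)
        tt = np.maximum(t, 0.0)
        a = self.sharpness
        with np.errstate(divide="ignore", invalid="ignore"):
            peak = np.where(
                tt > 0.0,
                (tt / self.peak_time) ** a * np.exp(a * (1.0 - tt / self.peak_time)),
                0.0,
            )
        tail = np.zeros_like(tt)
        onset = 1.0 - np.exp(-self.tail_onset_rate * tt)
        for frac, rate in zip(self.tail_fractions, self.tail_rates):
            tail += frac * np.exp(-rate * tt) * onset
        return self.amplitude * (peak + tail)


@dataclass(frozen=True)
class RegionTruth:
    """Ground-truth SRTM parameters of one target region."""

    region: str
    R1: float       # unitless delivery ratio
    k2: float       # 1/min
    BP_ND: float    # unitless

    def __post_init__(self) -> None:
        if self.R1 <= 0:
            raise ValueError(f"{self.region}: R1 must be > 0, got {self.R1}")
        if self.k2 <= 0:
            raise ValueError(f"{self.region}: k2 must be > 0, got {self.k2}")
        if self.BP_ND <= -1:
            raise ValueError(
                f"{self.region}: BP_ND must exceed -1 (got {self.BP_ND}); the "
                "apparent efflux rate k2/(1+BP_ND) is undefined otherwise"
            )

    @property
    def k2a(self) -> float:
        """Apparent efflux rate k2 / (1 + BP_ND), 1/min."""
        return self.k2 / (1.0 + self.BP_ND)


def generate_reference_tac(
    input_function: InputFunction,
    K1_ref: float,
    k2_ref: float,
    schedule: FrameSchedule,
    dt: float = DEFAULT_DT,
) -> TimeActivityCurve:
    """Reference-region TAC from one-tissue kinetics.

    C_R(t) = K1_ref · IF(t) ⊗ exp(−k2_ref·t), frame-averaged onto the
    schedule; the exact fine-grid curve rides along on ``tac.fine``.
    """
    if K1_ref <= 0 or k2_ref <= 0:
        raise ValueError("K1_ref and k2_ref must be positive")
    t = fine_times(schedule.total_end, dt)
    cr = K1_ref * exp_conv(input_function(t), dt, k2_ref)
    fine = FineCurve(t, cr)
    return TimeActivityCurve(schedule, frame_average(fine, schedule),
                             region="reference", fine=fine)


def generate_target_tac(
    ref_tac: TimeActivityCurve,
    truth: RegionTruth,
    schedule: FrameSchedule | None = None,
) -> TimeActivityCurve:
    """Target-region TAC from the SRTM forward model.

    Evaluates R1·C_R + (k2 − R1·k2a)·C_R ⊗ e^{−k2a·t} on the reference
    curve's fine grid and frame-averages onto ``schedule`` (defaults to the
    reference TAC's schedule).
    """
    if ref_tac.fine is None:
        raise ValueError(
            "reference TAC carries no fine-grid curve; generate it with "
            "generate_reference_tac"
        )
    schedule = schedule or ref_tac.schedule
    fine = ref_tac.fine
    conv = exp_conv(fine.values, fine.dt, truth.k2a)
    ct = truth.R1 * fine.values + (truth.k2 - truth.R1 * truth.k2a) * conv
    out_fine = FineCurve(fine.times, ct)
    return TimeActivityCurve(schedule, frame_average(out_fine, schedule),
                             region=truth.region, fine=out_fine)


def add_noise(
    tac: TimeActivityCurve,
    noise_scale: float,
    decay_constant: float = F18_DECAY_CONSTANT,
    seed: int | np.random.Generator = 0,
) -> TimeActivityCurve:
    """Add frame-dependent Gaussian noise to a TAC.

    The per-frame standard deviation is the count-based variance surrogate

        σ_i = noise_scale · sqrt( max(C_i, ε) · e^{λ·t_mid,i} / Δt_i ),

    i.e. variance proportional to decay-corrected activity, inflated by the
    decay factor at the frame midpoint and diluted by frame duration —
    short late frames are noisiest. Reproducible under a fixed seed; the
    noisy TAC drops the fine-grid curve (it no longer describes the data).
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if noise_scale == 0:
        return tac
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sched = tac.schedule
    sd = noise_scale * np.sqrt(
        np.maximum(tac.values, 1e-9)
        * np.exp(decay_constant * sched.midpoints)
        / sched.durations
    )
    noisy = tac.values + rng.normal(0.0, 1.0, sched.n_frames) * sd
    return TimeActivityCurve(sched, noisy, region=tac.region, fine=None)


@dataclass(frozen=True)
class TracerSpec:
    """Acquisition + kinetics description of one tracer arm."""

    name: str
    schedule: FrameSchedule
    regions: tuple[RegionTruth, ...]
    input_function: InputFunction = InputFunction()
    K1_ref: float = 0.5      # mL/min/mL
    k2_ref: float = 0.17     # 1/min
    reference_region: str = "cerebellum-grey"

    def region_names(self) -> list[str]:
        return [r.region for r in self.regions]


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate one multi-subject, multi-tracer cohort.

    ``bp_correlation`` specifies the across-subject correlation of BP_ND
    between (tracer, region) pairs, keyed "tracer/region"; pairs not listed
    are independent. It is imposed through a Gaussian copula on the
    log-normal BP_ND draws, so requested values are copula correlations —
    near-identical to the realized Pearson correlations at these CVs.
    """

    tracers: tuple[TracerSpec, ...]
    n_subjects: int = 12
    cv_R1: float = 0.10
    cv_k2: float = 0.15
    cv_BP: float = 0.25
    noise_scale: float = 0.05
    bp_correlation: Mapping[tuple[str, str], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        for cv in (self.cv_R1, self.cv_k2, self.cv_BP):
            if cv < 0:
                raise ValueError("coefficients of variation must be >= 0")

    def bp_variable_names(self) -> list[str]:
        return [f"{tr.name}/{r.region}" for tr in self.tracers for r in tr.regions]

    def correlation_matrix(self) -> np.ndarray:
        names = self.bp_variable_names()
        corr = np.eye(len(names))
        if self.bp_correlation:
            idx = {n: i for i, n in enumerate(names)}
            for (a, b), rho in self.bp_correlation.items():
                if a not in idx or b not in idx:
                    raise ValueError(f"correlation names {(a, b)} not in cohort regions")
                corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = float(rho)
        eig = np.linalg.eigvalsh(corr)
        if eig[0] < -1e-8:
            raise ValueError(
                f"BP_ND correlation matrix is not positive semidefinite "
                f"(smallest eigenvalue {eig[0]:.4g})"
            )
        return corr


@dataclass
class CohortDataset:
    """Simulated cohort: TAC sets per subject × tracer plus ground truth."""

    spec: CohortSpec
    tac_sets: dict[tuple[str, str], RegionalTACSet]
    truth: pd.DataFrame  # columns: subject, tracer, region, R1, k2, BP_ND

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.tac_sets})

    def sets_for_tracer(self, tracer: str) -> list[RegionalTACSet]:
        out = [ts for (s, tr), ts in sorted(self.tac_sets.items()) if tr == tracer]
        if not out:
            raise KeyError(f"no tracer {tracer!r} in cohort")
        return out

    def truth_wide(self, tracer: str, parameter: str = "BP_ND") -> pd.DataFrame:
        """subjects × regions table of one true parameter."""
        sub = self.truth[self.truth.tracer == tracer]
        return sub.pivot(index="subject", columns="region", values=parameter)


def _lognormal_factors(rng_normals: np.ndarray, cv: float) -> np.ndarray:
    """Mean-one log-normal multipliers from standard-normal draws."""
    if cv == 0:
        return np.ones_like(rng_normals)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * rng_normals - 0.5 * sigma * sigma)


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Simulate a full cohort from a :class:`CohortSpec`.

    Per-subject parameters are sampled log-normally around the tracer means
    (mean-preserving, CV as specified); BP_ND is sampled as 1 + BP_ND
    log-normal to respect the BP_ND > −1 constraint, with the requested
    cross-region/cross-tracer correlation induced via a Gaussian copula.
    Noise is applied per the count-based surrogate of :func:`add_noise`.
    """
    rng = np.random.default_rng(spec.seed)
    corr = spec.correlation_matrix()
    names = spec.bp_variable_names()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))

    z_bp = rng.standard_normal((spec.n_subjects, len(names))) @ chol.T
    tac_sets: dict[tuple[str, str], RegionalTACSet] = {}
    truth_rows = []
    subj_ids = [f"sub-{i + 1:02d}" for i in range(spec.n_subjects)]

    for tracer in spec.tracers:
        ref_mean = generate_reference_tac(
            tracer.input_function, tracer.K1_ref, tracer.k2_ref, tracer.schedule
        )
        for si, subject in enumerate(subj_ids):
            # mild subject-level spread of reference kinetics
            k1f = _lognormal_factors(rng.standard_normal(), spec.cv_R1)
            ref = ref_mean.scaled(float(k1f))
            tacs: dict[str, TimeActivityCurve] = {}
            ref_noisy = add_noise(ref, spec.noise_scale, seed=rng)
            ref_noisy.region = tracer.reference_region
            ref_noisy.fine = ref.fine if spec.noise_scale == 0 else None
            tacs[tracer.reference_region] = ref_noisy
            for mean_truth in tracer.regions:
                vi = names.index(f"{tracer.name}/{mean_truth.region}")
                bp1 = (1.0 + mean_truth.BP_ND) * _lognormal_factors(
                    z_bp[si, vi], spec.cv_BP
                )
                realized = RegionTruth(
                    region=mean_truth.region,
                    R1=mean_truth.R1
                    * float(_lognormal_factors(rng.standard_normal(), spec.cv_R1)),
                    k2=mean_truth.k2
                    * float(_lognormal_factors(rng.standard_normal(), spec.cv_k2)),
                    BP_ND=float(bp1 - 1.0),
                )
                tac = generate_target_tac(ref, realized)
                tac = add_noise(tac, spec.noise_scale, seed=rng)
                tacs[mean_truth.region] = tac
                truth_rows.append(
                    (subject, tracer.name, mean_truth.region,
                     realized.R1, realized.k2, realized.BP_ND)
                )
            tac_sets[(subject, tracer.name)] = RegionalTACSet(
                subject, tracer.name, tacs, tracer.reference_region
            )

    truth = pd.DataFrame(
        truth_rows, columns=["subject", "tracer", "region", "R1", "k2", "BP_ND"]
    )
    return CohortDataset(spec=spec, tac_sets=tac_sets, truth=truth)


def generate_phantom(
    atlas_labels: np.ndarray,
    regional_tacs: Mapping[int, TimeActivityCurve],
    noise_scale: float = 0.0,
    seed: int = 0,
    decay_constant: float = F18_DECAY_CONSTANT,
) -> np.ndarray:
    """Build a 4-D dynamic phantom from an integer atlas and per-label TACs.

    Every voxel's time series is its label's TAC plus independent frame noise
    (same variance surrogate as :func:`add_noise`); background label 0 stays
    zero. Returns a float array of shape ``atlas.shape + (n_frames,)``.
    """
    atlas = np.asarray(atlas_labels)
    labels = np.unique(atlas)
    labels = labels[labels != 0]
    missing = [int(l) for l in labels if int(l) not in regional_tacs]
    if missing:
        raise ValueError(f"no TAC supplied for atlas labels {missing}")
    if regional_tacs:
        schedules = {t.schedule for t in regional_tacs.values()}
        if len(schedules) > 1:
            raise ValueError("all phantom TACs must share one frame schedule")
    n_frames = next(iter(regional_tacs.values())).schedule.n_frames
    rng = np.random.default_rng(seed)
    out = np.zeros(atlas.shape + (n_frames,), dtype=float)
    for label in labels:
        tac = regional_tacs[int(label)]
        mask = atlas == label
        series = np.broadcast_to(tac.values, (int(mask.sum()), n_frames)).copy()
        if noise_scale > 0:
            sched = tac.schedule
            sd = noise_scale * np.sqrt(
                np.maximum(tac.values, 1e-9)
                * np.exp(decay_constant * sched.midpoints)
                / sched.durations
            )
            series += rng.normal(0.0, 1.0, series.shape) * sd
        out[mask] = series
    return out


def default_cohort_spec(
    n_subjects: int = 12, noise_scale: float = 0.05, seed: int = 0
) -> CohortSpec:
    """The package's default study conditions.

    Two tracer arms quantified against cerebellar grey matter: a fast
    AV45-like amyloid tracer (60 min, target k2 ≈ 0.2/min) and a slow
    AV1451-like tau tracer (120 min, target k2 ≈ 0.05/min), six target
    regions each, 12 subjects, and a cross-tracer BP_ND correlation
    structure linking amyloid thalamus signal to tau signal in thalamus,
    hippocampus and amygdala.
    """
    amyloid_regions = (
        RegionTruth("frontal", R1=0.95, k2=0.20, BP_ND=1.6),
        RegionTruth("temporal", R1=0.90, k2=0.20, BP_ND=1.4),
        RegionTruth("parietal", R1=0.92, k2=0.21, BP_ND=1.5),
        RegionTruth("occipital", R1=1.00, k2=0.22, BP_ND=1.0),
        RegionTruth("thalamus", R1=1.05, k2=0.23, BP_ND=0.6),
        RegionTruth("hippocampus", R1=0.80, k2=0.18, BP_ND=0.7),
        RegionTruth("amygdala", R1=0.82, k2=0.19, BP_ND=0.8),
    )
    tau_regions = (
        RegionTruth("frontal", R1=0.90, k2=0.05, BP_ND=0.35),
        RegionTruth("temporal", R1=0.88, k2=0.05, BP_ND=0.8),
        RegionTruth("parietal", R1=0.90, k2=0.05, BP_ND=0.6),
        RegionTruth("occipital", R1=0.95, k2=0.055, BP_ND=0.3),
        RegionTruth("thalamus", R1=1.00, k2=0.06, BP_ND=0.9),
        RegionTruth("hippocampus", R1=0.78, k2=0.045, BP_ND=0.7),
        RegionTruth("amygdala", R1=0.80, k2=0.05, BP_ND=0.85),
    )
    amyloid = TracerSpec(
        name="amyloid",
        schedule=default_schedule_av45(),
        regions=amyloid_regions,
        k2_ref=0.17,
    )
    tau = TracerSpec(
        name="tau",
        schedule=default_schedule_av1451(),
        regions=tau_regions,
        input_function=InputFunction(tail_rates=(0.04, 0.005)),
        k2_ref=0.06,
    )
    bp_corr = {
        ("amyloid/thalamus", "tau/thalamus"): 0.85,
        ("amyloid/thalamus", "tau/hippocampus"): 0.85,
        ("amyloid/thalamus", "tau/amygdala"): 0.72,
        ("tau/thalamus", "tau/hippocampus"): 0.80,
        ("tau/thalamus", "tau/amygdala"): 0.70,
        ("tau/hippocampus", "tau/amygdala"): 0.70,
        ("amyloid/frontal", "amyloid/temporal"): 0.60,
    }
    return CohortSpec(
        tracers=(amyloid, tau),
        n_subjects=n_subjects,
        noise_scale=noise_scale,
        bp_correlation=bp_corr,
        seed=seed,
    )


def _spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    for tr in d["tracers"]:
        tr["schedule"] = {
            "starts": list(map(float, tr["schedule"]["starts"])),
            "ends": list(map(float, tr["schedule"]["ends"])),
        }
        tr["regions"] = [dict(r) for r in tr["regions"]]
        tr["input_function"] = dict(tr["input_function"])
    if d["bp_correlation"]:
        d["bp_correlation"] = [
            {"a": a, "b": b, "rho": float(r)} for (a, b), r in d["bp_correlation"].items()
        ]
    return d


def write_cohort(dataset: CohortDataset, out_dir) -> dict[str, Path]:
    """Write a cohort as tidy TAC CSV + ground-truth CSV + spec YAML sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tacs": out / "tacs.csv",
        "truth": out / "truth.csv",
        "spec": out / "cohort_spec.yaml",
    }
    write_tac_table(list(dict(sorted(dataset.tac_sets.items())).values()), paths["tacs"])
    dataset.truth.to_csv(paths["truth"], index=False)
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(_spec_to_dict(dataset.spec), fh, sort_keys=False)
    return paths
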