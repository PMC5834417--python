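"""Forward-model, noise and cohort-sampling checks for the simulator."""

import numpy as np
import pytest

from refkin.convolve import exp_conv, fine_times, frame_average
from refkin.synthetic_data import (
    CohortSpec,
    InputFunction,
    RegionTruth,
    TracerSpec,
    add_noise,
    default_cohort_spec,
    default_schedule_av45,
    generate_cohort,
    generate_phantom,
    generate_reference_tac,
    generate_target_tac,
)
from refkin.tac_io import FineCurve, FrameSchedule, TimeActivityCurve


class TestReferenceTac:
    def test_zero_input_gives_zero_tac(self, av45_schedule):
        zero_if = InputFunction(amplitude=0.0)
        tac = generate_reference_tac(zero_if, 0.5, 0.17, av45_schedule)
        assert np.allclose(tac.values, 0.0)

    def test_linear_in_k1(self, bolus_if, av45_schedule):
        a = generate_reference_tac(bolus_if, 0.5, 0.17, av45_schedule)
        b = generate_reference_tac(bolus_if, 1.0, 0.17, av45_schedule)
        assert np.allclose(b.values, 2.0 * a.values, rtol=1e-12)

    def test_boxcar_input_matches_closed_form(self):
        """One-tissue response to a unit boxcar on [0,1] min has the exact
        solution (1−e^{−k2 t})/k2 during the pulse, decaying after it."""
        k2 = 0.1
        schedule = FrameSchedule.from_durations([30] * 20)  # 0–10 min
        # a discontinuous input carries an O(dt/2) sampling error at the
        # step; 1 ms grid keeps the whole check under the 0.1% tolerance
        dt = 0.001

        class Boxcar(InputFunction):
            def __call__(self, t):
                t = np.asarray(t, dtype=float)
                return ((t >= 0) & (t <= 1.0)).astype(float)

        tac = generate_reference_tac(Boxcar(), 1.0, k2, schedule, dt=dt)
        t = fine_times(schedule.total_end, dt)
        during = (1.0 - np.exp(-k2 * np.minimum(t, 1.0))) / k2
        exact = during * np.exp(-k2 * np.clip(t - 1.0, 0.0, None))
        expected = frame_average(FineCurve(t, exact), schedule)
        assert np.allclose(tac.values, expected, rtol=1e-3)

    def test_nonnegative_and_fine_curve_attached(self, ref_tac_fast):
        assert np.all(ref_tac_fast.values >= 0)
        assert ref_tac_fast.fine is not None
        assert ref_tac_fast.fine.times[0] == 0.0

    def test_invalid_rate_constants_rejected(self, bolus_if, av45_schedule):
        with pytest.raises(ValueError):
            generate_reference_tac(bolus_if, 0.0, 0.17, av45_schedule)


class TestTargetTac:
    def test_identity_when_r1_one_bp_zero(self, ref_tac_fast):
        truth = RegionTruth("t", R1=1.0, k2=0.15, BP_ND=0.0)
        tac = generate_target_tac(ref_tac_fast, truth)
        assert np.allclose(tac.values, ref_tac_fast.values, rtol=1e-10)

    def test_matches_brute_force_convolution(self, ref_tac_fast):
        """Forward model equals direct quadrature of the convolution
        integral evaluated sample by sample."""
        truth = RegionTruth("t", R1=0.8, k2=0.15, BP_ND=1.5)
        tac = generate_target_tac(ref_tac_fast, truth)
        t = ref_tac_fast.fine.times
        cr = ref_tac_fast.fine.values
        idx = np.arange(200, t.size, 400)  # spot-check samples
        conv = np.array(
            [np.trapezoid(cr[: i + 1] * np.exp(-truth.k2a * (t[i] - t[: i + 1])),
                          t[: i + 1]) for i in idx]
        )
        expected = truth.R1 * cr[idx] + (truth.k2 - truth.R1 * truth.k2a) * conv
        assert np.allclose(tac.fine.values[idx], expected, rtol=1e-3)

    def test_infinite_binding_limit(self, ref_tac_fast):
        """As BP_ND → ∞ (with R1 = 1), the target approaches
        C_R + k2·∫C_R — tracer accumulates irreversibly."""
        k2 = 0.15
        tac = generate_target_tac(
            ref_tac_fast, RegionTruth("t", R1=1.0, k2=k2, BP_ND=1e6)
        )
        fine = ref_tac_fast.fine
        limit = fine.values + k2 * exp_conv(fine.values, fine.dt, 0.0)
        assert np.allclose(tac.fine.values[1:], limit[1:], rtol=1e-4)

    def test_satisfies_srtm_ode(self, ref_tac_fast):
        """dC_T/dt = R1·dC_R/dt + k2·C_R − k2a·C_T on the fine grid."""
        truth = RegionTruth("t", R1=0.8, k2=0.15, BP_ND=1.5)
        tac = generate_target_tac(ref_tac_fast, truth)
        t = ref_tac_fast.fine.times
        cr = ref_tac_fast.fine.values
        ct = tac.fine.values
        dct = np.gradient(ct, t)
        rhs = truth.R1 * np.gradient(cr, t) + truth.k2 * cr - truth.k2a * ct
        scale = np.max(np.abs(dct))
        assert np.max(np.abs(dct - rhs)[5:]) < 1e-3 * scale

    def test_bp_below_minus_one_rejected(self):
        with pytest.raises(ValueError, match="BP_ND"):
            RegionTruth("t", R1=1.0, k2=0.1, BP_ND=-1.2)

    def test_requires_fine_curve(self, av45_schedule):
        bare = TimeActivityCurve(av45_schedule, np.ones(av45_schedule.n_frames))
        with pytest.raises(ValueError, match="fine"):
            generate_target_tac(bare, RegionTruth("t", 1.0, 0.1, 1.0))


class TestAddNoise:
    def test_zero_scale_is_identity(self, ref_tac_fast):
        assert add_noise(ref_tac_fast, 0.0) is ref_tac_fast

    def test_deterministic_under_seed(self, ref_tac_fast):
        a = add_noise(ref_tac_fast, 0.05, seed=7)
        b = add_noise(ref_tac_fast, 0.05, seed=7)
        assert np.array_equal(a.values, b.values)
        c = add_noise(ref_tac_fast, 0.05, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_empirical_sd_matches_variance_model(self):
        """Monte-Carlo SD of one frame within 3% of the analytic formula."""
        schedule = FrameSchedule.from_durations([60, 60])
        tac = TimeActivityCurve(schedule, np.array([40.0, 30.0]))
        scale, lam = 0.05, np.log(2) / 109.77
        rng = np.random.default_rng(123)
        draws = np.array(
            [add_noise(tac, scale, seed=rng).values for _ in range(10_000)]
        )
        sd_expected = scale * np.sqrt(
            tac.values * np.exp(lam * schedule.midpoints) / schedule.durations
        )
        assert np.allclose(draws.std(axis=0), sd_expected, rtol=0.03)


class TestCohort:
    def test_cv_zero_noise_zero_gives_identical_subjects(self):
        spec = default_cohort_spec(n_subjects=3, noise_scale=0.0)
        spec = CohortSpec(
            tracers=spec.tracers[:1], n_subjects=3,
            cv_R1=0.0, cv_k2=0.0, cv_BP=0.0, noise_scale=0.0, seed=1,
        )
        cohort = generate_cohort(spec)
        tracer = spec.tracers[0].name
        sets = cohort.sets_for_tracer(tracer)
        for region in sets[0].regions:
            ref_vals = sets[0].tacs[region].values
            for ts in sets[1:]:
                assert np.allclose(ts.tacs[region].values, ref_vals, rtol=1e-12)
        # realized truths equal the means
        for rt in spec.tracers[0].regions:
            got = cohort.truth[cohort.truth.region == rt.region]
            assert np.allclose(got.BP_ND, rt.BP_ND)
            assert np.allclose(got.k2, rt.k2)

    def test_copula_recovers_requested_bp_correlation(self):
        """Requested copula correlation 0.9 between two regions is realised
        as a sample Pearson r within ±0.03 at n = 500 subjects."""
        regions = (
            RegionTruth("a", 1.0, 0.2, 1.0),
            RegionTruth("b", 1.0, 0.2, 1.0),
        )
        tracer = TracerSpec("x", default_schedule_av45(), regions)
        spec = CohortSpec(
            tracers=(tracer,), n_subjects=500, noise_scale=0.0,
            bp_correlation={("x/a", "x/b"): 0.9}, seed=11,
        )
        truth = generate_cohort(spec).truth_wide("x")
        r = np.corrcoef(truth["a"], truth["b"])[0, 1]
        assert abs(r - 0.9) < 0.03

    def test_seed_reproducibility(self):
        spec = default_cohort_spec(n_subjects=3, seed=5)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for key in a.tac_sets:
            for region in a.tac_sets[key].regions:
                assert np.array_equal(
                    a.tac_sets[key].tacs[region].values,
                    b.tac_sets[key].tacs[region].values,
                )
        c = generate_cohort(default_cohort_spec(n_subjects=3, seed=6))
        key = next(iter(a.tac_sets))
        region = a.tac_sets[key].regions[0]
        assert not np.array_equal(
            a.tac_sets[key].tacs[region].values, c.tac_sets[key].tacs[region].values
        )

    def test_non_psd_correlation_rejected(self):
        regions = tuple(RegionTruth(n, 1.0, 0.2, 1.0) for n in "abc")
        tracer = TracerSpec("x", default_schedule_av45(), regions)
        spec = CohortSpec(
            tracers=(tracer,), n_subjects=3,
            bp_correlation={
                ("x/a", "x/b"): 0.95, ("x/a", "x/c"): 0.95, ("x/b", "x/c"): -0.9,
            },
            seed=0,
        )
        with pytest.raises(ValueError, match="eigenvalue"):
            generate_cohort(spec)

    def test_forward_linearity_in_input_amplitude(self, av45_schedule):
        """Scaling the input function scales every generated TAC."""
        truth = RegionTruth("t", 0.9, 0.2, 1.2)
        out = []
        for amp in (50.0, 100.0):
            ref = generate_reference_tac(
                InputFunction(amplitude=amp), 0.5, 0.17, av45_schedule
            )
            out.append(generate_target_tac(ref, truth).values)
        assert np.allclose(out[1], 2.0 * out[0], rtol=1e-12)


class TestPhantom:
    def make_atlas(self):
        atlas = np.zeros((6, 6, 2), dtype=int)
        atlas[:3, :, :] = 1
        atlas[3:, :3, :] = 2
        return atlas

    def test_noiseless_voxels_equal_their_tac(self, ref_tac_fast, target_tac_fast):
        tgt, _ = target_tac_fast
        atlas = self.make_atlas()
        dyn = generate_phantom(atlas, {1: ref_tac_fast, 2: tgt}, noise_scale=0.0)
        assert dyn.shape == atlas.shape + (ref_tac_fast.schedule.n_frames,)
        assert np.allclose(dyn[0, 0, 0], ref_tac_fast.values)
        assert np.allclose(dyn[4, 0, 0], tgt.values)
        assert np.all(dyn[atlas == 0] == 0)

    def test_missing_label_mapping_rejected(self, ref_tac_fast):
        with pytest.raises(ValueError, match=r"\[2\]"):
            generate_phantom(self.make_atlas(), {1: ref_tac_fast})

    def test_noisy_region_mean_near_truth(self, ref_tac_fast):
        """Mean over a 1000-voxel region stays within 3·SE of the true TAC."""
        atlas = np.ones((10, 10, 10), dtype=int)
        scale = 0.05
        dyn = generate_phantom(atlas, {1: ref_tac_fast}, noise_scale=scale, seed=3)
        sched = ref_tac_fast.schedule
        lam = np.log(2) / 109.77
        sd = scale * np.sqrt(
            np.maximum(ref_tac_fast.values, 1e-9)
            * np.exp(lam * sched.midpoints) / sched.durations
        )
        mean_tac = dyn.reshape(-1, sched.n_frames).mean(axis=0)
        se = sd / np.sqrt(1000)
        assert np.all(np.abs(mean_tac - ref_tac_fast.values) < 3.5 * se)
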