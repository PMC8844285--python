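"""Scene generation, detachment dynamics, rendering and ground truth."""

import numpy as np
import pytest
from scipy.stats import chisquare

from mtpef.electromechanics import (
    FieldCalibration,
    PulseProtocol,
    mt_linear_charge_density,
)
from mtpef.exceptions import InvalidParameterError, InvalidProtocolError
from mtpef.experiment import sweep_protocols
from mtpef.simulate import (
    STATE_BOUND,
    STATE_MOBILE,
    FilamentScene,
    ImagingParams,
    MotionModel,
    generate_scene,
    render_frame,
    render_signal,
    simulate_experiment,
)

F_AB = 50e-12

UNIFORM_FIELD = FieldCalibration(gap_start_um=-1e6, gap_width_um=2e6)
QUIET = ImagingParams(shot_noise=False, read_noise_sigma=0.0, gain_drift_sigma=0.0)


def _single_filament_scene(anchor_density, x=10.0, y=10.0, length=8.0):
    return FilamentScene(
        endpoints=np.array([[[x - length / 2, y], [x + length / 2, y]]]),
        anchor_density=np.array([float(anchor_density)]),
        intensity_per_um=np.array([5000.0]),
        states=np.zeros(1, dtype=np.int8),
        fov_um=(20.0, 20.0),
    )


class TestGenerateScene:
    def test_count_arithmetic(self):
        scene = generate_scene(10.0, (5.0, 5.0), seed=0)
        assert len(scene) == 250

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            generate_scene(0.0, (5.0, 5.0), seed=0)
        with pytest.raises(InvalidParameterError):
            generate_scene(1.0, (-5.0, 5.0), seed=0)
        with pytest.raises(InvalidParameterError):
            generate_scene(1.0, (5.0, 5.0), seed=None)

    def test_isotropic_orientations_at_zero_kappa(self):
        scene = generate_scene(10.0, (50.0, 50.0), alignment_kappa=0.0, seed=7)
        d = scene.endpoints[:, 1] - scene.endpoints[:, 0]
        theta = np.arctan2(d[:, 1], d[:, 0]) % np.pi
        counts, _ = np.histogram(theta, bins=18, range=(0, np.pi))
        assert chisquare(counts).pvalue > 0.01

    def test_concentrated_orientations_at_high_kappa(self):
        scene = generate_scene(4.0, (50.0, 50.0), alignment_kappa=8.0, seed=7)
        d = scene.endpoints[:, 1] - scene.endpoints[:, 0]
        theta = np.arctan2(d[:, 1], d[:, 0]) % np.pi
        # flow axis is pi/2; most filaments within 30 degrees of it
        assert np.mean(np.abs(theta - np.pi / 2) < np.pi / 6) > 0.8

    def test_anchor_counts_follow_poisson_moments(self):
        """Mean ~ anchor_density_mean * L and variance ~ mean, within 5%."""
        scene = generate_scene(
            4.0, (50.0, 50.0),
            length_dist_params={"mean_um": 10.0, "cv": 0.0},
            anchor_density_mean=210.0, seed=3,
        )
        counts = scene.anchor_density * scene.lengths_um
        assert len(scene) == 10000
        assert counts.mean() == pytest.approx(2100.0, rel=0.05)
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)

    def test_lengths_match_endpoint_distance(self):
        scene = generate_scene(1.0, (20.0, 20.0), seed=4)
        d = np.linalg.norm(scene.endpoints[:, 1] - scene.endpoints[:, 0], axis=1)
        np.testing.assert_allclose(d, scene.lengths_um, rtol=1e-12)
        assert np.all(scene.lengths_um > 0)

    def test_reproducible_for_fixed_seed(self):
        a = generate_scene(2.0, (30.0, 30.0), seed=9)
        b = generate_scene(2.0, (30.0, 30.0), seed=9)
        np.testing.assert_array_equal(a.endpoints, b.endpoints)
        np.testing.assert_array_equal(a.anchor_density, b.anchor_density)


class TestStateMachine:
    def test_illegal_transitions_rejected(self):
        scene = _single_filament_scene(200.0)
        scene.set_state([0], STATE_MOBILE)
        with pytest.raises(InvalidParameterError):
            scene.set_state([0], STATE_BOUND)

    def test_overlapping_protocols_rejected(self):
        scene = _single_filament_scene(200.0)
        protos = [
            PulseProtocol(amplitude_v=100.0, start_time_s=0.0),
            PulseProtocol(amplitude_v=200.0, start_time_s=5.0),
        ]
        with pytest.raises(InvalidProtocolError):
            simulate_experiment(scene, protos, UNIFORM_FIELD, MotionModel(),
                                F_AB, QUIET, duration_s=20.0, seed=1)


class TestDetachment:
    def test_zero_voltage_leaves_everything_bound(self):
        scene = generate_scene(0.5, (30.0, 20.0), seed=2)
        protos = sweep_protocols(voltages=[0.0])
        _, truth = simulate_experiment(scene, protos, UNIFORM_FIELD, MotionModel(),
                                       F_AB, QUIET, duration_s=20.0, seed=2)
        assert (truth.filaments.final_state == "bound").all()
        assert truth.filaments.detachment_voltage_v.isna().all()
        assert (truth.filaments.displacement_um == 0).all()

    @pytest.mark.parametrize("anchor, expected_v", [(200.0, 210.0), (210.0, 255.0)])
    def test_detachment_voltage_brackets_force_balance(self, anchor, expected_v):
        """D_AB(17.5 kV/cm) = 209.58/µm, so a filament anchored at 200/µm
        releases at 210 V while one at exactly 210/µm needs 255 V."""
        scene = _single_filament_scene(anchor)
        protos = sweep_protocols()
        _, truth = simulate_experiment(scene, protos, UNIFORM_FIELD, MotionModel(),
                                       F_AB, QUIET,
                                       duration_s=protos[-1].end_time_s + 2, seed=1)
        assert truth.filaments.detachment_voltage_v.iloc[0] == expected_v

    def test_detachment_oracle_and_monotonicity(self):
        """Recorded detachment voltages equal a brute-force independent scan of
        the force balance at each filament's initial midpoint, and the detached
        fraction is non-decreasing along the voltage sequence."""
        cal = FieldCalibration(gap_start_um=-40.0, gap_width_um=60.0)
        scene = generate_scene(0.5, (40.0, 30.0), anchor_density_mean=209.6, seed=6)
        protos = sweep_protocols()
        motion = MotionModel(mobility_um_per_s_per_kv_cm=0.0)  # freeze positions
        _, truth = simulate_experiment(scene, protos, cal, motion, F_AB, QUIET,
                                       duration_s=protos[-1].end_time_s + 2, seed=6)
        rho = mt_linear_charge_density()
        mid_x = scene.midpoints_um[:, 0]
        recorded = truth.filaments.detachment_voltage_v.to_numpy()
        for i in range(len(scene)):
            expected = np.nan
            for p in protos:
                e_local = cal.field_profile(mid_x[i], p.amplitude_v)
                if e_local * 1e5 * rho * 1e-6 > scene.anchor_density[i] * F_AB:
                    expected = p.amplitude_v
                    break
            assert (np.isnan(expected) and np.isnan(recorded[i])) or expected == recorded[i]
        detached = ~np.isnan(recorded)
        fractions = [
            np.mean(recorded[detached] <= v) for v in [p.amplitude_v for p in protos]
        ]
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))

    def test_determinism_bit_identical(self):
        scene = generate_scene(0.4, (25.0, 25.0), seed=8)
        protos = sweep_protocols(voltages=[210.0, 300.0])
        runs = [
            simulate_experiment(scene, protos, UNIFORM_FIELD, MotionModel(), F_AB,
                                ImagingParams(), duration_s=protos[-1].end_time_s + 2,
                                seed=8)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0][0].frames, runs[1][0].frames)
        assert runs[0][1].filaments.equals(runs[1][1].filaments)
        assert runs[0][1].frames.equals(runs[1][1].frames)


class TestRendering:
    def test_empty_scene_is_background_plane(self):
        scene = FilamentScene(
            endpoints=np.empty((0, 2, 2)), anchor_density=np.empty(0),
            intensity_per_um=np.empty(0), states=np.empty(0, dtype=np.int8),
            fov_um=(10.0, 10.0),
        )
        frame = render_frame(scene, QUIET, gain=1.0, rng=0, quantize=False)
        from mtpef.simulate import _background_plane, frame_shape

        np.testing.assert_array_equal(
            frame, _background_plane(QUIET, frame_shape((10.0, 10.0), QUIET))
        )

    def test_colocated_filaments_add(self):
        one = _single_filament_scene(200.0)
        two = FilamentScene(
            endpoints=np.repeat(one.endpoints, 2, axis=0),
            anchor_density=np.repeat(one.anchor_density, 2),
            intensity_per_um=np.repeat(one.intensity_per_um, 2),
            states=np.zeros(2, dtype=np.int8),
            fov_um=one.fov_um,
        )
        np.testing.assert_allclose(
            render_signal(two, QUIET), 2 * render_signal(one, QUIET), rtol=1e-12
        )

    def test_gain_linearity(self):
        scene = _single_filament_scene(200.0)
        f1 = render_frame(scene, QUIET, gain=1.0, rng=0, quantize=False)
        f2 = render_frame(scene, QUIET, gain=2.0, rng=0, quantize=False)
        np.testing.assert_allclose(f2, 2 * f1, rtol=1e-12)

    def test_invalid_gain_rejected(self):
        with pytest.raises(InvalidParameterError):
            render_frame(_single_filament_scene(1.0), QUIET, gain=0.0)

    def test_deposited_intensity_scales_with_length(self):
        short = _single_filament_scene(200.0, length=4.0)
        long = _single_filament_scene(200.0, length=8.0)
        ratio = render_signal(long, QUIET).sum() / render_signal(short, QUIET).sum()
        assert ratio == pytest.approx(2.0, rel=1e-6)


class TestMassBudget:
    def test_mass_conserved_with_crowding(self):
        """Noise off, crowding on: total fluorescence above background is
        conserved while filaments translocate inside the frame."""
        rng = np.random.default_rng(12)
        n = 20
        mid = rng.uniform(15.0, 25.0, size=(n, 2))  # keep well away from edges
        ang = rng.uniform(0, np.pi, size=n)
        half = 3.0 * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        scene = FilamentScene(
            endpoints=np.stack([mid - half, mid + half], axis=1),
            anchor_density=rng.uniform(50.0, 150.0, size=n),
            intensity_per_um=np.full(n, 5000.0),
            states=np.zeros(n, dtype=np.int8),
            fov_um=(40.0, 40.0),
        )
        protos = [PulseProtocol(amplitude_v=210.0, start_time_s=2.0)]
        motion = MotionModel(mobility_um_per_s_per_kv_cm=300.0, arrest_field_kv_cm=0.0)
        stack, truth = simulate_experiment(scene, protos, UNIFORM_FIELD, motion,
                                           F_AB, QUIET, duration_s=14.0, seed=12,
                                           quantize=False)
        assert (truth.filaments.final_state == "mobile").all()
        assert truth.filaments.displacement_um.max() > 1.0
        from mtpef.simulate import _background_plane

        totals = (stack.frames - _background_plane(QUIET, stack.shape)).sum(axis=(1, 2))
        np.testing.assert_allclose(totals, totals[0], rtol=1e-6)

    def test_mass_lost_without_crowding(self):
        """Crowding agent absent: mobile filaments leave the imaging plane and
        total fluorescence decays after the first detachment."""
        rng = np.random.default_rng(13)
        n = 30
        mid = rng.uniform(10.0, 20.0, size=(n, 2))  # interior, so motion cannot
        ang = rng.uniform(0, np.pi, size=n)         # carry clipped mass back in
        half = 2.5 * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        scene = FilamentScene(
            endpoints=np.stack([mid - half, mid + half], axis=1),
            anchor_density=rng.uniform(20.0, 100.0, size=n),
            intensity_per_um=np.full(n, 5000.0),
            states=np.zeros(n, dtype=np.int8),
            fov_um=(30.0, 30.0),
            crowding=False,
        )
        protos = [PulseProtocol(amplitude_v=300.0, start_time_s=2.0)]
        stack, truth = simulate_experiment(scene, protos, UNIFORM_FIELD, MotionModel(),
                                           F_AB, QUIET, duration_s=16.0, seed=13,
                                           quantize=False)
        assert (truth.filaments.final_state == "departed").any()
        totals = stack.frames.sum(axis=(1, 2))
        assert np.all(np.diff(totals) <= 1e-6 * totals[0])
        assert totals[-1] < 0.9 * totals[0]
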