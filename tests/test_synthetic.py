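import numpy as np
import pytest
from scipy import ndimage

from angiotrack.contrast import ContrastWindow
from angiotrack.errors import GenerationError, ValidationError
from angiotrack.synthetic import (
    BranchSpec,
    PhantomConfig,
    Stenosis,
    bolus_profile,
    default_test_suite_configs,
    generate_synthetic_cine,
    get_preset,
    reseeded,
)

from conftest import mini_config


def test_seeded_determinism(mini_phantom):
    seq2, truth2 = generate_synthetic_cine(mini_config())
    seq1, truth1 = mini_phantom
    np.testing.assert_array_equal(seq1.frames, seq2.frames)
    np.testing.assert_array_equal(truth1.true_masks, truth2.true_masks)
    np.testing.assert_array_equal(truth1.true_phase, truth2.true_phase)


def test_different_seed_changes_frames(mini_phantom):
    seq1, _ = mini_phantom
    seq2, _ = generate_synthetic_cine(mini_config(seed=8))
    assert not np.array_equal(seq1.frames, seq2.frames)


def test_static_limit_all_frames_identical():
    cfg = mini_config(motion_amplitude_px=0.0, noise_sigma=0.0, bolus_window=None)
    seq, truth = generate_synthetic_cine(cfg)
    for t in range(1, len(seq)):
        np.testing.assert_array_equal(seq.frames[t], seq.frames[0])
    assert truth.true_bolus_window is None


def test_phase_periodicity_without_noise_or_bolus():
    cfg = mini_config(noise_sigma=0.0, bolus_window=None)
    seq, truth = generate_synthetic_cine(cfg)
    period = truth.period_frames
    for t in range(len(seq) - period):
        np.testing.assert_array_equal(seq.frames[t], seq.frames[t + period])
        np.testing.assert_array_equal(truth.true_masks[t], truth.true_masks[t + period])


def test_phase_labels_mod_period(mini_phantom):
    _, truth = mini_phantom
    np.testing.assert_array_equal(
        truth.true_phase, np.arange(len(truth.true_phase)) % truth.period_frames
    )


def test_zero_motion_collapses_phase_labels():
    _, truth = generate_synthetic_cine(mini_config(motion_amplitude_px=0.0))
    np.testing.assert_array_equal(truth.true_phase, 0)


def test_geometry_present_every_frame(mini_phantom):
    _, truth = mini_phantom
    assert (truth.true_masks.sum(axis=(1, 2)) > 0).all()


def test_bolus_profile_shape():
    w = ContrastWindow(10, 20)
    assert bolus_profile(9, w) == 0.0
    assert bolus_profile(21, w) == 0.0
    assert bolus_profile(10, w) == pytest.approx(1 / 3)
    assert bolus_profile(11, w) == pytest.approx(2 / 3)
    assert bolus_profile(12, w) == 1.0
    assert bolus_profile(15, w) == 1.0
    assert bolus_profile(19, w) == pytest.approx(2 / 3)
    assert bolus_profile(20, w) == pytest.approx(1 / 3)
    assert bolus_profile(5, None) == 0.0


def test_plateau_frame_darker_on_mask_than_background():
    seq, truth = generate_synthetic_cine(mini_config(noise_sigma=0.0))
    w = truth.true_bolus_window
    t = (w.start + w.end) // 2  # plateau
    mask = truth.true_masks[t]
    on = seq.frames[t][mask].mean()
    off = seq.frames[t][~mask].mean()
    assert off - on >= 0.6 / 2  # at least vessel_contrast / 2


def test_dye_free_vs_plateau_difference_supported_on_dilated_mask():
    cfg = mini_config(noise_sigma=0.01)
    seq, truth = generate_synthetic_cine(cfg)
    w = truth.true_bolus_window
    period = truth.period_frames
    t_plateau = w.start + 4
    t_free = t_plateau % period  # same cardiac phase, pre-injection
    assert truth.true_phase[t_plateau] == truth.true_phase[t_free]
    diff = np.abs(seq.frames[t_plateau] - seq.frames[t_free])
    noise_bound = 5 * cfg.noise_sigma * np.sqrt(2)  # two independent noise draws
    dilated = ndimage.binary_dilation(truth.true_masks[t_plateau], iterations=3)
    assert (diff[~dilated] <= noise_bound).all()
    assert diff[truth.true_masks[t_plateau]].max() > noise_bound


def test_stenosis_halves_local_width():
    branch = BranchSpec(
        control_points=((30, 25), (48, 60), (70, 75)),
        width=6.0,
        stenosis=Stenosis(position=0.5, severity=0.5),
    )
    cfg = mini_config(
        vessel_tree=(branch,), motion_amplitude_px=0.0, noise_sigma=0.0
    )
    _, truth = generate_synthetic_cine(cfg)
    mask = truth.true_masks[0]

    from angiotrack.synthetic import _sample_branch

    pos, hw = _sample_branch(branch)
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    frac = arc / arc[-1]
    center = int(np.argmin(np.abs(frac - 0.5)))
    tangent = pos[center + 1] - pos[center - 1]
    tangent /= np.linalg.norm(tangent)
    normal = np.array([-tangent[1], tangent[0]])

    def width_along_normal(point):
        # walk both ways from the centerline until leaving the mask
        total = 0.0
        for sign in (+1, -1):
            step = 0.05
            d = 0.0
            while True:
                p = point + sign * (d + step) * normal
                r, c = int(round(p[0])), int(round(p[1]))
                if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
                    break
                d += step
            total += d
        return total

    w_center = width_along_normal(pos[center])
    assert w_center == pytest.approx(3.0, abs=1.0)
    # far from the stenosis the full width is preserved
    ref = int(np.argmin(np.abs(frac - 0.15)))
    t2 = pos[ref + 1] - pos[ref - 1]
    t2 /= np.linalg.norm(t2)
    normal = np.array([-t2[1], t2[0]])
    assert width_along_normal(pos[ref]) == pytest.approx(6.0, abs=1.0)


def test_taper_width_varies_along_branch():
    branch = BranchSpec(control_points=((25, 25), (48, 60), (70, 70)), width=(8.0, 2.0))
    cfg = mini_config(vessel_tree=(branch,), motion_amplitude_px=0.0, noise_sigma=0.0)
    _, truth = generate_synthetic_cine(cfg)
    mask = truth.true_masks[0]
    # count mask pixels near the two endpoints: thick end >> thin end
    thick = mask[20:31, 20:31].sum()
    thin = mask[65:76, 65:76].sum()
    assert thick > thin > 0


def test_geometry_leaving_frame_raises():
    with pytest.raises(GenerationError, match="amplitude"):
        generate_synthetic_cine(mini_config(motion_amplitude_px=40.0))


def test_vessels_leave_room_for_background(mini_phantom):
    _, truth = mini_phantom
    assert truth.true_masks.mean() < 0.2


class TestDefaultConfigs:
    def test_at_least_four_named_axes(self):
        cfgs = default_test_suite_configs()
        assert len(cfgs) >= 4
        names = {c.name for c in cfgs}
        assert {"high_curvature", "width_taper", "stenosed", "multi_branch"} <= names

    def test_dye_free_cycle_guaranteed(self):
        for cfg in default_test_suite_configs():
            assert cfg.bolus_window.start >= cfg.period_frames
            assert cfg.n_frames == 60 and cfg.period_frames == 20
            assert (cfg.bolus_window.start, cfg.bolus_window.end) == (20, 45)

    def test_regeneration_bit_identical(self):
        cfg = default_test_suite_configs()[2]
        s1, t1 = generate_synthetic_cine(cfg)
        s2, t2 = generate_synthetic_cine(cfg)
        np.testing.assert_array_equal(s1.frames, s2.frames)
        np.testing.assert_array_equal(t1.true_masks, t2.true_masks)

    def test_get_preset_and_reseed(self):
        cfg = get_preset("stenosed")
        assert cfg.name == "stenosed"
        assert reseeded(cfg, 99).seed == 99
        with pytest.raises(ValidationError):
            get_preset("nonexistent")


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            dict(n_frames=1),
            dict(period_frames=3),
            dict(bolus_window=ContrastWindow(8, 30)),
            dict(vessel_contrast=0.0),
            dict(vessel_contrast=1.5),
            dict(noise_sigma=-0.1),
            dict(motion_amplitude_px=-1.0),
            dict(background="starfield"),
            dict(vessel_tree=()),
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(ValidationError):
            mini_config(**overrides)

    def test_stenosis_validation(self):
        with pytest.raises(ValidationError):
            Stenosis(position=0.5, severity=1.0)
        with pytest.raises(ValidationError):
            Stenosis(position=1.2, severity=0.5)

    def test_branch_validation(self):
        with pytest.raises(ValidationError):
            BranchSpec(control_points=((1, 1),))
        with pytest.raises(ValidationError):
            BranchSpec(control_points=((1, 1), (2, 2)), width=0.0)


def test_export_roundtrip_dicom(tmp_path, mini_phantom):
    from angiotrack.cine_io import read_cine
    from angiotrack.synthetic import load_truth_bundle, save_simulation

    seq, truth = mini_phantom
    save_simulation(tmp_path / "sim", seq, truth, fmt="dicom")
    loaded = read_cine(tmp_path / "sim" / "cine.dcm")
    assert len(loaded) == len(seq)
    # global min-max renormalization preserves relative intensities
    corr = np.corrcoef(loaded.frames.ravel(), seq.frames.ravel())[0, 1]
    assert corr > 1 - 1e-6
    truth2 = load_truth_bundle(tmp_path / "sim")
    np.testing.assert_array_equal(truth2.true_masks, truth.true_masks)
    np.testing.assert_array_equal(truth2.true_phase, truth.true_phase)
    assert (truth2.true_bolus_window.start, truth2.true_bolus_window.end) == (
        truth.true_bolus_window.start,
        truth.true_bolus_window.end,
    )
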