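"""Unit tests for the synthetic data generators."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dynbody.synthetic import (
    ACTIONS,
    END_EFFECTORS,
    GroundTruth,
    JointTrajectory,
    Skeleton,
    default_skeleton,
    default_stimulus_pool,
    forward_kinematics,
    make_event_schedule,
    make_ground_truth,
    make_impossible,
    render_stick_video,
    simulate_bold,
    simulate_possible_trajectory,
    world_orientations,
)


# ---------------------------------------------------------------------------
# skeleton


class TestSkeleton:
    def test_default_counts(self, skeleton):
        assert skeleton.n_joints == 71
        assert len(skeleton.rotating_joints) == 56
        assert len(skeleton.no_rotation) == 15

    def test_tree_rooted_at_pelvis(self, skeleton):
        assert skeleton.joint_names[0] == "pelvis"
        assert skeleton.parent_index[0] == -1
        # every joint reaches the root
        for name in skeleton.joint_names:
            assert skeleton.chain_to_root(name)[-1] == "pelvis"

    def test_chain_offsets_nonzero(self, skeleton):
        for j in range(1, skeleton.n_joints):
            assert np.linalg.norm(skeleton.offset[j]) > 0

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cyclic|precede"):
            Skeleton(
                joint_names=["a", "b", "c"],
                parent_index=np.array([-1, 2, 1]),
                offset=np.ones((3, 3)),
            )


# ---------------------------------------------------------------------------
# trajectory generation


class TestSimulateTrajectory:
    def test_determinism(self, skeleton):
        a = simulate_possible_trajectory(skeleton, "kick", 70, seed=5)
        b = simulate_possible_trajectory(skeleton, "kick", 70, seed=5)
        assert np.array_equal(a.euler, b.euler)

    def test_zero_amplitude_static(self, skeleton):
        t = simulate_possible_trajectory(skeleton, "jump", 60, seed=1, amplitude_scale=0.0)
        assert np.allclose(t.euler, t.euler[0])

    @pytest.mark.parametrize("action", ACTIONS)
    def test_flexion_nonnegative_100_seeds(self, skeleton, action):
        # brute-force scan of generated elbow/knee flexion angles
        for seed in range(100):
            t = simulate_possible_trajectory(skeleton, action, 60, seed=seed)
            for j in ("l_elbow", "r_elbow", "l_knee", "r_knee"):
                assert t.joint_euler(j)[:, 0].min() >= 0.0

    def test_static_joints_zero(self, skeleton):
        t = simulate_possible_trajectory(skeleton, "wave", 60, seed=0)
        for name in skeleton.no_rotation:
            assert np.all(t.joint_euler(name) == 0)

    def test_all_rotating_joints_rotate(self, skeleton):
        t = simulate_possible_trajectory(skeleton, "wave", 60, seed=0)
        for name in skeleton.rotating_joints:
            assert np.any(t.joint_euler(name) != 0)

    def test_unknown_action(self, skeleton):
        with pytest.raises(ValueError, match="unknown action"):
            simulate_possible_trajectory(skeleton, "moonwalk", 60)

    @pytest.mark.parametrize("frames", [59, 91])
    def test_duration_out_of_range(self, skeleton, frames):
        with pytest.raises(ValueError, match="duration"):
            simulate_possible_trajectory(skeleton, "kick", frames)


# ---------------------------------------------------------------------------
# mirroring


class TestMakeImpossible:
    def test_zero_flexion_fixed_point(self, skeleton):
        t = simulate_possible_trajectory(skeleton, "wave", 60, seed=2)
        euler = t.euler.copy()
        for j in ("l_elbow", "r_elbow", "l_knee", "r_knee"):
            euler[:, skeleton.index(j), :] = 0.0
        t0 = JointTrajectory(skeleton, euler)
        out = make_impossible(t0)
        assert np.allclose(out.euler, t0.euler, atol=1e-9)

    def test_involution_on_mirrored_joints(self, skeleton):
        t = simulate_possible_trajectory(skeleton, "kick", 75, seed=3)
        twice = make_impossible(
            JointTrajectory(skeleton, make_impossible(t).euler, label="possible")
        )
        for j in ("l_elbow", "r_elbow", "l_knee", "r_knee"):
            assert np.allclose(twice.joint_euler(j), t.joint_euler(j), atol=1e-8)

    def test_flexion_negated_every_frame(self, skeleton):
        t = simulate_possible_trajectory(skeleton, "jump", 80, seed=4)
        out = make_impossible(t)
        for j in ("l_elbow", "r_elbow", "l_knee", "r_knee"):
            assert np.allclose(out.joint_euler(j)[:, 0], -t.joint_euler(j)[:, 0])
        assert out.label == "impossible"

    @pytest.mark.parametrize("seed", range(5))
    def test_end_effector_orientation_preserved(self, skeleton, seed):
        # forward-kinematics oracle: compare hand/foot world rotations
        t = simulate_possible_trajectory(skeleton, ACTIONS[seed % 4], 60, seed=seed)
        out = make_impossible(t)
        wo = world_orientations(skeleton, t)
        wi = world_orientations(skeleton, out)
        for eff in END_EFFECTORS:
            j = skeleton.index(eff)
            dev = (wo[j].inv() * wi[j]).magnitude()
            assert dev.max() < 1e-6

    def test_requires_possible_label(self, skeleton):
        t = simulate_possible_trajectory(skeleton, "kick", 60, seed=0)
        imp = make_impossible(t)
        with pytest.raises(ValueError, match="possible"):
            make_impossible(imp)

    def test_missing_joints(self, skeleton):
        t = simulate_possible_trajectory(skeleton, "kick", 60, seed=0)
        with pytest.raises(ValueError, match="lacks"):
            make_impossible(t, mirror_joints=("l_elbow", "no_such_joint"))


# ---------------------------------------------------------------------------
# forward kinematics


def _fk_oracle(skeleton, traj):
    """Independent FK using explicit homogeneous matrix chains."""

    def rx(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    def ry(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    def rz(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

    mats = {"x": rx, "y": ry, "z": rz}
    order = skeleton.rotation_order.lower()
    col = {"x": 0, "y": 1, "z": 2}

    F = traj.n_frames
    pos = np.zeros((F, skeleton.n_joints, 3))
    for f in range(F):
        world_R = [None] * skeleton.n_joints
        for j in range(skeleton.n_joints):
            ang = np.deg2rad(traj.euler[f, j])
            # intrinsic composition: multiply in order on the right
            L = np.eye(3)
            for ax in order:
                L = L @ mats[ax](ang[col[ax]])
            p = int(skeleton.parent_index[j])
            if p == -1:
                world_R[j] = L
            else:
                world_R[j] = world_R[p] @ L
                pos[f, j] = pos[f, p] + world_R[p] @ skeleton.offset[j]
    return pos


class TestForwardKinematics:
    def test_identity_pose_cumulative_offsets(self, skeleton):
        t = JointTrajectory(skeleton, np.zeros((3, skeleton.n_joints, 3)))
        kp = forward_kinematics(skeleton, t)
        expected = np.zeros((skeleton.n_joints, 3))
        for j in range(1, skeleton.n_joints):
            expected[j] = expected[skeleton.parent_index[j]] + skeleton.offset[j]
        assert np.allclose(kp[0], expected)
        assert np.allclose(kp[1], kp[0])

    def test_single_chain_90deg(self):
        sk = Skeleton(
            joint_names=["root", "child"],
            parent_index=np.array([-1, 0]),
            offset=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        )
        euler = np.zeros((1, 2, 3))
        euler[0, 0, 2] = 90.0  # rotate root about z
        kp = forward_kinematics(sk, JointTrajectory(sk, euler))
        assert np.allclose(kp[0, 1], [0.0, 1.0, 0.0], atol=1e-12)

    def test_matches_matrix_chain_oracle(self, skeleton):
        t = simulate_possible_trajectory(skeleton, "jump", 60, seed=7)
        short = JointTrajectory(skeleton, t.euler[:4])
        kp = forward_kinematics(skeleton, short)
        assert np.allclose(kp, _fk_oracle(skeleton, short), atol=1e-9)

    def test_root_position(self, skeleton):
        t = JointTrajectory(skeleton, np.zeros((2, skeleton.n_joints, 3)))
        kp = forward_kinematics(skeleton, t, root_position=(1.0, 2.0, 3.0))
        assert np.allclose(kp[:, 0, :], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# rendering


class TestRender:
    def test_static_pose_identical_frames(self, skeleton):
        t = simulate_possible_trajectory(skeleton, "kick", 60, seed=1, amplitude_scale=0.0)
        kp = forward_kinematics(skeleton, t)[:5]
        fr = render_stick_video(kp, 64, 32, skeleton=skeleton)
        assert fr.shape == (5, 64, 32)
        assert np.allclose(fr, fr[0])
        assert fr.min() >= 0 and fr.max() <= 1

    def test_translation_shifts_figure(self, skeleton):
        t = simulate_possible_trajectory(skeleton, "kick", 60, seed=1, amplitude_scale=0.0)
        kp = forward_kinematics(skeleton, t)[:1]
        ppm = 20.0
        a = render_stick_video(kp, 128, 96, skeleton=skeleton,
                               pixels_per_meter=ppm, center=(0, -0.5, 0))
        b = render_stick_video(kp + np.array([0.5, 0, 0]), 128, 96, skeleton=skeleton,
                               pixels_per_meter=ppm, center=(0, -0.5, 0))
        shift = int(round(0.5 * ppm))
        assert np.allclose(b[0][:, shift:], a[0][:, :-shift])

    def test_moving_clip_has_higher_pixel_variance(self, skeleton):
        moving = simulate_possible_trajectory(skeleton, "wave", 60, seed=2)
        static = simulate_possible_trajectory(skeleton, "wave", 60, seed=2, amplitude_scale=0.0)
        fm = render_stick_video(forward_kinematics(skeleton, moving), 64, 32, skeleton=skeleton)
        fs = render_stick_video(forward_kinematics(skeleton, static), 64, 32, skeleton=skeleton)
        assert fm.var(axis=0).sum() > fs.var(axis=0).sum()

    def test_degenerate_size(self, skeleton):
        kp = np.zeros((1, skeleton.n_joints, 3))
        with pytest.raises(ValueError, match="image size"):
            render_stick_video(kp, 1, 64, skeleton=skeleton)

    def test_nonfinite_rejected(self, skeleton):
        kp = np.full((1, skeleton.n_joints, 3), np.nan)
        with pytest.raises(ValueError, match="finite"):
            render_stick_video(kp, 32, 32, skeleton=skeleton)


# ---------------------------------------------------------------------------
# event schedule


@pytest.fixture(scope="module")
def events():
    return make_event_schedule(seed=11)


class TestSchedule:
    def test_63_nonblank_trials_per_run(self, events):
        for r, grp in events.groupby("run"):
            assert (grp["condition"] != "blank").sum() == 63

    def test_six_presentations_per_stimulus(self, events):
        stim = events[events["condition"] == "stimulus"]
        counts = stim["stimulus_id"].value_counts()
        assert len(counts) == 120
        assert (counts == 6).all()

    def test_twelve_runs_and_composition(self, events):
        assert sorted(events["run"].unique()) == list(range(12))
        for r, grp in events.groupby("run"):
            stim = grp[grp["condition"] == "stimulus"]
            assert stim["stimulus_id"].nunique() == 20
            pos = stim["stimulus_id"].str.startswith("pos")
            assert pos.sum() == 30 and (~pos).sum() == 30  # 10+10 stimuli x 3 reps
            assert (grp["condition"] == "target").sum() == 3
            assert (grp["condition"] == "blank").sum() == 3

    def test_reps1_no_targets_blanks(self):
        ev = make_event_schedule(
            pool=default_stimulus_pool(10), n_runs=1, n_sessions=1,
            stimuli_per_run=20, reps=1, n_targets=0, n_blanks=0, seed=0,
        )
        assert len(ev) == 20

    def test_isi_in_2_3_4_trs(self, events):
        tr = 2.3
        for _, grp in events.groupby("run"):
            on = grp["onset_s"].to_numpy()
            dur = grp["duration_s"].to_numpy()
            isi = (on[1:] - on[:-1] - dur[:-1]) / tr
            assert np.allclose(isi, np.round(isi))
            assert set(np.round(isi).astype(int)) <= {2, 3, 4}

    def test_onsets_strictly_increasing(self, events):
        for _, grp in events.groupby("run"):
            assert np.all(np.diff(grp["onset_s"].to_numpy()) > 0)

    def test_sessions_identical(self, events):
        for r in range(6):
            a = events[events["run"] == r].reset_index(drop=True)
            b = events[events["run"] == r + 6].reset_index(drop=True)
            assert (a["stimulus_id"] == b["stimulus_id"]).all()

    def test_bad_pool_size(self):
        with pytest.raises(ValueError, match="partition"):
            make_event_schedule(pool=default_stimulus_pool(7))


# ---------------------------------------------------------------------------
# BOLD simulation


class TestSimulateBold:
    def test_noiseless_identity(self, rng):
        X = rng.standard_normal((50, 4))
        W = rng.standard_normal((4, 3))
        gt = GroundTruth(band_weights={"a": W}, noise_sd=np.zeros(3), seed=0)
        runs = simulate_bold({"a": [X]}, gt)
        assert np.allclose(runs[0].Y, X @ W)

    def test_zero_weights_pure_noise_sd(self, rng):
        X = rng.standard_normal((10_000, 2))
        gt = GroundTruth(
            band_weights={"a": np.zeros((2, 4))}, noise_sd=np.full(4, 1.7), seed=3
        )
        Y = simulate_bold({"a": [X]}, gt)[0].Y
        assert np.allclose(Y.std(axis=0), 1.7, rtol=0.05)

    def test_requested_variance_fractions(self, rng):
        designs = {b: [rng.standard_normal((10_000, 3))] for b in "abcd"}
        fr = {"a": 0.5, "b": 0.3, "c": 0.2, "d": 0.0}
        gt = make_ground_truth(designs, fr, n_voxels=5, noise_sd=0.0, seed=1)
        parts = {b: designs[b][0] @ gt.band_weights[b] for b in designs}
        tot = sum(p.var(axis=0) for p in parts.values())
        for b in "abc":
            share = parts[b].var(axis=0) / tot
            assert np.allclose(share, fr[b], atol=0.02)
        assert np.all(parts["d"] == 0)

    def test_determinism(self, rng):
        X = rng.standard_normal((30, 2))
        gt = GroundTruth(band_weights={"a": np.ones((2, 2))}, noise_sd=np.ones(2), seed=9)
        a = simulate_bold({"a": [X]}, gt)[0].Y
        b = simulate_bold({"a": [X]}, gt)[0].Y
        assert np.array_equal(a, b)

    def test_dimension_mismatch(self, rng):
        gt = GroundTruth(band_weights={"a": np.ones((3, 2))}, noise_sd=np.ones(2), seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            simulate_bold({"a": [rng.standard_normal((10, 2))]}, gt)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            GroundTruth(band_weights={}, noise_sd=np.ones(1), seed=0,
                        band_fractions={"a": 0.8, "b": 0.4})
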