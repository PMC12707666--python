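"""Joint-angle trajectory generation, the mirroring operation and forward
kinematics.

Trajectories are smooth by construction: every Euler channel is a constant
offset plus at most three low-frequency sinusoids.  Elbow and knee flexion
channels are kept non-negative so generated movements are biomechanically
possible; the :func:`make_impossible` operation then negates exactly those
flexion rotations frame by frame and re-solves the wrist/ankle rotations so
the hand/foot world orientation is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .skeleton import END_EFFECTORS, Skeleton

__all__ = [
    "JointTrajectory",
    "ACTIONS",
    "simulate_possible_trajectory",
    "make_impossible",
    "forward_kinematics",
    "world_orientations",
]

ACTIONS = ("kick", "jump", "point", "wave")

MIN_FRAMES, MAX_FRAMES = 60, 90

#: joints whose x (flexion) channel is constrained to be >= 0
FLEXION_JOINTS = ("l_elbow", "r_elbow", "l_knee", "r_knee")

_AXIS_COL = {"x": 0, "y": 1, "z": 2}


@dataclass
class JointTrajectory:
    """Per-frame Euler rotations for every joint of a skeleton.

    ``euler`` has shape ``(frames, joints, 3)`` in degrees with the last axis
    fixed to ``(x, y, z)`` components; the composition order lives on the
    skeleton.  ``label`` tracks biomechanical plausibility.
    """

    skeleton: Skeleton
    euler: np.ndarray
    fps: float = 30.0
    label: str = "possible"

    def __post_init__(self) -> None:
        self.euler = np.asarray(self.euler, dtype=float)
        F, J, C = self.euler.shape
        if J != self.skeleton.n_joints or C != 3:
            raise ValueError("euler must have shape (frames, n_joints, 3)")
        if not np.all(np.isfinite(self.euler)):
            raise ValueError("non-finite Euler angles")

    @property
    def n_frames(self) -> int:
        return self.euler.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def joint_euler(self, name: str) -> np.ndarray:
        return self.euler[:, self.skeleton.index(name), :]


def _euler_to_rotations(skeleton: Skeleton, euler_xyz_deg: np.ndarray) -> Rotation:
    """Convert (..., 3) x/y/z Euler degrees to scipy rotations using the
    skeleton's composition order."""
    order = skeleton.rotation_order
    cols = [_AXIS_COL[ax] for ax in order.lower()]
    angles = np.asarray(euler_xyz_deg)[..., cols]
    return Rotation.from_euler(order, angles.reshape(-1, 3), degrees=True)

def _rotations_to_euler(skeleton: Skeleton, rot: Rotation) -> np.ndarray:
    order = skeleton.rotation_order
    ang = rot.as_euler(order, degrees=True)
    out = np.empty_like(ang)
    for k, ax in enumerate(order.lower()):
        out[..., _AXIS_COL[ax]] = ang[..., k]
    return out


# per-action drivers: joint -> (channel, offset_deg, amplitude_deg, cycles)
_ACTION_DRIVERS: dict[str, list[tuple[str, str, float, float, float]]] = {
    "kick": [
        ("r_hip", "x", 10.0, 35.0, 1.0),
        ("r_knee", "x", 45.0, 40.0, 1.0),
        ("r_ankle", "x", 0.0, 15.0, 1.0),
        ("l_hip", "x", 5.0, 8.0, 1.0),
    ],
    "jump": [
        ("l_knee", "x", 40.0, 35.0, 1.0),
        ("r_knee", "x", 40.0, 35.0, 1.0),
        ("l_hip", "x", -10.0, 25.0, 1.0),
        ("r_hip", "x", -10.0, 25.0, 1.0),
        ("l_shoulder", "z", 20.0, 40.0, 1.0),
        ("r_shoulder", "z", -20.0, 40.0, 1.0),
    ],
    "point": [
        ("r_shoulder", "z", -60.0, 25.0, 0.5),
        ("r_elbow", "x", 35.0, 30.0, 0.5),
        ("r_wrist", "y", 0.0, 10.0, 1.0),
    ],
    "wave": [
        ("r_shoulder", "z", -70.0, 10.0, 1.0),
        ("r_elbow", "x", 55.0, 30.0, 2.0),
        ("r_wrist", "z", 0.0, 20.0, 2.0),
    ],
}


def simulate_possible_trajectory(
    skeleton: Skeleton,
    action: str,
    duration_frames: int = 75,
    seed: int | np.random.Generator = 0,
    amplitude_scale: float = 1.0,
    fps: float = 30.0,
) -> JointTrajectory:
    """Generate a smooth, biomechanically possible action trajectory.

    Every rotating joint receives a small sinusoidal wiggle (so all 56
    rotating joints carry rotation data); action-specific driver joints
    receive larger excursions.  Elbow/knee flexion stays >= 0 because the
    constant offset of those channels always dominates the summed sinusoid
    amplitudes.  Deterministic given ``seed``.
    """
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}; expected one of {ACTIONS}")
    if not (MIN_FRAMES <= duration_frames <= MAX_FRAMES):
        raise ValueError(
            f"duration_frames must be in [{MIN_FRAMES}, {MAX_FRAMES}], got {duration_frames}"
        )
    rng = np.random.default_rng(seed)
    F = duration_frames
    t = np.arange(F) / F  # one clip = one unit of phase
    euler = np.zeros((F, skeleton.n_joints, 3))

    rotating = set(skeleton.rotating_joints)
    driven = {(j, c) for j, c, *_ in _ACTION_DRIVERS[action]}

    def _curve(offset: float, amps: np.ndarray, cycles: np.ndarray, phases: np.ndarray) -> np.ndarray:
        s = np.zeros(F)
        for a, f, p in zip(amps, cycles, phases):
            s += a * np.sin(2 * np.pi * f * t + p)
        return offset + amplitude_scale * s

    for name in skeleton.joint_names:
        j = skeleton.index(name)
        if name not in rotating:
            continue
        for ch, col in _AXIS_COL.items():
            n_sin = int(rng.integers(1, 4))
            amps = rng.uniform(0.5, 4.0, n_sin)
            cycles = rng.choice([0.5, 1.0, 1.5, 2.0, 3.0], n_sin)
            phases = rng.uniform(0, 2 * np.pi, n_sin)
            if name in FLEXION_JOINTS and ch == "x":
                # flexion >= 0: offset dominates total amplitude
                offset = float(np.sum(amps)) * max(amplitude_scale, 1.0) + rng.uniform(1.0, 5.0)
            else:
                offset = rng.uniform(-3.0, 3.0)
            if (name, ch) in driven:
                continue  # driver channels are set below
            euler[:, j, col] = _curve(offset, amps, cycles, phases)

    for name, ch, offset, amp, cyc in _ACTION_DRIVERS[action]:
        col = _AXIS_COL[ch]
        j = skeleton.index(name)
        phase = rng.uniform(0, 2 * np.pi)
        if name in FLEXION_JOINTS and ch == "x":
            # guarantee flexion >= 0 regardless of phase
            curve = offset + amplitude_scale * amp * (0.5 + 0.5 * np.sin(2 * np.pi * cyc * t + phase))
        else:
            curve = offset + amplitude_scale * amp * np.sin(2 * np.pi * cyc * t + phase)
        euler[:, j, col] = curve

    return JointTrajectory(skeleton=skeleton, euler=euler, fps=fps, label="possible")


def make_impossible(traj: JointTrajectory, mirror_joints: tuple[str, ...] = FLEXION_JOINTS) -> JointTrajectory:
    """Mirror elbow/knee rotations about the flexion axis at every frame.

    The local rotation of each wrist/ankle is then re-solved so that the
    hand/foot world orientation matches the original trajectory exactly (the
    shoulder/hip chain above the mirrored joint is untouched, so only the
    joint directly below the end effector needs adjustment).
    """
    if traj.label != "possible":
        raise ValueError("make_impossible expects a trajectory labeled 'possible'")
    skel = traj.skeleton
    for name in mirror_joints:
        if name not in skel._index:
            raise ValueError(f"skeleton lacks mirrored joint {name!r}")
    col = _AXIS_COL[skel.flexion_axis]

    orig_world = world_orientations(skel, traj)
    euler = traj.euler.copy()
    for name in mirror_joints:
        euler[:, skel.index(name), col] *= -1.0

    mirrored = JointTrajectory(skeleton=skel, euler=euler, fps=traj.fps, label="possible")
    new_world = world_orientations(skel, mirrored)

    for effector, solve_joint in END_EFFECTORS.items():
        if effector not in skel._index or solve_joint not in skel._index:
            continue
        j = skel.index(solve_joint)
        p = int(skel.parent_index[j])
        # want: A' L' = A L  =>  L' = A'^T A L
        A_old = orig_world[p]
        A_new = new_world[p]
        L_old = _euler_to_rotations(skel, traj.euler[:, j, :])
        L_new = A_new.inv() * A_old * L_old
        euler[:, j, :] = _rotations_to_euler(skel, L_new)

    return JointTrajectory(skeleton=skel, euler=euler, fps=traj.fps, label="impossible")


def world_orientations(skeleton: Skeleton, traj: JointTrajectory) -> list[Rotation]:
    """Per-joint world rotations, each a batch over frames."""
    world: list[Rotation] = []
    for j, name in enumerate(skeleton.joint_names):
        local = _euler_to_rotations(skeleton, traj.euler[:, j, :])
        p = int(skeleton.parent_index[j])
        world.append(local if p == -1 else world[p] * local)
    return world


def forward_kinematics(
    skeleton: Skeleton,
    traj: JointTrajectory,
    root_position: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """World keypoint positions, shape ``(frames, joints, 3)`` in meters.

    Child position = parent position + parent world rotation applied to the
    child's bone offset; the root sits at ``root_position`` in every frame.
    """
    F = traj.n_frames
    world_rot = world_orientations(skeleton, traj)
    pos = np.zeros((F, skeleton.n_joints, 3))
    pos[:, 0, :] = np.asarray(root_position, dtype=float)
    for j in range(1, skeleton.n_joints):
        p = int(skeleton.parent_index[j])
        pos[:, j, :] = pos[:, p, :] + world_rot[p].apply(skeleton.offset[j])
    return pos
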