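"""Biomechanical similarity-distance features.

Each joint's per-frame rotation is converted from Euler angles to an
axis-angle 3-vector; a manifold of normal (possible) movements pools those
vectors over frames and exemplars per joint.  The distance of a test clip to
the manifold is a Gaussian-kernel similarity: for joint ``j`` at frame ``t``,

    s_jt = (1/N) * sum_i exp(-||x_jt - m_ji||^2 / (2 sigma_j^2))

and the per-joint distance is the frame average of ``1 - s_jt`` (in [0, 1]).
Mirrored (impossible) movements lie off the manifold and score higher
distances than held-out possible movements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from ..synthetic.trajectory import JointTrajectory, _euler_to_rotations

__all__ = [
    "ManifoldModel",
    "SimDistFeatures",
    "euler_to_axis_angle",
    "select_rotating_joints",
    "build_manifold",
    "similarity_distance",
    "filter_finite_and_concat",
    "simdist_features",
]

_AXIS_COL = {"x": 0, "y": 1, "z": 2}


@dataclass
class ManifoldModel:
    """Per-joint axis-angle sample sets from possible movements."""

    samples: dict[str, np.ndarray]  # joint -> (n_samples, 3) radians*axis
    sigma: dict[str, float]  # joint -> kernel bandwidth, radians
    retained_joints: list[str]
    aggregate: str = "mean"  # kernel aggregation: mean | max | neglog

    def __post_init__(self) -> None:
        for j in self.retained_joints:
            if j not in self.samples or len(self.samples[j]) == 0:
                raise ValueError(f"empty manifold sample set for joint {j!r}")
            if self.sigma[j] <= 0:
                raise ValueError(f"non-positive bandwidth for joint {j!r}")


@dataclass
class SimDistFeatures:
    """Stimuli-by-joints distance matrix after finiteness filtering."""

    X: np.ndarray
    retained_joints: list[str]
    stimulus_ids: list[str]
    dropped_joints: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite distances after filtering")
        if np.any(self.X < 0):
            raise ValueError("negative distances")


def euler_to_axis_angle(euler_deg: np.ndarray, order: str = "ZXY") -> np.ndarray:
    """Convert x/y/z Euler degrees (..., 3) to axis-angle vectors (radians*axis).

    The returned vector is the unit rotation axis scaled by the rotation
    angle in [0, pi]; the zero rotation maps to the zero vector.
    """
    if not set(order.lower()) == {"x", "y", "z"}:
        raise ValueError(f"invalid rotation order {order!r}")
    e = np.asarray(euler_deg, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite Euler angles")
    cols = [_AXIS_COL[ax] for ax in order.lower()]
    shape = e.shape
    rot = Rotation.from_euler(order, e[..., cols].reshape(-1, 3), degrees=True)
    return rot.as_rotvec().reshape(shape)


def select_rotating_joints(trajectories: dict[str, JointTrajectory]) -> list[str]:
    """Joints whose rotation is not identically zero across all stimuli."""
    if not trajectories:
        return []
    skel = next(iter(trajectories.values())).skeleton
    any_rot = np.zeros(skel.n_joints, dtype=bool)
    for traj in trajectories.values():
        any_rot |= np.any(traj.euler != 0, axis=(0, 2))
    return [skel.joint_names[j] for j in range(skel.n_joints) if any_rot[j]]


def _axis_angle_per_joint(traj: JointTrajectory, joints: list[str]) -> dict[str, np.ndarray]:
    skel = traj.skeleton
    out = {}
    for name in joints:
        out[name] = euler_to_axis_angle(
            traj.euler[:, skel.index(name), :], skel.rotation_order
        )
    return out


def build_manifold(
    possible_trajectories: dict[str, JointTrajectory] | list[JointTrajectory],
    joints: list[str] | None = None,
    bandwidth_rule: str = "median",
    sigma_floor: float = 1e-3,
    sigma_fixed: float | None = None,
    frame_step: int = 1,
    aggregate: str = "mean",
) -> ManifoldModel:
    """Pool per-joint axis-angle samples over frames and exemplars.

    Bandwidths default to the median of all pairwise sample distances per
    joint (with a configurable floor for degenerate spreads); pass
    ``sigma_fixed`` to override.
    """
    if isinstance(possible_trajectories, dict):
        trajs = list(possible_trajectories.values())
    else:
        trajs = list(possible_trajectories)
    if len(trajs) < 2:
        raise ValueError("need at least two possible movements")
    if joints is None:
        joints = select_rotating_joints({str(i): t for i, t in enumerate(trajs)})

    samples: dict[str, np.ndarray] = {}
    sigma: dict[str, float] = {}
    for name in joints:
        pts = np.vstack([
            _axis_angle_per_joint(t, [name])[name][::frame_step] for t in trajs
        ])
        samples[name] = pts
        if sigma_fixed is not None:
            sigma[name] = float(sigma_fixed)
        elif bandwidth_rule == "median":
            d = pdist(pts) if len(pts) > 1 else np.zeros(1)
            sigma[name] = max(float(np.median(d)), sigma_floor)
        else:
            raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    return ManifoldModel(samples=samples, sigma=sigma, retained_joints=list(joints),
                         aggregate=aggregate)


def similarity_distance(
    test_trajectory: JointTrajectory, manifold: ManifoldModel
) -> dict[str, float]:
    """Per-joint kernel distance of one clip to the manifold (each in [0, 1],
    or unbounded for the ``neglog`` aggregation)."""
    aa = _axis_angle_per_joint(test_trajectory, manifold.retained_joints)
    out: dict[str, float] = {}
    for name in manifold.retained_joints:
        m = manifold.samples[name]
        sig = manifold.sigma[name]
        d2 = cdist(aa[name], m, "sqeuclidean")  # (frames, n_samples)
        k = np.exp(-d2 / (2.0 * sig**2))
        if manifold.aggregate == "mean":
            s = k.mean(axis=1)
            dist = float(np.mean(1.0 - s))
        elif manifold.aggregate == "max":
            s = k.max(axis=1)
            dist = float(np.mean(1.0 - s))
        elif manifold.aggregate == "neglog":
            s = k.mean(axis=1)
            with np.errstate(divide="ignore"):
                dist = float(np.mean(-np.log(s)))
        else:
            raise ValueError(f"unknown aggregation {manifold.aggregate!r}")
        out[name] = dist
    return out


def filter_finite_and_concat(
    per_stimulus: dict[str, dict[str, float]], joints: list[str] | None = None
) -> SimDistFeatures:
    """Drop joints with any non-finite distance; concatenate the rest."""
    ids = list(per_stimulus)
    if not ids:
        raise ValueError("no stimuli")
    if joints is None:
        joints = list(per_stimulus[ids[0]])
    M = np.array([[per_stimulus[sid][j] for j in joints] for sid in ids], dtype=float)
    finite = np.all(np.isfinite(M), axis=0)
    if not finite.any():
        raise ValueError("all joints dropped by the finiteness filter")
    retained = [j for j, f in zip(joints, finite) if f]
    dropped = [j for j, f in zip(joints, finite) if not f]
    return SimDistFeatures(
        X=M[:, finite], retained_joints=retained, stimulus_ids=ids, dropped_joints=dropped
    )


def simdist_features(
    trajectories: dict[str, JointTrajectory],
    labels: dict[str, str],
    manifold: ManifoldModel | None = None,
    **manifold_kwargs,
) -> SimDistFeatures:
    """End-to-end SimDist features for a stimulus set.

    The manifold is built from the possible movements only (all of them by
    default) and every stimulus — possible and impossible — is scored
    against it.
    """
    if manifold is None:
        poss = {sid: t for sid, t in trajectories.items() if labels[sid] == "possible"}
        manifold = build_manifold(poss, **manifold_kwargs)
    per_stim = {sid: similarity_distance(t, manifold) for sid, t in trajectories.items()}
    return filter_finite_and_concat(per_stim, joints=manifold.retained_joints)
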