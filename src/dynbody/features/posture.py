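"""Posture feature spaces: 3D keypoint coordinates and the categorical
possible/impossible indicators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..synthetic.skeleton import Skeleton
from ..synthetic.trajectory import JointTrajectory, forward_kinematics

__all__ = ["FeatureSpace", "extract_kp3d", "categorical_features"]

BAND_NAMES = ("kp3d", "simdist", "categorical", "moten")


@dataclass
class FeatureSpace:
    """A named stimuli-by-features matrix with aligned row labels."""

    name: str
    X: np.ndarray
    feature_names: list[str]
    stimulus_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (stimuli x features)")
        if self.X.shape != (len(self.stimulus_ids), len(self.feature_names)):
            raise ValueError("X shape does not match labels")
        if self.X.shape[1] == 0:
            raise ValueError("feature space has no features")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def row(self, stimulus_id: str) -> np.ndarray:
        return self.X[self.stimulus_ids.index(stimulus_id)]


def extract_kp3d(
    trajectories: dict[str, JointTrajectory],
    variance_threshold: float = 1e-8,
    skeleton: Skeleton | None = None,
    summary: str = "mean",
    n_subsampled_frames: int = 5,
) -> FeatureSpace:
    """3D keypoint features: root-centered joint positions summarized per clip.

    Coordinates are averaged over frames (``summary="mean"``) or a fixed
    number of evenly spaced frames is concatenated (``summary="frames"``).
    Keypoints whose total positional variance across the stimulus set falls
    below ``variance_threshold`` (in m^2) are dropped; the retained list is
    recorded in ``meta["retained_keypoints"]``.
    """
    if not trajectories:
        raise ValueError("empty stimulus set")
    ids = list(trajectories)
    skel = skeleton if skeleton is not None else trajectories[ids[0]].skeleton
    J = skel.n_joints

    per_stim = []
    for sid in ids:
        traj = trajectories[sid]
        kp = forward_kinematics(skel, traj)
        kp = kp - kp[:, [0], :]  # root-center: global translation never dominates
        if summary == "mean":
            per_stim.append(kp.mean(axis=0)[None])  # (1, J, 3)
        elif summary == "frames":
            sel = np.linspace(0, kp.shape[0] - 1, n_subsampled_frames).round().astype(int)
            per_stim.append(kp[sel])  # (n_sub, J, 3)
        else:
            raise ValueError(f"unknown summary {summary!r}")
    stack = np.stack(per_stim)  # (S, n_sum, J, 3)

    # variance across the stimulus set, totalled over coordinates & summaries
    var = stack.var(axis=0).sum(axis=(0, 2))  # (J,)
    keep = var > variance_threshold
    if not keep.any():
        raise ValueError("all keypoints dropped by the variance threshold")
    retained = [skel.joint_names[j] for j in range(J) if keep[j]]

    X = stack[:, :, keep, :].reshape(len(ids), -1)
    n_sum = stack.shape[1]
    names = [
        f"{joint}_{ax}" + (f"_f{s}" if n_sum > 1 else "")
        for s in range(n_sum)
        for joint in retained
        for ax in "xyz"
    ]
    return FeatureSpace(
        name="kp3d", X=X, feature_names=names, stimulus_ids=ids,
        meta={"retained_keypoints": retained, "variance_threshold": variance_threshold},
    )


def categorical_features(labels: dict[str, str] | list[tuple[str, str]]) -> FeatureSpace:
    """Two indicator features marking each stimulus possible or impossible."""
    items = list(labels.items()) if isinstance(labels, dict) else list(labels)
    if not items:
        raise ValueError("empty stimulus set")
    X = np.zeros((len(items), 2))
    ids = []
    for i, (sid, lab) in enumerate(items):
        if lab == "possible":
            X[i, 0] = 1.0
        elif lab == "impossible":
            X[i, 1] = 1.0
        else:
            raise ValueError(f"unknown plausibility label {lab!r}")
        ids.append(sid)
    return FeatureSpace(
        name="categorical", X=X, feature_names=["possible", "impossible"], stimulus_ids=ids
    )
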