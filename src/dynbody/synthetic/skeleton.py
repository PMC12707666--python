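"""Hierarchical skeleton model used by the synthetic motion generator.

The default skeleton mimics a full-body motion-capture marker set: 71 named
joints arranged in a tree rooted at the pelvis.  A fixed subset of 15 joints
(the axial chain and facial keypoints) carries no rotation data; the other 56
joints rotate, matching the keypoint counts the downstream feature spaces
expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Skeleton", "default_skeleton", "STATIC_JOINTS", "END_EFFECTORS"]

#: Joints that never carry rotation data: the axial/facial chain plus the
#: heel and toe-tip markers.
STATIC_JOINTS = (
    "pelvis", "spine1", "spine2", "chest", "neck", "head",
    "nose", "l_eye", "r_eye", "l_ear", "r_ear",
    "l_heel", "r_heel", "l_toe_end", "r_toe_end",
)

#: End effectors whose world orientation the mirroring operation preserves,
#: mapped to the joint whose local rotation is re-solved to achieve it.
END_EFFECTORS = {
    "l_hand": "l_wrist",
    "r_hand": "r_wrist",
    "l_foot": "l_ankle",
    "r_foot": "r_ankle",
}

_FINGERS = ("thumb", "index", "middle", "ring", "pinky")


@dataclass
class Skeleton:
    """A joint tree with fixed bone offsets and a global Euler convention.

    Parameters
    ----------
    joint_names
        Joint labels; ``parent_index[i]`` indexes the parent of joint ``i``
        (``-1`` for the root).  Parents always precede children.
    offset
        Per-joint bone offset from the parent, in meters, shape ``(J, 3)``.
    rotation_order
        Euler composition order (intrinsic); angles are stored with the last
        axis ordered ``(x, y, z)`` regardless of composition order.
    no_rotation
        Labels of joints flagged as carrying no rotation data.
    """

    joint_names: list[str]
    parent_index: np.ndarray
    offset: np.ndarray
    rotation_order: str = "ZXY"
    no_rotation: tuple[str, ...] = ()
    flexion_axis: str = "x"
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.parent_index = np.asarray(self.parent_index, dtype=int)
        self.offset = np.asarray(self.offset, dtype=float)
        if self.offset.shape != (self.n_joints, 3):
            raise ValueError("offset must have shape (n_joints, 3)")
        if self.parent_index[0] != -1:
            raise ValueError("first joint must be the root (parent -1)")
        if np.any(self.parent_index[1:] >= np.arange(1, self.n_joints)):
            raise ValueError("parents must precede children (cyclic graph?)")
        self._index = {n: i for i, n in enumerate(self.joint_names)}
        if len(self._index) != self.n_joints:
            raise ValueError("duplicate joint names")

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def rotating_joints(self) -> list[str]:
        return [n for n in self.joint_names if n not in self.no_rotation]

    def children(self, name: str) -> list[str]:
        j = self.index(name)
        return [self.joint_names[i] for i in np.flatnonzero(self.parent_index == j)]

    def chain_to_root(self, name: str) -> list[str]:
        """Joint names from ``name`` up to (and including) the root."""
        chain = [name]
        j = self.index(name)
        while self.parent_index[j] != -1:
            j = int(self.parent_index[j])
            chain.append(self.joint_names[j])
        return chain

    def bones(self) -> list[tuple[int, int]]:
        """(parent, child) index pairs for all non-root joints."""
        return [(int(self.parent_index[j]), j) for j in range(1, self.n_joints)]


def _arm(side: str, sign: float) -> list[tuple[str, str, tuple[float, float, float]]]:
    s = side
    out = [
        (f"{s}_shoulder", "chest", (sign * 0.18, 0.08, 0.0)),
        (f"{s}_uparm", f"{s}_shoulder", (sign * 0.14, 0.0, 0.0)),
        (f"{s}_elbow", f"{s}_uparm", (sign * 0.14, 0.0, 0.0)),
        (f"{s}_forearm", f"{s}_elbow", (sign * 0.13, 0.0, 0.0)),
        (f"{s}_wrist", f"{s}_forearm", (sign * 0.13, 0.0, 0.0)),
        (f"{s}_hand", f"{s}_wrist", (sign * 0.08, 0.0, 0.0)),
    ]
    for k, f in enumerate(_FINGERS):
        base = (sign * 0.04, 0.0, 0.02 - 0.01 * k)
        out.append((f"{s}_{f}1", f"{s}_hand", base))
        out.append((f"{s}_{f}2", f"{s}_{f}1", (sign * 0.03, 0.0, 0.0)))
        out.append((f"{s}_{f}3", f"{s}_{f}2", (sign * 0.02, 0.0, 0.0)))
    return out


def _leg(side: str, sign: float) -> list[tuple[str, str, tuple[float, float, float]]]:
    s = side
    return [
        (f"{s}_hip", "pelvis", (sign * 0.09, -0.05, 0.0)),
        (f"{s}_thigh", f"{s}_hip", (0.0, -0.21, 0.0)),
        (f"{s}_knee", f"{s}_thigh", (0.0, -0.21, 0.0)),
        (f"{s}_shin", f"{s}_knee", (0.0, -0.21, 0.0)),
        (f"{s}_ankle", f"{s}_shin", (0.0, -0.21, 0.0)),
        (f"{s}_heel", f"{s}_ankle", (0.0, -0.05, -0.04)),
        (f"{s}_foot", f"{s}_ankle", (0.0, -0.05, 0.10)),
        (f"{s}_toe", f"{s}_foot", (0.0, 0.0, 0.06)),
        (f"{s}_toe_end", f"{s}_toe", (0.0, 0.0, 0.03)),
    ]


def default_skeleton(rotation_order: str = "ZXY") -> Skeleton:
    """Build the default 71-joint skeleton (56 rotating, 15 static).

    Units are meters; the Y axis points up and X to the figure's left.
    """
    spec: list[tuple[str, str, tuple[float, float, float]]] = [
        ("pelvis", "", (0.0, 0.0, 0.0)),
        ("spine1", "pelvis", (0.0, 0.12, 0.0)),
        ("spine2", "spine1", (0.0, 0.12, 0.0)),
        ("chest", "spine2", (0.0, 0.12, 0.0)),
        ("neck", "chest", (0.0, 0.10, 0.0)),
        ("head", "neck", (0.0, 0.12, 0.0)),
        ("nose", "head", (0.0, 0.04, 0.10)),
        ("l_eye", "head", (0.03, 0.07, 0.08)),
        ("r_eye", "head", (-0.03, 0.07, 0.08)),
        ("l_ear", "head", (0.07, 0.05, 0.0)),
        ("r_ear", "head", (-0.07, 0.05, 0.0)),
    ]
    spec += _arm("l", +1.0) + _arm("r", -1.0)
    spec += _leg("l", +1.0) + _leg("r", -1.0)

    names = [n for n, _, _ in spec]
    idx = {n: i for i, n in enumerate(names)}
    parents = np.array([idx[p] if p else -1 for _, p, _ in spec], dtype=int)
    offsets = np.array([o for _, _, o in spec], dtype=float)
    skel = Skeleton(
        joint_names=names,
        parent_index=parents,
        offset=offsets,
        rotation_order=rotation_order,
        no_rotation=STATIC_JOINTS,
    )
    assert skel.n_joints == 71, skel.n_joints
    assert len(skel.rotating_joints) == 56
    return skel
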