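"""Orthographic stick-figure rendering of keypoint trajectories.

The renderer replaces avatar animation: the downstream motion-energy model
consumes only luminance frames, so anti-aliased line segments between
connected joints on a black background are sufficient.  Default geometry is
a tall 64x128 pixel frame matching the stimulus aspect ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line_aa

from .skeleton import Skeleton
from .trajectory import JointTrajectory

__all__ = ["StimulusClip", "render_stick_video"]

_VIEWS = {"frontal": (0, 1), "sagittal": (2, 1), "top": (0, 2)}


@dataclass
class StimulusClip:
    """One video stimulus: identity, trajectory and rendered frames."""

    id: str
    actor: str
    action: str
    plausibility: str  # "possible" | "impossible"
    trajectory: JointTrajectory
    frames: np.ndarray | None = None  # (T, H, W) luminance in [0, 1]

    def __post_init__(self) -> None:
        if self.plausibility not in ("possible", "impossible"):
            raise ValueError(f"bad plausibility {self.plausibility!r}")
        if self.frames is not None and self.frames.shape[0] != self.trajectory.n_frames:
            raise ValueError("frame count does not match trajectory")


def render_stick_video(
    keypoints: np.ndarray,
    image_h: int = 128,
    image_w: int = 64,
    view: str = "frontal",
    skeleton: Skeleton | None = None,
    bones: list[tuple[int, int]] | None = None,
    pixels_per_meter: float | None = None,
    center: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Render ``(T, J, 3)`` keypoints to ``(T, image_h, image_w)`` luminance.

    Orthographic projection onto the view plane; the figure is centered on
    the clip's mean keypoint unless an explicit world ``center`` is given.
    ``pixels_per_meter`` defaults to a scale that fits the whole clip with a
    10% margin.
    """
    kp = np.asarray(keypoints, dtype=float)
    if kp.ndim != 3 or kp.shape[2] != 3:
        raise ValueError("keypoints must have shape (frames, joints, 3)")
    if not np.all(np.isfinite(kp)):
        raise ValueError("non-finite keypoints")
    if image_h < 2 or image_w < 2:
        raise ValueError("degenerate image size")
    if view not in _VIEWS:
        raise ValueError(f"unknown view {view!r}")
    ax_u, ax_v = _VIEWS[view]

    if bones is None:
        if skeleton is None:
            raise ValueError("provide either a skeleton or explicit bones")
        bones = skeleton.bones()

    c = np.asarray(center, dtype=float) if center is not None else kp.reshape(-1, 3).mean(axis=0)
    rel = kp - c
    if pixels_per_meter is None:
        ext_u = max(2 * np.abs(rel[..., ax_u]).max(), 1e-6)
        ext_v = max(2 * np.abs(rel[..., ax_v]).max(), 1e-6)
        pixels_per_meter = 0.9 * min(image_w / ext_u, image_h / ext_v)

    u = image_w / 2.0 + rel[..., ax_u] * pixels_per_meter
    v = image_h / 2.0 - rel[..., ax_v] * pixels_per_meter  # image rows grow downward

    T = kp.shape[0]
    frames = np.zeros((T, image_h, image_w))
    for t in range(T):
        img = frames[t]
        for p, j in bones:
            r0, c0 = int(round(v[t, p])), int(round(u[t, p]))
            r1, c1 = int(round(v[t, j])), int(round(u[t, j]))
            r0 = min(max(r0, 0), image_h - 1)
            r1 = min(max(r1, 0), image_h - 1)
            c0 = min(max(c0, 0), image_w - 1)
            c1 = min(max(c1, 0), image_w - 1)
            rr, cc, val = line_aa(r0, c0, r1, c1)
            img[rr, cc] = np.maximum(img[rr, cc], val)
    return frames
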