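"""Synthetic data generation: skeletons, trajectories, videos, designs, BOLD."""

from __future__ import annotations

import numpy as np

from .skeleton import END_EFFECTORS, STATIC_JOINTS, Skeleton, default_skeleton
from .trajectory import (
    ACTIONS,
    JointTrajectory,
    forward_kinematics,
    make_impossible,
    simulate_possible_trajectory,
    world_orientations,
)
from .render import StimulusClip, render_stick_video
from .schedule import default_stimulus_pool, make_event_schedule, n_trs_per_run
from .bold import GroundTruth, RunTimeSeries, make_ground_truth, simulate_bold

__all__ = [
    "ACTIONS",
    "END_EFFECTORS",
    "STATIC_JOINTS",
    "Skeleton",
    "default_skeleton",
    "JointTrajectory",
    "simulate_possible_trajectory",
    "make_impossible",
    "forward_kinematics",
    "world_orientations",
    "StimulusClip",
    "render_stick_video",
    "default_stimulus_pool",
    "make_event_schedule",
    "n_trs_per_run",
    "GroundTruth",
    "RunTimeSeries",
    "make_ground_truth",
    "simulate_bold",
    "generate_stimulus_set",
]


def generate_stimulus_set(
    n_pairs: int = 60,
    n_actors: int = 17,
    seed: int = 0,
    skeleton: Skeleton | None = None,
    render: bool = False,
    image_h: int = 128,
    image_w: int = 64,
) -> list[StimulusClip]:
    """Generate possible/impossible stimulus twins across actors and actions.

    Stimulus ids follow the ``pos###``/``imp###`` convention of
    :func:`default_stimulus_pool` so clips align with generated schedules.
    """
    skel = skeleton if skeleton is not None else default_skeleton()
    rng = np.random.default_rng(seed)
    clips: list[StimulusClip] = []
    for k in range(n_pairs):
        action = ACTIONS[k % len(ACTIONS)]
        actor = f"actor{k % n_actors:02d}"
        frames = int(rng.integers(60, 91))
        traj = simulate_possible_trajectory(
            skel, action, duration_frames=frames, seed=rng.integers(0, 2**31)
        )
        twin = make_impossible(traj)
        for sid, t, pl in ((f"pos{k:03d}", traj, "possible"), (f"imp{k:03d}", twin, "impossible")):
            vid = None
            if render:
                kp = forward_kinematics(skel, t)
                vid = render_stick_video(kp, image_h=image_h, image_w=image_w, skeleton=skel)
            clips.append(
                StimulusClip(id=sid, actor=actor, action=action, plausibility=pl,
                             trajectory=t, frames=vid)
            )
    return clips
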