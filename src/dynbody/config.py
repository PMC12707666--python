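"""Pipeline configuration.

Defaults reproduce the experimental design constants (12 runs over 2
sessions, TR 2.3 s, 20 stimuli per run presented 3 times plus 3 targets and
3 blanks, 5 hemodynamic delays) while compute knobs (voxel count, search
budget, video geometry) default to desk scale.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0

    # stimulus set
    n_stimulus_pairs: int = 60  # 60 possible + 60 impossible
    n_actors: int = 17

    # experimental design
    n_runs: int = 12
    n_sessions: int = 2
    stimuli_per_run: int = 20
    reps: int = 3
    n_targets: int = 3
    n_blanks: int = 3
    tr_s: float = 2.3
    isi_trs: tuple[int, ...] = (2, 3, 4)

    # encoding model
    n_delays: int = 5
    n_outer_folds: int = 3
    n_inner_folds: int = 4
    lambda_min: float = 1e-3
    lambda_max: float = 1e5
    n_random_search: int = 20
    refine_steps: int = 10
    standardize_mode: str = "tr"

    # synthetic BOLD
    n_voxels: int = 50
    noise_sd: float = 1.0
    band_fractions: dict = field(default_factory=lambda: {
        "moten": 0.35, "simdist": 0.30, "kp3d": 0.20, "categorical": 0.15,
    })

    # motion-energy bank / rendering (desk scale)
    image_h: int = 64
    image_w: int = 32
    pixels_per_degree: float = 8.0
    fps: float = 30.0
    spatial_frequencies: tuple[float, ...] = (0.5, 1.0, 2.0)
    temporal_frequencies: tuple[float, ...] = (1.0, 4.0)
    max_positions_per_axis: int = 3

    # simdist
    simdist_frame_step: int = 3

    # group stage
    n_subjects: int = 4
    q_level: float = 0.05

    def __post_init__(self) -> None:
        if self.n_runs % self.n_sessions:
            raise ValueError("n_runs must divide into sessions")
        if self.stimuli_per_run * (self.n_runs // self.n_sessions) != 2 * self.n_stimulus_pairs:
            raise ValueError("stimulus pool does not partition into run-sets")
        if self.lambda_min <= 0 or self.lambda_max <= self.lambda_min:
            raise ValueError("invalid lambda range")
        fr = np.array(list(self.band_fractions.values()), dtype=float)
        if np.any(fr < 0) or fr.sum() > 1 + 1e-9:
            raise ValueError("band fractions must be nonnegative, sum <= 1")

    # -- seeds -------------------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        """Stage-specific seed derived from the master seed."""
        order = ["simulate", "features", "bold", "fit", "partition", "group"]
        if stage not in order:
            raise ValueError(f"unknown stage {stage!r}")
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return int(children[order.index(stage)].generate_state(1)[0])

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for k in ("isi_trs", "spatial_frequencies", "temporal_frequencies"):
            if k in kwargs and isinstance(kwargs[k], list):
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
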