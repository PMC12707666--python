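"""Synthetic BOLD generation: the generative twin of the encoding model.

Voxel time series follow the delayed linear model exactly,
``Y = sum_b X_b @ W_b + noise``, with per-band generating variance fractions
recorded so parameter-recovery tests have a ground truth to compare against.
Noise is white Gaussian by default; an AR(1) option is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroundTruth", "RunTimeSeries", "make_ground_truth", "simulate_bold"]


@dataclass
class GroundTruth:
    """Generating weights and noise level for a synthetic dataset."""

    band_weights: dict[str, np.ndarray]  # band -> (features, voxels)
    noise_sd: np.ndarray  # (voxels,)
    seed: int
    band_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.noise_sd = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if self.band_fractions:
            fr = np.array(list(self.band_fractions.values()))
            if np.any(fr < 0) or fr.sum() > 1 + 1e-9:
                raise ValueError("band fractions must be nonnegative and sum to <= 1")


@dataclass
class RunTimeSeries:
    """One run's voxel time series on the TR grid."""

    Y: np.ndarray  # (n_TR, voxels)
    run: int
    tr_s: float = 2.3

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("missing/non-finite values in time series")


def make_ground_truth(
    designs: dict[str, list[np.ndarray]],
    band_fractions: dict[str, float],
    n_voxels: int,
    noise_sd: float = 1.0,
    signal_var: float = 1.0,
    seed: int = 0,
) -> GroundTruth:
    """Draw random weights scaled so each band's signal variance share over
    the concatenated design matches ``band_fractions`` exactly per voxel.

    Bands with fraction 0 receive exactly zero weights.
    """
    rng = np.random.default_rng(seed)
    weights: dict[str, np.ndarray] = {}
    for band, runs in designs.items():
        X = np.vstack(runs)
        p = X.shape[1]
        f = band_fractions.get(band, 0.0)
        W = rng.standard_normal((p, n_voxels))
        if f <= 0:
            weights[band] = np.zeros((p, n_voxels))
            continue
        s = X @ W
        v = s.var(axis=0)
        v[v == 0] = 1.0
        weights[band] = W * np.sqrt(f * signal_var / v)
    return GroundTruth(
        band_weights=weights,
        noise_sd=np.full(n_voxels, float(noise_sd)),
        seed=int(seed) if np.isscalar(seed) else 0,
        band_fractions=dict(band_fractions),
    )


def simulate_bold(
    design_by_band: dict[str, list[np.ndarray]],
    ground_truth: GroundTruth,
    tr_s: float = 2.3,
    ar1: float = 0.0,
) -> list[RunTimeSeries]:
    """Simulate per-run voxel time series from band designs and known weights.

    ``design_by_band`` maps band name to a list of per-run (n_TR, features)
    matrices sharing the TR grid.  Deterministic given the ground truth seed.
    """
    bands = list(design_by_band)
    n_runs = {len(v) for v in design_by_band.values()}
    if len(n_runs) != 1:
        raise ValueError("bands disagree on the number of runs")
    n_runs = n_runs.pop()
    rng = np.random.default_rng(ground_truth.seed)
    out = []
    for r in range(n_runs):
        n_tr = design_by_band[bands[0]][r].shape[0]
        sig = None
        for b in bands:
            X = design_by_band[b][r]
            W = ground_truth.band_weights[b]
            if X.shape[0] != n_tr:
                raise ValueError("bands disagree on the TR grid")
            if X.shape[1] != W.shape[0]:
                raise ValueError(f"band {b!r}: design/weights dimension mismatch")
            part = X @ W
            sig = part if sig is None else sig + part
        eps = rng.standard_normal(sig.shape) * ground_truth.noise_sd
        if ar1:
            for t in range(1, eps.shape[0]):
                eps[t] += ar1 * eps[t - 1]
        out.append(RunTimeSeries(Y=sig + eps, run=r, tr_s=tr_s))
    return out
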