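"""Motion-energy features from a quadrature spatiotemporal Gabor bank.

Each channel is defined by a spatial position, orientation, spatial
frequency, temporal frequency and drift direction.  Filters come in
quadrature pairs (90 degree phase offset in both space and time); motion
energy is the sum of squares of the two phase-offset outputs, log
transformed and averaged over frames.

Spatial envelopes are Gaussian with size proportional to the spatial
wavelength, DC-corrected so uniform frames produce zero raw energy, and the
spatial grid tiling is proportional to the envelope size.  Temporal
convolution uses "same" padding with edge replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d
from skimage.color import rgb2lab

from .posture import FeatureSpace

__all__ = [
    "GaborBankConfig",
    "GaborBank",
    "to_luminance",
    "build_filter_bank",
    "motion_energy",
    "moten_features",
]

SF_RANGE = (0.5, 8.0)  # cycles/degree
TF_RANGE = (1.0, 16.0)  # Hz


@dataclass
class GaborBankConfig:
    image_h: int = 128
    image_w: int = 64
    pixels_per_degree: float = 16.0
    fps: float = 30.0
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    spatial_frequencies: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)
    temporal_frequencies: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)
    n_directions: int = 2
    envelope_wavelengths: float = 0.5  # spatial sigma in units of wavelength
    spacing_sigmas: float = 4.0  # grid spacing in units of spatial sigma
    grid_density: float = 1.0
    max_positions_per_axis: int = 6
    temporal_sigma_periods: float = 0.5  # temporal sigma in units of 1/tf
    log_epsilon_scale: float = 1e-5
    allow_out_of_range: bool = False


@dataclass
class GaborBank:
    """Precomputed spatial quadrature filters plus channel bookkeeping.

    ``channels`` holds one tuple ``(spatial_idx, y, x, orientation, sf, tf,
    direction)`` per motion-energy channel; ``spatial_even``/``spatial_odd``
    are (n_spatial, H*W) filter matrices shared across temporal channels.
    """

    config: GaborBankConfig
    channels: list[tuple]
    spatial_even: np.ndarray
    spatial_odd: np.ndarray
    temporal: dict[float, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.channels)


def to_luminance(frames: np.ndarray) -> np.ndarray:
    """CIE L* luminance per frame, in [0, 100].

    Accepts ``(T, H, W)`` grayscale or ``(T, H, W, 3)`` RGB, with values in
    [0, 1] or [0, 255] (auto-scaled).
    """
    f = np.asarray(frames, dtype=float)
    if f.ndim == 3:
        f = np.repeat(f[..., None], 3, axis=-1)
    if f.ndim != 4 or f.shape[-1] != 3:
        raise ValueError("frames must be (T, H, W) or (T, H, W, 3)")
    if f.max() > 1.0 + 1e-9:
        f = f / 255.0
    return rgb2lab(np.clip(f, 0.0, 1.0))[..., 0]


def _grid(dim: int, spacing: float, density: float, cap: int) -> np.ndarray:
    n = max(1, int(round(dim / spacing * density)))
    n = min(n, cap)
    return (np.arange(n) + 0.5) * dim / n


def build_filter_bank(config: GaborBankConfig | None = None, **kwargs) -> GaborBank:
    """Construct the quadrature Gabor bank for a frame geometry.

    The channel count is a pure function of the configuration:
    ``sum_sf n_positions(sf) * n_orientations * n_tf * n_directions``.
    """
    cfg = config if config is not None else GaborBankConfig(**kwargs)
    if cfg.image_h < 2 or cfg.image_w < 2 or cfg.pixels_per_degree <= 0:
        raise ValueError("invalid image geometry")
    if not cfg.allow_out_of_range:
        for sf in cfg.spatial_frequencies:
            if not (SF_RANGE[0] <= sf <= SF_RANGE[1]):
                raise ValueError(f"spatial frequency {sf} outside {SF_RANGE} cycles/deg")
        for tf in cfg.temporal_frequencies:
            if not (TF_RANGE[0] <= tf <= TF_RANGE[1]):
                raise ValueError(f"temporal frequency {tf} outside {TF_RANGE} Hz")
    if cfg.n_directions != 2:
        raise ValueError("exactly two opposite directions per orientation")

    yy, xx = np.mgrid[0:cfg.image_h, 0:cfg.image_w].astype(float)
    evens, odds, channels = [], [], []
    spatial_idx = 0
    for sf in cfg.spatial_frequencies:
        wavelength_px = cfg.pixels_per_degree / sf
        sigma = cfg.envelope_wavelengths * wavelength_px
        spacing = cfg.spacing_sigmas * sigma
        ys = _grid(cfg.image_h, spacing, cfg.grid_density, cfg.max_positions_per_axis)
        xs = _grid(cfg.image_w, spacing, cfg.grid_density, cfg.max_positions_per_axis)
        for cy in ys:
            for cx in xs:
                for ori in cfg.orientations:
                    th = np.deg2rad(ori)
                    u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
                    v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
                    env = np.exp(-(u**2 + v**2) / (2 * sigma**2))
                    carrier = 2 * np.pi * u / wavelength_px
                    even = env * np.cos(carrier)
                    odd = env * np.sin(carrier)
                    even -= env * (even.sum() / env.sum())  # zero-DC
                    odd -= env * (odd.sum() / env.sum())
                    scale = 1.0 / np.sqrt((env**2).sum())
                    evens.append(even.ravel() * scale)
                    odds.append(odd.ravel() * scale)
                    for tf in cfg.temporal_frequencies:
                        for d in (1.0, -1.0):
                            channels.append((spatial_idx, cy, cx, ori, sf, tf, d))
                    spatial_idx += 1

    temporal = {}
    for tf in cfg.temporal_frequencies:
        sigma_t = cfg.temporal_sigma_periods / tf
        half = max(1, int(np.ceil(3 * sigma_t * cfg.fps)))
        tt = np.arange(-half, half + 1) / cfg.fps
        env_t = np.exp(-(tt**2) / (2 * sigma_t**2))
        te = env_t * np.cos(2 * np.pi * tf * tt)
        to = env_t * np.sin(2 * np.pi * tf * tt)
        norm = 1.0 / np.sqrt((env_t**2).sum())
        temporal[tf] = (te * norm, to * norm)

    return GaborBank(
        config=cfg,
        channels=channels,
        spatial_even=np.array(evens),
        spatial_odd=np.array(odds),
        temporal=temporal,
    )


def motion_energy(
    frames: np.ndarray, bank: GaborBank, return_raw: bool = False
) -> np.ndarray:
    """Frame-averaged log motion energy per channel.

    Per channel: convolve with both quadrature spatiotemporal filters,
    square, sum, ``log(x + eps)``, average over frames.  ``eps`` scales with
    the clip's maximum raw energy to stabilise the log at zero contrast.
    """
    f = np.asarray(frames, dtype=float)
    if f.ndim != 3:
        raise ValueError("frames must be (T, H, W) luminance")
    if f.shape[0] < 2:
        raise ValueError("need at least two frames")
    cfg = bank.config
    if f.shape[1:] != (cfg.image_h, cfg.image_w):
        raise ValueError(
            f"frame geometry {f.shape[1:]} does not match bank "
            f"({cfg.image_h}, {cfg.image_w})"
        )
    flat = f.reshape(f.shape[0], -1)
    flat = flat - flat.mean(axis=1, keepdims=True)  # DC removal (filters are zero-DC)
    flat[np.abs(flat) < 1e-12 * max(1.0, np.abs(f).max())] = 0.0  # kill rounding dust
    resp_e = flat @ bank.spatial_even.T  # (T, n_spatial)
    resp_o = flat @ bank.spatial_odd.T

    # temporal quadrature responses per (spatial, tf)
    cache: dict[float, tuple[np.ndarray, ...]] = {}
    for tf, (te, to) in bank.temporal.items():
        ee = convolve1d(resp_e, te[::-1], axis=0, mode="nearest")
        eo = convolve1d(resp_e, to[::-1], axis=0, mode="nearest")
        oe = convolve1d(resp_o, te[::-1], axis=0, mode="nearest")
        oo = convolve1d(resp_o, to[::-1], axis=0, mode="nearest")
        cache[tf] = (ee, eo, oe, oo)

    raw = np.empty((f.shape[0], bank.n_channels))
    for c, (si, _, _, _, _, tf, d) in enumerate(bank.channels):
        ee, eo, oe, oo = cache[tf]
        g1 = ee[:, si] + d * oo[:, si]
        g2 = oe[:, si] - d * eo[:, si]
        raw[:, c] = g1**2 + g2**2

    if return_raw:
        return raw
    m = raw.max()
    eps = cfg.log_epsilon_scale * m if m > 0 else 1e-12
    return np.log(raw + eps).mean(axis=0)


def drifting_grating(
    bank: GaborBank,
    channel: int,
    n_frames: int = 40,
    phase: float = 0.0,
    contrast: float = 1.0,
) -> np.ndarray:
    """Full-field drifting sinusoid matched to one channel's tuning.

    Useful as an oracle stimulus: the matched channel should attain the
    bank's maximal raw energy, independently of ``phase``.
    """
    cfg = bank.config
    _, _, _, ori, sf, tf, d = bank.channels[channel]
    yy, xx = np.mgrid[0:cfg.image_h, 0:cfg.image_w].astype(float)
    th = np.deg2rad(ori)
    u = xx * np.cos(th) + yy * np.sin(th)
    k = 2 * np.pi * sf / cfg.pixels_per_degree
    t = np.arange(n_frames) / cfg.fps
    arg = k * u[None] - d * 2 * np.pi * tf * t[:, None, None] + phase
    return 0.5 + 0.5 * contrast * np.cos(arg)


def moten_features(
    clips: dict[str, np.ndarray], bank: GaborBank
) -> FeatureSpace:
    """Motion-energy feature matrix for a set of luminance clips."""
    ids = list(clips)
    X = np.stack([motion_energy(clips[sid], bank) for sid in ids])
    names = [
        f"pos({ch[1]:.0f},{ch[2]:.0f})_ori{ch[3]:.0f}_sf{ch[4]}_tf{ch[5]}_dir{'+' if ch[6] > 0 else '-'}"
        for ch in bank.channels
    ]
    return FeatureSpace(name="moten", X=X, feature_names=names, stimulus_ids=ids)
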