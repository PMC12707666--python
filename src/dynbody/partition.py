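"""Prediction scoring, per-band variance decomposition and the composite
HSV visualization map.

Fold-wise prediction accuracies are Fisher-z averaged; the joint model's
explained variance is decomposed into per-band contributions (covariance of
the measured signal with each band's partial prediction, normalized by the
signal variance), with negative contributions clipped to zero before the
fractions are formed.  The HSV composite mixes the residual (non motion
energy) fractions as RGB hues, maps residual strength to saturation between
the 23%/93% anchors, and prediction reliability to value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import rgb_to_hsv

logger = logging.getLogger(__name__)

__all__ = [
    "AccuracyMap",
    "HSVComposite",
    "accuracy",
    "fisher_average",
    "partial_correlations",
    "partial_contribution",
    "hsv_composite",
]

_R_CLIP = 1.0 - 1e-7


@dataclass
class AccuracyMap:
    """Voxel-wise joint and per-band accuracies and variance fractions."""

    r_joint: np.ndarray  # (voxels,)
    partial_r: dict[str, np.ndarray]  # band -> (voxels,)
    R2_joint: np.ndarray  # (voxels,)
    fraction_b: dict[str, np.ndarray]  # band -> (voxels,), NaN where undefined
    contributions: dict[str, np.ndarray] | None = None  # signed, pre-clip


@dataclass
class HSVComposite:
    H: np.ndarray
    S: np.ndarray
    V: np.ndarray
    s_min: float = 0.23
    s_max: float = 0.93

    def to_rgb(self) -> np.ndarray:
        """(n, 3) RGB in [0, 1] from the HSV channels."""
        import colorsys

        return np.array([
            colorsys.hsv_to_rgb(h, s, v)
            for h, s, v in zip(self.H, self.S, self.V)
        ])


def _corr_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two equally shaped matrices."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    num = (Ac * Bc).sum(axis=0)
    den = np.sqrt((Ac**2).sum(axis=0) * (Bc**2).sum(axis=0))
    bad = den <= 0
    if np.any(bad):
        logger.warning("zero-variance series in %d voxel(s); r set to 0", int(bad.sum()))
    return np.divide(num, den, out=np.zeros_like(num), where=~bad)


def fisher_average(r_by_fold: np.ndarray, axis: int = 0) -> np.ndarray:
    """Fisher z-transform, average over folds, back-transform."""
    z = np.arctanh(np.clip(r_by_fold, -_R_CLIP, _R_CLIP))
    return np.tanh(z.mean(axis=axis))


def accuracy(Y_true: np.ndarray, Y_pred: np.ndarray, fold_ids: np.ndarray) -> np.ndarray:
    """Per-voxel prediction accuracy: fold-wise Pearson r, Fisher-z averaged.

    ``fold_ids`` labels every time point with its outer test fold; each fold
    needs at least three time points.
    """
    fold_ids = np.asarray(fold_ids)
    rs = []
    for f in np.unique(fold_ids):
        m = fold_ids == f
        if m.sum() < 3:
            raise ValueError(f"fold {f} has fewer than 3 time points")
        rs.append(_corr_columns(Y_true[m], Y_pred[m]))
    return fisher_average(np.vstack(rs), axis=0)


def partial_correlations(
    Y: np.ndarray, band_preds: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Correlation of the measured series with each band's partial
    prediction, controlling for the other bands' predictions.

    Both sides are residualized on the remaining bands' predictions, per
    voxel, then correlated.
    """
    bands = list(band_preds)
    out: dict[str, np.ndarray] = {}
    n, v = Y.shape
    for b in bands:
        others = [band_preds[o] for o in bands if o != b]
        if not others:
            out[b] = _corr_columns(Y, band_preds[b])
            continue
        Z = np.stack(others, axis=2)  # (n, v, k)
        Zc = Z - Z.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        Pc = band_preds[b] - band_preds[b].mean(axis=0)
        G = np.einsum("nvk,nvl->vkl", Zc, Zc)
        G += 1e-12 * np.eye(Z.shape[2])
        by = np.linalg.solve(G, np.einsum("nvk,nv->vk", Zc, Yc)[..., None])[..., 0]
        bp = np.linalg.solve(G, np.einsum("nvk,nv->vk", Zc, Pc)[..., None])[..., 0]
        Yr = Yc - np.einsum("nvk,vk->nv", Zc, by)
        Pr = Pc - np.einsum("nvk,vk->nv", Zc, bp)
        out[b] = _corr_columns(Yr, Pr)
    return out


def partial_contribution(
    Y_true: np.ndarray, band_preds: dict[str, np.ndarray]
) -> AccuracyMap:
    """Decompose joint explained variance into per-band fractions.

    The signed contribution of band ``b`` is ``cov(Y, p_b) / var(Y)``; the
    contributions sum to the joint R^2 on noiseless data (the joint
    prediction is the sum of the partial predictions).  Negative
    contributions are clipped to zero (logged) before normalizing to
    fractions; voxels with non-positive joint R^2 get NaN fractions.
    """
    bands = list(band_preds)
    Y_pred = sum(band_preds.values())
    Yc = Y_true - Y_true.mean(axis=0)
    var_y = (Yc**2).mean(axis=0)
    resid = Y_true - Y_pred
    R2 = 1.0 - (resid - resid.mean(axis=0)).var(axis=0) / np.where(var_y > 0, var_y, np.nan)

    contrib = {}
    for b in bands:
        Pc = band_preds[b] - band_preds[b].mean(axis=0)
        contrib[b] = (Yc * Pc).mean(axis=0) / np.where(var_y > 0, var_y, np.nan)

    clipped = {b: np.clip(c, 0.0, None) for b, c in contrib.items()}
    n_neg = int(sum((c < 0).sum() for c in contrib.values()))
    if n_neg:
        logger.info("clipped %d negative band contributions to 0", n_neg)
    total = sum(clipped.values())
    valid = (R2 > 0) & (total > 0)
    fractions = {
        b: np.where(valid, c / np.where(total > 0, total, np.nan), np.nan)
        for b, c in clipped.items()
    }

    r_joint = _corr_columns(Y_true, Y_pred)
    return AccuracyMap(
        r_joint=r_joint,
        partial_r=partial_correlations(Y_true, band_preds),
        R2_joint=R2,
        fraction_b=fractions,
        contributions=contrib,
    )


def hsv_composite(
    fraction_b: dict[str, np.ndarray],
    r_joint: np.ndarray,
    s_min: float = 0.23,
    s_max: float = 0.93,
    moten_band: str = "moten",
    rgb_bands: tuple[str, str, str] = ("kp3d", "categorical", "simdist"),
    tie_tol: float = 1e-9,
) -> HSVComposite:
    """Composite map: hue from the residual kp3d/categorical/SimDist mix
    (pure red/green/blue respectively), saturation from residual strength
    rescaled between ``s_min``/``s_max``, value from min-max scaled r."""
    f_mot = np.nan_to_num(fraction_b.get(moten_band, 0.0), nan=0.0)
    residual = 1.0 - f_mot
    rgb = np.stack([np.nan_to_num(fraction_b[b], nan=0.0) for b in rgb_bands], axis=-1)
    total = rgb.sum(axis=-1, keepdims=True)
    rgb_norm = np.divide(rgb, total, out=np.zeros_like(rgb), where=total > 0)

    peak = rgb_norm.max(axis=-1, keepdims=True)
    rgb_disp = np.divide(rgb_norm, peak, out=np.zeros_like(rgb_norm), where=peak > 0)
    hsv = rgb_to_hsv(rgb_disp.reshape(-1, 1, 3)).reshape(-1, 3)
    H = hsv[:, 0]

    S = np.clip((residual - s_min) / (s_max - s_min), 0.0, 1.0)
    achromatic = (total.squeeze(-1) <= 0) | (
        rgb_norm.max(axis=-1) - rgb_norm.min(axis=-1) <= tie_tol
    )
    S = np.where(achromatic, 0.0, S)

    r = np.asarray(r_joint, dtype=float)
    finite = np.isfinite(r)
    lo = r[finite].min() if finite.any() else 0.0
    hi = r[finite].max() if finite.any() else 1.0
    V = np.clip((r - lo) / (hi - lo) if hi > lo else np.ones_like(r), 0.0, 1.0)
    return HSVComposite(H=H, S=S, V=V, s_min=s_min, s_max=s_max)
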