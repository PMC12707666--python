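"""Design-matrix construction and banded ridge regression with nested
cross-validation.

The TR-level design places each stimulus' feature vector at its onset TR and
appends delayed copies (default 5 delays of 1..5 TRs, spanning 11.5 s at
TR = 2.3 s) to absorb the hemodynamic lag.  Banded ridge fits all feature
spaces jointly with one regularization parameter per band; hyperparameters
are chosen by random search plus local refinement on inner validation folds,
and assessed on held-out runs of the outer folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import gamma as gamma_dist

from .features.posture import FeatureSpace

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "CVScheme",
    "BandedRidgeFit",
    "CVResult",
    "FoldResult",
    "build_design",
    "delay_design",
    "standardize",
    "canonical_hrf",
    "denoise_timeseries",
    "fit_banded_ridge",
    "predict_bands",
    "optimize_hyperparams",
    "cross_validate",
    "make_cv_scheme",
]

DEFAULT_LAMBDA_RANGE = (1e-3, 1e5)


# ---------------------------------------------------------------------------
# design construction


@dataclass
class DesignMatrix:
    """Per-band, per-run stimulus design matrices on the TR grid (undelayed).

    ``bands[name][r]`` is the (n_TR_r, n_features) matrix of run ``r``.
    Delayed copies are produced on demand by :func:`delay_design`.
    """

    bands: dict[str, list[np.ndarray]]
    tr_s: float = 2.3
    n_delays: int = 5
    feature_names: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {tuple(x.shape[0] for x in runs) for runs in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError("bands disagree on per-run TR counts")

    @property
    def n_runs(self) -> int:
        return len(next(iter(self.bands.values())))

    @property
    def n_trs(self) -> list[int]:
        return [x.shape[0] for x in next(iter(self.bands.values()))]

    @property
    def delay_span_s(self) -> float:
        """Temporal span covered by the delayed copies (start of the first
        delay to the end of the last), in seconds."""
        return self.n_delays * self.tr_s

    def delayed(self, band: str, runs: list[int] | None = None) -> np.ndarray:
        """Delayed design of one band, runs stacked in order (delays never
        cross run boundaries)."""
        idx = range(self.n_runs) if runs is None else runs
        return np.vstack([delay_design(self.bands[band][r], self.n_delays) for r in idx])


def build_design(
    events: pd.DataFrame,
    feature_spaces: dict[str, FeatureSpace],
    n_tr_per_run: int,
    tr_s: float = 2.3,
    n_delays: int = 5,
) -> DesignMatrix:
    """Place stimulus feature rows at their onset TRs.

    Blank and target trials contribute all-zero rows.  Raises if an onset
    falls beyond the run length or a stimulus lacks a feature row.
    """
    runs = sorted(events["run"].unique())
    bands: dict[str, list[np.ndarray]] = {name: [] for name in feature_spaces}
    for r in runs:
        ev = events[events["run"] == r]
        for name, fs in feature_spaces.items():
            X = np.zeros((n_tr_per_run, fs.n_features))
            for _, row in ev.iterrows():
                if row["condition"] != "stimulus":
                    continue
                t = int(round(row["onset_s"] / tr_s))
                if t >= n_tr_per_run:
                    raise ValueError(
                        f"onset {row['onset_s']} s beyond run length "
                        f"({n_tr_per_run} TRs at {tr_s} s)"
                    )
                sid = row["stimulus_id"]
                if sid not in fs.stimulus_ids:
                    raise ValueError(f"stimulus {sid!r} missing from band {name!r}")
                X[t] += fs.row(sid)
            bands[name].append(X)
    return DesignMatrix(
        bands=bands, tr_s=tr_s, n_delays=n_delays,
        feature_names={n: fs.feature_names for n, fs in feature_spaces.items()},
    )


def delay_design(X: np.ndarray, n_delays: int, delays: tuple[int, ...] | None = None) -> np.ndarray:
    """Concatenate time-shifted copies of ``X`` (shift forward by each delay,
    zero-padded at the start).  Default delays are 1..n_delays TRs."""
    if delays is None:
        delays = tuple(range(1, n_delays + 1))
    out = np.zeros((X.shape[0], X.shape[1] * len(delays)))
    p = X.shape[1]
    for k, d in enumerate(delays):
        if d == 0:
            out[:, k * p:(k + 1) * p] = X
        else:
            out[d:, k * p:(k + 1) * p] = X[:-d]
    return out


def standardize(
    train: np.ndarray, test: np.ndarray | None = None, eps: float = 1e-12
) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """Zero-mean/unit-variance columns using training statistics only.

    Zero-variance training columns are dropped (with a logged warning) from
    both matrices.  Returns ``(train_s, test_s, stats)`` where ``stats``
    records means, sds and the retained column indices.
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    keep = sd > eps
    if not keep.all():
        logger.warning("dropping %d zero-variance columns", int((~keep).sum()))
    tr = (train[:, keep] - mean[keep]) / sd[keep]
    te = None
    if test is not None:
        if test.shape[1] != train.shape[1]:
            raise ValueError("train/test feature columns differ")
        te = (test[:, keep] - mean[keep]) / sd[keep]
    return tr, te, {"mean": mean, "sd": sd, "keep": keep}


# ---------------------------------------------------------------------------
# denoising


def canonical_hrf(tr_s: float = 2.3, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled on the TR grid (peak 6 s,
    undershoot 16 s, undershoot ratio 1/6), peak-normalized."""
    t = np.arange(0, duration_s, tr_s)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return h / h.max()


def denoise_timeseries(
    Y: np.ndarray, regressors: np.ndarray
) -> np.ndarray:
    """Residualize voxel time series against a regressor matrix.

    Uses least squares (pseudo-inverse on rank deficiency, logged); the
    residuals are orthogonal to the regressor span.
    """
    X = np.asarray(regressors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] >= X.shape[0]:
        raise ValueError("regressors must span fewer dimensions than time points")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("rank-deficient nuisance regressors; using pseudo-inverse")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def hrf_onset_regressor(
    onsets_s: np.ndarray, n_tr: int, tr_s: float = 2.3, hrf: np.ndarray | None = None
) -> np.ndarray:
    """Stimulus-onset impulse train convolved with the canonical HRF."""
    if hrf is None:
        hrf = canonical_hrf(tr_s)
    stick = np.zeros(n_tr)
    for o in np.atleast_1d(onsets_s):
        t = int(round(o / tr_s))
        if 0 <= t < n_tr:
            stick[t] += 1.0
    return np.convolve(stick, hrf)[:n_tr]


# ---------------------------------------------------------------------------
# banded ridge


@dataclass
class BandedRidgeFit:
    """Fitted per-band weights and regularization strengths."""

    lambda_b: dict[str, float]
    W_b: dict[str, np.ndarray]  # band -> (features, voxels)
    search_log: list = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        for b, lam in self.lambda_b.items():
            if lam <= 0:
                raise ValueError(f"non-positive lambda for band {b!r}")
        for b, W in self.W_b.items():
            if not np.all(np.isfinite(W)):
                raise ValueError(f"non-finite weights for band {b!r}")


def fit_banded_ridge(
    X_bands: dict[str, np.ndarray], Y: np.ndarray, lambdas: dict[str, float]
) -> BandedRidgeFit:
    """Closed-form banded ridge via scaled-feature concatenation.

    Minimizes ``||Y - sum_b X_b W_b||^2 + sum_b lambda_b ||W_b||^2``:
    substituting ``X_b / sqrt(lambda_b)`` reduces the problem to ordinary
    ridge with unit penalty on the concatenated features.
    """
    bands = list(X_bands)
    n = {X.shape[0] for X in X_bands.values()}
    if len(n) != 1 or next(iter(n)) != Y.shape[0]:
        raise ValueError("inconsistent TR counts between bands and Y")
    n = n.pop()
    for b in bands:
        if lambdas[b] <= 0:
            raise ValueError(f"non-positive lambda for band {b!r}")
    scales = {b: 1.0 / np.sqrt(lambdas[b]) for b in bands}
    Xs = np.hstack([X_bands[b] * scales[b] for b in bands])
    p = Xs.shape[1]
    if p <= n:
        A = Xs.T @ Xs + np.eye(p)
        W = cho_solve(cho_factor(A), Xs.T @ Y)
    else:  # dual form for wide designs
        A = Xs @ Xs.T + np.eye(n)
        W = Xs.T @ cho_solve(cho_factor(A), Y)
    W_b = {}
    ofs = 0
    for b in bands:
        pb = X_bands[b].shape[1]
        W_b[b] = W[ofs:ofs + pb] * scales[b]
        ofs += pb
    return BandedRidgeFit(lambda_b=dict(lambdas), W_b=W_b)


def predict_bands(
    X_bands: dict[str, np.ndarray], fit: BandedRidgeFit
) -> dict[str, np.ndarray]:
    """Per-band partial predictions ``X_b @ W_b``."""
    return {b: X_bands[b] @ fit.W_b[b] for b in X_bands}


def predict(X_bands: dict[str, np.ndarray], fit: BandedRidgeFit) -> np.ndarray:
    parts = predict_bands(X_bands, fit)
    return sum(parts.values())


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVScheme:
    """Whole-run fold assignment: outer train/test splits plus an inner
    splitter for hyperparameter validation."""

    outer: list[tuple[list[int], list[int]]]
    n_inner: int = 4

    def __post_init__(self) -> None:
        for train, test in self.outer:
            if not test:
                raise ValueError("outer fold with no test runs")
            if set(train) & set(test):
                raise ValueError("run assigned to both train and test")

    def inner(self, train_runs: list[int]) -> list[tuple[list[int], list[int]]]:
        """Partition the training runs into inner train/validation folds."""
        runs = list(train_runs)
        k = self.n_inner
        if len(runs) < k:
            raise ValueError(f"cannot make {k} inner folds from {len(runs)} runs")
        blocks = [list(a) for a in np.array_split(runs, k)]
        return [
            ([r for j, b in enumerate(blocks) if j != i for r in b], blocks[i])
            for i in range(k)
        ]


def make_cv_scheme(
    n_runs: int = 12, n_outer: int = 3, n_inner: int = 4,
    seed: int | None = None,
) -> CVScheme:
    """Default scheme: 3 outer folds (train 8 / test 4 runs), 4 inner folds
    (train 6 / validate 2).  Outer test blocks are contiguous run groups
    unless a seed requests a shuffled assignment."""
    if n_runs < n_outer or n_runs < 2:
        raise ValueError(f"cannot cross-validate {n_runs} run(s) with {n_outer} folds")
    runs = np.arange(n_runs)
    if seed is not None:
        runs = np.random.default_rng(seed).permutation(runs)
    blocks = [list(map(int, b)) for b in np.array_split(runs, n_outer)]
    outer = [
        ([r for j, b in enumerate(blocks) if j != i for r in b], blocks[i])
        for i in range(n_outer)
    ]
    return CVScheme(outer=outer, n_inner=n_inner)


def _assemble(
    design: DesignMatrix,
    Y_runs: list[np.ndarray],
    train_runs: list[int],
    test_runs: list[int],
    mode: str = "tr",
) -> tuple[dict, dict, np.ndarray, np.ndarray]:
    """Delayed (and optionally standardized) fold matrices.

    ``mode="tr"`` standardizes each delayed design column with training-run
    statistics; ``mode="none"`` leaves the design raw.
    """
    Xtr, Xte = {}, {}
    for b in design.bands:
        tr = design.delayed(b, train_runs)
        te = design.delayed(b, test_runs)
        if mode == "tr":
            tr, te, _ = standardize(tr, te)
        elif mode != "none":
            raise ValueError(f"unknown standardization mode {mode!r}")
        Xtr[b], Xte[b] = tr, te
    Ytr = np.vstack([Y_runs[r] for r in train_runs])
    Yte = np.vstack([Y_runs[r] for r in test_runs])
    return Xtr, Xte, Ytr, Yte


def _mean_corr(Y: np.ndarray, P: np.ndarray) -> float:
    """Mean over voxels of the Pearson correlation of columns."""
    Yc = Y - Y.mean(axis=0)
    Pc = P - P.mean(axis=0)
    num = (Yc * Pc).sum(axis=0)
    den = np.sqrt((Yc**2).sum(axis=0) * (Pc**2).sum(axis=0))
    r = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return float(np.mean(r))


def optimize_hyperparams(
    design: DesignMatrix,
    Y_runs: list[np.ndarray],
    inner_folds: list[tuple[list[int], list[int]]],
    lambda_range: tuple[float, float] = DEFAULT_LAMBDA_RANGE,
    n_random: int = 100,
    refine_steps: int = 50,
    seed: int | np.random.Generator = 0,
    standardize_mode: str = "tr",
) -> tuple[dict[str, float], list]:
    """Per-band regularization by random log-uniform search plus coordinate
    refinement, scored by mean validation correlation over the inner folds."""
    if len(inner_folds) < 1 or n_random < 1:
        raise ValueError("empty search budget")
    rng = np.random.default_rng(seed)
    bands = list(design.bands)
    lo, hi = np.log10(lambda_range[0]), np.log10(lambda_range[1])

    folds = [
        _assemble(design, Y_runs, tr, va, standardize_mode) for tr, va in inner_folds
    ]

    def score(lam: dict[str, float]) -> float:
        vals = []
        for Xtr, Xva, Ytr, Yva in folds:
            fit = fit_banded_ridge(Xtr, Ytr, lam)
            vals.append(_mean_corr(Yva, predict(Xva, fit)))
        return float(np.mean(vals))

    log: list = []
    candidates = [
        {b: 10.0 ** rng.uniform(lo, hi) for b in bands} for _ in range(n_random)
    ]
    best, best_s = None, -np.inf
    for lam in candidates:
        s = score(lam)
        log.append((dict(lam), s))
        if s > best_s:
            best, best_s = dict(lam), s

    step = 10.0 ** 0.5
    for _ in range(refine_steps):
        improved = False
        for b in bands:
            for cand_lam in (best[b] * step, best[b] / step):
                cand_lam = float(np.clip(cand_lam, lambda_range[0], lambda_range[1]))
                if cand_lam == best[b]:
                    continue
                trial = dict(best)
                trial[b] = cand_lam
                s = score(trial)
                log.append((dict(trial), s))
                if s > best_s:
                    best, best_s = trial, s
                    improved = True
        if not improved:
            step = np.sqrt(step)
            if step < 1.05:
                break
    return best, log


@dataclass
class FoldResult:
    test_runs: list[int]
    fit: BandedRidgeFit
    Y_true: np.ndarray
    Y_pred: np.ndarray
    band_preds: dict[str, np.ndarray]


@dataclass
class CVResult:
    folds: list[FoldResult]
    fold_of_run: dict[int, int]

    def concatenated(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, np.ndarray]]:
        """(fold_ids, Y_true, Y_pred, band_preds) stacked over folds."""
        fid = np.concatenate([
            np.full(f.Y_true.shape[0], i) for i, f in enumerate(self.folds)
        ])
        Yt = np.vstack([f.Y_true for f in self.folds])
        Yp = np.vstack([f.Y_pred for f in self.folds])
        bands = {
            b: np.vstack([f.band_preds[b] for f in self.folds])
            for b in self.folds[0].band_preds
        }
        return fid, Yt, Yp, bands


def cross_validate(
    design: DesignMatrix,
    Y_runs: list[np.ndarray],
    cv: CVScheme,
    lambda_range: tuple[float, float] = DEFAULT_LAMBDA_RANGE,
    n_random: int = 100,
    refine_steps: int = 50,
    seed: int = 0,
    standardize_mode: str = "tr",
    fixed_lambdas: dict[str, float] | None = None,
) -> CVResult:
    """Outer-loop cross-validation: hyperparameters from the inner folds of
    each training set, weights fit on all training runs, predictions on the
    held-out runs.  Each run is tested exactly once."""
    if design.n_runs != len(Y_runs):
        raise ValueError("design and time series disagree on run count")
    folds = []
    fold_of_run: dict[int, int] = {}
    rng = np.random.default_rng(seed)
    for i, (train_runs, test_runs) in enumerate(cv.outer):
        if fixed_lambdas is None:
            lam, log = optimize_hyperparams(
                design, Y_runs, cv.inner(train_runs), lambda_range,
                n_random, refine_steps, rng, standardize_mode,
            )
        else:
            lam, log = dict(fixed_lambdas), []
        Xtr, Xte, Ytr, Yte = _assemble(design, Y_runs, train_runs, test_runs, standardize_mode)
        fit = fit_banded_ridge(Xtr, Ytr, lam)
        fit.search_log = log
        band_preds = predict_bands(Xte, fit)
        folds.append(FoldResult(
            test_runs=list(test_runs), fit=fit, Y_true=Yte,
            Y_pred=sum(band_preds.values()), band_preds=band_preds,
        ))
        for r in test_runs:
            if r in fold_of_run:
                raise ValueError(f"run {r} tested in two folds")
            fold_of_run[r] = i
    return CVResult(folds=folds, fold_of_run=fold_of_run)
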