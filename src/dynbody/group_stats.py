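"""Group-level inference: sign-flip permutation tests with FDR correction,
paired contrasts with effect sizes and retrospective power, and the
three-way repeated-measures ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationResult",
    "PairedTestResult",
    "AnovaResult",
    "signflip_permutation",
    "fdr_bh",
    "paired_contrast",
    "cohens_dz",
    "eta_p2_from_f",
    "retrospective_power",
    "rm_anova_3way",
]


@dataclass
class PermutationResult:
    observed: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_permutations: int
    exhaustive: bool


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    dz: float
    power: float
    n: int
    degenerate: bool = False
    q: float | None = None


@dataclass
class AnovaResult:
    """Per-effect F table of the within-subject decomposition."""

    table: pd.DataFrame  # index: effect; columns: F, df1, df2, p, eta_p2, SS, SS_err


def _all_sign_assignments(n: int) -> np.ndarray:
    """All 2^n distinct +/-1 assignments, identity first."""
    bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    return 1.0 - 2.0 * bits  # row 0 is all +1


def signflip_permutation(
    group_maps: np.ndarray,
    statistic: str = "mean",
    exhaustive_limit: int = 12,
    n_permutations: int = 2048,
    seed: int | np.random.Generator = 0,
    q_level: float = 0.05,
) -> PermutationResult:
    """Subject-wise sign-flipping permutation test on group maps.

    ``group_maps`` is (subjects, locations).  The null is built by negating
    each subject's map under every +/-1 assignment — exhaustively (2^N) when
    N <= ``exhaustive_limit``, otherwise by seeded Monte-Carlo with the
    identity assignment always included.  Two-sided p by null symmetry;
    exhaustive p-values are exact multiples of 1/2^N and never zero.
    """
    maps = np.atleast_2d(np.asarray(group_maps, dtype=float))
    if maps.shape[0] < 2:
        raise ValueError("need at least two subjects")
    if not np.all(np.isfinite(maps)):
        raise ValueError("non-finite map entries")
    if statistic != "mean":
        raise ValueError(f"unsupported statistic {statistic!r}")
    n = maps.shape[0]
    if n <= exhaustive_limit:
        signs = _all_sign_assignments(n)
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_permutations, n))
        signs[0] = 1.0
        exhaustive = False
    null = (signs @ maps) / n  # (n_perm, locations)
    observed = maps.mean(axis=0)
    p = np.mean(np.abs(null) >= np.abs(observed)[None, :], axis=0)
    q, _ = fdr_bh(p, q_level)
    return PermutationResult(
        observed=observed, p=p, q=q, n_permutations=signs.shape[0], exhaustive=exhaustive
    )


def fdr_bh(p_values: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and significance mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="stable")
    ranked = flat[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adj, 1.0)
    q = q.reshape(p.shape)
    return q, q < q_level


def cohens_dz(t: float, n: int) -> float:
    """Paired effect size |t| / sqrt(N)."""
    return abs(t) / np.sqrt(n)


def eta_p2_from_f(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    return F * df1 / (F * df1 + df2)


def retrospective_power(dz: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided retrospective power from the noncentral t distribution with
    noncentrality dz * sqrt(N)."""
    df = n - 1
    nc = dz * np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    )


def paired_contrast(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> PairedTestResult:
    """Paired t-test with Cohen's dz and retrospective power."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedTestResult(
            t=np.nan, df=n - 1, p=np.nan, dz=np.nan, power=np.nan, n=n, degenerate=True
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    dz = cohens_dz(t, n)
    return PairedTestResult(
        t=float(t), df=n - 1, p=float(p), dz=float(dz),
        power=retrospective_power(dz, n, alpha), n=n,
    )


def rm_anova_3way(
    values: np.ndarray, factor_names: tuple[str, str, str] = ("A", "B", "C")
) -> AnovaResult:
    """Fully within-subject three-way repeated-measures ANOVA.

    ``values`` is (subjects, a, b, c) with one observation per cell.  Each
    within effect is tested against its interaction with subjects; no
    sphericity correction is applied.  Partial eta squared per effect is
    SS_effect / (SS_effect + SS_error).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 4:
        raise ValueError("values must be (subjects, a, b, c)")
    if not np.all(np.isfinite(y)):
        raise ValueError("missing cells in the design")
    n = y.shape[0]
    sizes = y.shape

    def effect_ss(axes: tuple[int, ...]) -> float:
        """Sum of squares of the Moebius effect estimate for the factor
        subset indexed by ``axes`` (0 = subject)."""
        eta = np.zeros_like(y)
        for k in range(len(axes) + 1):
            for sub in combinations(axes, k):
                other = tuple(ax for ax in range(4) if ax not in sub)
                marg = y.mean(axis=other, keepdims=True)
                eta = eta + (-1.0) ** (len(axes) - len(sub)) * marg
        return float((eta**2).sum())

    rows = []
    within_axes = (1, 2, 3)
    for k in (1, 2, 3):
        for sub in combinations(within_axes, k):
            name = " x ".join(factor_names[ax - 1] for ax in sub)
            df1 = int(np.prod([sizes[ax] - 1 for ax in sub]))
            df2 = (n - 1) * df1
            ss = effect_ss(sub)
            ss_err = effect_ss((0,) + sub)
            ms, ms_err = ss / df1, ss_err / df2
            F = ms / ms_err if ms_err > 0 else 0.0
            p = float(stats.f.sf(F, df1, df2)) if ms_err > 0 else 1.0
            eta_p2 = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
            rows.append(
                {"effect": name, "F": F, "df1": df1, "df2": df2, "p": p,
                 "eta_p2": eta_p2, "SS": ss, "SS_err": ss_err}
            )
    table = pd.DataFrame(rows).set_index("effect")
    return AnovaResult(table=table)
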