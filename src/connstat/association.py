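"""Covariate-adjusted correlations with bootstrap confidence intervals.

The partial Pearson correlation between x and y given covariates Z is the
Pearson correlation of the least-squares residuals of x and y on
[intercept, Z]; its two-sided p-value uses ``t = r sqrt(df / (1 - r^2))``
with ``df = n - 2 - ncov``.  Uncertainty is quantified with a
nonparametric percentile bootstrap resampling subjects jointly
(1000 resamples by default, 95 % interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable
from .posthoc import MNCVector

__all__ = [
    "PartialCorrResult",
    "partial_pearson",
    "bootstrap_ci",
    "correlation_table",
    "DegenerateDataError",
]


class DegenerateDataError(ValueError):
    """Residual variance vanished; the correlation is undefined."""


@dataclass
class PartialCorrResult:
    network: str
    variable: str
    stratum: str | None
    r: float
    p: float
    n: int
    covariates: list[str]
    ci_low: float | None
    ci_high: float | None
    n_boot: int
    seed: int
    degenerate: bool = False


def _residualize(v: np.ndarray, c: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(c, v, rcond=None)
    return v - c @ beta


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation and two-sided p-value.

    With no covariates this reduces to the plain Pearson correlation with
    the usual t-test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        c = np.ones((n, 1))
        ncov = 0
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        c = np.column_stack([np.ones(n), covariates])
        ncov = covariates.shape[1]
    if n <= ncov + 2:
        raise ValueError(f"need n > ncov + 2 subjects (n={n}, ncov={ncov})")
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(c).all()):
        raise ValueError("inputs contain missing/non-finite values")
    rx = _residualize(x, c)
    ry = _residualize(y, c)
    sx, sy = np.sqrt((rx**2).sum()), np.sqrt((ry**2).sum())
    # relative floor: residuals at roundoff level of the centered data count
    # as "no residual variance" (e.g. x an exact affine function of Z)
    tol_x = 1e-10 * max(np.sqrt(((x - x.mean()) ** 2).sum()), 1e-300)
    tol_y = 1e-10 * max(np.sqrt(((y - y.mean()) ** 2).sum()), 1e-300)
    if sx <= tol_x or sy <= tol_y:
        raise DegenerateDataError("zero residual variance in x or y")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - ncov
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    max_degenerate_frac: float = 0.2,
) -> tuple[float, float]:
    """Percentile bootstrap 95 % interval for the partial correlation.

    Subjects are resampled jointly with replacement; resamples whose
    residual variance collapses are skipped (an instability error is raised
    when more than ``max_degenerate_frac`` of them do).  Deterministic
    given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("bootstrap needs at least 8 subjects")
    if covariates is None:
        c = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        c = np.column_stack([np.ones(n), covariates])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    cb = c[idx]                                   # (B, n, p)
    xb = x[idx][..., None]
    yb = y[idx][..., None]
    g = np.swapaxes(cb, 1, 2) @ cb                # (B, p, p)
    # tiny ridge guards resamples with repeated rows making G singular
    g += 1e-12 * np.eye(c.shape[1])
    bx = np.linalg.solve(g, np.swapaxes(cb, 1, 2) @ xb)
    by = np.linalg.solve(g, np.swapaxes(cb, 1, 2) @ yb)
    rx = (xb - cb @ bx)[..., 0]
    ry = (yb - cb @ by)[..., 0]
    sx = np.sqrt((rx**2).sum(axis=1))
    sy = np.sqrt((ry**2).sum(axis=1))
    ok = (sx > 1e-12) & (sy > 1e-12)
    if ok.mean() < 1.0 - max_degenerate_frac:
        raise DegenerateDataError(
            f"{(~ok).sum()} of {n_boot} bootstrap resamples were degenerate"
        )
    r = np.einsum("bi,bi->b", rx[ok], ry[ok]) / (sx[ok] * sy[ok])
    lo, hi = np.percentile(r, [2.5, 97.5])
    return float(lo), float(hi)


def correlation_table(
    mnc_sets: dict[str, MNCVector],
    cohort: CohortTable,
    variables: list[str],
    covariates: list[str],
    n_boot: int = 1000,
    seed: int = 0,
    stratify: str | None = None,
) -> list[PartialCorrResult]:
    """Partial-correlation table over (network, variable, stratum) cells.

    ``stratify`` names a cohort column (e.g. a sex indicator) whose levels
    define subgroups analyzed separately.  Missing variables are skipped;
    degenerate cells are flagged rather than raising.
    """
    results: list[PartialCorrResult] = []
    table = cohort.table
    strata: list[tuple[str | None, pd.Series]] = (
        [(None, pd.Series(True, index=table.index))]
        if stratify is None
        else [(str(lvl), table[stratify] == lvl) for lvl in dict.fromkeys(table[stratify])]
    )
    for net_name, mnc in mnc_sets.items():
        mvals = pd.Series(np.asarray(mnc.values, dtype=float),
                          index=mnc.subjects or table.index)
        for var in variables:
            if var not in table.columns:
                continue
            for stratum, mask in strata:
                sub = table[mask]
                x = mvals.loc[sub.index].to_numpy()
                y = sub[var].to_numpy(dtype=float)
                cov = sub[covariates].to_numpy(dtype=float) if covariates else None
                cell_seed = int(
                    np.random.SeedSequence([seed, len(results)]).generate_state(1)[0]
                    % (2**31)
                )
                try:
                    r, p = partial_pearson(x, y, cov)
                    lo, hi = bootstrap_ci(x, y, cov, n_boot=n_boot, seed=cell_seed)
                    results.append(PartialCorrResult(
                        net_name, var, stratum, r, p, len(x), list(covariates),
                        lo, hi, n_boot, cell_seed))
                except DegenerateDataError:
                    results.append(PartialCorrResult(
                        net_name, var, stratum, float("nan"), float("nan"), len(x),
                        list(covariates), None, None, n_boot, cell_seed,
                        degenerate=True))
    return results
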