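"""Between-subject analyses linking fitted parameters across tasks.

The headline analysis is a single-level mediation: age group (X)
predicting an exploration parameter from choice-task fits (Y), mediated
by each participant's assumed-volatility (drift variance) parameter from
estimation-task fits (M).  Because individual drift-variance estimates
are heavy-tailed, variables are rank-transformed before the regressions.
Path coefficients come from two least-squares regressions (M ~ X and
Y ~ X + M); significance uses a percentile bootstrap over participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MediationPaths",
    "rank_transform",
    "single_level_mediation",
    "partial_correlation",
]


def rank_transform(values) -> np.ndarray:
    """Ranks 1..n with ties receiving their average rank."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to rank")
    return stats.rankdata(x, method="average")


@dataclass(frozen=True)
class PathEstimate:
    estimate: float
    ci_lo: float
    ci_hi: float
    p_value: float


@dataclass(frozen=True)
class MediationPaths:
    """Mediation path coefficients with percentile-bootstrap inference.

    a: X -> M;  b: M -> Y controlling X;  c: total X -> Y;
    c_prime: direct X -> Y controlling M;  ab = a * b (indirect).
    The OLS identity a*b + c' = c holds exactly for the point estimates.
    """

    a: PathEstimate
    b: PathEstimate
    c: PathEstimate
    c_prime: PathEstimate
    ab: PathEstimate
    n: int
    n_boot: int


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(a, b, c, c') via closed-form OLS on batched inputs.

    Inputs shaped (..., n); returns (..., 4).  Slope of M~1+X is
    cov(x, m)/var(x); the two-predictor regression Y ~ 1 + X + M is
    solved from the 2x2 centred normal equations.
    """
    xc = x - x.mean(axis=-1, keepdims=True)
    mc = m - m.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    sxx = (xc * xc).sum(axis=-1)
    sxm = (xc * mc).sum(axis=-1)
    smm = (mc * mc).sum(axis=-1)
    sxy = (xc * yc).sum(axis=-1)
    smy = (mc * yc).sum(axis=-1)
    a = sxm / sxx
    c = sxy / sxx
    det = sxx * smm - sxm**2
    c_prime = (smm * sxy - sxm * smy) / det
    b = (sxx * smy - sxm * sxy) / det
    return np.stack([a, b, c, c_prime], axis=-1)


def _boot_p(draws: np.ndarray) -> float:
    """Two-sided percentile-bootstrap p-value (fraction crossing zero)."""
    lo = np.mean(draws < 0.0)
    hi = np.mean(draws > 0.0)
    return float(min(1.0, 2.0 * min(lo, hi)))


def single_level_mediation(
    x,
    m,
    y,
    n_boot: int = 10000,
    seed: int = 0,
    ranks: bool = False,
) -> MediationPaths:
    """Single-level mediation with percentile-bootstrap significance.

    ``x`` is the (binary or continuous) predictor, ``m`` the mediator,
    ``y`` the outcome, aligned per participant.  With ``ranks`` on, m
    and y are replaced by their ranks first (x, a group indicator, is
    left as is).  Participants are resampled with replacement;
    confidence intervals are percentile intervals and p-values the
    two-sided fraction of bootstrap draws crossing zero.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not (m.size == n and y.size == n):
        raise ValueError("x, m, y must be aligned")
    if n < 10:
        raise ValueError("need at least 10 participants")
    if np.ptp(m) == 0 or np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("constant x, m or y")
    if ranks:
        m = rank_transform(m)
        y = rank_transform(y)

    point = _paths(x, m, y)
    a0, b0, c0, cp0 = point
    ab0 = a0 * b0

    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 5))
    chunk = 20000
    done = 0
    while done < n_boot:
        k = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(k, n))
        p = _paths(x[idx], m[idx], y[idx])
        draws[done : done + k, :4] = p
        draws[done : done + k, 4] = p[:, 0] * p[:, 1]
        done += k

    def make(est: float, col: int) -> PathEstimate:
        lo, hi = np.percentile(draws[:, col], [2.5, 97.5])
        return PathEstimate(
            estimate=float(est),
            ci_lo=float(lo),
            ci_hi=float(hi),
            p_value=_boot_p(draws[:, col]),
        )

    return MediationPaths(
        a=make(a0, 0),
        b=make(b0, 1),
        c=make(c0, 2),
        c_prime=make(cp0, 3),
        ab=make(ab0, 4),
        n=n,
        n_boot=n_boot,
    )


def partial_correlation(m, y, controls=None) -> float:
    """Pearson correlation of m and y after regressing out the controls.

    With no controls this is the plain Pearson correlation.  Controls
    are given as an (n, k) array (or length-n vector); an intercept is
    always included in the projection.
    """
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = m.size
    if y.size != n:
        raise ValueError("m and y must be aligned")
    if controls is None:
        design = np.ones((n, 1))
    else:
        z = np.asarray(controls, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        design = np.column_stack([np.ones(n), z])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient controls")
    beta_m, *_ = np.linalg.lstsq(design, m, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rm = m - design @ beta_m
    ry = y - design @ beta_y
    denom = np.sqrt((rm * rm).sum() * (ry * ry).sum())
    if denom == 0:
        raise ValueError("zero residual variance")
    return float((rm * ry).sum() / denom)
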