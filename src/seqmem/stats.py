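"""Shared statistical routines.

Standard tests (ANOVA, Dunnett, Kolmogorov-Smirnov, t-tests) are invoked from
scipy/statsmodels by the analysis modules; this module houses the few pieces
not provided there: Goodman simultaneous multinomial confidence intervals, the
generalized (I x J x K) Cochran-Mantel-Haenszel statistic, orthogonal
polynomial trend contrasts, the circular-linear correlation used for phase
precession, and a guarded KL divergence.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def kl_divergence(p: np.ndarray, q: np.ndarray, eps: float = 1e-10) -> float:
    """KL(p || q) in nats with an epsilon floor on both arguments."""
    p = np.asarray(p, dtype=float) + eps
    q = np.asarray(q, dtype=float) + eps
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)))


def goodman_multinomial_ci(counts: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Goodman (1965) simultaneous CIs for multinomial cell probabilities.

    Returns an array (k, 2) of lower/upper bounds.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = counts.size
    if n <= 0:
        raise ValueError("empty multinomial sample")
    a = stats.chi2.ppf(1 - alpha / k, 1)
    lo = (a + 2 * counts - np.sqrt(a * (a + 4 * counts * (n - counts) / n))) / (2 * (n + a))
    hi = (a + 2 * counts + np.sqrt(a * (a + 4 * counts * (n - counts) / n))) / (2 * (n + a))
    return np.column_stack([lo, hi])


def cmh_general(tables: np.ndarray) -> tuple[float, int, float]:
    """Generalized Cochran-Mantel-Haenszel test of general association.

    ``tables`` has shape (K, R, C): K strata of R x C contingency tables.
    Returns (statistic, df, p).  df = (R - 1) * (C - 1).
    """
    tables = np.asarray(tables, dtype=float)
    if tables.ndim != 3:
        raise ValueError("tables must have shape (K, R, C)")
    K, R, C = tables.shape
    if K < 2:
        raise ValueError("need at least 2 strata")
    df = (R - 1) * (C - 1)
    U = np.zeros(df)
    V = np.zeros((df, df))
    for h in range(K):
        N = tables[h]
        n = N.sum()
        if n <= 1:
            continue
        r = N.sum(axis=1)  # row totals
        c = N.sum(axis=0)  # column totals
        E = np.outer(r, c) / n
        # deviations on the reduced (R-1)(C-1) cells
        U += (N - E)[: R - 1, : C - 1].ravel()
        Vr = (np.diag(r) * n - np.outer(r, r))[: R - 1, : R - 1]
        Vc = (np.diag(c) * n - np.outer(c, c))[: C - 1, : C - 1]
        V += np.kron(Vr, Vc) / (n * n * (n - 1))
    Q = float(U @ np.linalg.pinv(V) @ U)
    p = float(stats.chi2.sf(Q, df))
    return Q, df, p


def linear_trend_test(values: np.ndarray, levels: np.ndarray) -> tuple[float, float, float]:
    """OLS linear trend of ``values`` against ordered ``levels``.

    Returns (slope, t, p) from the linear term.
    """
    import statsmodels.api as sm

    x = sm.add_constant(np.asarray(levels, dtype=float))
    fit = sm.OLS(np.asarray(values, dtype=float), x).fit()
    return float(fit.params[1]), float(fit.tvalues[1]), float(fit.pvalues[1])


def quadratic_trend_test(values: np.ndarray, levels: np.ndarray) -> tuple[float, float, float]:
    """Quadratic trend contrast (coefficient on the squared term)."""
    import statsmodels.api as sm

    lv = np.asarray(levels, dtype=float)
    lv = (lv - lv.mean()) / (lv.std() if lv.std() else 1.0)
    x = sm.add_constant(np.column_stack([lv, lv**2]))
    fit = sm.OLS(np.asarray(values, dtype=float), x).fit()
    return float(fit.params[2]), float(fit.tvalues[2]), float(fit.pvalues[2])


def _resultant_length(phases_rad: np.ndarray) -> float:
    return float(np.abs(np.mean(np.exp(1j * phases_rad))))


def circ_lin_corr(
    x: np.ndarray,
    phase_deg: np.ndarray,
    slope_bound_cycles: float = 2.0,
) -> tuple[float, float, float]:
    """Circular-linear correlation between a linear variable and a phase.

    Fits the regression phase ~ 2*pi*a*x by maximizing the mean resultant
    length over a bounded slope range (|a| <= slope_bound_cycles per unit
    range of x), then computes the circular-circular correlation between the
    measured phase and the fitted phase (Kempter-style estimator).

    Returns (rho, p, slope_deg_per_unit_x).  The coefficient magnitude is
    invariant to a constant phase shift.
    """
    x = np.asarray(x, dtype=float)
    phi = np.radians(np.asarray(phase_deg, dtype=float))
    n = x.size
    if n < 4:
        return np.nan, np.nan, np.nan
    span = x.max() - x.min()
    if span <= 0:
        return 0.0, 1.0, 0.0
    bound = slope_bound_cycles / span

    def neg_r(a: float) -> float:
        return -_resultant_length(phi - 2 * np.pi * a * x)

    grid = np.linspace(-bound, bound, 257)
    r_grid = [-neg_r(a) for a in grid]
    a0 = grid[int(np.argmax(r_grid))]
    res = optimize.minimize_scalar(
        neg_r, bounds=(max(-bound, a0 - 2 * bound / 256), min(bound, a0 + 2 * bound / 256)),
        method="bounded",
    )
    a = float(res.x)

    # correlate against the phase predicted by the |slope| ramp so the sign
    # of rho carries the direction of the phase shift (negative = precession)
    theta = np.mod(2 * np.pi * abs(a) * x, 2 * np.pi)
    # circular means
    phi_bar = np.angle(np.mean(np.exp(1j * phi)))
    theta_bar = np.angle(np.mean(np.exp(1j * theta)))
    sp = np.sin(phi - phi_bar)
    st = np.sin(theta - theta_bar)
    denom = np.sqrt(np.sum(sp**2) * np.sum(st**2))
    if denom == 0:
        return 0.0, 1.0, float(np.degrees(2 * np.pi * a))
    rho = float(np.sum(sp * st) / denom)
    # asymptotic p (Jammalamadaka & SenGupta)
    l20 = np.mean(sp**2)
    l02 = np.mean(st**2)
    l22 = np.mean(sp**2 * st**2)
    if l22 <= 0:
        return rho, 1.0, float(np.degrees(2 * np.pi * a))
    z = rho * np.sqrt(n * l20 * l02 / l22)
    p = float(2 * stats.norm.sf(abs(z)))
    return rho, p, float(np.degrees(2 * np.pi * a))
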