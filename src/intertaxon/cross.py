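"""Postzygotic reproductive isolation from tetrad dissections.

Spore viability is (viable spores / dissected spores) x 100 with an exact
Clopper-Pearson 95% interval, classified against configurable thresholds
(default: below 20% reproductively isolated, above 50% compatible, between
the two partial isolation). Viability is regressed on nucleotide identity
(percent) by ordinary least squares, reporting slope, intercept, R-squared,
adjusted R-squared and the two-sided t-test p-value for the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CrossRecord:
    parent_a: str
    parent_b: str
    dissected: int
    viable: int
    viability: float  # percent
    ci_low: float  # percent, 95% exact
    ci_high: float


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    n_points: int


def viability(
    viable: int, dissected: int, parent_a: str = "A", parent_b: str = "B"
) -> CrossRecord:
    """Spore viability percent with a Clopper-Pearson 95% interval."""
    if dissected < 1:
        raise ValueError("dissected must be >= 1")
    if not 0 <= viable <= dissected:
        raise ValueError("viable must lie in [0, dissected]")
    pct = 100.0 * viable / dissected
    lo = 0.0 if viable == 0 else float(stats.beta.ppf(0.025, viable, dissected - viable + 1))
    hi = 1.0 if viable == dissected else float(
        stats.beta.ppf(0.975, viable + 1, dissected - viable)
    )
    return CrossRecord(parent_a, parent_b, dissected, viable, pct, 100.0 * lo, 100.0 * hi)


def fit_viability_regression(points: list[tuple[float, float]]) -> RegressionFit:
    """OLS of viability (%) on nucleotide identity (%).

    adj R^2 = 1 - (1 - R^2)(n-1)/(n-2) for the single predictor; the slope
    p-value is the two-sided t test with n-2 degrees of freedom.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("identity values are all equal; regression undefined")
    res = stats.linregress(x, y)
    n = len(points)
    r2 = 0.0 if np.isnan(res.rvalue) else res.rvalue**2  # flat response: r = 0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        adj_r_squared=float(1.0 - (1.0 - r2) * (n - 1) / (n - 2)),
        p_value=1.0 if np.isnan(res.pvalue) else float(res.pvalue),
        n_points=n,
    )


def isolation_class(
    viability_pct: float, isolated_below: float = 20.0, conspecific_above: float = 50.0
) -> str:
    """Reproductive-isolation label from the viability percentage."""
    if isolated_below >= conspecific_above:
        raise ValueError("isolated_below must be < conspecific_above")
    if not 0.0 <= viability_pct <= 100.0:
        raise ValueError("viability must lie in [0, 100]")
    if viability_pct < isolated_below:
        return "reproductively isolated"
    if viability_pct > conspecific_above:
        return "compatible"
    return "partial isolation"
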