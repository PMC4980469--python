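"""Effect sizes from p-values and the stratum heterogeneity contrast.

Permutation tests yield p-values but no effect estimates; the
normal-deviate conversion recovers a Cohen's d from a two-sided p and the
sample size:

    z = Phi^-1(1 - p/2),   d = 2 z / sqrt(n),
    se_d = sqrt(4/n + d^2 / (2 n)),   CI = d +/- 1.96 se_d.

Two strata are compared with the fixed-effect heterogeneity statistic
Q = (d_a - d_b)^2 / (se_a^2 + se_b^2) on 1 degree of freedom — an
indirect interaction test that takes the stratum sample sizes into
account.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats


@dataclasses.dataclass
class EffectEstimate:
    """Cohen's d with its standard error and 95% confidence interval."""

    d: float
    se_d: float
    ci_low: float
    ci_high: float
    source_p: float
    n: int


@dataclasses.dataclass
class StratumContrast:
    """Fixed-effect heterogeneity contrast between two effect estimates."""

    d_a: EffectEstimate
    d_b: EffectEstimate
    Q: float
    df: int
    p_contrast: float


def p_to_d(p: float, n: int) -> EffectEstimate:
    """Convert a two-sided p-value and sample size to Cohen's d.

    The conversion is sign-free (permutation p-values carry no direction):
    d is non-negative, strictly decreasing in p for fixed n and shrinking
    with n for fixed p < 1.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if n < 2:
        raise ValueError("n must be >= 2")
    z = stats.norm.ppf(1.0 - p / 2.0)
    d = 2.0 * z / np.sqrt(n)
    se = np.sqrt(4.0 / n + d * d / (2.0 * n))
    return EffectEstimate(
        d=float(d),
        se_d=float(se),
        ci_low=float(d - 1.96 * se),
        ci_high=float(d + 1.96 * se),
        source_p=float(p),
        n=int(n),
    )


def q_contrast(est_a: EffectEstimate, est_b: EffectEstimate) -> StratumContrast:
    """Heterogeneity Q between two strata, chi-square(1) upper-tail p."""
    var = est_a.se_d**2 + est_b.se_d**2
    q = (est_a.d - est_b.d) ** 2 / var
    return StratumContrast(
        d_a=est_a,
        d_b=est_b,
        Q=float(q),
        df=1,
        p_contrast=float(stats.chi2.sf(q, df=1)),
    )


@dataclasses.dataclass
class PhiResult:
    phi: float
    chi2: float
    n: int
    p: float


def phi_coefficient(table) -> PhiResult:
    """phi coefficient and Pearson chi-square of a 2x2 count table.

    phi = (ad - bc) / sqrt(product of margins); chi2 = n * phi^2.
    A zero margin leaves the association undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    (a, b), (c, d) = t
    n = t.sum()
    margins = np.array([a + b, c + d, a + c, b + d])
    if (margins == 0).any():
        raise ValueError("zero margin: phi undefined")
    phi = (a * d - b * c) / np.sqrt(np.prod(margins))
    chi2 = n * phi * phi
    return PhiResult(float(phi), float(chi2), int(n), float(stats.chi2.sf(chi2, df=1)))
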