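"""Cohort-level inference: correlations with AQ, JZS Bayes factors,
partial and compared correlations, reliability and disattenuation.

Evidence is summarized as lgBF, the base-10 logarithm of the Bayes factor
BF10 = p(data | H1) / p(data | H0); |lgBF| > 0.5 is conventionally
substantial evidence. The correlation Bayes factor is the default two-sided
JZS form (Jeffreys-Zellner-Siow prior on the regression slope, obtained by
integrating the g-prior against an inverse-chi-square mixing density),
which depends on the data only through (r, n):

    BF10 = sqrt(n/2) / Gamma(1/2) *
           Integral_0^inf (1+g)^((n-2)/2) [1+(1-r^2) g]^(-(n-1)/2)
                          g^(-3/2) exp(-n/(2g)) dg

The two-sample Bayes factor places a Cauchy(0, rscale) prior on the
standardized group difference and integrates the noncentral-t likelihood.
Both are evaluated by adaptive quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import integrate, special, stats as sps

__all__ = [
    "CorrelationResult", "ReliabilityResult",
    "lgbf_from_r", "lgbf_ttest", "pearson_with_evidence",
    "partial_correlation", "compare_correlations",
    "spearman_brown", "disattenuate", "reliability_suite",
]

DEFAULT_TTEST_SCALE = math.sqrt(2.0) / 2.0


@dataclass
class CorrelationResult:
    r: float
    ci95: Tuple[float, float]
    p: float
    lgbf: Optional[float]
    n: int

    def __str__(self) -> str:
        lg = f", lgBF = {self.lgbf:.2f}" if self.lgbf is not None else ""
        return (f"r = {self.r:.2f} [{self.ci95[0]:.2f}, {self.ci95[1]:.2f}], "
                f"p = {self.p:.3g}{lg} (n = {self.n})")


@dataclass
class ReliabilityResult:
    """Reliability of one index across splits and experiments."""

    split_half: float            # odd vs even trials, across participants
    split_half_boosted: float    # Spearman-Brown corrected to full length
    test_retest: float           # main vs no-report experiment
    disattenuated: float         # test-retest corrected for unreliability
    flagged: bool = False        # disattenuated estimate left the [-1, 1] range


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def lgbf_from_r(r: float, n: int) -> float:
    """Base-10 log of the default JZS correlation Bayes factor.

    Depends only on the sufficient statistics (r, n); symmetric in the sign
    of r and monotone increasing in |r| at fixed n. |r| = 1 returns +inf.
    """
    if n < 3:
        raise ValueError("n must be at least 3")
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError("r must lie in [-1, 1]")
    r2 = r * r
    if 1.0 - r2 < 1e-12:       # numerically perfect correlation: divergent
        return math.inf

    def log_integrand(g: float) -> float:
        return (0.5 * (n - 2) * math.log1p(g)
                - 0.5 * (n - 1) * math.log1p((1.0 - r2) * g)
                - 1.5 * math.log(g) - n / (2.0 * g))

    # peak-normalized integrand keeps the quadrature well-scaled at large n
    gs = np.exp(np.linspace(math.log(1e-3), math.log(1e6), 400))
    logs = np.array([log_integrand(g) for g in gs])
    m = float(logs.max())
    val, _ = integrate.quad(lambda g: math.exp(log_integrand(g) - m),
                            0.0, np.inf, limit=400)
    log_bf = (0.5 * math.log(n / 2.0) - math.log(special.gamma(0.5))
              + m + math.log(val))
    return log_bf / math.log(10.0)


def lgbf_ttest(t: float, n1: int, n2: int,
               scale: float = DEFAULT_TTEST_SCALE) -> float:
    """Base-10 log of the JZS two-sample Bayes factor from a t statistic.

    Cauchy(0, ``scale``) prior on the standardized effect size; the default
    scale is sqrt(2)/2. Effective sample size N = n1*n2/(n1+n2), df = n1+n2-2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both group sizes must be at least 2")
    N = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2
    sqrtN = math.sqrt(N)

    def integrand(d: float) -> float:
        return sps.nct.pdf(t, nu, d * sqrtN) * sps.cauchy.pdf(d, 0.0, scale)

    num, _ = integrate.quad(integrand, -np.inf, np.inf, limit=400)
    return math.log10(num / sps.t.pdf(t, nu))


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def _fisher_ci(r: float, n: int, df_offset: int = 3) -> Tuple[float, float]:
    if n - df_offset <= 0:     # too few points for a Fisher-z interval
        return -1.0, 1.0
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - df_offset)
    lo, hi = z - 1.959963984540054 * se, z + 1.959963984540054 * se
    return math.tanh(lo), math.tanh(hi)


def pearson_with_evidence(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with 95% CI (Fisher z), two-sided p (t transform) and lgBF."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = sps.pearsonr(x, y)
    r = float(r)
    lg = lgbf_from_r(r, n) if abs(r) < 1 else math.inf
    return CorrelationResult(r=r, ci95=_fisher_ci(r, n), p=float(p), lgbf=lg, n=n)


def partial_correlation(x, y, covariate) -> CorrelationResult:
    """First-order partial correlation of x and y controlling one covariate.

    Standard residual formula; p from the t transform with n-3 df, CI via
    Fisher z with the reduced effective sample size. No Bayes factor is
    attached (the JZS form above is defined for the simple correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[ok], y[ok], z[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete triples")
    rxy = float(np.corrcoef(x, y)[0, 1])
    rxz = float(np.corrcoef(x, z)[0, 1])
    ryz = float(np.corrcoef(y, z)[0, 1])
    denom = math.sqrt((1.0 - rxz ** 2) * (1.0 - ryz ** 2))
    if denom == 0:
        raise ValueError("covariate collinear with x or y; partial r undefined")
    r = (rxy - rxz * ryz) / denom
    df = n - 3
    tstat = r * math.sqrt(df) / math.sqrt(max(1.0 - r * r, 1e-300))
    p = 2.0 * sps.t.sf(abs(tstat), df)
    return CorrelationResult(r=r, ci95=_fisher_ci(r, n, df_offset=4),
                             p=float(p), lgbf=None, n=n)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> Tuple[float, float]:
    """Fisher z comparison of two independent correlations -> (z, two-sided p)."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both samples must exceed n = 3")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    return z, 2.0 * sps.norm.sf(abs(z))


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

def spearman_brown(r_half: float, k: float = 2.0) -> float:
    """Reliability of a k-times longer test from the half-test correlation."""
    if not -1.0 < r_half < 1.0:
        raise ValueError("r_half must lie in (-1, 1)")
    return k * r_half / (1.0 + (k - 1.0) * r_half)


def disattenuate(r_xy: float, rel_x: float, rel_y: float) -> Tuple[float, bool]:
    """Correlation corrected for measurement unreliability.

    Returns (r_xy / sqrt(rel_x * rel_y), flagged) where ``flagged`` marks a
    corrected value outside [-1, 1]; the value is reported unclipped.
    """
    if rel_x <= 0 or rel_y <= 0:
        raise ValueError("reliabilities must be positive")
    r = r_xy / math.sqrt(rel_x * rel_y)
    return r, abs(r) > 1.0


def _pearson_safe(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        return float("nan")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def reliability_suite(odd_main, even_main, odd_retest, even_retest,
                      main_index, retest_index) -> ReliabilityResult:
    """Reliability of one index combining split-half and test-retest designs.

    ``odd_*``/``even_*`` are per-participant index values from odd and even
    trials in each experiment (main and retest/no-report); ``main_index``
    and ``retest_index`` are full-data values over the shared participants,
    in matched order. Split-half pools both experiments' (odd, even) pairs
    as separate data points; the disattenuated test-retest correlation uses
    each experiment's Spearman-Brown boosted split-half reliability.
    """
    odd = np.concatenate([np.asarray(odd_main, float), np.asarray(odd_retest, float)])
    even = np.concatenate([np.asarray(even_main, float), np.asarray(even_retest, float)])
    split = _pearson_safe(odd, even)
    boosted = spearman_brown(split) if np.isfinite(split) and abs(split) < 1 \
        else split
    retest = _pearson_safe(np.asarray(main_index, float),
                           np.asarray(retest_index, float))
    rel_m = _pearson_safe(np.asarray(odd_main, float), np.asarray(even_main, float))
    rel_r = _pearson_safe(np.asarray(odd_retest, float), np.asarray(even_retest, float))

    def boost(r):
        if not np.isfinite(r) or abs(r) >= 1:
            return r
        return spearman_brown(r)

    rel_m, rel_r = boost(rel_m), boost(rel_r)
    if np.isfinite(retest) and rel_m > 0 and rel_r > 0:
        dis, flagged = disattenuate(retest, rel_m, rel_r)
    else:
        dis, flagged = float("nan"), False
    return ReliabilityResult(split_half=split, split_half_boosted=boosted,
                             test_retest=retest, disattenuated=dis, flagged=flagged)
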