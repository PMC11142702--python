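"""Cross-dataset meta-analysis, BH-FDR correction and MR power.

The meta-analysis pools log-scale estimates by inverse variance; the model
follows the I² rule common in replication MR: fixed-effect when I² < 50%,
DerSimonian–Laird random-effects otherwise. Printed OR/CI triplets can be
converted back to (beta, se) so published results are directly poolable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm

from .uvmr import Z95, _p_two_sided


@dataclass
class MetaResult:
    """Pooled estimate across k studies."""

    model: str  # "fixed" | "random"
    beta: float
    se: float
    p: float
    q: float
    i2: float
    k: int
    tau2: float = 0.0

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)


def estimate_from_or_ci(or_: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Recover (log-OR, se) from a printed OR with 95% CI.

    Assumes the CI is symmetric on the log scale: se = (ln hi − ln lo)/(2·z).
    """
    if not 0 < ci_low <= or_ <= ci_high:
        raise ValueError(f"need 0 < ci_low <= or <= ci_high, got ({or_}, {ci_low}, {ci_high})")
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
    if se <= 0:
        raise ValueError("degenerate CI with zero width")
    return math.log(or_), se


def meta_analyze(estimates: Sequence[tuple[float, float]], i2_random_threshold: float = 0.5) -> MetaResult:
    """Inverse-variance meta-analysis with the I² model rule.

    ``estimates`` is a list of (beta, se) on the log scale. The
    fixed-effect pooled estimate, Cochran's Q and I² are always computed;
    when I² >= ``i2_random_threshold`` (default 50%) the reported model
    switches to DerSimonian–Laird random effects with
    τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)).
    """
    if len(estimates) < 2:
        raise ValueError("meta-analysis needs >=2 studies")
    b = np.array([e[0] for e in estimates], dtype=float)
    s = np.array([e[1] for e in estimates], dtype=float)
    if (s <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    beta_fe = float(np.sum(w * b) / np.sum(w))
    se_fe = math.sqrt(1.0 / float(np.sum(w)))
    q = float(np.sum(w * (b - beta_fe) ** 2))
    k = len(estimates)
    df = k - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0

    if i2 < i2_random_threshold:
        beta, se, model, tau2 = beta_fe, se_fe, "fixed", 0.0
    else:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        wr = 1.0 / (s**2 + tau2)
        beta = float(np.sum(wr * b) / np.sum(wr))
        se = math.sqrt(1.0 / float(np.sum(wr)))
        model = "random"
    return MetaResult(model, beta, se, _p_two_sided(beta / se), q, i2, k, tau2)


def bh_fdr(pvals: Sequence[float], family_size: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``family_size`` lets the caller declare a larger testing family than
    the p-values supplied (unlisted members assumed non-significant);
    the multiplier then uses the family size with ranks among the listed
    values — an explicit, documented approximation. Defaults to the number
    of p-values supplied.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = family_size if family_size is not None else p.size
    if m < p.size:
        raise ValueError("family_size must be >= number of p-values")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(adjusted, None, 1.0, out=adjusted)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def mr_power_binary(
    n: float,
    r2_xz: float,
    case_fraction: float,
    or_: float,
    alpha: float = 0.05,
) -> float:
    """Approximate power of an MR test with a binary outcome.

    Uses the asymptotic variance of the IV log-OR estimate,
    Var ≈ 1/(n·R²·K(1−K)): power = Φ(√(n·R²·K(1−K))·|ln OR| − z₁₋α/₂)
    for outcome sample size ``n``, instrument variance explained
    ``r2_xz``, case fraction ``K`` and hypothesized odds ratio.
    """
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must lie in (0, 1)")
    if not 0 <= r2_xz < 1:
        raise ValueError("r2_xz must lie in [0, 1)")
    if n <= 0 or or_ <= 0:
        raise ValueError("n and or_ must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    b = abs(math.log(or_))
    ncp = math.sqrt(n * r2_xz * case_fraction * (1.0 - case_fraction)) * b
    return float(norm.cdf(ncp - norm.ppf(1.0 - alpha / 2.0)))
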