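"""Univariable two-sample MR estimators.

All estimators consume harmonized :class:`~mrkit.instruments.InstrumentRecord`
lists and return :class:`MREstimate` objects on the log-effect scale with a
95% normal-theory interval on the odds-ratio scale. The primary estimator is
multiplicative random-effects IVW; MR-Egger, the weighted median and a
constrained-maximum-likelihood (cML) estimator with BIC selection of the
number of invalid instruments provide pleiotropy-robust complements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2, norm

from .instruments import InstrumentRecord

#: normal 97.5% quantile used for every 95% interval in the package
Z95 = 1.959964


@dataclass
class MREstimate:
    """One method's causal estimate.

    ``beta`` is the causal log-effect per unit of exposure; ``or_`` its
    exponential with a 95% CI; ``extra`` carries method-specific fields
    (e.g. ``egger_intercept``, ``cml_k_invalid``).
    """

    method: str
    beta: float
    se: float
    p: float
    n_snp: int
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n_snp": self.n_snp,
            **self.extra,
        }


def _xysw(records: Sequence[InstrumentRecord]):
    x = np.array([r.exposure_beta for r in records], dtype=float)
    y = np.array([r.outcome_beta for r in records], dtype=float)
    sx = np.array([r.exposure_se for r in records], dtype=float)
    sy = np.array([r.outcome_se for r in records], dtype=float)
    return x, y, sx, sy


def _p_two_sided(z: float) -> float:
    return float(min(1.0, max(np.nextafter(0, 1), 2.0 * norm.sf(abs(z)))))


def wald_ratio(rec: InstrumentRecord) -> MREstimate:
    """Single-SNP causal estimate: outcome beta over exposure beta.

    The first-order standard error σy/|βx| ignores exposure-beta noise, the
    convention for genome-wide significant instruments.
    """
    if rec.exposure_beta == 0:
        raise ValueError(f"{rec.variant_id}: exposure beta is 0, Wald ratio undefined")
    beta = rec.outcome_beta / rec.exposure_beta
    se = rec.outcome_se / abs(rec.exposure_beta)
    return MREstimate("wald", beta, se, _p_two_sided(beta / se), 1, {"variant_id": rec.variant_id})


def _ivw_core(x: np.ndarray, y: np.ndarray, sy: np.ndarray):
    """Weighted through-origin regression; returns (beta, fixed se, Q)."""
    w = 1.0 / sy**2
    sxx = float(np.sum(w * x * x))
    beta = float(np.sum(w * x * y)) / sxx
    q = float(np.sum(w * (y - beta * x) ** 2))
    return beta, math.sqrt(1.0 / sxx), q


def ivw(records: Sequence[InstrumentRecord]) -> MREstimate:
    """Multiplicative random-effects inverse-variance-weighted estimate.

    Weighted regression of outcome betas on exposure betas through the
    origin with weights 1/σy²; equivalently the 1/var-weighted mean of the
    per-SNP Wald ratios. The fixed-effect standard error is inflated by
    max(1, √(Q/(J−1))) so heterogeneity widens but never narrows the
    interval.
    """
    if len(records) < 2:
        raise ValueError("ivw needs >=2 instruments; use wald_ratio for a single SNP")
    x, y, _, sy = _xysw(records)
    beta, se_fe, q = _ivw_core(x, y, sy)
    scale = max(1.0, math.sqrt(q / (len(records) - 1)))
    se = se_fe * scale
    return MREstimate(
        "ivw_mre",
        beta,
        se,
        _p_two_sided(beta / se),
        len(records),
        {"q": q, "q_df": len(records) - 1, "overdispersion": scale},
    )


def egger(records: Sequence[InstrumentRecord]) -> MREstimate:
    """MR-Egger: weighted regression with a pleiotropy intercept.

    Exposure betas are oriented non-negative (outcome betas co-flipped)
    before fitting so the intercept estimates average directional
    pleiotropy; weights are 1/σy² with multiplicative overdispersion on
    J−2 degrees of freedom. The intercept, its se and p are reported in
    ``extra``.
    """
    if len(records) < 3:
        raise ValueError("egger needs >=3 instruments")
    x, y, _, sy = _xysw(records)
    sign = np.where(x < 0, -1.0, 1.0)
    x, y = x * sign, y * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(x), x])
    xtwx = X.T @ (w[:, None] * X)
    if np.linalg.cond(xtwx) > 1e12:
        raise ValueError("degenerate design: exposure betas collinear with the intercept")
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    df = len(records) - 2
    scale = max(1.0, math.sqrt(q / df)) if df > 0 else 1.0
    cov = np.linalg.inv(xtwx) * scale**2
    slope, slope_se = float(coef[1]), math.sqrt(cov[1, 1])
    icpt, icpt_se = float(coef[0]), math.sqrt(cov[0, 0])
    return MREstimate(
        "egger",
        slope,
        slope_se,
        _p_two_sided(slope / slope_se),
        len(records),
        {
            "egger_intercept": icpt,
            "egger_intercept_se": icpt_se,
            "egger_intercept_p": _p_two_sided(icpt / icpt_se),
            "q": q,
            "q_df": df,
            "overdispersion": scale,
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Linear interpolation of the weighted empirical CDF at 0.5."""
    order = np.argsort(ratios)
    b = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(b[0])
    if s[-1] <= 0.5:
        return float(b[-1])
    return float(np.interp(0.5, s, b))


def weighted_median(
    records: Sequence[InstrumentRecord],
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> MREstimate:
    """Weighted-median MR: consistent while valid SNPs carry >50% of weight.

    Wald ratios are ordered and the weighted empirical CDF (cumulative
    weight minus half the SNP's own weight) is interpolated at 0.5, with
    ratio-form weights βx²/σy². The standard error is a seeded parametric
    bootstrap (per-SNP betas redrawn from their sampling normals).
    """
    if len(records) < 3:
        raise ValueError("weighted_median needs >=3 instruments")
    x, y, sx, sy = _xysw(records)
    est = _weighted_median_point(y / x, x**2 / sy**2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boots = np.empty(n_boot)
    xb = rng.normal(x, sx, size=(n_boot, len(x)))
    yb = rng.normal(y, sy, size=(n_boot, len(x)))
    for i in range(n_boot):
        boots[i] = _weighted_median_point(yb[i] / xb[i], xb[i] ** 2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        "weighted_median", est, se, _p_two_sided(est / se), len(records), {"n_boot": n_boot}
    )


def _cml_fit_k(x, y, sx2, sy2, k, theta0, tol=1e-8, maxit=200):
    """Coordinate ascent for a fixed number K of invalid instruments.

    Invalid SNPs carry a free pleiotropy parameter which absorbs their
    outcome residual; profiling the true exposure effects out, each valid
    SNP contributes (βy − θβx)²/(2(σy² + θ²σx²)) to the objective and the
    K invalid SNPs are those with the largest such standardized residuals.
    """
    theta = theta0
    invalid = np.zeros(len(x), dtype=bool)
    for _ in range(maxit):
        resid = (y - theta * x) ** 2 / (sy2 + theta**2 * sx2)
        new_invalid = np.zeros_like(invalid)
        if k > 0:
            new_invalid[np.argsort(resid)[-k:]] = True
        v = ~new_invalid
        if v.sum() < 2:
            return None
        g = (x[v] / sx2[v] + theta * y[v] / sy2[v]) / (1.0 / sx2[v] + theta**2 / sy2[v])
        denom = float(np.sum(g**2 / sy2[v]))
        if denom <= 0:
            return None
        theta_new = float(np.sum(g * y[v] / sy2[v])) / denom
        converged = abs(theta_new - theta) < tol and (new_invalid == invalid).all()
        theta, invalid = theta_new, new_invalid
        if converged:
            break
    else:
        return None

    v = ~invalid
    g = (x[v] / sx2[v] + theta * y[v] / sy2[v]) / (1.0 / sx2[v] + theta**2 / sy2[v])
    negloglik = float(np.sum((x[v] - g) ** 2 / (2 * sx2[v]) + (y[v] - theta * g) ** 2 / (2 * sy2[v])))
    # Observed information for theta with the nuisance exposure effects
    # profiled out (arrowhead Schur complement).
    i_tt = float(np.sum(g**2 / sy2[v]))
    i_tg = (2 * theta * g - y[v]) / sy2[v]
    i_gg = 1.0 / sx2[v] + theta**2 / sy2[v]
    info = i_tt - float(np.sum(i_tg**2 / i_gg))
    se = math.sqrt(1.0 / info) if info > 0 else math.sqrt(1.0 / i_tt)
    return theta, se, negloglik, invalid


def cml(
    records: Sequence[InstrumentRecord],
    n_exposure: float | None = None,
    n_outcome: float | None = None,
    max_k: int | None = None,
    seed: int | None = 0,
) -> MREstimate:
    """Constrained maximum likelihood MR with BIC model selection.

    For each candidate count K of invalid instruments (0..``max_k``) the
    bivariate-normal likelihood of the observed exposure/outcome betas is
    maximized subject to exactly K SNPs carrying free pleiotropy
    parameters; K is chosen by BIC with effective sample size
    min(n_exposure, n_outcome). The selected model's estimate, its
    observed-information standard error, and the invalid set are returned
    (``extra['cml_k_invalid']``).
    """
    if len(records) < 3:
        raise ValueError("cml needs >=3 instruments")
    x, y, sx, sy = _xysw(records)
    sx2, sy2 = sx**2, sy**2
    j = len(records)
    if n_exposure is None:
        n_exposure = float(np.median([r.exposure_n or 0 for r in records])) or float(j)
    if n_outcome is None:
        n_outcome = float(np.median([r.outcome_n or 0 for r in records])) or float(j)
    n_eff = max(2.0, min(n_exposure, n_outcome))
    if max_k is None:
        max_k = max(0, j - 3)
    max_k = min(max_k, j - 2)

    theta0, _, _ = _ivw_core(x, y, sy)
    best = None
    fits = {}
    for k in range(max_k + 1):
        fit = _cml_fit_k(x, y, sx2, sy2, k, theta0)
        if fit is None:
            continue
        theta, se, nll, invalid = fit
        bic = 2.0 * nll + math.log(n_eff) * k
        fits[k] = bic
        if best is None or bic < best[0]:
            best = (bic, k, theta, se, invalid)
    if best is None:
        raise RuntimeError(f"cml failed to converge for every K in 0..{max_k}")
    bic, k_sel, theta, se, invalid = best
    return MREstimate(
        "cml",
        theta,
        se,
        _p_two_sided(theta / se),
        j,
        {
            "cml_k_invalid": k_sel,
            "bic": bic,
            "invalid_ids": [records[i].variant_id for i in np.flatnonzero(invalid)],
        },
    )


def run_uvmr(
    records: Sequence[InstrumentRecord],
    n_boot: int = 1000,
    seed: int | None = 0,
    max_k: int | None = None,
) -> Mapping[str, MREstimate | list[MREstimate]]:
    """Dispatch all applicable estimators for the instrument count at hand.

    J=1: Wald ratio only. J=2: per-SNP Wald ratios plus IVW. J>=3: all of
    IVW, MR-Egger, weighted median and cML, plus the per-SNP Wald table.
    """
    if not records:
        raise ValueError("no instrument records supplied")
    j = len(records)
    if j == 1:
        return {"wald": wald_ratio(records[0])}
    out: dict[str, MREstimate | list[MREstimate]] = {
        "wald": [wald_ratio(r) for r in records],
        "ivw_mre": ivw(records),
    }
    if j >= 3:
        out["egger"] = egger(records)
        out["weighted_median"] = weighted_median(records, n_boot=n_boot, seed=seed)
        out["cml"] = cml(records, max_k=max_k, seed=seed)
    return out


def q_statistic(records: Sequence[InstrumentRecord]) -> tuple[float, int, float]:
    """Cochran's Q about the IVW fit: (Q, df, upper-tail p)."""
    if len(records) < 2:
        raise ValueError("Q needs >=2 instruments")
    x, y, _, sy = _xysw(records)
    _, _, q = _ivw_core(x, y, sy)
    df = len(records) - 1
    return q, df, float(chi2.sf(q, df))
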