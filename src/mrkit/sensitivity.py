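"""Heterogeneity, pleiotropy and influence diagnostics for univariable MR.

Covers Cochran's Q / I² heterogeneity, the MR-Egger intercept test for
directional pleiotropy, the simulation-based MR-PRESSO global/outlier/
distortion tests, and leave-one-out influence analysis, plus plot-ready
funnel and LOO tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .instruments import InstrumentRecord
from .uvmr import MREstimate, egger, ivw, q_statistic

logger = logging.getLogger("mrkit.sensitivity")


@dataclass
class SensitivityReport:
    """Bundle of diagnostics for one instrument set."""

    q: float
    q_df: int
    q_p: float
    i2: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_p: float | None = None
    presso_corrected: MREstimate | None = None
    loo: list[MREstimate] = field(default_factory=list)


def _i2(q: float, q_df: int) -> float:
    return max(0.0, (q - q_df) / q) if q > 0 else 0.0


def cochran_q(records: Sequence[InstrumentRecord]) -> tuple[float, int, float, float]:
    """Cochran's Q about the IVW fit, with I² = max(0, (Q − df)/Q)."""
    q, df, p = q_statistic(records)
    return q, df, p, _i2(q, df)


def egger_intercept_test(records: Sequence[InstrumentRecord]) -> tuple[float, float, float]:
    """MR-Egger intercept, its se and two-sided p.

    p < 0.05 flags directional pleiotropy; the caller interprets.
    """
    fit = egger(records)
    return fit.extra["egger_intercept"], fit.extra["egger_intercept_se"], fit.extra["egger_intercept_p"]


def _loo_thetas(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out through-origin WLS slopes, vectorized.

    Works on 1-D arrays or row-wise on 2-D (n_sim, J) arrays.
    """
    sxy = np.sum(w * x * y, axis=-1, keepdims=True)
    sxx = np.sum(w * x * x, axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    records: Sequence[InstrumentRecord],
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    significance: float = 0.05,
    seed: int | np.random.Generator | None = 0,
) -> tuple[float, list[str], float | None, MREstimate]:
    """MR-PRESSO global, outlier and distortion tests.

    The global test compares the observed residual sum of squares of the
    leave-one-out IVW fits, Σⱼ wⱼ(βyⱼ − θ̂₋ⱼ βxⱼ)², against its null
    distribution from ``n_sim`` parametric simulations under the fitted
    model (betas redrawn from their sampling normals around the
    leave-one-out expectations). Per-SNP outlier p-values compare each
    observed residual to its simulated distribution, Bonferroni-adjusted
    across SNPs; flagged outliers are removed iteratively while the global
    p stays below ``significance``. The distortion test compares the
    before/after IVW estimates against distortions from removing equally
    many random SNPs.

    Returns ``(global_p, outliers, distortion_p, corrected)`` where
    ``corrected`` is the IVW estimate on the retained set. The distortion
    p is None when no outlier was removed.
    """
    if len(records) < 4:
        raise ValueError("mr_presso needs >=4 instruments")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    recs = list(records)

    retained = recs
    outliers: list[str] = []
    global_p: float | None = None
    while True:
        round_p, snp_p = _presso_round(retained, n_sim, rng)
        if global_p is None:
            global_p = round_p  # reported p is the initial global test
        if round_p >= significance:
            break
        flag = np.flatnonzero(snp_p * len(retained) < outlier_alpha)
        if flag.size == 0:
            logger.warning(
                "MR-PRESSO global p=%.4g but no individual outlier reaches "
                "Bonferroni significance; unresolved horizontal pleiotropy",
                round_p,
            )
            break
        outliers.extend(retained[i].variant_id for i in flag)
        retained = [r for i, r in enumerate(retained) if i not in set(flag)]
        if len(retained) < 4:
            if len(retained) < 2:
                raise RuntimeError("MR-PRESSO: no instruments survive outlier removal")
            break

    corrected = ivw(retained)
    distortion_p = None
    if outliers:
        distortion_p = _distortion_test(recs, outliers, corrected.beta, n_sim, rng)
    return global_p, outliers, distortion_p, corrected


def _presso_round(records, n_sim, rng):
    x = np.array([r.exposure_beta for r in records])
    y = np.array([r.outcome_beta for r in records])
    sx = np.array([r.exposure_se for r in records])
    sy = np.array([r.outcome_se for r in records])
    w = 1.0 / sy**2

    theta_loo = np.squeeze(_loo_thetas(x, y, w))
    d_obs = w * (y - theta_loo * x) ** 2
    rss_obs = float(d_obs.sum())

    xs = rng.normal(x, sx, size=(n_sim, x.size))
    ys = rng.normal(theta_loo * x, sy, size=(n_sim, x.size))
    theta_loo_s = _loo_thetas(xs, ys, w)
    d_sim = w * (ys - theta_loo_s * xs) ** 2
    rss_sim = d_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))
    # Per-SNP outlier p as the plain empirical proportion (minimum 0), so a
    # residual beyond every simulation stays flaggable after Bonferroni at
    # any simulation count; the global p keeps the +1 smoothing.
    snp_p = np.mean(d_sim >= d_obs, axis=0)
    return global_p, snp_p


def _distortion_test(all_records, outlier_ids, beta_after, n_sim, rng):
    """Is the outlier-removal shift larger than random removals produce?"""
    beta_before = ivw(all_records).beta
    if beta_before == 0:
        return None
    obs = (beta_after - beta_before) / abs(beta_before)
    j, k = len(all_records), len(outlier_ids)
    if j - k < 2:
        return None
    sims = np.empty(n_sim)
    idx = np.arange(j)
    for s in range(n_sim):
        keep = rng.choice(idx, size=j - k, replace=False)
        sims[s] = (ivw([all_records[i] for i in keep]).beta - beta_before) / abs(beta_before)
    return float((1 + np.sum(np.abs(sims) >= abs(obs))) / (1 + n_sim))


def leave_one_out(records: Sequence[InstrumentRecord]) -> list[MREstimate]:
    """IVW re-estimated J times, each omitting one SNP.

    Each estimate's ``extra['omitted']`` names the left-out variant.
    """
    if len(records) < 3:
        raise ValueError("leave_one_out needs >=3 instruments")
    out = []
    for i in range(len(records)):
        est = ivw([r for j, r in enumerate(records) if j != i])
        est.extra["omitted"] = records[i].variant_id
        out.append(est)
    return out


def sensitivity_report(
    records: Sequence[InstrumentRecord],
    n_sim: int = 1000,
    seed: int | None = 0,
    run_presso: bool = True,
) -> SensitivityReport:
    """Run every applicable diagnostic for the instrument count at hand."""
    q, df, qp, i2 = cochran_q(records)
    rep = SensitivityReport(q=q, q_df=df, q_p=qp, i2=i2)
    if len(records) >= 3:
        rep.egger_intercept, rep.egger_intercept_se, rep.egger_intercept_p = egger_intercept_test(records)
        rep.loo = leave_one_out(records)
    if run_presso and len(records) >= 4:
        gp, outl, dp, corr = mr_presso(records, n_sim=n_sim, seed=seed)
        rep.presso_global_p, rep.presso_outliers = gp, outl
        rep.presso_distortion_p, rep.presso_corrected = dp, corr
    return rep


def funnel_table(records: Sequence[InstrumentRecord]) -> pd.DataFrame:
    """Plot-ready funnel data: per-SNP Wald ratio against its precision."""
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "wald_ratio": [r.wald for r in records],
            "precision": [abs(r.exposure_beta) / r.outcome_se for r in records],
        }
    )


def loo_table(loo: Sequence[MREstimate]) -> pd.DataFrame:
    """Plot-ready leave-one-out table (one row per omitted SNP)."""
    return pd.DataFrame(
        [
            {
                "omitted": e.extra.get("omitted"),
                "beta": e.beta,
                "se": e.se,
                "or": e.or_,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p": e.p,
            }
            for e in loo
        ]
    )
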