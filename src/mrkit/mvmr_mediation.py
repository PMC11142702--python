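"""Multivariable MR and two-step mediation decomposition.

MVMR regresses outcome betas jointly on several exposures' betas to
estimate each exposure's direct effect conditional on the others. The
mediation module decomposes a total causal effect into direct and
indirect (mediated) components, by the difference method
(indirect = total − direct) or the product-of-coefficients method, with
the proportion mediated and delta-method uncertainty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .instruments import InstrumentRecord, harmonize
from .io import SummaryStatSet
from .uvmr import MREstimate, Z95, _p_two_sided

logger = logging.getLogger("mrkit.mvmr")


@dataclass
class MVMRResult:
    """Per-exposure direct effects from one joint fit."""

    exposures: list[str]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n_snp: int
    overdispersion: float = 1.0

    def estimate(self, exposure: str) -> MREstimate:
        i = self.exposures.index(exposure)
        return MREstimate(
            "mvmr_ivw",
            float(self.beta[i]),
            float(self.se[i]),
            float(self.p[i]),
            self.n_snp,
            {"exposure": exposure, "conditional_on": [e for e in self.exposures if e != exposure]},
        )

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposures,
                "n_snp": self.n_snp,
                "beta": self.beta,
                "se": self.se,
                "or": np.exp(self.beta),
                "ci_low": np.exp(self.beta - Z95 * self.se),
                "ci_high": np.exp(self.beta + Z95 * self.se),
                "p": self.p,
            }
        )


def mvmr_ivw(
    exposure_betas: pd.DataFrame | np.ndarray,
    outcome_beta: Sequence[float],
    outcome_se: Sequence[float],
    exposures: Sequence[str] | None = None,
) -> MVMRResult:
    """Multivariable IVW: weighted multi-exposure regression, no intercept.

    ``exposure_betas`` is a (J SNPs × E exposures) matrix (DataFrame column
    names label the exposures); weights are 1/σy². Standard errors carry a
    multiplicative overdispersion factor max(1, √(Q/(J−E))).

    Raises ValueError on a rank-deficient exposure matrix (naming the
    collinear exposures) or J < E + 2.
    """
    if isinstance(exposure_betas, pd.DataFrame):
        exposures = exposures or [str(c) for c in exposure_betas.columns]
        X = exposure_betas.to_numpy(dtype=float)
    else:
        X = np.asarray(exposure_betas, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        exposures = list(exposures) if exposures else [f"x{i+1}" for i in range(X.shape[1])]
    y = np.asarray(outcome_beta, dtype=float)
    sy = np.asarray(outcome_se, dtype=float)
    j, e = X.shape
    if j < e + 2:
        raise ValueError(f"need at least {e + 2} SNPs for {e} exposures, got {j}")
    if np.linalg.matrix_rank(X) < e:
        norms = np.linalg.norm(X, axis=0)
        suspect = [exposures[i] for i in np.flatnonzero(norms < 1e-12 * max(norms.max(), 1.0))]
        raise ValueError(
            "rank-deficient exposure matrix"
            + (f": zero/collinear exposures {suspect}" if suspect else f" over {exposures}")
        )
    w = 1.0 / sy**2
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(q / (j - e))) if j > e else 1.0
    cov = np.linalg.inv(xtwx) * scale**2
    se = np.sqrt(np.diag(cov))
    p = 2.0 * norm.sf(np.abs(coef / se))
    return MVMRResult(list(exposures), coef, se, p, j, scale)


def _align_to_anchor(rec: InstrumentRecord, anchor: InstrumentRecord) -> InstrumentRecord | None:
    """Re-express a record on the anchor's effect allele, or None if alien."""
    from .io import complement

    if (rec.effect_allele, rec.other_allele) == (anchor.effect_allele, anchor.other_allele):
        return rec
    flipped = rec.flipped()
    if (flipped.effect_allele, flipped.other_allele) == (anchor.effect_allele, anchor.other_allele):
        return flipped
    comp = (complement(rec.effect_allele), complement(rec.other_allele))
    if comp == (anchor.effect_allele, anchor.other_allele):
        return rec
    if comp == (anchor.other_allele, anchor.effect_allele):
        return rec.flipped()
    return None


def build_mvmr_table(
    exposure_sets: Mapping[str, SummaryStatSet],
    outcome: SummaryStatSet,
    snps: Sequence[str],
    **harmonize_kwargs,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Harmonize several exposures and one outcome onto shared alleles.

    ``snps`` is typically the union of each exposure's clumped genome-wide
    hits. Every exposure is harmonized to the outcome; the first exposure's
    allele coding anchors the rest. SNPs missing from any study are
    dropped. Returns ``(exposure_beta_frame, outcome_beta, outcome_se)``
    indexed by variant_id.
    """
    labels = list(exposure_sets)
    per_exposure: dict[str, dict[str, InstrumentRecord]] = {}
    for label in labels:
        recs, _ = harmonize(exposure_sets[label], outcome, snps, **harmonize_kwargs)
        per_exposure[label] = {r.variant_id: r for r in recs}
    shared = [
        v for v in snps if all(v in per_exposure[label] for label in labels)
    ]
    if not shared:
        raise ValueError("no SNPs shared across all exposures and the outcome")
    rows, ybeta, yse, kept_ids = [], [], [], []
    for v in shared:
        anchor = per_exposure[labels[0]][v]
        betas = {labels[0]: anchor.exposure_beta}
        ok = True
        for label in labels[1:]:
            aligned = _align_to_anchor(per_exposure[label][v], anchor)
            if aligned is None:
                ok = False
                break
            betas[label] = aligned.exposure_beta
        if not ok:
            logger.info("%s: irreconcilable alleles across exposures; dropped", v)
            continue
        rows.append(betas)
        ybeta.append(anchor.outcome_beta)
        yse.append(anchor.outcome_se)
        kept_ids.append(v)
    frame = pd.DataFrame(rows, index=kept_ids, columns=labels)
    return frame, np.asarray(ybeta), np.asarray(yse)


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition with the proportion mediated."""

    total: float
    total_se: float
    direct: float
    direct_se: float
    indirect: float
    indirect_se: float
    proportion: float | None
    proportion_ci: tuple[float, float] | None
    p: float
    method: str

    def indirect_ci(self) -> tuple[float, float]:
        return (self.indirect - Z95 * self.indirect_se, self.indirect + Z95 * self.indirect_se)


def mediation(
    total: tuple[float, float] | MREstimate,
    direct: tuple[float, float] | MREstimate | None = None,
    x_to_m: tuple[float, float] | MREstimate | None = None,
    m_to_y_given_x: tuple[float, float] | MREstimate | None = None,
    method: str = "difference",
    proportion_ci_method: str = "delta",
    n_mc: int = 10_000,
    seed: int | None = 0,
) -> MediationResult:
    """Two-step MR mediation decomposition.

    Difference method: indirect = total − direct with
    se = √(se_total² + se_direct²). Product method:
    indirect = β(x→m)·β(m→y|x) with the first-order delta-method se.
    The proportion mediated is indirect/total with a 95% CI by the delta
    method (default) or, with ``proportion_ci_method='mc'``, by seeded
    Monte-Carlo propagation of the input estimates' sampling normals
    (percentile interval over ``n_mc`` draws); it is None (with a
    warning) when the total effect is zero. The difference-method
    variance treats total and direct estimates as independent, a
    conservative convention for two-sample summary data.
    """
    if proportion_ci_method not in ("delta", "mc"):
        raise ValueError("proportion_ci_method must be 'delta' or 'mc'")

    def unpack(v):
        if v is None:
            return None
        if isinstance(v, MREstimate):
            return v.beta, v.se
        return float(v[0]), float(v[1])

    t, t_se = unpack(total)
    if method == "difference":
        if direct is None:
            raise ValueError("difference method requires the MVMR direct effect")
        d, d_se = unpack(direct)
        ind = t - d
        ind_se = math.sqrt(t_se**2 + d_se**2)
    elif method == "product":
        if x_to_m is None or m_to_y_given_x is None:
            raise ValueError("product method requires x_to_m and m_to_y_given_x")
        a, a_se = unpack(x_to_m)
        b, b_se = unpack(m_to_y_given_x)
        ind = a * b
        ind_se = math.sqrt(a**2 * b_se**2 + b**2 * a_se**2)
        d, d_se = unpack(direct) if direct is not None else (t - ind, math.nan)
    else:
        raise ValueError("method must be 'difference' or 'product'")

    p = _p_two_sided(ind / ind_se) if ind_se > 0 else 1.0
    if t == 0:
        logger.warning("total effect is zero; proportion mediated undefined")
        prop, prop_ci = None, None
    else:
        prop = ind / t
        if proportion_ci_method == "mc":
            rng = np.random.default_rng(seed)
            ts = rng.normal(t, t_se, n_mc)
            if method == "difference":
                ds = rng.normal(d, d_se, n_mc)
                props = (ts - ds) / ts
            else:
                inds = rng.normal(a, a_se, n_mc) * rng.normal(b, b_se, n_mc)
                props = inds / ts
            prop_ci = tuple(np.percentile(props, [2.5, 97.5]))
        else:
            if method == "difference":
                # prop = 1 − direct/total; total and direct taken independent.
                var = (d / t**2) ** 2 * t_se**2 + (1.0 / t) ** 2 * d_se**2
            else:
                var = (1.0 / t) ** 2 * ind_se**2 + (ind / t**2) ** 2 * t_se**2
            prop_se = math.sqrt(var)
            prop_ci = (prop - Z95 * prop_se, prop + Z95 * prop_se)
    return MediationResult(t, t_se, d, d_se, ind, ind_se, prop, prop_ci, p, method)


def classify_mediator(result: MediationResult, alpha: float = 0.05) -> str:
    """Label a candidate: 'mediator' when the indirect path is significant."""
    return "mediator" if result.p < alpha else "attenuator/confounder-like"


def effect_from_ci(estimate: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Recover (effect, se) from a 95% CI on the effect (not OR) scale."""
    if not ci_low <= estimate <= ci_high:
        raise ValueError("CI must bracket the estimate")
    se = (ci_high - ci_low) / (2.0 * Z95)
    if se <= 0:
        raise ValueError("degenerate CI with zero width")
    return estimate, se
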