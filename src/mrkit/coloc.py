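"""Approximate-Bayes-factor colocalization for a pair of trait regions.

Under a single-causal-variant assumption per trait, the five hypotheses
H0 (no association), H1/H2 (one trait associated), H3 (two distinct
causal variants) and H4 (one shared causal variant) are scored by
enumerating per-variant Wakefield approximate Bayes factors; PP.H4 > 0.8
is the conventional evidence threshold for a shared variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .io import SummaryStatSet

logger = logging.getLogger("mrkit.coloc")


@dataclass
class ColocPosterior:
    """Posterior probabilities PP.H0..PP.H4 over a region pair."""

    pp: dict[str, float]
    n_variants: int
    priors: tuple[float, float, float]

    def __post_init__(self) -> None:
        total = sum(self.pp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors sum to {total}, not 1")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")

    @property
    def h4(self) -> float:
        return self.pp["PP.H4"]


def define_region(stats: SummaryStatSet, window_kb: float = 100.0) -> list[str]:
    """Variants within ±window_kb of the strongest association.

    The reference variant is the one with smallest p (ties broken by lower
    position); the region is the closed interval around its position on
    its chromosome.
    """
    if len(stats) == 0:
        raise ValueError("empty summary-statistic set")
    t = stats.table.sort_values(["p", "position"], kind="mergesort")
    ref = t.iloc[0]
    half = window_kb * 1000.0
    inside = stats.table[
        (stats.table["chromosome"] == ref["chromosome"])
        & (stats.table["position"] >= ref["position"] - half)
        & (stats.table["position"] <= ref["position"] + half)
    ]
    return list(inside["variant_id"])


def compute_labf(beta: float, se: float, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one variant.

    lABF = ½[log(σ²/(σ²+W)) + z²·W/(σ²+W)] with z = β/σ and W = prior_sd²,
    the prior variance of a true effect.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    return 0.5 * (math.log(v / (v + w)) + z**2 * r)


def _default_prior_sd(stats: SummaryStatSet) -> float:
    # Conventional effect-scale priors: 0.15 for quantitative traits,
    # 0.2 for log-OR effects of case-control traits.
    return 0.2 if stats.binary_trait else 0.15


def coloc_abf(
    region1: SummaryStatSet,
    region2: SummaryStatSet,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
) -> ColocPosterior:
    """Enumeration colocalization over the variants shared by both regions.

    Priors: ``p1``/``p2`` per-variant probabilities of causality for each
    trait, ``p12`` for a shared causal variant. Computations run in log
    space throughout.
    """
    shared = [v for v in region1.table["variant_id"] if v in region2]
    if not shared:
        raise ValueError("regions share no variant ids")
    logger.info("colocalization over %d shared variants", len(shared))
    sd1 = prior_sd1 if prior_sd1 is not None else _default_prior_sd(region1)
    sd2 = prior_sd2 if prior_sd2 is not None else _default_prior_sd(region2)

    t1 = region1.table.set_index("variant_id").loc[shared]
    t2 = region2.table.set_index("variant_id").loc[shared]
    l1 = np.array([compute_labf(b, s, sd1) for b, s in zip(t1["beta"], t1["se"])])
    l2 = np.array([compute_labf(b, s, sd2) for b, s in zip(t2["beta"], t2["se"])])

    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))
    # H3 sums over ordered distinct pairs: sum_i sum_{j != i} BF1_i BF2_j.
    both, sign = logsumexp([s1 + s2, s12], b=[1.0, -1.0], return_sign=True)
    s3 = float(both) if sign > 0 else -np.inf

    lh = np.array(
        [
            0.0,
            math.log(p1) + s1,
            math.log(p2) + s2,
            math.log(p1) + math.log(p2) + s3,
            math.log(p12) + s12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocPosterior(
        pp={f"PP.H{i}": float(pp[i]) for i in range(5)},
        n_variants=len(shared),
        priors=(p1, p2, p12),
    )
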