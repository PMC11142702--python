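"""Synthetic GWAS summary statistics with known causal truth.

The generator emulates the statistical structure two-sample MR assumes —
instrument relevance, exclusion and exchangeability — and its controlled
violations: uncorrelated (direct) and correlated (confounder-mediated)
horizontal pleiotropy, mediator chains, and LD blocks. Effects for binary
outcomes are generated directly on the log-OR scale with Gaussian
sampling noise; per-SNP standard errors follow the analytic
1/√(2·MAF·(1−MAF)·n) form, so generated data are exactly replayable from
the stored truth record.

Default scales mirror a large lipid-GWAS / disease-GWAS pairing: ~10⁶
exposure samples, ~5×10⁵ outcome samples, 100 instruments jointly
explaining 8% of exposure variance, and a causal log-OR of 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import LDMatrix, SummaryStatSet, clamp_p

#: allele pairs that are never strand-ambiguous
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"), ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T")]


@dataclass
class SimulationConfig:
    """Generating parameters for paired exposure/outcome summary statistics.

    ``theta`` is the true causal effect of the exposure on the outcome
    (log-OR scale for a binary outcome). ``pleiotropy_frac`` of SNPs carry
    direct outcome effects ~N(pleiotropy_mean, pleiotropy_sd²);
    ``correlated_frac`` act through a shared confounder whose outcome
    loading is ``confounder_effect`` per unit of its exposure loading.
    ``mediator_chain`` = (beta_x_to_m, beta_m_to_y, beta_x_direct) turns on
    the three-trait mediation generator. ``ld_blocks`` is a list of
    (block_size, within_block_r) pairs; remaining SNPs are independent.
    """

    n_snp: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2: float = 0.08
    n_exposure: int = 1_320_016
    n_outcome: int = 470_866
    n_mediator: int = 757_601
    theta: float = 0.1
    pleiotropy_frac: float = 0.0
    pleiotropy_sd: float = 0.1
    pleiotropy_mean: float = 0.0
    correlated_frac: float = 0.0
    confounder_effect: float = 0.3
    mediator_chain: tuple[float, float, float] | None = None
    ld_blocks: list[tuple[int, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 < self.exposure_h2 < 1:
            raise ValueError("exposure_h2 must lie in (0, 1)")
        for frac in (self.pleiotropy_frac, self.correlated_frac):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.ld_blocks is not None:
            if sum(b for b, _ in self.ld_blocks) > self.n_snp:
                raise ValueError("ld_blocks exceed n_snp")
            if any(abs(r) >= 1 or b < 1 for b, r in self.ld_blocks):
                raise ValueError("block r must lie in (-1, 1) and sizes be >= 1")


def _layout(n_snp: int, ld_blocks, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chromosome/position layout and LD correlation matrix.

    Block members sit 5 kb apart; independent loci are separated by 20 Mb
    (beyond any clumping window), cycling through chromosomes 1..22.
    """
    chrom = np.empty(n_snp, dtype=object)
    pos = np.empty(n_snp, dtype=int)
    r = np.eye(n_snp)
    blocks = list(ld_blocks or [])
    idx = 0
    locus = 0
    while idx < n_snp:
        c = str(locus % 22 + 1)
        base = 1_000_000 + (locus // 22) * 20_000_000
        if blocks:
            size, rho = blocks.pop(0)
            sl = slice(idx, idx + size)
            chrom[sl] = c
            pos[sl] = base + 5_000 * np.arange(size)
            r[sl, sl] = rho
            r[np.arange(idx, idx + size), np.arange(idx, idx + size)] = 1.0
            idx += size
        else:
            chrom[idx] = c
            pos[idx] = base
            idx += 1
        locus += 1
    return chrom, pos, r


def _stats_frame(ids, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    z = beta / se
    p = np.array([clamp_p(2.0 * norm.sf(abs(x))) for x in z])
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chrom,
            "position": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )


def _correlated_noise(rng, r: np.ndarray, size: int | None = None) -> np.ndarray:
    l = np.linalg.cholesky(r + 1e-12 * np.eye(len(r)))
    z = rng.standard_normal(len(r) if size is None else (size, len(r)))
    return z @ l.T


def simulate_two_sample(cfg: SimulationConfig):
    """Generate paired exposure/outcome summary statistics with known truth.

    Returns ``(exposure, outcome, truth)``. ``truth`` records every
    generating quantity (MAFs, joint and LD-propagated marginal effects,
    pleiotropy, noise draws, the LD matrix) so each observed beta can be
    reconstructed exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snp
    chrom, pos, r = _layout(n, cfg.ld_blocks, rng)
    ids = [f"rs{i + 1}" for i in range(n)]
    maf = rng.uniform(*cfg.maf_range, size=n)
    flip = rng.random(n) < 0.5
    eaf = np.where(flip, 1.0 - maf, maf)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    var_per_allele = 2.0 * maf * (1.0 - maf)
    gamma = rng.standard_normal(n)
    gamma *= np.sqrt(cfg.exposure_h2 / np.sum(var_per_allele * gamma**2))

    n_corr = int(round(cfg.correlated_frac * n))
    corr_idx = rng.choice(n, size=n_corr, replace=False) if n_corr else np.array([], dtype=int)
    u = np.zeros(n)
    if n_corr:
        u[corr_idx] = rng.normal(0.0, cfg.pleiotropy_sd, size=n_corr)

    n_pleio = int(round(cfg.pleiotropy_frac * n))
    pleio_idx = rng.choice(n, size=n_pleio, replace=False) if n_pleio else np.array([], dtype=int)
    alpha = np.zeros(n)
    if n_pleio:
        alpha[pleio_idx] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_pleio)

    gamma_x = gamma + u  # confounder loading feeds the exposure
    # Marginal (LD-propagated) effects are what a GWAS reports.
    marg_x = r @ gamma_x
    marg_y = r @ (cfg.theta * gamma_x + alpha + cfg.confounder_effect * u)

    se_x = 1.0 / np.sqrt(var_per_allele * cfg.n_exposure)
    se_y = 1.0 / np.sqrt(var_per_allele * cfg.n_outcome)
    noise_x = _correlated_noise(rng, r) * se_x
    noise_y = _correlated_noise(rng, r) * se_y
    bx = marg_x + noise_x
    by = marg_y + noise_y

    exposure = SummaryStatSet(
        "sim_exposure",
        "SIM",
        _stats_frame(ids, chrom, pos, ea, oa, eaf, bx, se_x, cfg.n_exposure),
        binary_trait=False,
    )
    outcome = SummaryStatSet(
        "sim_outcome",
        "SIM",
        _stats_frame(ids, chrom, pos, ea, oa, eaf, by, se_y, cfg.n_outcome),
        binary_trait=True,
    )
    truth = {
        "config": cfg,
        "theta": cfg.theta,
        "maf": maf,
        "eaf": eaf,
        "gamma_joint": gamma_x,
        "marginal_exposure": marg_x,
        "marginal_outcome": marg_y,
        "alpha_pleiotropy": alpha,
        "pleiotropy_idx": pleio_idx,
        "confounder_loading": u,
        "correlated_idx": corr_idx,
        "noise_exposure": noise_x,
        "noise_outcome": noise_y,
        "se_exposure": se_x,
        "se_outcome": se_y,
        "ld": LDMatrix(ids, r),
    }
    return exposure, outcome, truth


def simulate_mediation(cfg: SimulationConfig):
    """Three-trait chain X → M → Y with a direct X → Y path.

    ``cfg.mediator_chain`` = (a, b, c) with a = X→M, b = M→Y, c = direct
    X→Y; the true total effect is c + a·b and the true proportion mediated
    a·b/(c + a·b). Half the SNPs instrument the exposure, half the
    mediator (with the same h² budget each). Returns
    ``(exposure, mediator, outcome, truth)``.
    """
    if cfg.mediator_chain is None:
        raise ValueError("cfg.mediator_chain must be set for simulate_mediation")
    a, b, c = cfg.mediator_chain
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snp
    total = 2 * n
    chrom, pos, r = _layout(total, None, rng)
    ids = [f"rs{i + 1}" for i in range(total)]
    maf = rng.uniform(*cfg.maf_range, size=total)
    flip = rng.random(total) < 0.5
    eaf = np.where(flip, 1.0 - maf, maf)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=total)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    var_per_allele = 2.0 * maf * (1.0 - maf)

    gamma = np.zeros(total)  # SNP -> X
    delta = np.zeros(total)  # SNP -> M (mediator-specific)
    g = rng.standard_normal(n)
    gamma[:n] = g * np.sqrt(cfg.exposure_h2 / np.sum(var_per_allele[:n] * g**2))
    d = rng.standard_normal(n)
    delta[n:] = d * np.sqrt(cfg.exposure_h2 / np.sum(var_per_allele[n:] * d**2))

    eff_x = gamma
    eff_m = a * gamma + delta
    eff_y = (c + a * b) * gamma + b * delta

    se_x = 1.0 / np.sqrt(var_per_allele * cfg.n_exposure)
    se_m = 1.0 / np.sqrt(var_per_allele * cfg.n_mediator)
    se_y = 1.0 / np.sqrt(var_per_allele * cfg.n_outcome)
    nx = rng.standard_normal(total) * se_x
    nm = rng.standard_normal(total) * se_m
    ny = rng.standard_normal(total) * se_y

    exposure = SummaryStatSet(
        "sim_exposure", "SIM", _stats_frame(ids, chrom, pos, ea, oa, eaf, eff_x + nx, se_x, cfg.n_exposure)
    )
    mediator = SummaryStatSet(
        "sim_mediator", "SIM", _stats_frame(ids, chrom, pos, ea, oa, eaf, eff_m + nm, se_m, cfg.n_mediator)
    )
    outcome = SummaryStatSet(
        "sim_outcome",
        "SIM",
        _stats_frame(ids, chrom, pos, ea, oa, eaf, eff_y + ny, se_y, cfg.n_outcome),
        binary_trait=True,
    )
    total_effect = c + a * b
    truth = {
        "config": cfg,
        "beta_x_to_m": a,
        "beta_m_to_y": b,
        "beta_x_direct": c,
        "total_effect": total_effect,
        "indirect_effect": a * b,
        "proportion_mediated": a * b / total_effect if total_effect != 0 else None,
        "gamma": gamma,
        "delta": delta,
        "noise": (nx, nm, ny),
        "exposure_snps": ids[:n],
        "mediator_snps": ids[n:],
    }
    return exposure, mediator, outcome, truth


def simulate_coloc_region(
    n_variants: int,
    ld_block_r: float = 0.0,
    scenario: str = "H4",
    z_causal: float = 8.0,
    seed: int = 0,
    n_samples: int = 100_000,
):
    """One region, two traits, under a named colocalization hypothesis.

    H4 plants a single causal variant shared by both traits with marginal
    |z| = ``z_causal`` (propagated through the region's exchangeable LD,
    correlation ``ld_block_r``); H3 plants distinct causal variants; H0 is
    pure noise. Returns ``(region1, region2, truth)``.
    """
    if n_variants < 2:
        raise ValueError("need at least 2 variants in a region")
    if scenario not in ("H0", "H3", "H4"):
        raise ValueError("scenario must be one of H0, H3, H4")
    rng = np.random.default_rng(seed)
    r = np.full((n_variants, n_variants), float(ld_block_r))
    np.fill_diagonal(r, 1.0)
    ids = [f"rs{i + 1}" for i in range(n_variants)]
    pos = 1_000_000 + 1_000 * np.arange(n_variants)
    chrom = np.array(["1"] * n_variants, dtype=object)
    maf = rng.uniform(0.05, 0.5, size=n_variants)
    eaf = maf
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_variants)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    causal1 = causal2 = None
    mu1 = np.zeros(n_variants)
    mu2 = np.zeros(n_variants)
    if scenario in ("H3", "H4"):
        causal1 = int(rng.integers(n_variants))
        mu1 = z_causal * r[:, causal1]
        if scenario == "H4":
            causal2 = causal1
            mu2 = mu1.copy()
        else:
            choices = [i for i in range(n_variants) if i != causal1]
            causal2 = int(rng.choice(choices))
            mu2 = z_causal * r[:, causal2]

    z1 = mu1 + _correlated_noise(rng, r)
    z2 = mu2 + _correlated_noise(rng, r)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_samples)
    region1 = SummaryStatSet(
        "sim_trait1", "SIM", _stats_frame(ids, chrom, pos, ea, oa, eaf, z1 * se, se, n_samples)
    )
    region2 = SummaryStatSet(
        "sim_trait2", "SIM", _stats_frame(ids, chrom, pos, ea, oa, eaf, z2 * se, se, n_samples)
    )
    truth = {
        "scenario": scenario,
        "causal1": causal1,
        "causal2": causal2,
        "z_causal": z_causal,
        "ld": LDMatrix(ids, r),
        "z1": z1,
        "z2": z2,
    }
    return region1, region2, truth


def write_simulation(exposure, outcome, truth, out_dir) -> dict[str, str]:
    """Write generated sets as GWAS-SSF TSVs plus a truth JSON."""
    import json
    from pathlib import Path

    from .io import write_ld_matrix, write_summary_stats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": str(write_summary_stats(exposure, out / "exposure.tsv")),
        "outcome": str(write_summary_stats(outcome, out / "outcome.tsv")),
    }
    if "ld" in truth:
        paths["ld"] = str(write_ld_matrix(truth["ld"], out / "ld.tsv"))
    serializable = {}
    for k, v in truth.items():
        if k in ("ld", "config", "noise"):
            continue
        serializable[k] = v.tolist() if isinstance(v, np.ndarray) else v
    cfg = truth.get("config")
    if cfg is not None:
        serializable["config"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()
        }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(serializable, indent=1, default=str))
    paths["truth"] = str(truth_path)
    return paths
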