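"""Selection, quality filtering and harmonization of genetic instruments.

Instruments are genome-wide significant SNPs for the exposure, pruned to
approximate linkage equilibrium by greedy clumping, screened for strength
(F >= 10) and causal direction (Steiger), and allele-aligned between the
exposure and outcome studies so both effects refer to the same allele.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .io import LDMatrix, SummaryStatSet, complement, is_palindromic

logger = logging.getLogger("mrkit.instruments")


@dataclass
class ClumpConfig:
    """Greedy LD-clumping parameters.

    Defaults: genome-wide significance 5e-8, independence r² < 0.001
    within a 10,000 kb window.
    """

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


@dataclass
class InstrumentRecord:
    """One harmonized instrument: exposure and outcome effects share an allele.

    ``f_stat`` and ``r2_exposure`` follow the single-SNP formulas
    R² = 2·MAF·(1−MAF)·β² and F = (n−2)·R²/(1−R²).
    """

    variant_id: str
    chromosome: str = ""
    position: int = 0
    effect_allele: str = ""
    other_allele: str = ""
    exposure_beta: float = 0.0
    exposure_se: float = 1.0
    exposure_eaf: float | None = None
    exposure_p: float = 1.0
    exposure_n: float | None = None
    outcome_beta: float = 0.0
    outcome_se: float = 1.0
    outcome_eaf: float | None = None
    outcome_p: float = 1.0
    outcome_n: float | None = None
    r2_exposure: float | None = None
    f_stat: float | None = None
    proxy_of: str | None = None

    @property
    def wald(self) -> float:
        """Per-SNP Wald ratio (outcome effect over exposure effect)."""
        return self.outcome_beta / self.exposure_beta

    @property
    def ivw_weight(self) -> float:
        """Ratio-form IVW weight βx²/σy²."""
        return self.exposure_beta**2 / self.outcome_se**2

    def flipped(self) -> "InstrumentRecord":
        """Re-express the record on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            exposure_beta=-self.exposure_beta,
            outcome_beta=-self.outcome_beta,
            exposure_eaf=None if self.exposure_eaf is None else 1.0 - self.exposure_eaf,
            outcome_eaf=None if self.outcome_eaf is None else 1.0 - self.outcome_eaf,
        )


def snp_r2(eaf: float, beta: float) -> float:
    """Variance in the trait explained by one SNP: 2·MAF·(1−MAF)·β².

    ``eaf`` is the effect-allele frequency; the minor-allele frequency is
    min(eaf, 1−eaf). Summing over an instrument set gives the set's
    explained variance.
    """
    if not 0 < eaf < 1:
        raise ValueError(f"eaf must lie in (0, 1), got {eaf}")
    maf = min(eaf, 1.0 - eaf)
    return 2.0 * maf * (1.0 - maf) * beta**2


def f_statistic(r2: float, n: float, k: int = 1) -> float:
    """Instrument-strength F-statistic ((n−k−1)/k)·(R²/(1−R²)).

    Values below 10 conventionally flag a weak instrument.
    """
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if n <= k + 1:
        raise ValueError(f"need n > k+1, got n={n}, k={k}")
    return ((n - k - 1) / k) * (r2 / (1.0 - r2))


def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


def select_instruments(
    stats: SummaryStatSet, ld: LDMatrix | None, cfg: ClumpConfig | None = None
) -> list[str]:
    """Greedy p-value clumping of genome-wide significant variants.

    Candidates below ``cfg.p_threshold`` are sorted by ascending p (ties by
    chromosome then position); the best is kept and every remaining
    candidate on the same chromosome within ``window_kb`` with r² >=
    ``r2_threshold`` to it is discarded. Variants absent from ``ld`` are
    treated as independent with a logged warning.
    """
    cfg = cfg or ClumpConfig()
    t = stats.table
    cand = t[t["p"] < cfg.p_threshold].copy()
    if cand.empty:
        return []
    cand["_ck"] = cand["chromosome"].map(_chrom_sort_key)
    cand = cand.sort_values(["p", "_ck", "position"], kind="mergesort")

    missing = [v for v in cand["variant_id"] if ld is not None and v not in ld]
    if ld is None:
        logger.warning("no LD matrix supplied; treating all candidates as independent")
    elif missing:
        logger.warning("%d candidate(s) absent from LD matrix, treated as independent", len(missing))

    window_bp = cfg.window_kb * 1000.0
    kept: list[str] = []
    rows = list(cand.itertuples())
    alive = [True] * len(rows)
    for i, row in enumerate(rows):
        if not alive[i]:
            continue
        kept.append(row.variant_id)
        alive[i] = False
        for j in range(i + 1, len(rows)):
            other = rows[j]
            if not alive[j] or other.chromosome != row.chromosome:
                continue
            if abs(other.position - row.position) > window_bp:
                continue
            if ld is None or row.variant_id not in ld or other.variant_id not in ld:
                continue
            if ld.r2_between(row.variant_id, other.variant_id) >= cfg.r2_threshold:
                alive[j] = False
    return kept


def _r2_from_z(beta: float, se: float, n: float) -> float:
    """Per-SNP trait variance explained, from the association z-score.

    Uses R² = F/(F + n − 2) with F = (β/σ)², which needs no allele
    frequency and treats exposure and outcome symmetrically.
    """
    f = (beta / se) ** 2
    return f / (f + n - 2.0)


def steiger_filter(
    records: Iterable[InstrumentRecord], method: str = "z"
) -> tuple[list[InstrumentRecord], list[InstrumentRecord]]:
    """Directionality filter: drop SNPs better correlated with the outcome.

    For each record the trait variance explained is computed on both sides
    (``method='z'``: from the z-score and sample size; ``method='eaf'``:
    2·MAF(1−MAF)β², requiring eaf on both sides) and the SNP is dropped
    when r²_outcome > r²_exposure. Ties are retained. A Steiger z-test
    p-value is attached to each record's bookkeeping but not used for
    filtering. Records whose sample size (or eaf under ``method='eaf'``)
    is missing cannot be assessed and are dropped with a warning.

    Returns ``(kept, dropped)``, a disjoint partition of the input.
    """
    if method not in ("z", "eaf"):
        raise ValueError("method must be 'z' or 'eaf'")
    kept: list[InstrumentRecord] = []
    dropped: list[InstrumentRecord] = []
    for rec in records:
        if rec.exposure_n is None or rec.outcome_n is None:
            logger.warning("%s: missing sample size, cannot assess direction; dropped", rec.variant_id)
            dropped.append(rec)
            continue
        if method == "eaf":
            if rec.exposure_eaf is None or rec.outcome_eaf is None:
                logger.warning("%s: missing eaf for Steiger method 'eaf'; dropped", rec.variant_id)
                dropped.append(rec)
                continue
            r2_exp = snp_r2(rec.exposure_eaf, rec.exposure_beta)
            r2_out = snp_r2(rec.outcome_eaf, rec.outcome_beta)
        else:
            r2_exp = _r2_from_z(rec.exposure_beta, rec.exposure_se, rec.exposure_n)
            r2_out = _r2_from_z(rec.outcome_beta, rec.outcome_se, rec.outcome_n)
        (kept if r2_out <= r2_exp else dropped).append(rec)
    return kept, dropped


def steiger_p(rec: InstrumentRecord, method: str = "z") -> float:
    """Two-sided p for equal exposure/outcome correlations (Fisher z test)."""
    if rec.exposure_n is None or rec.outcome_n is None:
        raise ValueError("sample sizes required for the Steiger test")
    if method == "eaf":
        if rec.exposure_eaf is None or rec.outcome_eaf is None:
            raise ValueError("eaf required on both sides for method 'eaf'")
        r_exp = math.sqrt(snp_r2(rec.exposure_eaf, rec.exposure_beta))
        r_out = math.sqrt(snp_r2(rec.outcome_eaf, rec.outcome_beta))
    else:
        r_exp = math.sqrt(_r2_from_z(rec.exposure_beta, rec.exposure_se, rec.exposure_n))
        r_out = math.sqrt(_r2_from_z(rec.outcome_beta, rec.outcome_se, rec.outcome_n))
    r_exp = min(r_exp, 1.0 - 1e-15)
    r_out = min(r_out, 1.0 - 1e-15)
    z = (math.atanh(r_exp) - math.atanh(r_out)) / math.sqrt(
        1.0 / (rec.exposure_n - 3) + 1.0 / (rec.outcome_n - 3)
    )
    return float(2.0 * norm.sf(abs(z)))


def find_proxy(
    target: str,
    outcome_stats: SummaryStatSet,
    ld: LDMatrix,
    r2_min: float = 0.8,
) -> str | None:
    """Best available LD proxy for a variant missing from the outcome study.

    Returns the outcome-present variant with maximal r² to ``target`` among
    those exceeding ``r2_min``, or None. ``target`` must itself be absent
    from the outcome set.
    """
    if target in outcome_stats:
        raise ValueError(f"{target} is present in the outcome set; no proxy needed")
    if target not in ld:
        logger.warning("%s absent from LD matrix; no proxy search possible", target)
        return None
    best, best_r2 = None, r2_min
    for vid in outcome_stats.table["variant_id"]:
        if vid == target or vid not in ld:
            continue
        r2 = ld.r2_between(target, vid)
        if r2 > best_r2:
            best, best_r2 = vid, r2
    return best


@dataclass
class HarmonizationDrop:
    variant_id: str
    reason: str


def _alignment(exp_ea, exp_oa, out_ea, out_oa) -> str | None:
    """Classify outcome allele coding relative to the exposure's.

    Returns 'same', 'swap', 'strand', 'strand_swap' or None (irreconcilable).
    """
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return "same"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return "swap"
    c_ea, c_oa = complement(out_ea), complement(out_oa)
    if (c_ea, c_oa) == (exp_ea, exp_oa):
        return "strand"
    if (c_ea, c_oa) == (exp_oa, exp_ea):
        return "strand_swap"
    return None


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    snps: Sequence[str],
    ld: LDMatrix | None = None,
    use_proxies: bool = False,
    proxy_r2_min: float = 0.8,
    palindromic_eaf_margin: float = 0.08,
    compute_strength: bool = True,
) -> tuple[list[InstrumentRecord], list[HarmonizationDrop]]:
    """Align exposure and outcome records to one shared effect allele.

    For each selected SNP present in both studies (or reachable through an
    LD proxy when ``use_proxies``), the outcome record is re-expressed on
    the exposure's effect allele: swapped codings negate the outcome beta
    and reflect its eaf; strand-flipped codings are complemented first.
    Palindromic SNPs (A/T, C/G) are kept only when both eafs are available
    and both lie outside the ambiguity zone |eaf − 0.5| <= ``margin``, with
    a frequency-inferred flip when the eafs disagree in direction; all
    other failures are dropped with a recorded reason.

    Returns the harmonized records plus the drop log. Raises ValueError if
    nothing harmonizes.
    """
    records: list[InstrumentRecord] = []
    drops: list[HarmonizationDrop] = []
    outcome_ids = set(outcome.table["variant_id"])

    for snp in snps:
        try:
            erow = exposure.row(snp)
        except KeyError:
            drops.append(HarmonizationDrop(snp, "absent_from_exposure"))
            continue
        proxy_of = None
        if snp in outcome_ids:
            orow = outcome.row(snp)
        elif use_proxies and ld is not None:
            proxy = find_proxy(snp, outcome, ld, proxy_r2_min)
            if proxy is None:
                drops.append(HarmonizationDrop(snp, "absent_from_outcome_no_proxy"))
                continue
            orow = outcome.row(proxy)
            proxy_of = snp
        else:
            drops.append(HarmonizationDrop(snp, "absent_from_outcome"))
            continue

        exp_ea, exp_oa = erow["effect_allele"], erow["other_allele"]
        exp_eaf = None if np.isnan(erow.get("eaf", np.nan)) else float(erow["eaf"])
        out_eaf = None if np.isnan(orow.get("eaf", np.nan)) else float(orow["eaf"])
        out_beta, out_se = float(orow["beta"]), float(orow["se"])

        if proxy_of is not None:
            # Proxy effect is transported onto the target's alleles through
            # the sign of the LD correlation; the proxy's own alleles no
            # longer apply.
            r_sign = 1.0 if ld.r_between(snp, orow["variant_id"]) >= 0 else -1.0
            out_beta *= r_sign
            if out_eaf is not None and r_sign < 0:
                out_eaf = 1.0 - out_eaf
            align = "same"
        else:
            align = _alignment(exp_ea, exp_oa, orow["effect_allele"], orow["other_allele"])

        if align is None:
            drops.append(HarmonizationDrop(snp, "allele_mismatch"))
            continue

        palindromic = is_palindromic(exp_ea, exp_oa)
        if palindromic and proxy_of is None:
            if exp_eaf is None or out_eaf is None:
                drops.append(HarmonizationDrop(snp, "palindromic_missing_eaf"))
                continue
            if (
                abs(exp_eaf - 0.5) <= palindromic_eaf_margin
                or abs(out_eaf - 0.5) <= palindromic_eaf_margin
            ):
                drops.append(HarmonizationDrop(snp, "palindromic_ambiguous_eaf"))
                continue
            # For palindromic SNPs allele labels cannot distinguish strands:
            # infer orientation purely from the frequencies.
            align = "same" if (exp_eaf - 0.5) * (out_eaf - 0.5) > 0 else "swap"

        if align in ("swap", "strand_swap"):
            out_beta = -out_beta
            if out_eaf is not None:
                out_eaf = 1.0 - out_eaf
        # 'strand' and 'strand_swap' only relabel alleles; eaf refers to the
        # same physical allele either way.

        rec = InstrumentRecord(
            variant_id=snp,
            chromosome=str(erow["chromosome"]),
            position=int(erow["position"]),
            effect_allele=exp_ea,
            other_allele=exp_oa,
            exposure_beta=float(erow["beta"]),
            exposure_se=float(erow["se"]),
            exposure_eaf=exp_eaf,
            exposure_p=float(erow["p"]),
            exposure_n=float(erow["n"]),
            outcome_beta=out_beta,
            outcome_se=out_se,
            outcome_eaf=out_eaf,
            outcome_p=float(orow["p"]),
            outcome_n=float(orow["n"]),
            proxy_of=proxy_of,
        )
        if compute_strength and exp_eaf is not None:
            rec.r2_exposure = snp_r2(exp_eaf, rec.exposure_beta)
            rec.f_stat = f_statistic(rec.r2_exposure, rec.exposure_n)
        records.append(rec)

    if not records:
        raise ValueError("no records survived harmonization")
    return records, drops


def f_filter(
    records: Iterable[InstrumentRecord], f_min: float = 10.0
) -> tuple[list[InstrumentRecord], list[InstrumentRecord]]:
    """Drop weak instruments (F below ``f_min``); records lacking F are kept."""
    kept, dropped = [], []
    for rec in records:
        if rec.f_stat is not None and rec.f_stat < f_min:
            dropped.append(rec)
        else:
            kept.append(rec)
    return kept, dropped
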