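"""End-to-end orchestration of a two-sample MR analysis.

A :class:`RunConfig` (usually loaded from YAML) names the input files and
the stages to run; :func:`run_pipeline` executes
select → harmonize → Steiger → F-filter → UVMR → sensitivity →
meta / FDR / MVMR-mediation / drug-target / colocalization, writing one
TSV or JSON per stage plus a machine-readable manifest with seeds,
versions and SNP bookkeeping (in = kept + dropped at every filter).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .coloc import coloc_abf
from .drug_target import drug_target_mr, drug_target_table, extract_cis_instruments, read_gene_targets
from .instruments import ClumpConfig, f_filter, harmonize, select_instruments, steiger_filter
from .io import LDMatrix, SummaryStatSet, read_ld_matrix, read_summary_stats
from .meta_fdr_power import bh_fdr, estimate_from_or_ci, meta_analyze
from .mvmr_mediation import build_mvmr_table, mediation, mvmr_ivw
from .sensitivity import funnel_table, loo_table, sensitivity_report
from .uvmr import MREstimate, run_uvmr

logger = logging.getLogger("mrkit.pipeline")

ALL_STAGES = (
    "instruments",
    "uvmr",
    "sensitivity",
    "meta",
    "fdr",
    "mvmr",
    "mediation",
    "drugtarget",
    "coloc",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the abort message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "mrkit_run"
    seed: int = 0
    stages: list[str] = dc_field(default_factory=lambda: list(ALL_STAGES[:3]))
    exposure: dict[str, Any] | None = None  # {path, label?, ancestry?, binary?, column_map?}
    outcome: dict[str, Any] | None = None
    mediators: list[dict[str, Any]] = dc_field(default_factory=list)
    ld: str | None = None
    clump: dict[str, Any] = dc_field(default_factory=dict)
    use_proxies: bool = False
    f_min: float = 10.0
    presso_n_sim: int = 1000
    fdr_family_size: int | None = None
    meta_input: str | None = None
    gene_targets: str | None = None
    coloc_regions: tuple[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "coloc_regions" in raw and raw["coloc_regions"] is not None:
            raw["coloc_regions"] = tuple(raw["coloc_regions"])
        return cls(**raw)

    def validate_paths(self) -> None:
        paths = []
        for spec in filter(None, [self.exposure, self.outcome, *self.mediators]):
            paths.append(spec["path"])
        paths += [p for p in (self.ld, self.meta_input, self.gene_targets) if p]
        if self.coloc_regions:
            paths += list(self.coloc_regions)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _load_stats(spec: dict[str, Any]) -> SummaryStatSet:
    return read_summary_stats(
        spec["path"],
        column_map=spec.get("column_map"),
        binary_trait=bool(spec.get("binary", False)),
        trait_label=spec.get("label", ""),
        ancestry_label=spec.get("ancestry", "NA"),
    )


def _estimates_table(results: dict) -> pd.DataFrame:
    rows = []
    for method, est in results.items():
        if isinstance(est, list):
            rows.extend(e.as_dict() for e in est)
        else:
            rows.append(est.as_dict())
    return pd.DataFrame(rows)


def prepare_instruments(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    ld: LDMatrix | None,
    cfg: RunConfig,
) -> tuple[list, dict[str, int], list[tuple[str, str]]]:
    """Significance → clump → harmonize (+proxies) → Steiger → F >= f_min.

    Returns the surviving records, per-filter bookkeeping counts, and a
    drop log of (variant_id, reason) for every excluded SNP.
    """
    clump_cfg = ClumpConfig(**cfg.clump) if cfg.clump else ClumpConfig()
    selected = select_instruments(exposure, ld, clump_cfg)
    counts = {"candidates_selected": len(selected)}
    if not selected:
        raise PipelineError("instruments", "no genome-wide significant instruments after clumping")
    try:
        records, drops = harmonize(exposure, outcome, selected, ld=ld, use_proxies=cfg.use_proxies)
    except ValueError as exc:
        raise PipelineError("harmonize", str(exc)) from exc
    drop_log = [(d.variant_id, d.reason) for d in drops]
    counts["harmonized"] = len(records)
    counts["harmonize_dropped"] = len(drops)
    drop_reasons: dict[str, int] = {}
    for d in drops:
        drop_reasons[d.reason] = drop_reasons.get(d.reason, 0) + 1
    counts["harmonize_drop_reasons"] = drop_reasons  # type: ignore[assignment]
    kept, dropped = steiger_filter(records)
    drop_log += [(r.variant_id, "steiger_direction") for r in dropped]
    counts["steiger_kept"], counts["steiger_dropped"] = len(kept), len(dropped)
    kept, weak = f_filter(kept, cfg.f_min)
    drop_log += [(r.variant_id, "weak_instrument_f") for r in weak]
    counts["f_kept"], counts["f_dropped"] = len(kept), len(weak)
    if not kept:
        raise PipelineError("instruments", "no instruments survive Steiger/F filtering")
    return kept, counts, drop_log


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order; returns the run manifest.

    Any stage hard-error aborts with the stage name; outputs written by
    earlier stages are retained.
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in cfg.stages]
    unknown = set(cfg.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    manifest: dict[str, Any] = {
        "mrkit_version": __version__,
        "seed": cfg.seed,
        "stages": stages,
        "filter_order": "significance>clump>harmonize>steiger>f",
        "counts": {},
        "outputs": {},
    }

    ld = read_ld_matrix(cfg.ld) if cfg.ld else None
    records = None
    needs_instruments = any(s in stages for s in ("instruments", "uvmr", "sensitivity"))
    if needs_instruments:
        if cfg.exposure is None or cfg.outcome is None:
            raise PipelineError("instruments", "exposure and outcome files are required")
        exposure = _load_stats(cfg.exposure)
        outcome = _load_stats(cfg.outcome)
        records, counts, drop_log = prepare_instruments(exposure, outcome, ld, cfg)
        manifest["counts"]["instruments"] = counts
        if "instruments" in stages:
            from .instruments import steiger_p

            rows = [
                {
                    "variant_id": r.variant_id,
                    "status": "kept",
                    "drop_reason": "",
                    "chromosome": r.chromosome,
                    "position": r.position,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "exposure_beta": r.exposure_beta,
                    "exposure_se": r.exposure_se,
                    "outcome_beta": r.outcome_beta,
                    "outcome_se": r.outcome_se,
                    "wald_ratio": r.wald,
                    "f_stat": r.f_stat,
                    "steiger_p": steiger_p(r),
                    "proxy_of": r.proxy_of,
                }
                for r in records
            ]
            rows += [
                {"variant_id": vid, "status": "dropped", "drop_reason": reason}
                for vid, reason in drop_log
            ]
            path = out / "instruments.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            manifest["outputs"]["instruments"] = str(path)

    if "uvmr" in stages:
        results = run_uvmr(records, seed=cfg.seed)
        path = out / "uvmr.tsv"
        _estimates_table(results).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["uvmr"] = str(path)

    if "sensitivity" in stages:
        try:
            rep = sensitivity_report(records, n_sim=cfg.presso_n_sim, seed=cfg.seed)
        except ValueError as exc:
            raise PipelineError("sensitivity", str(exc)) from exc
        summary = {
            "q": rep.q,
            "q_df": rep.q_df,
            "q_p": rep.q_p,
            "i2": rep.i2,
            "egger_intercept": rep.egger_intercept,
            "egger_intercept_p": rep.egger_intercept_p,
            "presso_global_p": rep.presso_global_p,
            "presso_outliers": rep.presso_outliers,
            "presso_distortion_p": rep.presso_distortion_p,
            "presso_corrected": rep.presso_corrected.as_dict() if rep.presso_corrected else None,
        }
        path = out / "sensitivity.json"
        path.write_text(json.dumps(summary, indent=1))
        funnel_table(records).to_csv(out / "funnel.tsv", sep="\t", index=False)
        if rep.loo:
            loo_table(rep.loo).to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
        manifest["outputs"]["sensitivity"] = str(path)

    if "meta" in stages:
        if not cfg.meta_input:
            raise PipelineError("meta", "meta_input TSV is required")
        df = pd.read_csv(cfg.meta_input, sep="\t")
        if {"beta", "se"}.issubset(df.columns):
            ests = list(zip(df["beta"], df["se"]))
        elif {"or", "ci_low", "ci_high"}.issubset(df.columns):
            ests = [estimate_from_or_ci(o, l, h) for o, l, h in zip(df["or"], df["ci_low"], df["ci_high"])]
        else:
            raise PipelineError("meta", "need columns (beta, se) or (or, ci_low, ci_high)")
        res = meta_analyze(ests)
        path = out / "meta.json"
        path.write_text(
            json.dumps(
                {
                    "model": res.model,
                    "beta": res.beta,
                    "se": res.se,
                    "or": res.or_,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "q": res.q,
                    "i2": res.i2,
                    "k": res.k,
                },
                indent=1,
            )
        )
        manifest["outputs"]["meta"] = str(path)

    if "fdr" in stages:
        uvmr_path = out / "uvmr.tsv"
        if not uvmr_path.exists():
            raise PipelineError("fdr", "fdr stage needs the uvmr stage's output")
        df = pd.read_csv(uvmr_path, sep="\t")
        df["p_fdr"] = bh_fdr(df["p"].to_numpy(), cfg.fdr_family_size)
        df["interpretation"] = [
            "significant" if (p < 0.05 and pf < 0.05) else ("suggestive" if p < 0.05 else "null")
            for p, pf in zip(df["p"], df["p_fdr"])
        ]
        df.to_csv(uvmr_path, sep="\t", index=False)
        manifest["outputs"]["fdr"] = str(uvmr_path)

    if "mvmr" in stages or "mediation" in stages:
        if not cfg.mediators:
            raise PipelineError("mvmr", "at least one mediator file is required")
        exposure = _load_stats(cfg.exposure)
        outcome = _load_stats(cfg.outcome)
        clump_cfg = ClumpConfig(**cfg.clump) if cfg.clump else ClumpConfig()
        total_est = run_uvmr(records, seed=cfg.seed)["ivw_mre"] if records else None
        med_rows = []
        mvmr_frames = []
        for spec in cfg.mediators:
            med = _load_stats(spec)
            label_x = exposure.trait_label or "exposure"
            label_m = med.trait_label or "mediator"
            snps = sorted(
                set(select_instruments(exposure, ld, clump_cfg))
                | set(select_instruments(med, ld, clump_cfg))
            )
            frame, ybeta, yse = build_mvmr_table({label_x: exposure, label_m: med}, outcome, snps)
            fit = mvmr_ivw(frame, ybeta, yse)
            t = fit.as_table()
            mvmr_frames.append(t.assign(adjusted_for=label_m))
            if "mediation" in stages and total_est is not None:
                direct = fit.estimate(label_x)
                res = mediation(total_est, (direct.beta, direct.se), method="difference")
                med_rows.append(
                    {
                        "mediator": label_m,
                        "total": res.total,
                        "total_se": res.total_se,
                        "direct": res.direct,
                        "direct_se": res.direct_se,
                        "indirect": res.indirect,
                        "indirect_se": res.indirect_se,
                        "proportion_pct": None if res.proportion is None else 100 * res.proportion,
                        "p": res.p,
                    }
                )
        if "mvmr" in stages:
            path = out / "mvmr.tsv"
            pd.concat(mvmr_frames).to_csv(path, sep="\t", index=False)
            manifest["outputs"]["mvmr"] = str(path)
        if "mediation" in stages and med_rows:
            path = out / "mediation.tsv"
            pd.DataFrame(med_rows).to_csv(path, sep="\t", index=False)
            manifest["outputs"]["mediation"] = str(path)

    if "drugtarget" in stages:
        if not cfg.gene_targets:
            raise PipelineError("drugtarget", "gene_targets BED-like file is required")
        exposure = _load_stats(cfg.exposure)
        outcome = _load_stats(cfg.outcome)
        results: dict[str, MREstimate] = {}
        for target in read_gene_targets(cfg.gene_targets):
            cis = extract_cis_instruments(exposure, target, ld)
            if not cis:
                continue
            try:
                recs, _ = harmonize(exposure, outcome, cis, ld=ld)
            except ValueError:
                continue
            results[target.name] = drug_target_mr(recs, ld=ld)
        if results:
            table = drug_target_table(results)
            table["p_fdr"] = bh_fdr(table["p"].to_numpy())
            path = out / "drug_target.tsv"
            table.to_csv(path, sep="\t", index=False)
            manifest["outputs"]["drugtarget"] = str(path)

    if "coloc" in stages:
        if not cfg.coloc_regions:
            raise PipelineError("coloc", "coloc_regions (two files) required")
        r1 = read_summary_stats(cfg.coloc_regions[0])
        r2 = read_summary_stats(cfg.coloc_regions[1], binary_trait=True)
        post = coloc_abf(r1, r2)
        path = out / "coloc.json"
        path.write_text(
            json.dumps({"pp": post.pp, "n_variants": post.n_variants, "priors": post.priors}, indent=1)
        )
        manifest["outputs"]["coloc"] = str(path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    manifest["manifest_path"] = str(manifest_path)
    return manifest
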