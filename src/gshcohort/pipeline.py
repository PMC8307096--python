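"""End-to-end orchestration: QC filter -> Bayesian rank correlations per
group -> hierarchical GLMs -> frequentist replication, assembled into a
single serializable report shaped like the study's demographic and
posterior-summary tables.

Every stage draws its seed deterministically from the master seed and the
stage name, so a stage can be re-run in isolation and two runs with the
same seed produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .cohort import CohortTable, filter_by_crlb
from .errors import DegenerateInputError, PipelineError
from .freq import (
    anova_tukey,
    hierarchical_regression,
    median_split,
    pearson_chi2,
    two_sample_t,
)
from .glm import build_priors, fit_group_covariate_model, fit_group_model
from .rankcorr import bayesian_spearman

logger = logging.getLogger("gshcohort")

__all__ = ["RunSettings", "AnalysisReport", "run_full_analysis", "render_report", "stage_seed"]

#: (group, score) pairs for the Bayesian rank-correlation stage
RANK_PAIRS = [("CHR", "sofas"), ("CHR", "sops_total"), ("CHR", "cast"), ("HC", "sofas")]

#: demographic scores compared by the group-deflection GLM
SCORE_VARIABLES = ["cast", "audit_c", "sofas"]


@dataclass
class RunSettings:
    """Sampler and filtering settings for a full run."""

    n_kept: int = 11000
    thin: int = 10
    burn_in: int = 1000
    crlb_threshold: float = 30.0

    @classmethod
    def from_json(cls, path) -> "RunSettings":
        with open(path) as fh:
            return cls(**json.load(fh))


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed and stage name."""
    return (int(master_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class AnalysisReport:
    demographics: list = field(default_factory=list)
    rank_correlations: dict = field(default_factory=dict)
    glm_scores: dict = field(default_factory=dict)
    glm_gsh_adjusted: dict = field(default_factory=dict)
    frequentist_replication: dict = field(default_factory=dict)
    run_metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(**d)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return inner

    return wrap


def _glm_block(post) -> dict:
    block = {name: s.to_dict() for name, s in post.summaries.items()}
    return {
        "parameters": block,
        "difference": post.difference.to_dict(),
        "effect_size": post.effect_size.to_dict(),
        "difference_order": f"beta_{post.labels[1]} - beta_{post.labels[0]}",
        "ess": {k: round(v, 1) for k, v in post.samples.diagnostics["ess"].items()},
        "n_per_group": post.samples.diagnostics["n_per_group"],
    }


@_stage("crlb_filter")
def _filter_stage(cohort: CohortTable, threshold: float) -> CohortTable:
    filtered = filter_by_crlb(cohort, threshold)
    for g in ("CHR", "HC"):
        if len(filtered.select(g)) == 0:
            raise DegenerateInputError(f"group {g} is empty after CRLB filtering")
    logger.info("CRLB filter (<%g%%): %d -> %d records", threshold, len(cohort), len(filtered))
    return filtered


def run_full_analysis(cohort: CohortTable, settings: RunSettings | None = None, seed: int = 0) -> AnalysisReport:
    """Run the complete analysis on a validated cohort.

    Stages, in order: CRLB quality filter; Bayesian Spearman correlations
    of GSH against SOFAS/SOPS/CAST in CHR and SOFAS in HC; hierarchical
    group GLMs on each demographic score; the GSH model with group
    deflections plus the SOFAS covariate; the frequentist replication
    suite. Errors are re-raised with the failing stage's name attached.
    """
    settings = settings or RunSettings()
    report = AnalysisReport()
    report.run_metadata = {
        "seed": int(seed),
        "settings": asdict(settings),
        "version": __version__,
        "n_input": len(cohort),
        "provenance": cohort.provenance,
    }

    data = _filter_stage(cohort, settings.crlb_threshold)
    report.run_metadata["n_after_qc"] = len(data)

    # --- Bayesian rank correlations -------------------------------------
    for group, score in RANK_PAIRS:
        key = f"{group}:{score}"
        gsh = data.values("gsh", group=group)
        sc = data.values(score, group=group)
        if np.all(np.isnan(sc)):
            logger.warning("rank correlation %s skipped: no %s values in %s", key, score, group)
            continue

        @_stage(f"rank_correlation[{key}]")
        def _run(gsh=gsh, sc=sc, key=key):
            res = bayesian_spearman(
                gsh, sc,
                n_kept=settings.n_kept, thin=settings.thin, burn_in=settings.burn_in,
                seed=stage_seed(seed, f"rank:{key}"),
            )
            logger.info(
                "rank correlation %s: n=%d mode=%.3f pp=%.3f bf10=%.3g acc=%.2f",
                key, res.n, res.rho_summary.mode, res.rho_summary.pp, res.bf10,
                res.draws.diagnostics["acceptance_rate"],
            )
            return res

        res = _run()
        report.rank_correlations[key] = {
            "rho": res.rho_summary.to_dict(),
            "bf10": res.bf10,
            "n": res.n,
        }

    # --- hierarchical GLMs on the demographic scores ---------------------
    for var in SCORE_VARIABLES:

        @_stage(f"glm_scores[{var}]")
        def _run(var=var):
            y = data.values(var)
            groups = np.array([r.group for r in data.records])
            keep = np.isfinite(y)
            spec = build_priors(y[keep])
            post = fit_group_model(
                y[keep], groups[keep], spec,
                n_kept=settings.n_kept, thin=settings.thin, burn_in=settings.burn_in,
                seed=stage_seed(seed, f"glm:{var}"),
            )
            logger.info("score GLM %s: diff mode=%.3f pp=%.3f", var,
                        post.difference.mode, post.difference.pp)
            return post

        report.glm_scores[var] = _glm_block(_run())

    # --- GSH model with the SOFAS covariate ------------------------------
    @_stage("glm_gsh_adjusted")
    def _run_gsh():
        gsh = data.values("gsh")
        sofas = data.values("sofas")
        groups = np.array([r.group for r in data.records])
        keep = np.isfinite(gsh) & np.isfinite(sofas)
        spec = build_priors(gsh[keep], covariate=sofas[keep])
        post = fit_group_covariate_model(
            gsh[keep], groups[keep], sofas[keep], spec,
            n_kept=settings.n_kept, thin=settings.thin, burn_in=settings.burn_in,
            seed=stage_seed(seed, "glm:gsh~group+sofas"),
        )
        logger.info("GSH GLM: diff mode=%.3f pp=%.3f effect size mode=%.3f",
                    post.difference.mode, post.difference.pp, post.effect_size.mode)
        return post

    report.glm_gsh_adjusted = _glm_block(_run_gsh())

    # --- frequentist replication ------------------------------------------
    @_stage("frequentist")
    def _run_freq():
        return _frequentist_block(data)

    demo, repl = _run_freq()
    report.demographics = demo
    report.frequentist_replication = repl
    return report


def _demographic_rows(data: CohortTable) -> list:
    rows = []
    chr_recs = data.select("CHR")
    hc_recs = data.select("HC")
    counts = [
        [sum(r.gender == "male" for r in chr_recs), sum(r.gender == "female" for r in chr_recs)],
        [sum(r.gender == "male" for r in hc_recs), sum(r.gender == "female" for r in hc_recs)],
    ]
    try:
        res = pearson_chi2(counts)
        rows.append({"variable": "gender", "counts": counts, **res.to_dict()})
    except (DegenerateInputError, ValueError) as exc:
        logger.warning("gender chi-squared skipped: %s", exc)
    for var in ["age", "cast", "audit_c", "sofas", "gsh"]:
        a = data.values(var, group="CHR")
        b = data.values(var, group="HC")
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        try:
            res = two_sample_t(a, b, pooled=True)
        except DegenerateInputError as exc:
            logger.warning("t-test for %s skipped: %s", var, exc)
            continue
        rows.append({"variable": var, "n": [int(a.size), int(b.size)], **res.to_dict()})
    return rows


def _frequentist_block(data: CohortTable) -> tuple[list, dict]:
    demo = _demographic_rows(data)
    out: dict = {}

    # hierarchical regression: GSH ~ SOFAS, then + diagnosis (CHR=0, HC=1)
    gsh = data.values("gsh")
    sofas = data.values("sofas")
    dummy = np.array([0.0 if r.group == "CHR" else 1.0 for r in data.records])
    keep = np.isfinite(gsh) & np.isfinite(sofas)
    hr = hierarchical_regression(gsh[keep], sofas[keep], dummy[keep], names=["sofas", "group_hc"])
    out["hierarchical_regression"] = hr.to_dict()

    # median split of CHR glutathione
    chr_gsh = data.values("gsh", group="CHR")
    chr_sofas = data.values("sofas", group="CHR")
    k = np.isfinite(chr_gsh)
    chr_gsh, chr_sofas = chr_gsh[k], chr_sofas[k]
    labels = median_split(chr_gsh)
    split = {
        "threshold": float(np.median(chr_gsh)),
        "n_low": int(np.sum(labels == "low")),
        "n_high": int(np.sum(labels == "high")),
    }
    try:
        t = two_sample_t(chr_sofas[labels == "low"], chr_sofas[labels == "high"], pooled=True)
        split["sofas_t_test"] = t.to_dict()
    except DegenerateInputError as exc:
        logger.warning("median-split t-test skipped: %s", exc)
    out["median_split"] = split

    # three-group ANOVA: low-GSH CHR, high-GSH CHR, HC
    hc_gsh = data.values("gsh", group="HC")
    hc_sofas = data.values("sofas", group="HC")
    kh = np.isfinite(hc_gsh)
    values_gsh = np.concatenate([chr_gsh, hc_gsh[kh]])
    values_sofas = np.concatenate([chr_sofas, hc_sofas[kh]])
    groups3 = np.concatenate([np.where(labels == "low", "CHR-lowGSH", "CHR-highGSH"), ["HC"] * int(kh.sum())])
    anova = {}
    for name, vals in [("gsh", values_gsh), ("sofas", values_sofas)]:
        try:
            omnibus, pairs = anova_tukey(vals, groups3)
            anova[name] = {
                "omnibus": omnibus.to_dict(),
                "tukey": [
                    {"groups": list(p["groups"]), "diff": p["diff"], "p_adj": p["p_adj"]}
                    for p in pairs
                ],
            }
        except DegenerateInputError as exc:
            logger.warning("ANOVA on %s skipped: %s", name, exc)
    out["anova_median_split"] = anova
    return demo, out


# ---------------------------------------------------------------------------
# rendering

_GLM_ROW_ORDER = ["beta0", "beta_CHR", "beta_HC", "beta_cov", "sigma_beta", "sigma_i"]


def render_report(report: AnalysisReport, fmt: str = "json") -> str:
    """Serialize a report as ``json``, ``csv`` or a human-readable ``text`` grid."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if fmt == "csv":
        return _render_csv(report)
    if fmt == "text":
        return _render_text(report)
    raise ValueError(f"unknown format {fmt!r}; expected json, csv or text")


def _iter_glm_rows(report):
    blocks = [("gsh_adjusted", report.glm_gsh_adjusted)]
    blocks += [(f"score:{v}", b) for v, b in report.glm_scores.items()]
    for block_name, block in blocks:
        if not block:
            continue
        params = block["parameters"]
        for name in _GLM_ROW_ORDER:
            if name in params:
                yield block_name, name, params[name]
        yield block_name, "difference", block["difference"]
        yield block_name, "effect_size", block["effect_size"]


def _render_csv(report: AnalysisReport) -> str:
    lines = ["table,row,mean,median,mode,hdi_low,hdi_high,pp"]
    for block, name, s in _iter_glm_rows(report):
        lines.append(
            f"{block},{name},{s['mean']:.6g},{s['median']:.6g},{s['mode']:.6g},"
            f"{s['hdi_low']:.6g},{s['hdi_high']:.6g},{s['pp']:.4g}"
        )
    for key, rc in report.rank_correlations.items():
        s = rc["rho"]
        lines.append(
            f"rank,{key},{s['mean']:.6g},{s['median']:.6g},{s['mode']:.6g},"
            f"{s['hdi_low']:.6g},{s['hdi_high']:.6g},{s['pp']:.4g}"
        )
    lines.append("")
    lines.append("demographics,variable,statistic,df,p_value,estimate,method")
    for row in report.demographics:
        df = row["df"]
        df = "/".join(str(x) for x in df) if isinstance(df, list) else df
        est = "" if row.get("estimate") is None else f"{row['estimate']:.6g}"
        lines.append(
            f"demographics,{row['variable']},{row['statistic']:.6g},{df},{row['p_value']:.4g},{est},{row['method']}"
        )
    return "\n".join(lines) + "\n"


def _render_text(report: AnalysisReport) -> str:
    out = []
    out.append("Posterior summaries (mean / median / mode / 95% HDI / PP)")
    out.append("-" * 78)
    hdr = f"{'table':<16}{'parameter':<14}{'mean':>9}{'median':>9}{'mode':>9}{'hdi_low':>9}{'hdi_high':>9}{'pp':>7}"
    out.append(hdr)
    for block, name, s in _iter_glm_rows(report):
        out.append(
            f"{block:<16}{name:<14}{s['mean']:>9.3f}{s['median']:>9.3f}{s['mode']:>9.3f}"
            f"{s['hdi_low']:>9.3f}{s['hdi_high']:>9.3f}{s['pp']:>7.3f}"
        )
    for key, rc in report.rank_correlations.items():
        s = rc["rho"]
        out.append(
            f"{'rank':<16}{key:<14}{s['mean']:>9.3f}{s['median']:>9.3f}{s['mode']:>9.3f}"
            f"{s['hdi_low']:>9.3f}{s['hdi_high']:>9.3f}{s['pp']:>7.3f}"
            f"   BF10={rc['bf10']:.3g} (n={rc['n']})"
        )
    out.append("")
    out.append("Demographics")
    out.append("-" * 78)
    out.append(f"{'variable':<12}{'statistic':>11}{'df':>10}{'p':>9}  method")
    for row in report.demographics:
        df = row["df"]
        df = "/".join(f"{x:g}" for x in df) if isinstance(df, list) else f"{df:g}"
        out.append(f"{row['variable']:<12}{row['statistic']:>11.3f}{df:>10}{row['p_value']:>9.3f}  {row['method']}")
    return "\n".join(out) + "\n"
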