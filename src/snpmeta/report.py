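"""Full-pipeline orchestration and machine-readable reports.

:func:`run_full_analysis` drives, per variant: pooling under all five genetic
contrasts with automatic effect-model selection, the publication-bias suite
(when at least three studies contribute), a leave-one-out robustness summary,
a rerun excluding HWE-violating control arms, and stratified (subgroup)
analyses.  :func:`write_report` emits a summary-table TSV (rounded the way
such tables are printed: OR to 3 decimals, I^2 to 2), a full-precision JSON
that round-trips to an equal :class:`AnalysisReport`, and forest/funnel
plot-data TSVs per contrast.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .bias import BiasReport
from .corpus import StudyCorpus
from .contrasts import GENETIC_MODELS
from .model import GenotypeMetaAnalysis, leave_one_out, subgroup_analysis
from .perstudy import EffectEstimate
from .pooling import MetaConfig, PoolResult, HeterogeneityResult, Z_95


@dataclass(frozen=True)
class LeaveOneOutSummary:
    """Range of the leave-one-out reruns and whether robustness held."""

    min_or: float
    max_or: float
    sign_change: bool          # any rerun crossing OR = 1 relative to the full fit
    all_significant: bool      # every rerun keeping p < 0.05


@dataclass(frozen=True)
class ReportRow:
    variant: str
    stratum: str               # "overall" or "factor:level"
    contrast: str
    pool: PoolResult
    per_study: tuple[EffectEstimate, ...] = ()
    bias: BiasReport | None = None
    loo: LeaveOneOutSummary | None = None
    hwe_rerun: PoolResult | None = None


@dataclass
class AnalysisReport:
    rows: list[ReportRow]
    config: MetaConfig
    provenance: str
    notes: list[str] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)


def _loo_summary(corpus, variant, contrast, config, full_pool) -> LeaveOneOutSummary:
    runs = leave_one_out(corpus, variant, contrast, config)
    ors = [p.pooled_or for _, p in runs]
    base_side = full_pool.pooled_or > 1.0
    return LeaveOneOutSummary(
        min_or=min(ors),
        max_or=max(ors),
        sign_change=any((o > 1.0) != base_side for o in ors),
        all_significant=all(p.p_or < 0.05 for _, p in runs),
    )


def run_full_analysis(
    corpus: StudyCorpus,
    config: MetaConfig | None = None,
    variants: list[str] | None = None,
    subgroup_factors: tuple[str, ...] = ("ethnicity",),
) -> AnalysisReport:
    """Run the complete meta-analysis; deterministic given corpus and config."""
    config = config or MetaConfig()
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    if variants is None:
        variants = list(dict.fromkeys(r.variant for r in corpus))
    report = AnalysisReport(rows=[], config=config, provenance=corpus.provenance)
    for variant in variants:
        if not any(r.variant == variant for r in corpus):
            report.errors[variant] = f"variant {variant!r} absent from corpus"
            continue
        for contrast in GENETIC_MODELS:
            model = GenotypeMetaAnalysis(corpus, variant, contrast, config)
            res = model.fit()
            bias = res.bias() if res.k >= 3 else None
            loo = (_loo_summary(corpus, variant, contrast, config, res.pool)
                   if res.k >= 2 else None)
            report.rows.append(ReportRow(
                variant=variant, stratum="overall", contrast=contrast,
                pool=res.pool, per_study=tuple(res.effects),
                bias=bias, loo=loo, hwe_rerun=res.hwe_exclusion_refit().pool,
            ))
            overall = res.pool
            for factor in subgroup_factors:
                try:
                    strata = subgroup_analysis(corpus, variant, contrast, factor, config)
                except ValueError as exc:
                    note = f"{variant}/{contrast}: subgroup factor skipped: {exc}"
                    if note not in report.notes:
                        report.notes.append(note)
                    continue
                for level, pool in strata.items():
                    if (pool.pooled_or > 1.0) != (overall.pooled_or > 1.0):
                        report.notes.append(
                            f"{variant}/{contrast}: {factor}={level} pooled OR "
                            f"({pool.pooled_or:.3f}) lies on the opposite side of 1 "
                            f"from the overall estimate ({overall.pooled_or:.3f}); "
                            f"check per-stratum allele orientation in the source data"
                        )
                    report.rows.append(ReportRow(
                        variant=variant, stratum=f"{factor}:{level}",
                        contrast=contrast, pool=pool,
                    ))
    return report


# ---------------------------------------------------------------------------
# serialization

def report_to_dict(report: AnalysisReport) -> dict:
    return dataclasses.asdict(report)


def _pool_from(d: dict | None) -> PoolResult | None:
    if d is None:
        return None
    het = d.get("heterogeneity")
    return PoolResult(**{
        **d,
        "heterogeneity": HeterogeneityResult(**het) if het else None,
        "excluded_study_ids": tuple(d["excluded_study_ids"]),
    })


def report_from_dict(data: dict) -> AnalysisReport:
    rows = []
    for r in data["rows"]:
        bias = r.get("bias")
        rows.append(ReportRow(
            variant=r["variant"], stratum=r["stratum"], contrast=r["contrast"],
            pool=_pool_from(r["pool"]),
            per_study=tuple(EffectEstimate(**e) for e in r["per_study"]),
            bias=BiasReport(**{**bias, "adjusted": _pool_from(bias["adjusted"])})
            if bias else None,
            loo=LeaveOneOutSummary(**r["loo"]) if r.get("loo") else None,
            hwe_rerun=_pool_from(r.get("hwe_rerun")),
        ))
    return AnalysisReport(
        rows=rows, config=MetaConfig(**data["config"]),
        provenance=data["provenance"], notes=list(data["notes"]),
        errors=dict(data["errors"]),
    )


# ---------------------------------------------------------------------------
# file output

_TSV_HEADER = [
    "variant", "stratum", "contrast", "effect_model", "k",
    "I2", "P_H", "OR", "ci_low", "ci_high", "Z", "P_OR",
    "P_Begg", "P_Egger", "trimfill_k0", "excluded",
]


def _fmt(x, nd=3):
    return "" if x is None else f"{x:.{nd}f}"


def write_report(report: AnalysisReport, outdir) -> list[Path]:
    """Write report.tsv, report.json and per-contrast forest/funnel TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    tsv = outdir / "report.tsv"
    with open(tsv, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for r in report.rows:
            h = r.pool.heterogeneity
            cells = [
                r.variant, r.stratum, r.contrast, r.pool.effect_model, str(r.pool.k),
                _fmt(h.I2, 2) if h else "", _fmt(h.P_H) if h else "",
                _fmt(r.pool.pooled_or), _fmt(r.pool.ci_low), _fmt(r.pool.ci_high),
                _fmt(r.pool.z), _fmt(r.pool.p_or),
                _fmt(r.bias.begg_p) if r.bias else "",
                _fmt(r.bias.egger_p) if r.bias else "",
                str(r.bias.k0) if r.bias else "",
                ";".join(r.pool.excluded_study_ids),
            ]
            fh.write("\t".join(cells) + "\n")
    written.append(tsv)

    js = outdir / "report.json"
    with open(js, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report), fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(js)

    for r in report.rows:
        if r.stratum != "overall" or not r.per_study:
            continue
        stem = f"{r.variant}_{r.contrast}"
        forest = outdir / f"forest_{stem}.tsv"
        with open(forest, "w", encoding="utf-8") as fh:
            fh.write("study_id\todds_ratio\tci_low\tci_high\trow_type\n")
            for e in r.per_study:
                fh.write(
                    f"{e.study_id}\t{_fmt(e.odds_ratio)}\t"
                    f"{_fmt(math.exp(e.log_or - Z_95 * e.se))}\t"
                    f"{_fmt(math.exp(e.log_or + Z_95 * e.se))}\tstudy\n"
                )
            fh.write(
                f"pooled ({r.pool.effect_model})\t{_fmt(r.pool.pooled_or)}\t"
                f"{_fmt(r.pool.ci_low)}\t{_fmt(r.pool.ci_high)}\tpooled\n"
            )
        written.append(forest)
        funnel = outdir / f"funnel_{stem}.tsv"
        with open(funnel, "w", encoding="utf-8") as fh:
            fh.write("study_id\todds_ratio\tse\trow_type\n")
            for e in r.per_study:
                fh.write(f"{e.study_id}\t{_fmt(e.odds_ratio)}\t{_fmt(e.se)}\tstudy\n")
            fh.write(f"pooled\t{_fmt(r.pool.pooled_or)}\t\tpooled\n")
        written.append(funnel)
    return written
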