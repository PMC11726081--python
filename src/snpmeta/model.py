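"""The modelling surface: a meta-analysis model and its fitted results.

:class:`GenotypeMetaAnalysis` is built from a study corpus, a variant and a
genetic contrast; ``fit()`` selects the effect model from the heterogeneity of
the per-study log odds ratios (unless overridden) and returns a
:class:`MetaAnalysisResults` carrying the pooled estimate, its 95% CI and Z
test, the heterogeneity block, and handles for the downstream diagnostics:
``summary()``, ``leave_one_out()``, ``subgroups()``, ``bias()`` and the
forest/funnel plot-data frames.

>>> corpus = load_cdkn2a_corpus()
>>> res = GenotypeMetaAnalysis(corpus, "rs3731217", "allelic").fit()
>>> round(res.pooled_or, 3)
0.735
"""

from __future__ import annotations

import math

import pandas as pd

from .corpus import StudyCorpus, load_corpus, load_cdkn2a_corpus, hwe_filtered
from .contrasts import GENETIC_MODELS, collapse
from .perstudy import EffectEstimate, study_effect
from .pooling import (
    MetaConfig,
    PoolResult,
    Z_95,
    heterogeneity,
    pool_dl,
    pool_iv,
    pool_mh,
    select_model,
)
from .bias import BiasReport, bias_report

SUBGROUP_FACTORS = ("ethnicity", "genotyping_method", "source")


class GenotypeMetaAnalysis:
    """Meta-analysis of one variant under one genetic contrast.

    Parameters
    ----------
    corpus : StudyCorpus
        The study collection; records of other variants are ignored.
    variant : str
        Variant identifier to analyse (must occur in the corpus).
    contrast : str
        One of ``allelic``, ``homozygote``, ``heterozygote``, ``dominant``,
        ``recessive``.
    config : MetaConfig, optional
        Estimator and threshold configuration.
    """

    def __init__(self, corpus: StudyCorpus, variant: str, contrast: str = "allelic",
                 config: MetaConfig | None = None):
        if contrast not in GENETIC_MODELS:
            raise ValueError(f"unknown contrast {contrast!r}; expected one of {GENETIC_MODELS}")
        self.corpus = corpus
        self.variant = variant
        self.contrast = contrast
        self.config = config or MetaConfig()
        self.records = list(corpus.subset(variant))
        if not self.records:
            raise ValueError(f"variant {variant!r} absent from corpus")
        self._tables = [collapse(r.cases, r.controls, contrast) for r in self.records]
        self.excluded_study_ids = tuple(
            r.study_id for r, t in zip(self.records, self._tables) if t.is_degenerate
        )
        self._kept = [(r, t) for r, t in zip(self.records, self._tables) if not t.is_degenerate]

    @classmethod
    def from_csv(cls, path, variant: str, contrast: str = "allelic",
                 config: MetaConfig | None = None) -> "GenotypeMetaAnalysis":
        return cls(load_corpus(path), variant, contrast, config)

    @property
    def tables(self):
        """Non-degenerate 2x2 tables, in corpus order."""
        return [t for _, t in self._kept]

    @property
    def effects(self) -> list[EffectEstimate]:
        """Per-study (continuity-corrected where needed) log OR estimates."""
        return [
            study_effect(t, study_id=r.study_id, model=self.contrast,
                         correction=self.config.correction)
            for r, t in self._kept
        ]

    @property
    def k(self) -> int:
        return len(self._kept)

    def fit(self, effect_model: str = "auto") -> "MetaAnalysisResults":
        """Pool the studies; ``effect_model`` in {"auto", "fixed", "random"}."""
        if self.k == 0:
            raise ValueError(
                f"no informative studies: all {len(self.records)} tables are "
                f"degenerate under the {self.contrast} contrast"
            )
        effects = self.effects
        het = heterogeneity(effects) if self.k >= 2 else None
        if effect_model == "auto":
            chosen = "fixed" if het is None else select_model(
                het, self.config.i2_threshold, self.config.ph_threshold)
        elif effect_model in ("fixed", "random"):
            chosen = effect_model
        else:
            raise ValueError(f"effect_model must be auto/fixed/random, got {effect_model!r}")
        if chosen == "random":
            pool = pool_dl(effects, het, excluded=self.excluded_study_ids)
        elif self.config.fixed_method == "mh":
            pool = pool_mh(self.tables, het, excluded=self.excluded_study_ids)
        elif self.config.fixed_method == "iv":
            pool = pool_iv(effects, het, excluded=self.excluded_study_ids)
        else:
            raise ValueError(f"unknown fixed_method {self.config.fixed_method!r}")
        return MetaAnalysisResults(self, pool, effects)


class MetaAnalysisResults:
    """Fitted pooled estimate plus diagnostics, statsmodels-results style."""

    def __init__(self, model: GenotypeMetaAnalysis, pool: PoolResult,
                 effects: list[EffectEstimate]):
        self.model = model
        self.pool = pool
        self.effects = effects

    # -- flat accessors -------------------------------------------------
    pooled_or = property(lambda self: self.pool.pooled_or)
    ci_low = property(lambda self: self.pool.ci_low)
    ci_high = property(lambda self: self.pool.ci_high)
    z = property(lambda self: self.pool.z)
    p_value = property(lambda self: self.pool.p_or)
    effect_model = property(lambda self: self.pool.effect_model)
    k = property(lambda self: self.pool.k)
    heterogeneity = property(lambda self: self.pool.heterogeneity)

    # -- diagnostics ----------------------------------------------------
    def leave_one_out(self) -> list[tuple[str, PoolResult]]:
        """Refit omitting each study in turn (same model-selection rule)."""
        return leave_one_out(self.model.corpus, self.model.variant,
                             self.model.contrast, self.model.config)

    def subgroups(self, factor: str = "ethnicity") -> dict[str, PoolResult]:
        return subgroup_analysis(self.model.corpus, self.model.variant,
                                 self.model.contrast, factor, self.model.config)

    def bias(self) -> BiasReport:
        """Begg/Egger tests and trim-and-fill (requires k >= 3)."""
        return bias_report(self.effects, self.model.config)

    def hwe_exclusion_refit(self) -> "MetaAnalysisResults":
        """Refit on the corpus with HWE-violating control arms removed."""
        filtered = hwe_filtered(self.model.corpus, self.model.config.hwe_alpha)
        return GenotypeMetaAnalysis(filtered, self.model.variant,
                                    self.model.contrast, self.model.config).fit()

    # -- plot-data exports ---------------------------------------------
    def forest_data(self) -> pd.DataFrame:
        """Per-study OR with 95% CI and weight, plus the pooled diamond row."""
        rows = []
        w_sum = sum(1.0 / e.variance for e in self.effects)
        for e in self.effects:
            rows.append({
                "study_id": e.study_id,
                "odds_ratio": e.odds_ratio,
                "ci_low": math.exp(e.log_or - Z_95 * e.se),
                "ci_high": math.exp(e.log_or + Z_95 * e.se),
                "weight_pct": 100.0 / (e.variance * w_sum),
                "row_type": "study",
            })
        rows.append({
            "study_id": f"pooled ({self.effect_model})",
            "odds_ratio": self.pooled_or,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "weight_pct": 100.0,
            "row_type": "pooled",
        })
        return pd.DataFrame(rows)

    def funnel_data(self) -> pd.DataFrame:
        """Per-study (OR, SE) pairs plus the pooled reference line."""
        df = pd.DataFrame({
            "study_id": [e.study_id for e in self.effects],
            "odds_ratio": [e.odds_ratio for e in self.effects],
            "se": [e.se for e in self.effects],
        })
        df.attrs["pooled_or"] = self.pooled_or
        return df

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        m = self.model
        lines = [
            f"Genotype meta-analysis: {m.variant}, {m.contrast} contrast",
            "=" * 60,
            f"studies pooled (k)        {self.k}",
            f"effect model              {self.effect_model} ({self.pool.method})",
            f"pooled OR [95% CI]        {self.pooled_or:.3f} [{self.ci_low:.3f}, {self.ci_high:.3f}]",
            f"Z (p)                     {self.z:.3f} ({self.p_value:.3g})",
        ]
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(
                f"heterogeneity             Q={h.Q:.2f} (df={h.df}, P={h.P_H:.3f}), "
                f"I2={h.I2:.2f}%, tau2={h.tau2:.4f}"
            )
        if self.pool.excluded_study_ids:
            lines.append(f"excluded (degenerate)     {', '.join(self.pool.excluded_study_ids)}")
        lines.append("=" * 60)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<MetaAnalysisResults {self.model.variant}/{self.model.contrast}: "
                f"OR={self.pooled_or:.3f} ({self.effect_model}, k={self.k})>")


def leave_one_out(corpus: StudyCorpus, variant: str, contrast: str,
                  config: MetaConfig | None = None) -> list[tuple[str, PoolResult]]:
    """Systematically omit one study at a time and re-pool the remainder.

    Each rerun applies the same effect-model selection rule as the full fit.
    """
    config = config or MetaConfig()
    sub = corpus.subset(variant)
    if len(sub) < 2:
        raise ValueError("leave-one-out requires at least two studies")
    out = []
    for omit in sub.study_ids():
        rest = StudyCorpus([r for r in sub if r.study_id != omit], sub.provenance)
        res = GenotypeMetaAnalysis(rest, variant, contrast, config).fit()
        out.append((omit, res.pool))
    return out


def subgroup_analysis(corpus: StudyCorpus, variant: str, contrast: str,
                      factor: str, config: MetaConfig | None = None
                      ) -> dict[str, PoolResult]:
    """Pool independently within each level of a stratification factor.

    Strata with a single study are reported as that study's own OR with the
    ``single_study`` flag set.  Raises when the factor is not populated on
    every record (e.g. source of controls on the bundled corpus).
    """
    config = config or MetaConfig()
    if factor not in SUBGROUP_FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {SUBGROUP_FACTORS}")
    sub = corpus.subset(variant)
    values = [getattr(r, factor) for r in sub]
    if any(v is None or v == "" for v in values):
        raise ValueError(f"factor {factor!r} not populated on every record")
    levels = list(dict.fromkeys(values))  # stable order of first appearance
    if not levels:
        raise ValueError("empty stratum set")
    out: dict[str, PoolResult] = {}
    for level in levels:
        stratum = StudyCorpus([r for r in sub if getattr(r, factor) == level],
                              sub.provenance)
        out[level] = GenotypeMetaAnalysis(stratum, variant, contrast, config).fit().pool
    return out
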