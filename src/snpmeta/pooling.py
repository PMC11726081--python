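"""Fixed- and random-effects pooling of 2x2 tables on the log odds-ratio scale.

Three pooled estimators are provided:

* :func:`pool_mh` — Mantel-Haenszel fixed-effect odds ratio on raw counts,
  with the Robins-Breslow-Greenland variance for its log.  Tolerates zero
  cells without correction.
* :func:`pool_iv` — inverse-variance fixed-effect pooling of per-study log
  odds ratios (the "fixed" estimator of the mainstream commercial
  meta-analysis packages, which several published genetic meta-analyses label
  Mantel-Haenszel).
* :func:`pool_dl` — DerSimonian-Laird random-effects pooling, with the moment
  estimator of the between-study variance tau^2.

Heterogeneity is quantified by Cochran's Q on inverse-variance weights,
I^2 = max(0, (Q - df)/Q) * 100 and the DL tau^2.  The effect-model selection
rule is *random* when I^2 exceeds a threshold (default 50%) **or** the Q test
is significant (default alpha 0.05), *fixed* otherwise; both thresholds are
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .contrasts import TwoByTwo
from .perstudy import EffectEstimate

Z_95 = 1.959963984540054  # normal 97.5% point; 95% CI multiplier


@dataclass(frozen=True)
class MetaConfig:
    """Analysis-wide knobs with their conventional defaults."""

    fixed_method: str = "iv"          # "iv" or "mh"
    i2_threshold: float = 50.0        # percent; random effects above this
    ph_threshold: float = 0.05        # Q-test alpha; random effects below this
    correction: str = "add-half"      # per-study zero-cell policy
    hwe_alpha: float = 0.05           # control-HWE exclusion threshold
    bias_alpha: float = 0.05          # Begg/Egger trigger for trim-and-fill
    trim_side: str = "auto"           # side on which trim-and-fill imputes


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran Q with df, its p-value, I^2 (percent) and DL tau^2."""

    Q: float
    df: int
    P_H: float
    I2: float
    tau2: float


@dataclass(frozen=True)
class PoolResult:
    """A pooled odds ratio with 95% CI, Z test, and embedded heterogeneity."""

    pooled_or: float
    ci_low: float
    ci_high: float
    z: float
    p_or: float
    effect_model: str                 # "fixed" or "random"
    method: str                       # "mh", "iv" or "dl"
    k: int
    heterogeneity: HeterogeneityResult | None = None
    excluded_study_ids: tuple[str, ...] = ()
    log_or: float = 0.0
    se: float = float("nan")
    single_study: bool = False


def _finish(log_or: float, se: float, *, effect_model: str, method: str, k: int,
            heterogeneity: HeterogeneityResult | None,
            excluded: tuple[str, ...] = (), single: bool = False) -> PoolResult:
    z = log_or / se
    return PoolResult(
        pooled_or=math.exp(log_or),
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        z=z,
        p_or=float(2 * stats.norm.sf(abs(z))),
        effect_model=effect_model,
        method=method,
        k=k,
        heterogeneity=heterogeneity,
        excluded_study_ids=excluded,
        log_or=log_or,
        se=se,
        single_study=single,
    )


def pool_mh(
    tables: list[TwoByTwo],
    heterogeneity_result: HeterogeneityResult | None = None,
    excluded: tuple[str, ...] = (),
) -> PoolResult:
    """Mantel-Haenszel fixed-effect pooled OR with RBG variance.

    Operates on raw (uncorrected) counts; studies with zero cells contribute
    through their non-zero cross-product.  Degenerate tables must be removed
    by the caller (their MH weights are zero anyway).
    """
    tables = [t for t in tables if not t.is_degenerate]
    if not tables:
        raise ValueError("no non-degenerate tables to pool")
    R = S = 0.0
    sum_PR = sum_mix = sum_QS = 0.0
    for t in tables:
        a, b, c, d = t.case_exposed, t.case_unexposed, t.ctrl_exposed, t.ctrl_unexposed
        n = t.n
        r_i = a * d / n          # concordant cross-product
        s_i = b * c / n          # discordant cross-product
        p_i = (a + d) / n
        q_i = (b + c) / n
        R += r_i
        S += s_i
        sum_PR += p_i * r_i
        sum_mix += p_i * s_i + q_i * r_i
        sum_QS += q_i * s_i
    if R == 0 or S == 0:
        raise ValueError("Mantel-Haenszel estimate undefined: a pooled cross-product is zero")
    log_or = math.log(R / S)
    var = sum_PR / (2 * R * R) + sum_mix / (2 * R * S) + sum_QS / (2 * S * S)
    return _finish(log_or, math.sqrt(var), effect_model="fixed", method="mh",
                   k=len(tables), heterogeneity=heterogeneity_result,
                   excluded=excluded, single=len(tables) == 1)


def pool_iv(
    effects: list[EffectEstimate],
    heterogeneity_result: HeterogeneityResult | None = None,
    excluded: tuple[str, ...] = (),
) -> PoolResult:
    """Inverse-variance fixed-effect pooling of per-study log odds ratios."""
    if not effects:
        raise ValueError("no effects to pool")
    w = np.array([1.0 / e.variance for e in effects])
    y = np.array([e.log_or for e in effects])
    mu = float((w * y).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    return _finish(mu, se, effect_model="fixed", method="iv", k=len(effects),
                   heterogeneity=heterogeneity_result, excluded=excluded,
                   single=len(effects) == 1)


def heterogeneity(effects: list[EffectEstimate]) -> HeterogeneityResult:
    """Cochran Q, its p-value, I^2 and the DL moment estimate of tau^2."""
    if len(effects) < 2:
        raise ValueError("heterogeneity requires at least two effects")
    w = np.array([1.0 / e.variance for e in effects])
    y = np.array([e.log_or for e in effects])
    mu = (w * y).sum() / w.sum()
    Q = float((w * (y - mu) ** 2).sum())
    df = len(effects) - 1
    P_H = float(stats.chi2.sf(Q, df))
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    C = float(w.sum() - (w ** 2).sum() / w.sum())
    tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
    return HeterogeneityResult(Q=Q, df=df, P_H=P_H, I2=I2, tau2=tau2)


def pool_dl(
    effects: list[EffectEstimate],
    heterogeneity_result: HeterogeneityResult | None = None,
    excluded: tuple[str, ...] = (),
) -> PoolResult:
    """DerSimonian-Laird random-effects pooling.

    With tau^2 = 0 (homogeneous effects) this reduces exactly to
    inverse-variance fixed pooling.
    """
    if len(effects) < 2:
        raise ValueError("random-effects pooling requires k >= 2; use fixed-effect pooling")
    het = heterogeneity_result or heterogeneity(effects)
    w = np.array([1.0 / (e.variance + het.tau2) for e in effects])
    y = np.array([e.log_or for e in effects])
    mu = float((w * y).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    return _finish(mu, se, effect_model="random", method="dl", k=len(effects),
                   heterogeneity=het, excluded=excluded)


def select_model(
    h: HeterogeneityResult,
    i2_threshold: float = 50.0,
    ph_threshold: float = 0.05,
) -> str:
    """Choose the effect model from heterogeneity: random iff I^2 > threshold
    or the Q test is significant; fixed otherwise."""
    return "random" if (h.I2 > i2_threshold or h.P_H < ph_threshold) else "fixed"
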