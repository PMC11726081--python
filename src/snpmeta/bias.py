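"""Small-study (publication) bias: Begg's rank test, Egger's regression,
and the Duval-Tweedie trim-and-fill correction.

All three operate on per-study log odds ratios and standard errors.  Begg's
test rank-correlates variance-standardized deviations from the fixed pooled
effect with the per-study variances (Kendall score, normal approximation with
continuity correction and tie-adjusted variance).  Egger's test regresses the
standardized effect on precision by OLS and t-tests the intercept on k-2 df.
Trim-and-fill iterates the L0 estimator of the number of suppressed studies,
imputes their mirror images about the trimmed pooled effect, and re-pools the
augmented set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .perstudy import EffectEstimate
from .pooling import (
    HeterogeneityResult,
    MetaConfig,
    PoolResult,
    heterogeneity,
    pool_dl,
    pool_iv,
    select_model,
)


@dataclass(frozen=True)
class TrimAndFillResult:
    """Outcome of the trim-and-fill adjustment."""

    k0: int
    side: str                              # side on which studies were imputed
    imputed: tuple[EffectEstimate, ...]    # the k0 mirror-imputed effects
    adjusted: PoolResult | None            # pooling of the augmented set; None when k0 = 0
    iterations: int


@dataclass(frozen=True)
class BiasReport:
    """Begg + Egger tests and, when either triggers, the trim-and-fill result."""

    begg_statistic: float      # continuity-corrected standardized Kendall score
    begg_p: float
    egger_intercept: float
    egger_se: float
    egger_p: float
    k0: int
    adjusted: PoolResult | None


def _require_k(effects, k_min: int, what: str) -> None:
    if len(effects) < k_min:
        raise ValueError(f"insufficient studies for {what}: need k >= {k_min}, got {len(effects)}")


def _tie_term(values, f) -> float:
    return sum(f(t) for t in Counter(values).values() if t > 1)


def begg_test(effects: list[EffectEstimate]) -> tuple[float, float]:
    """Begg-Mazumdar rank correlation test for funnel asymmetry.

    Returns the continuity-corrected standardized Kendall score and its
    two-sided normal p-value.  Invariant to the ordering of the studies.
    """
    _require_k(effects, 3, "Begg's test")
    y = np.array([e.log_or for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    mu = (w * y).sum() / w.sum()
    v_star = v - 1.0 / w.sum()   # variance of (y_i - fixed pooled estimate)
    t = (y - mu) / np.sqrt(v_star)
    n = len(effects)
    score = 0
    for i in range(n):
        for j in range(i + 1, n):
            score += int(np.sign(t[j] - t[i]) * np.sign(v[j] - v[i]))
    # tau-b style tie-adjusted variance of the Kendall score
    var = (
        n * (n - 1) * (2 * n + 5)
        - _tie_term(t.tolist(), lambda k: k * (k - 1) * (2 * k + 5))
        - _tie_term(v.tolist(), lambda k: k * (k - 1) * (2 * k + 5))
    ) / 18.0
    if n > 2:
        var += (
            _tie_term(t.tolist(), lambda k: k * (k - 1) * (k - 2))
            * _tie_term(v.tolist(), lambda k: k * (k - 1) * (k - 2))
        ) / (9.0 * n * (n - 1) * (n - 2))
    var += (
        _tie_term(t.tolist(), lambda k: k * (k - 1))
        * _tie_term(v.tolist(), lambda k: k * (k - 1))
    ) / (2.0 * n * (n - 1))
    if var <= 0:
        return 0.0, 1.0
    z = 0.0 if score == 0 else (abs(score) - 1) / math.sqrt(var) * math.copysign(1, score)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def egger_test(effects: list[EffectEstimate]) -> tuple[float, float, float]:
    """Egger's regression test: OLS of log_or/se on 1/se.

    Returns (intercept, its SE, two-sided t p-value on k-2 df).  A nonzero
    intercept indicates that small (imprecise) studies report systematically
    different effects than precision alone predicts.
    """
    _require_k(effects, 3, "Egger's test")
    se = np.array([e.se for e in effects])
    y = np.array([e.log_or for e in effects]) / se
    x = sm.add_constant(1.0 / se)
    fit = sm.OLS(y, x).fit()
    return float(fit.params[0]), float(fit.bse[0]), float(fit.pvalues[0])


def trim_and_fill(
    effects: list[EffectEstimate],
    side: str = "auto",
    config: MetaConfig | None = None,
    max_iter: int = 50,
) -> TrimAndFillResult:
    """Duval-Tweedie trim-and-fill with the L0 estimator.

    ``side`` is where missing studies are presumed suppressed ("left" means
    effects more negative than the pool are missing); ``auto`` infers it from
    the sign of the Egger intercept (a positive intercept means small studies
    skew positive, so the missing studies lie on the left).  Trimming and the
    interim pooled estimate use fixed inverse-variance pooling; the final
    adjusted pool of the augmented set applies the usual effect-model
    selection rule.
    """
    _require_k(effects, 3, "trim-and-fill")
    config = config or MetaConfig()
    if side == "auto":
        intercept, _, _ = egger_test(effects)
        side = "left" if intercept >= 0 else "right"
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'auto', 'left' or 'right', got {side!r}")

    # mirror so that the excess (over-represented) side is always the right
    flip = -1.0 if side == "right" else 1.0
    x = np.array([e.log_or for e in effects]) * flip
    w = np.array([1.0 / e.variance for e in effects])
    n = len(effects)
    order = np.argsort(x)          # ascending; trimming removes from the top

    k0 = 0
    for iteration in range(1, max_iter + 1):
        keep = order[: n - k0] if k0 else order
        mu = float((w[keep] * x[keep]).sum() / w[keep].sum())
        centered = x - mu
        ranks = stats.rankdata(np.abs(centered))
        t_pos = float(ranks[centered > 0].sum())
        l0 = (4.0 * t_pos - n * (n + 1)) / (2.0 * n - 1.0)
        k0_new = max(0, min(int(math.floor(l0 + 0.5)), n - 2))
        if k0_new == k0:
            break
        k0 = k0_new
    else:
        raise RuntimeError(
            f"trim-and-fill did not converge in {max_iter} iterations (last k0={k0})"
        )

    if k0 == 0:
        return TrimAndFillResult(0, side, (), None, iteration)

    keep = order[: n - k0]
    mu = float((w[keep] * x[keep]).sum() / w[keep].sum())
    imputed = []
    for idx in order[n - k0:]:
        e = effects[idx]
        mirrored = flip * (2.0 * mu - x[idx])
        imputed.append(EffectEstimate(
            study_id=f"filled:{e.study_id}", model=e.model,
            log_or=mirrored, se=e.se, corrected=e.corrected,
        ))
    augmented = list(effects) + imputed
    het = heterogeneity(augmented)
    if select_model(het, config.i2_threshold, config.ph_threshold) == "random":
        adjusted = pool_dl(augmented, het)
    else:
        adjusted = pool_iv(augmented, het)
    return TrimAndFillResult(k0, side, tuple(imputed), adjusted, iteration)


def bias_report(
    effects: list[EffectEstimate],
    config: MetaConfig | None = None,
) -> BiasReport:
    """Run the full bias suite; trim-and-fill only when a test triggers.

    Either Begg's or Egger's test significant at ``config.bias_alpha``
    triggers the correction (which test the original analysts keyed on is
    rarely stated; triggering on either is the conservative reading).
    """
    config = config or MetaConfig()
    stat, begg_p = begg_test(effects)
    intercept, egger_se, egger_p = egger_test(effects)
    k0, adjusted = 0, None
    if begg_p < config.bias_alpha or egger_p < config.bias_alpha:
        tf = trim_and_fill(effects, side=config.trim_side, config=config)
        k0, adjusted = tf.k0, tf.adjusted
    return BiasReport(
        begg_statistic=stat, begg_p=begg_p,
        egger_intercept=intercept, egger_se=egger_se, egger_p=egger_p,
        k0=k0, adjusted=adjusted,
    )
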