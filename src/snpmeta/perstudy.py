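"""Per-study statistics: Hardy-Weinberg testing, allele frequency, log odds ratio."""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .corpus import GenotypeCounts
from .contrasts import TwoByTwo


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square goodness-of-fit of genotype counts to HWE proportions.

    One degree of freedom (three classes minus one estimated allele
    frequency), no continuity correction.  ``monomorphic`` flags samples in
    which an allele is absent; those fit HWE trivially (chi2 = 0, p = 1).
    """

    chi_square: float
    p_value: float
    expected_counts: tuple[float, float, float]
    monomorphic: bool = False


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio with its Woolf standard error."""

    study_id: str
    model: str
    log_or: float
    se: float
    corrected: bool = False

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def variance(self) -> float:
        return self.se ** 2


def minor_allele_frequency(g: GenotypeCounts) -> float:
    """Frequency of the designated minor allele: (AB + 2*BB) / 2N.

    The orientation is the variant's global one, so the value may exceed 0.5
    in populations where the globally minor allele is locally the major one.
    """
    if g.total <= 0:
        raise ValueError("genotype total must be positive")
    return g.n_minor / (2 * g.total)


def hwe_chi_square(g: GenotypeCounts) -> HWEResult:
    """Test genotype counts against Hardy-Weinberg proportions (p^2, 2pq, q^2).

    Uses the sample allele frequency, Pearson chi-square with 1 df and no
    Yates correction — the variant that reproduces published per-study HWE
    p-values computed with the common online calculators.
    """
    n = g.total
    if n <= 0:
        raise ValueError("genotype total must be positive")
    q = g.n_minor / (2 * n)
    p = 1.0 - q
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    if q == 0.0 or q == 1.0:
        return HWEResult(0.0, 1.0, expected, monomorphic=True)
    observed = (g.n_AA, g.n_AB, g.n_BB)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HWEResult(chi2, float(stats.chi2.sf(chi2, 1)), expected)


def study_effect(
    table: TwoByTwo,
    study_id: str = "",
    model: str = "",
    correction: str = "add-half",
) -> EffectEstimate:
    """Log odds ratio and Woolf SE ``sqrt(1/a + 1/b + 1/c + 1/d)`` of one table.

    ``correction='add-half'`` adds 0.5 to all four cells of a table containing
    any zero cell (per-study, the standard sparse-data treatment);
    ``correction='none'`` raises on zero cells.  Degenerate tables (an empty
    exposure column in both arms) carry no information and always raise.
    """
    if table.is_degenerate:
        raise ValueError("degenerate table: an exposure column is empty in both arms")
    corrected = False
    if table.has_zero_cell:
        if correction == "add-half":
            table = table.corrected(0.5)
            corrected = True
        elif correction == "none":
            raise ValueError("zero cell with correction='none'")
        else:
            raise ValueError(f"unknown correction policy {correction!r}")
    a, b, c, d = table.cells
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(study_id=study_id, model=model, log_or=log_or, se=se, corrected=corrected)
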