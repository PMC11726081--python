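"""Synthetic case-control genotype corpora with known truth.

The generator emulates the statistical structure the analysis assumes:
control genotypes drawn from Hardy-Weinberg proportions at a chosen minor
allele frequency, and case genotype probabilities tilted by a multiplicative
per-allele odds ratio psi — genotype risk proportional to ``psi**m`` for m
copies of the minor allele.  Under that log-additive model the population
allelic odds ratio equals psi exactly, which gives every downstream estimator
a closed-form truth to recover.  Between-study heterogeneity is introduced by
drawing each study's log psi from Normal(log psi, tau^2); funnel asymmetry by
deleting the smallest studies whose realized effect falls on the weaker side
of the truth.

Randomness is split into one independent stream per study (seeded from the
global seed and the study index), so corpora are bit-reproducible regardless
of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .corpus import ETHNICITIES, StudyCorpus, StudyRecord, GenotypeCounts
from .contrasts import collapse
from .perstudy import study_effect


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings.

    Defaults mirror a mid-sized published SNP meta-analysis: 14 studies, a
    control minor-allele frequency of 0.13 and a protective per-allele odds
    ratio of 0.75, with study sizes spanning the range seen in real corpora.
    """

    k_studies: int = 14
    maf: float = 0.13
    psi: float = 0.75
    tau: float = 0.0
    n_case_range: tuple[int, int] = (50, 1500)
    n_ctrl_range: tuple[int, int] = (50, 5200)
    suppress: int = 0
    seed: int = 0
    variant: str = "rs3731217"

    def validate(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.psi <= 0:
            raise ValueError("psi must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        for lo, hi in (self.n_case_range, self.n_ctrl_range):
            if lo <= 0 or hi < lo:
                raise ValueError("size ranges must be positive and ordered")
        if self.suppress < 0:
            raise ValueError("suppress must be non-negative")


def _genotype_probs(q: float, psi: float) -> tuple[np.ndarray, np.ndarray]:
    p = 1.0 - q
    ctrl = np.array([p * p, 2 * p * q, q * q])          # AA, AB, BB under HWE
    case = ctrl * np.array([1.0, psi, psi * psi])       # multiplicative risk
    return ctrl, case / case.sum()


def simulate_study(config: SimulationConfig, study_psi: float,
                   sizes: tuple[int, int], index: int = 0) -> StudyRecord:
    """Draw one study: multinomial genotype counts in each arm.

    ``sizes`` is (n_cases, n_controls).  Fully reproducible from
    ``(config.seed, index)``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2 * index + 1])
    ctrl_p, case_p = _genotype_probs(config.maf, study_psi)
    n_case, n_ctrl = sizes
    case = rng.multinomial(n_case, case_p)
    ctrl = rng.multinomial(n_ctrl, ctrl_p)
    return StudyRecord(
        study_id=f"sim_{index:03d}",
        author_year=f"Synthetic {index}",
        country="Simulated",
        ethnicity=ETHNICITIES[index % len(ETHNICITIES)],
        genotyping_method="simulation",
        variant=config.variant,
        cases=GenotypeCounts(*(int(c) for c in case)),
        controls=GenotypeCounts(*(int(c) for c in ctrl)),
    )


def _weakness(record: StudyRecord, direction: float) -> float:
    """How far a study's realized allelic effect sits on the weak side.

    ``direction`` is +1 when the true effect is protective-or-null (weak
    studies have the larger log OR) and -1 for risk-increasing effects.
    """
    table = collapse(record.cases, record.controls, "allelic")
    if table.is_degenerate:
        return math.inf
    return direction * study_effect(table, correction="add-half").log_or


def simulate_corpus(config: SimulationConfig) -> StudyCorpus:
    """Generate ``k_studies`` studies, then optionally suppress some.

    Per-study effects are ``log psi_i ~ Normal(log psi, tau^2)``.  With
    ``suppress`` > 0 the corpus loses that many studies, chosen as the
    smallest-n studies among those whose realized allelic effect lies on the
    weaker side of the true effect — the classic publication-bias mechanism
    that produces one-sided funnel truncation.
    """
    config.validate()
    if config.suppress >= config.k_studies:
        raise ValueError("suppress must be smaller than k_studies")
    records: list[StudyRecord] = []
    for i in range(config.k_studies):
        rng = np.random.default_rng([config.seed, 2 * i])
        n_case = int(rng.integers(config.n_case_range[0], config.n_case_range[1] + 1))
        n_ctrl = int(rng.integers(config.n_ctrl_range[0], config.n_ctrl_range[1] + 1))
        log_psi_i = rng.normal(math.log(config.psi), config.tau)
        records.append(simulate_study(config, math.exp(log_psi_i), (n_case, n_ctrl), i))
    if config.suppress:
        direction = 1.0 if config.psi <= 1.0 else -1.0
        scored = sorted(
            records,
            key=lambda r: (
                _weakness(r, direction) <= 0.0,          # weak-side studies first
                r.cases.total + r.controls.total,        # smallest first
            ),
        )
        drop = {r.study_id for r in scored[: config.suppress]}
        records = [r for r in records if r.study_id not in drop]
    return StudyCorpus(records, provenance=f"simulated corpus (seed={config.seed})")
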