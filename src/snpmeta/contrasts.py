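"""Genetic contrasts: collapse genotype triples into 2x2 exposure tables.

Five standard genetic models are supported, each reducing the three genotype
classes (AA major homozygote, AB heterozygote, BB minor homozygote) to a
two-level exposure:

============  =====================  ==========================
model         exposed                unexposed
============  =====================  ==========================
allelic       B alleles              A alleles   (unit: alleles)
homozygote    BB individuals         AA individuals
heterozygote  AB individuals         AA individuals
dominant      BB+AB individuals      AA individuals
recessive     BB individuals         AB+AA individuals
============  =====================  ==========================

The allelic model counts 2N chromosomes as independent observations; the four
genotype models count individuals.  A table is *degenerate* under a model when
an exposure column is empty in both arms (for example no BB carrier anywhere):
such a study carries no information about the contrast and is excluded from
pooling by the callers, with the exclusion logged on the result.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import GenotypeCounts

GENETIC_MODELS = ("allelic", "homozygote", "heterozygote", "dominant", "recessive")


@dataclass(frozen=True)
class TwoByTwo:
    """A case-control 2x2 exposure table.

    Cells are counts; half-integers appear only after continuity correction.
    The odds ratio is (case_exposed * ctrl_unexposed) / (case_unexposed * ctrl_exposed).
    """

    case_exposed: float
    case_unexposed: float
    ctrl_exposed: float
    ctrl_unexposed: float

    @property
    def n(self) -> float:
        return self.case_exposed + self.case_unexposed + self.ctrl_exposed + self.ctrl_unexposed

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.case_exposed, self.case_unexposed, self.ctrl_exposed, self.ctrl_unexposed)

    @property
    def has_zero_cell(self) -> bool:
        return any(c == 0 for c in self.cells)

    @property
    def is_degenerate(self) -> bool:
        """True when an exposure column is empty in both arms."""
        return (self.case_exposed == 0 and self.ctrl_exposed == 0) or (
            self.case_unexposed == 0 and self.ctrl_unexposed == 0
        )

    def corrected(self, delta: float = 0.5) -> "TwoByTwo":
        """All four cells shifted by ``delta`` (continuity correction)."""
        return TwoByTwo(*(c + delta for c in self.cells))


def collapse(cases: GenotypeCounts, controls: GenotypeCounts, model: str) -> TwoByTwo:
    """Collapse a pair of genotype triples into the 2x2 table of ``model``."""
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}; expected one of {GENETIC_MODELS}")

    def one(g: GenotypeCounts) -> tuple[int, int]:
        if model == "allelic":
            return g.n_minor, g.n_major
        if model == "homozygote":
            return g.n_BB, g.n_AA
        if model == "heterozygote":
            return g.n_AB, g.n_AA
        if model == "dominant":
            return g.n_BB + g.n_AB, g.n_AA
        return g.n_BB, g.n_AB + g.n_AA  # recessive

    ce, cu = one(cases)
    ke, ku = one(controls)
    return TwoByTwo(ce, cu, ke, ku)
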