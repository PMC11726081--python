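"""Study corpus: data model, CSV I/O, validation and the bundled CDKN2A/ALL corpus.

A corpus is an ordered collection of case-control genotype studies for one or
more biallelic SNPs.  Genotypes are stored on a fixed per-variant orientation:
``AA`` is the homozygote of the designated reference (major) allele, ``BB`` the
homozygote of the designated minor allele.  For the bundled CDKN2A corpus the
minor allele is C for rs3731217 and T for rs3731249, and that orientation is
kept globally even for the two studies whose control minor-allele frequency
exceeds 0.5 -- pooling is only meaningful on a single orientation.

Several columns of a published genotype table are redundant (allele counts,
minor-allele frequency, Hardy-Weinberg p-value can all be recomputed from the
genotype counts); :func:`validate_record` exploits that redundancy so that a
mis-transcribed digit cannot pass silently.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

ETHNICITIES = ("Asian", "Caucasian", "African", "Hispanic")
VARIANTS = ("rs3731217", "rs3731249")

#: minor (risk/protective) allele per variant, used only for display
MINOR_ALLELE = {"rs3731217": "C", "rs3731249": "T"}
MAJOR_ALLELE = {"rs3731217": "T", "rs3731249": "C"}

CSV_COLUMNS = [
    "study_id", "author_year", "country", "ethnicity", "genotyping_method",
    "variant", "n_case", "n_control",
    "case_AA", "case_AB", "case_BB", "ctrl_AA", "ctrl_AB", "ctrl_BB",
    "reported_maf", "reported_hwe_p", "nos",
]

MAF_TOLERANCE = 0.0005
HWE_TOLERANCE = 0.005


class CorpusError(Exception):
    """Schema, parse or validation failure while loading a corpus."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts of one study arm on the fixed variant orientation.

    ``n_AA`` counts major-allele homozygotes, ``n_AB`` heterozygotes and
    ``n_BB`` minor-allele homozygotes.  Construction is permissive; use
    :func:`validate_record` (or ``violations``) to check invariants so that
    invalid transcriptions are reported rather than thrown mid-parse.
    """

    n_AA: int
    n_AB: int
    n_BB: int

    @property
    def total(self) -> int:
        return self.n_AA + self.n_AB + self.n_BB

    @property
    def n_major(self) -> int:
        """Count of major (reference) alleles: 2*AA + AB."""
        return 2 * self.n_AA + self.n_AB

    @property
    def n_minor(self) -> int:
        """Count of minor alleles: AB + 2*BB."""
        return self.n_AB + 2 * self.n_BB

    def violations(self, label: str = "") -> list[str]:
        out = []
        tag = f"{label}: " if label else ""
        for name in ("n_AA", "n_AB", "n_BB"):
            v = getattr(self, name)
            if not isinstance(v, int):
                out.append(f"{tag}{name} is not an integer ({v!r})")
            elif v < 0:
                out.append(f"{tag}{name} is negative ({v})")
        if not out and self.total <= 0:
            out.append(f"{tag}genotype total is zero")
        return out


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study of one variant (a row of the corpus table)."""

    study_id: str
    author_year: str
    country: str
    ethnicity: str
    genotyping_method: str
    variant: str
    cases: GenotypeCounts
    controls: GenotypeCounts
    reported_maf: float | None = None
    reported_hwe_p: float | None = None
    nos_score: int | None = None
    source: str | None = None  # source of controls; not populated in the bundled corpus


@dataclass
class StudyCorpus:
    """Ordered, id-unique collection of study records."""

    records: list[StudyRecord] = field(default_factory=list)
    provenance: str = ""

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, variant: str | None = None, **fields) -> "StudyCorpus":
        """Records matching ``variant`` and any exact field filters, in order."""
        if variant is not None and variant not in VARIANTS:
            raise CorpusError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        recs = [
            r for r in self.records
            if (variant is None or r.variant == variant)
            and all(getattr(r, k) == v for k, v in fields.items())
        ]
        return StudyCorpus(recs, provenance=self.provenance)

    def study_ids(self) -> list[str]:
        return [r.study_id for r in self.records]


def validate_record(record: StudyRecord) -> list[str]:
    """Return human-readable invariant violations for one record (empty = valid).

    Checks genotype-count sanity, the closed label sets, and -- when the
    redundant published columns are supplied -- agreement of the printed
    minor-allele frequency (within +/-0.0005) and control Hardy-Weinberg
    p-value (within +/-0.005) with recomputation from the genotype counts.
    """
    from .perstudy import hwe_chi_square, minor_allele_frequency

    out: list[str] = []
    out += record.cases.violations("cases")
    out += record.controls.violations("controls")
    if record.ethnicity not in ETHNICITIES:
        out.append(f"ethnicity {record.ethnicity!r} not in {ETHNICITIES}")
    if record.variant not in VARIANTS:
        out.append(f"variant {record.variant!r} not in {VARIANTS}")
    if out:
        return out  # frequency checks need sane counts
    if record.reported_maf is not None:
        maf = minor_allele_frequency(record.controls)
        if abs(maf - record.reported_maf) > MAF_TOLERANCE:
            out.append(
                f"control minor-allele frequency {maf:.4f} disagrees with "
                f"reported {record.reported_maf:.4f} (tolerance {MAF_TOLERANCE})"
            )
    if record.reported_hwe_p is not None:
        hwe = hwe_chi_square(record.controls)
        if abs(hwe.p_value - record.reported_hwe_p) > HWE_TOLERANCE:
            out.append(
                f"control HWE p {hwe.p_value:.4f} disagrees with reported "
                f"{record.reported_hwe_p:.4f} (tolerance {HWE_TOLERANCE})"
            )
    return out


def _parse_int(value: str, column: str, row_id: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise CorpusError(f"row {row_id}: column {column!r} is not an integer: {value!r}")


def _parse_opt_float(value: str) -> float | None:
    value = value.strip()
    return float(value) if value else None


def _read_rows(handle: Iterable[str], name: str) -> StudyCorpus:
    reader = csv.DictReader(handle)
    if reader.fieldnames is None:
        raise CorpusError(f"{name}: empty file, no header")
    missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise CorpusError(f"{name}: missing columns {missing}")
    corpus = StudyCorpus(provenance=name)
    seen: set[str] = set()
    for row in reader:
        rid = row["study_id"]
        if rid in seen:
            raise CorpusError(f"duplicate study_id {rid!r}")
        seen.add(rid)
        cases = GenotypeCounts(*(_parse_int(row[c], c, rid) for c in ("case_AA", "case_AB", "case_BB")))
        controls = GenotypeCounts(*(_parse_int(row[c], c, rid) for c in ("ctrl_AA", "ctrl_AB", "ctrl_BB")))
        record = StudyRecord(
            study_id=rid,
            author_year=row["author_year"],
            country=row["country"],
            ethnicity=row["ethnicity"],
            genotyping_method=row["genotyping_method"],
            variant=row["variant"],
            cases=cases,
            controls=controls,
            reported_maf=_parse_opt_float(row["reported_maf"]),
            reported_hwe_p=_parse_opt_float(row["reported_hwe_p"]),
            nos_score=int(row["nos"]) if row["nos"].strip() else None,
        )
        n_case = _parse_int(row["n_case"], "n_case", rid)
        n_ctrl = _parse_int(row["n_control"], "n_control", rid)
        problems = validate_record(record)
        if cases.total != n_case:
            problems.append(f"case genotype total {cases.total} != declared n_case {n_case}")
        if controls.total != n_ctrl:
            problems.append(f"control genotype total {controls.total} != declared n_control {n_ctrl}")
        if problems:
            raise CorpusError(f"row {rid}: " + "; ".join(problems))
        corpus.records.append(record)
    if not corpus.records:
        raise CorpusError(f"{name}: no records")
    return corpus


def load_corpus(path) -> StudyCorpus:
    """Load and fully validate a corpus CSV; abort with row-identified diagnostics."""
    with open(path, newline="", encoding="utf-8") as fh:
        return _read_rows(fh, str(path))


def loads_corpus(text: str, name: str = "<string>") -> StudyCorpus:
    """Parse a corpus from CSV text (convenience for tests and pipelines)."""
    return _read_rows(io.StringIO(text), name)


def write_corpus(corpus: StudyCorpus, path) -> None:
    """Write the corpus back in the standard CSV dialect (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in corpus:
            writer.writerow([
                r.study_id, r.author_year, r.country, r.ethnicity,
                r.genotyping_method, r.variant,
                r.cases.total, r.controls.total,
                r.cases.n_AA, r.cases.n_AB, r.cases.n_BB,
                r.controls.n_AA, r.controls.n_AB, r.controls.n_BB,
                "" if r.reported_maf is None else f"{r.reported_maf:.3f}",
                "" if r.reported_hwe_p is None else f"{r.reported_hwe_p:.3f}",
                "" if r.nos_score is None else r.nos_score,
            ])


def corpus_totals(corpus: StudyCorpus, variant: str) -> tuple[int, int]:
    """Total cases and controls over the records of one variant."""
    if variant not in VARIANTS:
        raise CorpusError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    sub = [r for r in corpus if r.variant == variant]
    return (sum(r.cases.total for r in sub), sum(r.controls.total for r in sub))


def load_cdkn2a_corpus() -> StudyCorpus:
    """The bundled corpus: 22 published case-control studies of CDKN2A
    rs3731217 (14 studies) and rs3731249 (8 studies) versus pediatric acute
    lymphoblastic leukemia.

    The one blank ``reported_hwe_p`` cell (Kreile 2016) reflects a defect in
    the published table, where the HWE column repeats the MAF value
    digit-for-digit and matches no recomputation; the genotype counts of that
    row verify against the redundant allele-count and MAF columns.
    """
    text = resources.files("snpmeta.data").joinpath("cdkn2a_all_corpus.csv").read_text("utf-8")
    corpus = loads_corpus(text, "bundled CDKN2A pediatric-ALL corpus")
    return corpus


def hwe_filtered(corpus: StudyCorpus, alpha: float = 0.05) -> StudyCorpus:
    """Corpus restricted to studies whose controls are consistent with HWE.

    Removes studies with control HWE p < ``alpha`` (the sensitivity rerun).
    On the bundled corpus this is a no-op: every included study's controls
    satisfy HWE at the 0.05 level.
    """
    from .perstudy import hwe_chi_square

    keep = [r for r in corpus if hwe_chi_square(r.controls).p_value >= alpha]
    out = StudyCorpus(keep, provenance=corpus.provenance + f" [HWE-filtered at {alpha}]")
    return out
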