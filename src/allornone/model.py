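"""Domain types for the all-or-none SNP analysis of replicated selection lines.

The experimental design this package models is a replicated selection
experiment: several independently bred "selected" lines and several unselected
"control" lines derived from one outbred base population.  Per-line allele
frequencies of a panel of SNPs are screened for the *all-or-none* pattern: a
locus fixed for the same allele in every replicate line of one line type while
fixed in no replicate line of the other type.

Coordinate conventions
----------------------
SNP positions are 1-based (dbSNP convention).  Gene intervals are stored
internally 0-based half-open; BED output is 0-based half-open and GFF3 output
1-based inclusive, matching each format's standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# ---------------------------------------------------------------------------
# errors

class AllOrNoneError(Exception):
    """Base class for all package errors."""


class FormatError(AllOrNoneError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(AllOrNoneError):
    """A value violates a domain invariant (e.g. frequency outside [0, 1])."""


class DesignMismatchError(AllOrNoneError):
    """A panel references line ids absent from the line design (or vice versa)."""


class ParameterError(AllOrNoneError):
    """An operation was called with an out-of-range parameter."""


class CapabilityError(AllOrNoneError):
    """The exact method cannot handle the problem size; use Monte Carlo."""


# ---------------------------------------------------------------------------
# enumerated string values

SELECTED = "selected"
CONTROL = "control"
LINETYPES = (SELECTED, CONTROL)

FAMILIES = ("Vmn1r", "Vmn2r", "Fpr", "other")

NUCLEOTIDES = "ACGT"


def infer_family(gene_id: str) -> str:
    """Receptor family from a gene symbol prefix (Vmn1r*, Vmn2r*, Fpr*)."""
    for fam in ("Vmn1r", "Vmn2r", "Fpr"):
        if gene_id.startswith(fam):
            return fam
    return "other"


# ---------------------------------------------------------------------------
# SNP panel

@dataclass
class SnpRecord:
    """One SNP with its focal-allele frequency in every replicate line.

    ``pos`` is 1-based.  ``freqs`` maps line id -> frequency of
    ``focal_allele`` in that line, each in [0, 1].
    """

    snp_id: str
    chrom: str
    pos: int
    focal_allele: str
    other_allele: str
    freqs: dict[str, float]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if self.focal_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: focal and other allele are identical")
        for line_id, f in self.freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(
                    f"{self.snp_id}: frequency {f!r} for line {line_id} outside [0, 1]"
                )


@dataclass
class LineDesign:
    """Replicate-line layout plus the drift parameters of the breeding design.

    ``lines`` is an ordered list of (line_id, linetype) with linetype one of
    ``"selected"`` / ``"control"``.  ``ne`` is the effective population size
    per line and ``generations`` the number of generations of breeding; the
    defaults (35 and 88) are the values of the high-runner mouse selection
    experiment this package was built around.
    """

    lines: list[tuple[str, str]]
    ne: int = 35
    generations: int = 88

    def __post_init__(self) -> None:
        if self.ne < 1:
            raise ParameterError(f"ne must be >= 1, got {self.ne}")
        if self.generations < 0:
            raise ParameterError(f"generations must be >= 0, got {self.generations}")
        seen: set[str] = set()
        for line_id, linetype in self.lines:
            if linetype not in LINETYPES:
                raise ValidationError(f"unknown linetype {linetype!r} for line {line_id}")
            if line_id in seen:
                raise ValidationError(f"duplicate line id {line_id!r}")
            seen.add(line_id)
        for lt in LINETYPES:
            if not any(t == lt for _, t in self.lines):
                raise ValidationError(f"design has no {lt} line")

    @property
    def line_ids(self) -> list[str]:
        return [lid for lid, _ in self.lines]

    def ids_of(self, linetype: str) -> list[str]:
        return [lid for lid, lt in self.lines if lt == linetype]

    @property
    def selected_ids(self) -> list[str]:
        return self.ids_of(SELECTED)

    @property
    def control_ids(self) -> list[str]:
        return self.ids_of(CONTROL)


def _panel_sort_key(rec: SnpRecord) -> tuple[str, int]:
    return (rec.chrom, rec.pos)


@dataclass
class SnpPanel:
    """A coordinate-sorted collection of :class:`SnpRecord` plus its design.

    Records are re-sorted by (chrom, pos) on construction; snp ids must be
    unique and every record must carry a frequency for every design line.
    """

    design: LineDesign
    records: list[SnpRecord]

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=_panel_sort_key)
        ids: set[str] = set()
        expected = set(self.design.line_ids)
        for rec in self.records:
            if rec.snp_id in ids:
                raise ValidationError(f"duplicate snp id {rec.snp_id!r}")
            ids.add(rec.snp_id)
            got = set(rec.freqs)
            if got != expected:
                missing = expected - got
                extra = got - expected
                raise DesignMismatchError(
                    f"{rec.snp_id}: line ids do not match design "
                    f"(missing {sorted(missing)}, unknown {sorted(extra)})"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]


# ---------------------------------------------------------------------------
# genes and expression

@dataclass
class GeneModel:
    """A gene with strand and exon structure, 0-based half-open coordinates.

    ``exons`` are listed in transcription order: the first exon is the 5'-most,
    which for a minus-strand gene is the genomically *rightmost* one.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    family: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.family not in FAMILIES:
            raise ValidationError(f"{self.gene_id}: unknown family {self.family!r}")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene must have >= 1 exon")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"{self.gene_id}: bad span [{self.start}, {self.end})")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(
                    f"{self.gene_id}: exon [{s}, {e}) outside gene span "
                    f"[{self.start}, {self.end})"
                )
        genomic = self.genomic_exons()
        for (s1, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValidationError(f"{self.gene_id}: overlapping exons")
        # transcription order: ascending starts on '+', descending on '-'
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValidationError(f"{self.gene_id}: exons not in transcription order")

    def genomic_exons(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class DeGeneRecord:
    """Differential-expression call for one gene (q < 0.05 means DE)."""

    gene_id: str
    log2fc: float
    qvalue: float
    family: str = "other"

    def __post_init__(self) -> None:
        if not 0.0 <= self.qvalue <= 1.0:
            raise ValidationError(f"{self.gene_id}: q-value {self.qvalue} outside [0, 1]")
        if self.family not in FAMILIES:
            raise ValidationError(f"{self.gene_id}: unknown family {self.family!r}")

    @property
    def is_de(self) -> bool:
        return self.qvalue < 0.05


# ---------------------------------------------------------------------------
# derived results

@dataclass
class ClassifiedSnp:
    """Outcome of the all-or-none classification of one SNP.

    ``fixed_linetype`` names the line type whose replicates are all fixed for
    the same allele; ``fixed_allele`` is ``"focal"`` or ``"other"`` relative to
    the record's focal allele.  Both are ``"none"`` when the SNP is not
    all-or-none.
    """

    snp: SnpRecord
    is_all_or_none: bool
    fixed_linetype: str = "none"
    fixed_allele: str = "none"

    def __post_init__(self) -> None:
        if self.is_all_or_none:
            if self.fixed_linetype == "none" or self.fixed_allele == "none":
                raise ValidationError(
                    f"{self.snp.snp_id}: all-or-none SNP must name linetype and allele"
                )
        elif self.fixed_linetype != "none" or self.fixed_allele != "none":
            raise ValidationError(
                f"{self.snp.snp_id}: non all-or-none SNP cannot fix linetype/allele"
            )

    @property
    def fixed_base(self) -> str:
        if self.fixed_allele == "focal":
            return self.snp.focal_allele
        if self.fixed_allele == "other":
            return self.snp.other_allele
        return "none"


@dataclass
class SnpCluster:
    """A padded genomic interval around a proximity group of SNPs.

    ``start``/``end`` are 1-based padded bounds (first SNP - pad, last SNP +
    pad, clamped at 1 and at the chromosome length when known); ``members``
    are the snp ids in position order.
    """

    cluster_id: str
    chrom: str
    start: int
    end: int
    members: list[str]
    size: int = field(default=0)

    def __post_init__(self) -> None:
        if self.size == 0:
            self.size = len(self.members)
        if self.size != len(self.members) and self.members:
            raise ValidationError(f"{self.cluster_id}: size != number of members")
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"{self.cluster_id}: bad interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SnpGeneAnnotation:
    """One (SNP, gene) proximity relation in the style of a locus table.

    ``relation`` is ``"upstream"``/``"downstream"`` (strand-aware, with a
    positive ``distance_bp``) or ``"exon k"``/``"intron k"`` (1-based in
    transcription order, distance 0).  The carrier fields ``chrom``, ``pos``,
    ``gene_strand`` and ``allele_label`` are filled in by the annotator so the
    table writer needs no extra lookups.
    """

    snp_id: str
    gene_id: str
    relation: str
    distance_bp: int
    chrom: str = ""
    pos: int = 0
    gene_strand: str = "."
    allele_label: str = ""

    def __post_init__(self) -> None:
        intragenic = self.relation.startswith(("exon", "intron"))
        if intragenic and self.distance_bp != 0:
            raise ValidationError(f"{self.snp_id}/{self.gene_id}: intragenic distance must be 0")
        if not intragenic and self.distance_bp <= 0:
            raise ValidationError(
                f"{self.snp_id}/{self.gene_id}: {self.relation} distance must be > 0"
            )


@dataclass
class DriftNullResult:
    """Neutral-drift probabilities of line fixation and of the all-or-none pattern.

    Probabilities refer to a single locus starting at frequency ``p0`` in every
    line, evolving independently for ``generations`` Wright-Fisher generations
    with ``two_n`` gametes per generation.
    """

    p0: float
    two_n: int
    generations: int
    p_fix_focal: float
    p_fix_other: float
    p_segregating: float
    p_all_or_none: float
    mode: str = "not_fixed_for_focal"
    delta: float = 0.0
    expected_count: float | None = None
    mc_ci: tuple[float, float] | None = None


@dataclass
class PermutationResult:
    """Result of a one-sided upper permutation test with the add-one estimator."""

    statistic_name: str
    observed: float
    null_samples: list[float]
    p_value: float
    n_perm: int
    seed: int
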