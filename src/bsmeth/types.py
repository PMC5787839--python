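"""Domain types shared across the pipeline.

Coordinates are 1-based inclusive everywhere inside the package (the GFF3 /
Bismark convention); BED's 0-based half-open coordinates are converted at the
I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CONTEXTS = ("CG", "CHG", "CHH")

#: columns of a cytosine-record table (Bismark-style cytosine report layout)
RECORD_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_meth",
    "count_unmeth",
    "context",
    "trinucleotide",
]

#: additional columns carried by a site-methylation table
SITE_COLUMNS = RECORD_COLUMNS + ["ml_raw", "ml_corrected", "covered"]

VALID_BASES = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class ValidationError(ValueError):
    """Raised when parsed records violate a domain invariant."""


class CapacityError(ValueError):
    """Raised when a simulated genome cannot host the requested features."""


@dataclass
class GenomeSequence:
    """An in-memory genome: ordered chromosomes of uppercase DNA.

    Parameters
    ----------
    chroms
        Mapping of chromosome name to sequence; insertion order is the
        canonical chromosome order used by every writer.
    spike_in_chrom
        Optional name of the unmethylated spike-in control chromosome
        (e.g. the lambda phage genome added before bisulfite treatment).
    """

    chroms: dict[str, str]
    spike_in_chrom: str | None = None

    def __post_init__(self) -> None:
        if not self.chroms:
            raise ValidationError("genome has no chromosomes")
        for name, seq in self.chroms.items():
            if len(seq) == 0:
                raise ValidationError(f"chromosome {name!r} has length 0")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains non-IUPAC characters: "
                    f"{sorted(bad)}"
                )
        if self.spike_in_chrom is not None and self.spike_in_chrom not in self.chroms:
            raise ValidationError(
                f"spike_in_chrom {self.spike_in_chrom!r} not among chromosomes"
            )

    @property
    def names(self) -> list[str]:
        return list(self.chroms)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}


def _intervals_sorted_nonoverlapping(intervals: list[tuple[int, int]]) -> bool:
    prev_end = 0
    for start, end in intervals:
        if start <= prev_end or end < start:
            return False
        prev_end = end
    return True


@dataclass
class GeneModel:
    """A protein-coding gene with transcript structure.

    ``exons`` are 1-based inclusive intervals sorted along the chromosome;
    ``utr5``/``utr3``/``cds`` partition the exonic bases.
    """

    gene_id: str
    chrom: str
    strand: str
    transcript_start: int
    transcript_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    expression: float | None = None
    de_label: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.transcript_end < self.transcript_start:
            raise ValidationError(f"gene {self.gene_id}: end < start")
        if not self.exons:
            self.exons = [(self.transcript_start, self.transcript_end)]
        self.exons = sorted(self.exons)
        if not _intervals_sorted_nonoverlapping(self.exons):
            raise ValidationError(f"gene {self.gene_id}: exons overlap")
        for start, end in self.exons + self.cds + self.utr5 + self.utr3:
            if start < self.transcript_start or end > self.transcript_end:
                raise ValidationError(
                    f"gene {self.gene_id}: child feature {start}-{end} outside "
                    f"transcript span {self.transcript_start}-{self.transcript_end}"
                )

    @property
    def length(self) -> int:
        return self.transcript_end - self.transcript_start + 1


#: TE classes recognised by default; anything else maps to "other".
DEFAULT_TE_CLASSES = ("LTR_Gypsy", "LTR_Copia", "hAT_Tag1", "hAT_Tip100", "other")


@dataclass
class TEAnnotation:
    """A transposable-element annotation (1-based inclusive span)."""

    te_id: str
    chrom: str
    strand: str
    start: int
    end: int
    te_class: str = "other"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"TE {self.te_id}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1
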