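"""Core domain types shared by the pipeline stages.

Coordinates are 0-based half-open throughout (BED convention); strand is
"+" or "-"; gene features are named in transcription direction, so the
5' UTR of a minus-strand gene lies at the right-hand (higher-coordinate)
end of its span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class MappingStatus(str, Enum):
    UNIQUE = "unique"
    MULTI = "multi"
    UNMAPPED = "unmapped"
    CONTAMINANT = "contaminant"


@dataclass(frozen=True)
class CloneRead:
    """One sequenced clone: id plus raw nucleotide string."""

    id: str
    sequence: str


@dataclass
class ClipTag:
    """A distinct extracted insert with its clone support."""

    sequence: str
    count: int
    clone_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.count != len(self.clone_ids):
            raise ValueError("count must equal len(clone_ids)")


@dataclass
class TagAlignment:
    """A tag's genomic placement (or lack of one)."""

    tag_id: str
    chrom: str | None
    start: int
    end: int
    strand: str
    status: MappingStatus

    def __post_init__(self) -> None:
        if self.chrom is not None and not self.start < self.end:
            raise ValueError(f"empty interval for {self.tag_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Strand-aware transcript structure with derived introns.

    ``exons`` are sorted, disjoint genomic blocks; ``cds`` is the genomic
    (start, end) of the coding span or None for non-coding / unknown loci.
    ``known`` is an input flag: False marks EST-supported but unannotated
    loci that cannot be assigned sub-features.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None
    known: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"empty exon in {self.gene_id}")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if e0 > s1:
                raise ValueError(f"exons overlap/unsorted in {self.gene_id}")
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.start <= cs < ce <= self.end):
                raise ValueError(f"CDS outside exon span in {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exon blocks, genomic order."""
        return [
            (e0, s1)
            for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
            if s1 > e0
        ]


@dataclass
class FeatureAssignment:
    """Where a uniquely mapped tag lands relative to the annotation."""

    tag_id: str
    category: str  # intergenic | unknown_gene | intron | utr5 | cds | utr3
    gene_id: str | None
    overlap_fraction: float

    def __post_init__(self) -> None:
        if (self.category == "intergenic") != (self.gene_id is None):
            raise ValueError("intergenic iff gene_id is None")


@dataclass
class IntronContext:
    """A tag's containing intron and its splice-site distances.

    Distances use the exclusive-gap convention: the number of intronic
    nucleotides strictly between the splice junction and the tag's
    proximal end, so dist_upstream + tag_length + dist_downstream equals
    the intron length exactly. Upstream means the donor (5') side in
    transcription direction.
    """

    tag_id: str
    gene_id: str
    intron_start: int
    intron_end: int
    intron_length: int
    dist_upstream: int
    dist_downstream: int
    tag_length: int

    def __post_init__(self) -> None:
        if self.dist_upstream < 0 or self.dist_downstream < 0:
            raise ValueError("negative splice-site distance")
        if self.dist_upstream + self.tag_length + self.dist_downstream != self.intron_length:
            raise ValueError("distance conservation violated")


@dataclass
class MappingSummary:
    n_total: int
    n_contaminant: int
    n_unmapped_or_multi: int
    n_unique: int

    def __post_init__(self) -> None:
        if self.n_contaminant + self.n_unmapped_or_multi + self.n_unique != self.n_total:
            raise ValueError("mapping counts do not sum to total")

    @property
    def fractions(self) -> dict[str, float]:
        if self.n_total == 0:
            return {"contaminant": 0.0, "unmapped_or_multi": 0.0, "unique": 0.0}
        t = self.n_total
        return {
            "contaminant": self.n_contaminant / t,
            "unmapped_or_multi": self.n_unmapped_or_multi / t,
            "unique": self.n_unique / t,
        }


@dataclass
class DESummary:
    """Categorized counts of a two-condition differential-expression table."""

    n_shared_down: int = 0
    n_shared_up: int = 0
    n_only_control: int = 0
    n_only_kd: int = 0
    n_shared_down_strong: int = 0
    n_shared_up_strong: int = 0

    @property
    def n_down(self) -> int:
        return self.n_shared_down + self.n_only_control

    @property
    def n_up(self) -> int:
        return self.n_shared_up + self.n_only_kd

    @property
    def n_shared(self) -> int:
        return self.n_shared_down + self.n_shared_up

    def as_dict(self) -> dict[str, int]:
        return {
            "n_down": self.n_down,
            "n_up": self.n_up,
            "n_shared_down": self.n_shared_down,
            "n_shared_up": self.n_shared_up,
            "n_only_control": self.n_only_control,
            "n_only_kd": self.n_only_kd,
            "n_shared_down_strong": self.n_shared_down_strong,
            "n_shared_up_strong": self.n_shared_up_strong,
        }
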