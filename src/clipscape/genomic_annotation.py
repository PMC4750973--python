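"""Classify uniquely mapped tags against gene models, and transcript-level
ORF logic: premature-stop detection for an alternative exon and virtual
RT-PCR product sizing.

Classification is by majority overlap of per-base feature labels.
A tag overlapping several genes is assigned to a known gene before an
unknown one, then by larger overlap, then by lexicographic gene id, so
assignments are stable. Sub-feature ties (a tag straddling a boundary
exactly) break toward cds, then intron, then utr5, then utr3.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .models import FeatureAssignment, GeneModel, MappingStatus, TagAlignment
from .seq import STOP_CODONS_DNA, to_dna

_TIE_ORDER = ("cds", "intron", "utr5", "utr3")


class GeneIndex:
    """Interval index over gene spans, one tree per chromosome."""

    def __init__(self, models: list[GeneModel]):
        self.models = {g.gene_id: g for g in models}
        self.trees: dict[str, IntervalTree] = {}
        for g in models:
            self.trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [self.models[iv.data] for iv in tree.overlap(start, end)]


def base_label(gene: GeneModel, pos: int) -> str:
    """Feature label of a single genomic base within the gene span."""
    in_exon = any(s <= pos < e for s, e in gene.exons)
    if not in_exon:
        return "intron"
    if gene.cds is None:
        return "cds"  # unknown/non-coding: exonic bases have no UTR/CDS split
    cs, ce = gene.cds
    if cs <= pos < ce:
        return "cds"
    if pos < cs:
        return "utr5" if gene.strand == "+" else "utr3"
    return "utr3" if gene.strand == "+" else "utr5"


def classify_within_gene(alignment: TagAlignment, gene: GeneModel) -> str:
    """Majority per-base label of the tag's bases inside the gene span."""
    votes = {lab: 0 for lab in _TIE_ORDER}
    for pos in range(max(alignment.start, gene.start), min(alignment.end, gene.end)):
        votes[base_label(gene, pos)] += 1
    if sum(votes.values()) == 0:
        raise ValueError("tag does not overlap the gene span")
    best = max(votes.values())
    for lab in _TIE_ORDER:  # tie-break priority
        if votes[lab] == best:
            return lab


def assign_gene_context(
    alignment: TagAlignment, index: GeneIndex | list[GeneModel]
) -> FeatureAssignment:
    """Assign a uniquely mapped tag to a gene and sub-feature, or intergenic."""
    if alignment.status is not MappingStatus.UNIQUE:
        raise ValueError("only uniquely mapped tags can be annotated")
    if isinstance(index, list):
        index = GeneIndex(index)
    if alignment.chrom not in index.trees and index.trees:
        # a chromosome entirely absent from the annotation is an input error
        raise ValueError(f"chromosome {alignment.chrom!r} absent from annotation")
    candidates = index.overlapping(alignment.chrom, alignment.start, alignment.end)
    if not candidates:
        return FeatureAssignment(alignment.tag_id, "intergenic", None, 0.0)

    def overlap(g: GeneModel) -> int:
        return min(alignment.end, g.end) - max(alignment.start, g.start)

    candidates.sort(key=lambda g: (not g.known, -overlap(g), g.gene_id))
    gene = candidates[0]
    frac = overlap(gene) / alignment.length
    if not gene.known:
        return FeatureAssignment(alignment.tag_id, "unknown_gene", gene.gene_id, frac)
    sub = classify_within_gene(alignment, gene)
    return FeatureAssignment(alignment.tag_id, sub, gene.gene_id, frac)


def category_fractions(assignments: list[FeatureAssignment]) -> dict[str, float]:
    """Within-known-gene category fractions (the pie-chart numbers)."""
    within = [a for a in assignments if a.category in _TIE_ORDER]
    if not within:
        return {lab: 0.0 for lab in _TIE_ORDER}
    return {
        lab: sum(1 for a in within if a.category == lab) / len(within)
        for lab in _TIE_ORDER
    }


# ---------------------------------------------------------------------------
# ORF logic

@dataclass
class PrematureStopResult:
    stop_found: bool
    stop_codon_index: int | None  # codon offset from the CDS start, 0-based
    frame_preserved: bool


def _first_stop_codon(seq_dna: str, cds_offset: int) -> int | None:
    for ci in range((len(seq_dna) - cds_offset) // 3):
        codon = seq_dna[cds_offset + 3 * ci : cds_offset + 3 * ci + 3]
        if codon in STOP_CODONS_DNA:
            return ci
    return None


def detect_premature_stop(
    skip_transcript: str, inclusion_transcript: str, cds_offset: int
) -> PrematureStopResult:
    """Does including the alternative exon introduce a premature stop?

    Both transcripts are spliced exonic sequences (RNA or DNA alphabet);
    the inclusion isoform is the skip isoform with one extra exon. Codons
    are read from ``cds_offset``. A premature stop is an in-frame stop in
    the inclusion isoform occurring strictly before the skip isoform's
    first stop (or anywhere, when the skip isoform has none within the
    given sequence). ``frame_preserved`` is true when the exon length is a
    multiple of 3, i.e. downstream codons stay in frame.
    """
    skip = to_dna(skip_transcript.upper())
    incl = to_dna(inclusion_transcript.upper())
    if cds_offset < 0 or cds_offset >= len(incl):
        raise ValueError("CDS offset outside the transcript")
    if len(incl) < len(skip):
        raise ValueError("inclusion isoform shorter than skip isoform")
    exon_len = len(incl) - len(skip)
    if exon_len < 1:
        raise ValueError("alternative exon must have length >= 1")
    stop_incl = _first_stop_codon(incl, cds_offset)
    stop_skip = _first_stop_codon(skip, cds_offset)
    premature = stop_incl is not None and (stop_skip is None or stop_incl < stop_skip)
    return PrematureStopResult(
        stop_found=premature,
        stop_codon_index=stop_incl if premature else None,
        frame_preserved=exon_len % 3 == 0,
    )


def rtpcr_product_sizes(
    isoforms: dict[str, list[tuple[str, int]]],
    forward: tuple[str, int],
    reverse: tuple[str, int],
) -> dict[str, int]:
    """Virtual RT-PCR product length per isoform.

    Each isoform is an ordered list of (exon_name, exon_length) in
    transcript orientation. ``forward``/``reverse`` give (exon_name,
    offset) of each primer's 5' end within its exon, transcript
    coordinates. The product spans both primer 5' ends inclusive, so for
    isoforms differing only by an exon between the primers the size
    difference equals that exon's length.
    """
    out = {}
    for name, exons in isoforms.items():
        pos = {}
        cum = 0
        for exon_name, length in exons:
            pos[exon_name] = cum
            cum += length
        for primer_name, (exon_name, off) in (("forward", forward), ("reverse", reverse)):
            if exon_name not in pos:
                raise ValueError(f"{primer_name} primer exon {exon_name!r} absent from isoform {name!r}")
        f = pos[forward[0]] + forward[1]
        r = pos[reverse[0]] + reverse[1]
        if f > r:
            raise ValueError(f"forward primer downstream of reverse in isoform {name!r}")
        out[name] = r - f + 1
    return out


def virtual_pcr(spliced_seq: str, fwd_primer: str, rev_primer: str) -> int:
    """Product size by string search: forward primer sense, reverse primer
    reverse-complemented. Independent check for the coordinate arithmetic."""
    from .seq import revcomp

    seq = to_dna(spliced_seq.upper())
    fwd = to_dna(fwd_primer.upper())
    rev = revcomp(to_dna(rev_primer.upper()))
    i = seq.find(fwd)
    j = seq.find(rev)
    if i == -1 or j == -1:
        raise ValueError("primer not found in spliced sequence")
    return j + len(rev) - i
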