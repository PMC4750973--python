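"""Tag placement and triage: contaminant screening, exact-match mapping,
import of external alignments, and the mapped/unmapped/contaminant summary.

The built-in mapper is an exact substring search of both genome strands —
enough to exercise the pipeline on synthetic genomes. Real-genome
alignments from external tools (BLAT/BLAST et al.) enter through
``import_alignments`` as BED6.

Contaminant screening runs before genome mapping: a tag matching both the
contaminant reference and the genome is reported as contaminant, mirroring
the usual CLIP triage order (bacterial rRNA is the classic contaminant).
"""

from __future__ import annotations

from .models import ClipTag, MappingStatus, MappingSummary, TagAlignment
from .seq import find_all, revcomp


def flag_contaminants(
    tags: list[ClipTag], contaminant_ref: dict[str, str]
) -> dict[str, bool]:
    """Tag sequence -> True when it occurs in the contaminant reference
    (exact substring, either strand)."""
    if not contaminant_ref:
        raise ValueError("contaminant reference is empty")
    refs = [s.upper() for s in contaminant_ref.values()]
    flags = {}
    for t in tags:
        seq = t.sequence.upper()
        rc = revcomp(seq)
        flags[t.sequence] = any(seq in r or rc in r for r in refs)
    return flags


def map_tags_exact(
    tags: list[ClipTag],
    genome: dict[str, str],
    *,
    tag_ids: dict[str, str] | None = None,
    min_len: int = 1,
    max_hits_reported: int = 10,
) -> list[TagAlignment]:
    """Exact substring mapping of each tag against both strands.

    One alignment record per placement; 0 hits yields a single
    status=unmapped record with no coordinates, >=2 hits yield
    status=multi records. Minus-strand hits carry forward-reference
    coordinates with strand "-".
    """
    alignments: list[TagAlignment] = []
    for i, t in enumerate(tags):
        tid = (tag_ids or {}).get(t.sequence, f"tag{i:05d}")
        seq = t.sequence.upper()
        if len(seq) < min_len:
            raise ValueError(f"tag {tid} shorter than min_len={min_len}")
        rc = revcomp(seq)
        hits: list[tuple[str, int, str]] = []
        for chrom, ref in genome.items():
            hits += [(chrom, p, "+") for p in find_all(ref, seq)]
            # a palindromic tag matches both strands at the same locus;
            # count the placement once, on the forward strand
            if rc != seq:
                hits += [(chrom, p, "-") for p in find_all(ref, rc)]
        if not hits:
            alignments.append(TagAlignment(tid, None, 0, 1, "+", MappingStatus.UNMAPPED))
            continue
        status = MappingStatus.UNIQUE if len(hits) == 1 else MappingStatus.MULTI
        for chrom, p, strand in hits[:max_hits_reported]:
            alignments.append(
                TagAlignment(tid, chrom, p, p + len(seq), strand, status)
            )
    return alignments


def import_alignments(
    bed_path,
    tags: list[ClipTag] | None = None,
    *,
    known_chroms: set[str] | None = None,
    multi_whitelist: set[str] | None = None,
) -> list[TagAlignment]:
    """Read BED6 alignments; tags with several lines become status=multi
    unless whitelisted. Round-trips with the BED writer."""
    from .io import read_bed6

    records = read_bed6(bed_path)
    if known_chroms is not None:
        for chrom, start, end, name, _ in records:
            if chrom not in known_chroms:
                raise ValueError(f"unknown chromosome {chrom!r} for tag {name}")
    per_tag: dict[str, int] = {}
    for _, _, _, name, _ in records:
        per_tag[name] = per_tag.get(name, 0) + 1
    out = []
    for chrom, start, end, name, strand in records:
        multi = per_tag[name] > 1 and name not in (multi_whitelist or set())
        out.append(
            TagAlignment(
                name, chrom, start, end, strand,
                MappingStatus.MULTI if multi else MappingStatus.UNIQUE,
            )
        )
    return out


def triage_tags(
    tags: list[ClipTag],
    genome: dict[str, str],
    contaminant_ref: dict[str, str] | None,
) -> tuple[list[TagAlignment], dict[str, MappingStatus]]:
    """Screen contaminants then map the rest; returns all alignment records
    plus the per-tag final status (keyed by tag sequence)."""
    status: dict[str, MappingStatus] = {}
    clean: list[ClipTag] = []
    if contaminant_ref:
        flags = flag_contaminants(tags, contaminant_ref)
    else:
        flags = {t.sequence: False for t in tags}
    tag_ids = {t.sequence: f"tag{i:05d}" for i, t in enumerate(tags)}
    for t in tags:
        if flags[t.sequence]:
            status[t.sequence] = MappingStatus.CONTAMINANT
        else:
            clean.append(t)
    alignments = map_tags_exact(clean, genome, tag_ids=tag_ids)
    by_id = {tag_ids[t.sequence]: t.sequence for t in clean}
    for a in alignments:
        status[by_id[a.tag_id]] = a.status
    return alignments, status


def summarize_mapping(status_by_tag: dict[str, MappingStatus]) -> MappingSummary:
    """Count distinct tags per triage class."""
    n_cont = sum(1 for s in status_by_tag.values() if s is MappingStatus.CONTAMINANT)
    n_uni = sum(1 for s in status_by_tag.values() if s is MappingStatus.UNIQUE)
    n_rest = len(status_by_tag) - n_cont - n_uni
    return MappingSummary(
        n_total=len(status_by_tag),
        n_contaminant=n_cont,
        n_unmapped_or_multi=n_rest,
        n_unique=n_uni,
    )
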