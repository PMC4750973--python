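"""Flat-file interchange: BED12/GTF gene models, BED6 alignments, TSV tables.

BED is 0-based half-open; GTF is 1-based inclusive. Internally everything
is 0-based half-open, so the GTF writer shifts starts by +1.
"""

from __future__ import annotations

from pathlib import Path

from .models import GeneModel, MappingStatus, TagAlignment


def write_bed12(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in models:
            start, end = g.start, g.end
            thick = g.cds if g.cds is not None else (start, start)
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - start) for s, _ in g.exons)
            # score column carries the known/unknown flag (1 known, 0 unknown)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom, start, end, g.gene_id, int(g.known), g.strand,
                            thick[0], thick[1], "0,0,0", len(g.exons), sizes, starts,
                        ],
                    )
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> list[GeneModel]:
    models = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"{path}:{ln}: expected 12 BED columns, got {len(f)}")
        chrom, start = f[0], int(f[1])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        thick = (int(f[6]), int(f[7]))
        cds = thick if thick[1] > thick[0] else None
        models.append(
            GeneModel(
                gene_id=f[3], chrom=chrom, strand=f[5], exons=exons, cds=cds,
                known=bool(int(f[4])),
            )
        )
    return models


def write_gtf(models: list[GeneModel], path: str | Path, source: str = "clipscape") -> None:
    with open(path, "w") as fh:
        for g in models:
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                f'gene_status "{"known" if g.known else "unknown"}";'
            )
            rows = [("transcript", g.start, g.end)]
            rows += [("exon", s, e) for s, e in g.exons]
            if g.cds is not None:
                cs, ce = g.cds
                for s, e in g.exons:
                    lo, hi = max(s, cs), min(e, ce)
                    if lo < hi:
                        rows.append(("CDS", lo, hi))
            for feat, s, e in rows:
                fh.write(
                    f"{g.chrom}\t{source}\t{feat}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_bed6(alignments: list[TagAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            if a.chrom is None:
                continue
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.tag_id}\t0\t{a.strand}\n")


def read_bed6(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Parse BED6 lines to (chrom, start, end, name, strand) tuples."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split()
        if len(f) < 6:
            raise ValueError(f"{path}:{ln}: expected >=6 BED columns, got {len(f)}")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
        if f[5] not in "+-":
            raise ValueError(f"{path}:{ln}: bad strand {f[5]!r}")
        out.append((f[0], start, end, f[3], f[5]))
    return out
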