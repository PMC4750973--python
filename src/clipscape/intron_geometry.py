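"""Geometry of intronic tags: containing-intron length, strand-aware
distances to both splice sites, summary statistics, splice-site proximity
fractions and intron length bins.

Distance convention: the exclusive gap — the number of intronic
nucleotides strictly between the splice junction and the tag's proximal
end. A tag abutting the junction has distance 0, and for every context
dist_upstream + tag_length + dist_downstream == intron_length.
"Upstream" is the donor (5') splice site in transcription direction, so
flipping a gene's strand swaps the two distances exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import GeneModel, IntronContext, TagAlignment


def locate_containing_intron(alignment: TagAlignment, gene: GeneModel) -> IntronContext:
    """Find the intron fully containing the tag and measure both gaps."""
    for (s, e) in gene.introns:
        if s <= alignment.start and alignment.end <= e:
            left = alignment.start - s
            right = e - alignment.end
            if gene.strand == "+":
                up, down = left, right
            else:
                up, down = right, left
            return IntronContext(
                tag_id=alignment.tag_id,
                gene_id=gene.gene_id,
                intron_start=s,
                intron_end=e,
                intron_length=e - s,
                dist_upstream=up,
                dist_downstream=down,
                tag_length=alignment.length,
            )
        if max(alignment.start, s) < min(alignment.end, e):
            raise ValueError(
                f"tag {alignment.tag_id} straddles an intron boundary of {gene.gene_id}"
            )
    raise ValueError(f"tag {alignment.tag_id} lies in no intron of {gene.gene_id}")


@dataclass
class MetricSummary:
    mean: float
    sem: float
    median: float
    min: float
    max: float
    n: int
    sem_defined: bool = True


_METRICS = ("intron_length", "dist_upstream", "dist_downstream")


def summarize_geometry(contexts: list[IntronContext]) -> dict[str, MetricSummary]:
    """Mean ± SEM, median and range per metric, as in the published
    intron-length tables. SEM uses the sample sd (n-1); with a single
    context it is reported as 0 and flagged undefined."""
    if not contexts:
        raise ValueError("no intron contexts to summarize")
    out = {}
    for metric in _METRICS:
        vals = np.array([getattr(c, metric) for c in contexts], dtype=float)
        n = len(vals)
        sem_defined = n > 1
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if sem_defined else 0.0
        out[metric] = MetricSummary(
            mean=float(vals.mean()),
            sem=sem,
            median=float(np.median(vals)),
            min=float(vals.min()),
            max=float(vals.max()),
            n=n,
            sem_defined=sem_defined,
        )
    return out


def proximity_fractions(
    contexts: list[IntronContext], threshold: int = 500
) -> dict[str, float]:
    """Fractions of tags within ``threshold`` nt of a splice site."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not contexts:
        return {"within_upstream": 0.0, "within_downstream": 0.0, "within_either": 0.0}
    n = len(contexts)
    up = sum(1 for c in contexts if c.dist_upstream <= threshold)
    down = sum(1 for c in contexts if c.dist_downstream <= threshold)
    either = sum(
        1 for c in contexts if min(c.dist_upstream, c.dist_downstream) <= threshold
    )
    return {
        "within_upstream": up / n,
        "within_downstream": down / n,
        "within_either": either / n,
    }


def length_bins(contexts, bounds: list[int]) -> list[float]:
    """Fractions of intron lengths per half-open bin
    (-inf, b1), [b1, b2), ..., [bk, inf). Accepts contexts or raw lengths."""
    if list(bounds) != sorted(set(bounds)):
        raise ValueError("bounds must be strictly increasing")
    lengths = [
        c.intron_length if isinstance(c, IntronContext) else float(c) for c in contexts
    ]
    if not lengths:
        return [0.0] * (len(bounds) + 1)
    edges = [-np.inf] + list(bounds) + [np.inf]
    counts, _ = np.histogram(lengths, bins=edges)
    return (counts / len(lengths)).tolist()


def geometry_table(summaries: dict[str, dict[str, MetricSummary]]):
    """Side-by-side comparison of several datasets' geometry summaries
    (one row-block per dataset, one column per metric)."""
    import pandas as pd

    rows = []
    for dataset, summary in summaries.items():
        for stat in ("mean", "sem", "median", "min", "max", "n"):
            rows.append(
                {
                    "dataset": dataset,
                    "statistic": stat,
                    **{m: getattr(summary[m], stat) for m in _METRICS},
                }
            )
    return pd.DataFrame(rows)


def contexts_to_table(contexts: list[IntronContext]):
    """One row per intronic tag: tag, gene, intron coordinates, length and
    both splice-site distances."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "tag_id": c.tag_id,
                "gene_id": c.gene_id,
                "intron_start": c.intron_start,
                "intron_end": c.intron_end,
                "intron_length": c.intron_length,
                "dist_upstream": c.dist_upstream,
                "dist_downstream": c.dist_downstream,
                "tag_length": c.tag_length,
            }
            for c in contexts
        ]
    )


def contexts_from_table(df) -> list[IntronContext]:
    """Inverse of :func:`contexts_to_table`; accepts any table with the
    same column schema (e.g. an externally supplied intronic-tag table)."""
    return [
        IntronContext(
            tag_id=str(r.tag_id),
            gene_id=str(r.gene_id),
            intron_start=int(r.intron_start),
            intron_end=int(r.intron_end),
            intron_length=int(r.intron_length),
            dist_upstream=int(r.dist_upstream),
            dist_downstream=int(r.dist_downstream),
            tag_length=int(r.tag_length),
        )
        for r in df.itertuples()
    ]
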