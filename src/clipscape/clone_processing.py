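"""Tag extraction: find both cloning adapters in the correct orientation,
trim them, and tabulate the distinct inserts.

A well-formed clone reads adapter5 + insert + adapter3 on one of its two
strands. The search tries the clone as given, then (optionally) its
reverse complement; rejection reasons distinguish missing adapters, wrong
orientation, size failures, and residual adapter sequence inside the
insert (which would make the placement ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import ClipTag, CloneRead
from .seq import revcomp, validate_dna

REJECTION_REASONS = (
    "no_adapter5",
    "no_adapter3",
    "wrong_orientation",
    "too_short",
    "too_long",
    "ambiguous_multiple_placements",
)


@dataclass
class ExtractionResult:
    clone_id: str
    insert: str | None
    reason: str | None  # None iff insert accepted

    @property
    def accepted(self) -> bool:
        return self.insert is not None


@dataclass
class ExtractionReport:
    n_clones: int = 0
    n_accepted: int = 0
    rejections: dict[str, int] = field(default_factory=dict)

    def record(self, result: ExtractionResult) -> None:
        self.n_clones += 1
        if result.accepted:
            self.n_accepted += 1
        else:
            self.rejections[result.reason] = self.rejections.get(result.reason, 0) + 1


def _hamming_find(seq: str, query: str, max_mismatches: int) -> list[int]:
    """Start positions where query matches seq within the mismatch budget."""
    if max_mismatches == 0:
        from .seq import find_all

        return find_all(seq, query)
    hits = []
    m = len(query)
    for i in range(len(seq) - m + 1):
        mm = 0
        window = seq[i : i + m]
        for a, b in zip(window, query):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        if mm <= max_mismatches:
            hits.append(i)
    return hits


def _try_strand(seq: str, a5: str, a3: str, max_mismatches: int) -> tuple[str | None, str]:
    """Attempt extraction on one strand.

    Returns (insert, status) where status is 'ok', 'no_adapter5',
    'no_adapter3' or 'wrong_orientation'.
    """
    h5 = _hamming_find(seq, a5, max_mismatches)
    h3 = _hamming_find(seq, a3, max_mismatches)
    if not h5 and not h3:
        return None, "no_adapter5"
    if not h5:
        return None, "no_adapter5"
    if not h3:
        return None, "no_adapter3"
    # leftmost adapter5, rightmost adapter3
    start5 = h5[0]
    start3 = h3[-1]
    if start5 + len(a5) > start3:
        return None, "wrong_orientation"
    return seq[start5 + len(a5) : start3], "ok"


def extract_tag(
    clone: CloneRead,
    adapter5: str,
    adapter3: str,
    *,
    max_mismatches: int = 0,
    min_len: int = 15,
    max_len: int | None = None,
    search_rc: bool = True,
) -> ExtractionResult:
    """Excise the insert between the two adapters, or reject with a reason."""
    if not adapter5 or not adapter3:
        raise ValueError("adapters must be non-empty")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    seq = validate_dna(clone.sequence, context=f"clone {clone.id}")
    a5, a3 = adapter5.upper(), adapter3.upper()

    insert, status = _try_strand(seq, a5, a3, max_mismatches)
    if insert is None and search_rc:
        insert_rc, status_rc = _try_strand(revcomp(seq), a5, a3, max_mismatches)
        if insert_rc is not None:
            insert, status = insert_rc, status_rc
        else:
            # merge the two strand failures, most informative first:
            # an orientation clash beats a missing 3' adapter (which itself
            # implies the 5' adapter was found on that strand)
            for reason in ("wrong_orientation", "no_adapter3", "no_adapter5"):
                if reason in (status, status_rc):
                    status = reason
                    break
    if insert is None:
        return ExtractionResult(clone.id, None, status)
    if a5 in insert or a3 in insert:
        return ExtractionResult(clone.id, None, "ambiguous_multiple_placements")
    if len(insert) < min_len:
        return ExtractionResult(clone.id, None, "too_short")
    if max_len is not None and len(insert) > max_len:
        return ExtractionResult(clone.id, None, "too_long")
    return ExtractionResult(clone.id, insert, None)


def extract_all(
    clones: list[CloneRead], adapter5: str, adapter3: str, **kwargs
) -> list[ExtractionResult]:
    return [extract_tag(c, adapter5, adapter3, **kwargs) for c in clones]


def tabulate_tags(
    results: list[ExtractionResult],
) -> tuple[list[ClipTag], ExtractionReport]:
    """Group accepted inserts by distinct sequence; report rejections.

    Returned tags are sorted by descending clone count, then sequence, so
    the table is stable under input permutation.
    """
    report = ExtractionReport()
    by_seq: dict[str, list[str]] = {}
    for r in results:
        report.record(r)
        if r.accepted:
            by_seq.setdefault(r.insert, []).append(r.clone_id)
    tags = [
        ClipTag(sequence=s, count=len(ids), clone_ids=sorted(ids))
        for s, ids in by_seq.items()
    ]
    tags.sort(key=lambda t: (-t.count, t.sequence))
    return tags, report


def write_tag_table(tags: list[ClipTag], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "tag_id": [f"tag{i:05d}" for i in range(len(tags))],
            "sequence": [t.sequence for t in tags],
            "count": [t.count for t in tags],
            "clone_ids": [",".join(t.clone_ids) for t in tags],
        }
    ).to_csv(path, sep="\t", index=False)
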