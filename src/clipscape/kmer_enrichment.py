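"""k-mer incidence over a tag set, uniform-baseline comparison, top-k-mer
ranking, per-tag motif-count histograms, and the Welch group comparison.

Counting conventions (they matter for reproducibility):

* tags are counted as DISTINCT sequences, unweighted by clone support;
* windows overlap at step 1, so "UGUG" contains two UGs;
* windows containing N are excluded from both the counts and the window
  total;
* tags shorter than k contribute zero windows;
* the baseline incidence is total_windows / 4**k — the incidence expected
  if every k-mer of that length were equally represented. An optional
  composition-adjusted expectation (product of observed mononucleotide
  frequencies) is available but is not the default.

All k-mers are reported in the RNA alphabet (UG, not TG) because binding
motifs of RNA-binding proteins are conventionally written as RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq import count_overlapping, to_rna

RNA_BASES = "ACGU"


@dataclass
class KmerTable:
    k: int
    counts: dict[str, int]
    total_windows: int

    @property
    def expected_uniform(self) -> float:
        return self.total_windows / 4**self.k

    def expected_composition(self) -> dict[str, float]:
        """Expectation under the observed mononucleotide composition."""
        base_counts = {b: 0 for b in RNA_BASES}
        for kmer, c in self.counts.items():
            for b in kmer:
                base_counts[b] += c
        denom = sum(base_counts.values())
        freqs = {b: (base_counts[b] / denom if denom else 0.25) for b in RNA_BASES}
        out = {}
        for kmer, _ in self.counts.items():
            p = 1.0
            for b in kmer:
                p *= freqs[b]
            out[kmer] = p * self.total_windows
        return out


@dataclass
class MotifCountDistribution:
    motif: str
    histogram: dict[int, int] = field(default_factory=dict)

    @property
    def n_tags(self) -> int:
        return sum(self.histogram.values())

    def counts_vector(self) -> np.ndarray:
        """One entry per tag (expanded from the histogram)."""
        return np.array(
            [k for k, v in sorted(self.histogram.items()) for _ in range(v)]
        )


def _as_rna_sequences(tags) -> list[str]:
    seqs = []
    for t in tags:
        seq = t if isinstance(t, str) else t.sequence
        seqs.append(to_rna(seq.upper()))
    return seqs


def count_kmers(tags, k: int) -> KmerTable:
    """Overlapping k-mer counts summed over distinct tags."""
    if not 1 <= k <= 6:
        raise ValueError("k must be in 1..6")
    counts: dict[str, int] = {}
    total = 0
    for seq in _as_rna_sequences(tags):
        for i in range(max(len(seq) - k + 1, 0)):
            w = seq[i : i + k]
            if "N" in w:
                continue
            counts[w] = counts.get(w, 0) + 1
            total += 1
    return KmerTable(k=k, counts=counts, total_windows=total)


def rank_kmers(table: KmerTable, top_n: int) -> list[tuple[str, int]]:
    """Most frequent k-mers, descending count, ties lexicographic."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def motif_count_distribution(tags, motif: str) -> MotifCountDistribution:
    """Histogram of per-tag overlapping motif occurrence counts."""
    motif_rna = to_rna(motif.upper())
    hist: dict[int, int] = {}
    for seq in _as_rna_sequences(tags):
        n = count_overlapping(seq, motif_rna)
        hist[n] = hist.get(n, 0) + 1
    return MotifCountDistribution(motif=motif_rna, histogram=hist)


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    direction: str


def welch_one_tailed(a, b, direction: str = "greater") -> WelchResult:
    """Welch's unequal-variance t-test with a one-tailed p.

    ``direction="greater"`` tests mean(a) > mean(b). Degrees of freedom by
    Welch–Satterthwaite.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            # no variance, no difference: evidence is exactly neutral
            return WelchResult(t=0.0, df=float(len(a) + len(b) - 2), p=0.5, direction=direction)
        raise ValueError("both groups degenerate with different means")
    alt = {"greater": "greater", "less": "less"}[direction]
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alt)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue), direction=direction)


def compare_group_motif_counts(
    group_a_tags, group_b_tags, motif: str, direction: str = "greater"
) -> WelchResult:
    """One-tailed Welch comparison of per-tag motif counts between two tag
    groups (e.g. UG counts in UTR tags vs CDS tags)."""
    motif_rna = to_rna(motif.upper())
    a = [count_overlapping(s, motif_rna) for s in _as_rna_sequences(group_a_tags)]
    b = [count_overlapping(s, motif_rna) for s in _as_rna_sequences(group_b_tags)]
    return welch_one_tailed(a, b, direction=direction)


def write_kmer_table(table: KmerTable, path) -> None:
    import pandas as pd

    rows = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["kmer", "count"])
    df["expected_uniform"] = table.expected_uniform
    df.to_csv(path, sep="\t", index=False)
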