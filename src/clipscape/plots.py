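"""Best-effort figures: k-mer incidence bars with the uniform-expectation
line, and per-tag motif-count histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .kmer_enrichment import KmerTable, MotifCountDistribution, rank_kmers


def plot_kmer_incidence(table: KmerTable, path, highlight_top: int | None = None):
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    labels = [k for k, _ in ranked]
    values = [v for _, v in ranked]
    top = {k for k, _ in rank_kmers(table, highlight_top)} if highlight_top else set()
    colors = ["crimson" if k in top else "steelblue" for k in labels]
    fig, ax = plt.subplots(figsize=(max(6, len(labels) * 0.12), 4))
    ax.bar(range(len(labels)), values, color=colors)
    ax.axhline(table.expected_uniform, ls=":", color="green",
               label="expected (uniform)")
    if len(labels) <= 20:
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=90, fontsize=7)
    else:
        ax.set_xticks([])
    ax.set_ylabel("incidence")
    ax.set_xlabel(f"{table.k}-mer (ranked)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_motif_histograms(dists: list[MotifCountDistribution], path):
    fig, ax = plt.subplots(figsize=(6, 4))
    width = 0.8 / max(len(dists), 1)
    for i, d in enumerate(dists):
        xs = sorted(d.histogram)
        ax.bar(
            [x + i * width for x in xs],
            [d.histogram[x] for x in xs],
            width=width,
            label=d.motif,
        )
    ax.set_xlabel("motif occurrences per tag")
    ax.set_ylabel("number of tags")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
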