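"""End-to-end orchestration: clones -> tags -> mapping -> annotation ->
intron geometry -> k-mer enrichment, from a single config, with a
machine-readable summary.

Every number in the summary JSON is produced by calling the stage modules
directly — the pipeline adds no arithmetic of its own — so each value can
be recomputed independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import clone_processing, genomic_annotation, intron_geometry, kmer_enrichment
from . import synthetic, tag_mapping
from .models import MappingStatus

log = logging.getLogger("clipscape")


@dataclass
class PipelineConfig:
    """Constants the analysis applies across its stages."""

    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    min_tag_len: int = 15
    proximity_threshold: int = 500
    length_bin_bounds: tuple[int, ...] = (10_000, 100_000)
    kmer_ks: tuple[int, ...] = (2, 6)
    motifs: tuple[str, ...] = ("UG", "CA")
    top_n_kmers: int = 20
    search_rc: bool = True
    outdir: Path | None = None
    make_figures: bool = False


@dataclass
class PipelineResult:
    tags: list
    report: clone_processing.ExtractionReport
    mapping_summary: object
    assignments: list
    category_fractions: dict
    contexts: list
    geometry: dict | None
    proximity: dict | None
    length_fractions: list | None
    kmer_tables: dict
    rankings: dict
    motif_distributions: dict
    truth: synthetic.TruthManifest
    summary: dict


def run_clip_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full synthetic-study pipeline under one seeded config."""
    sim = config.sim
    log.info("stage: simulate (seed=%d)", sim.seed)
    genome = synthetic.generate_genome(sim)
    genes = synthetic.generate_gene_models(genome, sim)
    genome, sites = synthetic.plant_binding_sites(genome, genes, sim)
    contam = synthetic.generate_contaminant_reference(sim)
    clones, truth = synthetic.simulate_clip_clones(genome, sites, sim, contam)
    truth.genes = genes

    log.info("stage: extract (%d clones)", len(clones))
    results = clone_processing.extract_all(
        clones, sim.adapter5, sim.adapter3,
        min_len=config.min_tag_len, search_rc=config.search_rc,
    )
    tags, report = clone_processing.tabulate_tags(results)

    log.info("stage: map (%d distinct tags)", len(tags))
    alignments, status = tag_mapping.triage_tags(tags, genome, contam)
    mapping_summary = tag_mapping.summarize_mapping(status)
    unique_alns = [a for a in alignments if a.status is MappingStatus.UNIQUE]

    log.info("stage: annotate (%d unique placements)", len(unique_alns))
    index = genomic_annotation.GeneIndex(genes)
    assignments = [genomic_annotation.assign_gene_context(a, index) for a in unique_alns]
    fractions = genomic_annotation.category_fractions(assignments)

    log.info("stage: intron geometry")
    aln_by_id = {a.tag_id: a for a in unique_alns}
    contexts = []
    for fa in assignments:
        if fa.category == "intron":
            gene = index.models[fa.gene_id]
            a = aln_by_id[fa.tag_id]
            try:
                contexts.append(intron_geometry.locate_containing_intron(a, gene))
            except ValueError:
                continue  # straddlers classified intron by majority have no single intron
    geometry = intron_geometry.summarize_geometry(contexts) if contexts else None
    proximity = (
        intron_geometry.proximity_fractions(contexts, config.proximity_threshold)
        if contexts else None
    )
    length_fracs = (
        intron_geometry.length_bins(contexts, list(config.length_bin_bounds))
        if contexts else None
    )

    log.info("stage: k-mers")
    genic_tags = _genic_tag_sequences(tags, status, assignments, unique_alns)
    kmer_tables = {k: kmer_enrichment.count_kmers(genic_tags, k) for k in config.kmer_ks}
    rankings = {
        k: kmer_enrichment.rank_kmers(t, config.top_n_kmers)
        for k, t in kmer_tables.items()
    }
    motif_dists = {
        m: kmer_enrichment.motif_count_distribution(genic_tags, m)
        for m in config.motifs
    }

    summary = _build_summary(
        report, mapping_summary, fractions, geometry, proximity, length_fracs,
        kmer_tables, rankings, motif_dists, config,
    )
    result = PipelineResult(
        tags=tags, report=report, mapping_summary=mapping_summary,
        assignments=assignments, category_fractions=fractions, contexts=contexts,
        geometry=geometry, proximity=proximity, length_fractions=length_fracs,
        kmer_tables=kmer_tables, rankings=rankings,
        motif_distributions=motif_dists, truth=truth, summary=summary,
    )
    if config.outdir is not None:
        _write_outputs(result, config)
    return result


def _genic_tag_sequences(tags, status, assignments, unique_alns):
    """Distinct tag sequences that map uniquely within genes."""
    genic_ids = {
        fa.tag_id for fa in assignments if fa.category not in ("intergenic",)
    }
    seq_by_id = {}
    tag_ids = {t.sequence: f"tag{i:05d}" for i, t in enumerate(tags)}
    for t in tags:
        tid = tag_ids[t.sequence]
        if tid in genic_ids:
            seq_by_id[tid] = t.sequence
    return list(seq_by_id.values())


def _metric_summary_dict(geometry):
    return {
        metric: {
            "mean": ms.mean, "sem": ms.sem, "median": ms.median,
            "min": ms.min, "max": ms.max, "n": ms.n,
        }
        for metric, ms in geometry.items()
    }


def _build_summary(report, mapping_summary, fractions, geometry, proximity,
                   length_fracs, kmer_tables, rankings, motif_dists, config):
    return {
        "extraction": {
            "n_clones": report.n_clones,
            "n_accepted": report.n_accepted,
            "rejections": dict(sorted(report.rejections.items())),
        },
        "mapping": {
            "n_total": mapping_summary.n_total,
            "n_contaminant": mapping_summary.n_contaminant,
            "n_unmapped_or_multi": mapping_summary.n_unmapped_or_multi,
            "n_unique": mapping_summary.n_unique,
            "fractions": mapping_summary.fractions,
        },
        "category_fractions": fractions,
        "intron_geometry": _metric_summary_dict(geometry) if geometry else None,
        "proximity_fractions": proximity,
        "length_bin_fractions": length_fracs,
        "kmers": {
            str(k): {
                "total_windows": t.total_windows,
                "expected_uniform": t.expected_uniform,
                "top": rankings[k],
            }
            for k, t in kmer_tables.items()
        },
        "motif_histograms": {
            m: dict(sorted(d.histogram.items())) for m, d in motif_dists.items()
        },
        "config": {
            "seed": config.sim.seed,
            "n_clones": config.sim.n_clones,
            "proximity_threshold": config.proximity_threshold,
            "length_bin_bounds": list(config.length_bin_bounds),
        },
    }


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n"
    )
    clone_processing.write_tag_table(result.tags, outdir / "tags.tsv")
    if result.contexts:
        intron_geometry.contexts_to_table(result.contexts).to_csv(
            outdir / "intron_contexts.tsv", sep="\t", index=False
        )
    for k, table in result.kmer_tables.items():
        kmer_enrichment.write_kmer_table(table, outdir / f"kmers_k{k}.tsv")
    if config.make_figures:
        from . import plots

        plots.plot_kmer_incidence(
            result.kmer_tables[min(result.kmer_tables)], outdir / "dinucleotides.png"
        )
        if max(result.kmer_tables) >= 6 and 6 in result.kmer_tables:
            plots.plot_kmer_incidence(
                result.kmer_tables[6], outdir / "hexamers.png",
                highlight_top=config.top_n_kmers,
            )
        plots.plot_motif_histograms(
            list(result.motif_distributions.values()), outdir / "motif_histograms.png"
        )


def run_comparison(datasets: dict[str, list]) -> "object":
    """Side-by-side geometry summaries for several intron-context sets
    (e.g. one per CLIP study)."""
    if not datasets:
        raise ValueError("no datasets given")
    summaries = {
        name: intron_geometry.summarize_geometry(ctxs) for name, ctxs in datasets.items()
    }
    return intron_geometry.geometry_table(summaries)
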