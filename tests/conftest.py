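"""Shared fixtures: a desk-scale simulated world with full ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from clipscape import synthetic
from clipscape.models import CloneRead, GeneModel
from clipscape.synthetic import IntronLengthLaw, SimConfig


def desk_sim_config(seed: int = 7, **overrides) -> SimConfig:
    """A small, fast simulation: one 300 kb chromosome, short introns."""
    defaults = dict(
        seed=seed,
        chrom_length=300_000,
        n_genes=15,
        intron_length_law=IntronLengthLaw(median=600, cutoff=3000, frac_above=0.10),
        n_sites=25,
        n_clones=300,
        contaminant_rate=0.1,
        malformed_rate=0.05,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class World:
    config: SimConfig
    genome: dict
    genes: list
    sites: list
    contaminants: dict
    clones: list
    truth: synthetic.TruthManifest


def build_world(config: SimConfig) -> World:
    genome = synthetic.generate_genome(config)
    genes = synthetic.generate_gene_models(genome, config)
    genome, sites = synthetic.plant_binding_sites(genome, genes, config)
    contam = synthetic.generate_contaminant_reference(config)
    clones, truth = synthetic.simulate_clip_clones(genome, sites, config, contam)
    truth.genes = genes
    return World(config, genome, genes, sites, contam, clones, truth)


@pytest.fixture(scope="session")
def world() -> World:
    return build_world(desk_sim_config())


@pytest.fixture()
def toy_gene_plus() -> GeneModel:
    """+ strand: exon [100,300) | intron | exon [800,1000) | intron |
    exon [1500,1800); CDS [200,1700) so UTR5=[100,200), UTR3=[1700,1800)."""
    return GeneModel(
        gene_id="toy+",
        chrom="chr1",
        strand="+",
        exons=[(100, 300), (800, 1000), (1500, 1800)],
        cds=(200, 1700),
    )


@pytest.fixture()
def toy_gene_minus() -> GeneModel:
    """Same layout on the minus strand: UTR5 is now the right-hand end."""
    return GeneModel(
        gene_id="toy-",
        chrom="chr1",
        strand="-",
        exons=[(100, 300), (800, 1000), (1500, 1800)],
        cds=(200, 1700),
    )


def make_clone(insert: str, a5: str = "GGG", a3: str = "CCC", cid: str = "c1") -> CloneRead:
    return CloneRead(cid, a5 + insert + a3)
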