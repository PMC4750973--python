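"""Ground-truth simulator: genomes, gene models, planted binding sites,
CLIP clone libraries and differential-expression tables.

Every downstream stage of the pipeline has a recovery test against the
truth manifest this module emits. The generator emulates the structure of
a Sanger-cloned CLIP experiment: each well-formed clone is
``adapter5 + insert + adapter3`` (optionally emitted reverse-complemented,
since plasmid clones are read from either end), inserts come either from
planted UG-rich binding sites, from random genomic background, or from a
bacterial-rRNA-like contaminant reference, and a configurable fraction of
clones is malformed (missing or mis-oriented adapters).

Gene models follow a minimal one-transcript-per-gene layout — 5'UTR,
two or more CDS exons, 3'UTR — with intron lengths drawn from a
heavy-tailed (log-normal) law so that a realistic fraction of introns
exceeds 10 kb.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import CloneRead, GeneModel
from .seq import revcomp, to_dna, validate_dna

_BASES = np.array(list("ACGT"))

# log-normal sigma solving P(X > cutoff) = frac for X with the given median
def lognormal_sigma(median: float, cutoff: float, frac_above: float) -> float:
    """Spread of a log-normal intron-length law, fixed by its median and
    the probability mass above a "large intron" cutoff."""
    from scipy.stats import norm

    if not 0 < frac_above < 1:
        raise ValueError("frac_above must be in (0,1)")
    if cutoff <= median:
        raise ValueError("cutoff must exceed the median")
    return math.log(cutoff / median) / norm.ppf(1 - frac_above)


@dataclass
class IntronLengthLaw:
    """Heavy-tailed intron-length distribution.

    ``lognormal`` with a stated median and either an explicit sigma or a
    (cutoff, frac_above) pair; ``fixed`` pins every intron to one length.
    """

    name: str = "lognormal"
    median: float = 3000.0
    sigma: float | None = None
    cutoff: float = 10_000.0
    frac_above: float = 0.15
    min_length: int = 60

    def resolved_sigma(self) -> float:
        if self.sigma is not None:
            return self.sigma
        return lognormal_sigma(self.median, self.cutoff, self.frac_above)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.name == "fixed":
            return np.full(n, int(self.median), dtype=int)
        if self.name != "lognormal":
            raise ValueError(f"unknown intron length law {self.name!r}")
        draws = rng.lognormal(mean=math.log(self.median), sigma=self.resolved_sigma(), size=n)
        return np.maximum(draws.astype(int), self.min_length)


@dataclass
class SimConfig:
    """All the knobs of one simulation, with the default study conditions."""

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 2_000_000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_genes: int = 60
    intron_length_law: IntronLengthLaw = field(default_factory=IntronLengthLaw)
    n_exons_range: tuple[int, int] = (3, 6)
    exon_length_range: tuple[int, int] = (80, 300)
    utr5_len: int = 150
    utr3_len: int = 300
    unknown_gene_rate: float = 0.1
    motif: str = "UGUGUG"
    n_sites: int = 40
    site_tag_rate: float = 0.5
    contaminant_rate: float = 0.1
    malformed_rate: float = 0.05
    tag_length_min: int = 20
    tag_length_max: int = 60
    adapter5: str = "GTTCAGAGTTCTACAGTCCG"
    adapter3: str = "GTGTCAGTCACTTCCAGCGG"
    n_clones: int = 500
    rc_emission_prob: float = 0.5
    contaminant_ref_length: int = 1500

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or (comp > 1).any():
            raise ValueError("base_composition must be 4 probabilities in [0,1]")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        for name in ("site_tag_rate", "contaminant_rate", "malformed_rate", "rc_emission_prob", "unknown_gene_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.tag_length_max < self.tag_length_min:
            raise ValueError("tag_length_max < tag_length_min")
        if self.tag_length_min < 6:
            raise ValueError("minimum tag length must be >= 6 (largest k-mer)")
        if self.chrom_length < 1:
            raise ValueError("chrom_length must be >= 1")
        if not self.adapter5 or not self.adapter3:
            raise ValueError("adapters must be non-empty")
        if self.adapter5 in self.adapter3 or self.adapter3 in self.adapter5:
            raise ValueError("adapters must not be substrings of each other")

    @property
    def motif_dna(self) -> str:
        return to_dna(self.motif)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        d = json.loads(Path(path).read_text())
        law = d.pop("intron_length_law", None)
        cfg = cls(**d)
        if law is not None:
            cfg.intron_length_law = IntronLengthLaw(**law)
        return cfg


@dataclass(frozen=True)
class PlantedSite:
    """One motif copy written into an intron."""

    site_id: str
    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str


@dataclass(frozen=True)
class CloneTruth:
    clone_id: str
    origin: str  # site | background | contaminant | malformed
    insert: str | None  # the intended insert, genome-forward DNA; None for malformed
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    site_id: str | None = None
    malformation: str | None = None


@dataclass
class DETruth:
    gene_id: str
    category: str  # up | down | unchanged | only_control | only_kd
    fold_change: float


@dataclass
class TruthManifest:
    """Everything the generator knows that the pipeline must recover."""

    clones: list[CloneTruth] = field(default_factory=list)
    sites: list[PlantedSite] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    de: list[DETruth] = field(default_factory=list)

    def clones_by_origin(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.clones:
            out[c.origin] = out.get(c.origin, 0) + 1
        return out

    def write_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame([dataclasses.asdict(c) for c in self.clones]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# genome

def generate_genome(config: SimConfig) -> dict[str, str]:
    """Draw chromosome sequences i.i.d. from the base composition."""
    rng = np.random.default_rng(config.seed)
    genome = {}
    for i in range(config.n_chroms):
        draws = rng.choice(_BASES, size=config.chrom_length, p=list(config.base_composition))
        genome[f"chr{i + 1}"] = "".join(draws)
    return genome


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# gene models

def _sample_gene_structure(config: SimConfig, rng: np.random.Generator,
                           budget: int) -> tuple[list[int], list[int]] | None:
    """Exon and intron lengths for one gene, or None if it will not fit
    inside the per-gene placement budget."""
    law = config.intron_length_law
    for _ in range(200):
        n_exons = int(rng.integers(config.n_exons_range[0], config.n_exons_range[1] + 1))
        exon_lens = rng.integers(
            config.exon_length_range[0], config.exon_length_range[1] + 1, size=n_exons
        ).tolist()
        exon_lens[0] += config.utr5_len
        exon_lens[-1] += config.utr3_len
        intron_lens = law.sample(n_exons - 1, rng).tolist()
        if sum(exon_lens) + sum(intron_lens) <= budget:
            return exon_lens, intron_lens
    return None


def generate_gene_models(genome: dict[str, str], config: SimConfig) -> list[GeneModel]:
    """Place non-overlapping genes on the chromosomes.

    Each gene gets a 5'UTR, >=2 CDS exons and a 3'UTR; the UTRs sit in the
    terminal exons (transcription direction). Intron lengths come from the
    configured heavy-tailed law, resampled if a draw would not fit the
    gene's placement slot.
    """
    rng = np.random.default_rng(config.seed + 1)
    chroms = list(genome)
    per_chrom = -(-config.n_genes // len(chroms))  # ceil
    models: list[GeneModel] = []
    gid = 0
    for chrom in chroms:
        n_here = min(per_chrom, config.n_genes - gid)
        if n_here <= 0:
            break
        clen = len(genome[chrom])
        slot = clen // n_here
        cursor = 0
        for j in range(n_here):
            slot_end = min((j + 1) * slot, clen)
            budget = slot_end - cursor - 20  # leave a margin between genes
            struct = _sample_gene_structure(config, rng, budget)
            if struct is None:
                raise ValueError(
                    f"genome too small for {config.n_genes} genes "
                    f"(failed at gene {gid} on {chrom})"
                )
            exon_lens, intron_lens = struct
            gene_len = sum(exon_lens) + sum(intron_lens)
            offset = int(rng.integers(0, max(budget - gene_len, 0) + 1))
            start = cursor + offset
            exons = []
            pos = start
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + el))
                pos += el
                if i < len(intron_lens):
                    pos += intron_lens[i]
            strand = "+" if rng.random() < 0.5 else "-"
            known = rng.random() >= config.unknown_gene_rate
            if strand == "+":
                cds = (exons[0][0] + config.utr5_len, exons[-1][1] - config.utr3_len)
            else:
                cds = (exons[0][0] + config.utr3_len, exons[-1][1] - config.utr5_len)
            models.append(
                GeneModel(
                    gene_id=f"gene{gid:04d}",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds=cds if known else None,
                    known=known,
                )
            )
            cursor = exons[-1][1] + 10
            gid += 1
    return models


# ---------------------------------------------------------------------------
# binding sites

def plant_binding_sites(
    genome: dict[str, str], gene_models: list[GeneModel], config: SimConfig
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Overwrite the genome with motif copies at uniform intronic positions.

    The motif is written in the gene's sense orientation (reverse
    complemented on minus-strand genes) so that tags read in transcript
    sense carry the motif as specified. Genome length is preserved; planted
    intervals do not overlap.
    """
    motif = config.motif_dna
    rng = np.random.default_rng(config.seed + 2)
    # Uniform over positions: weight introns by their eligible width.
    intron_spans = []
    for g in gene_models:
        for (s, e) in g.introns:
            width = (e - len(motif) - 1) - (s + 1)
            if width > 0:
                intron_spans.append((g.chrom, s + 1, e - len(motif) - 1, g.gene_id, g.strand))
    if not intron_spans:
        if config.n_sites > 0:
            raise ValueError("no intron can hold the motif")
        return dict(genome), []
    widths = np.array([e - s for (_, s, e, _, _) in intron_spans], dtype=float)
    total_capacity = int(widths.sum()) // max(len(motif), 1)
    if config.n_sites > total_capacity:
        raise ValueError(f"requested {config.n_sites} sites exceeds intronic capacity")
    mutable = {c: list(s) for c, s in genome.items()}
    placed: list[PlantedSite] = []
    occupied: dict[str, set[int]] = {c: set() for c in genome}
    attempts = 0
    while len(placed) < config.n_sites:
        attempts += 1
        if attempts > config.n_sites * 200:
            raise ValueError("could not place all sites without overlap")
        idx = int(rng.choice(len(intron_spans), p=widths / widths.sum()))
        chrom, lo, hi, gene_id, strand = intron_spans[idx]
        pos = int(rng.integers(lo, hi))
        span = range(pos, pos + len(motif))
        if any(p in occupied[chrom] for p in span):
            continue
        written = motif if strand == "+" else revcomp(motif)
        mutable[chrom][pos : pos + len(motif)] = list(written)
        occupied[chrom].update(span)
        placed.append(
            PlantedSite(
                site_id=f"site{len(placed):04d}",
                chrom=chrom,
                start=pos,
                end=pos + len(motif),
                gene_id=gene_id,
                strand=strand,
            )
        )
    return {c: "".join(s) for c, s in mutable.items()}, placed


# ---------------------------------------------------------------------------
# clones

def generate_contaminant_reference(config: SimConfig) -> dict[str, str]:
    """A bacterial-rRNA-like reference, independent of the genome."""
    rng = np.random.default_rng(config.seed + 3)
    seq = "".join(rng.choice(_BASES, size=config.contaminant_ref_length,
                             p=[0.24, 0.26, 0.30, 0.20]))
    return {"contam_rrna": seq}


def simulate_clip_clones(
    genome: dict[str, str],
    sites: list[PlantedSite],
    config: SimConfig,
    contaminant_ref: dict[str, str] | None = None,
) -> tuple[list[CloneRead], TruthManifest]:
    """Emit a clone library with per-clone ground truth.

    Clone origins are drawn per clone: contaminant with ``contaminant_rate``,
    malformed with ``malformed_rate``, otherwise a genomic insert which
    overlaps a planted site with ``site_tag_rate`` (falling back to
    background when no sites exist). Well-formed clones are
    adapter5+insert+adapter3, reverse-complemented as a whole with
    ``rc_emission_prob``.
    """
    rng = np.random.default_rng(config.seed + 4)
    if contaminant_ref is None:
        contaminant_ref = generate_contaminant_reference(config)
    contam_seq = next(iter(contaminant_ref.values()))
    a5, a3 = config.adapter5.upper(), config.adapter3.upper()
    chroms = list(genome)
    clones: list[CloneRead] = []
    truth = TruthManifest(sites=list(sites))

    def tag_len() -> int:
        return int(rng.integers(config.tag_length_min, config.tag_length_max + 1))

    for i in range(config.n_clones):
        cid = f"clone{i:05d}"
        u = rng.random()
        if u < config.contaminant_rate:
            L = tag_len()
            start = int(rng.integers(0, len(contam_seq) - L + 1))
            insert = contam_seq[start : start + L]
            rec = CloneTruth(cid, "contaminant", insert)
        elif u < config.contaminant_rate + config.malformed_rate:
            L = tag_len()
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, len(genome[chrom]) - L + 1))
            core = genome[chrom][start : start + L]
            kind = ["no_adapter5", "no_adapter3", "swapped"][int(rng.integers(3))]
            if kind == "no_adapter5":
                seq = core + a3
            elif kind == "no_adapter3":
                seq = a5 + core
            else:  # adapters present but in the wrong order on both strands
                seq = a3 + core + a5
            clone_seq = seq
            truth.clones.append(CloneTruth(cid, "malformed", None, malformation=kind))
            if rng.random() < config.rc_emission_prob:
                clone_seq = revcomp(clone_seq)
            clones.append(CloneRead(cid, clone_seq))
            continue
        elif sites and rng.random() < config.site_tag_rate:
            site = sites[int(rng.integers(len(sites)))]
            L = max(tag_len(), site.end - site.start + 2)
            # window fully containing the planted motif
            lo = max(site.end - L, 0)
            hi = min(site.start, len(genome[site.chrom]) - L)
            start = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
            g = genome[site.chrom][start : start + L]
            insert = g if site.strand == "+" else revcomp(g)
            rec = CloneTruth(
                cid, "site", insert, chrom=site.chrom, start=start, end=start + L,
                site_id=site.site_id,
            )
        else:
            L = tag_len()
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, len(genome[chrom]) - L + 1))
            insert = genome[chrom][start : start + L]
            rec = CloneTruth(cid, "background", insert, chrom=chrom, start=start, end=start + L)
        truth.clones.append(rec)
        clone_seq = a5 + rec.insert + a3
        if rng.random() < config.rc_emission_prob:
            clone_seq = revcomp(clone_seq)
        clones.append(CloneRead(cid, validate_dna(clone_seq, context=cid)))
    return clones, truth


def write_clones_fasta(clones: list[CloneRead], path: str | Path) -> None:
    write_fasta({c.id: c.sequence for c in clones}, path)


# ---------------------------------------------------------------------------
# differential expression

@dataclass
class DESimConfig:
    """Shape of a simulated two-condition expression table."""

    seed: int = 0
    n_genes: int = 1000
    frac_up: float = 0.25
    frac_down: float = 0.25
    frac_only_control: float = 0.02
    frac_only_kd: float = 0.09
    fold_threshold: float = 1.5
    fold_scale: float = 0.6  # exponential excess above the threshold, log2 units
    mean_log2_expr: float = 4.0
    sd_log2_expr: float = 2.0

    def __post_init__(self) -> None:
        total = self.frac_up + self.frac_down + self.frac_only_control + self.frac_only_kd
        if total > 1.0 + 1e-12:
            raise ValueError("category fractions must sum to <= 1")


def simulate_de_table(config: DESimConfig):
    """Simulate an FPKM-like table with known per-gene categories.

    Returns (DataFrame[gene_id, expr_control, expr_kd, significant], truth).
    Up/down genes get fold changes >= the threshold; exclusive genes have
    exactly zero expression on one side; unchanged genes get sub-threshold
    folds and significant=False.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    cats = (
        ["up"] * round(config.frac_up * n)
        + ["down"] * round(config.frac_down * n)
        + ["only_control"] * round(config.frac_only_control * n)
        + ["only_kd"] * round(config.frac_only_kd * n)
    )
    cats += ["unchanged"] * (n - len(cats))
    rng.shuffle(cats)
    rows, truth = [], []
    for i, cat in enumerate(cats):
        gid = f"g{i:05d}"
        base = float(2.0 ** rng.normal(config.mean_log2_expr, config.sd_log2_expr))
        if cat == "up":
            fold = config.fold_threshold * 2.0 ** rng.exponential(config.fold_scale)
            ctrl, kd, sig = base, base * fold, True
        elif cat == "down":
            fold = config.fold_threshold * 2.0 ** rng.exponential(config.fold_scale)
            ctrl, kd, sig = base * fold, base, True
        elif cat == "only_control":
            ctrl, kd, sig, fold = base, 0.0, True, math.inf
        elif cat == "only_kd":
            ctrl, kd, sig, fold = 0.0, base, True, math.inf
        else:
            fold = 2.0 ** rng.uniform(0, math.log2(config.fold_threshold) * 0.95)
            hi = base * fold
            if rng.random() < 0.5:
                ctrl, kd = base, hi
            else:
                ctrl, kd = hi, base
            sig = False
        if cat == "down":
            true_fold = ctrl / kd
        elif cat == "up":
            true_fold = kd / ctrl
        else:
            true_fold = fold
        rows.append((gid, ctrl, kd, sig))
        truth.append(DETruth(gid, cat, float(true_fold) if true_fold != math.inf else math.inf))
    df = pd.DataFrame(rows, columns=["gene_id", "expr_control", "expr_kd", "significant"])
    return df, truth


def de_truth_summary(truth: list[DETruth], strong_threshold: float = 2.0):
    """DESummary implied by the generator's own records (the oracle)."""
    from .models import DESummary

    s = DESummary()
    for t in truth:
        if t.category == "up":
            s.n_shared_up += 1
            if t.fold_change > strong_threshold:
                s.n_shared_up_strong += 1
        elif t.category == "down":
            s.n_shared_down += 1
            if t.fold_change > strong_threshold:
                s.n_shared_down_strong += 1
        elif t.category == "only_control":
            s.n_only_control += 1
        elif t.category == "only_kd":
            s.n_only_kd += 1
    return s
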