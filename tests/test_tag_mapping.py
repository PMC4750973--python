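"""Mapping triage: contaminant screen, exact mapper vs brute force, BED import."""

import numpy as np
import pytest

from clipscape.io import write_bed6
from clipscape.models import ClipTag, MappingStatus, TagAlignment
from clipscape.seq import revcomp
from clipscape.tag_mapping import (
    flag_contaminants,
    import_alignments,
    map_tags_exact,
    summarize_mapping,
    triage_tags,
)

from conftest import build_world, desk_sim_config


def tag(seq, cid="x"):
    return ClipTag(sequence=seq, count=1, clone_ids=[cid])


def brute_force_hits(genome, seq):
    """All placements of seq on either strand, by scanning every position."""
    rc = revcomp(seq)
    hits = []
    for chrom, ref in genome.items():
        for i in range(len(ref) - len(seq) + 1):
            window = ref[i : i + len(seq)]
            if window == seq:
                hits.append((chrom, i, "+"))
            elif window == rc and rc != seq:
                hits.append((chrom, i, "-"))
    return hits


class TestContaminants:
    def test_substring_of_reference_is_flagged(self):
        ref = {"rrna": "A" * 5 + "CGTACGTTGCATGCAAGCTT" + "G" * 5}
        assert flag_contaminants([tag("CGTACGTTGCATGCAAGCTT")], ref)["CGTACGTTGCATGCAAGCTT"]

    def test_reverse_strand_match_is_flagged(self):
        ref = {"rrna": "CGTACGTTGCATGCAAGCTT"}
        seq = revcomp("CGTACGTTGCATGCAAGCTT")
        assert flag_contaminants([tag(seq)], ref)[seq]

    def test_absent_tag_not_flagged(self):
        ref = {"rrna": "CGTACGTTGCATGCAAGCTT"}
        assert not flag_contaminants([tag("TTTTTTTTTTTTTTT")], ref)["TTTTTTTTTTTTTTT"]

    def test_simulated_contaminants_exactly_recovered(self, world):
        from clipscape.clone_processing import extract_all, tabulate_tags

        cfg = world.config
        tags, _ = tabulate_tags(extract_all(world.clones, cfg.adapter5, cfg.adapter3))
        flags = flag_contaminants(tags, world.contaminants)
        truth_contaminant = {
            rec.insert for rec in world.truth.clones if rec.origin == "contaminant"
        }
        flagged = {s for s, f in flags.items() if f}
        assert flagged >= truth_contaminant
        # non-contaminant genomic tags must not be flagged
        genomic = {rec.insert for rec in world.truth.clones
                   if rec.origin in ("site", "background")}
        assert not (flagged & (genomic - truth_contaminant))


class TestExactMapper:
    def test_multi_enumeration(self):
        alns = map_tags_exact([tag("AAAA")], {"chr1": "AAAAAA"})
        assert all(a.status is MappingStatus.MULTI for a in alns)
        assert len(alns) == 3

    def test_unmapped(self):
        alns = map_tags_exact([tag("ACGTACGTACGTACG")], {"chr1": "T" * 100})
        assert len(alns) == 1 and alns[0].status is MappingStatus.UNMAPPED

    def test_minus_strand_unique(self):
        seq = "ACGGTTCAGATTCCA"
        genome = {"chr1": "T" * 30 + revcomp(seq) + "T" * 30}
        alns = map_tags_exact([tag(seq)], genome)
        assert len(alns) == 1
        a = alns[0]
        assert (a.status, a.strand, a.start, a.end) == (MappingStatus.UNIQUE, "-", 30, 45)
        assert brute_force_hits(genome, seq) == [("chr1", 30, "-")]

    def test_agrees_with_bruteforce_on_random_tags(self):
        rng = np.random.default_rng(17)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=20_000))}
        tags = []
        for _ in range(100):
            if rng.random() < 0.7:  # genomic tag, either strand
                L = int(rng.integers(12, 30))
                s = int(rng.integers(0, 20_000 - L))
                t = genome["chr1"][s : s + L]
                if rng.random() < 0.5:
                    t = revcomp(t)
            else:  # random tag, usually unmapped
                t = "".join(rng.choice(list("ACGT"), size=int(rng.integers(12, 30))))
            tags.append(tag(t))
        alns = map_tags_exact(tags, genome, max_hits_reported=10**9)
        by_tag = {}
        for a in alns:
            by_tag.setdefault(a.tag_id, []).append(a)
        for i, t in enumerate(tags):
            expected = brute_force_hits(genome, t.sequence)
            got = by_tag[f"tag{i:05d}"]
            if not expected:
                assert got[0].status is MappingStatus.UNMAPPED
            else:
                assert sorted((a.chrom, a.start, a.strand) for a in got) == sorted(expected)
                want = MappingStatus.UNIQUE if len(expected) == 1 else MappingStatus.MULTI
                assert all(a.status is want for a in got)


class TestImportExport:
    def test_bed_line_parses(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t120\ttag7\t0\t+\n")
        (a,) = import_alignments(p)
        assert (a.chrom, a.start, a.end, a.tag_id, a.strand, a.status) == (
            "chr1", 100, 120, "tag7", "+", MappingStatus.UNIQUE,
        )

    def test_two_lines_same_tag_is_multi(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t120\tt\t0\t+\nchr2\t5\t25\tt\t0\t-\n")
        alns = import_alignments(p)
        assert all(a.status is MappingStatus.MULTI for a in alns)

    def test_round_trip_identity(self, tmp_path):
        alns = [
            TagAlignment("t1", "chr1", 10, 30, "+", MappingStatus.UNIQUE),
            TagAlignment("t2", "chr2", 40, 55, "-", MappingStatus.UNIQUE),
        ]
        p = tmp_path / "a.bed"
        write_bed6(alns, p)
        back = import_alignments(p)
        assert [(a.tag_id, a.chrom, a.start, a.end, a.strand) for a in back] == [
            (a.tag_id, a.chrom, a.start, a.end, a.strand) for a in alns
        ]

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t120\tt\t0\t+\nchr1\tBAD\t120\tt\t0\t+\n")
        with pytest.raises(ValueError, match=":2"):
            import_alignments(p)

    def test_unknown_chrom_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrZ\t1\t10\tt\t0\t+\n")
        with pytest.raises(ValueError, match="chrZ"):
            import_alignments(p, known_chroms={"chr1"})


class TestSummary:
    def test_published_style_totals(self):
        """564 distinct tags, 148 contaminant, 197 unmapped-or-multi leaves
        219 uniquely mapped — a 38.8% unique fraction."""
        status = {}
        for i in range(148):
            status[f"c{i}"] = MappingStatus.CONTAMINANT
        for i in range(197):
            status[f"m{i}"] = MappingStatus.MULTI
        for i in range(219):
            status[f"u{i}"] = MappingStatus.UNIQUE
        s = summarize_mapping(status)
        assert (s.n_total, s.n_unique) == (564, 219)
        assert s.fractions["unique"] == pytest.approx(0.388, abs=5e-4)
        assert sum(s.fractions.values()) == pytest.approx(1.0)

    def test_all_unique(self):
        s = summarize_mapping({"a": MappingStatus.UNIQUE, "b": MappingStatus.UNIQUE})
        assert s.fractions == {"contaminant": 0.0, "unmapped_or_multi": 0.0, "unique": 1.0}

    def test_simulated_summary_matches_truth(self):
        from clipscape.clone_processing import extract_all, tabulate_tags

        w = build_world(desk_sim_config(seed=29, n_clones=250))
        cfg = w.config
        tags, _ = tabulate_tags(extract_all(w.clones, cfg.adapter5, cfg.adapter3))
        _, status = triage_tags(tags, w.genome, w.contaminants)
        s = summarize_mapping(status)
        assert s.n_total == len(tags)
        truth_contam = {r.insert for r in w.truth.clones if r.origin == "contaminant"}
        assert s.n_contaminant == sum(1 for t in tags if t.sequence in truth_contam)
        assert s.n_contaminant + s.n_unmapped_or_multi + s.n_unique == s.n_total
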