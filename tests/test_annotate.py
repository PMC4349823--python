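"""Annotation interval arithmetic, intergenic derivation, candidate filtering."""

import numpy as np
import pytest

from srnaseg.annotate import (
    Feature,
    GenomicInterval,
    build_intergenic_features,
    classify_candidates,
    conserved_segments,
    load_wmel_conserved_regions,
    read_annotation,
    write_annotation,
)
from srnaseg.errors import ContentError, ParseError
from srnaseg.profile import ClassProfile

GFF = """##gff-version 3
##sequence-region chr 1 5000
chr\ttest\tCDS\t100\t400\t.\t+\t.\tID=geneA;Name=geneA
chr\ttest\tCDS\t900\t1400\t.\t-\t.\tID=geneB;Name=geneB
chr\ttest\ttRNA\t1500\t1575\t.\t+\t.\tID=trnA;Name=tRNA-Ala
chr\ttest\tCDS\t1700\t2400\t.\t+\t.\tID=geneC;Name=geneC
"""


def cds(start, end, name):
    return Feature(GenomicInterval("chr", start, end), "CDS", name)


class TestReadAnnotation:
    def test_roles_and_order(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(GFF)
        feats = read_annotation(path)
        assert [f.role for f in feats] == ["CDS", "CDS", "tRNA", "CDS"]
        starts = [f.interval.start for f in feats]
        assert starts == sorted(starts)

    def test_out_of_order_file_sorted(self, tmp_path):
        lines = GFF.strip().splitlines()
        shuffled = "\n".join(lines[:2] + [lines[5], lines[2], lines[4], lines[3]]) + "\n"
        path = tmp_path / "b.gff3"
        path.write_text(shuffled)
        feats = read_annotation(path)
        starts = [f.interval.start for f in feats]
        assert starts == sorted(starts)

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\nchr\tonly\tthree\n")
        with pytest.raises(ParseError, match="line 2"):
            read_annotation(path)

    def test_unknown_type_becomes_other(self, tmp_path):
        path = tmp_path / "u.gff3"
        path.write_text("##gff-version 3\nchr\tt\trepeat_region\t5\t50\t.\t+\t.\tID=rep1\n")
        feats = read_annotation(path)
        assert feats[0].role == "other"

    def test_round_trip_through_writer(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(GFF)
        feats = read_annotation(path)
        out = tmp_path / "out.gff3"
        write_annotation(feats, out, genome_length=5000, ref_id="chr")
        again = read_annotation(out)
        assert [(f.interval.start, f.interval.end, f.role) for f in feats] == [
            (f.interval.start, f.interval.end, f.role) for f in again
        ]


class TestBuildIntergenic:
    def test_simple_gaps_with_terminal(self):
        feats = [cds(1, 100, "a"), cds(201, 300, "b")]
        gaps = build_intergenic_features(feats, 400)
        assert [(g.interval.start, g.interval.end) for g in gaps] == [(101, 200), (301, 400)]
        assert [g.id for g in gaps] == ["IG-1", "IG-2"]
        assert all(g.role == "intergenic" for g in gaps)

    def test_adjacent_genes_no_gap(self):
        feats = [cds(1, 100, "a"), cds(101, 200, "b")]
        assert build_intergenic_features(feats, 200) == []

    def test_nested_genes_collapsed(self):
        feats = [cds(1, 300, "outer"), cds(50, 120, "inner")]
        gaps = build_intergenic_features(feats, 500)
        assert [(g.interval.start, g.interval.end) for g in gaps] == [(301, 500)]

    def test_partition_property(self):
        """Intergenic gaps plus the annotation union tile the genome exactly."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            starts = np.sort(rng.choice(np.arange(1, 900), size=8, replace=False))
            feats = [
                cds(int(s), int(min(s + rng.integers(5, 120), 950)), f"g{i}")
                for i, s in enumerate(starts)
            ]
            gaps = build_intergenic_features(feats, 1000)
            covered = np.zeros(1001, dtype=int)
            for f in feats:
                covered[f.interval.start : f.interval.end + 1] = 1
            total = covered[1:].sum() + sum(g.interval.length for g in gaps)
            assert total == 1000
            for g in gaps:
                assert covered[g.interval.start : g.interval.end + 1].sum() == 0

    def test_genome_shorter_than_annotation_rejected(self):
        with pytest.raises(ContentError):
            build_intergenic_features([cds(1, 500, "a")], 400)


def flat_profile(start, values):
    coords = np.arange(start, start + len(values))
    return ClassProfile("chr", coords, np.asarray(values, float), 1, 100)


class TestConservedSegments:
    def test_long_run_kept(self):
        prof = flat_profile(1000, [0.9] * 60)
        (seg,) = conserved_segments(prof)
        assert (seg.start, seg.end, seg.length) == (1000, 1059, 60)

    def test_exact_threshold_length_dropped(self):
        prof = flat_profile(1000, [0.9] * 50)
        assert conserved_segments(prof) == []

    def test_dip_splits_run_below_threshold(self):
        vals = [0.9] * 40 + [0.3] + [0.9] * 39
        prof = flat_profile(1, vals)
        assert conserved_segments(prof) == []

    def test_coordinate_gap_breaks_run(self):
        coords = np.concatenate([np.arange(1, 41), np.arange(100, 140)])
        prof = ClassProfile("chr", coords, np.full(80, 0.95), 1, 10)
        assert conserved_segments(prof, len_min=30) != []
        assert all(s.length == 40 for s in conserved_segments(prof, len_min=30))
        assert conserved_segments(prof, len_min=50) == []

    def test_every_reported_segment_satisfies_thresholds(self):
        rng = np.random.default_rng(5)
        vals = rng.random(2000)
        prof = flat_profile(1, vals)
        for seg in conserved_segments(prof, p_min=0.5, len_min=10):
            sel = vals[seg.start - 1 : seg.end]
            assert seg.length == seg.end - seg.start + 1 > 10
            assert sel.min() >= 0.5


class TestClassifyCandidates:
    FEATS = [
        cds(100, 400, "geneA"),
        cds(900, 1400, "geneB"),
        Feature(GenomicInterval("chr", 1500, 1575), "tRNA", "trnA", "tRNA-Ala"),
        cds(1700, 2400, "geneC"),
    ]

    def test_intergenic_segment_gets_flanks(self):
        seg = GenomicInterval("chr", 500, 800)
        out = classify_candidates([seg], self.FEATS)
        (cand,) = out.candidates
        assert cand.upstream_feature == "geneA"
        assert cand.downstream_feature == "geneB"
        assert cand.length == 301

    def test_single_base_cds_overlap_rejected(self):
        seg = GenomicInterval("chr", 500, 900)  # touches geneB at 900
        out = classify_candidates([seg], self.FEATS)
        assert out.candidates == [] and out.rejected == [seg]

    def test_segment_inside_trna_binned_separately(self):
        seg = GenomicInterval("chr", 1510, 1570)
        out = classify_candidates([seg], self.FEATS)
        assert out.candidates == []
        assert out.annotated_noncoding[0][1].id == "trnA"

    def test_profile_stats_attached(self):
        prof = flat_profile(500, [0.8] * 100)
        seg = GenomicInterval("chr", 500, 599)
        out = classify_candidates([seg], self.FEATS, profile=prof, class_conservation=0.95)
        cand = out.candidates[0]
        assert cand.mean_profile == pytest.approx(0.8)
        assert cand.min_profile == pytest.approx(0.8)
        assert cand.class_conservation == 0.95


class TestPublishedRegions:
    def test_inclusive_lengths_match_published_values(self):
        df = load_wmel_conserved_regions()
        row = df[(df.upstream == "WD1081") & (df.downstream == "WD1082")].iloc[0]
        assert (row.start, row.end, row.length_nt) == (1039579, 1039870, 292)
        row = df[df.upstream == "rho"].iloc[0]
        assert (row.start, row.end, row.length_nt) == (768936, 768988, 53)

    def test_all_nineteen_pass_length_filter(self):
        df = load_wmel_conserved_regions()
        assert len(df) == 19
        assert (df.length_nt > 50).all()


class TestExports:
    def test_candidate_fasta_export(self, tmp_path):
        from srnaseg.annotate import classify_candidates, export_candidate_fasta

        genome = tmp_path / "g.fa"
        genome.write_text(">chr\n" + "ACGT" * 500 + "\n")
        feats = [cds(100, 400, "geneA"), cds(900, 1400, "geneB")]
        seg = GenomicInterval("chr", 501, 520)
        out = classify_candidates([seg], feats)
        fasta = tmp_path / "cand.fa"
        export_candidate_fasta(out, genome, fasta)
        text = fasta.read_text()
        assert text.startswith(">candidate-1 chr:501-520\n")
        seq = text.strip().splitlines()[1]
        assert len(seq) == 20
        assert seq == ("ACGT" * 500)[500:520]
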