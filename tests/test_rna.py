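"""RNA off-target variant filtering chain and edit-type labeling."""

import numpy as np
import pytest

from beamplicon.rna import (RNAFilterParams, VariantRecord,
                            annotate_strand_from_bed,
                            control_confidence_filter, gfp_background_filter,
                            label_edit_type, load_variants, percentile,
                            rna_pipeline, write_variant_tsv)
from beamplicon.simulate import RNASimParams, simulate_rna_tables
from oracles import rna_filter_reference


def _v(pos, ref="A", alt="G", depth=100, alt_depth=10, strand="+",
       contig="chr1", group=""):
    return VariantRecord(contig=contig, position=pos, ref=ref, alt=alt,
                         depth=depth, alt_depth=alt_depth,
                         gene_strand=strand, group=group)


class TestPercentile:
    def test_linear_interpolation_1_to_100(self):
        assert percentile(list(range(1, 101)), 90) == pytest.approx(90.1)

    def test_single_value_and_endpoints(self):
        assert percentile([7.0], 35) == 7.0
        vals = [3.0, 1.0, 2.0]
        assert percentile(vals, 100) == 3.0
        assert percentile(vals, 0) == 1.0


class TestControlConfidenceFilter:
    def _tables(self):
        oe = [_v(i, depth=d) for i, d in enumerate(range(10, 110, 10), 1)]
        # OE depths 10..100 -> 90th percentile = 91
        control = [_v(v.position, depth=500, alt_depth=0) for v in oe]
        return oe, control

    def test_clean_control_retained(self):
        oe, control = self._tables()
        assert control_confidence_filter(oe, control) == oe

    def test_consensus_boundary_98_excluded_99_retained(self):
        oe, control = self._tables()
        control[0] = _v(1, depth=500, alt_depth=10)   # ref fraction 0.98
        control[1] = _v(2, depth=500, alt_depth=5)    # ref fraction 0.99
        retained = control_confidence_filter(oe, control)
        assert oe[0] not in retained
        assert oe[1] in retained

    def test_control_depth_at_or_below_percentile_excluded(self):
        oe, control = self._tables()
        control[2] = _v(3, depth=91, alt_depth=0)  # == 90th pct: not greater
        control[3] = _v(4, depth=92, alt_depth=0)
        retained = control_confidence_filter(oe, control)
        assert oe[2] not in retained and oe[3] in retained

    def test_locus_absent_from_control_excluded(self):
        oe, control = self._tables()
        retained = control_confidence_filter(oe, control[1:])
        assert oe[0] not in retained and len(retained) == len(oe) - 1

    def test_empty_oe_table(self):
        assert control_confidence_filter([], [_v(1)]) == []


class TestGfpBackgroundFilter:
    def test_depth_boundary(self):
        keep = _v(1, depth=10, alt_depth=1)
        drop = _v(2, depth=9, alt_depth=1)
        assert gfp_background_filter([keep, drop]) == [keep]

    def test_zero_alt_excluded(self):
        assert gfp_background_filter([_v(1, depth=50, alt_depth=0)]) == []


class TestLabelEditType:
    @pytest.mark.parametrize("ref,alt,strand,expected", [
        ("A", "G", "+", "A-to-I"),
        ("T", "C", "-", "A-to-I"),
        ("C", "T", "+", "C-to-U"),
        ("G", "A", "-", "C-to-U"),
        ("A", "G", "-", "other"),
        ("C", "T", "-", "other"),
        ("A", "C", "+", "other"),
        ("A", "G", "unknown", "other"),
    ])
    def test_strand_aware_rules(self, ref, alt, strand, expected):
        assert label_edit_type(_v(1, ref=ref, alt=alt, strand=strand)) == expected


class TestPipeline:
    def test_oracle_equivalence_random_tables(self, rng):
        """Retained set matches a straight-line reimplementation across
        20 random 100-row tables."""
        for seed in range(20):
            local = np.random.default_rng(1000 + seed)
            oe, control, gfp = [], [], []
            for pos in range(1, 101):
                depth = int(local.integers(5, 300))
                oe.append(_v(pos, depth=depth,
                             alt_depth=int(local.integers(1, depth + 1)),
                             strand="+" if local.random() < 0.5 else "-"))
                if local.random() < 0.9:  # some loci missing from control
                    cdepth = int(local.integers(5, 800))
                    control.append(_v(pos, depth=cdepth,
                                      alt_depth=int(local.integers(0, cdepth // 3 + 1))))
                if local.random() < 0.3:
                    gdepth = int(local.integers(5, 60))
                    gfp.append(_v(pos, depth=gdepth,
                                  alt_depth=int(local.integers(0, gdepth + 1))))
            expected = rna_filter_reference(oe, control, gfp)
            got = rna_pipeline(oe, control, gfp)
            assert got.n_sites == len(expected)
            assert got.editing_fractions == [v.alt_fraction for v in expected]

    def test_background_only_input_yields_zero_sites(self):
        oe = [_v(1, depth=50, alt_depth=5), _v(2, depth=60, alt_depth=6)]
        control = [_v(1, depth=500, alt_depth=0), _v(2, depth=500, alt_depth=0)]
        gfp = [_v(1, depth=20, alt_depth=2), _v(2, depth=20, alt_depth=2)]
        assert rna_pipeline(oe, control, gfp).n_sites == 0

    def test_planted_edits_full_recall_no_false_positives(self):
        oe, control, gfp, truth = simulate_rna_tables(RNASimParams(seed=5))
        summary = rna_pipeline(oe, control, gfp)
        true_loci = truth[truth["kind"] == "true_edit"]
        assert summary.n_sites == len(true_loci) == 20
        assert summary.by_type == {"A-to-I": 20}

    def test_order_independence(self):
        oe, control, gfp, _ = simulate_rna_tables(RNASimParams(seed=6))
        fwd = rna_pipeline(oe, control, gfp)
        rev = rna_pipeline(oe[::-1], control[::-1], gfp[::-1])
        assert fwd.n_sites == rev.n_sites
        assert sorted(fwd.editing_fractions) == sorted(rev.editing_fractions)

    def test_monotone_in_thresholds(self):
        oe, control, gfp, _ = simulate_rna_tables(
            RNASimParams(seed=7, control_depth_range=(100, 400)))
        base = rna_pipeline(oe, control, gfp, RNAFilterParams()).n_sites
        tighter = rna_pipeline(oe, control, gfp,
                               RNAFilterParams(coverage_percentile=99.0)).n_sites
        assert tighter <= base

    def test_filter_log_monotone(self):
        oe, control, gfp, _ = simulate_rna_tables(RNASimParams(seed=8))
        log = rna_pipeline(oe, control, gfp).filter_log
        assert (log["n_input"] >= log["n_control_confident"]
                >= log["n_after_background_subtraction"])


class TestTableIO:
    def test_tsv_round_trip(self, tmp_path):
        oe, *_ = simulate_rna_tables(RNASimParams(seed=9))
        p = tmp_path / "oe.tsv"
        write_variant_tsv(oe, p)
        back = load_variants(p, group="overexpression")
        assert [(v.key, v.depth, v.alt_depth, v.gene_strand) for v in back] \
            == [(v.key, v.depth, v.alt_depth, v.gene_strand) for v in oe]

    def test_vcf_loading(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE_STRAND,Number=1,Type=String,Description="s">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tA\tG\t.\t.\tGENE_STRAND=+\tDP:AD\t50:45,5\n")
        recs = load_variants(vcf, group="overexpression")
        assert len(recs) == 1
        v = recs[0]
        assert (v.key, v.depth, v.alt_depth) == (("chr1", 100, "A", "G"), 50, 5)
        assert v.gene_strand == "+"

    def test_bed_strand_annotation(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t0\t150\tgeneA\t0\t-\nchr1\t150\t300\tgeneB\t0\t+\n")
        variants = [_v(100, strand="unknown"), _v(200, strand="unknown"),
                    _v(999, strand="unknown")]
        out = annotate_strand_from_bed(variants, bed)
        assert [v.gene_strand for v in out] == ["-", "+", "unknown"]
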