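"""SV catalog tests: polymorphism, size classes, gene intersection, report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svqtl import (
    GeneModel,
    SVRecord,
    classify_polymorphism,
    flowering_filter,
    intersect_genes,
    qtl_sv_report,
    size_classes,
)
from svqtl.svcat import size_class

FOUNDERS = [f"P{i}" for i in range(1, 8)]


def _sv(id, start, end, svtype="DEL", size=None, alt_in=(), chrom="A02", unknown=()):
    alleles = {f: (1 if f in alt_in else 0) for f in FOUNDERS}
    for f in unknown:
        alleles[f] = None
    return SVRecord(id, chrom, start, end, svtype, size, alleles)


class TestPolymorphism:
    def test_three_of_seven_carriers_is_polymorphic(self):
        part = classify_polymorphism([_sv("sv1", 0, 288, alt_in=("P2", "P4", "P6"))])
        assert [s.id for s in part.polymorphic] == ["sv1"]

    def test_shared_difference_from_reference_is_monomorphic(self):
        part = classify_polymorphism([_sv("sv1", 0, 100, alt_in=FOUNDERS)])
        assert [s.id for s in part.monomorphic] == ["sv1"]

    def test_reference_like_everywhere_is_monomorphic(self):
        part = classify_polymorphism([_sv("sv1", 0, 100)])
        assert [s.id for s in part.monomorphic] == ["sv1"]

    def test_unknown_alleles_ignored_unless_all_unknown(self):
        partial = _sv("sv1", 0, 100, alt_in=("P2",), unknown=("P3", "P4"))
        nothing = _sv("sv2", 0, 100, unknown=FOUNDERS)
        part = classify_polymorphism([partial, nothing])
        assert [s.id for s in part.polymorphic] == ["sv1"]
        assert [s.id for s in part.unknown] == ["sv2"]

    def test_partition_property_counts_sum(self):
        rng = np.random.default_rng(8)
        svs = []
        for i in range(40):
            carriers = tuple(np.array(FOUNDERS)[rng.uniform(size=7) < 0.4])
            svs.append(_sv(f"s{i}", i * 1000, i * 1000 + 100, alt_in=carriers))
        part = classify_polymorphism(svs)
        assert len(part.polymorphic) + len(part.monomorphic) + len(part.unknown) == 40


class TestSizeClasses:
    @pytest.mark.parametrize(
        "size,label",
        [
            (30, "30-99"),
            (99, "30-99"),
            (100, "100-999"),
            (429, "100-999"),
            (263, "100-999"),
            (999, "100-999"),
            (1000, "1000-9999"),
            (9999, "1000-9999"),
            (10_000, ">=10000"),
            (26_000, ">=10000"),
        ],
    )
    def test_half_open_bin_assignment(self, size, label):
        assert size_class(size) == label

    def test_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            size_class(29)
        with pytest.raises(ValueError, match="below minimum"):
            SVRecord("x", "A02", 0, 10, "DEL")

    def test_counts_invariant_under_shuffling(self):
        rng = np.random.default_rng(9)
        svs = [
            _sv(f"s{i}", i * 1000, i * 1000 + int(s), size=None, alt_in=("P2",))
            for i, s in enumerate(rng.integers(30, 20_000, 30))
        ]
        t1 = size_classes(svs)
        shuffled = list(svs)
        rng.shuffle(shuffled)
        t2 = size_classes(shuffled)
        pd.testing.assert_frame_equal(t1, t2)
        assert t1["total"].sum() == 30
        assert (t1["DEL"] + t1["INS"]).equals(t1["total"])


class TestIntersection:
    GENES = [
        GeneModel("g1", "A02", 100, 500, "+", "ATP binding"),
        GeneModel("g2", "A02", 200, 300, "+", ""),
        GeneModel("gp", "A02", 50_000, 60_000, "+", ""),
        GeneModel("gm", "A02", 40_000, 50_000, "-", ""),
    ]

    def test_overlap_is_intragenic(self):
        hits = intersect_genes([_sv("d1", 400, 900, alt_in=("P2",))], self.GENES)
        assert ("d1", "g1", "intragenic") in set(map(tuple, hits.to_numpy()))

    def test_half_open_boundary_touch_is_no_overlap(self):
        hits = intersect_genes([_sv("d1", 100, 200, alt_in=("P2",))], self.GENES)
        intragenic = set(hits[hits["relation"] == "intragenic"]["gene"])
        assert "g2" not in intragenic  # DEL ends where g2 begins
        assert "g1" in intragenic

    def test_promoter_window_respects_strand(self):
        # DEL at [41000, 42000): inside the 10 kb window upstream of gp's
        # start (+ strand, window [40000, 50000)), but NOT upstream of gm
        # (- strand: its promoter is [50000, 60000))
        hits = intersect_genes([_sv("d1", 41_000, 42_000, alt_in=("P2",))], self.GENES)
        pairs = set(zip(hits["gene"], hits["relation"]))
        assert ("gp", "promoter") in pairs
        assert ("gm", "promoter") not in pairs

    def test_insertion_intersects_as_anchor_point(self):
        ins = _sv("i1", 250, 250, svtype="INS", size=40, alt_in=("P2",))
        hits = intersect_genes([ins], self.GENES)
        genes = set(hits[hits["relation"] == "intragenic"]["gene"])
        assert genes == {"g1", "g2"}

    def test_unknown_chromosome_rejected_with_record_list(self):
        with pytest.raises(ValueError, match="stray"):
            intersect_genes([_sv("stray", 0, 100, alt_in=("P2",), chrom="Z01")], self.GENES)

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_matches_quadratic_all_pairs_oracle(self, data):
        n_sv = data.draw(st.integers(1, 8))
        svs = []
        for i in range(n_sv):
            start = data.draw(st.integers(0, 70_000))
            length = data.draw(st.integers(30, 5_000))
            svs.append(_sv(f"s{i}", start, start + length, alt_in=("P2",)))
        hits = intersect_genes(svs, self.GENES, promoter_bp=10_000)
        observed = set(map(tuple, hits.to_numpy()))
        expected = set()
        for sv in svs:
            s, e = sv.interval()
            for g in self.GENES:
                if s < g.end and e > g.start:
                    expected.add((sv.id, g.id, "intragenic"))
                ps, pe = (
                    (max(0, g.start - 10_000), g.start)
                    if g.strand == "+"
                    else (g.end, g.end + 10_000)
                )
                if s < pe and e > ps:
                    expected.add((sv.id, g.id, "promoter"))
        assert observed == expected


class TestFloweringFilter:
    @pytest.mark.parametrize(
        "annotation,flagged",
        [
            ("regulation of flower development", True),
            ("entrainment of circadian clock", True),
            ("Vegetative to reproductive phase transition", True),
            ("ATP binding", False),
            ("", False),
            ("pollen wall assembly", True),
        ],
    )
    def test_keyword_substring_matching(self, annotation, flagged):
        gene = GeneModel("g", "A02", 0, 100, "+", annotation)
        assert (gene in flowering_filter([gene])) is flagged


class TestReport:
    def test_percentages_mirror_gene_ratios(self):
        rng = np.random.default_rng(10)
        genes = []
        for i in range(92):
            start = 1000 + i * 3000
            ann = "regulation of flower development" if i < 10 else "ATP binding"
            genes.append(GeneModel(f"g{i}", "A02", start, start + 2000, "+", ann))
        sv = _sv("sv1", 1500, 1900, alt_in=("P2",))  # inside flowering gene g0
        qtls = pd.DataFrame([{"qtl": "A02_1", "chrom": "A02", "start": 0, "end": 300_000}])
        # short promoter window so the hit stays purely intragenic
        report = qtl_sv_report(qtls, [sv], genes, promoter_bp=500)
        row = report.iloc[0]
        assert row["n_genes"] == 92
        assert row["pct_flowering"] == pytest.approx(10.9, abs=0.05)
        assert row["n_flowering_with_sv"] == 1
        assert "sv1: 400 bp DEL" in row["sv_details"]

    def test_qtl_without_sv_genes_gets_dashes(self):
        genes = [GeneModel("g0", "A02", 1000, 2000, "+", "ATP binding")]
        qtls = pd.DataFrame([{"qtl": "A02_1", "chrom": "A02", "start": 0, "end": 10_000}])
        report = qtl_sv_report(qtls, [], genes)
        assert report.iloc[0]["flowering_sv_genes"] == "-"
        assert report.iloc[0]["sv_details"] == "-"
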