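"""Gene-relative TSS classification and upstream sequence extraction."""

import numpy as np
import pytest

from tsscall.classify import (assign_primary_secondary, classify,
                              upstream_sequence)
from tsscall.model import (FORWARD, REVERSE, ConditionRecord, ConsolidatedTss,
                           GeneRecord)
from tsscall.params import ParameterSet

from oracles import oracle_classify

PARAMS = ParameterSet()


def make_tss(position, strand=FORWARD, height=10.0, condition="A"):
    record = ConditionRecord(detected=True, enriched=True,
                             step_height=height, position=position)
    return ConsolidatedTss("c1", position, strand, {condition: record})


def gene(start, end, strand=FORWARD, tag="b0001", name="thrL"):
    return GeneRecord("c1", tag, name, "some product", start, end, strand)


def class_names(tss):
    return sorted(c.tss_class for c in tss.classifications)


class TestGeometry:
    def test_upstream_tss_is_primary_with_utr(self):
        t = make_tss(900)
        classify([t], [gene(1000, 2000)], PARAMS)
        (cls,) = t.classifications
        assert cls.tss_class == "primary"
        assert cls.utr_length == 100
        assert cls.locus_tag == "b0001"

    def test_inside_gene_opposite_strand_is_antisense_only(self):
        t = make_tss(1500, FORWARD)
        classify([t], [gene(1000, 2000, REVERSE)], PARAMS)
        assert class_names(t) == ["antisense"]

    def test_far_from_all_genes_is_orphan(self):
        t = make_tss(5000)
        classify([t], [gene(3000, 4000), gene(3500, 3900, REVERSE)], PARAMS)
        assert class_names(t) == ["orphan"]
        assert t.classifications[0].locus_tag == ""

    def test_tss_at_gene_start_is_internal_not_primary(self):
        t = make_tss(1000)
        classify([t], [gene(1000, 2000)], PARAMS)
        assert class_names(t) == ["internal"]

    def test_upstream_beyond_utr_window_not_associated(self):
        t = make_tss(699)  # 301 bp upstream
        classify([t], [gene(1000, 2000)], PARAMS)
        assert class_names(t) == ["orphan"]

    def test_reverse_gene_upstream_is_downstream_coordinate(self):
        t = make_tss(2100, REVERSE)
        classify([t], [gene(1000, 2000, REVERSE)], PARAMS)
        (cls,) = t.classifications
        assert cls.tss_class == "primary"
        assert cls.utr_length == 100

    def test_antisense_boundary_distance_inclusive(self):
        genes = [gene(1000, 2000)]
        near = make_tss(850, REVERSE)   # 150 bp from gene start
        far = make_tss(849, REVERSE)    # 151 bp
        classify([near, far], genes, PARAMS)
        assert class_names(near) == ["antisense"]
        assert class_names(far) == ["orphan"]

    def test_primary_and_antisense_simultaneously(self):
        genes = [gene(1000, 2000, FORWARD, tag="bF"),
                 gene(500, 880, REVERSE, tag="bR")]
        t = make_tss(900)
        classify([t], genes, PARAMS)
        assert class_names(t) == ["antisense", "primary"]


class TestPrimarySecondary:
    def test_strongest_upstream_tss_is_primary(self):
        weak = make_tss(750, height=20)    # utr 250
        strong = make_tss(960, height=80)  # utr 40
        classify([weak, strong], [gene(1000, 2000)], PARAMS)
        assert class_names(strong) == ["primary"]
        assert class_names(weak) == ["secondary"]

    def test_single_upstream_tss_is_primary(self):
        t = make_tss(800)
        classify([t], [gene(1000, 2000)], PARAMS)
        assert class_names(t) == ["primary"]

    def test_equal_heights_tie_breaks_to_smaller_utr(self):
        a = make_tss(900, height=50)  # utr 100
        b = make_tss(800, height=50)  # utr 200
        classify([a, b], [gene(1000, 2000)], PARAMS)
        assert class_names(a) == ["primary"]
        assert class_names(b) == ["secondary"]

    def test_first_mode_picks_five_prime_most(self):
        a = make_tss(900, height=80)
        b = make_tss(800, height=20)
        classify([a, b], [gene(1000, 2000)],
                 PARAMS.replace(primary_mode="first"))
        assert class_names(b) == ["primary"]
        assert class_names(a) == ["secondary"]

    def test_shared_upstream_region_evaluated_per_gene(self):
        """One TSS can be primary for one gene and secondary for another."""
        g1, g2 = gene(1000, 1200, tag="b1"), gene(1100, 1300, tag="b2")
        strong = make_tss(950, height=90)
        weak = make_tss(900, height=30)
        classify([strong, weak], [g1, g2], PARAMS)
        by_gene = {(c.locus_tag, c.tss_class) for c in strong.classifications}
        assert ("b1", "primary") in by_gene and ("b2", "primary") in by_gene
        by_gene_weak = {(c.locus_tag, c.tss_class)
                        for c in weak.classifications}
        assert by_gene_weak == {("b1", "secondary"), ("b2", "secondary")}

    def test_assign_primary_secondary_direct(self):
        strong, weak = make_tss(960, height=80), make_tss(750, height=20)
        primary, secondaries = assign_primary_secondary(
            [(weak, 250), (strong, 40)], mode="strongest")
        assert primary is strong and secondaries == [weak]
        primary, _ = assign_primary_secondary(
            [(weak, 250), (strong, 40)], mode="first")
        assert primary is weak


class TestInvariants:
    def _random_instance(self, rng):
        genes = [gene(int(start), int(start + rng.integers(20, 60)),
                      rng.choice([FORWARD, REVERSE]), tag=f"g{i}")
                 for i, start in enumerate(
                     rng.integers(1, 1500, rng.integers(1, 8)))]
        positions = np.unique(rng.integers(1, 1600, rng.integers(1, 25)))
        tss = [make_tss(int(pos), rng.choice([FORWARD, REVERSE]),
                        height=float(rng.integers(1, 100)))
               for pos in positions]
        return genes, tss

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            genes, tss = self._random_instance(rng)
            classify(tss, genes, PARAMS)
            strengths = {(t.position, t.strand): t.max_enriched_height
                         for t in tss}
            for t in tss:
                expected = oracle_classify(t.position, t.strand, strengths,
                                           genes, PARAMS)
                assert set(class_names(t)) == expected

    def test_every_tss_classified_and_orphan_exclusive(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            genes, tss = self._random_instance(rng)
            classify(tss, genes, PARAMS)
            for t in tss:
                assert len(t.classifications) >= 1
                names = class_names(t)
                if "orphan" in names:
                    assert names == ["orphan"]

    def test_at_most_one_primary_per_gene(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            genes, tss = self._random_instance(rng)
            classify(tss, genes, PARAMS)
            per_gene = {}
            for t in tss:
                for c in t.classifications:
                    if c.tss_class == "primary":
                        per_gene[c.locus_tag] = per_gene.get(c.locus_tag, 0) + 1
            assert all(n == 1 for n in per_gene.values())


class TestUpstreamSequence:
    GENOME = {"c1": "ACGTACGTACGTACGTACGT"}  # 20 bp

    def test_forward_excludes_tss_base(self):
        t = make_tss(9)
        assert upstream_sequence(t, self.GENOME, 4) == "ACGT"  # bases 5..8

    def test_forward_truncated_at_origin(self):
        t = make_tss(3)
        assert upstream_sequence(t, self.GENOME, 50) == "AC"

    def test_reverse_is_reverse_complement_downstream(self):
        t = make_tss(9, REVERSE)
        # bases 10..13 are "CGTA"; reverse complement is "TACG"
        assert upstream_sequence(t, self.GENOME, 4) == "TACG"

    def test_reverse_non_palindromic_window(self):
        genome = {"c1": "AAAAACCCGGTTTTTTTTTT"}
        t = make_tss(5, REVERSE)
        # bases 6..10 = "CCCGG" -> reverse complement "CCGGG"
        assert upstream_sequence(t, genome, 5) == "CCGGG"

    def test_unknown_replicon_raises(self):
        with pytest.raises(LookupError):
            upstream_sequence(make_tss(5), {"other": "ACGT"}, 4)
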