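"""Basal+extension domains and CRE assignment against the walk oracle."""

import numpy as np
import pytest

from cresig.cre import CRESet, ENHANCER, TARGET_SPECIFIC
from cresig.domains import (
    assign_cres,
    basal_domain,
    extend_domains,
    signed_tss_distance,
)
from cresig.intervals import GenomicInterval, IntervalSet
from cresig.io import ChromSizes, GeneModel

from conftest import oracle_extend


def gene(gid, tss, strand="+", chrom="chr1"):
    return GeneModel(gid, gid.upper(), chrom, strand, tss)


SIZES = ChromSizes({"chr1": 10_000_000})


class TestBasalDomain:
    def test_plus_strand_default_window(self):
        assert basal_domain(gene("g", 10_000)) == GenomicInterval("chr1", 5_000, 11_000)

    def test_minus_strand_mirror(self):
        assert basal_domain(gene("g", 10_000, "-")) == GenomicInterval("chr1", 9_000, 15_000)

    def test_clipping_at_chromosome_start_and_end(self):
        assert basal_domain(gene("g", 2_000)) == GenomicInterval("chr1", 0, 3_000)
        sizes = ChromSizes({"chr1": 10_500})
        assert basal_domain(gene("g", 10_000), sizes) == GenomicInterval("chr1", 5_000, 10_500)

    def test_unknown_chromosome_errors(self):
        with pytest.raises(KeyError):
            basal_domain(gene("g", 100, chrom="chrZ"), SIZES)


class TestExtendDomains:
    def test_lone_gene_caps_at_max_extension(self):
        [d] = extend_domains([gene("g", 5_000_000)], SIZES)
        assert d.extended == GenomicInterval("chr1", 4_000_000, 6_000_000)
        assert d.basal == GenomicInterval("chr1", 4_995_000, 5_001_000)

    def test_two_genes_stop_at_neighbor_basal_boundaries(self):
        g1, g2 = gene("g1", 100_000), gene("g2", 140_000)
        d1, d2 = extend_domains([g1, g2], SIZES)
        assert d1.extended.end == 135_000  # left edge of g2's basal window
        assert d2.extended.start == 101_000  # right edge of g1's basal window

    def test_overlapping_basal_blocks_extension(self):
        # basal windows overlap; extension toward each other is zero
        g1, g2 = gene("g1", 100_000), gene("g2", 104_000)
        d1, d2 = extend_domains([g1, g2], SIZES)
        assert d1.extended.end == d1.basal.end
        assert d2.extended.start == d2.basal.start

    def test_max_extension_zero_reduces_to_basal(self):
        genes = [gene("g1", 50_000), gene("g2", 80_000, "-")]
        for d in extend_domains(genes, SIZES, max_extension=0):
            assert d.extended == d.basal

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            extend_domains([gene("g", 1_000), gene("g", 2_000)], SIZES)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_annotations_match_walk_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chrom_len = 200_000
        sizes = ChromSizes({"chr1": chrom_len})
        n = int(rng.integers(2, 9))
        genes = [
            gene(f"g{i}", int(rng.integers(0, chrom_len)), "+-"[int(rng.integers(2))])
            for i in range(n)
        ]
        up, down, max_ext = 2_000, 500, 20_000
        domains = extend_domains(genes, sizes, up, down, max_ext)
        expected = oracle_extend(genes, sizes, up, down, max_ext)
        for d in domains:
            assert (d.extended.start, d.extended.end) == expected[d.gene_id], d.gene_id
            # structural invariants
            assert d.extended.start <= d.basal.start <= d.basal.end <= d.extended.end
            assert d.extended.start >= max(0, d.tss - max_ext) or d.extended.start == d.basal.start
            assert d.extended.end <= min(chrom_len, d.tss + max_ext) or d.extended.end == d.basal.end


class TestSignedDistance:
    def test_plus_strand(self):
        assert signed_tss_distance(GenomicInterval("chr1", 1100, 1200), gene("g", 1000)) == 150

    def test_minus_strand_flips_sign(self):
        assert signed_tss_distance(GenomicInterval("chr1", 1100, 1200), gene("g", 1000, "-")) == -150

    def test_cre_centred_on_tss(self):
        assert signed_tss_distance(GenomicInterval("chr1", 900, 1100), gene("g", 1000)) == 0

    def test_chromosome_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            signed_tss_distance(GenomicInterval("chr2", 0, 10), gene("g", 1000))


class TestAssignCres:
    def make_cres(self, spans):
        return CRESet("heart", ENHANCER, IntervalSet(GenomicInterval("chr1", s, e) for s, e in spans), TARGET_SPECIFIC)

    def test_cre_in_one_basal_domain(self):
        domains = extend_domains([gene("g1", 100_000), gene("g2", 3_000_000)], SIZES)
        result = assign_cres(self.make_cres([(99_000, 99_500)]), domains)
        assert [a.gene_id for a in result.assignments] == ["g1"]
        [a] = result.assignments
        assert a.signed_distance == 99_250 - 100_000
        assert len(result.unassigned) == 0

    def test_cre_in_overlapping_extended_domains_assigned_to_both(self):
        domains = extend_domains([gene("g1", 100_000), gene("g2", 300_000)], SIZES)
        # between the two genes, inside both extended domains
        result = assign_cres(self.make_cres([(200_000, 200_400)]), domains)
        assert sorted(a.gene_id for a in result.assignments) == ["g1", "g2"]

    def test_cre_beyond_cap_is_unassigned(self):
        domains = extend_domains([gene("g1", 100_000)], SIZES)
        result = assign_cres(self.make_cres([(5_000_000, 5_000_300)]), domains)
        assert result.assignments == []
        assert len(result.unassigned) == 1

    def test_assignment_count_conservation(self, rng):
        genes = [gene(f"g{i}", int(t)) for i, t in enumerate(rng.integers(10_000, 9_000_000, 15))]
        domains = extend_domains(genes, SIZES)
        spans = [(int(s), int(s) + 500) for s in rng.integers(0, 9_500_000, 40)]
        result = assign_cres(self.make_cres(spans), domains)
        per_gene = sum(1 for a in result.assignments)
        per_cre = {}
        for a in result.assignments:
            per_cre[(a.cre.start, a.cre.end)] = per_cre.get((a.cre.start, a.cre.end), 0) + 1
        assert per_gene == sum(per_cre.values())
        assert len(per_cre) + len(result.unassigned) == len(self.make_cres(spans).intervals)
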