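"""Taxonomy voting, overlap geometry, pair correlations, upstream regions
and interaction densities."""

import numpy as np
import pandas as pd
import pytest

from metasrna.annotation_io import Contig, GeneFeature, GenomeAnnotation, TranscriptFeature
from metasrna.community_analytics import (
    InteractionRecord,
    Lineage,
    assign_srna_taxonomy,
    contig_taxonomy,
    extract_upstream,
    interaction_density,
    overlap_profile,
    pair_correlations,
    parse_lineage,
)
from metasrna.expression import ExpressionMatrix
from metasrna.srna_discovery import SRNACatalog, SRNARecord


def srna(start, end, strand="+", tid="as1", contig="c1"):
    t = TranscriptFeature(tid, contig, start, end, strand, 20.0, 5.0)
    return SRNARecord(transcript=t, label="antisense")


class TestContigTaxonomy:
    def test_unanimous_vote_has_full_support(self):
        lin = parse_lineage("Archaea;Euryarchaeota;Halobacteria")
        out = contig_taxonomy([(lin, 1.0), (lin, 1.0)])
        assert out.name_at("class") == "Halobacteria"
        assert out.support[2] == pytest.approx(1.0)

    def test_weighted_majority_support(self):
        out = contig_taxonomy([(parse_lineage("Archaea"), 600.0),
                               (parse_lineage("Bacteria"), 300.0)])
        assert out.name_at("domain") == "Archaea"
        assert out.support[0] == pytest.approx(2 / 3)

    def test_even_tie_keeps_lexicographic_first_and_flags(self):
        out = contig_taxonomy([(parse_lineage("Archaea"), 1.0),
                               (parse_lineage("Bacteria"), 1.0)])
        assert out.name_at("domain") == "Archaea"
        assert out.tie is True

    def test_descent_stops_below_majority(self):
        out = contig_taxonomy([
            (parse_lineage("Bacteria;Cyanobacteria"), 4.0),
            (parse_lineage("Bacteria;Bacteroidetes"), 3.0),
            (parse_lineage("Bacteria;Proteobacteria"), 3.0),
        ])
        assert out.name_at("domain") == "Bacteria"
        assert out.name_at("phylum") is None

    def test_empty_gene_list_gives_empty_lineage(self):
        assert contig_taxonomy([]).deepest is None

    def test_permutation_and_weight_scale_invariance(self):
        genes = [(parse_lineage("Archaea;Euryarchaeota"), 10.0),
                 (parse_lineage("Bacteria;Cyanobacteria"), 4.0),
                 (parse_lineage("Archaea;Nanohaloarchaeota"), 2.0)]
        a = contig_taxonomy(genes)
        b = contig_taxonomy(list(reversed(genes)))
        c = contig_taxonomy([(l, w * 7.5) for l, w in genes])
        assert a == b == c

    def test_assignment_copies_contig_lineage(self, cfg):
        lin = parse_lineage("Archaea;Euryarchaeota")
        cat = SRNACatalog(records=[srna(0, 100, tid="a", contig="c1"),
                                   srna(200, 300, tid="b", contig="c1"),
                                   srna(0, 100, tid="c", contig="c2")],
                          config=cfg)
        with pytest.warns(UserWarning, match="c2"):
            assign_srna_taxonomy(cat, {"c1": lin})
        assert cat.records[0].taxonomy == cat.records[1].taxonomy == lin
        assert cat.records[2].taxonomy is None


class TestOverlapProfile:
    def gene(self, start, end, strand):
        return GeneFeature("g1", "c1", start, end, strand)

    def test_plus_strand_projection(self):
        prof = overlap_profile(srna(100, 150, "-"), self.gene(100, 200, "+"))
        assert (prof.rel_start, prof.rel_end) == (0.0, 0.5)

    def test_minus_strand_gene_measures_from_its_five_prime_end(self):
        prof = overlap_profile(srna(150, 200, "+"), self.gene(100, 200, "-"))
        assert (prof.rel_start, prof.rel_end) == (0.0, 0.5)

    def test_full_coverage_spans_unit_interval(self):
        prof = overlap_profile(srna(50, 250, "-"), self.gene(100, 200, "+"))
        assert (prof.rel_start, prof.rel_end) == (0.0, 1.0)
        assert prof.overlap_nt == 100

    def test_disjoint_features_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            overlap_profile(srna(300, 400, "-"), self.gene(100, 200, "+"))

    def test_mirroring_contig_and_strands_is_invariant(self):
        # mirror about the midpoint of a 1000-nt contig and flip strands
        gene = self.gene(100, 200, "+")
        a = overlap_profile(srna(150, 400, "-"), gene)
        mirrored_gene = GeneFeature("g1", "c1", 1000 - 200, 1000 - 100, "-")
        b = overlap_profile(srna(1000 - 400, 1000 - 150, "+"), mirrored_gene)
        assert (a.rel_start, a.rel_end) == (b.rel_start, b.rel_end)


class TestPairCorrelations:
    def mat(self, rows, features, kind="standardized_tpm"):
        vals = np.asarray(rows, dtype=float)
        cols = [f"s{i}" for i in range(vals.shape[1])]
        return ExpressionMatrix(pd.DataFrame(vals, index=features, columns=cols), kind)

    def test_perfect_anticorrelation(self, cfg):
        x = np.arange(10, dtype=float)
        a = self.mat([x], ["a1"])
        t = self.mat([100.0 - x], ["g1"])
        (c,) = pair_correlations(a, t, [("a1", "g1")], cfg)
        assert c.pearson_r == pytest.approx(-1.0)
        assert c.significant

    def test_perfect_correlation(self, cfg):
        x = np.arange(10, dtype=float)
        (c,) = pair_correlations(self.mat([x], ["a1"]), self.mat([x], ["g1"]),
                                 [("a1", "g1")], cfg)
        assert c.pearson_r == pytest.approx(1.0)

    def test_zero_variance_reported_na(self, cfg):
        (c,) = pair_correlations(self.mat([np.ones(5)], ["a1"]),
                                 self.mat([np.arange(5)], ["g1"]),
                                 [("a1", "g1")], cfg)
        assert np.isnan(c.pearson_r) and not c.significant

    def test_fewer_than_three_shared_samples_rejected(self, cfg):
        with pytest.raises(ValueError, match="3 shared"):
            pair_correlations(self.mat([[1, 2]], ["a1"]), self.mat([[1, 2]], ["g1"]),
                              [("a1", "g1")], cfg)


class TestUpstream:
    def annotation(self, length=300):
        seq = "".join("ACGT"[i % 4] for i in range(length))
        return GenomeAnnotation({"c1": Contig("c1", length, seq)}, [])

    def test_plus_strand_window_ends_at_start(self, cfg):
        ann = self.annotation()
        region = extract_upstream(srna(100, 200, "+"), ann, cfg)
        assert region.sequence == ann.contigs["c1"].sequence[50:100]
        assert not region.truncated

    def test_minus_strand_window_is_reverse_complement_after_end(self, cfg):
        ann = self.annotation()
        region = extract_upstream(srna(100, 200, "-"), ann, cfg)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        expected = "".join(comp[b] for b in reversed(ann.contigs["c1"].sequence[200:250]))
        assert region.sequence == expected

    def test_contig_edge_truncates_and_flags(self, cfg):
        region = extract_upstream(srna(20, 120, "+"), self.annotation(), cfg)
        assert len(region.sequence) == 20 and region.truncated

    def test_zero_upstream_gives_empty_flagged(self, cfg):
        region = extract_upstream(srna(0, 100, "+"), self.annotation(), cfg)
        assert region.sequence == "" and region.truncated


class TestInteractionDensity:
    def rec(self, s, e, p, target="m1", energy=-10.0):
        return InteractionRecord("s1", target, s, e, energy, p)

    def test_uniform_records_stack_and_peak_at_leftmost_max(self, cfg):
        recs = [self.rec(10, 20, 0.001, target=f"m{i}") for i in range(100)]
        dens = interaction_density(recs, 100, cfg)
        assert dens.counts[9:20].tolist() == [100] * 11
        assert dens.counts.sum() == 100 * 11
        assert dens.peak == 10

    def test_only_the_top_n_by_pvalue_contribute(self, cfg):
        good = [self.rec(10, 10, 0.001, target=f"g{i}") for i in range(100)]
        bad = [self.rec(50, 50, 0.9, target=f"b{i}") for i in range(50)]
        dens = interaction_density(good + bad, 100, cfg)
        assert dens.counts[9] == 100 and dens.counts[49] == 0
        assert dens.n_used == 100

    def test_energy_ranking_switch(self, cfg):
        low_e = [self.rec(10, 10, 0.9, target=f"e{i}", energy=-30.0) for i in range(100)]
        low_p = [self.rec(50, 50, 0.001, target=f"p{i}", energy=-1.0) for i in range(100)]
        by_p = interaction_density(low_e + low_p, 100, cfg, rank_by="pvalue")
        by_e = interaction_density(low_e + low_p, 100, cfg, rank_by="energy")
        assert by_p.counts[49] == 100 and by_p.counts[9] == 0
        assert by_e.counts[9] == 100 and by_e.counts[49] == 0

    def test_total_mass_equals_sum_of_kept_spans(self, cfg):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(150):
            s = int(rng.integers(1, 90))
            e = int(rng.integers(s, 100))
            recs.append(self.rec(s, e, float(rng.uniform()), target=f"m{i}"))
        dens = interaction_density(recs, 100, cfg)
        kept = sorted(recs, key=lambda r: (r.pvalue, r.energy, r.target_id))[:100]
        assert dens.counts.sum() == sum(r.srna_end - r.srna_start + 1 for r in kept)

    def test_empty_record_list_gives_zero_counts(self, cfg):
        dens = interaction_density([], 80, cfg)
        assert dens.counts.sum() == 0 and dens.peak is None

    def test_out_of_range_position_rejected(self, cfg):
        with pytest.raises(ValueError, match="outside"):
            interaction_density([self.rec(5, 120, 0.1)], 100, cfg)
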