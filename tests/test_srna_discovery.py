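"""Classification rules, the six-frame reading-frame filter and the dynamic
contig-edge correction."""

import numpy as np
import pytest

from metasrna.annotation_io import (
    Contig,
    GeneFeature,
    PipelineConfig,
    TranscriptFeature,
)
from metasrna.srna_discovery import (
    SRNARecord,
    classify_transcript,
    compute_edge_threshold,
    discover_srnas,
    effective_genes,
    longest_orf_fraction,
    catalog_to_frame,
)

from conftest import make_annotation


def transcript(start, end, strand="+", cov=20.0, tpm=10.0, tid="t1"):
    return TranscriptFeature(tid, "c1", start, end, strand, cov, tpm)


def six_frame_oracle(seq):
    """Independent brute force: enumerate stop positions in each of the six
    frames and measure the largest stop-free gap in codons."""
    stops = {"TAA", "TAG", "TGA"}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    best = 0
    for s in (seq, "".join(comp[b] for b in reversed(seq))):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]
            stop_idx = [-1] + [i for i, c in enumerate(codons) if c in stops] + [len(codons)]
            for a, b in zip(stop_idx, stop_idx[1:]):
                best = max(best, b - a - 1)
    return best * 3 / len(seq) if len(seq) >= 3 else 0.0


class TestEffectiveGenes:
    def gene(self, length, start=1000):
        return GeneFeature("g1", "c1", start, start + length, "+")

    def test_small_peptide_in_long_transcript_removed(self, cfg):
        t = transcript(950, 1230)  # length 280 > 3 x 90
        assert effective_genes(t, [self.gene(90)], cfg) == []

    def test_ratio_bound_is_strict(self, cfg):
        t = transcript(960, 1230)  # length 270 == 3 x 90: not "more than"
        assert len(effective_genes(t, [self.gene(90)], cfg)) == 1

    def test_gene_at_size_bound_retained(self, cfg):
        t = transcript(900, 1300)  # length 400, gene length 100 not < 100
        assert len(effective_genes(t, [self.gene(100)], cfg)) == 1


class TestClassification:
    def test_far_from_genes_on_both_strands_is_intergenic(self, cfg):
        ann = make_annotation(genes=[("g1", 100, 200, "+"), ("g2", 435, 500, "-")])
        rec = classify_transcript(transcript(235, 400), ann, cfg)
        assert rec.label == "intergenic"
        assert rec.nearest_gene_distance_same == 35
        assert rec.nearest_gene_distance_opposite == 35

    def test_opposite_overlap_at_bound_is_antisense(self, cfg):
        ann = make_annotation(genes=[("g1", 100, 200, "+"), ("g2", 500, 700, "-")])
        rec = classify_transcript(transcript(240, 510), ann, cfg)  # overlap 10
        assert rec.label == "antisense"
        assert rec.antisense_genes == [("g2", 10)]

    def test_opposite_overlap_below_bound_is_ambiguous(self, cfg):
        ann = make_annotation(genes=[("g1", 100, 200, "+"), ("g2", 500, 700, "-")])
        rec = classify_transcript(transcript(240, 509), ann, cfg)  # overlap 9
        assert rec.label == "ambiguous"

    def test_any_same_strand_overlap_is_coding(self, cfg):
        ann = make_annotation(genes=[("g1", 100, 200, "+")])
        rec = classify_transcript(transcript(199, 400), ann, cfg)  # 1 nt overlap
        assert rec.label == "coding"

    def test_gene_29nt_away_opposite_strand_is_ambiguous(self, cfg):
        ann = make_annotation(genes=[("g1", 100, 200, "-")])
        rec = classify_transcript(transcript(229, 400), ann, cfg)
        assert rec.label == "ambiguous"

    def test_no_genes_at_all_is_intergenic(self, cfg):
        rec = classify_transcript(transcript(1000, 1200), make_annotation(), cfg)
        assert rec.label == "intergenic"

    def test_unknown_contig_is_an_error(self, cfg):
        t = TranscriptFeature("t1", "cX", 0, 100, "+", 1.0, 1.0)
        with pytest.raises(Exception, match="cX"):
            classify_transcript(t, make_annotation(), cfg)

    def test_every_transcript_gets_exactly_one_label(self, bundle, session_cfg):
        catalog = discover_srnas(bundle.annotation, bundle.transcripts, session_cfg)
        labels = {"intergenic", "antisense", "coding", "ambiguous"}
        assert all(r.label in labels for r in catalog.records)
        assert len(catalog.records) == len(bundle.transcripts)

    def test_raising_margins_never_adds_candidates(self, bundle, session_cfg):
        base = discover_srnas(bundle.annotation, bundle.transcripts, session_cfg)
        strict = PipelineConfig(min_gene_distance=60, min_antisense_overlap=25)
        harder = discover_srnas(bundle.annotation, bundle.transcripts, strict)
        n = lambda cat, lab: sum(r.label == lab for r in cat.records)
        assert n(harder, "intergenic") <= n(base, "intergenic")
        assert n(harder, "antisense") <= n(base, "antisense")


class TestOrfFraction:
    def test_agrees_with_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(50, 501))
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
            assert longest_orf_fraction(seq) == pytest.approx(six_frame_oracle(seq))

    def test_all_stop_frame_value_matches_oracle(self):
        seq = "TAATAATAA"
        assert longest_orf_fraction(seq) == pytest.approx(six_frame_oracle(seq))

    def test_stop_free_homopolymer_is_one(self):
        assert longest_orf_fraction("A" * 90) == 1.0

    def test_too_short_sequence_is_zero(self):
        assert longest_orf_fraction("AC") == 0.0

    def test_atg_mode_requires_a_start_codon(self):
        # GCA tiling has no ATG and no stop: full frame but no ORF start
        assert longest_orf_fraction("GCA" * 30, mode="atg") == 0.0
        assert longest_orf_fraction("ATG" + "GCA" * 29 + "TAA", mode="atg") > 0.9


class TestEdgeThreshold:
    def contigs(self, n=20, length=10_000):
        return {f"c{i}": Contig(f"c{i}", length) for i in range(n)}

    def records(self, edge_distances):
        recs = []
        for i, d in enumerate(edge_distances):
            t = TranscriptFeature(f"t{i}", "c0", 600, 700, "+", 20.0, 1.0)
            r = SRNARecord(transcript=t, label="intergenic")
            r.edge_distance = int(d)
            recs.append(r)
        return recs

    def test_no_candidates_gives_zero_threshold(self, cfg):
        report = compute_edge_threshold([], self.contigs(), cfg)
        assert report.chosen_d == 0 and report.grid == []

    def test_candidates_at_contig_centers_give_zero(self, cfg):
        report = compute_edge_threshold(self.records([5000] * 50), self.contigs(), cfg)
        assert report.chosen_d == 0

    def test_strong_edge_pileup_advances_past_it(self, cfg):
        # 30 of 100 candidates within 50 nt of an edge where p0(50) = 0.1
        # (exact binomial tail ~2.4e-8): the threshold must move beyond 50.
        contigs = self.contigs(n=20, length=1000)  # p0(50) = 100/1000
        dists = [10] * 30 + [400] * 70
        report = compute_edge_threshold(self.records(dists), contigs, cfg)
        assert report.chosen_d > 50

    def test_p0_is_monotone_in_distance(self, cfg):
        report = compute_edge_threshold(self.records([5000] * 10), self.contigs(), cfg)
        p0s = [row[3] for row in report.grid]
        assert all(a <= b for a, b in zip(p0s, p0s[1:]))
        assert all(0.0 <= p <= 1.0 for p in p0s)


class TestDiscovery:
    def test_empty_transcript_list_gives_empty_catalog(self, bundle, session_cfg):
        catalog = discover_srnas(bundle.annotation, [], session_cfg)
        assert catalog.records == []
        assert all(step[1] == 0 and step[2] == 0 for step in catalog.provenance)

    def test_rerun_is_byte_identical(self, bundle, session_cfg):
        a = catalog_to_frame(discover_srnas(bundle.annotation, bundle.transcripts,
                                            session_cfg))
        b = catalog_to_frame(discover_srnas(bundle.annotation, bundle.transcripts,
                                            session_cfg))
        assert a.to_csv() == b.to_csv()

    def test_provenance_telescopes_and_matches_flags(self, bundle, session_cfg):
        catalog = discover_srnas(bundle.annotation, bundle.transcripts, session_cfg)
        for (_, _, n_out), (_, n_in, _) in zip(catalog.provenance,
                                               catalog.provenance[1:]):
            assert n_out == n_in
        assert catalog.provenance[-1][2] == len(catalog.surviving())
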