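"""Classification of assembled transcripts into intergenic/antisense sRNA
candidates and the geometric noncoding filters.

The classification rules operate on stranded gene intervals from the
metagenome annotation:

* *intergenic* — the transcript is at least ``min_gene_distance`` nt away from
  every gene on **both** strands;
* *antisense* — at least ``min_gene_distance`` nt from every gene on its own
  strand, but overlapping a gene on the opposite strand by at least
  ``min_antisense_overlap`` nt;
* *coding* — any same-strand gene overlap;
* *ambiguous* — everything else (retained, flagged, never silently dropped).

Small-peptide genes (< ``small_peptide_max`` nt) fully contained in a
transcript more than ``small_peptide_transcript_ratio`` times their length do
not count as genes for these rules.

Candidates then pass a length window (``min_len``–``max_len`` nt, bounds
inclusive), a six-frame reading-frame filter (no stop-free stretch longer than
``max_orf_fraction`` of the transcript), and a dynamic contig-edge correction:
the minimum allowed distance to a contig tip is raised until candidates are no
longer statistically enriched near tips (exact one-sided binomial test against
a uniform-placement null on a distance grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .annotation_io import (
    AnnotationError,
    Contig,
    GeneFeature,
    GenomeAnnotation,
    PipelineConfig,
    TranscriptFeature,
    extract_sequence,
)

__all__ = [
    "SRNARecord",
    "SRNACatalog",
    "EdgeReport",
    "effective_genes",
    "classify_transcript",
    "longest_orf_fraction",
    "apply_noncoding_filters",
    "compute_edge_threshold",
    "discover_srnas",
    "catalog_to_frame",
    "catalog_from_frame",
]

LABELS = ("intergenic", "antisense", "coding", "ambiguous")
STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))


@dataclass
class SRNARecord:
    """One classified transcript with its filter provenance."""

    transcript: TranscriptFeature
    label: str
    antisense_genes: List[Tuple[str, int]] = field(default_factory=list)
    nearest_gene_distance_same: float = float("inf")
    nearest_gene_distance_opposite: float = float("inf")
    edge_distance: int = 0
    orf_fraction: Optional[float] = None
    filter_flags: Set[str] = field(default_factory=set)
    conserved: bool = False
    rfam_family: Optional[str] = None
    taxonomy: Optional[object] = None

    @property
    def is_candidate(self) -> bool:
        return self.label in ("intergenic", "antisense")

    @property
    def passes(self) -> bool:
        return self.is_candidate and not self.filter_flags


@dataclass
class SRNACatalog:
    """Classified records plus the provenance log of every filtering stage."""

    records: List[SRNARecord]
    config: PipelineConfig
    edge_threshold: Optional[int] = None
    provenance: List[Tuple[str, int, int]] = field(default_factory=list)

    def add_step(self, step: str, n_in: int, n_out: int) -> None:
        if self.provenance and self.provenance[-1][2] != n_in:
            raise ValueError(
                f"provenance does not telescope: step {step!r} n_in={n_in} but "
                f"previous n_out={self.provenance[-1][2]}"
            )
        self.provenance.append((step, n_in, n_out))

    def surviving(self) -> List[SRNARecord]:
        """Candidates with no fail/homology/housekeeping flags."""
        return [r for r in self.records if r.passes]

    def regulatory_set(self) -> List[SRNARecord]:
        """Alias of :meth:`surviving`: the regulatory sRNA set (housekeeping
        Rfam members carry the ``rfam_housekeeping`` flag and are excluded
        here while remaining in the full ncRNA catalog)."""
        return self.surviving()

    def ncrna_catalog(self) -> List[SRNARecord]:
        """Candidates failing no geometric/coverage/protein filter; retains
        housekeeping Rfam ncRNAs (tRNA, RNase P, SRP)."""
        return [
            r for r in self.records
            if r.is_candidate and not (r.filter_flags - {"rfam_housekeeping"})
        ]

    def get(self, transcript_id: str) -> Optional[SRNARecord]:
        for r in self.records:
            if r.transcript.id == transcript_id:
                return r
        return None


@dataclass
class EdgeReport:
    """Grid scan of the contig-edge enrichment test."""

    grid: List[Tuple[int, int, int, float, float]]  # (d, n, k, p0, pvalue)
    chosen_d: int


def _interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in nt between two half-open intervals; 0 when they overlap or touch."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def effective_genes(transcript: TranscriptFeature, genes: Iterable[GeneFeature],
                    cfg: PipelineConfig) -> List[GeneFeature]:
    """Drop small-peptide genes that do not count for classification.

    A gene shorter than ``small_peptide_max`` nt that lies fully within the
    transcript is ignored when the transcript is more than
    ``small_peptide_transcript_ratio`` times the gene's length (strictly).
    """
    t_len = transcript.length
    kept = []
    for g in genes:
        inside = g.start >= transcript.start and g.end <= transcript.end
        small = g.length < cfg.small_peptide_max
        if small and inside and t_len > cfg.small_peptide_transcript_ratio * g.length:
            continue
        kept.append(g)
    return kept


def classify_transcript(transcript: TranscriptFeature, annotation: GenomeAnnotation,
                        cfg: PipelineConfig) -> SRNARecord:
    """Assign one of intergenic/antisense/coding/ambiguous to a transcript."""
    contig = annotation.contigs.get(transcript.contig_id)
    if contig is None:
        raise AnnotationError(
            f"transcript {transcript.id} on unknown contig {transcript.contig_id!r}"
        )
    genes = effective_genes(transcript, annotation.genes_on(transcript.contig_id), cfg)
    same = [g for g in genes if g.strand == transcript.strand]
    opposite = [g for g in genes if g.strand != transcript.strand]

    ts, te = transcript.start, transcript.end

    def dist(g: GeneFeature) -> int:
        return 0 if _overlap(ts, te, g.start, g.end) > 0 else _interval_distance(ts, te, g.start, g.end)

    nearest_same = min((dist(g) for g in same), default=float("inf"))
    nearest_opp = min((dist(g) for g in opposite), default=float("inf"))
    same_overlap = any(_overlap(ts, te, g.start, g.end) > 0 for g in same)
    as_genes = sorted(
        ((g.id, _overlap(ts, te, g.start, g.end)) for g in opposite
         if _overlap(ts, te, g.start, g.end) > 0),
        key=lambda item: (-item[1], item[0]),
    )
    max_opp_overlap = as_genes[0][1] if as_genes else 0

    if same_overlap:
        label = "coding"
    elif nearest_same >= cfg.min_gene_distance and nearest_opp >= cfg.min_gene_distance:
        label = "intergenic"
    elif nearest_same >= cfg.min_gene_distance and max_opp_overlap >= cfg.min_antisense_overlap:
        label = "antisense"
    else:
        label = "ambiguous"

    edge_distance = min(ts, contig.length - te)
    return SRNARecord(
        transcript=transcript,
        label=label,
        antisense_genes=as_genes,
        nearest_gene_distance_same=nearest_same,
        nearest_gene_distance_opposite=nearest_opp,
        edge_distance=edge_distance,
    )


def longest_orf_fraction(seq: str, mode: str = "stop_free") -> float:
    """Fraction of the sequence covered by its longest reading frame.

    A reading frame is the longest stop-codon-free codon stretch, scanned over
    all six frames (both strands); stops are TAA/TAG/TGA and ``N`` never forms
    a stop. ``mode="atg"`` instead measures the longest ATG-initiated,
    stop-free stretch.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 3:
        return 0.0
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp.get(b, "N") for b in reversed(seq))
    best = 0
    for strand_seq in (seq, rc):
        for frame in range(3):
            run = 0
            started = mode != "atg"
            for i in range(frame, n - 2, 3):
                codon = strand_seq[i:i + 3]
                if codon in STOP_CODONS:
                    run = 0
                    started = mode != "atg"
                else:
                    if mode == "atg" and not started and codon == "ATG":
                        started = True
                    if started:
                        run += 1
                        best = max(best, run)
    return best * 3 / n


def apply_noncoding_filters(records: List[SRNARecord], annotation: GenomeAnnotation,
                            cfg: PipelineConfig, orf_mode: str = "stop_free") -> List[SRNARecord]:
    """Set ``length_fail``/``orf_fail`` flags on intergenic/antisense records.

    The length window is inclusive at both bounds; the reading-frame filter
    fails a record whose longest frame exceeds ``max_orf_fraction`` (strictly)
    of its length. Flagged records stay in the catalog.
    """
    for rec in records:
        if not rec.is_candidate:
            continue
        t = rec.transcript
        if t.length < cfg.min_len or t.length > cfg.max_len:
            rec.filter_flags.add("length_fail")
        contig = annotation.contigs.get(t.contig_id)
        if contig is None or contig.sequence is None:
            raise AnnotationError(
                f"contig {t.contig_id} has no sequence; cannot run reading-frame filter"
            )
        seq = extract_sequence(annotation, t.contig_id, t.start, t.end, "+")
        rec.orf_fraction = longest_orf_fraction(seq, mode=orf_mode)
        if rec.orf_fraction > cfg.max_orf_fraction:
            rec.filter_flags.add("orf_fail")
    return records


def compute_edge_threshold(records: Sequence[SRNARecord], contigs: Mapping[str, Contig],
                           cfg: PipelineConfig, alternative: str = "greater") -> EdgeReport:
    """Dynamically choose the minimum allowed distance to a contig edge.

    For each distance ``d`` on the grid {0, step, …, edge_grid_max}, the
    uniform-placement probability of a candidate falling within ``d`` of a tip
    is ``p0(d) = Σ_c min(2d, L_c) / Σ_c L_c``; the observed count of candidates
    with ``edge_distance < d`` is tested against Binomial(n, p0) with an exact
    one-sided test. Because the grid scan asks one family-level question — is
    any edge zone enriched? — each grid point is compared against a
    Bonferroni-corrected level ``edge_alpha / m`` (m = number of nonzero grid
    points), keeping the family-wise false-alarm rate of the whole scan at
    ``edge_alpha``. The chosen threshold is the smallest grid ``d`` such that
    no distance ≥ d is significantly enriched; if the grid maximum itself is
    still enriched, the threshold is clamped there.

    ``alternative="two-sided"`` switches to a two-sided test.
    """
    n = len(records)
    grid_ds = list(range(0, cfg.edge_grid_max + 1, cfg.edge_grid_step))
    if n == 0:
        return EdgeReport(grid=[], chosen_d=0)
    lengths = np.array([c.length for c in contigs.values()], dtype=float)
    total = lengths.sum()
    edge_distances = np.array([r.edge_distance for r in records])
    m_tests = max(1, sum(1 for d in grid_ds if d > 0))
    level = cfg.edge_alpha / m_tests
    grid: List[Tuple[int, int, int, float, float]] = []
    significant: List[bool] = []
    for d in grid_ds:
        p0 = float(np.minimum(2.0 * d, lengths).sum() / total)
        k = int((edge_distances < d).sum())
        if d == 0:
            pval = 1.0  # k = 0 by definition; no test
        else:
            pval = float(binomtest(k, n, min(p0, 1.0), alternative=alternative).pvalue)
        grid.append((d, n, k, p0, pval))
        significant.append(pval < level)
    if any(significant):
        last = max(i for i, s in enumerate(significant) if s)
        chosen = grid_ds[last + 1] if last + 1 < len(grid_ds) else grid_ds[-1]
    else:
        chosen = 0
    return EdgeReport(grid=grid, chosen_d=chosen)


def discover_srnas(annotation: GenomeAnnotation, transcripts: Sequence[TranscriptFeature],
                   cfg: PipelineConfig, orf_mode: str = "stop_free",
                   edge_alternative: str = "greater") -> SRNACatalog:
    """Run classification, edge correction and the length/ORF filters.

    Returns a catalog holding *every* transcript (coding and ambiguous ones
    flagged by label, never dropped) with a telescoping provenance log. The
    output is deterministic for identical inputs.
    """
    catalog = SRNACatalog(records=[], config=cfg)
    records = [classify_transcript(t, annotation, cfg) for t in transcripts]
    catalog.records = records
    candidates = [r for r in records if r.is_candidate]
    catalog.add_step("classify", len(records), len(candidates))

    report = compute_edge_threshold(candidates, annotation.contigs, cfg,
                                    alternative=edge_alternative)
    catalog.edge_threshold = report.chosen_d
    catalog.edge_report = report  # kept for auditability
    for rec in candidates:
        if rec.edge_distance < report.chosen_d:
            rec.filter_flags.add("edge_fail")
    after_edge = [r for r in candidates if "edge_fail" not in r.filter_flags]
    catalog.add_step("edge_filter", len(candidates), len(after_edge))

    apply_noncoding_filters(records, annotation, cfg, orf_mode=orf_mode)
    after_len = [r for r in after_edge if "length_fail" not in r.filter_flags]
    catalog.add_step("length_filter", len(after_edge), len(after_len))
    after_orf = [r for r in after_len if "orf_fail" not in r.filter_flags]
    catalog.add_step("orf_filter", len(after_len), len(after_orf))
    return catalog


_FRAME_COLUMNS = [
    "transcript_id", "contig_id", "start", "end", "strand", "coverage", "tpm",
    "label", "filter_flags", "antisense_genes", "nearest_same", "nearest_opposite",
    "edge_distance", "orf_fraction", "conserved", "rfam_family", "taxonomy",
]


def catalog_to_frame(catalog: SRNACatalog) -> pd.DataFrame:
    """Tabular view of the catalog (the flags TSV written by the CLI)."""
    rows = []
    for rec in sorted(catalog.records,
                      key=lambda r: (r.transcript.contig_id, r.transcript.start,
                                     r.transcript.id)):
        t = rec.transcript
        rows.append({
            "transcript_id": t.id, "contig_id": t.contig_id,
            "start": t.start, "end": t.end, "strand": t.strand,
            "coverage": t.coverage, "tpm": t.tpm, "label": rec.label,
            "filter_flags": ",".join(sorted(rec.filter_flags)),
            "antisense_genes": ";".join(f"{g}:{ov}" for g, ov in rec.antisense_genes),
            "nearest_same": rec.nearest_gene_distance_same,
            "nearest_opposite": rec.nearest_gene_distance_opposite,
            "edge_distance": rec.edge_distance,
            "orf_fraction": rec.orf_fraction,
            "conserved": rec.conserved,
            "rfam_family": rec.rfam_family or "",
            "taxonomy": str(rec.taxonomy) if rec.taxonomy is not None else "",
        })
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def catalog_from_frame(frame: pd.DataFrame, cfg: PipelineConfig) -> SRNACatalog:
    """Rebuild a catalog from the flags table (CLI stage hand-off)."""
    records = []
    for row in frame.itertuples(index=False):
        t = TranscriptFeature(
            id=row.transcript_id, contig_id=row.contig_id,
            start=int(row.start), end=int(row.end), strand=row.strand,
            coverage=None if pd.isna(row.coverage) else float(row.coverage),
            tpm=None if pd.isna(row.tpm) else float(row.tpm),
        )
        flags = set(str(row.filter_flags).split(",")) if isinstance(row.filter_flags, str) and row.filter_flags else set()
        as_genes = []
        if isinstance(row.antisense_genes, str) and row.antisense_genes:
            for part in row.antisense_genes.split(";"):
                gid, ov = part.rsplit(":", 1)
                as_genes.append((gid, int(ov)))
        records.append(SRNARecord(
            transcript=t, label=row.label, antisense_genes=as_genes,
            nearest_gene_distance_same=float(row.nearest_same),
            nearest_gene_distance_opposite=float(row.nearest_opposite),
            edge_distance=int(row.edge_distance),
            orf_fraction=None if pd.isna(row.orf_fraction) else float(row.orf_fraction),
            filter_flags=flags,
            conserved=bool(row.conserved),
            rfam_family=row.rfam_family or None if isinstance(row.rfam_family, str) else None,
        ))
    return SRNACatalog(records=records, config=cfg)
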