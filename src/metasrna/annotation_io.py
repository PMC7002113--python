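"""Readers/writers for the standard genomics formats and the shared coordinate model.

All intervals are stored internally as 0-based half-open ``[start, end)``.
GFF3 and GTF files on disk use the conventional 1-based inclusive coordinates;
the conversion happens exactly once, in this module. Strands are ``"+"``/``"-"``.

The :class:`PipelineConfig` object collects every numeric threshold used by the
downstream classification, filtering and statistics stages, with the defaults
of the community sRNA discovery protocol this package implements (50–500 nt
size window, 30 nt gene distance, 10 nt antisense overlap, 5×/10× coverage,
the protein-homology and conservation cutoffs, FDR 5%, etc.).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

__all__ = [
    "PipelineConfig",
    "Contig",
    "GeneFeature",
    "TranscriptFeature",
    "GenomeAnnotation",
    "HitRecord",
    "AnnotationError",
    "read_annotation",
    "read_transcripts",
    "read_blast_table",
    "write_srna_gff",
    "extract_sequence",
    "BLAST6_COLUMNS",
]


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass
class PipelineConfig:
    """Thresholds and tunables shared by every pipeline stage.

    Distances and lengths are in nucleotides; coverage thresholds are in ×
    assembly coverage; identity/coverage cutoffs for homology searches are in
    percent.
    """

    min_gene_distance: int = 30
    min_antisense_overlap: int = 10
    small_peptide_max: int = 100
    small_peptide_transcript_ratio: float = 3.0
    max_orf_fraction: float = 1.0 / 3.0
    min_len: int = 50
    max_len: int = 500
    cov_threshold_intergenic: float = 5.0
    cov_threshold_antisense: float = 10.0
    prot_min_qcov: float = 30.0
    prot_min_bitscore: float = 50.0
    prot_max_evalue: float = 1e-4
    prot_min_identity: float = 30.0
    cons_max_evalue: float = 1e-3
    cons_min_identity: float = 70.0
    cons_min_qcov: float = 50.0
    de_fdr: float = 0.05
    corr_alpha: float = 0.01
    upstream_len: int = 50
    top_n_interactions: int = 100
    edge_alpha: float = 0.05
    edge_grid_step: int = 10
    edge_grid_max: int = 500
    count_scale: float = 1e6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise AnnotationError(
                f"min_len ({self.min_len}) must not exceed max_len ({self.max_len})"
            )
        if not (0.0 < self.max_orf_fraction < 1.0):
            raise AnnotationError("max_orf_fraction must lie strictly in (0, 1)")
        positive = [
            "min_gene_distance", "min_antisense_overlap", "small_peptide_max",
            "small_peptide_transcript_ratio", "min_len", "max_len",
            "cov_threshold_intergenic", "cov_threshold_antisense",
            "prot_min_qcov", "prot_min_bitscore", "prot_max_evalue",
            "prot_min_identity", "cons_max_evalue", "cons_min_identity",
            "cons_min_qcov", "de_fdr", "corr_alpha", "upstream_len",
            "top_n_interactions", "edge_alpha", "edge_grid_step",
            "edge_grid_max", "count_scale",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise AnnotationError(f"{name} must be > 0")

    def to_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class Contig:
    id: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise AnnotationError(f"contig {self.id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AnnotationError(
                f"contig {self.id}: sequence length {len(self.sequence)} != declared {self.length}"
            )


@dataclass
class GeneFeature:
    id: str
    contig_id: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    product: str = ""
    taxonomy: Optional[object] = None
    ftype: str = "CDS"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(f"gene {self.id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptFeature:
    id: str
    contig_id: str
    start: int
    end: int
    strand: str
    coverage: Optional[float] = None  # None = absent in the source GTF
    tpm: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"transcript {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"transcript {self.id}: strand must be '+' or '-'")
        if self.coverage is not None and self.coverage < 0:
            raise AnnotationError(f"transcript {self.id}: coverage must be >= 0")
        if self.tpm is not None and self.tpm < 0:
            raise AnnotationError(f"transcript {self.id}: TPM must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeAnnotation:
    """Contigs plus a per-contig, per-strand interval index of gene features."""

    def __init__(self, contigs: Mapping[str, Contig], genes: Iterable[GeneFeature]):
        self.contigs: Dict[str, Contig] = dict(contigs)
        self.genes: List[GeneFeature] = []
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        self._by_contig: Dict[str, List[GeneFeature]] = {}
        for gene in genes:
            self.add_gene(gene)

    def add_gene(self, gene: GeneFeature) -> None:
        contig = self.contigs.get(gene.contig_id)
        if contig is None:
            raise AnnotationError(f"gene {gene.id} references unknown contig {gene.contig_id!r}")
        if gene.end > contig.length:
            raise AnnotationError(
                f"gene {gene.id} end {gene.end} exceeds contig {contig.id} length {contig.length}"
            )
        self.genes.append(gene)
        key = (gene.contig_id, gene.strand)
        self._trees.setdefault(key, IntervalTree())[gene.start:gene.end] = gene
        self._by_contig.setdefault(gene.contig_id, []).append(gene)

    def genes_on(self, contig_id: str, strand: Optional[str] = None) -> List[GeneFeature]:
        """All genes on a contig (optionally one strand), in (start, id) order."""
        if strand is None:
            out = list(self._by_contig.get(contig_id, []))
        else:
            out = [iv.data for iv in self._trees.get((contig_id, strand), IntervalTree())]
        return sorted(out, key=lambda g: (g.start, g.id))

    def overlapping(self, contig_id: str, start: int, end: int,
                    strand: Optional[str] = None) -> List[GeneFeature]:
        """Genes overlapping [start, end) by >= 1 nt, in (start, id) order."""
        hits: List[GeneFeature] = []
        strands = ("+", "-") if strand is None else (strand,)
        for s in strands:
            tree = self._trees.get((contig_id, s))
            if tree is not None:
                hits.extend(iv.data for iv in tree.overlap(start, end))
        return sorted(hits, key=lambda g: (g.start, g.id))

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class HitRecord:
    """One row of a 12-column BLAST tabular (outfmt 6) search result."""

    query_id: str
    subject_id: str
    identity: float
    align_len: int
    qstart: int
    qend: int
    evalue: float
    bitscore: float
    query_cover: float  # percent of the query spanned by the aligned region

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise AnnotationError(f"hit {self.query_id}->{self.subject_id}: identity out of [0, 100]")
        if self.evalue < 0:
            raise AnnotationError(f"hit {self.query_id}->{self.subject_id}: negative E-value")


def _parse_feature_line(line: str, lineno: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise AnnotationError(f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}")
    try:
        start = int(fields[3])
        end = int(fields[4])
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: non-integer coordinate: {exc}") from exc
    if end < start:
        raise AnnotationError(f"line {lineno}: end ({end}) < start ({start})")
    feat = feature_from_line(line)
    return feat, start, end


def read_annotation(gff_path, fasta_path) -> GenomeAnnotation:
    """Load a metagenome assembly (FASTA) and its gene annotation (GFF3).

    All feature rows are loaded as stranded gene intervals; 1-based inclusive
    coordinates are converted to the internal 0-based half-open convention.
    Contig lengths (and sequences) come from the FASTA.
    """
    contigs: Dict[str, Contig] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        contigs[rec.id] = Contig(id=rec.id, length=len(seq), sequence=seq)
    annotation = GenomeAnnotation(contigs, [])
    anon = 0
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            feat, start, end = _parse_feature_line(line, lineno)
            if feat.seqid not in contigs:
                raise AnnotationError(
                    f"line {lineno}: GFF seqid {feat.seqid!r} not present in FASTA"
                )
            attrs = {k.lower(): v for k, v in feat.attributes.items()}
            gid = (attrs.get("id") or attrs.get("gene_id") or [None])[0]
            if gid is None:
                anon += 1
                gid = f"{feat.seqid}:{start}-{end}:{lineno}"
            product = (attrs.get("product") or attrs.get("name") or [""])[0]
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            annotation.add_gene(GeneFeature(
                id=gid, contig_id=feat.seqid, start=start - 1, end=end,
                strand=strand, product=product, ftype=feat.featuretype or "CDS",
            ))
    return annotation


def read_transcripts(gtf_path) -> List[TranscriptFeature]:
    """Read assembled transcripts from a StringTie-dialect GTF.

    Only ``transcript`` rows are used (single-exon prokaryotic model; exon rows
    are ignored). The per-transcript assembly coverage and TPM are taken from
    the ``cov``/``coverage`` and ``TPM`` attributes, matched case-insensitively.
    A transcript missing either attribute is kept with the value marked absent
    and a warning; the coverage thresholding stage later rejects it.
    """
    transcripts: List[TranscriptFeature] = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            feat, start, end = _parse_feature_line(line, lineno)
            if (feat.featuretype or "").lower() != "transcript":
                continue
            attrs = {k.lower(): v for k, v in feat.attributes.items()}
            tid = (attrs.get("transcript_id") or attrs.get("id") or [None])[0]
            if tid is None:
                tid = f"{feat.seqid}:{start}-{end}:{lineno}"
            cov_raw = attrs.get("cov") or attrs.get("coverage")
            tpm_raw = attrs.get("tpm")
            coverage = float(cov_raw[0]) if cov_raw else None
            tpm = float(tpm_raw[0]) if tpm_raw else None
            if coverage is None:
                warnings.warn(f"transcript {tid} (line {lineno}): no cov/coverage attribute")
            if tpm is None:
                warnings.warn(f"transcript {tid} (line {lineno}): no TPM attribute")
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            transcripts.append(TranscriptFeature(
                id=tid, contig_id=feat.seqid, start=start - 1, end=end,
                strand=strand, coverage=coverage, tpm=tpm,
            ))
    return transcripts


BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def read_blast_table(path, query_lengths: Mapping[str, int]) -> List[HitRecord]:
    """Parse standard 12-column BLAST tabular output (``-outfmt 6``).

    Query coverage is always recomputed from the aligned query span
    (``|qend - qstart| + 1``, orientation-independent) over the query length,
    so every BLAST dialect behaves identically.
    """
    hits: List[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise AnnotationError(f"line {lineno}: expected 12 columns, got {len(fields)}")
            try:
                pident = float(fields[2])
                align_len = int(fields[3])
                qstart = int(fields[6])
                qend = int(fields[7])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: non-numeric field: {exc}") from exc
            qid = fields[0]
            qlen = query_lengths.get(qid)
            if qlen is None:
                warnings.warn(f"line {lineno}: unknown query id {qid!r}; hit skipped")
                continue
            qcov = (abs(qend - qstart) + 1) / qlen * 100.0
            hits.append(HitRecord(
                query_id=qid, subject_id=fields[1], identity=pident,
                align_len=align_len, qstart=qstart, qend=qend,
                evalue=evalue, bitscore=bitscore, query_cover=qcov,
            ))
    return hits


def write_srna_gff(catalog, path) -> None:
    """Serialize a classified sRNA catalog to GFF3 (type ``ncRNA``).

    Output is sorted by (contig, start, id) and carries the class label,
    filter flags and linked antisense genes in column 9; it round-trips
    through :func:`read_annotation`.
    """
    records = sorted(
        catalog.records,
        key=lambda r: (r.transcript.contig_id, r.transcript.start, r.transcript.id),
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            t = rec.transcript
            attrs = [f"ID={t.id}", f"class={rec.label}"]
            if rec.filter_flags:
                attrs.append("filter_flags=" + ",".join(sorted(rec.filter_flags)))
            if rec.antisense_genes:
                attrs.append("genes=" + ",".join(g for g, _ in rec.antisense_genes))
            if rec.rfam_family:
                attrs.append("rfam_family=" + rec.rfam_family.replace(";", "%3B"))
            if rec.conserved:
                attrs.append("conserved=true")
            fh.write("\t".join([
                t.contig_id, "metasrna", "ncRNA",
                str(t.start + 1), str(t.end), ".", t.strand, ".",
                ";".join(attrs),
            ]) + "\n")


def extract_sequence(annotation: GenomeAnnotation, contig_id: str,
                     start: int, end: int, strand: str) -> str:
    """Return the sequence of ``[start, end)``; minus strand gives the
    reverse complement."""
    contig = annotation.contigs.get(contig_id)
    if contig is None:
        raise AnnotationError(f"unknown contig {contig_id!r}")
    if contig.sequence is None:
        raise AnnotationError(f"contig {contig_id} has no sequence loaded")
    if not (0 <= start < end <= contig.length):
        raise AnnotationError(
            f"interval [{start}, {end}) out of range for contig {contig_id} "
            f"(length {contig.length})"
        )
    seq = contig.sequence[start:end]
    if strand == "-":
        return reverse_complement(seq)
    return seq
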