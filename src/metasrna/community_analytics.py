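"""Community-level analytics for a classified sRNA catalog.

* Taxonomy: a contig's lineage is the rank-wise weighted majority vote of the
  lineages of the genes it carries (gene length as default weight); an sRNA
  inherits the lineage of its contig.
* Overlap geometry: where an antisense sRNA sits along its target mRNA,
  expressed on the mRNA's 5'→3' axis as relative coordinates in [0, 1].
* Expression correlation: Pearson r (with t-distribution p, n−2 df) between an
  asRNA and its putative target across replicate samples.
* Upstream regions: the 50 nt upstream of each sRNA start, for external motif
  searches (emitted as FASTA).
* Interaction density: per-position counts of the top-N predicted sRNA–mRNA
  interactions along the sRNA, with the peak position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GeneFeature, GenomeAnnotation, PipelineConfig, extract_sequence
from .srna_discovery import SRNACatalog, SRNARecord, _overlap

__all__ = [
    "RANKS",
    "Lineage",
    "OverlapProfile",
    "PairCorrelation",
    "InteractionRecord",
    "InteractionDensity",
    "UpstreamRegion",
    "parse_lineage",
    "contig_taxonomy",
    "assign_srna_taxonomy",
    "overlap_profile",
    "pair_correlations",
    "extract_upstream",
    "interaction_density",
    "read_taxonomy_table",
    "read_interaction_table",
    "write_upstream_fasta",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class Lineage:
    """Ranked lineage domain→species; a rank may be absent (None).

    ``support[i]`` is the weight fraction of genes backing ``names[i]``;
    ``tie`` marks a lineage whose winning name was a tie broken
    lexicographically."""

    names: Tuple[Optional[str], ...] = (None,) * len(RANKS)
    support: Tuple[float, ...] = (0.0,) * len(RANKS)
    tie: bool = False

    def __str__(self) -> str:
        present = [n for n in self.names if n is not None]
        return ";".join(present)

    @property
    def deepest(self) -> Optional[str]:
        present = [n for n in self.names if n is not None]
        return present[-1] if present else None

    def name_at(self, rank: str) -> Optional[str]:
        return self.names[RANKS.index(rank)]


def parse_lineage(text: str) -> Lineage:
    """Build a Lineage from a semicolon-ranked string (domain first)."""
    parts = [p.strip() for p in text.split(";") if p.strip()]
    names = tuple(parts[i] if i < len(parts) else None for i in range(len(RANKS)))
    support = tuple(1.0 if n is not None else 0.0 for n in names)
    return Lineage(names=names, support=support)


def contig_taxonomy(genes: Sequence[Tuple[Lineage, float]]) -> Lineage:
    """Weighted rank-wise majority vote over the genes of a contig.

    Descends from domain while the winning name holds ≥ 0.5 of the total gene
    weight; deeper ranks are left absent once support drops below a majority.
    A 50/50 tie keeps the lexicographically first name and sets ``tie``."""
    if not genes:
        return Lineage()
    for _, w in genes:
        if w <= 0:
            raise ValueError("gene weights must be > 0")
    total = sum(w for _, w in genes)
    names: List[Optional[str]] = []
    supports: List[float] = []
    tie = False
    for depth in range(len(RANKS)):
        votes: Dict[str, float] = {}
        for lineage, w in genes:
            name = lineage.names[depth]
            if name is not None:
                votes[name] = votes.get(name, 0.0) + w
        if not votes:
            break
        best_w = max(votes.values())
        winners = sorted(n for n, w in votes.items() if w == best_w)
        winner = winners[0]
        support = best_w / total
        if support < 0.5:
            break
        if len(winners) > 1:
            tie = True
        names.append(winner)
        supports.append(support)
    pad = len(RANKS) - len(names)
    return Lineage(
        names=tuple(names) + (None,) * pad,
        support=tuple(supports) + (0.0,) * pad,
        tie=tie,
    )


def assign_srna_taxonomy(catalog: SRNACatalog,
                         contig_taxa: Mapping[str, Lineage]) -> SRNACatalog:
    """Copy each record's contig lineage onto the record."""
    for rec in catalog.records:
        lineage = contig_taxa.get(rec.transcript.contig_id)
        if lineage is None:
            warnings.warn(
                f"contig {rec.transcript.contig_id} has no taxonomy; "
                f"record {rec.transcript.id} left unassigned"
            )
            rec.taxonomy = None
        else:
            rec.taxonomy = lineage
    return catalog


@dataclass
class OverlapProfile:
    asrna_id: str
    gene_id: str
    rel_start: float  # on the mRNA 5'->3' axis
    rel_end: float
    overlap_nt: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.rel_start < self.rel_end <= 1.0):
            raise ValueError(
                f"relative overlap [{self.rel_start}, {self.rel_end}] out of [0, 1]"
            )


def overlap_profile(asrna: SRNARecord, gene: GeneFeature) -> OverlapProfile:
    """Project the asRNA–gene overlap onto the mRNA's 5'→3' axis.

    For a minus-strand gene, position 0 of the axis is the gene's right edge."""
    t = asrna.transcript
    ov_start = max(t.start, gene.start)
    ov_end = min(t.end, gene.end)
    if ov_end <= ov_start:
        raise ValueError(f"asRNA {t.id} does not overlap gene {gene.id}")
    length = gene.length
    if gene.strand == "+":
        rel_start = (ov_start - gene.start) / length
        rel_end = (ov_end - gene.start) / length
    else:
        rel_start = (gene.end - ov_end) / length
        rel_end = (gene.end - ov_start) / length
    return OverlapProfile(
        asrna_id=t.id, gene_id=gene.id,
        rel_start=rel_start, rel_end=rel_end, overlap_nt=ov_end - ov_start,
    )


@dataclass
class PairCorrelation:
    asrna_id: str
    target_id: str
    pearson_r: float
    pvalue: float
    significant: bool


def pair_correlations(asrna_expr, target_expr,
                      pairs: Sequence[Tuple[str, str]],
                      cfg: PipelineConfig) -> List[PairCorrelation]:
    """Pearson correlation of asRNA vs target expression across replicates.

    Uses the samples shared by both matrices (≥ 3 required); two-sided p from
    the t distribution with n−2 df; significant iff p < ``corr_alpha``.
    Zero-variance vectors give NaN r/p and are never significant."""
    shared = [s for s in asrna_expr.sample_ids if s in set(target_expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, have {len(shared)}")
    out = []
    for asrna_id, target_id in pairs:
        x = asrna_expr.values.loc[asrna_id, shared].to_numpy(dtype=float)
        y = target_expr.values.loc[target_id, shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out.append(PairCorrelation(asrna_id, target_id, float("nan"),
                                       float("nan"), False))
            continue
        r, p = stats.pearsonr(x, y)
        out.append(PairCorrelation(asrna_id, target_id, float(r), float(p),
                                   bool(p < cfg.corr_alpha)))
    return out


@dataclass
class UpstreamRegion:
    srna_id: str
    sequence: str
    truncated: bool


def extract_upstream(record: SRNARecord, annotation: GenomeAnnotation,
                     cfg: PipelineConfig) -> UpstreamRegion:
    """The ``upstream_len`` nt upstream of the sRNA's transcription start.

    Plus strand: the window ending at start−1; minus strand: reverse
    complement of the window beginning at end+1. Truncated (and flagged) at
    contig edges; zero available upstream gives an empty sequence."""
    t = record.transcript
    contig = annotation.contigs[t.contig_id]
    n = cfg.upstream_len
    if t.strand == "+":
        lo, hi = max(0, t.start - n), t.start
    else:
        lo, hi = t.end, min(contig.length, t.end + n)
    if hi <= lo:
        return UpstreamRegion(t.id, "", True)
    seq = extract_sequence(annotation, t.contig_id, lo, hi, t.strand)
    return UpstreamRegion(t.id, seq, truncated=(hi - lo) < n)


def write_upstream_fasta(catalog: SRNACatalog, annotation: GenomeAnnotation,
                         cfg: PipelineConfig, path) -> None:
    """FASTA of upstream regions of surviving sRNAs, for motif tools."""
    with open(path, "w") as fh:
        for rec in sorted(catalog.surviving(),
                          key=lambda r: (r.transcript.contig_id, r.transcript.start,
                                         r.transcript.id)):
            region = extract_upstream(rec, annotation, cfg)
            if not region.sequence:
                continue
            suffix = " truncated" if region.truncated else ""
            fh.write(f">{region.srna_id}_upstream{suffix}\n{region.sequence}\n")


@dataclass
class InteractionRecord:
    """One predicted sRNA–mRNA hybridization (1-based inclusive sRNA span)."""

    srna_id: str
    target_id: str
    srna_start: int
    srna_end: int
    energy: float  # kcal/mol
    pvalue: float


@dataclass
class InteractionDensity:
    counts: np.ndarray  # length = sRNA length, index 0 = position 1
    peak: Optional[int]  # 1-based position of highest density (None if empty)
    n_used: int


def interaction_density(records: Sequence[InteractionRecord], srna_length: int,
                        cfg: PipelineConfig, rank_by: str = "pvalue") -> InteractionDensity:
    """Per-position interaction counts from the top-N predicted targets.

    Records are ranked by ascending p-value (ties by ascending hybridization
    energy, then target id); ``rank_by="energy"`` swaps the first two keys.
    Only the top ``top_n_interactions`` records contribute. The peak is the
    smallest position attaining the maximum count."""
    for rec in records:
        if not (1 <= rec.srna_start <= rec.srna_end <= srna_length):
            raise ValueError(
                f"interaction span [{rec.srna_start}, {rec.srna_end}] outside "
                f"[1, {srna_length}] for target {rec.target_id}"
            )
    if rank_by == "pvalue":
        key = lambda r: (r.pvalue, r.energy, r.target_id)
    elif rank_by == "energy":
        key = lambda r: (r.energy, r.pvalue, r.target_id)
    else:
        raise ValueError("rank_by must be 'pvalue' or 'energy'")
    kept = sorted(records, key=key)[: cfg.top_n_interactions]
    counts = np.zeros(srna_length, dtype=int)
    for rec in kept:
        counts[rec.srna_start - 1: rec.srna_end] += 1
    peak = int(np.argmax(counts)) + 1 if kept else None
    return InteractionDensity(counts=counts, peak=peak, n_used=len(kept))


def read_taxonomy_table(path, default_weight: float = 1.0) -> Dict[str, List[Tuple[Lineage, float]]]:
    """Read a per-gene taxonomy TSV (gene_id, contig_id, lineage[, weight])
    into per-contig (lineage, weight) lists."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "contig_id", "lineage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    per_contig: Dict[str, List[Tuple[Lineage, float]]] = {}
    for row in df.itertuples(index=False):
        w = float(getattr(row, "weight", default_weight))
        per_contig.setdefault(str(row.contig_id), []).append(
            (parse_lineage(str(row.lineage)), w)
        )
    return per_contig


def read_interaction_table(path) -> List[InteractionRecord]:
    """Read a minimal hybridization-prediction TSV: srna_id, target_id,
    srna_start, srna_end, energy, pvalue."""
    df = pd.read_csv(path, sep="\t")
    required = {"srna_id", "target_id", "srna_start", "srna_end", "energy", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    return [InteractionRecord(
        srna_id=str(r.srna_id), target_id=str(r.target_id),
        srna_start=int(r.srna_start), srna_end=int(r.srna_end),
        energy=float(r.energy), pvalue=float(r.pvalue),
    ) for r in df.itertuples(index=False)]
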