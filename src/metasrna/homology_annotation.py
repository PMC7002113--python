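"""Homology-based exclusion and annotation of sRNA candidates.

Three independent annotations from pre-computed search tables:

* protein homology against a protein database (BLAST outfmt 6) — a candidate
  with a single hit satisfying *all four* printed cutoffs simultaneously
  (query cover > 30%, bitscore > 50, E < 1e-4, identity > 30%; strict
  inequalities) is flagged as protein-coding and excluded;
* Rfam covariance-model hits — housekeeping families (tRNA, RNase P, SRP) are
  flagged and excluded from the regulatory sRNA set while remaining in the
  ncRNA catalog with their family annotation;
* nucleotide conservation (blastn against a nucleotide database) — a candidate
  is marked conserved when some hit has E ≤ 1e-3, identity ≥ 70% and query
  coverage ≥ 50% (inclusive bounds).

No search is ever executed here; only tabular outputs are parsed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd

from .annotation_io import HitRecord, PipelineConfig
from .srna_discovery import SRNACatalog

__all__ = [
    "RfamHit",
    "DEFAULT_HOUSEKEEPING_TOKENS",
    "is_housekeeping_family",
    "read_rfam_table",
    "filter_protein_homology",
    "flag_rfam",
    "flag_conserved",
]


@dataclass
class RfamHit:
    query_id: str
    family_accession: str
    family_name: str
    clan: Optional[str]
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"Rfam hit {self.query_id}: negative E-value")


# Normalized substrings identifying the housekeeping ncRNA families excluded
# from the regulatory set: tRNAs, RNase P and the signal recognition particle.
DEFAULT_HOUSEKEEPING_TOKENS = frozenset(
    {"trna", "rnase p", "rnase_p", "rnasep", "srp", "signal recognition particle"}
)


def is_housekeeping_family(name: str,
                           tokens: Iterable[str] = DEFAULT_HOUSEKEEPING_TOKENS) -> bool:
    norm = name.strip().lower().replace("-", " ").replace("_", " ")
    padded = f" {norm} "
    for token in tokens:
        t = token.replace("_", " ")
        if t in ("srp",):  # short token: match as a word, not a substring
            if f" {t} " in padded or norm.startswith(t + " ") or norm == t or norm.endswith(" " + t):
                return True
        elif t in norm:
            return True
    return False


def read_rfam_table(path) -> List[RfamHit]:
    """Read a minimal cmscan-like TSV.

    Required columns: ``query_id``, ``family_accession``, ``family_name``,
    ``evalue``, ``score``; optional ``clan``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"query_id", "family_accession", "family_name", "evalue", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Rfam table missing columns: {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        clan = getattr(row, "clan", None)
        hits.append(RfamHit(
            query_id=str(row.query_id),
            family_accession=str(row.family_accession),
            family_name=str(row.family_name),
            clan=None if clan is None or pd.isna(clan) else str(clan),
            evalue=float(row.evalue), score=float(row.score),
        ))
    return hits


def _hits_by_query(catalog: SRNACatalog, hits: Sequence) -> Dict[str, list]:
    known = {r.transcript.id for r in catalog.records}
    grouped: Dict[str, list] = {}
    for hit in hits:
        if hit.query_id not in known:
            warnings.warn(f"hit references unknown transcript {hit.query_id!r}; ignored")
            continue
        grouped.setdefault(hit.query_id, []).append(hit)
    return grouped


def filter_protein_homology(catalog: SRNACatalog, hits: Sequence[HitRecord],
                            cfg: PipelineConfig) -> SRNACatalog:
    """Flag candidates with significant protein homology (``protein_homology``).

    A record is flagged iff some single hit simultaneously has query cover >
    ``prot_min_qcov``, bitscore > ``prot_min_bitscore``, E-value <
    ``prot_max_evalue`` and identity > ``prot_min_identity`` (all strict)."""
    grouped = _hits_by_query(catalog, hits)
    n_in = len(catalog.surviving())
    for rec in catalog.records:
        for hit in grouped.get(rec.transcript.id, []):
            if (hit.query_cover > cfg.prot_min_qcov
                    and hit.bitscore > cfg.prot_min_bitscore
                    and hit.evalue < cfg.prot_max_evalue
                    and hit.identity > cfg.prot_min_identity):
                rec.filter_flags.add("protein_homology")
                break
    catalog.add_step("protein_homology", n_in, len(catalog.surviving()))
    return catalog


def flag_rfam(catalog: SRNACatalog, rfam_hits: Sequence[RfamHit],
              housekeeping_families: Optional[Set[str]] = None,
              cfg: Optional[PipelineConfig] = None) -> SRNACatalog:
    """Annotate Rfam families and flag housekeeping ones (``rfam_housekeeping``).

    Every hit annotates its record with the best (lowest-E) family name;
    records hit by a tRNA/RNase P/SRP model are excluded from the regulatory
    sRNA set but stay in the ncRNA catalog."""
    tokens = (
        {t.lower() for t in housekeeping_families}
        if housekeeping_families is not None else DEFAULT_HOUSEKEEPING_TOKENS
    )
    grouped = _hits_by_query(catalog, rfam_hits)
    n_in = len(catalog.surviving())
    for rec in catalog.records:
        hits = grouped.get(rec.transcript.id)
        if not hits:
            continue
        best = min(hits, key=lambda h: (h.evalue, -h.score, h.family_name))
        rec.rfam_family = best.family_name
        if any(is_housekeeping_family(h.family_name, tokens) for h in hits):
            rec.filter_flags.add("rfam_housekeeping")
    catalog.add_step("rfam_housekeeping", n_in, len(catalog.surviving()))
    return catalog


def flag_conserved(catalog: SRNACatalog, nt_hits: Sequence[HitRecord],
                   cfg: PipelineConfig, coverage_from: str = "query") -> SRNACatalog:
    """Mark candidates conserved in a nucleotide database.

    ``conserved = True`` iff some hit has E ≤ ``cons_max_evalue``, identity ≥
    ``cons_min_identity`` and coverage ≥ ``cons_min_qcov`` (inclusive bounds).
    Coverage is query coverage by default (``coverage_from="query"``)."""
    if coverage_from not in ("query",):
        raise ValueError("only query coverage is available from outfmt 6 input")
    grouped = _hits_by_query(catalog, nt_hits)
    for rec in catalog.records:
        for hit in grouped.get(rec.transcript.id, []):
            if (hit.evalue <= cfg.cons_max_evalue
                    and hit.identity >= cfg.cons_min_identity
                    and hit.query_cover >= cfg.cons_min_qcov):
                rec.conserved = True
                break
    return catalog
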