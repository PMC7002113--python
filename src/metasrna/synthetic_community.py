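"""Synthetic microbial-community fixtures with planted ground truth.

:func:`generate_community` emits a miniature metagenome (FASTA), its gene
annotation (GFF3) and a set of assembled transcripts (StringTie-dialect GTF)
in which the true class of every transcript is known by construction:
intergenic and antisense sRNAs placed with safe margins, coding and ambiguous
transcripts, and boundary decoys sitting exactly one unit inside/outside every
classification and filter threshold (gene distance 29/30 nt, antisense
overlap 9/10 nt, length 49/50/500/501 nt, coverage 4.9/5.0× and 9.9/10.0×).
Planted sRNA sequences are built stop-rich so the six-frame reading-frame
filter passes them; one decoy carries a stop-free sequence and must fail it.
All features sit far from contig tips, so the dynamic edge correction should
leave them untouched.

:func:`generate_counts` emits transcript- and contig-level count tables for
two groups of replicates under a negative-binomial model (variance
``mu + alpha*mu^2``), with optional per-transcript fold changes (true
expression changes) and per-contig abundance shifts (organism-abundance
changes that contig normalization must cancel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation_io import (
    Contig,
    GeneFeature,
    GenomeAnnotation,
    PipelineConfig,
    TranscriptFeature,
)
from .expression import ExpressionMatrix

__all__ = [
    "TruthRecord",
    "SyntheticTruth",
    "CommunityBundle",
    "CountBundle",
    "generate_community",
    "generate_counts",
]

STOPS = ("TAA", "TAG", "TGA")


@dataclass
class TruthRecord:
    transcript_id: str
    contig_id: str
    label: str
    expected_flags: Set[str] = field(default_factory=set)
    kind: str = "regular"  # regular | decoy:<rule> | coding | small_peptide

    @property
    def survives(self) -> bool:
        return self.label in ("intergenic", "antisense") and not self.expected_flags


@dataclass
class SyntheticTruth:
    records: Dict[str, TruthRecord]
    seed: int

    def labels(self) -> Dict[str, str]:
        return {tid: rec.label for tid, rec in self.records.items()}


@dataclass
class CommunityBundle:
    annotation: GenomeAnnotation
    transcripts: List[TranscriptFeature]
    truth: SyntheticTruth
    paths: Dict[str, Path] = field(default_factory=dict)


@dataclass
class CountBundle:
    transcripts: ExpressionMatrix
    contigs: ExpressionMatrix
    design: Dict[str, str]


def _six_frame_max_run(seq: str) -> int:
    """Longest stop-free codon stretch (nt) over all six frames; the
    generator's own brute-force checker for constructing compliant
    sequences."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(seq))
    best = 0
    for s in (seq, rc):
        for frame in range(3):
            run = 0
            for i in range(frame, len(s) - 2, 3):
                if s[i:i + 3] in STOPS:
                    run = 0
                else:
                    run += 1
                    best = max(best, run)
    return best * 3


def _stop_rich_sequence(length: int, rng: np.random.Generator,
                        max_run_nt: int) -> str:
    """A pseudo-random sequence whose six-frame stop-free runs stay short.

    Starts from a TTAA tiling (stops in every frame on both strands every
    12 nt) and applies random point mutations, reverting any that stretch a
    stop-free run beyond ``max_run_nt``."""
    base = ("TTAA" * (length // 4 + 1))[:length]
    if _six_frame_max_run(base) > max_run_nt:
        raise ValueError(f"cannot build a stop-rich sequence of length {length}")
    seq = list(base)
    alphabet = "ACGT"
    for _ in range(length // 2):
        pos = int(rng.integers(0, length))
        old = seq[pos]
        seq[pos] = alphabet[int(rng.integers(0, 4))]
        if _six_frame_max_run("".join(seq)) > max_run_nt:
            seq[pos] = old
    return "".join(seq)


def _stop_free_sequence(length: int) -> str:
    """GCA tiling: no stop codon in any of the six frames."""
    return ("GCA" * (length // 3 + 1))[:length]


def _opposite(strand: str) -> str:
    return "-" if strand == "+" else "+"


def generate_community(n_contigs: int, n_genes: int, n_srnas: int, seed: int,
                       cfg: Optional[PipelineConfig] = None,
                       out_dir=None, include_decoys: bool = True) -> CommunityBundle:
    """Generate a ground-truthed community fixture.

    ``n_genes`` counts all annotated genes, including the anchor/host genes
    consumed by planted sRNAs; it must be large enough for the requested
    ``n_srnas`` (one gene per planted sRNA plus the decoy set). Deterministic
    for a given seed. When ``out_dir`` is given, writes ``assembly.fasta``,
    ``genes.gff``, ``transcripts.gtf``, ``truth.tsv`` and ``truth.json``.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    edge_clear = cfg.edge_grid_max + 100

    # --- plan blocks ------------------------------------------------------
    plans: List[dict] = []
    for i in range(n_srnas):
        kind = "intergenic" if i % 2 == 0 else "antisense"
        length = int(rng.integers(60, 301))
        if kind == "intergenic":
            cov = float(np.round(rng.uniform(cfg.cov_threshold_intergenic + 1, 50), 2))
        else:
            cov = float(np.round(rng.uniform(cfg.cov_threshold_antisense + 1, 50), 2))
        plans.append({
            "type": kind, "length": length, "cov": cov,
            "tpm": float(np.round(rng.uniform(1, 100), 2)),
            "kind": "regular", "flags": set(),
        })
    if include_decoys:
        d = cfg.min_gene_distance
        ov = cfg.min_antisense_overlap
        decoys = [
            {"type": "intergenic", "gap_left": d - 1, "label": "ambiguous",
             "kind": f"decoy:dist{d-1}"},
            {"type": "intergenic", "gap_left": d, "label": "intergenic",
             "kind": f"decoy:dist{d}"},
            {"type": "antisense", "overlap": ov - 1, "label": "ambiguous",
             "kind": f"decoy:ovl{ov-1}"},
            {"type": "antisense", "overlap": ov, "label": "antisense",
             "kind": f"decoy:ovl{ov}"},
            {"type": "intergenic", "length": cfg.min_len - 1,
             "flags": {"length_fail"}, "kind": f"decoy:len{cfg.min_len-1}"},
            {"type": "intergenic", "length": cfg.min_len,
             "kind": f"decoy:len{cfg.min_len}"},
            {"type": "intergenic", "length": cfg.max_len,
             "kind": f"decoy:len{cfg.max_len}"},
            {"type": "intergenic", "length": cfg.max_len + 1,
             "flags": {"length_fail"}, "kind": f"decoy:len{cfg.max_len+1}"},
            {"type": "intergenic", "cov": cfg.cov_threshold_intergenic - 0.1,
             "flags": {"coverage_fail"}, "kind": "decoy:cov_low_intergenic"},
            {"type": "intergenic", "cov": cfg.cov_threshold_intergenic,
             "kind": "decoy:cov_pass_intergenic"},
            {"type": "antisense", "cov": cfg.cov_threshold_antisense - 0.1,
             "flags": {"coverage_fail"}, "kind": "decoy:cov_low_antisense"},
            {"type": "antisense", "cov": cfg.cov_threshold_antisense,
             "kind": "decoy:cov_pass_antisense"},
            {"type": "intergenic", "stop_free": True, "flags": {"orf_fail"},
             "kind": "decoy:orf"},
            {"type": "small_peptide", "kind": "small_peptide"},
        ]
        for spec in decoys:
            plan = {
                "type": spec["type"],
                "length": spec.get("length", 150),
                "cov": spec.get("cov", 20.0),
                "tpm": 10.0,
                "kind": spec["kind"],
                "flags": set(spec.get("flags", set())),
                "label": spec.get("label"),
                "gap_left": spec.get("gap_left"),
                "overlap": spec.get("overlap"),
                "stop_free": spec.get("stop_free", False),
            }
            plans.append(plan)
    n_coding = max(3, n_srnas // 10)
    for _ in range(n_coding):
        plans.append({"type": "coding", "kind": "coding", "flags": set()})

    genes_in_blocks = sum(1 for p in plans if p["type"] != "coding") + n_coding
    if n_genes < genes_in_blocks:
        raise ValueError(
            f"infeasible geometry: {genes_in_blocks} genes are needed to anchor the "
            f"planted transcripts but only n_genes={n_genes} were requested"
        )
    n_standalone = n_genes - genes_in_blocks

    # --- place blocks round-robin on contigs ------------------------------
    contig_ids = [f"contig_{i+1}" for i in range(n_contigs)]
    cursors = {cid: edge_clear for cid in contig_ids}
    genes: List[GeneFeature] = []
    transcripts: List[TranscriptFeature] = []
    truth_records: Dict[str, TruthRecord] = {}
    designed_seq: Dict[str, List[Tuple[int, int, str]]] = {cid: [] for cid in contig_ids}
    gene_counter = 0
    transcript_counter = 0
    gap_far = 200  # clearance guaranteeing classification-irrelevant distance

    def new_gene(cid: str, start: int, length: int, strand: str) -> GeneFeature:
        nonlocal gene_counter
        gene_counter += 1
        g = GeneFeature(id=f"gene_{gene_counter}", contig_id=cid, start=start,
                        end=start + length, strand=strand,
                        product="hypothetical protein")
        genes.append(g)
        return g

    def new_transcript(cid: str, start: int, length: int, strand: str,
                       cov: float, tpm: float) -> TranscriptFeature:
        nonlocal transcript_counter
        transcript_counter += 1
        t = TranscriptFeature(id=f"STRG.{transcript_counter}.1", contig_id=cid,
                              start=start, end=start + length, strand=strand,
                              coverage=cov, tpm=tpm)
        transcripts.append(t)
        return t

    for idx, plan in enumerate(plans):
        cid = contig_ids[idx % n_contigs]
        cur = cursors[cid]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if plan["type"] == "intergenic":
            gene_len = int(rng.integers(300, 901))
            new_gene(cid, cur, gene_len, strand)
            gap_left = plan.get("gap_left")
            if gap_left is None:
                gap_left = int(rng.integers(cfg.min_gene_distance + 10, 121))
            s_strand = "+" if rng.integers(0, 2) == 0 else "-"
            t = new_transcript(cid, cur + gene_len + gap_left, plan["length"],
                               s_strand, plan["cov"], plan["tpm"])
            label = plan.get("label") or "intergenic"
            seq_kind = "stop_free" if plan.get("stop_free") else "stop_rich"
            designed_seq[cid].append((t.start, t.end, seq_kind))
            truth_records[t.id] = TruthRecord(t.id, cid, label,
                                              set(plan["flags"]), plan["kind"])
            cursors[cid] = t.end + gap_far
        elif plan["type"] == "antisense":
            gene_len = int(rng.integers(300, 901))
            host = new_gene(cid, cur, gene_len, strand)
            overlap = plan.get("overlap")
            if overlap is None:
                overlap = int(rng.integers(cfg.min_antisense_overlap + 5, 41))
            t = new_transcript(cid, host.end - overlap, plan["length"],
                               _opposite(strand), plan["cov"], plan["tpm"])
            label = plan.get("label") or "antisense"
            designed_seq[cid].append((t.start, t.end, "stop_rich"))
            truth_records[t.id] = TruthRecord(t.id, cid, label,
                                              set(plan["flags"]), plan["kind"])
            cursors[cid] = t.end + gap_far
        elif plan["type"] == "small_peptide":
            # transcript > 3x an internal small-peptide gene: the gene is
            # ignored by classification and the transcript stays intergenic
            t_len = 280
            g_len = 90
            s_strand = "+" if rng.integers(0, 2) == 0 else "-"
            t = new_transcript(cid, cur, t_len, s_strand, 20.0, 10.0)
            new_gene(cid, t.start + 95, g_len, strand)
            designed_seq[cid].append((t.start, t.end, "stop_rich"))
            truth_records[t.id] = TruthRecord(t.id, cid, "intergenic", set(),
                                              plan["kind"])
            cursors[cid] = t.end + gap_far
        elif plan["type"] == "coding":
            gene_len = int(rng.integers(300, 901))
            g = new_gene(cid, cur, gene_len, strand)
            t = new_transcript(cid, g.start + 20, gene_len + 40, strand,
                               float(np.round(rng.uniform(5, 50), 2)),
                               float(np.round(rng.uniform(1, 100), 2)))
            truth_records[t.id] = TruthRecord(t.id, cid, "coding", set(), "coding")
            cursors[cid] = t.end + gap_far
        else:  # pragma: no cover
            raise ValueError(f"unknown plan type {plan['type']!r}")

    for j in range(n_standalone):
        cid = contig_ids[j % n_contigs]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        gene_len = int(rng.integers(300, 901))
        new_gene(cid, cursors[cid], gene_len, strand)
        cursors[cid] = cursors[cid] + gene_len + int(rng.integers(60, 151))

    # --- sequences --------------------------------------------------------
    contigs: Dict[str, Contig] = {}
    alphabet = np.array(list("ACGT"))
    for cid in contig_ids:
        length = cursors[cid] + edge_clear
        seq = "".join(alphabet[rng.integers(0, 4, size=length)])
        chars = list(seq)
        for start, end, seq_kind in designed_seq[cid]:
            n = end - start
            if seq_kind == "stop_free":
                planted = _stop_free_sequence(n)
            else:
                max_run = max(9, (n // 3) - 3)
                planted = _stop_rich_sequence(n, rng, max_run)
            chars[start:end] = list(planted)
        contigs[cid] = Contig(id=cid, length=length, sequence="".join(chars))

    annotation = GenomeAnnotation(contigs, genes)
    truth = SyntheticTruth(records=truth_records, seed=seed)
    bundle = CommunityBundle(annotation=annotation, transcripts=transcripts,
                             truth=truth)
    if out_dir is not None:
        bundle.paths = _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: CommunityBundle, out_dir: Path) -> Dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "assembly.fasta",
        "gff": out_dir / "genes.gff",
        "gtf": out_dir / "transcripts.gtf",
        "truth_tsv": out_dir / "truth.tsv",
        "truth_json": out_dir / "truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for cid in sorted(bundle.annotation.contigs):
            seq = bundle.annotation.contigs[cid].sequence
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(bundle.annotation.genes,
                        key=lambda g: (g.contig_id, g.start, g.id)):
            fh.write("\t".join([
                g.contig_id, "metasrna_sim", "CDS", str(g.start + 1), str(g.end),
                ".", g.strand, "0", f"ID={g.id};product={g.product}",
            ]) + "\n")
    with open(paths["gtf"], "w") as fh:
        for t in bundle.transcripts:
            attrs = (f'transcript_id "{t.id}"; cov "{t.coverage}"; '
                     f'TPM "{t.tpm}";')
            row = [t.contig_id, "StringTie", "transcript", str(t.start + 1),
                   str(t.end), "1000", t.strand, ".", attrs]
            fh.write("\t".join(row) + "\n")
            row[2] = "exon"
            fh.write("\t".join(row) + "\n")
    rows = []
    for tid, rec in bundle.truth.records.items():
        rows.append({
            "transcript_id": tid, "contig_id": rec.contig_id, "label": rec.label,
            "expected_flags": ",".join(sorted(rec.expected_flags)),
            "kind": rec.kind, "survives": rec.survives,
        })
    pd.DataFrame(rows).to_csv(paths["truth_tsv"], sep="\t", index=False)
    with open(paths["truth_json"], "w") as fh:
        json.dump({
            "seed": bundle.truth.seed,
            "records": {tid: {
                "contig_id": r.contig_id, "label": r.label,
                "expected_flags": sorted(r.expected_flags), "kind": r.kind,
            } for tid, r in bundle.truth.records.items()},
        }, fh, indent=1, sort_keys=True)
    return paths


def generate_counts(truth: SyntheticTruth, n_per_group: int, nb_mean: float,
                    nb_dispersion: float,
                    abundance_shift: Optional[Mapping[str, float]] = None,
                    effect: Optional[Mapping[str, float]] = None,
                    seed: int = 0, n_background_genes: int = 25,
                    background_mean_factor: float = 3.0) -> CountBundle:
    """Two-group NB count tables for the transcripts in ``truth``.

    Group "2017" applies ``2**effect[transcript]`` (true expression change)
    and ``abundance_shift[contig]`` (organism abundance change) to the NB
    mean; group "2016" is the baseline. Contig counts are the sum of the
    contig's transcript counts plus ``n_background_genes`` background gene
    draws, all sharing the contig shift — so contig normalization cancels the
    shift but not the true effect.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if nb_mean <= 0 or nb_dispersion <= 0:
        raise ValueError("nb_mean and nb_dispersion must be > 0")
    abundance_shift = dict(abundance_shift or {})
    effect = dict(effect or {})
    rng = np.random.default_rng(seed)
    samples = ([f"y2016_r{i+1:02d}" for i in range(n_per_group)]
               + [f"y2017_r{i+1:02d}" for i in range(n_per_group)])
    design = {s: ("2016" if s.startswith("y2016") else "2017") for s in samples}
    is_2017 = np.array([design[s] == "2017" for s in samples])

    r = 1.0 / nb_dispersion

    def nb_draw(mu: np.ndarray) -> np.ndarray:
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    tids = list(truth.records)
    t_counts = np.zeros((len(tids), len(samples)), dtype=float)
    feature_to_contig = {}
    for i, tid in enumerate(tids):
        contig = truth.records[tid].contig_id
        feature_to_contig[tid] = contig
        shift = abundance_shift.get(contig, 1.0)
        lfc = effect.get(tid, 0.0)
        mu = nb_mean * np.where(is_2017, (2.0 ** lfc) * shift, 1.0)
        t_counts[i] = nb_draw(mu)

    contig_ids = sorted(set(feature_to_contig.values()))
    c_counts = np.zeros((len(contig_ids), len(samples)), dtype=float)
    for j, cid in enumerate(contig_ids):
        member = [i for i, tid in enumerate(tids) if feature_to_contig[tid] == cid]
        c_counts[j] = t_counts[member].sum(axis=0)
        shift = abundance_shift.get(cid, 1.0)
        mu_bg = nb_mean * background_mean_factor * np.where(is_2017, shift, 1.0)
        for _ in range(n_background_genes):
            c_counts[j] += nb_draw(mu_bg)

    return CountBundle(
        transcripts=ExpressionMatrix(
            values=pd.DataFrame(t_counts, index=tids, columns=samples),
            kind="raw_count", feature_to_contig=feature_to_contig,
        ),
        contigs=ExpressionMatrix(
            values=pd.DataFrame(c_counts, index=contig_ids, columns=samples),
            kind="raw_count",
        ),
        design=design,
    )
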