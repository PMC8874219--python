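"""Transcript-model construction and hierarchical selection.

One junction-set model is chosen per gene through a three-tier hierarchy:

1. the gene's curated MANE transcript, provided every one of its junctions
   is also derivable from some transcript of that gene in the working
   (GENCODE-style) annotation;
2. otherwise a *RefSeq composite* — the union of junctions over the gene's
   RefSeq transcripts;
3. otherwise the union of junctions over the gene's annotation transcripts.

Junctions use 1-based fully-closed intron coordinates: for consecutive
exons the junction is ``(exon_i.end + 1, exon_{i+1}.start − 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

from .junctions import SpliceJunction

__all__ = [
    "TranscriptModel",
    "CvReport",
    "gtf_to_junctions",
    "build_union",
    "select_transcript",
    "cv_mrsd_report",
]

TIERS = ("MANE", "refseq_composite", "gencode_union")


@dataclass(frozen=True)
class TranscriptModel:
    """A gene's selected junction set with its provenance tier."""

    gene_id: str
    transcript_id: str
    tier: str
    junctions: tuple[SpliceJunction, ...]

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if not self.junctions:
            raise ValueError(
                f"{self.gene_id}/{self.transcript_id}: transcript model needs "
                "at least one junction"
            )
        if len(set(self.junctions)) != len(self.junctions):
            raise ValueError(f"{self.transcript_id}: duplicate junctions in model")

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def span(self) -> tuple[str, int, int]:
        """(chrom, min start, max end) over the model's junctions."""
        chrom = self.junctions[0].chrom
        return (
            chrom,
            min(j.start for j in self.junctions),
            max(j.end for j in self.junctions),
        )


@dataclass(frozen=True)
class CvReport:
    """Inter-transcript MRSD variability for one gene.

    ``cv_mrsd`` is the population coefficient of variation over the gene's
    transcripts with finite MRSD; it is ``None`` (undefined) when fewer
    than two transcripts are feasible.  ``math.inf`` encodes UNFEASIBLE.
    """

    gene_id: str
    n_transcripts: int
    n_feasible: int
    cv_mrsd: float | None
    min_mrsd: float
    selected_mrsd: float


def _exons_to_junctions(
    exons: Sequence[tuple[int, int]], chrom: str, strand: str, transcript_id: str
) -> list[SpliceJunction]:
    exons = sorted(exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1:
            raise ValueError(
                f"{transcript_id}: overlapping exons ({s1}-{e1}, {s2}-{e2})"
            )
    return [
        SpliceJunction(chrom, e1 + 1, s2 - 1, strand)
        for (_, e1), (s2, _) in zip(exons, exons[1:])
    ]


def gtf_to_junctions(
    gtf_path: str | Path, gene_id: str | None = None
) -> dict[str, dict[str, list[SpliceJunction]]]:
    """Extract per-transcript junction lists from a GTF.

    Returns ``{gene_id: {transcript_id: [junctions ...]}}``; single-exon
    transcripts yield empty lists.  GTF strand ``.`` maps to ``unknown``.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[tuple[str, str], dict] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes["gene_id"][0]
        if gene_id is not None and gid != gene_id:
            continue
        tid = exon.attributes["transcript_id"][0]
        rec = per_tx.setdefault(
            (gid, tid),
            {"chrom": exon.seqid, "strand": exon.strand, "exons": []},
        )
        rec["exons"].append((exon.start, exon.end))
    out: dict[str, dict[str, list[SpliceJunction]]] = {}
    for (gid, tid), rec in per_tx.items():
        strand = rec["strand"] if rec["strand"] in ("+", "-") else "unknown"
        out.setdefault(gid, {})[tid] = _exons_to_junctions(
            rec["exons"], rec["chrom"], strand, tid
        )
    if gene_id is not None and gene_id not in out:
        raise KeyError(f"gene {gene_id!r} not found in {gtf_path}")
    return out


def build_union(
    transcripts: Iterable[Sequence[SpliceJunction]],
) -> tuple[SpliceJunction, ...]:
    """Deduplicated union of junctions, sorted by (chrom, start, end, strand)."""
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("need at least one transcript")
    return tuple(sorted({j for tx in transcripts for j in tx}))


def select_transcript(
    gene_id: str,
    mane_transcripts: Mapping[str, Sequence[SpliceJunction]],
    refseq_transcripts: Mapping[str, Sequence[SpliceJunction]],
    gencode_transcripts: Mapping[str, Sequence[SpliceJunction]],
) -> TranscriptModel:
    """Choose one junction-set model for a gene via the three-tier hierarchy.

    A MANE transcript is used only when all of its junctions appear in the
    union of the gene's annotation-derived junctions (coordinate identity);
    an unsupported MANE transcript falls through to the next tier.  Genes
    that are single-exon in every source raise: they have no junctions and
    no depth requirement can be defined for them.
    """
    if not gencode_transcripts:
        raise KeyError(f"gene {gene_id!r} absent from the GENCODE annotation input")
    gencode_union = set(build_union(list(gencode_transcripts.values())))

    for tid, junctions in mane_transcripts.items():
        if junctions and set(junctions) <= gencode_union:
            return TranscriptModel(gene_id, tid, "MANE", tuple(junctions))

    refseq_lists = [jx for jx in refseq_transcripts.values() if jx]
    if refseq_lists:
        union = build_union(refseq_lists)
        label = f"{gene_id}_refseq_composite"
        return TranscriptModel(gene_id, label, "refseq_composite", union)

    if not gencode_union:
        raise ValueError(
            f"gene {gene_id!r} is single-exon in every source: no junctions"
        )
    return TranscriptModel(
        gene_id,
        f"{gene_id}_gencode_union",
        "gencode_union",
        tuple(sorted(gencode_union)),
    )


def cv_mrsd_report(
    gene_id: str,
    per_transcript_mrsds: Mapping[str, float],
    selected_transcript_id: str | None = None,
) -> CvReport:
    """Summarise MRSD spread across a gene's transcripts.

    ``per_transcript_mrsds`` maps transcript id → MRSD in millions of reads,
    with ``math.inf`` for unfeasible transcripts.  The coefficient of
    variation uses the population (n-denominator) standard deviation over
    finite values only; unfeasible transcripts are excluded from the CV but
    reflected in ``n_feasible`` for feasibility-discordance reporting.
    """
    values = dict(per_transcript_mrsds)
    if not values:
        raise ValueError(f"{gene_id}: no transcript MRSD values")
    finite = [v for v in values.values() if math.isfinite(v)]
    cv: float | None = None
    if len(finite) >= 2:
        mean = sum(finite) / len(finite)
        if mean > 0:
            sd = math.sqrt(sum((v - mean) ** 2 for v in finite) / len(finite))
            cv = sd / mean
        else:
            cv = 0.0
    min_mrsd = min(finite) if finite else math.inf
    selected = (
        values[selected_transcript_id]
        if selected_transcript_id is not None
        else min_mrsd
    )
    return CvReport(
        gene_id=gene_id,
        n_transcripts=len(values),
        n_feasible=len(finite),
        cv_mrsd=cv,
        min_mrsd=min_mrsd,
        selected_mrsd=selected,
    )
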