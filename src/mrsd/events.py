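"""Aberrant splice-event scoring, filtering and ranking.

A case sample's splice junctions are scored per gene against a control
reference set using five metrics:

* **read count** — split reads supporting the junction in the case;
* **NRC** (normalized read count) — ratio of the event's read count to the
  highest-count *adjoining canonical* junction of the gene's transcript
  model (adjoining = shares the event's donor or acceptor coordinate, with
  a nearest-flanking fallback).  NRC may exceed 1;
* **NRC fold change** — the case NRC divided by the highest NRC for the
  same junction among controls (each control normalized against its own
  canonical counts); events absent from every control are *singletons*;
* **number of samples** — case + controls in which the junction is seen;
* **rank** — position after sorting singletons (by decreasing read count)
  above non-singletons (by decreasing fold change).

Filtering retains events that are singletons or that show strictly higher
NRC than every control; the read-count (≥2) and NRC (>0.25) thresholds
are applied separately so their effect on sensitivity can be examined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .junctions import ReferenceSet, SpliceJunction
from .transcripts import TranscriptModel

__all__ = [
    "SpliceEvent",
    "adjoining_canonical",
    "compute_nrc",
    "compute_fold_change",
    "score_events",
    "filter_events",
    "apply_thresholds",
    "rank_events",
    "SpliceEventScorer",
    "SpliceEventResults",
]


@dataclass(frozen=True)
class SpliceEvent:
    """One junction of one case sample with its Box-style metrics.

    ``nrc_fold_change`` is ``None`` for singletons (no control carries the
    junction); ``max_control_nrc`` is ``None`` in the same case.  ``flagged``
    marks events whose NRC could not be computed (no canonical junction
    with nonzero reads); they carry ``nrc = nan`` and never pass filters.
    """

    junction: SpliceJunction
    sample_id: str
    gene_id: str
    read_count: int
    nrc: float
    nrc_fold_change: float | None
    n_samples: int
    max_control_nrc: float | None = None
    rank: int | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("an event needs at least one supporting read")
        if self.n_samples < 1:
            raise ValueError("n_samples counts the case itself, so ≥ 1")

    @property
    def is_singleton(self) -> bool:
        return self.n_samples == 1


def adjoining_canonical(
    junction: SpliceJunction, model: TranscriptModel
) -> list[SpliceJunction]:
    """Canonical junctions adjoining an event junction.

    Preference: canonical junctions (other than the event itself) sharing
    the event's donor (start) or acceptor (end) coordinate; if none share
    a splice site, fall back to the nearest flanking canonical junction on
    each side.
    """
    canon = [j for j in model.junctions if j != junction]
    if not canon:
        return []
    shared = [j for j in canon if j.start == junction.start or j.end == junction.end]
    if shared:
        return shared
    left = [j for j in canon if j.start < junction.start]
    right = [j for j in canon if j.end > junction.end]
    out = []
    if left:
        out.append(max(left, key=lambda j: (j.start, j.end)))
    if right:
        out.append(min(right, key=lambda j: (j.end, j.start)))
    return out


def compute_nrc(
    event_junction: SpliceJunction,
    sample_counts: Mapping[SpliceJunction, int],
    model: TranscriptModel,
) -> float:
    """Normalized read count of an event within one sample.

    Raises ``ValueError`` when no adjoining canonical junction has nonzero
    reads in the sample (the pipeline flags such events instead of
    scoring them).
    """
    reads = int(sample_counts.get(event_junction, 0))
    if reads < 1:
        raise ValueError(f"event junction {event_junction} has no reads in sample")
    adjoining = adjoining_canonical(event_junction, model)
    denom = max((int(sample_counts.get(j, 0)) for j in adjoining), default=0)
    if denom == 0:
        raise ValueError(
            f"no adjoining canonical junction of {model.gene_id} has nonzero "
            f"reads; NRC undefined for {event_junction}"
        )
    return reads / denom


def compute_fold_change(
    event_nrc: float, control_nrcs_for_junction: Sequence[float]
) -> float | None:
    """Case NRC over the highest control NRC; ``None`` means singleton.

    Controls with NRC exactly 0 are treated as not carrying the junction.
    """
    if event_nrc <= 0:
        raise ValueError("event NRC must be positive")
    present = [v for v in control_nrcs_for_junction if v > 0]
    if not present:
        return None
    return event_nrc / max(present)


def _control_nrc(
    junction: SpliceJunction,
    count: int,
    canonical_max: int,
) -> float:
    """A control's own-sample NRC (∞ when it uses the junction against a
    silent canonical background)."""
    if count <= 0:
        return 0.0
    if canonical_max == 0:
        return math.inf
    return count / canonical_max


def score_events(
    case_counts: Mapping[SpliceJunction, int],
    case_id: str,
    controls: ReferenceSet,
    models: Sequence[TranscriptModel],
    pad: int = 0,
) -> list[SpliceEvent]:
    """Score every case junction that falls within a gene model's span.

    Each control's NRC for a junction is computed against that control's
    own canonical counts.  Junctions outside every model span (after
    ``pad`` bp extension) are ignored: intergenic junctions are out of
    scope.
    """
    events: list[SpliceEvent] = []
    for model in models:
        chrom, lo, hi = model.span
        in_gene = [
            j
            for j in case_counts
            if j.chrom == chrom
            and j.start >= lo - pad
            and j.end <= hi + pad
            and case_counts[j] > 0
        ]
        if not in_gene:
            continue
        adjoin = {j: adjoining_canonical(j, model) for j in in_gene}
        # control canonical counts: samples × model junctions
        canon_cols = {j: controls.column(j) for j in model.junctions}
        for j in sorted(in_gene):
            reads = int(case_counts[j])
            ctrl_counts = controls.column(j)
            n_samples = 1 + int((ctrl_counts > 0).sum())
            try:
                nrc = compute_nrc(j, case_counts, model)
            except ValueError:
                events.append(
                    SpliceEvent(
                        junction=j,
                        sample_id=case_id,
                        gene_id=model.gene_id,
                        read_count=reads,
                        nrc=math.nan,
                        nrc_fold_change=None,
                        n_samples=n_samples,
                        flagged=True,
                    )
                )
                continue
            ctrl_nrcs = []
            for i in range(controls.n_samples):
                cmax = max(
                    (int(canon_cols[cj][i]) for cj in adjoin[j]), default=0
                )
                ctrl_nrcs.append(_control_nrc(j, int(ctrl_counts[i]), cmax))
            fc = compute_fold_change(nrc, ctrl_nrcs)
            max_ctrl = max((v for v in ctrl_nrcs if v > 0), default=None)
            events.append(
                SpliceEvent(
                    junction=j,
                    sample_id=case_id,
                    gene_id=model.gene_id,
                    read_count=reads,
                    nrc=nrc,
                    nrc_fold_change=fc,
                    n_samples=n_samples,
                    max_control_nrc=max_ctrl,
                )
            )
    return events


def filter_events(events: Iterable[SpliceEvent]) -> list[SpliceEvent]:
    """Retain singletons and events with NRC strictly above every control."""
    out = []
    for ev in events:
        if ev.flagged or not math.isfinite(ev.nrc):
            continue
        if ev.max_control_nrc is None:
            out.append(ev)
        elif ev.nrc > ev.max_control_nrc:
            out.append(ev)
    return out


def apply_thresholds(
    events: Iterable[SpliceEvent], min_reads: int = 2, min_nrc: float = 0.25
) -> list[SpliceEvent]:
    """Read-count and NRC thresholds (NRC threshold spares singletons)."""
    return [
        ev
        for ev in events
        if ev.read_count >= min_reads and (ev.is_singleton or ev.nrc > min_nrc)
    ]


def _rank_key(ev: SpliceEvent):
    jkey = (ev.junction.chrom, ev.junction.start, ev.junction.end, ev.junction.strand)
    if ev.is_singleton:
        return (0, -ev.read_count, jkey)
    return (1, -(ev.nrc_fold_change or 0.0), -ev.read_count, jkey)


def rank_events(events: Sequence[SpliceEvent]) -> list[SpliceEvent]:
    """Assign 1-based ranks: singletons (by decreasing read count) above
    non-singletons (by decreasing NRC fold change; ties by read count,
    then coordinates)."""
    ordered = sorted(events, key=_rank_key)
    return [replace(ev, rank=i) for i, ev in enumerate(ordered, start=1)]


class SpliceEventScorer:
    """Case-versus-controls splice-event analysis.

    Parameters
    ----------
    controls
        Control reference set (the background cohort).
    transcript_models
        Gene models providing canonical junctions and gene spans.
    """

    def __init__(
        self, controls: ReferenceSet, transcript_models: Sequence[TranscriptModel]
    ):
        self.controls = controls
        self.transcript_models = list(transcript_models)

    def fit(
        self,
        case_counts: Mapping[SpliceJunction, int],
        case_id: str = "case",
        min_reads: int = 2,
        min_nrc: float = 0.25,
        pad: int = 0,
    ) -> "SpliceEventResults":
        """Score, filter, threshold and rank one case sample's events."""
        scored = score_events(
            case_counts, case_id, self.controls, self.transcript_models, pad=pad
        )
        retained = apply_thresholds(
            filter_events(scored), min_reads=min_reads, min_nrc=min_nrc
        )
        ranked = rank_events(retained)
        return SpliceEventResults(self, case_id, scored, ranked, min_reads, min_nrc)


class SpliceEventResults:
    """Scored and ranked events for one case sample."""

    def __init__(
        self,
        scorer: SpliceEventScorer,
        case_id: str,
        all_events: list[SpliceEvent],
        ranked: list[SpliceEvent],
        min_reads: int,
        min_nrc: float,
    ):
        self.scorer = scorer
        self.case_id = case_id
        self.all_events = all_events
        self.ranked = ranked
        self.min_reads = min_reads
        self.min_nrc = min_nrc

    def __len__(self):
        return len(self.ranked)

    def __iter__(self):
        return iter(self.ranked)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.ranked:
            rows.append(
                {
                    "rank": ev.rank,
                    "gene_id": ev.gene_id,
                    "chrom": ev.junction.chrom,
                    "start": ev.junction.start,
                    "end": ev.junction.end,
                    "strand": ev.junction.strand,
                    "read_count": ev.read_count,
                    "nrc": round(ev.nrc, 6),
                    "nrc_fold_change": (
                        "singleton"
                        if ev.nrc_fold_change is None
                        else round(ev.nrc_fold_change, 6)
                    ),
                    "n_samples": ev.n_samples,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "rank",
                "gene_id",
                "chrom",
                "start",
                "end",
                "strand",
                "read_count",
                "nrc",
                "nrc_fold_change",
                "n_samples",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        n_single = sum(1 for ev in self.ranked if ev.is_singleton)
        lines = [
            f"Splice-event results for sample {self.case_id}",
            f"scored junctions:   {len(self.all_events)}",
            f"retained events:    {len(self.ranked)} "
            f"(min_reads={self.min_reads}, min_nrc>{self.min_nrc})",
            f"  singletons:       {n_single}",
            f"  non-singletons:   {len(self.ranked) - n_single}",
        ]
        return "\n".join(lines)
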