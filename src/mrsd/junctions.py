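"""Splice-junction containers and per-sample junction-count I/O.

A splice junction is an intron inferred from split-read alignments,
identified by chromosome, 1-based first/last intronic base and strand.
Junction identity — the universal join key throughout the package — is the
full tuple ``(chrom, start, end, strand)``; a junction with strand
``"unknown"`` matches only ``"unknown"``.

Counts are *uniquely mapping* split reads only.  The per-sample library
size ``d`` (total uniquely mapping reads, in millions) cannot be recovered
from junction counts and is always supplied explicitly, typically through
a sample manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpliceJunction",
    "SampleDepth",
    "ReferenceSet",
    "read_star_sj",
    "read_junction_tsv",
    "write_junction_tsv",
    "read_manifest",
    "assemble_reference_set",
    "subset_by_transcript",
]

#: STAR SJ.out.tab strand codes.
_STAR_STRAND = {0: "unknown", 1: "+", 2: "-"}

_VALID_STRANDS = frozenset({"+", "-", "unknown"})


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """An intron: chrom, 1-based first and last intronic base, strand."""

    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("junction chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"junction start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class SampleDepth:
    """A sample id with its total uniquely-mapping read count in millions."""

    sample_id: str
    depth_millions: float

    def __post_init__(self) -> None:
        if not self.depth_millions > 0:
            raise ValueError(
                f"sample {self.sample_id!r}: depth must be positive, "
                f"got {self.depth_millions}"
            )


@dataclass
class ReferenceSet:
    """Control-cohort junction counts: a samples × junctions count matrix.

    Parameters
    ----------
    samples
        Per-sample identifiers and library sizes (millions of uniquely
        mapping reads).
    junctions
        Column labels of ``counts``.
    counts
        Non-negative integer matrix, one row per sample, one column per
        junction.
    tissue_label
        Free-text label for the cohort (e.g. ``"whole_blood"``).
    """

    samples: list[SampleDepth]
    junctions: list[SpliceJunction]
    counts: np.ndarray
    tissue_label: str = ""
    _index: dict[SpliceJunction, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), len(self.junctions)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples × {len(self.junctions)} junctions"
            )
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("junction counts must be non-negative")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in reference set")
        self._index = {j: k for k, j in enumerate(self.junctions)}
        if len(self._index) != len(self.junctions):
            raise ValueError("duplicate junctions in reference set")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def depths(self) -> np.ndarray:
        """Library sizes in millions, aligned with matrix rows."""
        return np.array([s.depth_millions for s in self.samples])

    def column(self, junction: SpliceJunction) -> np.ndarray:
        """Counts for one junction across samples (zeros if never seen)."""
        k = self._index.get(junction)
        if k is None:
            return np.zeros(self.n_samples, dtype=self.counts.dtype)
        return self.counts[:, k]

    def sample_counts(self, sample_id: str) -> dict[SpliceJunction, int]:
        """One sample's nonzero junction counts as a plain mapping."""
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                row = self.counts[i]
                return {
                    j: int(c) for j, c in zip(self.junctions, row) if c > 0
                }
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        cols = pd.Index(
            [f"{j.chrom}:{j.start}-{j.end}({j.strand})" for j in self.junctions],
            name="junction",
        )
        return pd.DataFrame(
            self.counts, index=[s.sample_id for s in self.samples], columns=cols
        )


def read_star_sj(path: str | Path) -> dict[SpliceJunction, int]:
    """Read a STAR ``SJ.out.tab`` file into junction → unique-read count.

    Columns (no header): chrom, intron start (1-based), intron end
    (1-based), strand code (0 undefined / 1 ``+`` / 2 ``-``), motif,
    annotated flag, unique reads, multimapping reads, max overhang.
    Only the unique-read column is kept; multimappers are discarded.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    if df.shape[1] < 9:
        raise ValueError(
            f"{path}: expected ≥9 tab-separated columns (STAR SJ.out.tab), "
            f"found {df.shape[1]}"
        )
    if df.isna().any(axis=None):
        bad = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}: malformed row at line {bad}")
    out: dict[SpliceJunction, int] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        strand_code = int(row[3])
        if strand_code not in _STAR_STRAND:
            raise ValueError(f"{path}: line {line_no}: bad strand code {strand_code}")
        count = int(row[6])
        if count < 0:
            raise ValueError(f"{path}: line {line_no}: negative unique-read count")
        j = SpliceJunction(str(row[0]), int(row[1]), int(row[2]), _STAR_STRAND[strand_code])
        if j in out:
            raise ValueError(f"{path}: line {line_no}: duplicate junction {j}")
        out[j] = count
    return out


def read_junction_tsv(path: str | Path) -> dict[SpliceJunction, int]:
    """Read the generic junction TSV (header: chrom start end strand unique_reads)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    except pd.errors.EmptyDataError:
        return {}
    required = {"chrom", "start", "end", "strand", "unique_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[SpliceJunction, int] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        count = int(row.unique_reads)
        if count < 0:
            raise ValueError(f"{path}: line {line_no}: negative unique-read count")
        j = SpliceJunction(row.chrom, int(row.start), int(row.end), row.strand)
        if j in out:
            raise ValueError(f"{path}: line {line_no}: duplicate junction {j}")
        out[j] = count
    return out


def write_junction_tsv(counts: Mapping[SpliceJunction, int], path: str | Path) -> None:
    """Write junction counts in the generic TSV format (sorted by coordinate)."""
    rows = [
        (j.chrom, j.start, j.end, j.strand, int(c))
        for j, c in sorted(counts.items())
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "unique_reads"]
    ).to_csv(path, sep="\t", index=False)


def _read_counts_any(path: str | Path) -> dict[SpliceJunction, int]:
    """Dispatch on file content: headered generic TSV vs headerless STAR."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("chrom"):
        return read_junction_tsv(path)
    return read_star_sj(path)


def read_manifest(
    path: str | Path,
) -> list[tuple[str, dict[SpliceJunction, int], float]]:
    """Read a sample manifest TSV (sample_id, path, depth_millions).

    Junction-count paths are resolved relative to the manifest's directory.
    Returns ``(sample_id, counts, depth_millions)`` triples ready for
    :func:`assemble_reference_set`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "path": str})
    required = {"sample_id", "path", "depth_millions"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        out.append((row.sample_id, _read_counts_any(p), float(row.depth_millions)))
    return out


def assemble_reference_set(
    samples: Iterable[tuple[str, Mapping[SpliceJunction, int], float]],
    tissue_label: str = "",
) -> ReferenceSet:
    """Collate per-sample junction counts into one samples × junctions matrix.

    The junction universe is the union over samples, sorted by coordinate;
    a junction absent from a sample contributes a zero count.  Sample order
    is preserved.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one sample")
    ids = [sid for sid, _, _ in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    universe = sorted({j for _, counts, _ in samples for j in counts})
    col = {j: k for k, j in enumerate(universe)}
    matrix = np.zeros((len(samples), len(universe)), dtype=np.int64)
    depths = []
    for i, (sid, counts, d) in enumerate(samples):
        depths.append(SampleDepth(sid, d))
        for j, c in counts.items():
            matrix[i, col[j]] = c
    return ReferenceSet(depths, universe, matrix, tissue_label)


def subset_by_transcript(ref: ReferenceSet, model) -> ReferenceSet:
    """Restrict a reference set to a transcript model's junctions.

    The returned columns are exactly the model's junctions in model order;
    junctions never observed in the cohort (including strand mismatches)
    appear as all-zero columns.
    """
    junctions = list(model.junctions)
    if not junctions:
        raise ValueError(
            f"transcript model {getattr(model, 'transcript_id', model)!r} has no "
            "junctions (single-exon transcripts have no junctions and no MRSD)"
        )
    matrix = np.column_stack([ref.column(j) for j in junctions])
    return ReferenceSet(list(ref.samples), junctions, matrix, ref.tissue_label)
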