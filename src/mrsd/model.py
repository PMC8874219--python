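"""Minimum required sequencing depth (MRSD) estimation.

For a transcript with junction read counts ``R`` in a control sample
sequenced to depth ``d`` million uniquely mapping reads, the per-sample
required depth for ``r``-read coverage of proportion ``p`` of junctions is

    MRSD = r · d / R_p        (millions of reads)

where ``R_p`` is the read count at the order-statistic position of ``R``
(ascending) at which proportion ``p`` of the counts are greater than or
equal to it.  ``R_p = 0`` means no finite depth achieves the target in
that sample and the transcript is *unfeasible* there.  Across the ``n``
control samples, the reported MRSD is the ⌈m·n⌉-th smallest per-sample
value (unfeasible = +∞), i.e. the depth that holds true for at least
proportion ``m`` of controls.  No interpolation is used anywhere: read
counts are integers and interpolation would manufacture unobserved values.

The public surface follows the estimator/results idiom:
``MRSDModel(reference_set, transcript_models).fit(params)`` returns an
:class:`MRSDResults` carrying the per-transcript table, feasibility
classes, per-sample detail and a text ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .junctions import ReferenceSet, subset_by_transcript
from .transcripts import TranscriptModel

__all__ = [
    "UNFEASIBLE",
    "MRSDParameters",
    "MRSDResult",
    "MRSDModel",
    "MRSDResults",
    "order_counts",
    "critical_count",
    "per_sample_mrsd",
    "aggregate_mrsd",
    "compute_mrsd_table",
    "classify",
    "format_mrsd",
    "read_mrsd_tsv",
]


def read_mrsd_tsv(path) -> pd.DataFrame:
    """Read an MRSD table TSV, mapping the literal ``"unfeasible"`` back
    to +∞ in ``mrsd_millions``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str})
    df["mrsd_millions"] = [
        math.inf if str(v).strip().lower() == "unfeasible" else float(v)
        for v in df["mrsd_millions"]
    ]
    return df

#: Sentinel for "no finite sequencing depth achieves the target".
#: Rendered as the literal string ``"unfeasible"`` in all tabular output.
UNFEASIBLE = math.inf


@dataclass(frozen=True)
class MRSDParameters:
    """MRSD model parameters.

    r
        Desired reads per splice junction (default 8).
    p
        Proportion of the transcript's junctions that must reach ``r``
        reads (default 0.75).
    m
        Proportion of control samples for which the returned depth must
        hold true (default 0.95; 0.99 is the stricter suggested setting).
    """

    r: int = 8
    p: float = 0.75
    m: float = 0.95

    def __post_init__(self) -> None:
        if not (isinstance(self.r, (int, np.integer)) and self.r > 0):
            raise ValueError(f"r must be a positive integer, got {self.r!r}")
        if not 0 < self.p <= 1:
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if not 0 < self.m <= 1:
            raise ValueError(f"m must be in (0, 1], got {self.m}")


def order_counts(R: Sequence[int]) -> list[int]:
    """Ascending stable sort of a junction count vector."""
    if len(R) == 0:
        raise ValueError("empty count vector")
    return sorted(R)


def critical_count(R_ordered: Sequence[int], p: float) -> int:
    """The critical count ``R_p`` of an ascending count vector.

    ``R_p`` is the element at 1-based index ``⌊n·(1−p)⌋ + 1`` — the largest
    index whose suffix proportion ``(n − i + 1)/n`` is still ≥ p, i.e. the
    count that proportion ``p`` of the junctions meet or exceed.
    """
    n = len(R_ordered)
    if n == 0:
        raise ValueError("empty count vector")
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    # Largest 1-based i with (n − i + 1)/n ≥ p  ⇔  i = n + 1 − ⌈p·n⌉
    # (equals ⌊n(1−p)⌋ + 1 in exact arithmetic); small guard against
    # p·n landing a ulp above an integer.
    i = n + 1 - int(math.ceil(p * n - 1e-9))
    i = min(max(i, 1), n)
    return int(R_ordered[i - 1])


def per_sample_mrsd(r: int, R_p: int, d: float) -> float:
    """Required depth (millions of reads) for one sample: ``r·d/R_p``.

    Returns ``UNFEASIBLE`` (+∞) when ``R_p`` is 0: the sample shows no
    coverage of the critical junction, so no scaling of its depth reaches
    the target.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if R_p < 0:
        raise ValueError("R_p must be non-negative")
    if d <= 0:
        raise ValueError("d must be positive")
    if R_p == 0:
        return UNFEASIBLE
    return r * d / R_p


def aggregate_mrsd(per_sample_values: Sequence[float], m: float) -> float:
    """Aggregate per-sample required depths at MRSD parameter ``m``.

    Unfeasible samples enter as +∞; the result is the ⌈m·n⌉-th smallest
    value — the depth sufficient for at least proportion ``m`` of the
    controls — and is ``UNFEASIBLE`` when that order statistic is +∞.
    """
    n = len(per_sample_values)
    if n == 0:
        raise ValueError("no per-sample values")
    if not 0 < m <= 1:
        raise ValueError(f"m must be in (0, 1], got {m}")
    k = int(math.ceil(m * n - 1e-9))  # 1-based order-statistic index
    value = sorted(per_sample_values)[k - 1]
    return value


def classify(mrsd_value: float, threshold: float = 100.0) -> str:
    """Feasibility bracket: LOW_MRSD (< threshold), HIGH_MRSD (≥), UNFEASIBLE."""
    if math.isinf(mrsd_value):
        return "UNFEASIBLE"
    return "LOW_MRSD" if mrsd_value < threshold else "HIGH_MRSD"


def format_mrsd(value: float, digits: int = 4) -> str:
    """Render an MRSD value for tabular output (∞ → ``"unfeasible"``)."""
    return "unfeasible" if math.isinf(value) else f"{round(value, digits):g}"


@dataclass(frozen=True)
class MRSDResult:
    """Per-transcript MRSD estimate.

    ``per_sample`` holds ``(sample_id, R_p, d, per-sample MRSD)`` for each
    control; ``mrsd`` is +∞ (``UNFEASIBLE``) when fewer than ⌈m·n⌉ samples
    have nonzero critical counts.  ``error`` is set (and ``mrsd`` NaN) when
    the transcript could not be scored at all.
    """

    transcript_id: str
    gene_id: str
    tier: str
    n_junctions: int
    mrsd: float
    params: MRSDParameters
    per_sample: tuple[tuple[str, int, float, float], ...] = ()
    error: str | None = None

    @property
    def feasible(self) -> bool:
        return math.isfinite(self.mrsd)


def _score_one(
    ref: ReferenceSet, model: TranscriptModel, params: MRSDParameters
) -> MRSDResult:
    sub = subset_by_transcript(ref, model)
    # Vectorised critical count: per sample, the ⌊J(1−p)⌋-th (0-based)
    # smallest junction count.
    J = sub.counts.shape[1]
    i0 = J - int(math.ceil(params.p * J - 1e-9))  # 0-based, mirrors critical_count
    i0 = min(max(i0, 0), J - 1)
    ordered = np.sort(sub.counts, axis=1)
    rp = ordered[:, i0].astype(np.int64)
    depths = sub.depths
    with np.errstate(divide="ignore"):
        values = np.where(rp > 0, params.r * depths / np.where(rp > 0, rp, 1), UNFEASIBLE)
    mrsd = aggregate_mrsd(values.tolist(), params.m)
    per_sample = tuple(
        (s.sample_id, int(k), float(d), float(v))
        for s, k, d, v in zip(sub.samples, rp, depths, values)
    )
    return MRSDResult(
        transcript_id=model.transcript_id,
        gene_id=model.gene_id,
        tier=model.tier,
        n_junctions=model.n_junctions,
        mrsd=float(mrsd),
        params=params,
        per_sample=per_sample,
    )


def compute_mrsd_table(
    ref: ReferenceSet,
    models: Iterable[TranscriptModel],
    params: MRSDParameters | None = None,
) -> list[MRSDResult]:
    """Score every transcript model against a reference set.

    A model that cannot be scored (e.g. no junctions) yields a
    per-transcript error record rather than failing the whole table.
    Results do not depend on the order of samples in the reference set.
    """
    if ref.n_samples == 0:
        raise ValueError("reference set has no samples")
    params = params or MRSDParameters()
    out: list[MRSDResult] = []
    for model in models:
        try:
            out.append(_score_one(ref, model, params))
        except (ValueError, AttributeError) as exc:
            out.append(
                MRSDResult(
                    transcript_id=getattr(model, "transcript_id", str(model)),
                    gene_id=getattr(model, "gene_id", ""),
                    tier=getattr(model, "tier", "gencode_union"),
                    n_junctions=0,
                    mrsd=math.nan,
                    params=params,
                    error=str(exc),
                )
            )
    return out


class MRSDModel:
    """Sequencing-depth requirement model for a control cohort.

    Parameters
    ----------
    reference_set
        Control-cohort junction counts (:class:`~mrsd.junctions.ReferenceSet`).
    transcript_models
        One selected junction-set model per gene/transcript to score.

    Examples
    --------
    >>> model = MRSDModel(ref, models)          # doctest: +SKIP
    >>> res = model.fit(r=8, p=0.75, m=0.95)    # doctest: +SKIP
    >>> res.to_frame().head()                   # doctest: +SKIP
    """

    def __init__(
        self,
        reference_set: ReferenceSet,
        transcript_models: Sequence[TranscriptModel],
    ):
        if reference_set.n_samples < 1:
            raise ValueError("reference set must contain at least one sample")
        self.reference_set = reference_set
        self.transcript_models = list(transcript_models)

    @classmethod
    def from_files(
        cls,
        manifest_path,
        gtf_path,
        mane_path=None,
        refseq_gtf_path=None,
        tissue_label: str = "",
    ) -> "MRSDModel":
        """Build from a sample manifest and annotation files.

        The manifest is a TSV (sample_id, path, depth_millions) pointing at
        STAR ``SJ.out.tab`` or generic junction TSV files; the GTF provides
        the working annotation, with optional MANE transcript list
        (TSV: gene_id, transcript_id) and RefSeq GTF for the selection
        hierarchy.
        """
        from .junctions import assemble_reference_set, read_manifest
        from .transcripts import gtf_to_junctions, select_transcript

        ref = assemble_reference_set(read_manifest(manifest_path), tissue_label)
        gencode = gtf_to_junctions(gtf_path)
        refseq = gtf_to_junctions(refseq_gtf_path) if refseq_gtf_path else {}
        mane_map: dict[str, set[str]] = {}
        if mane_path:
            mane_df = pd.read_csv(mane_path, sep="\t", dtype=str)
            for row in mane_df.itertuples(index=False):
                mane_map.setdefault(row.gene_id, set()).add(row.transcript_id)
        models = []
        for gid, txs in gencode.items():
            mane_txs = {
                tid: jx
                for tid, jx in txs.items()
                if tid in mane_map.get(gid, ())
            }
            try:
                models.append(
                    select_transcript(gid, mane_txs, refseq.get(gid, {}), txs)
                )
            except ValueError:
                continue  # single-exon gene: nothing to score
        return cls(ref, models)

    def fit(
        self,
        params: MRSDParameters | None = None,
        *,
        r: int | None = None,
        p: float | None = None,
        m: float | None = None,
        threshold: float = 100.0,
    ) -> "MRSDResults":
        """Estimate MRSD for every transcript model.

        Either pass a full :class:`MRSDParameters` or override individual
        parameters by keyword.  ``threshold`` (millions of reads) sets the
        LOW/HIGH feasibility bracket boundary.
        """
        base = params or MRSDParameters()
        overrides = {
            k: v for k, v in {"r": r, "p": p, "m": m}.items() if v is not None
        }
        if overrides:
            base = replace(base, **overrides)
        results = compute_mrsd_table(self.reference_set, self.transcript_models, base)
        return MRSDResults(self, base, results, threshold)


class MRSDResults:
    """Fitted MRSD table with feasibility classes and prediction helpers."""

    def __init__(
        self,
        model: MRSDModel,
        params: MRSDParameters,
        results: list[MRSDResult],
        threshold: float = 100.0,
    ):
        self.model = model
        self.params = params
        self.results = results
        self.threshold = threshold

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    @property
    def mrsd(self) -> pd.Series:
        """Per-transcript MRSD in millions of reads (+∞ = unfeasible)."""
        return pd.Series(
            {res.transcript_id: res.mrsd for res in self.results}, name="mrsd_millions"
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular results; unfeasible is +∞ here, a string only on disk."""
        rows = []
        for res in self.results:
            rows.append(
                {
                    "gene_id": res.gene_id,
                    "transcript_id": res.transcript_id,
                    "tier": res.tier,
                    "n_junctions": res.n_junctions,
                    "mrsd_millions": res.mrsd,
                    "class": (
                        "ERROR" if res.error else classify(res.mrsd, self.threshold)
                    ),
                    "r": res.params.r,
                    "p": res.params.p,
                    "m": res.params.m,
                    "n_samples": self.model.reference_set.n_samples,
                    "tissue_label": self.model.reference_set.tissue_label,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df["mrsd_millions"] = [
            "unfeasible" if math.isinf(v) else ("" if math.isnan(v) else f"{v:.4f}")
            for v in df["mrsd_millions"]
        ]
        df.to_csv(path, sep="\t", index=False)

    def predict(self, depth_millions: float) -> pd.Series:
        """Would a run of ``depth_millions`` reads suffice per transcript?

        Positive iff the transcript's MRSD is finite and ≤ the offered
        depth; unfeasible and errored transcripts predict insufficient.
        """
        return pd.Series(
            {
                res.transcript_id: bool(
                    math.isfinite(res.mrsd) and depth_millions >= res.mrsd
                )
                for res in self.results
            },
            name="predicted_sufficient",
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        finite = [res.mrsd for res in self.results if res.error is None and math.isfinite(res.mrsd)]
        n_unf = sum(
            1 for res in self.results if res.error is None and math.isinf(res.mrsd)
        )
        n_err = sum(1 for res in self.results if res.error is not None)
        classes = (
            self.to_frame()["class"].value_counts().to_dict() if self.results else {}
        )
        ref = self.model.reference_set
        lines = [
            "MRSD model results",
            "==================",
            f"tissue:            {ref.tissue_label or '(unlabelled)'}",
            f"control samples:   {ref.n_samples}",
            f"median depth d:    {np.median(ref.depths):.1f} M reads",
            f"parameters:        r={self.params.r}, p={self.params.p}, m={self.params.m}",
            f"transcripts:       {len(self.results)}",
            f"  feasible:        {len(finite)}"
            + (
                f" (median MRSD {np.median(finite):.2f} M reads)"
                if finite
                else ""
            ),
            f"  unfeasible:      {n_unf}",
            f"  errors:          {n_err}",
            f"brackets (<{self.threshold:g} M): "
            f"LOW={classes.get('LOW_MRSD', 0)}, HIGH={classes.get('HIGH_MRSD', 0)}, "
            f"UNFEASIBLE={classes.get('UNFEASIBLE', 0)}",
        ]
        return "\n".join(lines)
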