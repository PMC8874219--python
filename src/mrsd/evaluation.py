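"""Validation experiments for depth predictions and event ranking.

Covers: PPV/NPV of depth-sufficiency predictions on independent samples,
held-out calibration at exactly the predicted depth, binomial read
thinning (gene-level downsampling), rank-stability under thinning,
bootstrap background event counts across control-cohort sizes, the
MRSD-versus-TPM comparison, and gene-panel / VUS feasibility reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import SpliceEventScorer, adjoining_canonical
from .junctions import ReferenceSet, SpliceJunction, subset_by_transcript
from .model import MRSDResults, classify
from .transcripts import TranscriptModel

__all__ = [
    "required_junctions",
    "coverage_achieved",
    "PredictionEvaluation",
    "evaluate_ppv_npv",
    "evaluate_reference",
    "calibration_coverage",
    "CalibrationReport",
    "downsample_gene",
    "rank_stability_experiment",
    "BootstrapSummary",
    "bootstrap_background",
    "TpmComparison",
    "compare_tpm",
    "panel_report",
    "vus_feasibility",
]


def required_junctions(p: float, n_junctions: int) -> int:
    """⌈p·n⌉ with a guard against p·n landing a ulp above an integer."""
    return max(1, int(math.ceil(p * n_junctions - 1e-9)))


def coverage_achieved(counts: Sequence[int], r: int, p: float) -> bool:
    """Did ≥ ⌈p·n⌉ junctions receive ≥ r reads?  (Same rule as the MRSD
    critical count, so self-evaluation is exactly consistent.)"""
    counts = np.asarray(counts)
    return int((counts >= r).sum()) >= required_junctions(p, len(counts))


@dataclass
class PredictionEvaluation:
    """PPV/NPV of depth-sufficiency predictions.

    ``ppv``/``npv`` are NaN when there were no positive/negative
    predictions.  ``outcomes`` has one row per (transcript, sample) with
    the predicted and achieved flags.
    """

    ppv: float
    npv: float
    n_positive: int
    n_negative: int
    outcomes: pd.DataFrame

    def summary(self) -> str:
        return (
            f"PPV {self.ppv:.3f} over {self.n_positive} positive predictions; "
            f"NPV {self.npv:.3f} over {self.n_negative} negative predictions"
        )


def _models_by_transcript(results: MRSDResults) -> dict[str, TranscriptModel]:
    return {m.transcript_id: m for m in results.model.transcript_models}


def _outcome_rows(
    results: MRSDResults,
    counts_for: Mapping[str, np.ndarray],
    depth: float,
    sample_id: str,
) -> list[dict]:
    params = results.params
    rows = []
    for res in results.results:
        if res.error is not None:
            continue
        counts = counts_for.get(res.transcript_id)
        if counts is None:
            continue
        positive = math.isfinite(res.mrsd) and depth >= res.mrsd
        achieved = coverage_achieved(counts, params.r, params.p)
        rows.append(
            {
                "transcript_id": res.transcript_id,
                "sample_id": sample_id,
                "predicted_sufficient": positive,
                "achieved": achieved,
            }
        )
    return rows


def _finish(rows: list[dict]) -> PredictionEvaluation:
    df = pd.DataFrame(
        rows, columns=["transcript_id", "sample_id", "predicted_sufficient", "achieved"]
    )
    pos = df[df["predicted_sufficient"]]
    neg = df[~df["predicted_sufficient"]]
    ppv = float(pos["achieved"].mean()) if len(pos) else math.nan
    npv = float((~neg["achieved"]).mean()) if len(neg) else math.nan
    return PredictionEvaluation(ppv, npv, len(pos), len(neg), df)


def evaluate_ppv_npv(
    results: MRSDResults,
    test_counts: Mapping[SpliceJunction, int],
    depth_millions: float,
    sample_id: str = "test",
) -> PredictionEvaluation:
    """Score depth-sufficiency predictions against one independent sample.

    Positive prediction: the sample's depth meets or exceeds the finite
    MRSD (unfeasible transcripts always predict insufficient).  Achieved:
    ≥ ⌈p·n⌉ of the transcript's junctions carry ≥ r reads in the sample.
    """
    models = _models_by_transcript(results)
    counts_for = {
        tid: np.array([test_counts.get(j, 0) for j in m.junctions])
        for tid, m in models.items()
    }
    return _finish(_outcome_rows(results, counts_for, depth_millions, sample_id))


def evaluate_reference(
    results: MRSDResults, test_set: ReferenceSet
) -> PredictionEvaluation:
    """Pool PPV/NPV over every sample of an independent reference set."""
    models = _models_by_transcript(results)
    rows: list[dict] = []
    submatrices = {
        tid: subset_by_transcript(test_set, m).counts for tid, m in models.items()
    }
    for i, sample in enumerate(test_set.samples):
        counts_for = {tid: sub[i] for tid, sub in submatrices.items()}
        rows.extend(
            _outcome_rows(results, counts_for, sample.depth_millions, sample.sample_id)
        )
    return _finish(rows)


@dataclass
class CalibrationReport:
    """Held-out coverage at exactly the predicted depth.

    ``pooled_coverage`` averages achievement over all (transcript,
    held-out sample) pairs; ``mc_se`` is the Monte-Carlo standard error at
    the resolution of the held-out samples (the MC draws, shared across
    transcripts): sqrt(m(1−m)/n_heldout).
    """

    m: float
    n_heldout: int
    n_transcripts: int
    pooled_coverage: float
    per_transcript: pd.DataFrame

    @property
    def mc_se(self) -> float:
        return math.sqrt(self.m * (1 - self.m) / self.n_heldout)


def calibration_coverage(
    synth,
    results: MRSDResults,
    n_heldout: int = 500,
    seed: int = 1,
) -> CalibrationReport:
    """Sequence fresh same-model samples at each transcript's predicted
    MRSD and measure how often the coverage target is achieved.

    ``synth`` is a generated cohort (``SyntheticReferenceSet``) providing
    ``draw_samples``.  Held-out samples are drawn once at the deepest
    finite MRSD and binomially thinned per transcript to its exact
    predicted depth — thinning a count drawn at depth D down to depth t is
    distributionally a fresh draw at depth t.
    """
    finite = [
        res for res in results.results if res.error is None and math.isfinite(res.mrsd)
    ]
    if not finite:
        raise ValueError("no feasible transcripts to calibrate")
    d_max = max(res.mrsd for res in finite)
    heldout = synth.draw_samples([d_max] * n_heldout, seed=seed)
    rng = np.random.default_rng(seed + 1)
    params = results.params
    models = _models_by_transcript(results)
    rows = []
    hits = 0
    total = 0
    for res in finite:
        model = models[res.transcript_id]
        counts = subset_by_transcript(heldout, model).counts
        thinned = rng.binomial(counts, res.mrsd / d_max)
        need = required_junctions(params.p, model.n_junctions)
        achieved = (thinned >= params.r).sum(axis=1) >= need
        cov = float(achieved.mean())
        hits += int(achieved.sum())
        total += len(achieved)
        rows.append(
            {
                "transcript_id": res.transcript_id,
                "mrsd_millions": res.mrsd,
                "coverage": cov,
            }
        )
    return CalibrationReport(
        m=params.m,
        n_heldout=n_heldout,
        n_transcripts=len(finite),
        pooled_coverage=hits / total,
        per_transcript=pd.DataFrame(rows),
    )


def downsample_gene(
    counts: Mapping[SpliceJunction, int] | np.ndarray,
    fraction_removed: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Binomially thin junction counts, retaining each read with
    probability 1 − fraction_removed.

    Thinning is the exact count-marginal of removing a uniform random
    subset of reads; it mimics reduced expression of the gene.
    """
    if not 0 <= fraction_removed < 1:
        raise ValueError("fraction_removed must be in [0, 1)")
    rng = rng or np.random.default_rng(seed)
    keep = 1.0 - fraction_removed
    if fraction_removed == 0:
        return dict(counts) if isinstance(counts, Mapping) else np.asarray(counts).copy()
    if isinstance(counts, Mapping):
        keys = sorted(counts)
        vals = rng.binomial([counts[k] for k in keys], keep)
        return {k: int(v) for k, v in zip(keys, vals)}
    return rng.binomial(np.asarray(counts), keep)


def rank_stability_experiment(
    case_counts: Mapping[SpliceJunction, int],
    scorer: SpliceEventScorer,
    events_of_interest: Sequence[SpliceJunction],
    fractions: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    seed: int = 0,
    case_id: str = "case",
    min_reads: int = 2,
    min_nrc: float = 0.25,
) -> pd.DataFrame:
    """Re-run event scoring at successive thinning levels.

    Returns one row per (fraction, event of interest) with the event's
    read count, rank and a detection flag; an undetected event (lost to
    thinning or filtering) has NaN read count and rank.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        thinned = downsample_gene(case_counts, f, rng=rng)
        res = scorer.fit(
            thinned, case_id=case_id, min_reads=min_reads, min_nrc=min_nrc
        )
        by_junction = {ev.junction: ev for ev in res.ranked}
        for j in events_of_interest:
            ev = by_junction.get(j)
            rows.append(
                {
                    "fraction_removed": f,
                    "chrom": j.chrom,
                    "start": j.start,
                    "end": j.end,
                    "strand": j.strand,
                    "read_count": ev.read_count if ev else math.nan,
                    "rank": ev.rank if ev else math.nan,
                    "detected": ev is not None,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BootstrapSummary:
    """Background event counts over bootstrap control draws."""

    control_size: int
    n_bootstraps: int
    median_singletons: float
    median_non_singletons: float
    singleton_counts: np.ndarray
    non_singleton_counts: np.ndarray


def _case_event_arrays(
    case_counts: Mapping[SpliceJunction, int],
    control_pool: ReferenceSet,
    models: Sequence[TranscriptModel],
):
    """Precompute, per scoreable case junction: case NRC/reads, pool-control
    NRC matrix and presence matrix (each control against its own canonical
    counts).  Junctions with undefined case NRC are excluded."""
    from .events import _control_nrc, compute_nrc

    case_nrc: list[float] = []
    case_reads: list[int] = []
    nrc_cols: list[np.ndarray] = []
    presence_cols: list[np.ndarray] = []
    for model in models:
        chrom, lo, hi = model.span
        in_gene = [
            j
            for j, c in case_counts.items()
            if c > 0 and j.chrom == chrom and j.start >= lo and j.end <= hi
        ]
        canon_cols = {j: control_pool.column(j) for j in model.junctions}
        for j in sorted(in_gene):
            try:
                nrc = compute_nrc(j, case_counts, model)
            except ValueError:
                continue
            adjoin = adjoining_canonical(j, model)
            ctrl_counts = control_pool.column(j)
            cmax = (
                np.max(np.column_stack([canon_cols[cj] for cj in adjoin]), axis=1)
                if adjoin
                else np.zeros(control_pool.n_samples, dtype=np.int64)
            )
            col = np.array(
                [
                    _control_nrc(j, int(c), int(cm))
                    for c, cm in zip(ctrl_counts, cmax)
                ]
            )
            case_nrc.append(nrc)
            case_reads.append(int(case_counts[j]))
            nrc_cols.append(col)
            presence_cols.append(ctrl_counts > 0)
    if not case_nrc:
        raise ValueError("case sample has no scoreable junctions in any model")
    return (
        np.array(case_nrc),
        np.array(case_reads),
        np.column_stack(nrc_cols),
        np.column_stack(presence_cols),
    )


def bootstrap_background(
    case_counts: Mapping[SpliceJunction, int],
    control_pool: ReferenceSet,
    models: Sequence[TranscriptModel],
    control_size: int,
    n_bootstraps: int = 2000,
    seed: int = 0,
    min_reads: int = 1,
) -> BootstrapSummary:
    """Background splice-event counts versus control-cohort size.

    Per bootstrap replicate, ``control_size`` controls are drawn from the
    pool with replacement and the case's junctions are filtered exactly as
    in event scoring (retained iff no drawn control carries the junction —
    a singleton — or the case NRC strictly exceeds every drawn control's).
    Control NRCs against their own canonical counts do not depend on the
    draw, so they are precomputed once and each replicate reduces to
    max/any over drawn rows; this is equivalent to re-running the event
    filter per replicate.  Bit-reproducible for a fixed seed.
    """
    if control_pool.n_samples < control_size:
        raise ValueError("control pool smaller than requested control size")
    case_nrc, case_reads, nrc_matrix, presence = _case_event_arrays(
        case_counts, control_pool, models
    )
    rng = np.random.default_rng(seed)
    readable = case_reads >= min_reads
    singles = np.empty(n_bootstraps, dtype=np.int64)
    non_singles = np.empty(n_bootstraps, dtype=np.int64)
    for b in range(n_bootstraps):
        idx = rng.integers(0, control_pool.n_samples, size=control_size)
        any_present = presence[idx].any(axis=0)
        ctrl_max = nrc_matrix[idx].max(axis=0)
        retained = readable & (case_nrc > ctrl_max)
        singles[b] = int((retained & ~any_present).sum())
        non_singles[b] = int((retained & any_present).sum())
    return BootstrapSummary(
        control_size=control_size,
        n_bootstraps=n_bootstraps,
        median_singletons=float(np.median(singles)),
        median_non_singletons=float(np.median(non_singles)),
        singleton_counts=singles,
        non_singleton_counts=non_singles,
    )


@dataclass
class TpmComparison:
    """log–log regression of MRSD on TPM plus bracket overlap."""

    r_squared: float
    slope: float
    intercept: float
    n_genes: int
    bracket_summary: pd.DataFrame


def compare_tpm(
    mrsd_table: pd.DataFrame, tpm_table: pd.DataFrame, threshold: float = 100.0
) -> TpmComparison:
    """Correlate predicted depth requirements with relative expression.

    The regression uses log10(MRSD) on log10(TPM) over genes with finite
    MRSD and TPM > 0; unfeasible genes and zero TPMs are excluded from the
    log-transformed comparison but appear in the bracket summary, which
    tabulates the TPM distribution within each feasibility bracket.
    Expects columns ``gene_id``/``mrsd_millions`` and ``gene_id``/``tpm``.
    """
    merged = mrsd_table.merge(tpm_table, on="gene_id", how="inner")
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared genes between MRSD and TPM tables")
    merged["bracket"] = [
        classify(v, threshold) for v in merged["mrsd_millions"]
    ]
    usable = merged[
        np.isfinite(merged["mrsd_millions"]) & (merged["tpm"] > 0)
    ]
    if len(usable) < 3:
        raise ValueError("fewer than 3 genes with finite MRSD and nonzero TPM")
    fit = stats.linregress(
        np.log10(usable["tpm"]), np.log10(usable["mrsd_millions"])
    )
    bracket = (
        merged.groupby("bracket")["tpm"]
        .agg(["count", "median", lambda s: s.quantile(0.25), lambda s: s.quantile(0.75)])
        .rename(columns={"<lambda_0>": "q25", "<lambda_1>": "q75"})
        .reset_index()
    )
    return TpmComparison(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_genes=len(usable),
        bracket_summary=bracket,
    )


def panel_report(
    mrsd_tables: Mapping[str, pd.DataFrame],
    panels: pd.DataFrame,
    threshold: float = 100.0,
) -> pd.DataFrame:
    """Per-panel, per-tissue proportion of low-MRSD genes and best tissue.

    ``panels`` needs columns ``panel_name``/``gene_id`` (a ``rating``
    column, if present, is filtered to ``green`` first).  Tissues tying
    for the highest proportion are all reported (``best_tissue`` is a
    comma-joined list).  Panels with no mappable genes are flagged and
    carry NaN proportions.
    """
    if "rating" in panels.columns:
        panels = panels[panels["rating"].str.lower() == "green"]
    class_by_tissue = {}
    for tissue, table in mrsd_tables.items():
        class_by_tissue[tissue] = {
            row.gene_id: classify(row.mrsd_millions, threshold)
            for row in table.itertuples(index=False)
        }
    rows = []
    for panel_name, group in panels.groupby("panel_name"):
        genes = sorted(set(group["gene_id"]))
        props: dict[str, float] = {}
        for tissue, classes in class_by_tissue.items():
            mapped = [g for g in genes if g in classes]
            props[tissue] = (
                sum(classes[g] == "LOW_MRSD" for g in mapped) / len(mapped)
                if mapped
                else math.nan
            )
        defined = {t: v for t, v in props.items() if not math.isnan(v)}
        if defined:
            best = max(defined.values())
            best_tissues = sorted(t for t, v in defined.items() if v == best)
        else:
            best_tissues = []
        rows.append(
            {
                "panel_name": panel_name,
                "n_genes": len(genes),
                **{f"prop_low_{t}": v for t, v in props.items()},
                "best_tissue": ",".join(best_tissues),
                "skipped": not defined,
            }
        )
    return pd.DataFrame(rows)


_VUS_LABELS = {
    "uncertain significance",
    "conflicting interpretations of pathogenicity",
}


def vus_feasibility(
    variant_table: pd.DataFrame,
    mrsd_tables: Mapping[str, pd.DataFrame],
    spliceai_min: float = 0.5,
    threshold: float = 100.0,
) -> tuple[pd.DataFrame, dict]:
    """Filter variants of uncertain significance with predicted splice
    impact and annotate per-tissue feasibility.

    Variants are retained when their clinical significance is "uncertain
    significance" or "conflicting interpretations of pathogenicity" and
    their splice-impact score is ≥ ``spliceai_min`` (inclusive).  Each
    retained variant is annotated LOW_MRSD/HIGH_MRSD/UNFEASIBLE per tissue
    via its gene, or "unscored" when the gene is absent.  The summary
    reports the fraction of retained variants in a low-MRSD gene in at
    least one tissue.
    """
    required = {"variant_id", "gene_id", "clinical_significance", "spliceai_max"}
    missing = required - set(variant_table.columns)
    if missing:
        raise ValueError(f"variant table missing columns {sorted(missing)}")
    sig = variant_table["clinical_significance"].str.lower()
    kept = variant_table[
        sig.isin(_VUS_LABELS) & (variant_table["spliceai_max"] >= spliceai_min)
    ].copy()
    class_by_tissue = {
        tissue: {
            row.gene_id: classify(row.mrsd_millions, threshold)
            for row in table.itertuples(index=False)
        }
        for tissue, table in mrsd_tables.items()
    }
    low_any = np.zeros(len(kept), dtype=bool)
    for tissue, classes in class_by_tissue.items():
        col = [classes.get(g, "unscored") for g in kept["gene_id"]]
        kept[f"class_{tissue}"] = col
        low_any |= np.array([c == "LOW_MRSD" for c in col])
    kept["low_mrsd_any_tissue"] = low_any
    summary = {
        "n_input": int(len(variant_table)),
        "n_retained": int(len(kept)),
        "fraction_low_any_tissue": float(low_any.mean()) if len(kept) else math.nan,
    }
    return kept, summary
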