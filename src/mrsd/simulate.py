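"""Synthetic reference sets, case samples and annotation fixtures.

The generator emulates the statistical structure of a control RNA-seq
splice-junction cohort:

* per-sample library size ``d`` (millions of uniquely mapping reads) drawn
  log-normally around a typical bulk poly-A depth;
* per-gene expression drawn log-normally on the scale of *junction reads
  per million*, spanning clearly-feasible to unfeasible genes;
* junction counts drawn negative-binomially (gamma–Poisson) around
  ``expr_g · d_s · bias_{g,j}``, with ``var = μ + dispersion·μ²``
  (``dispersion = 0`` gives the Poisson limit, ``exact_counts`` the
  noiseless rounded-mean limit);
* optional 3′ bias: a multiplicative ramp across a gene's junction order
  (geometric mean 1) that depresses 5′ junction coverage without changing
  total gene expression, mimicking the coverage unevenness of poly-A
  enriched libraries.

Every generated dataset carries machine-readable ground truth so tests
assert against known quantities, never magic numbers.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .junctions import ReferenceSet, SampleDepth, SpliceJunction
from .transcripts import TranscriptModel

__all__ = [
    "GeneratorConfig",
    "SyntheticReferenceSet",
    "InjectedEvent",
    "AnnotationFixture",
    "generate_reference_set",
    "inject_aberrant_event",
    "generate_annotation_fixture",
    "models_to_gtf",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic junction-count generator.

    Defaults describe the study conditions used throughout the tests:
    150 control samples (the size of the larger reference cohorts),
    library sizes log-normal around 75 M uniquely mapping reads, per-gene
    junction rates log-normal with median 0.3 reads per million and wide
    spread (σ=1.5) so the cohort spans low- and high-requirement genes as
    well as unfeasible ones, and moderate bulk-RNA-seq overdispersion
    (var = μ + 0.1 μ²).
    """

    n_samples: int = 150
    n_genes: int = 200
    junctions_per_gene: tuple[int, int] = (3, 15)
    depth_mean_millions: float = 75.0
    depth_log_sd: float = 0.3
    expression_log_median: float = math.log(0.3)
    expression_log_sd: float = 1.5
    dispersion: float = 0.1
    three_prime_bias: float = 0.0
    exact_counts: bool = False
    tissue_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        lo, hi = self.junctions_per_gene
        if not (2 <= lo <= hi):
            raise ValueError("junctions_per_gene must satisfy 2 <= lo <= hi")
        if self.dispersion < 0 or self.three_prime_bias < 0:
            raise ValueError("dispersion and three_prime_bias must be >= 0")
        if self.depth_mean_millions <= 0:
            raise ValueError("depth_mean_millions must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        data = json.loads(Path(path).read_text())
        if "junctions_per_gene" in data:
            data["junctions_per_gene"] = tuple(data["junctions_per_gene"])
        return cls(**data)


def _gene_junctions(gene_idx: int, n_junctions: int) -> list[SpliceJunction]:
    """Deterministic junction coordinates: gene g occupies a 1 Mb block on
    chr1 with 100 bp exons every 2 kb."""
    base = 1_000_000 * (gene_idx + 1)
    return [
        SpliceJunction("chr1", base + 2000 * i + 101, base + 2000 * (i + 1) - 1, "+")
        for i in range(n_junctions)
    ]


def _bias_weights(n_junctions: int, strength: float) -> np.ndarray:
    """Multiplicative 3′ ramp with geometric mean 1 (last junction = most
    3′ = best covered)."""
    if strength == 0 or n_junctions == 1:
        return np.ones(n_junctions)
    x = np.linspace(-0.5, 0.5, n_junctions)
    return np.exp(strength * x)


@dataclass
class SyntheticReferenceSet:
    """A generated cohort plus its ground truth.

    ``truth`` has one row per gene: expression (junction reads per million),
    TPM (relative expression scaled to 1e6 total), junction count.
    ``per_million`` gives each junction's expected unique-read count per
    million reads of depth (expression × bias), aligned with
    ``reference_set.junctions``.
    """

    reference_set: ReferenceSet
    models: list[TranscriptModel]
    truth: pd.DataFrame
    per_million: np.ndarray
    config: GeneratorConfig

    def draw_samples(
        self,
        depths: Sequence[float],
        seed: int,
        sample_prefix: str = "heldout",
    ) -> ReferenceSet:
        """Fresh samples from the same generative model at given depths."""
        rng = np.random.default_rng(seed)
        depths = np.asarray(depths, dtype=float)
        mu = depths[:, None] * self.per_million[None, :]
        counts = _draw_counts(mu, self.config, rng)
        samples = [
            SampleDepth(f"{sample_prefix}{i:04d}", float(d))
            for i, d in enumerate(depths)
        ]
        return ReferenceSet(
            samples,
            list(self.reference_set.junctions),
            counts,
            self.config.tissue_label + "_heldout",
        )


def _draw_counts(
    mu: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.exact_counts:
        return np.rint(mu).astype(np.int64)
    if config.dispersion == 0:
        return rng.poisson(mu).astype(np.int64)
    k = 1.0 / config.dispersion
    lam = rng.gamma(shape=k, scale=mu / k)
    return rng.poisson(lam).astype(np.int64)


def generate_reference_set(config: GeneratorConfig) -> SyntheticReferenceSet:
    """Generate a reference cohort with known per-gene ground truth."""
    rng = np.random.default_rng(config.seed)
    n_junc_per_gene = rng.integers(
        config.junctions_per_gene[0],
        config.junctions_per_gene[1] + 1,
        size=config.n_genes,
    )
    expr = np.exp(
        rng.normal(config.expression_log_median, config.expression_log_sd, config.n_genes)
    )
    # mean-preserving lognormal depths
    sigma = config.depth_log_sd
    depths = np.exp(
        rng.normal(
            math.log(config.depth_mean_millions) - 0.5 * sigma**2,
            sigma,
            config.n_samples,
        )
    )

    junctions: list[SpliceJunction] = []
    per_million_parts: list[np.ndarray] = []
    models: list[TranscriptModel] = []
    rows = []
    for g in range(config.n_genes):
        J = int(n_junc_per_gene[g])
        jx = _gene_junctions(g, J)
        bias = _bias_weights(J, config.three_prime_bias)
        junctions.extend(jx)
        per_million_parts.append(expr[g] * bias)
        gid = f"GENE{g:04d}"
        models.append(TranscriptModel(gid, f"TX{g:04d}", "gencode_union", tuple(jx)))
        rows.append(
            {
                "gene_id": gid,
                "transcript_id": f"TX{g:04d}",
                "expr_per_million": expr[g],
                "n_junctions": J,
            }
        )
    per_million = np.concatenate(per_million_parts)
    truth = pd.DataFrame(rows)
    truth["tpm"] = truth["expr_per_million"] / truth["expr_per_million"].sum() * 1e6

    mu = depths[:, None] * per_million[None, :]
    counts = _draw_counts(mu, config, rng)
    samples = [
        SampleDepth(f"ctrl{i:04d}", float(d)) for i, d in enumerate(depths)
    ]
    ref = ReferenceSet(samples, junctions, counts, config.tissue_label)
    return SyntheticReferenceSet(ref, models, truth, per_million, config)


@dataclass(frozen=True)
class InjectedEvent:
    """Ground truth for one injected aberrant junction."""

    junction: SpliceJunction
    gene_id: str
    reads: int
    target_nrc: float
    attained_nrc: float
    singleton: bool
    anchor: SpliceJunction
    anchor_reads: int
    control_ids: tuple[str, ...] = ()
    max_control_nrc: float | None = None


def inject_aberrant_event(
    case_counts: dict[SpliceJunction, int],
    model: TranscriptModel,
    target_nrc: float,
    reads: int,
    singleton: bool = True,
    controls: ReferenceSet | None = None,
    n_carrier_controls: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[dict[SpliceJunction, int], ReferenceSet | None, InjectedEvent]:
    """Add a novel junction to a case sample with a prescribed NRC.

    The novel junction shares its donor with the model's first canonical
    junction (the *anchor*); the case's anchor count is set so that
    ``NRC = reads / anchor ≈ target_nrc`` (the nearest attainable value
    with integer counts is recorded in the truth record).  For
    non-singleton events, carrier controls receive support at roughly half
    the case NRC — always strictly below it — so the event remains
    retainable.  Inputs are not mutated; modified copies are returned.
    """
    if target_nrc <= 0:
        raise ValueError("target_nrc must be positive")
    if reads < 1:
        raise ValueError("reads must be >= 1")
    rng = rng or np.random.default_rng(0)
    anchor = model.junctions[0]
    width = anchor.end - anchor.start
    novel = SpliceJunction(
        anchor.chrom,
        anchor.start,
        anchor.end - max(1, width // 4),
        anchor.strand,
    )
    if novel in model.junctions:
        raise ValueError("could not place a novel junction distinct from the model")

    anchor_reads = max(1, int(round(reads / target_nrc)))
    attained = reads / anchor_reads
    case = dict(case_counts)
    case[anchor] = anchor_reads
    case[novel] = reads

    new_controls = controls
    control_ids: tuple[str, ...] = ()
    max_ctrl_nrc: float | None = None
    if not singleton:
        if controls is None:
            raise ValueError("non-singleton injection needs a control set")
        anchor_counts = controls.column(anchor)
        # carriers need enough anchor coverage that 1 supporting read keeps
        # their NRC strictly below the case's
        eligible = np.flatnonzero(anchor_counts > 2.0 / attained)
        if len(eligible) == 0:
            raise ValueError("no control has enough anchor coverage to carry the event")
        chosen = rng.choice(
            eligible, size=min(n_carrier_controls, len(eligible)), replace=False
        )
        novel_col = np.zeros(controls.n_samples, dtype=np.int64)
        ctrl_nrcs = []
        for i in chosen:
            c = max(1, int(math.floor(0.5 * attained * anchor_counts[i])))
            novel_col[i] = c
            ctrl_nrcs.append(c / anchor_counts[i])
        max_ctrl_nrc = max(ctrl_nrcs)
        control_ids = tuple(controls.samples[i].sample_id for i in sorted(chosen))
        counts = np.column_stack([controls.counts, novel_col])
        new_controls = ReferenceSet(
            list(controls.samples),
            list(controls.junctions) + [novel],
            counts,
            controls.tissue_label,
        )

    record = InjectedEvent(
        junction=novel,
        gene_id=model.gene_id,
        reads=reads,
        target_nrc=target_nrc,
        attained_nrc=attained,
        singleton=singleton,
        anchor=anchor,
        anchor_reads=anchor_reads,
        control_ids=control_ids,
        max_control_nrc=max_ctrl_nrc,
    )
    return case, new_controls, record


def _junctions_to_exons(
    junctions: Sequence[SpliceJunction], flank: int = 100
) -> list[tuple[int, int]]:
    jx = sorted(junctions)
    exons = [(jx[0].start - flank, jx[0].start - 1)]
    for a, b in zip(jx, jx[1:]):
        exons.append((a.end + 1, b.start - 1))
    exons.append((jx[-1].end + 1, jx[-1].end + flank))
    return exons


def _gtf_lines(
    gene_id: str, transcript_id: str, chrom: str, strand: str,
    exons: Sequence[tuple[int, int]], source: str = "synthetic"
) -> list[str]:
    attrs = f'gene_id "{gene_id}"; transcript_id "{transcript_id}";'
    lines = []
    for start, end in exons:
        lines.append(
            "\t".join(
                [chrom, source, "exon", str(start), str(end), ".", strand, ".", attrs]
            )
        )
    return lines


def models_to_gtf(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as a GTF of exon features (inverse of the
    junction extraction: exons fill the gaps between junctions plus
    100 bp terminal flanks)."""
    lines: list[str] = []
    for m in models:
        chrom = m.junctions[0].chrom
        strand = m.junctions[0].strand
        strand = strand if strand in "+-" else "."
        exons = _junctions_to_exons(m.junctions)
        lines.extend(_gtf_lines(m.gene_id, m.transcript_id, chrom, strand, exons))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class AnnotationFixture:
    """Paths and expected outcomes of a generated annotation fixture."""

    gencode_gtf: Path
    refseq_gtf: Path
    mane_tsv: Path
    expected_tiers: dict[str, str]  # gene_id → expected selection tier
    single_exon_genes: tuple[str, ...]


def generate_annotation_fixture(out_dir: str | Path) -> AnnotationFixture:
    """Write a small GTF + MANE/RefSeq fixture covering every selection tier.

    Genes:
      * ``MANEG`` — MANE transcript listed and fully annotation-supported;
      * ``REFSG`` — no MANE entry, two RefSeq transcripts (composite);
      * ``UNIOG`` — neither (falls to the annotation union);
      * ``MANEX`` — MANE list names a transcript absent from the working
        annotation (unsupported → falls through to RefSeq);
      * ``MONOG`` — single-exon (no junctions; selection must refuse it).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def make(gene_idx: int, n_junc: int) -> list[SpliceJunction]:
        return _gene_junctions(gene_idx, n_junc)

    gencode_lines: list[str] = []
    refseq_lines: list[str] = []
    mane_rows: list[tuple[str, str]] = []

    # MANEG: two GENCODE transcripts; tx1 is the MANE pick.
    jx = make(0, 5)
    gencode_lines += _gtf_lines(
        "MANEG", "MANEG_tx1", "chr1", "+", _junctions_to_exons(jx)
    )
    gencode_lines += _gtf_lines(
        "MANEG", "MANEG_tx2", "chr1", "+", _junctions_to_exons(jx[:3])
    )
    mane_rows.append(("MANEG", "MANEG_tx1"))

    # REFSG: GENCODE present (needed to be scoreable), RefSeq provides two
    # transcripts whose union is the composite.
    jx = make(1, 6)
    gencode_lines += _gtf_lines(
        "REFSG", "REFSG_tx1", "chr1", "+", _junctions_to_exons(jx)
    )
    refseq_lines += _gtf_lines(
        "REFSG", "NM_0001", "chr1", "+", _junctions_to_exons(jx[:4])
    )
    refseq_lines += _gtf_lines(
        "REFSG", "NM_0002", "chr1", "+", _junctions_to_exons(jx[2:])
    )

    # UNIOG: GENCODE only, two transcripts → union tier.
    jx = make(2, 4)
    gencode_lines += _gtf_lines(
        "UNIOG", "UNIOG_tx1", "chr1", "-", _junctions_to_exons(jx[:3])
    )
    gencode_lines += _gtf_lines(
        "UNIOG", "UNIOG_tx2", "chr1", "-", _junctions_to_exons(jx[1:])
    )

    # MANEX: MANE names a transcript that the working annotation lacks;
    # RefSeq catches the fall-through.
    jx = make(3, 5)
    gencode_lines += _gtf_lines(
        "MANEX", "MANEX_tx1", "chr1", "+", _junctions_to_exons(jx)
    )
    refseq_lines += _gtf_lines(
        "MANEX", "NM_0003", "chr1", "+", _junctions_to_exons(jx)
    )
    mane_rows.append(("MANEX", "NM_9999"))

    # MONOG: single exon.
    gencode_lines += _gtf_lines(
        "MONOG", "MONOG_tx1", "chr1", "+", [(9_000_000, 9_001_000)]
    )

    gencode_gtf = out_dir / "gencode.gtf"
    refseq_gtf = out_dir / "refseq.gtf"
    mane_tsv = out_dir / "mane.tsv"
    gencode_gtf.write_text("\n".join(gencode_lines) + "\n")
    refseq_gtf.write_text("\n".join(refseq_lines) + "\n")
    pd.DataFrame(mane_rows, columns=["gene_id", "transcript_id"]).to_csv(
        mane_tsv, sep="\t", index=False
    )
    return AnnotationFixture(
        gencode_gtf=gencode_gtf,
        refseq_gtf=refseq_gtf,
        mane_tsv=mane_tsv,
        expected_tiers={
            "MANEG": "MANE",
            "REFSG": "refseq_composite",
            "UNIOG": "gencode_union",
            "MANEX": "refseq_composite",
        },
        single_exon_genes=("MONOG",),
    )
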