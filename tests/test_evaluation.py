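"""PPV/NPV, thinning, bootstrap background, TPM/panel/VUS reports."""

import math

import numpy as np
import pandas as pd
import pytest

from mrsd import (
    GeneratorConfig,
    MRSDModel,
    MRSDParameters,
    ReferenceSet,
    SpliceEventScorer,
    SpliceJunction,
    TranscriptModel,
    assemble_reference_set,
    bootstrap_background,
    calibration_coverage,
    compare_tpm,
    coverage_achieved,
    downsample_gene,
    evaluate_ppv_npv,
    evaluate_reference,
    filter_events,
    generate_reference_set,
    inject_aberrant_event,
    panel_report,
    rank_stability_experiment,
    score_events,
    vus_feasibility,
)


def _j(start, end):
    return SpliceJunction("chr1", start, end, "+")


@pytest.fixture()
def tiny_fit():
    """One control sample; gene A well covered, gene B silent."""
    a = [_j(101, 199), _j(301, 399), _j(501, 599), _j(701, 799)]
    b = [_j(2101, 2199), _j(2301, 2399)]
    counts = {j: 20 for j in a}
    ref = assemble_reference_set([("ctrl", counts, 50.0)])
    models = [
        TranscriptModel("A", "tA", "MANE", tuple(a)),
        TranscriptModel("B", "tB", "MANE", tuple(b)),
    ]
    return MRSDModel(ref, models).fit(MRSDParameters(r=8, p=0.75, m=0.95)), a, b


class TestCoverageRule:
    def test_matches_critical_count_rule(self):
        # 3 of 4 junctions at ≥ r ⇔ achieved at p = 0.75
        assert coverage_achieved([8, 8, 8, 0], r=8, p=0.75)
        assert not coverage_achieved([8, 8, 0, 0], r=8, p=0.75)


class TestPpvNpv:
    def test_positive_achieved_counts_toward_ppv(self, tiny_fit):
        fit, a, b = tiny_fit
        test_counts = {j: 50 for j in a}
        ev = evaluate_ppv_npv(fit, test_counts, depth_millions=100.0)
        row = ev.outcomes.set_index("transcript_id").loc["tA"]
        assert row["predicted_sufficient"] and row["achieved"]
        assert ev.ppv == pytest.approx(1.0)

    def test_unfeasible_covered_anyway_counts_against_npv(self, tiny_fit):
        fit, a, b = tiny_fit
        test_counts = {j: 50 for j in a + b}
        ev = evaluate_ppv_npv(fit, test_counts, depth_millions=100.0)
        row = ev.outcomes.set_index("transcript_id").loc["tB"]
        assert not row["predicted_sufficient"] and row["achieved"]
        assert ev.npv < 1.0

    def test_empty_sample_all_negative_ppv_undefined(self, tiny_fit):
        fit, *_ = tiny_fit
        ev = evaluate_ppv_npv(fit, {}, depth_millions=0.001)
        assert ev.n_positive == 0
        assert math.isnan(ev.ppv)
        assert ev.npv == pytest.approx(1.0)

    def test_partition_is_exact(self, tiny_fit):
        fit, a, _ = tiny_fit
        ev = evaluate_ppv_npv(fit, {j: 50 for j in a}, depth_millions=100.0)
        assert ev.n_positive + ev.n_negative == len(ev.outcomes)


class TestCalibration:
    def test_heldout_coverage_concentrates_near_m(self, small_synth):
        fit = MRSDModel(small_synth.reference_set, small_synth.models).fit()
        rep = calibration_coverage(small_synth, fit, n_heldout=100, seed=3)
        assert 0.8 < rep.pooled_coverage <= 1.0
        assert abs(rep.pooled_coverage - 0.95) <= 4 * rep.mc_se

    def test_ppv_on_fresh_samples_at_least_m(self, small_synth):
        fit = MRSDModel(small_synth.reference_set, small_synth.models).fit()
        fresh = small_synth.draw_samples(
            np.full(40, small_synth.reference_set.depths.mean()), seed=8
        )
        ev = evaluate_reference(fit, fresh)
        se = math.sqrt(0.95 * 0.05 / 40)
        assert ev.ppv >= 0.95 - 3 * se


class TestDownsampling:
    def test_fraction_zero_identity(self):
        counts = {_j(1, 10): 7, _j(20, 30): 0}
        assert downsample_gene(counts, 0.0, seed=0) == counts

    def test_binomial_moments(self):
        draws = np.array(
            [downsample_gene(np.array([1000]), 0.5, seed=s)[0] for s in range(2000)]
        )
        assert draws.mean() == pytest.approx(500.0, abs=3.0)
        assert draws.var() == pytest.approx(250.0, rel=0.15)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            downsample_gene({}, 1.0)


class TestRankStability:
    def test_zero_thinning_reproduces_baseline(self, small_synth):
        ref = small_synth.reference_set
        case = ref.sample_counts(ref.samples[0].sample_id)
        controls = ReferenceSet(
            list(ref.samples[1:]), list(ref.junctions), ref.counts[1:], "c"
        )
        case, _, rec = inject_aberrant_event(
            case, small_synth.models[0], target_nrc=1.0, reads=60
        )
        scorer = SpliceEventScorer(controls, small_synth.models)
        baseline = scorer.fit(case, min_reads=2, min_nrc=0.0)
        base_rank = {e.junction: e.rank for e in baseline.ranked}[rec.junction]
        table = rank_stability_experiment(
            case, scorer, [rec.junction], fractions=(0.0,), seed=5, min_nrc=0.0
        )
        assert table.iloc[0]["detected"]
        assert table.iloc[0]["rank"] == base_rank
        assert table.iloc[0]["read_count"] == 60


class TestBootstrap:
    def _setup(self, small_synth):
        ref = small_synth.reference_set
        case = ref.sample_counts(ref.samples[0].sample_id)
        pool = ReferenceSet(
            list(ref.samples[1:]), list(ref.junctions), ref.counts[1:], "pool"
        )
        return case, pool

    def test_bit_reproducible(self, small_synth):
        case, pool = self._setup(small_synth)
        kw = dict(control_size=20, n_bootstraps=50, seed=17)
        a = bootstrap_background(case, pool, small_synth.models, **kw)
        b = bootstrap_background(case, pool, small_synth.models, **kw)
        np.testing.assert_array_equal(a.singleton_counts, b.singleton_counts)
        np.testing.assert_array_equal(a.non_singleton_counts, b.non_singleton_counts)

    def test_vectorized_path_matches_event_filter(self, small_synth):
        """One replicate recomputed through the object pipeline agrees."""
        case, pool = self._setup(small_synth)
        summ = bootstrap_background(
            case, pool, small_synth.models,
            control_size=15, n_bootstraps=1, seed=23, min_reads=1,
        )
        idx = np.random.default_rng(23).integers(0, pool.n_samples, size=15)
        drawn = ReferenceSet(
            [
                type(pool.samples[0])(f"b{k}", pool.samples[i].depth_millions)
                for k, i in enumerate(idx)
            ],
            list(pool.junctions),
            pool.counts[idx],
            "drawn",
        )
        events = filter_events(
            score_events(case, "case", drawn, small_synth.models)
        )
        n_single = sum(1 for e in events if e.is_singleton)
        assert summ.singleton_counts[0] == n_single
        assert summ.non_singleton_counts[0] == len(events) - n_single

    def test_pool_too_small_rejected(self, small_synth):
        case, pool = self._setup(small_synth)
        with pytest.raises(ValueError):
            bootstrap_background(
                case, pool, small_synth.models, control_size=10_000
            )


class TestCompareTpm:
    def test_exact_generator_gives_inverse_proportionality(self):
        cfg = GeneratorConfig(
            n_samples=50, n_genes=40, seed=9, exact_counts=True,
            expression_log_median=0.0, expression_log_sd=1.0,
        )
        synth = generate_reference_set(cfg)
        fit = MRSDModel(synth.reference_set, synth.models).fit()
        cmp = compare_tpm(
            fit.to_frame(), synth.truth[["gene_id", "tpm"]]
        )
        assert cmp.r_squared > 0.99
        assert cmp.slope == pytest.approx(-1.0, abs=0.05)

    def test_too_few_shared_genes(self):
        mrsd_df = pd.DataFrame({"gene_id": ["a"], "mrsd_millions": [10.0]})
        tpm_df = pd.DataFrame({"gene_id": ["a"], "tpm": [5.0]})
        with pytest.raises(ValueError, match="3"):
            compare_tpm(mrsd_df, tpm_df)

    def test_empty_intersection(self):
        mrsd_df = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "mrsd_millions": [1.0, 2.0, 3.0]}
        )
        tpm_df = pd.DataFrame({"gene_id": ["x", "y", "z"], "tpm": [1, 2, 3]})
        with pytest.raises(ValueError):
            compare_tpm(mrsd_df, tpm_df)


def _mrsd_table(classes):
    """gene → mrsd giving the requested class at threshold 100."""
    value = {"LOW_MRSD": 10.0, "HIGH_MRSD": 500.0, "UNFEASIBLE": math.inf}
    return pd.DataFrame(
        {"gene_id": list(classes), "mrsd_millions": [value[c] for c in classes.values()]}
    )


class TestPanelReport:
    def test_best_tissue_by_hand_count(self):
        tables = {
            "blood": _mrsd_table({"g1": "HIGH_MRSD", "g2": "HIGH_MRSD", "g3": "LOW_MRSD"}),
            "lcl": _mrsd_table({"g1": "LOW_MRSD", "g2": "LOW_MRSD", "g3": "UNFEASIBLE"}),
        }
        panels = pd.DataFrame(
            {"panel_name": ["P1", "P1", "P2"], "gene_id": ["g1", "g2", "g3"]}
        )
        rep = panel_report(tables, panels).set_index("panel_name")
        assert rep.loc["P1", "prop_low_blood"] == pytest.approx(0.0)
        assert rep.loc["P1", "prop_low_lcl"] == pytest.approx(1.0)
        assert rep.loc["P1", "best_tissue"] == "lcl"
        assert rep.loc["P2", "best_tissue"] == "blood"

    def test_tie_reported_jointly(self):
        tables = {
            "a": _mrsd_table({"g1": "LOW_MRSD"}),
            "b": _mrsd_table({"g1": "LOW_MRSD"}),
        }
        panels = pd.DataFrame({"panel_name": ["P"], "gene_id": ["g1"]})
        rep = panel_report(tables, panels)
        assert rep.iloc[0]["best_tissue"] == "a,b"

    def test_unmappable_panel_flagged(self):
        tables = {"a": _mrsd_table({"g1": "LOW_MRSD"})}
        panels = pd.DataFrame({"panel_name": ["P"], "gene_id": ["unknown_gene"]})
        rep = panel_report(tables, panels)
        assert bool(rep.iloc[0]["skipped"])

    def test_rating_filter(self):
        tables = {"a": _mrsd_table({"g1": "LOW_MRSD", "g2": "HIGH_MRSD"})}
        panels = pd.DataFrame(
            {
                "panel_name": ["P", "P"],
                "gene_id": ["g1", "g2"],
                "rating": ["green", "amber"],
            }
        )
        rep = panel_report(tables, panels)
        assert rep.iloc[0]["n_genes"] == 1
        assert rep.iloc[0]["prop_low_a"] == pytest.approx(1.0)


class TestVus:
    def _variants(self):
        rows = []
        # 5 retainable VUS in low genes? gene classes below: g1..g4 low, g5 high
        labels = ["Uncertain significance"] * 8 + ["Pathogenic", "Benign"]
        genes = ["g1", "g2", "g3", "g4", "g5", "g5", "g6", "g5", "g1", "g2"]
        scores = [0.9, 0.8, 0.7, 0.5, 0.6, 0.55, 0.9, 0.4, 0.99, 0.99]
        for i, (lab, g, s) in enumerate(zip(labels, genes, scores)):
            rows.append(
                {
                    "variant_id": f"v{i}",
                    "gene_id": g,
                    "clinical_significance": lab,
                    "spliceai_max": s,
                }
            )
        return pd.DataFrame(rows)

    def test_filtering_and_fraction(self):
        tables = {
            "blood": _mrsd_table(
                {"g1": "LOW_MRSD", "g2": "LOW_MRSD", "g3": "LOW_MRSD",
                 "g4": "LOW_MRSD", "g5": "HIGH_MRSD"}
            )
        }
        kept, summary = vus_feasibility(self._variants(), tables)
        # v7 fails the score cutoff; pathogenic/benign excluded
        assert set(kept["variant_id"]) == {f"v{i}" for i in range(7)}
        assert summary["n_retained"] == 7
        # 4 of 7 retained variants sit in low-MRSD genes
        assert summary["fraction_low_any_tissue"] == pytest.approx(4 / 7)

    def test_boundary_score_inclusive(self):
        tables = {"t": _mrsd_table({"g4": "LOW_MRSD"})}
        kept, _ = vus_feasibility(self._variants(), tables)
        assert "v3" in set(kept["variant_id"])  # spliceai_max exactly 0.5

    def test_unscored_gene_annotated(self):
        tables = {"t": _mrsd_table({"g1": "LOW_MRSD"})}
        kept, _ = vus_feasibility(self._variants(), tables)
        assert (
            kept.set_index("variant_id").loc["v6", "class_t"] == "unscored"
        )  # g6 absent from table

    def test_conflicting_interpretations_label_retained(self):
        df = self._variants()
        df.loc[0, "clinical_significance"] = (
            "Conflicting interpretations of pathogenicity"
        )
        tables = {"t": _mrsd_table({"g1": "LOW_MRSD"})}
        kept, _ = vus_feasibility(df, tables)
        assert "v0" in set(kept["variant_id"])
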