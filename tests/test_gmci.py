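import numpy as np
import pandas as pd
import pytest

from gmeb.gmci import (
    GmciCalibrationError,
    Indicator,
    assess,
    build_indicators,
    calibrate,
    evaluate,
)
from gmeb.simulate import ImpactParams, concat_datasets, simulate_impacted


@pytest.fixture(scope="module")
def calibrated(baseline_sim, impacted_strong):
    cands = build_indicators(baseline_sim.dataset)
    return calibrate(cands, baseline_sim.dataset, impacted_strong, seed=23)


class TestBuildIndicators:
    def test_diversity_indicators_always_present(self, baseline_sim):
        cands = build_indicators(baseline_sim.dataset)
        ids = {c.id for c in cands}
        assert {"shannon", "faith_pd"} <= ids

    def test_rare_taxa_filtered_by_occurrence_and_abundance(self, baseline_sim):
        from gmeb.datasets import aggregate_rank, relative_abundance

        cands = build_indicators(baseline_sim.dataset)
        ds = baseline_sim.dataset
        for rank in ("phylum", "genus"):
            rel = relative_abundance(aggregate_rank(ds.table, ds.taxonomy, rank))
            occ = (rel > 0).mean(axis=0)
            mean_ab = rel.mean(axis=0)
            for c in cands:
                if c.rank == rank:
                    assert occ[c.taxon] >= 0.2
                    assert mean_ab[c.taxon] >= 0.005

    def test_keystones_and_biomarkers_obey_same_filter(self, baseline_sim):
        cands = build_indicators(baseline_sim.dataset,
                                 keystones=["Genus001", "NoSuchGenus"],
                                 biomarkers=["Genus002"])
        kinds = {(c.kind, c.taxon) for c in cands}
        assert ("key_species", "NoSuchGenus") not in kinds

    def test_reconstructed_wells_rejected_as_baseline(self, impacted_strong):
        with pytest.raises(Exception, match="newly constructed"):
            build_indicators(impacted_strong)


class TestCalibrate:
    def test_strong_effect_vets_indicators(self, calibrated):
        assert len(calibrated.indicators) >= 1
        for ind in calibrated.indicators:
            assert ind.accuracy > ind.error
        assert sum(i.weight for i in calibrated.indicators) == pytest.approx(1.0, abs=1e-12)

    def test_zero_effect_refuses(self, baseline_sim):
        null = simulate_impacted(baseline_sim, ImpactParams(0.0, 0.0, seed=31))
        null_ds = null.dataset.subset_samples(null.dataset.table.sample_ids[:30])
        cands = build_indicators(baseline_sim.dataset)
        with pytest.raises(GmciCalibrationError) as exc:
            calibrate(cands, baseline_sim.dataset, null_ds, seed=23)
        assert exc.value.report is not None  # per-indicator report attached

    def test_same_seed_reproduces_model(self, baseline_sim, impacted_strong):
        cands = build_indicators(baseline_sim.dataset)
        a = calibrate(cands, baseline_sim.dataset, impacted_strong, seed=40)
        b = calibrate(cands, baseline_sim.dataset, impacted_strong, seed=40)
        for x, y in zip(a.indicators, b.indicators):
            assert (x.id, x.expectation, x.alarm_oe, x.weight) == \
                   (y.id, y.expectation, y.alarm_oe, y.weight)

    def test_too_few_samples_rejected(self, baseline_sim, impacted_strong):
        cands = build_indicators(baseline_sim.dataset)
        small = baseline_sim.dataset.subset_samples(baseline_sim.dataset.table.sample_ids[:5])
        with pytest.raises(Exception):
            calibrate(cands, small, impacted_strong, seed=0)


def _probe_values(model, factor_fn):
    return pd.DataFrame(
        {i.id: [i.expectation * factor_fn(i)] for i in model.indicators}, index=["probe"])


class TestAssess:
    def test_all_ratios_one_gives_zero(self, calibrated):
        res = assess(calibrated, _probe_values(calibrated, lambda i: 1.0))
        assert res.gmci["probe"] == pytest.approx(0.0, abs=1e-12)
        assert not res.flagged["probe"]

    def test_all_ratios_at_alarm_give_exactly_threshold(self, calibrated):
        res = assess(calibrated, _probe_values(calibrated, lambda i: i.alarm_oe))
        assert res.gmci["probe"] == pytest.approx(1.0, abs=1e-9)
        assert res.flagged["probe"]

    def test_larger_deviations_strictly_increase_gmci(self, calibrated):
        g1 = assess(calibrated, _probe_values(calibrated, lambda i: i.alarm_oe)).gmci["probe"]
        g2 = assess(calibrated, _probe_values(calibrated, lambda i: i.alarm_oe**2)).gmci["probe"]
        assert g2 > g1

    def test_zero_observation_capped(self, calibrated):
        vals = _probe_values(calibrated, lambda i: 1.0)
        vals.iloc[0, 0] = 0.0
        res = assess(calibrated, vals)
        w0 = calibrated.indicators[0].weight
        assert res.scores.iloc[0, 0] == pytest.approx(w0 * 10.0)

    def test_invariant_to_sample_order(self, calibrated, baseline_sim):
        ds = baseline_sim.dataset
        fwd = assess(calibrated, ds).gmci
        rev = assess(calibrated, ds.subset_samples(ds.table.sample_ids[::-1])).gmci
        np.testing.assert_allclose(fwd.sort_index(), rev.sort_index(), atol=1e-12)

    def test_invariant_to_weight_renormalization(self, calibrated, baseline_sim):
        import copy

        scaled = copy.deepcopy(calibrated)
        for ind in scaled.indicators:
            ind.weight *= 3.0
        a = assess(calibrated, baseline_sim.dataset).gmci
        b = assess(scaled, baseline_sim.dataset).gmci
        np.testing.assert_allclose(b, 3.0 * a, atol=1e-9)


class TestEvaluate:
    def test_perfect_separation(self, calibrated):
        n = len(calibrated.indicators)
        vals = pd.DataFrame(
            {i.id: [i.expectation] * 3 + [i.expectation * i.alarm_oe**2] * 3
             for i in calibrated.indicators},
            index=[f"b{k}" for k in range(3)] + [f"i{k}" for k in range(3)])
        labels = pd.Series(["baseline"] * 3 + ["impacted"] * 3, index=vals.index)
        res = evaluate(calibrated, vals, labels)
        assert res["accuracy"] == 1.0 and res["error"] == 0.0

    def test_flag_everything_has_unit_error(self, calibrated):
        vals = pd.DataFrame(
            {i.id: [i.expectation * i.alarm_oe**3] * 4 for i in calibrated.indicators},
            index=list("abcd"))
        labels = pd.Series(["baseline", "baseline", "impacted", "impacted"],
                           index=vals.index)
        res = evaluate(calibrated, vals, labels)
        assert res["accuracy"] == 1.0 and res["error"] == 1.0

    def test_holdout_performance_on_strong_effect(self, calibrated, baseline_sim,
                                                  impacted_strong):
        hb = calibrated.reference["holdout_baseline"]
        hi = calibrated.reference["holdout_impacted"]
        hold = concat_datasets(baseline_sim.dataset.subset_samples(hb),
                               impacted_strong.subset_samples(hi))
        labels = pd.Series(["baseline"] * len(hb) + ["impacted"] * len(hi),
                           index=list(hb) + list(hi))
        res = evaluate(calibrated, hold, labels)
        assert res["accuracy"] >= 0.8
        assert res["error"] <= 0.2


def test_model_json_round_trip(calibrated, tmp_path):
    from gmeb.gmci import GmciModel

    path = tmp_path / "model.json"
    calibrated.to_json(path)
    back = GmciModel.from_json(path)
    assert [i.id for i in back.indicators] == [i.id for i in calibrated.indicators]
    assert back.indicators[0].alarm_oe == calibrated.indicators[0].alarm_oe
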