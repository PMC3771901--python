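import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoquant import SimulationConfig, generate_psm_table
from mitoquant.channels import ChannelDesign
from mitoquant.differential import (ComparisonScheme,
                                    DifferentialAbundanceModel, RatioTest,
                                    classify_differential, default_schemes,
                                    exclude_contaminants, intersect_calls,
                                    mann_whitney_p)
from mitoquant.identification import (apply_confidence_filters,
                                      estimate_peptide_fdr,
                                      infer_quantifiable_proteins)
from mitoquant.reporter import normalize_channels

from _oracles import mann_whitney_exact_oracle

LOF_SCHEME = default_schemes()["LOF"]


class TestMannWhitney:
    def test_clean_separation_exact_p(self):
        assert mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_lists_p_one(self):
        assert mann_whitney_p([5.0, 6.0, 7.0], [5.0, 6.0, 7.0]) == 1.0

    def test_short_list_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_p([1.0], [2.0, 3.0])

    def test_exact_branch_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(150):
            na, nb = rng.integers(2, 7, size=2)
            a, b = rng.normal(size=na), rng.normal(size=nb)
            assert mann_whitney_p(a, b) == pytest.approx(
                mann_whitney_exact_oracle(a, b), abs=1e-12)


def _tests(ratios, ps):
    return [RatioTest(r, p, 6) for r, p in zip(ratios, ps)]


class TestConsensusRule:
    @pytest.mark.parametrize("ratios,ps,expect", [
        # one ratio past the gate with p<0.05 and 3+ same-trend significant
        ([1.62, 1.71, 1.55, 1.41], [0.01, 0.02, 0.03, 0.21], "up"),
        # criterion 2 fails: only one significant trend ratio
        ([1.8, 1.1, 0.95, 1.05], [0.01, 0.3, 0.6, 0.5], "none"),
        ([0.60, 0.62, 0.65, 0.80], [0.01, 0.02, 0.04, 0.03], "down"),
        ([1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0], "none"),
        # gate ratio not significant -> criterion 1 fails
        ([1.62, 1.3, 1.25, 1.28], [0.30, 0.01, 0.01, 0.01], "none"),
        # trend consensus below the gate is enough only for criterion 2
        ([1.30, 1.35, 1.28, 1.40], [0.01, 0.01, 0.01, 0.01], "none"),
    ])
    def test_worked_examples(self, ratios, ps, expect):
        call = classify_differential(_tests(ratios, ps), LOF_SCHEME)
        assert call.direction == expect

    def test_boundary_ratio_is_strict(self):
        call = classify_differential(
            _tests([1.5, 1.4, 1.3, 1.2], [0.01] * 4), LOF_SCHEME)
        assert not call.criterion1_met and call.direction == "none"
        loose = ComparisonScheme("LOF", LOF_SCHEME.pairs, strict=False)
        call = classify_differential(
            _tests([1.5, 1.4, 1.3, 1.2], [0.01] * 4), loose)
        assert call.direction == "up"

    def test_conflicting_directions_flagged_none(self):
        # criterion 1 met only downward, criterion 2 only upward
        call = classify_differential(
            _tests([0.5, 1.2, 1.3, 1.4], [0.01, 0.01, 0.01, 0.01]),
            LOF_SCHEME)
        assert call.direction == "none"
        assert call.flag == "criteria_direction_conflict"

    def test_undefined_ratio_and_untestable_flags(self):
        call = classify_differential(
            _tests([np.nan, 2.0, 2.0, 2.0], [0.01] * 4), LOF_SCHEME)
        assert call.direction == "none" and call.flag == "undefined_ratio"
        call = classify_differential(
            _tests([2.0] * 4, [np.nan, 0.01, 0.01, 0.01]), LOF_SCHEME)
        assert call.direction == "none" and call.flag == "untestable"

    @given(st.floats(min_value=1.0, max_value=5.0))
    @settings(max_examples=50, deadline=None)
    def test_up_call_monotone_under_ratio_inflation(self, c):
        ratios = [1.62, 1.71, 1.55, 1.41]
        ps = [0.01, 0.02, 0.03, 0.04]
        base = classify_differential(_tests(ratios, ps), LOF_SCHEME)
        assert base.direction == "up"
        inflated = classify_differential(
            _tests([r * c for r in ratios], ps), LOF_SCHEME)
        assert inflated.direction == "up"


def test_intersect_calls_mean_sem():
    cols = {f"ratio_{i}": v for i, v in enumerate([1.5, 1.6, 1.7, 1.6], 1)}
    lof = pd.DataFrame([{"protein_id": "P1", "direction": "up", **cols},
                        {"protein_id": "P2", "direction": "up", **cols}])
    hof = pd.DataFrame([{"protein_id": "P1", "direction": "down", **cols}])
    shared = intersect_calls(lof, hof)
    assert shared["protein_id"].tolist() == ["P1"]
    assert shared["mean_ratio_lof"].iloc[0] == pytest.approx(1.60)
    assert shared["sem_ratio_lof"].iloc[0] == pytest.approx(0.0408, abs=2e-4)
    # disjoint differential sets -> empty intersection
    hof2 = hof.assign(protein_id="P9")
    assert intersect_calls(lof, hof2).empty


def test_exclude_contaminants():
    calls = pd.DataFrame([
        {"protein_id": "P1", "direction": "up",
         "excluded_as_contaminant": False},
        {"protein_id": "P2", "direction": "down",
         "excluded_as_contaminant": False},
    ])
    ann = pd.DataFrame({"protein_id": ["P1", "P2"],
                        "organelle": ["nucleus", "mitochondria"]})
    out, n = exclude_contaminants(calls, ann, {"nucleus", "extracellular"})
    assert n == 1
    assert out.loc[out["protein_id"] == "P1", "direction"].iloc[0] == "none"
    assert out.loc[out["protein_id"] == "P2", "direction"].iloc[0] == "down"
    same, n0 = exclude_contaminants(calls, ann, set())
    assert n0 == 0 and same.equals(calls)


def _fit(cfg):
    psms, truth = generate_psm_table(cfg)
    conf = apply_confidence_filters(psms)
    _, filtered, _ = estimate_peptide_fdr(conf)
    groups, retained = infer_quantifiable_proteins(filtered)
    retained, _ = normalize_channels(retained, cfg.channel_design)
    model = DifferentialAbundanceModel.from_psm_table(
        retained, groups, cfg.channel_design)
    return model.fit(), truth


def test_direction_agrees_with_majority_trend(small_cfg):
    res, _ = _fit(small_cfg)
    called = res.calls.loc[res.calls["direction"] != "none"]
    ratios = called[[f"ratio_{i}" for i in range(1, 5)]].to_numpy()
    for row, direction in zip(ratios, called["direction"]):
        trend = (row > 1).sum()
        assert (trend >= 3) == (direction == "up")


def test_null_simulation_rarely_calls():
    """Under a global null the consensus rule calls well under 5% of
    proteins (it is much stricter than a single alpha=0.05 test)."""
    rates = []
    for seed in range(5):
        cfg = SimulationConfig(n_proteins=150, seed=400 + seed,
                               frac_differential_lof=0.0,
                               frac_differential_hof=0.0)
        res, _ = _fit(cfg)
        calls = res.calls
        rates.append((calls["direction"] != "none").mean())
    assert np.mean(rates) <= 0.05


def test_parameter_recovery_sensitivity_and_fdp():
    """Strong effects, modest noise, >=6 PSMs per protein: the caller
    recovers >=90% of true effects with <=10% false discoveries."""
    tp = fp = fn = 0
    for seed in range(3):
        cfg = SimulationConfig(n_proteins=200, seed=500 + seed,
                               effect_log2_range=(1.0, 2.0),
                               noise_sigma=0.1,
                               psms_per_protein_mean=8.0,
                               psms_per_protein_min=6)
        res, truth = _fit(cfg)
        truth = truth.set_index("protein_id")
        for group in ("LOF", "HOF"):
            called = set(res.differential(group)["protein_id"])
            true_set = set(
                truth.index[truth[f"is_differential_{group.lower()}"]])
            tp += len(called & true_set)
            fp += len(called - true_set)
            fn += len(true_set - called)
    assert tp / (tp + fn) >= 0.9
    assert fp / max(tp + fp, 1) <= 0.1


def test_summary_mentions_counts(small_cfg):
    res, _ = _fit(small_cfg)
    text = res.summary()
    assert "LOF" in text and "HOF" in text and "differential" in text
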