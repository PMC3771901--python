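import numpy as np
import pandas as pd
import pytest

from mitoquant.channels import ChannelDesign, PurityMatrix
from mitoquant.reporter import (aggregate_protein_intensities,
                                correct_isotope_impurity,
                                fold_change_distribution,
                                normalize_channels, replicate_correlation)

SAMPLES = list(ChannelDesign().channel_map)


def _random_purity(rng, n=6):
    m = np.eye(n) * rng.uniform(0.86, 0.93)
    for j in range(n):
        bleed = rng.uniform(0.0, 0.012, size=n)
        bleed[j] = 0.0
        m[:, j] += bleed
    return PurityMatrix(m, list(range(n)))


def test_identity_purity_is_noop():
    p = PurityMatrix.identity([113, 115])
    x = np.array([10.0, 20.0])
    corrected, clamped = correct_isotope_impurity(x, p)
    np.testing.assert_array_equal(corrected, x)
    assert not clamped.any()


def test_impurity_round_trip_recovers_truth():
    rng = np.random.default_rng(0)
    for _ in range(200):
        p = _random_purity(rng)
        x = rng.uniform(0.0, 1e5, size=6)
        observed = p.matrix @ x
        corrected, clamped = correct_isotope_impurity(observed, p)
        np.testing.assert_allclose(corrected, x, rtol=1e-8, atol=1e-6)
        assert not clamped.any()


def test_negative_solution_clamped_and_flagged():
    p = PurityMatrix(np.array([[0.9, 0.05], [0.05, 0.9]]), [113, 115])
    # observed vector inconsistent with any non-negative truth
    corrected, clamped = correct_isotope_impurity(
        np.array([0.0, 100.0]), p)
    assert corrected[0] == 0.0 and clamped[0]
    assert corrected[1] > 0 and not clamped[1]


def test_purity_matrix_validation():
    with pytest.raises(ValueError):
        PurityMatrix(np.array([[0.4, 0.5], [0.5, 0.4]]), [1, 2])  # not dominant
    with pytest.raises(ValueError):
        PurityMatrix(np.array([[0.9, 0.3], [0.3, 0.9]]), [1, 2])  # colsum > 1
    with pytest.raises(ValueError):
        PurityMatrix(-np.eye(2), [1, 2])


def test_normalization_matches_reference_median():
    rng = np.random.default_rng(1)
    psms = pd.DataFrame({s: rng.uniform(10, 100, 50) for s in SAMPLES})
    psms["C2"] = psms["C1"] * 2.0
    out, scalars = normalize_channels(psms, ChannelDesign())
    assert scalars["C1"] == 1.0
    assert scalars["C2"] == pytest.approx(0.5)
    ref_median = np.median(out["C1"])
    for s in SAMPLES:
        assert np.median(out[s]) == pytest.approx(ref_median, abs=1e-9)


def test_normalization_idempotent():
    rng = np.random.default_rng(2)
    psms = pd.DataFrame({s: rng.uniform(1, 9, 40) * (i + 1)
                         for i, s in enumerate(SAMPLES)})
    once, _ = normalize_channels(psms, ChannelDesign())
    twice, scalars = normalize_channels(once, ChannelDesign())
    pd.testing.assert_frame_equal(once, twice)
    assert all(v == pytest.approx(1.0) for v in scalars.values())


def _toy_table():
    rng = np.random.default_rng(3)
    psms = pd.DataFrame({s: rng.uniform(10, 100, 12) for s in SAMPLES})
    psms["protein_id"] = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4
    psms["peptide"] = [f"pep{i}" for i in range(12)]
    groups = pd.DataFrame({"protein_id": ["P1", "P2", "P3"],
                           "unique_labeled_peptide_count": [2, 2, 2],
                           "spectral_count": [4, 4, 4]})
    return psms, groups


def test_aggregation_sums_psm_intensities():
    psms, groups = _toy_table()
    table = aggregate_protein_intensities(psms, groups, ChannelDesign())
    for pid in ("P1", "P2", "P3"):
        expect = psms.loc[psms["protein_id"] == pid, SAMPLES].sum()
        np.testing.assert_allclose(table.loc[pid, SAMPLES], expect)
    # permutation invariance
    shuffled = psms.sample(frac=1.0, random_state=0)
    table2 = aggregate_protein_intensities(shuffled, groups, ChannelDesign())
    pd.testing.assert_frame_equal(table, table2)


def test_aggregation_linearity_preserves_ratios():
    psms, groups = _toy_table()
    t1 = aggregate_protein_intensities(psms, groups, ChannelDesign())
    scaled = psms.copy()
    scaled[SAMPLES] = scaled[SAMPLES] * 7.5
    t2 = aggregate_protein_intensities(scaled, groups, ChannelDesign())
    np.testing.assert_allclose(t2[SAMPLES], t1[SAMPLES] * 7.5)
    np.testing.assert_allclose(t2["LOF1"] / t2["C1"], t1["LOF1"] / t1["C1"])


def test_aggregation_requires_psms_for_every_protein():
    psms, groups = _toy_table()
    groups2 = pd.concat([groups, pd.DataFrame(
        [{"protein_id": "P9", "unique_labeled_peptide_count": 2,
          "spectral_count": 2}])], ignore_index=True)
    with pytest.raises(ValueError):
        aggregate_protein_intensities(psms, groups2, ChannelDesign())


def test_replicate_correlation_perfect_cases():
    table = pd.DataFrame({"C1": [10.0, 20, 40, 80, 160]})
    table["C2"] = table["C1"]
    r, slope, n, nexc = replicate_correlation(table, "C1", "C2")
    assert r == pytest.approx(1.0) and slope == pytest.approx(1.0)
    table["C2"] = table["C1"] * 2  # +1 on log2 scale
    r, slope, _, _ = replicate_correlation(table, "C1", "C2")
    assert r == pytest.approx(1.0) and slope == pytest.approx(1.0)


def test_replicate_correlation_matches_formula_oracle():
    table = pd.DataFrame({"C1": [8.0, 16, 33, 70, 100],
                          "C2": [9.0, 14, 40, 60, 120]})
    r, slope, n, nexc = replicate_correlation(table, "C1", "C2")
    la, lb = np.log2(table["C1"]), np.log2(table["C2"])
    cov = np.cov(la, lb, ddof=1)
    assert r == pytest.approx(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))
    assert slope == pytest.approx(cov[0, 1] / cov[0, 0])
    assert n == 5 and nexc == 0


def test_replicate_correlation_excludes_zeros():
    table = pd.DataFrame({"C1": [10.0, 0.0, 40, 80, 160],
                          "C2": [10.0, 20, 0.0, 80, 160]})
    r, slope, n, nexc = replicate_correlation(table, "C1", "C2")
    assert n == 3 and nexc == 2
    with pytest.raises(ValueError):
        replicate_correlation(table.head(3), "C1", "C2")


def test_fold_change_bins_and_boundaries():
    table = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0],
                          "b": [1.1, 1.15, 1.3, 1.6]})
    bins = fold_change_distribution(table, "a", "b")
    assert bins == {"<1.2": 50.0, "1.2-1.5": 25.0, ">1.5": 25.0}
    identical = pd.DataFrame({"a": [3.0, 4.0], "b": [3.0, 4.0]})
    assert fold_change_distribution(identical, "a", "b")["<1.2"] == 100.0
    # both boundary folds land in the middle bin
    boundary = pd.DataFrame({"a": [1.0, 1.0], "b": [1.2, 1.5]})
    assert fold_change_distribution(boundary, "a", "b")["1.2-1.5"] == 100.0
    with pytest.raises(ValueError):
        fold_change_distribution(pd.DataFrame({"a": [0.0], "b": [1.0]}),
                                 "a", "b")
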