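import numpy as np
import pandas as pd
import pytest

from mitoquant.mrm import (digest_tryptic, normalize_and_test,
                           quantify_protein, select_mrm_peptides)
from mitoquant.simulate import generate_mrm_table


class TestDigest:
    def test_cleaves_after_k_r(self):
        assert digest_tryptic("MAGWKTTESTPEPTIDERLVCK") == [
            "MAGWK", "TTESTPEPTIDER", "LVCK"]

    def test_no_cleavage_before_proline(self):
        assert digest_tryptic("AAKPGGR") == ["AAKPGGR"]

    def test_no_cut_sites_returns_whole_sequence(self):
        assert digest_tryptic("AGWTTESTPEPTIDE") == ["AGWTTESTPEPTIDE"]

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            digest_tryptic("AGW1TEST")


class TestPeptideSelection:
    PROTEOME = {
        "P1": "MAGWKTTESTPEPTIDERLVCK",
        "P2": "AAAGGGKTTESTPEPTIDERWWWVVVGGK",  # shares TTESTPEPTIDER
    }

    def test_four_rules(self):
        picked = select_mrm_peptides(self.PROTEOME)
        # TTESTPEPTIDER: right length, no C/M, but shared by P1 and P2
        assert "TTESTPEPTIDER" not in picked["P1"]
        assert "TTESTPEPTIDER" not in picked["P2"]
        # LVCK: contains C and is too short
        assert "LVCK" not in picked["P1"]
        # MAGWK: contains M
        assert "MAGWK" not in picked["P1"]
        assert picked["P2"] == ["AAAGGGK", "WWWVVVGGK"]

    def test_selected_peptides_repass_rules(self):
        picked = select_mrm_peptides(self.PROTEOME)
        digests = {p: digest_tryptic(s) for p, s in self.PROTEOME.items()}
        for pid, peps in picked.items():
            for pep in peps:
                assert 7 <= len(pep) <= 25
                assert "C" not in pep and "M" not in pep
                owners = [q for q, d in digests.items() if pep in d]
                assert owners == [pid]
                assert pep in digests[pid]  # no missed cleavage


def _transitions(areas, sns):
    return pd.DataFrame({
        "protein_id": "P1", "peptide": "PEP",
        "transition_id": [f"y{i}" for i in range(len(areas))],
        "area": areas, "signal_to_noise": sns,
        "sample": "C", "bio_replicate": 1, "tech_replicate": 1})


class TestQuantify:
    def test_sums_qualified_areas(self):
        out = quantify_protein(_transitions([100, 200, 300], [12, 15, 20]))
        assert out["abundance"].iloc[0] == 600

    def test_low_sn_excluded(self):
        out = quantify_protein(_transitions([100, 200, 300], [5, 15, 20]))
        assert out["abundance"].iloc[0] == 500
        assert out["n_transitions_used"].iloc[0] == 2

    def test_sn_exactly_ten_excluded(self):
        out = quantify_protein(_transitions([100, 200], [10.0, 20]))
        assert out["abundance"].iloc[0] == 200

    def test_all_filtered_flagged(self):
        out = quantify_protein(_transitions([100, 200], [1, 2]))
        assert out["all_filtered"].iloc[0]
        assert np.isnan(out["abundance"].iloc[0])

    def test_removing_transition_decomposes_sum(self):
        full = quantify_protein(_transitions([100, 200, 300], [12, 15, 20]))
        dropped = quantify_protein(
            _transitions([100, 300], [12, 20]))
        assert (full["abundance"].iloc[0] - dropped["abundance"].iloc[0]
                == 200)


def _abundances(c, lof):
    rows = []
    for i, v in enumerate(c):
        rows.append({"protein_id": "P1", "sample": "C",
                     "bio_replicate": 1 + i // 3,
                     "tech_replicate": 1 + i % 3, "abundance": v})
    for i, v in enumerate(lof):
        rows.append({"protein_id": "P1", "sample": "LOF",
                     "bio_replicate": 1 + i // 3,
                     "tech_replicate": 1 + i % 3, "abundance": v})
    return pd.DataFrame(rows)


class TestNormalizeAndTest:
    def test_exact_halving_degenerate(self):
        out = normalize_and_test(_abundances([100.0] * 6, [50.0] * 6))
        row = out.iloc[0]
        assert row["mean_ratio"] == pytest.approx(0.5)
        assert row["degenerate_variance"]
        assert row["p_value"] == 0.0

    def test_identical_groups(self):
        out = normalize_and_test(_abundances([100.0] * 6, [100.0] * 6))
        row = out.iloc[0]
        assert row["mean_ratio"] == pytest.approx(1.0)
        assert row["p_value"] == pytest.approx(1.0)

    def test_t_statistic_matches_pooled_formula(self):
        c = np.array([10.0, 12.0, 11.0])
        x = np.array([15.0, 14.0, 16.0])
        out = normalize_and_test(_abundances(list(c), list(x)))
        sp2 = ((c.var(ddof=1) * 2 + x.var(ddof=1) * 2) / 4)
        t_hand = (x.mean() - c.mean()) / np.sqrt(sp2 * (2 / 3))
        assert out["t_statistic"].iloc[0] == pytest.approx(t_hand)
        assert out["n"].iloc[0] == 3

    def test_single_replicate_rejected(self):
        df = _abundances([100.0, 110.0], [50.0])
        with pytest.raises(ValueError):
            normalize_and_test(df)


def test_two_fold_suppression_recovered(small_tables):
    """Simulated 2-fold HOF suppression: normalized MRM ratio lands within
    10% of 0.5 across seeds at modest noise."""
    _, truth = small_tables
    truth = truth.copy()
    pid = truth["protein_id"].iloc[0]
    truth.loc[truth["protein_id"] == pid, "true_log2fc_hof"] = -1.0
    ratios = []
    for seed in range(10):
        table = generate_mrm_table([pid], truth, seed=seed,
                                   noise_sigma=0.1, frac_below_sn=0.0)
        tested = normalize_and_test(quantify_protein(table))
        ratios.append(tested.loc[tested["sample"] == "HOF",
                                 "mean_ratio"].iloc[0])
    assert abs(np.mean(ratios) - 0.5) <= 0.05
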