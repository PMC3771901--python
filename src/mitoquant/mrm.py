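"""MRM confirmation: proteotypic peptide selection and transition-area
quantification.

Candidate peptides for targeted assays must be tryptic with zero missed
cleavages, 7-25 residues, free of cysteine and methionine (chemically
unstable residues) and unique to one protein in the proteome.  A protein's
abundance in a run is the sum of its transition peak areas with
signal-to-noise strictly above 10; group ratios are normalized to the mean
control abundance and compared with a two-sample t-test.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


def digest_tryptic(sequence: str) -> list[str]:
    """In-silico tryptic digest with zero missed cleavages.

    Cleaves C-terminal to K or R except when the next residue is P.
    """
    seq = sequence.strip().upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid amino acids: {sorted(bad)}")
    peptides, start = [], 0
    for i, aa in enumerate(seq):
        if aa in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            peptides.append(seq[start:i + 1])
            start = i + 1
    if start < len(seq):
        peptides.append(seq[start:])
    return peptides


def select_mrm_peptides(sequences: Mapping[str, str],
                        min_len: int = 7,
                        max_len: int = 25) -> dict[str, list[str]]:
    """Candidate MRM peptides per protein under the four selection rules:
    unique in the digested proteome, no C or M, 7-25 residues, no missed
    cleavage (guaranteed by the digest).

    Uniqueness is evaluated against the supplied proteome: a peptide
    produced by more than one protein (or twice by one) is rejected.
    """
    digests = {pid: digest_tryptic(seq) for pid, seq in sequences.items()}
    occurrence = Counter()
    for peps in digests.values():
        occurrence.update(set(peps))
    multi_within = {p for peps in digests.values()
                    for p, c in Counter(peps).items() if c > 1}
    out = {}
    for pid, peps in digests.items():
        kept = []
        for p in dict.fromkeys(peps):  # preserve order, dedupe
            if occurrence[p] > 1 or p in multi_within:
                continue
            if not min_len <= len(p) <= max_len:
                continue
            if "C" in p or "M" in p:
                continue
            kept.append(p)
        out[pid] = kept
    return out


def quantify_protein(transitions: pd.DataFrame,
                     sn_min: float = 10.0) -> pd.DataFrame:
    """Per protein/sample/replicate abundance as the sum of qualified
    transition areas (signal-to-noise strictly above ``sn_min``).

    Protein-sample-replicate combinations where every transition fails the
    filter appear with NaN abundance and ``all_filtered=True``.
    """
    work = transitions.copy()
    work["qualified"] = work["signal_to_noise"] > sn_min
    keys = ["protein_id", "sample", "bio_replicate", "tech_replicate"]
    agg = work.groupby(keys).apply(
        lambda g: pd.Series({
            "abundance": (g.loc[g["qualified"], "area"].sum()
                          if g["qualified"].any() else np.nan),
            "n_transitions_used": int(g["qualified"].sum()),
            "all_filtered": not g["qualified"].any(),
        }), include_groups=False).reset_index()
    agg["n_transitions_used"] = agg["n_transitions_used"].astype(int)
    agg["all_filtered"] = agg["all_filtered"].astype(bool)
    return agg


def normalize_and_test(abundances: pd.DataFrame,
                       control: str = "C",
                       average_technical: bool = False,
                       equal_var: bool = True) -> pd.DataFrame:
    """Normalize abundances to the mean control abundance and test each
    group against control.

    By default every biological x technical measurement is a replicate
    (n = 2 x 3 = 6 per group in the reference design); set
    ``average_technical`` to collapse technical replicates first.  The test
    is a two-sided two-sample t-test, pooled variance by default (Welch via
    ``equal_var=False``).  Degenerate zero-variance comparisons are flagged:
    identical groups get p = 1, separated constant groups p = 0.
    """
    work = abundances.dropna(subset=["abundance"]).copy()
    if average_technical:
        work = (work.groupby(["protein_id", "sample", "bio_replicate"])
                ["abundance"].mean().reset_index())
    rows = []
    for pid, sub in work.groupby("protein_id"):
        ctrl = sub.loc[sub["sample"] == control, "abundance"].to_numpy()
        if len(ctrl) < 2:
            raise ValueError(
                f"protein {pid}: need >=2 control replicates")
        ctrl_mean = ctrl.mean()
        for grp, g in sub.groupby("sample"):
            if grp == control:
                continue
            x = g["abundance"].to_numpy(dtype=float)
            if len(x) < 2:
                raise ValueError(
                    f"protein {pid}, group {grp}: single replicate")
            ratios = x / ctrl_mean
            degenerate = x.std(ddof=1) == 0 and ctrl.std(ddof=1) == 0
            if degenerate:
                p = 1.0 if np.isclose(x.mean(), ctrl_mean) else 0.0
                t = np.inf if p == 0.0 else 0.0
            else:
                t, p = stats.ttest_ind(x, ctrl, equal_var=equal_var)
            rows.append({
                "protein_id": pid, "sample": grp,
                "mean_ratio": float(ratios.mean()),
                "sem_ratio": float(ratios.std(ddof=1) / np.sqrt(len(ratios))),
                "n": int(len(x)),
                "t_statistic": float(t), "p_value": float(p),
                "degenerate_variance": bool(degenerate),
            })
    return pd.DataFrame(rows)
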