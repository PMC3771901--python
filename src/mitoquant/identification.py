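"""PSM filtering, target-decoy FDR, protein inference and identification QC.

Quantifiable evidence must clear three gates, applied in order: a
confidence filter (peptide probability >= 0.80 and protein probability
>= 0.90, boundaries inclusive), a target-decoy peptide-level FDR threshold
of 0.5%, and a >= 2 tag-labeled unique peptides rule per protein.  Peptides
mapping to more than one accession are excluded both from the uniqueness
count and from downstream quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FilterThresholds:
    peptide_prob_min: float = 0.80
    protein_prob_min: float = 0.90
    peptide_fdr_max: float = 0.005
    min_unique_labeled_peptides: int = 2


def apply_confidence_filters(psms: pd.DataFrame,
                             thresholds: FilterThresholds = FilterThresholds()
                             ) -> pd.DataFrame:
    """Retain PSMs meeting the peptide and protein probability thresholds
    (inclusive)."""
    for col in ("peptide_prob", "protein_prob"):
        if col not in psms.columns:
            raise KeyError(f"missing probability column {col!r}")
    keep = ((psms["peptide_prob"] >= thresholds.peptide_prob_min)
            & (psms["protein_prob"] >= thresholds.protein_prob_min))
    return psms.loc[keep].copy()


def estimate_peptide_fdr(psms: pd.DataFrame,
                         fdr_max: float = 0.005,
                         plus_one: bool = False
                         ) -> tuple[float, pd.DataFrame, float]:
    """Choose a peptide-probability cutoff controlling the target-decoy FDR.

    Returns ``(cutoff, filtered, fdr_at_cutoff)`` where ``cutoff`` is the
    most permissive score with ``#decoys>=cutoff / #targets>=cutoff`` at or
    below ``fdr_max`` and ``filtered`` contains the target PSMs at or above
    it (decoys removed).  ``plus_one`` switches the estimator to
    ``(#decoys+1)/#targets``.
    """
    if "is_decoy" not in psms.columns:
        raise KeyError("missing is_decoy column")
    is_decoy = psms["is_decoy"].astype(bool).to_numpy()
    if (~is_decoy).sum() == 0:
        raise ValueError("no target PSMs")
    scores = psms["peptide_prob"].to_numpy(dtype=float)

    order = np.argsort(scores)[::-1]  # descending score
    dec_cum = np.cumsum(is_decoy[order]).astype(float)
    tgt_cum = np.cumsum(~is_decoy[order]).astype(float)
    if plus_one:
        dec_cum = dec_cum + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(tgt_cum > 0, dec_cum / tgt_cum, np.inf)

    sorted_scores = scores[order]
    # candidate cutoffs are the distinct scores; the FDR at a cutoff is the
    # ratio at the last (lowest-scoring) PSM sharing that score
    last_of_score = np.nonzero(np.append(
        sorted_scores[1:] != sorted_scores[:-1], True))[0]
    cand_scores = sorted_scores[last_of_score]
    cand_fdr = fdr[last_of_score]
    ok = cand_fdr <= fdr_max
    if not ok.any():
        raise ValueError(
            f"no score cutoff attains FDR <= {fdr_max}; "
            "check the decoy score distribution")
    # most permissive = lowest score cutoff that satisfies the bound
    pick = np.nonzero(ok)[0][-1]
    cutoff = float(cand_scores[pick])
    realized = float(cand_fdr[pick])
    filtered = psms.loc[(scores >= cutoff) & ~is_decoy].copy()
    return cutoff, filtered, realized


def _accession_sets(protein_ids: pd.Series) -> pd.Series:
    return protein_ids.astype(str).str.split(";")


def infer_quantifiable_proteins(psms: pd.DataFrame,
                                min_unique_labeled_peptides: int = 2
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Infer quantifiable proteins from filtered PSMs.

    A peptide is *unique* when its sequence maps to exactly one accession;
    shared peptides are dropped from uniqueness counting and from
    quantification.  A protein is quantifiable when it has at least
    ``min_unique_labeled_peptides`` distinct tag-labeled unique peptides.

    Returns ``(groups, retained_psms)`` where ``groups`` has one row per
    quantifiable protein (protein_id, unique_labeled_peptide_count,
    spectral_count) and ``retained_psms`` are the unique-mapping PSMs of
    those proteins.
    """
    if psms.empty:
        empty = pd.DataFrame(columns=[
            "protein_id", "unique_labeled_peptide_count", "spectral_count"])
        return empty, psms.copy()
    acc = _accession_sets(psms["protein_ids"])
    n_acc = acc.str.len()
    unique_map = n_acc == 1
    work = psms.loc[unique_map].copy()
    work["protein_id"] = acc[unique_map].str[0]

    labeled = work.loc[work["is_labeled"].astype(bool)]
    pep_counts = (labeled.groupby("protein_id")["peptide"]
                  .nunique().rename("unique_labeled_peptide_count"))
    spectral = (work.groupby("protein_id")["peptide"]
                .size().rename("spectral_count"))
    groups = pd.concat([pep_counts, spectral], axis=1).fillna(0)
    groups["unique_labeled_peptide_count"] = (
        groups["unique_labeled_peptide_count"].astype(int))
    groups = groups.loc[
        groups["unique_labeled_peptide_count"] >= min_unique_labeled_peptides]
    groups = groups.reset_index().sort_values("protein_id",
                                              ignore_index=True)
    retained = work.loc[work["protein_id"].isin(groups["protein_id"])].copy()
    return groups, retained


def injection_overlap(set_a, set_b, mode: str = "jaccard") -> float:
    """Percentage overlap between the peptide sets of two injections.

    ``jaccard`` uses the union as denominator; ``mean-relative`` the mean of
    the two set sizes.
    """
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("both peptide sets are empty")
    inter = len(a & b)
    if mode == "jaccard":
        return 100.0 * inter / len(a | b)
    if mode == "mean-relative":
        return 100.0 * inter / ((len(a) + len(b)) / 2.0)
    raise ValueError(f"unknown overlap mode {mode!r}")


def filter_report(before: pd.DataFrame,
                  after_confidence: pd.DataFrame,
                  after_fdr: pd.DataFrame,
                  groups: pd.DataFrame,
                  retained: pd.DataFrame,
                  cutoff: float,
                  realized_fdr: float) -> dict:
    """Machine-readable audit of the identification funnel."""
    return {
        "psms_input": int(len(before)),
        "psms_after_confidence": int(len(after_confidence)),
        "psms_after_fdr": int(len(after_fdr)),
        "fdr_score_cutoff": float(cutoff),
        "fdr_realized": float(realized_fdr),
        "psms_quantifiable": int(len(retained)),
        "proteins_quantifiable": int(len(groups)),
    }
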