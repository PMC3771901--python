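"""Protein-mRNA concordance: matching, quadrant classification and rates.

Differential proteins are joined to their genes' expression-array log2
fold changes and plotted protein (ordinate) against mRNA (abscissa).
Sign agreement places a gene in quadrant 1 (both up) or 3 (both down) —
concordant, transcriptionally driven; disagreement places it in quadrant
2 or 4 — discordant, suggesting post-transcriptional regulation.  A zero
on either axis is a boundary case, excluded from the counts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def match_mrna(differential: pd.DataFrame,
               mrna: pd.DataFrame,
               group: str,
               id_map: Mapping[str, str] | None = None
               ) -> tuple[pd.DataFrame, int]:
    """Join differential proteins to their group's mRNA records.

    ``differential`` needs ``protein_id`` and ``protein_log2fc`` columns;
    ``mrna`` needs ``gene_id``, ``group`` and ``mrna_log2fc``.  ``id_map``
    translates protein accessions to gene ids (identity by default).
    Returns ``(matched, n_uncovered)``; uncovered proteins are excluded
    from quadrant statistics and only counted.
    """
    sub = mrna.loc[mrna["group"] == group, ["gene_id", "mrna_log2fc"]]
    if sub["gene_id"].duplicated().any():
        dupes = sub.loc[sub["gene_id"].duplicated(), "gene_id"].unique()
        raise ValueError(f"duplicate mRNA records for {list(dupes)[:3]}")
    out = differential.copy()
    out["gene_id"] = (out["protein_id"].map(id_map) if id_map
                      else out["protein_id"])
    matched = out.merge(sub, on="gene_id", how="inner")
    return matched, int(len(out) - len(matched))


def assign_quadrant(protein_log2fc: float, mrna_log2fc: float
                    ) -> tuple[str, bool]:
    """Cartesian quadrant of (mRNA, protein) and whether it is concordant.

    Returns ``(quadrant, concordant)`` with quadrant one of
    '1','2','3','4','boundary'.
    """
    p, m = float(protein_log2fc), float(mrna_log2fc)
    if not (np.isfinite(p) and np.isfinite(m)):
        raise ValueError("fold changes must be finite")
    if p == 0.0 or m == 0.0:
        return "boundary", False
    if p > 0 and m > 0:
        return "1", True
    if p > 0 and m < 0:
        return "2", False
    if p < 0 and m < 0:
        return "3", True
    return "4", False


def assign_quadrants(matched: pd.DataFrame) -> pd.DataFrame:
    """Vectorized quadrant assignment over a matched table."""
    out = matched.copy()
    qs, conc = zip(*(assign_quadrant(p, m) for p, m in
                     zip(out["protein_log2fc"], out["mrna_log2fc"]))) \
        if len(out) else ((), ())
    out["quadrant"] = list(qs)
    out["concordant"] = list(conc)
    return out


def concordance_rate(assignments: pd.DataFrame
                     ) -> tuple[dict[str, int], int]:
    """Quadrant counts and the concordant percentage.

    Percentage = 100*(Q1+Q3)/(Q1+Q2+Q3+Q4), rounded to the nearest integer
    as reported; boundary cases are counted but not in the denominator.
    """
    counts = {q: int((assignments["quadrant"] == q).sum())
              for q in ("1", "2", "3", "4", "boundary")}
    total = counts["1"] + counts["2"] + counts["3"] + counts["4"]
    if total == 0:
        raise ValueError("no non-boundary assignments")
    pct = int(round(100.0 * (counts["1"] + counts["3"]) / total))
    return counts, pct


def category_concordance(assignments: pd.DataFrame,
                         annotation: pd.DataFrame) -> pd.DataFrame:
    """Concordant/total per functional category.

    Boundary assignments are excluded.  Returns a table with columns
    category, concordant, total, percent (rounded to integer).
    """
    ann = annotation.set_index("protein_id")["category"]
    work = assignments.loc[assignments["quadrant"] != "boundary"].copy()
    work["category"] = work["protein_id"].map(ann)
    rows = []
    for cat, sub in work.groupby("category", dropna=False):
        conc = int(sub["concordant"].sum())
        tot = int(len(sub))
        rows.append({"category": cat, "concordant": conc, "total": tot,
                     "percent": int(round(100.0 * conc / tot))})
    return pd.DataFrame(rows).sort_values("category", ignore_index=True)


def pooled_concordance(pairs: Sequence[tuple[int, int]]) -> int:
    """Pooled concordant percentage over (concordant, total) category
    counts, rounded to the nearest integer."""
    conc = sum(k for k, _ in pairs)
    tot = sum(n for _, n in pairs)
    if tot == 0:
        raise ValueError("no proteins in the pooled categories")
    return int(round(100.0 * conc / tot))
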