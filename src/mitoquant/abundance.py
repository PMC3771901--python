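"""Spectral-count abundance strata, protein-length control and
functional-category proportion comparisons.

Spectral count (the number of MS/MS spectra matched to a protein) is a
rough absolute-abundance proxy.  Proteins are stratified as high (> 50
spectra), medium (10-50, inclusive) or low (< 10); the length-bin table
checks that strata are not merely a protein-size artefact.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

STRATA = ("high", "medium", "low")

#: length bins in amino acids; the top bin is open-ended (lengths beyond
#: 10000 are counted there with a warning upstream)
LENGTH_BINS = (0, 100, 500, 1000, 5000, np.inf)
LENGTH_LABELS = ("<=100", "100-500", "500-1000", "1000-5000", ">5000")


def stratify_abundance(spectral_count: int) -> str:
    """Map a spectral count to its stratum: >50 high, 10-50 medium
    (inclusive endpoints), <10 low."""
    c = int(spectral_count)
    if c < 0:
        raise ValueError("spectral count must be non-negative")
    if c > 50:
        return "high"
    if c >= 10:
        return "medium"
    return "low"


def stratify_abundance_series(counts: pd.Series) -> pd.Series:
    c = counts.astype(int)
    if (c < 0).any():
        raise ValueError("spectral counts must be non-negative")
    return pd.Series(
        np.where(c > 50, "high", np.where(c >= 10, "medium", "low")),
        index=counts.index, name="stratum")


def stratum_distribution(proteins: pd.DataFrame,
                         subset: Iterable[str] | None = None
                         ) -> dict[str, float]:
    """Percentage of proteins per stratum over ``subset`` (all by default).

    ``proteins`` must carry ``protein_id`` and ``spectral_count``.
    """
    work = proteins
    if subset is not None:
        subset = set(subset)
        work = proteins.loc[proteins["protein_id"].isin(subset)]
    if work.empty:
        raise ValueError("empty protein subset")
    strata = stratify_abundance_series(work["spectral_count"])
    n = len(work)
    return {s: 100.0 * int((strata == s).sum()) / n for s in STRATA}


def length_group_distribution(proteins: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum percentage distribution across protein-length bins.

    Rows are strata, columns length bins; each row sums to 100 (within
    rounding).  Requires ``spectral_count`` and ``length`` columns.
    """
    if (proteins["length"] <= 0).any():
        raise ValueError("protein lengths must be positive")
    work = proteins.copy()
    work["stratum"] = stratify_abundance_series(work["spectral_count"])
    work["length_bin"] = pd.cut(work["length"], bins=LENGTH_BINS,
                                labels=LENGTH_LABELS, right=True)
    out = np.zeros((len(STRATA), len(LENGTH_LABELS)))
    for i, s in enumerate(STRATA):
        sub = work.loc[work["stratum"] == s]
        if len(sub) == 0:
            continue
        counts = sub["length_bin"].value_counts()
        for j, lbl in enumerate(LENGTH_LABELS):
            out[i, j] = 100.0 * int(counts.get(lbl, 0)) / len(sub)
    return pd.DataFrame(out, index=list(STRATA), columns=list(LENGTH_LABELS))


def category_distribution(proteins: pd.DataFrame,
                          annotation: pd.DataFrame,
                          subset: Iterable[str] | None = None,
                          directions: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Per-category counts and percentages over a protein subset.

    When ``directions`` (protein_id, direction) is given — the differential
    calls of a group — an up/down split per category is added.  Percentages
    are of the subset size; unannotated proteins leave a remainder, so the
    percentages sum to at most 100.
    """
    ids = proteins["protein_id"]
    if subset is not None:
        ids = ids[ids.isin(set(subset))]
    n = len(ids)
    ann = annotation.set_index("protein_id")["category"]
    cats = ids.map(ann)
    rows = []
    for cat in sorted(c for c in cats.dropna().unique()
                      if c != "unassigned"):
        members = set(ids[cats == cat])
        row = {"category": cat, "count": len(members),
               "percent": 100.0 * len(members) / n if n else 0.0}
        if directions is not None:
            d = directions.loc[directions["protein_id"].isin(members),
                               "direction"]
            row["n_up"] = int((d == "up").sum())
            row["n_down"] = int((d == "down").sum())
        rows.append(row)
    return pd.DataFrame(rows)


def compare_proportions(k_a: int, n_a: int, k_b: int, n_b: int,
                        method: str = "fisher") -> float:
    """Two-sided p-value comparing proportions k_a/n_a vs k_b/n_b.

    Fisher's exact test on the 2x2 table by default (appropriate for the
    small category counts involved); a two-proportion z-test with pooled
    variance is available via ``method='z'``.
    """
    for k, n in ((k_a, n_a), (k_b, n_b)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError("invalid counts")
    if method == "fisher":
        table = [[k_a, n_a - k_a], [k_b, n_b - k_b]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "z":
        p_pool = (k_a + k_b) / (n_a + n_b)
        se = np.sqrt(p_pool * (1 - p_pool) * (1 / n_a + 1 / n_b))
        if se == 0:
            return 1.0
        z = (k_a / n_a - k_b / n_b) / se
        return float(2 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown method {method!r}")
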