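"""Reporter-ion quantification: impurity correction, channel normalization,
protein rollup and replicate QC.

Correction order follows the physics: isotope-impurity correction is a
per-spectrum effect and is undone at the PSM level first; channel
normalization (equalizing each channel's PSM-level median to the control
channel's) follows; protein intensities are then the sum of their retained
PSMs' corrected, normalized intensities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .channels import ChannelDesign, PurityMatrix


def correct_isotope_impurity(observed: np.ndarray,
                             purity: PurityMatrix
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Undo reporter cross-channel bleed by solving ``P @ x = observed``.

    ``observed`` is a vector of per-channel intensities or an array of
    shape ``(n, n_channels)``.  Negative solution components (possible for
    noisy spectra near zero) are clamped to 0; the returned boolean mask of
    the same shape flags clamped entries.
    """
    p = purity.matrix
    obs = np.asarray(observed, dtype=float)
    vec = obs.ndim == 1
    if vec:
        obs = obs[None, :]
    if obs.shape[1] != p.shape[0]:
        raise ValueError("intensity vector length does not match matrix")
    try:
        corrected = np.linalg.solve(p, obs.T).T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by ctor
        raise ValueError("singular purity matrix") from exc
    clamped = corrected < 0
    corrected = np.where(clamped, 0.0, corrected)
    if vec:
        return corrected[0], clamped[0]
    return corrected, clamped


def correct_psm_table(psms: pd.DataFrame,
                      purity: PurityMatrix,
                      design: ChannelDesign) -> tuple[pd.DataFrame, int]:
    """Apply impurity correction to every PSM's reporter vector.

    Returns the corrected table and the number of clamped (negative after
    correction) intensity entries.
    """
    samples = design.samples
    p = purity.reorder(design.channels)
    corrected, clamped = correct_isotope_impurity(
        psms[samples].to_numpy(dtype=float), p)
    out = psms.copy()
    out[samples] = corrected
    return out, int(clamped.sum())


def normalize_channels(psms: pd.DataFrame,
                       design: ChannelDesign
                       ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Scale each channel so its PSM-level median equals the reference
    channel's median; returns the scaled table and the scalars used."""
    samples = design.samples
    medians = {s: float(np.median(psms[s].to_numpy(dtype=float)))
               for s in samples}
    ref = medians[design.reference_sample]
    scalars = {}
    out = psms.copy()
    for s in samples:
        if medians[s] <= 0:
            raise ValueError(f"channel {s} has non-positive median intensity")
        scalars[s] = ref / medians[s]
        out[s] = out[s].to_numpy(dtype=float) * scalars[s]
    return out, scalars


def aggregate_protein_intensities(psms: pd.DataFrame,
                                  groups: pd.DataFrame,
                                  design: ChannelDesign) -> pd.DataFrame:
    """Roll PSM intensities up to proteins by summation.

    Returns a table indexed by protein_id with one summed-intensity column
    per sample plus ``spectral_count``.  PSM-level values stay available in
    the input table for the rank statistics downstream.
    """
    if "protein_id" not in psms.columns:
        raise KeyError("psms must carry a resolved protein_id column")
    wanted = set(groups["protein_id"])
    missing = wanted - set(psms["protein_id"])
    if missing:
        raise ValueError(
            f"proteins without retained PSMs: {sorted(missing)[:3]}")
    samples = design.samples
    sums = (psms.loc[psms["protein_id"].isin(wanted)]
            .groupby("protein_id")[samples].sum())
    table = sums.join(groups.set_index("protein_id")["spectral_count"])
    return table.sort_index()


def replicate_correlation(table: pd.DataFrame,
                          sample_a: str,
                          sample_b: str) -> tuple[float, float, int, int]:
    """Pearson r and least-squares slope between two samples' log2 protein
    intensities.

    Proteins with a non-positive intensity in either sample are excluded
    pairwise (never imputed).  Returns ``(r, slope, n_used, n_excluded)``.
    """
    a = table[sample_a].to_numpy(dtype=float)
    b = table[sample_b].to_numpy(dtype=float)
    ok = (a > 0) & (b > 0)
    n_excluded = int((~ok).sum())
    if ok.sum() < 3:
        raise ValueError("fewer than 3 proteins with positive intensities")
    la, lb = np.log2(a[ok]), np.log2(b[ok])
    r = float(stats.pearsonr(la, lb).statistic)
    slope = float(stats.linregress(la, lb).slope)
    return r, slope, int(ok.sum()), n_excluded


def fold_change_distribution(table: pd.DataFrame,
                             sample_a: str,
                             sample_b: str) -> dict[str, float]:
    """Distribution of between-replicate fold changes.

    Per protein, fold = max(a, b)/min(a, b); bins are [1, 1.2), [1.2, 1.5]
    and (1.5, inf) — both boundary folds land in the middle bin, matching
    the usual "smaller than 1.2 / between 1.2 and 1.5 / larger than 1.5"
    reading.  Returns percentages keyed '<1.2', '1.2-1.5', '>1.5'.
    """
    a = table[sample_a].to_numpy(dtype=float)
    b = table[sample_b].to_numpy(dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("fold changes require positive intensities")
    fold = np.maximum(a, b) / np.minimum(a, b)
    n = len(fold)
    low = (fold < 1.2).sum()
    mid = ((fold >= 1.2) & (fold <= 1.5)).sum()
    high = (fold > 1.5).sum()
    return {"<1.2": 100.0 * low / n,
            "1.2-1.5": 100.0 * mid / n,
            ">1.5": 100.0 * high / n}
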