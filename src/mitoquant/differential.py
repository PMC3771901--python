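"""Replicate-consensus differential-abundance calling.

Each sample group has two biological replicates, so comparing a group
against the two control replicates yields four crossed ratios per protein
(e.g. LOF1/C1, LOF1/C2, LOF2/C1, LOF2/C2), each with a Mann-Whitney p-value
computed on the protein's PSM-level reporter intensities in the two
channels.  A protein is called differential when both criteria hold:

1. at least one of the four ratios is > 1.5 or < 0.67 with p < 0.05, and
2. at least three of the four ratios lie on the same side of 1.0
   ("same trend"), each with p < 0.05.

Criterion 2 deliberately does not require the trend ratios to clear the
1.5/0.67 gate: the consensus is about reproducible direction across
replicate crossings, with one ratio large enough to matter.  The two
criteria must agree in direction; conflicting proteins are reported as not
called with a diagnostic flag.  This consensus is considerably stricter
than a single test at alpha = 0.05, so no multiple-testing correction is
applied by default (an optional Benjamini-Hochberg switch exists for
exploration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .channels import ChannelDesign

#: largest per-group size for which the exact Mann-Whitney null is used
EXACT_N_MAX = 12


def mann_whitney_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses the exact null distribution when ``min(len(a), len(b)) <= 12`` and
    the pooled values carry no ties, otherwise the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Mann-Whitney needs at least 2 values per side")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(a), len(b)) <= EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


@dataclass(frozen=True)
class ComparisonScheme:
    """The four replicate-cross comparisons for one group vs control."""

    group: str
    pairs: tuple[tuple[str, str], ...]
    up_threshold: float = 1.5
    down_threshold: float = 0.67
    alpha: float = 0.05
    #: strict inequalities on the fold gate (">1.5 or <0.67"); set False for
    #: inclusive boundaries
    strict: bool = True

    def __post_init__(self) -> None:
        if len(self.pairs) != 4:
            raise ValueError("a comparison scheme has exactly 4 pairs")
        if not self.down_threshold < 1.0 < self.up_threshold:
            raise ValueError("need down_threshold < 1 < up_threshold")


def default_schemes(design: ChannelDesign | None = None
                    ) -> dict[str, ComparisonScheme]:
    return {
        "LOF": ComparisonScheme("LOF", (("LOF1", "C1"), ("LOF1", "C2"),
                                        ("LOF2", "C1"), ("LOF2", "C2"))),
        "HOF": ComparisonScheme("HOF", (("HOF1", "C1"), ("HOF1", "C2"),
                                        ("HOF2", "C1"), ("HOF2", "C2"))),
    }


@dataclass(frozen=True)
class RatioTest:
    ratio: float
    p_value: float
    n_psms_used: int


@dataclass
class DifferentialCall:
    protein_id: str
    group: str
    direction: str  # up / down / none
    criterion1_met: bool
    criterion2_met: bool
    excluded_as_contaminant: bool = False
    flag: str = ""


def compute_ratio_tests(protein_intensity: pd.Series,
                        psm_intensities: dict[str, np.ndarray],
                        scheme: ComparisonScheme) -> list[RatioTest]:
    """The four ratio tests for one protein.

    The ratio compares protein-level summed intensities; the p-value
    compares the protein's PSM-level intensity sets between the two
    channels.  A zero control intensity makes the ratio undefined (NaN);
    fewer than 2 PSMs makes the p-value undefined (NaN).
    """
    out = []
    for sample, control in scheme.pairs:
        num = float(protein_intensity[sample])
        den = float(protein_intensity[control])
        ratio = num / den if den > 0 else float("nan")
        xa = psm_intensities[sample]
        xb = psm_intensities[control]
        if len(xa) >= 2 and len(xb) >= 2:
            p = mann_whitney_p(xa, xb)
        else:
            p = float("nan")
        out.append(RatioTest(ratio, p, int(min(len(xa), len(xb)))))
    return out


def classify_differential(tests: Sequence[RatioTest],
                          scheme: ComparisonScheme) -> DifferentialCall:
    """Apply the two-criteria consensus rule to four ratio tests."""
    if len(tests) != 4:
        raise ValueError("expected exactly 4 ratio tests")
    ratios = np.array([t.ratio for t in tests], dtype=float)
    pvals = np.array([t.p_value for t in tests], dtype=float)
    call = DifferentialCall("", scheme.group, "none", False, False)
    if np.isnan(ratios).any():
        call.flag = "undefined_ratio"
        return call
    if np.isnan(pvals).any():
        call.flag = "untestable"
        return call
    sig = pvals < scheme.alpha
    if scheme.strict:
        extreme_up = ratios > scheme.up_threshold
        extreme_down = ratios < scheme.down_threshold
    else:
        extreme_up = ratios >= scheme.up_threshold
        extreme_down = ratios <= scheme.down_threshold
    c1_up = bool((extreme_up & sig).any())
    c1_down = bool((extreme_down & sig).any())
    c2_up = int((sig & (ratios > 1.0)).sum()) >= 3
    c2_down = int((sig & (ratios < 1.0)).sum()) >= 3
    call.criterion1_met = c1_up or c1_down
    call.criterion2_met = c2_up or c2_down
    if call.criterion1_met and call.criterion2_met:
        if (c1_up and c2_up) and not (c1_down or c2_down):
            call.direction = "up"
        elif (c1_down and c2_down) and not (c1_up or c2_up):
            call.direction = "down"
        else:
            call.flag = "criteria_direction_conflict"
    return call


def exclude_contaminants(calls: pd.DataFrame,
                         annotation: pd.DataFrame,
                         excluded_organelles: Iterable[str]
                         ) -> tuple[pd.DataFrame, int]:
    """Reset differential calls of proteins annotated to excluded
    organelles; unannotated proteins are retained untouched.

    Returns the updated call table and the number of calls revoked.
    """
    excluded = set(excluded_organelles)
    out = calls.copy()
    if not excluded:
        return out, 0
    org = annotation.set_index("protein_id")["organelle"]
    hit = out["protein_id"].map(org).isin(excluded)
    revoked = hit & (out["direction"] != "none")
    out.loc[hit, "excluded_as_contaminant"] = True
    out.loc[revoked, "direction"] = "none"
    return out, int(revoked.sum())


def intersect_calls(calls_lof: pd.DataFrame,
                    calls_hof: pd.DataFrame) -> pd.DataFrame:
    """Proteins called differential in both groups, with per-group mean and
    SEM (sd/sqrt(4), sample sd) of the four ratios."""
    ratio_cols = [f"ratio_{i}" for i in range(1, 5)]
    frames = {}
    for name, df in (("lof", calls_lof), ("hof", calls_hof)):
        hit = df.loc[df["direction"] != "none",
                     ["protein_id", "direction"] + ratio_cols].copy()
        r = hit[ratio_cols].to_numpy(dtype=float)
        hit[f"mean_ratio_{name}"] = r.mean(axis=1)
        hit[f"sem_ratio_{name}"] = r.std(axis=1, ddof=1) / 2.0
        hit = hit.rename(columns={"direction": f"direction_{name}"})
        frames[name] = hit.drop(columns=ratio_cols)
    shared = frames["lof"].merge(frames["hof"], on="protein_id", how="inner")
    return shared.sort_values("protein_id", ignore_index=True)


class DifferentialAbundanceModel:
    """Differential-abundance model over a quantified protein table.

    Parameters
    ----------
    protein_table : DataFrame indexed by protein_id with one summed,
        corrected, normalized intensity column per sample (the output of
        ``reporter.aggregate_protein_intensities``).
    psms : DataFrame of the retained PSMs with a resolved ``protein_id``
        column and per-sample intensity columns; supplies the PSM-level
        intensity sets the rank tests run on.
    design : ChannelDesign.
    schemes : mapping group -> ComparisonScheme; defaults to the
        LOF/HOF-vs-control crossings.
    """

    def __init__(self,
                 protein_table: pd.DataFrame,
                 psms: pd.DataFrame,
                 design: ChannelDesign | None = None,
                 schemes: dict[str, ComparisonScheme] | None = None,
                 bh_correction: bool = False):
        self.design = design or ChannelDesign()
        self.protein_table = protein_table
        self.psms = psms
        self.schemes = schemes or default_schemes(self.design)
        self.bh_correction = bh_correction

    @classmethod
    def from_psm_table(cls, psms: pd.DataFrame, groups: pd.DataFrame,
                       design: ChannelDesign | None = None,
                       **kwargs) -> "DifferentialAbundanceModel":
        from .reporter import aggregate_protein_intensities
        design = design or ChannelDesign()
        table = aggregate_protein_intensities(psms, groups, design)
        return cls(table, psms, design, **kwargs)

    def fit(self) -> "DifferentialAbundanceResults":
        samples = self.design.samples
        by_protein = {
            pid: {s: sub[s].to_numpy(dtype=float) for s in samples}
            for pid, sub in self.psms.groupby("protein_id")
        }
        records = []
        for group, scheme in self.schemes.items():
            for pid, row in self.protein_table.iterrows():
                psm_int = by_protein.get(
                    pid, {s: np.empty(0) for s in samples})
                tests = compute_ratio_tests(row, psm_int, scheme)
                rec = {"protein_id": pid, "group": group,
                       "n_psms": len(next(iter(psm_int.values())))}
                for i, t in enumerate(tests, start=1):
                    rec[f"ratio_{i}"] = t.ratio
                    rec[f"p_{i}"] = t.p_value
                rec["_tests"] = tests
                records.append(rec)
        calls = pd.DataFrame(records)
        if self.bh_correction and len(calls):
            for i in range(1, 5):
                calls[f"p_{i}"] = _benjamini_hochberg(
                    calls[f"p_{i}"].to_numpy(dtype=float))
        rows = []
        for rec in calls.to_dict("records"):
            scheme = self.schemes[rec["group"]]
            tests = rec.pop("_tests")
            if self.bh_correction:
                tests = [RatioTest(t.ratio, rec[f"p_{i}"], t.n_psms_used)
                         for i, t in enumerate(tests, start=1)]
            c = classify_differential(tests, scheme)
            rec.update(direction=c.direction,
                       criterion1_met=c.criterion1_met,
                       criterion2_met=c.criterion2_met,
                       excluded_as_contaminant=False,
                       flag=c.flag)
            rows.append(rec)
        table = pd.DataFrame(rows, columns=[
            "protein_id", "group", "n_psms",
            "ratio_1", "ratio_2", "ratio_3", "ratio_4",
            "p_1", "p_2", "p_3", "p_4",
            "direction", "criterion1_met", "criterion2_met",
            "excluded_as_contaminant", "flag"])
        return DifferentialAbundanceResults(self, table)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


class DifferentialAbundanceResults:
    """Fitted differential calls with per-group accessors and a summary."""

    def __init__(self, model: DifferentialAbundanceModel,
                 calls: pd.DataFrame):
        self.model = model
        self.calls = calls

    def group_calls(self, group: str) -> pd.DataFrame:
        return self.calls.loc[self.calls["group"] == group].reset_index(
            drop=True)

    def differential(self, group: str) -> pd.DataFrame:
        g = self.group_calls(group)
        return g.loc[g["direction"] != "none"].reset_index(drop=True)

    def exclude_contaminants(self, annotation: pd.DataFrame,
                             excluded_organelles: Iterable[str]
                             ) -> "DifferentialAbundanceResults":
        calls, n = exclude_contaminants(self.calls, annotation,
                                        excluded_organelles)
        res = DifferentialAbundanceResults(self.model, calls)
        res.n_contaminants_excluded = n
        return res

    @property
    def shared(self) -> pd.DataFrame:
        groups = list(self.model.schemes)
        if len(groups) < 2:
            raise ValueError("need two groups for an intersection")
        return intersect_calls(self.group_calls(groups[0]),
                               self.group_calls(groups[1]))

    def mean_log2fc(self, group: str) -> pd.Series:
        """log2 of the mean of the four ratios, per differential protein;
        the protein-axis coordinate of the mRNA concordance plot."""
        d = self.differential(group)
        ratios = d[[f"ratio_{i}" for i in range(1, 5)]].to_numpy(dtype=float)
        return pd.Series(np.log2(ratios.mean(axis=1)),
                         index=d["protein_id"], name="protein_log2fc")

    def summary(self) -> str:
        lines = ["Differential abundance (replicate-consensus rule)",
                 "=" * 50]
        for group, scheme in self.model.schemes.items():
            d = self.differential(group)
            up = int((d["direction"] == "up").sum())
            down = int((d["direction"] == "down").sum())
            g = self.group_calls(group)
            untestable = int((g["flag"] == "untestable").sum())
            lines.append(
                f"{group:>4}: {len(d):4d} differential "
                f"({up} up, {down} down) of {len(g)} tested; "
                f"{untestable} untestable; gate >{scheme.up_threshold} or "
                f"<{scheme.down_threshold}, alpha={scheme.alpha}")
        try:
            lines.append(f"shared between groups: {len(self.shared)}")
        except ValueError:
            pass
        return "\n".join(lines)
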