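"""End-to-end orchestration: identification -> quantification ->
differential calling -> concordance -> abundance profile (-> MRM).

The run report mirrors the analysis funnel (spectra in, PSMs retained per
filter, quantifiable proteins, differential calls per group, shared calls,
concordance rates, abundance strata) so every headline number is auditable
from the stage outputs alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance, concordance, identification, mrm, reporter
from .channels import ChannelDesign, PurityMatrix
from .differential import (ComparisonScheme, DifferentialAbundanceModel,
                           DifferentialAbundanceResults, default_schemes)
from .identification import FilterThresholds
from .io import write_mask, write_table
from .simulate import (SimulationConfig, annotation_from_truth,
                       generate_labeled_mask, generate_mrm_table,
                       generate_mrna_table, generate_psm_table)

DEFAULT_EXCLUDED_ORGANELLES = ("nucleus", "extracellular", "cytoskeleton")


@dataclass
class RunConfig:
    """All pipeline knobs, defaulting to the reference protocol's values."""

    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    design: ChannelDesign = field(default_factory=ChannelDesign)
    purity: PurityMatrix | None = None
    normalize: bool = True
    excluded_organelles: tuple[str, ...] = DEFAULT_EXCLUDED_ORGANELLES
    up_threshold: float = 1.5
    down_threshold: float = 0.67
    alpha: float = 0.05
    strict_fold_gate: bool = True
    overlap_mode: str = "jaccard"
    sn_min: float = 10.0

    def schemes(self) -> dict[str, ComparisonScheme]:
        base = default_schemes(self.design)
        return {g: ComparisonScheme(g, s.pairs, self.up_threshold,
                                    self.down_threshold, self.alpha,
                                    self.strict_fold_gate)
                for g, s in base.items()}


@dataclass
class PipelineResult:
    report: dict
    protein_table: pd.DataFrame
    retained_psms: pd.DataFrame
    results: DifferentialAbundanceResults
    quadrants: dict[str, pd.DataFrame]


def run_pipeline(psms: pd.DataFrame,
                 config: RunConfig | None = None,
                 mrna: pd.DataFrame | None = None,
                 annotation: pd.DataFrame | None = None,
                 mrm_transitions: pd.DataFrame | None = None
                 ) -> PipelineResult:
    """Execute the full analysis on in-memory tables.

    ``mrna``, ``annotation`` and ``mrm_transitions`` are optional; the
    corresponding report sections appear only when they are supplied.
    """
    cfg = config or RunConfig()
    report: dict = {}

    # --- identification ---------------------------------------------------
    conf = identification.apply_confidence_filters(psms, cfg.thresholds)
    cutoff, fdr_filtered, realized = identification.estimate_peptide_fdr(
        conf, cfg.thresholds.peptide_fdr_max)
    groups, retained = identification.infer_quantifiable_proteins(
        fdr_filtered, cfg.thresholds.min_unique_labeled_peptides)
    if groups.empty:
        raise ValueError("no quantifiable proteins after filtering")
    report["identification"] = identification.filter_report(
        psms, conf, fdr_filtered, groups, retained, cutoff, realized)
    inj = retained.groupby("injection")["peptide"].agg(set)
    if len(inj) >= 2:
        keys = sorted(inj.index)[:2]
        report["identification"]["peptide_injection_overlap_pct"] = (
            identification.injection_overlap(inj[keys[0]], inj[keys[1]],
                                             cfg.overlap_mode))

    # --- reporter quantification -----------------------------------------
    n_clamped = 0
    if cfg.purity is not None:
        retained, n_clamped = reporter.correct_psm_table(
            retained, cfg.purity, cfg.design)
    scalars: dict[str, float] = {s: 1.0 for s in cfg.design.samples}
    if cfg.normalize:
        retained, scalars = reporter.normalize_channels(retained, cfg.design)
    table = reporter.aggregate_protein_intensities(
        retained, groups, cfg.design)
    qc: dict = {"normalization_scalars": scalars,
                "clamped_intensities": n_clamped}
    for a, b in (("C1", "C2"), ("LOF1", "LOF2"), ("HOF1", "HOF2")):
        if a in table.columns and b in table.columns:
            r, slope, n_used, n_exc = reporter.replicate_correlation(
                table, a, b)
            qc[f"pearson_r_{a}_{b}"] = r
            qc[f"slope_{a}_{b}"] = slope
    ref = cfg.design.reference_sample
    other_control = [s for s in cfg.design.samples
                     if cfg.design.group_of(s) == "C" and s != ref]
    if other_control:
        qc["replicate_fold_bins"] = reporter.fold_change_distribution(
            table, ref, other_control[0])
    report["quantification"] = qc

    # --- differential calling --------------------------------------------
    model = DifferentialAbundanceModel(table, retained, cfg.design,
                                       schemes=cfg.schemes())
    results = model.fit()
    if annotation is not None and cfg.excluded_organelles:
        results = results.exclude_contaminants(annotation,
                                               cfg.excluded_organelles)
    diff: dict = {}
    for group in cfg.schemes():
        d = results.differential(group)
        diff[group] = {"n_differential": int(len(d)),
                       "n_up": int((d["direction"] == "up").sum()),
                       "n_down": int((d["direction"] == "down").sum())}
    shared = results.shared
    diff["n_shared"] = int(len(shared))
    diff["n_differential_union"] = int(pd.concat(
        [results.differential(g)["protein_id"]
         for g in cfg.schemes()]).nunique())
    diff["n_contaminants_excluded"] = int(
        getattr(results, "n_contaminants_excluded", 0))
    report["differential"] = diff

    # --- concordance -------------------------------------------------------
    quadrants: dict[str, pd.DataFrame] = {}
    if mrna is not None:
        conc_report = {}
        for group in cfg.schemes():
            fc = results.mean_log2fc(group).reset_index()
            matched, uncovered = concordance.match_mrna(fc, mrna, group)
            assigned = concordance.assign_quadrants(matched)
            quadrants[group] = assigned
            entry = {"n_differential": int(len(fc)),
                     "n_covered": int(len(matched)),
                     "n_uncovered": int(uncovered)}
            if len(assigned) and (assigned["quadrant"] != "boundary").any():
                counts, pct = concordance.concordance_rate(assigned)
                entry["quadrant_counts"] = counts
                entry["concordant_pct"] = pct
            conc_report[group] = entry
        report["concordance"] = conc_report

    # --- abundance profile -------------------------------------------------
    proteins = table.reset_index()[["protein_id", "spectral_count"]]
    profile = {"strata_identified_pct":
               abundance.stratum_distribution(proteins)}
    diff_ids = pd.concat([results.differential(g)["protein_id"]
                          for g in cfg.schemes()]).unique()
    if len(diff_ids):
        profile["strata_differential_pct"] = abundance.stratum_distribution(
            proteins, diff_ids)
    if annotation is not None:
        merged = proteins.merge(annotation[["protein_id", "length"]],
                                on="protein_id", how="inner")
        if len(merged):
            profile["length_distribution"] = (
                abundance.length_group_distribution(merged)
                .round(2).to_dict())
    report["abundance_profile"] = profile

    # --- MRM confirmation ----------------------------------------------------
    if mrm_transitions is not None:
        ab = mrm.quantify_protein(mrm_transitions, cfg.sn_min)
        tested = mrm.normalize_and_test(ab)
        report["mrm"] = {
            "n_targets": int(tested["protein_id"].nunique()),
            "ratios": {
                f"{r.protein_id}:{r.sample}":
                    {"mean_ratio": r.mean_ratio, "p_value": r.p_value}
                for r in tested.itertuples()},
        }

    return PipelineResult(report, table, retained, results, quadrants)


def simulate_bundle(cfg: SimulationConfig,
                    out_dir,
                    n_mrm_targets: int = 10,
                    write_masks: bool = False,
                    mask_fractions: dict[str, float] | None = None
                    ) -> dict:
    """Write every synthetic input the pipeline consumes, plus the truth.

    Returns a manifest of the files written.  MRM targets are the
    largest-effect differential proteins of each group.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    psms, truth = generate_psm_table(cfg)
    mrna = generate_mrna_table(truth, cfg.mrna_concordance_prob,
                               seed=cfg.seed, coverage=cfg.mrna_coverage)
    ann = annotation_from_truth(truth)

    strength = np.maximum(truth["true_log2fc_lof"].abs(),
                          truth["true_log2fc_hof"].abs())
    targets = (truth.loc[strength > 0, "protein_id"]
               .iloc[np.argsort(-strength[strength > 0].to_numpy())]
               .head(n_mrm_targets).tolist())
    if not targets:
        targets = truth["protein_id"].head(n_mrm_targets).tolist()
    mrm_table = generate_mrm_table(targets, truth, seed=cfg.seed,
                                   noise_sigma=cfg.noise_sigma)

    manifest = {}
    for name, df in (("psms", psms), ("mrna", mrna), ("mrm", mrm_table),
                     ("annotation", ann), ("truth", truth)):
        path = out / f"{name}.tsv"
        write_table(df, path)
        manifest[name] = str(path)
    if write_masks:
        fractions = mask_fractions or {"C": 0.30, "LOF": 0.40, "HOF": 0.32}
        mask_dir = out / "masks"
        paths = []
        for gi, (grp, frac) in enumerate(sorted(fractions.items())):
            for k in range(9):
                m = generate_labeled_mask(
                    256, 256, frac, seed=cfg.seed + 1000 * gi + k)
                p = mask_dir / f"{grp}_{k:02d}.png"
                write_mask(m, p)
                paths.append(str(p))
        manifest["masks"] = paths
    return manifest
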