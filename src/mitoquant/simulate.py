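"""Synthetic-data generators with known ground truth.

These generators emulate, at the report level, every input the analysis
consumes: a PSM report from a 6-channel isobaric-tag run (two control, two
hypoxia-adapted and two hyperoxia-adapted samples), an expression-array
fold-change table, an MRM transition report, and labeled electron-micrograph
masks for point-counting stereology.  Simulation starts at the PSM report —
no chromatography, isotopic envelopes or raw spectra are modelled.

The forward model for reporter intensities is multiplicative on the log2
scale: a protein's baseline abundance is lognormal, each PSM carries its own
ionization efficiency, each channel applies the protein's true group effect,
lognormal measurement noise is added per channel, and finally the reporter
purity matrix mixes channels.  With all noise terms at zero and an identity
purity matrix the pipeline must recover the true fold changes exactly; that
limit is the main correctness oracle for the downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .channels import ChannelDesign, PurityMatrix

__all__ = [
    "SimulationConfig",
    "generate_psm_table",
    "generate_mrna_table",
    "generate_mrm_table",
    "generate_labeled_mask",
    "annotation_from_truth",
]

#: default functional-category mix (9 categories + unassigned remainder),
#: loosely following the composition of an insect flight-muscle
#: mitochondrial proteome (respiration-heavy).
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "respiratory_chain": 0.20,
    "membrane_transporter": 0.15,
    "carbohydrate_lipid_metabolism": 0.14,
    "calcium_regulation": 0.08,
    "peptide_amino_acid_metabolism": 0.08,
    "oxidation_sensitive": 0.07,
    "chaperone": 0.08,
    "translation": 0.09,
    "detoxification": 0.06,
    "unassigned": 0.05,
}

CONTAMINANT_ORGANELLES = ("nucleus", "extracellular", "cytoskeleton")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Fractions are in [0, 1]; effect sizes are |log2 fold change| bounds and
    must be positive; ``noise_sigma`` and ``psm_baseline_sigma`` are standard
    deviations of multiplicative lognormal noise on the log2 scale.
    """

    n_proteins: int = 500
    frac_differential_lof: float = 0.08
    frac_differential_hof: float = 0.10
    #: shared differential proteins as a fraction of the differential union
    frac_shared_differential: float = 15 / 115
    effect_log2_range: tuple[float, float] = (0.8, 2.0)
    noise_sigma: float = 0.1
    psm_baseline_sigma: float = 0.3
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    psms_per_protein_mean: float = 8.0
    psms_per_protein_min: int = 1
    decoy_fraction: float = 0.10
    frac_unlabeled: float = 0.01
    frac_contaminant: float = 0.03
    purity_matrix: PurityMatrix | None = None
    channel_design: ChannelDesign = field(default_factory=ChannelDesign)
    mrna_concordance_prob: float = 0.58
    mrna_coverage: float = 0.96
    category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        for name in ("frac_differential_lof", "frac_differential_hof",
                     "frac_shared_differential", "decoy_fraction",
                     "frac_unlabeled", "frac_contaminant",
                     "mrna_concordance_prob", "mrna_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.effect_log2_range
        if lo <= 0 or hi < lo:
            raise ValueError("effect_log2_range must be positive and ordered")
        if self.noise_sigma < 0 or self.psm_baseline_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.psms_per_protein_min < 1:
            raise ValueError("psms_per_protein_min must be >= 1")
        if self.psms_per_protein_mean < self.psms_per_protein_min:
            raise ValueError("psms_per_protein_mean below the minimum")
        total = sum(self.category_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("category_weights must sum to 1")
        if self.purity_matrix is not None:
            want = self.channel_design.channels
            if sorted(self.purity_matrix.channels) != sorted(want):
                raise ValueError("purity matrix channels do not match design")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng_child(seed: int, stream: int) -> np.random.Generator:
    # one root SeedSequence per config seed, split per generator so each
    # table can be regenerated independently of the others
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(8)[stream])


def _assign_differential(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_proteins
    n_lof = round(cfg.frac_differential_lof * n)
    n_hof = round(cfg.frac_differential_hof * n)
    f = cfg.frac_shared_differential
    # solve shared = f * union, union = n_lof + n_hof - shared
    n_shared = int(round(f * (n_lof + n_hof) / (1.0 + f)))
    n_shared = min(n_shared, n_lof, n_hof)
    perm = rng.permutation(n)
    lof_idx = perm[:n_lof]
    hof_idx = np.concatenate(
        [perm[:n_shared], perm[n_lof:n_lof + (n_hof - n_shared)]])

    lo, hi = cfg.effect_log2_range
    sign_lof = rng.choice([-1.0, 1.0], size=n)
    sign_hof = rng.choice([-1.0, 1.0], size=n)
    sign_hof[perm[:n_shared]] = sign_lof[perm[:n_shared]]  # shared direction

    fc_lof = np.zeros(n)
    fc_hof = np.zeros(n)
    fc_lof[lof_idx] = sign_lof[lof_idx] * rng.uniform(lo, hi, size=n_lof)
    fc_hof[hof_idx] = sign_hof[hof_idx] * rng.uniform(lo, hi, size=n_hof)
    return fc_lof, fc_hof


def generate_psm_table(
        cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a PSM report and its ground truth.

    Returns ``(psms, truth)``.  ``psms`` has one row per peptide-spectrum
    match with identification metadata and one reporter-intensity column per
    sample; ``truth`` has one row per simulated protein with its true log2
    fold changes, differential flags, functional annotation and length.

    The simulator-only columns ``is_false_target`` (target PSMs that are
    wrong matches, score-distributed like decoys) exist for evaluating FDR
    control; no analysis stage reads them.
    """
    rng = _rng_child(cfg.seed, 0)
    design = cfg.channel_design
    samples = design.samples
    n = cfg.n_proteins

    protein_ids = np.array([f"P{i:05d}" for i in range(n)])
    abundance = 2.0 ** rng.normal(cfg.baseline_log2_mean,
                                  cfg.baseline_log2_sd, size=n)
    lengths = np.clip(
        np.round(2.0 ** rng.normal(np.log2(450.0), 0.9, size=n)),
        50, 9000).astype(int)

    fc_lof, fc_hof = _assign_differential(cfg, rng)

    # functional category and organelle annotation
    cats = list(cfg.category_weights)
    weights = np.array([cfg.category_weights[c] for c in cats])
    category = rng.choice(cats, size=n, p=weights / weights.sum())
    organelle = np.full(n, "mitochondria", dtype=object)
    contam = rng.random(n) < cfg.frac_contaminant
    organelle[contam] = rng.choice(CONTAMINANT_ORGANELLES, size=contam.sum())

    # PSM counts: protein-specific Poisson rate proportional to abundance,
    # shifted so every protein yields at least psms_per_protein_min PSMs;
    # ties spectral counts to abundance, giving the heavy-tailed spread the
    # abundance strata assume.
    lam = ((cfg.psms_per_protein_mean - cfg.psms_per_protein_min)
           * abundance / abundance.mean())
    n_psms = rng.poisson(lam) + cfg.psms_per_protein_min
    total = int(n_psms.sum())
    idx = np.repeat(np.arange(n), n_psms)

    # per-channel true effects (log2): replicates of a strain share the
    # strain's effect, controls sit at baseline
    group_fc = {"C": np.zeros(n), "LOF": fc_lof, "HOF": fc_hof}
    effects = np.column_stack(
        [group_fc[design.group_of(s)] for s in samples])

    base = (abundance[idx] / n_psms[idx]
            * 2.0 ** rng.normal(0.0, cfg.psm_baseline_sigma, size=total))
    true_mat = base[:, None] * 2.0 ** effects[idx]
    if cfg.noise_sigma > 0:
        true_mat = true_mat * 2.0 ** rng.normal(
            0.0, cfg.noise_sigma, size=true_mat.shape)

    purity = cfg.purity_matrix
    if purity is not None:
        p = purity.reorder(design.channels).matrix
        observed = true_mat @ p.T
    else:
        observed = true_mat

    # distinct peptides per protein: ~60% of PSM count, at least 2 where
    # possible, assigned round-robin so every peptide is actually observed
    n_pep = np.minimum(n_psms, np.maximum(2, np.round(0.6 * n_psms))).astype(int)
    pep_slot = np.concatenate([np.arange(k) % n_pep[i]
                               for i, k in enumerate(n_psms)])
    peptides = np.array([f"{protein_ids[i]}_pep{j:02d}"
                         for i, j in zip(idx, pep_slot)])

    protein_prob_map = np.where(
        rng.random(n) < 0.97,
        0.90 + 0.10 * rng.random(n),
        0.50 + 0.40 * rng.random(n))

    psms = pd.DataFrame({
        "spectrum_id": [f"scan{k:06d}" for k in range(total)],
        "peptide": peptides,
        "protein_ids": protein_ids[idx],
        "peptide_prob": rng.beta(12.0, 1.0, size=total),
        "protein_prob": protein_prob_map[idx],
        "is_decoy": np.zeros(total, dtype=bool),
        "is_labeled": rng.random(total) >= cfg.frac_unlabeled,
        "is_false_target": np.zeros(total, dtype=bool),
        "injection": np.where(rng.random(total) < 0.5, "inj1", "inj2"),
    })
    for j, s in enumerate(samples):
        psms[s] = observed[:, j]

    # decoy PSMs plus an equal number of wrong target matches, both with
    # scores from a low distribution overlapping the target score tail
    if cfg.decoy_fraction > 0:
        n_dec = int(round(cfg.decoy_fraction / (1.0 - cfg.decoy_fraction)
                          * total))
        extra_frames = []
        for kind in ("decoy", "false"):
            if n_dec == 0:
                continue
            inten = (2.0 ** rng.normal(cfg.baseline_log2_mean - 2.0,
                                       cfg.baseline_log2_sd, size=n_dec)
                     [:, None]
                     * 2.0 ** rng.normal(0.0, max(cfg.noise_sigma, 0.2),
                                         size=(n_dec, len(samples))))
            if kind == "decoy":
                prot = [f"DECOY_{k:05d}" for k in range(n_dec)]
                pep = [f"DECOYPEP_{k:05d}" for k in range(n_dec)]
                pprob = rng.beta(3.0, 5.0, size=n_dec)
            else:
                hit = rng.integers(0, n, size=n_dec)
                prot = protein_ids[hit]
                pep = [f"FALSEPEP_{k:05d}" for k in range(n_dec)]
                pprob = protein_prob_map[hit]
            frame = pd.DataFrame({
                "spectrum_id": [f"scan_{kind}{k:06d}" for k in range(n_dec)],
                "peptide": pep,
                "protein_ids": prot,
                "peptide_prob": rng.beta(3.0, 5.0, size=n_dec),
                "protein_prob": pprob,
                "is_decoy": kind == "decoy",
                "is_labeled": rng.random(n_dec) >= cfg.frac_unlabeled,
                "is_false_target": kind == "false",
                "injection": np.where(rng.random(n_dec) < 0.5,
                                      "inj1", "inj2"),
            })
            for j, s in enumerate(samples):
                frame[s] = inten[:, j]
            extra_frames.append(frame)
        if extra_frames:
            psms = pd.concat([psms] + extra_frames, ignore_index=True)

    truth = pd.DataFrame({
        "protein_id": protein_ids,
        "true_log2fc_lof": fc_lof,
        "true_log2fc_hof": fc_hof,
        "is_differential_lof": fc_lof != 0.0,
        "is_differential_hof": fc_hof != 0.0,
        "category": category,
        "organelle": organelle,
        "length": lengths,
        "baseline_abundance": abundance,
        "n_psms": n_psms,
    })
    return psms, truth


def annotation_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Project the ground-truth table onto an annotation table
    (protein_id, organelle, category, length)."""
    return truth[["protein_id", "organelle", "category", "length"]].copy()


def generate_mrna_table(truth: pd.DataFrame,
                        concordance_prob: float,
                        seed: int,
                        coverage: float = 0.96,
                        magnitude_range: tuple[float, float] = (0.3, 2.0),
                        null_sd: float = 0.25) -> pd.DataFrame:
    """Simulate an expression-array fold-change table matched to ``truth``.

    For each covered gene and each group, a differential protein's mRNA
    log2 fold change agrees in sign with the protein's true effect with
    probability ``concordance_prob`` (magnitude uniform in
    ``magnitude_range``); non-differential proteins get small centred
    changes.  A fraction ``1 - coverage`` of genes is absent, emulating
    array non-coverage.  Gene ids equal protein ids.
    """
    if truth.empty:
        raise ValueError("ground truth is empty")
    if not 0.0 <= concordance_prob <= 1.0:
        raise ValueError("concordance_prob must lie in [0, 1]")
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    lo, hi = magnitude_range
    covered = rng.random(len(truth)) < coverage
    rows = []
    for group in ("LOF", "HOF"):
        fc = truth[f"true_log2fc_{group.lower()}"].to_numpy()
        mag = rng.uniform(lo, hi, size=len(truth))
        agree = rng.random(len(truth)) < concordance_prob
        sign = np.where(agree, np.sign(fc), -np.sign(fc))
        val = np.where(fc != 0.0, sign * mag,
                       rng.normal(0.0, null_sd, size=len(truth)))
        rows.append(pd.DataFrame({
            "gene_id": truth["protein_id"].to_numpy()[covered],
            "group": group,
            "mrna_log2fc": val[covered],
        }))
    return pd.concat(rows, ignore_index=True)


def generate_mrm_table(targets: Sequence[str],
                       truth: pd.DataFrame,
                       transitions_per_peptide: int = 3,
                       seed: int = 0,
                       noise_sigma: float = 0.1,
                       frac_below_sn: float = 0.1,
                       bio_replicates: int = 2,
                       tech_replicates: int = 3) -> pd.DataFrame:
    """Simulate an MRM transition report for ``targets``.

    One proteotypic peptide per target, ``transitions_per_peptide``
    transitions, measured in control/LOF/HOF x ``bio_replicates`` biological
    x ``tech_replicates`` technical injections.  Transition areas scale with
    the group's true fold change under multiplicative lognormal noise;
    signal-to-noise is drawn so that ``frac_below_sn`` of transitions falls
    below the S/N>10 quantification filter.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("empty target list")
    known = set(truth["protein_id"])
    missing = [t for t in targets if t not in known]
    if missing:
        raise ValueError(f"targets not in ground truth: {missing[:3]}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    tr = truth.set_index("protein_id")
    rows = []
    for pid in targets:
        fc = {"C": 0.0,
              "LOF": float(tr.at[pid, "true_log2fc_lof"]),
              "HOF": float(tr.at[pid, "true_log2fc_hof"])}
        peptide = f"PEP_{pid}"
        base_areas = 1e5 * 2.0 ** rng.normal(0.0, 1.0,
                                             size=transitions_per_peptide)
        q1 = np.round(rng.uniform(400.0, 900.0), 2)
        for t in range(transitions_per_peptide):
            q3 = np.round(rng.uniform(200.0, 1200.0), 2)
            for group in ("C", "LOF", "HOF"):
                for bio in range(1, bio_replicates + 1):
                    for tech in range(1, tech_replicates + 1):
                        area = base_areas[t] * 2.0 ** fc[group]
                        if noise_sigma > 0:
                            area *= 2.0 ** rng.normal(0.0, noise_sigma)
                        if rng.random() < frac_below_sn:
                            sn = rng.uniform(1.0, 10.0)
                        else:
                            sn = rng.uniform(10.5, 120.0)
                        rows.append((pid, peptide, f"{peptide}_y{t+1}",
                                     q1, q3, area, sn, group, bio, tech))
    return pd.DataFrame(rows, columns=[
        "protein_id", "peptide", "transition_id", "q1", "q3", "area",
        "signal_to_noise", "sample", "bio_replicate", "tech_replicate"])


def generate_labeled_mask(width: int,
                          height: int,
                          true_fraction: float,
                          seed: int = 0,
                          smooth_sigma: float = 8.0,
                          excluded_fraction: float = 0.0) -> np.ndarray:
    """Simulate a labeled micrograph mask for stereology.

    Returns an ``(height, width)`` uint8 array with labels
    {0 excluded, 1 cytoplasm, 2 mitochondrion}.  Mitochondrial regions are
    connected blobs (thresholded smooth Gaussian field); the threshold is
    set at the exact quantile so the realized mitochondrial pixel fraction
    of the non-excluded area is within 1% of ``true_fraction``.
    """
    if width < 8 or height < 8:
        raise ValueError("mask dimensions too small")
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must lie in [0, 1]")
    if not 0.0 <= excluded_fraction < 1.0:
        raise ValueError("excluded_fraction must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    field_ = ndimage.gaussian_filter(
        rng.standard_normal((height, width)), smooth_sigma, mode="wrap")
    mask = np.ones((height, width), dtype=np.uint8)
    if excluded_fraction > 0:
        excl_field = ndimage.gaussian_filter(
            rng.standard_normal((height, width)), smooth_sigma, mode="wrap")
        thr = np.quantile(excl_field, 1.0 - excluded_fraction)
        mask[excl_field >= thr] = 0
    inside = mask == 1
    vals = field_[inside]
    if true_fraction >= 1.0:
        mask[inside] = 2
    elif true_fraction > 0.0:
        thr = np.quantile(vals, 1.0 - true_fraction)
        mito = inside & (field_ >= thr)
        mask[mito] = 2
    return mask
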