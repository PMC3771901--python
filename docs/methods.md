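# Methods

## Scope and model

`mitoquant` implements report-level quantitative analysis of a 6-channel
isobaric-tag experiment comparing two adapted fly strains (LOF, HOF)
against room-air controls (C), two biological replicates each.  The
pipeline consumes PSM report tables (peptide-spectrum matches with
confidence scores, decoy flags and per-channel reporter intensities); the
database search that produces them is out of scope, as are chromatography,
labeling chemistry and raw-spectrum processing.

The quantitative model is multiplicative on the log2 scale.  For protein
*i* with true group effect `beta_g` (log2 fold change vs control), the
reporter intensity of PSM *k* in the channel of sample *s* is

    I_iks = b_ik * 2^(beta_g(s)) * 2^(eps_iks),   eps ~ N(0, sigma^2)

where `b_ik` is the PSM's ionization-scaled share of the protein's
baseline abundance.  Observed intensities are additionally mixed across
channels by the reagent purity matrix `P` (`obs = P @ true`).  The
analysis inverts this model stepwise: impurity correction solves the
linear system per spectrum; median normalization to the control channel
removes global loading differences; summation rolls PSMs up to proteins;
ratio statistics compare channels.

## Identification filters

Defaults follow the reference protocol: peptide probability ≥ 0.80 and
protein probability ≥ 0.90 (inclusive boundaries), target-decoy peptide
FDR ≤ 0.5%, and ≥ 2 distinct tag-labeled unique peptides per protein.
The FDR estimator is the plain decoy/target ratio at the score cutoff —
the common practice of the instrument generation this design comes from —
with an optional `(decoys+1)/targets` correction.  The chosen cutoff is
the most permissive score satisfying the bound.  "Unique" means the
peptide sequence maps to exactly one accession in the supplied table
(modifications ignored); shared peptides are excluded from uniqueness
counting *and* from quantification.  No parsimony-style protein grouping
is attempted beyond accession identity.

Injection overlap defaults to the Jaccard form
(`100·|A∩B|/|A∪B|`); a mean-relative denominator is available because the
published 78% figure does not state its denominator.

## Differential consensus rule

Per protein and group, the four crossed ratios (sample replicate ÷
control replicate) are computed from protein-level summed intensities;
each ratio's p-value is a two-sided Mann-Whitney U test on the protein's
PSM-level intensities in the two channels.  The exact null distribution
is used when both sides have ≤ 12 observations and the pooled values are
tie-free; otherwise the normal approximation with tie and continuity
corrections.  A protein is called differential iff

1. at least one ratio is > 1.5 or < 0.67 with p < 0.05 (strict
   inequalities; configurable to inclusive), and
2. at least three ratios lie on the same side of 1.0, each with p < 0.05.

Criterion 2 deliberately requires only a reproducible *direction*, not
that the trend ratios clear the 1.5/0.67 gate — mean fold changes around
1.3 in confirmed calls are only consistent with this reading.  The two
criteria must agree in direction; conflicts are reported as no-calls with
a diagnostic flag, as are proteins with undefined ratios (zero control
intensity) or too few PSMs to test (< 2 per channel) — nothing is
silently dropped.  Because the consensus is far stricter than a single
α = 0.05 test (measured null-call rate ≈ 0 at the default study size), no
multiple-testing correction is applied by default; Benjamini-Hochberg
across proteins is available but off.

Annotated contaminants (default: nucleus, extracellular, cytoskeleton)
have their calls revoked and flagged rather than removed.  Shared calls
between groups report mean ± SEM (sd/√4) of the four ratios.

## Concordance and abundance profile

A differential protein's plotted fold change is the log2 of the mean of
its four ratios (matching the mean ± SEM presentation of the calls); the
mRNA axis is the expression-array log2 fold change, consumed as given.
Quadrants follow Cartesian numbering with protein on the ordinate;
quadrants 1/3 are concordant.  An exact zero on either axis is a boundary
case: counted, excluded from the rate's denominator.  Percentages are
reported rounded to integers.  The concordance rate is invariant to
swapping the axes (Q2 and Q4 exchange).

Spectral-count strata are > 50 (high), 10–50 inclusive (medium), < 10
(low); the three strata partition the non-negative integers.  Length bins
are (0,100], (100,500], (500,1000], (1000,5000] and an open-ended top bin
(the nominal 10000 cap is treated as open for robustness).  Category
proportions are compared with Fisher's exact test — chosen over an
unnamed large-sample test because the per-category counts are small — with
a two-proportion z-test as an alternative.

## MRM quantification

Digestion is strict trypsin (cleave after K/R, not before P, zero missed
cleavages).  Candidate peptides must be proteome-unique, C/M-free and
7–25 aa.  Abundance per protein/sample/replicate is the sum of transition
areas with S/N strictly above 10.  Ratios are normalized to the mean
control abundance and tested with a two-sided pooled-variance t-test
(Welch optional).  All biological × technical measurements enter the test
(n = 2 × 3 = 6 per group in the reference design); collapsing technical
replicates first is available via `average_technical=True`, but is not
the default because the reference analysis is reported at n = 6, which is
only attainable when technical replicates count as measurements.
Zero-variance degenerate comparisons are flagged explicitly (p = 1 when
groups coincide, p = 0 with a `degenerate_variance` flag when separated).

## Stereology

Grid intercepts are read at the cell centers of an evenly spaced
rows × cols lattice (9 × 13 by default); cell centers avoid border-pixel
bias and make manual recounts reproducible.  Volume fraction is
`100·mito/(mito+cyto)`; excluded intercepts never enter the denominator.
Object density is the 8-connected component count of the mitochondrion
label per non-excluded area.  Group means are reported ± SEM (sd/√n) and
compared with a two-sample t-test by default (the reference figure does
not name its test); Mann-Whitney is available.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

- Baseline protein abundance lognormal (log2 mean 10, sd 2), producing
  the heavy-tailed spectral-count spread the strata assume.
- PSM count per protein: Poisson with a protein-specific rate
  proportional to abundance, shifted so every protein has at least
  `psms_per_protein_min` (default 1) PSMs; the mean is
  `psms_per_protein_mean` (default 8).
- Differential fractions default to 8% (LOF) and 10% (HOF) with a shared
  fraction of 15/115 of the differential union, matching the scale of
  the motivating study; effect magnitudes uniform in [0.8, 2.0] log2
  units, shared proteins sharing a direction.
- Noise: per-PSM ionization spread (log2 sd 0.3) plus per-channel
  measurement noise (log2 sd 0.1); both multiplicative lognormal.
  Channel loading biases are off by default so that the zero-noise limit
  is exactly invertible.
- Decoy PSMs (10% of the table) and an equal number of wrong target
  matches share a low score distribution (Beta(3,5)) overlapping the
  target tail (Beta(12,1)); the wrong-match flag is a simulator-only
  column no pipeline stage reads, used to measure realized FDR.
- mRNA fold changes agree in sign with the protein truth with probability
  0.58 (between the 55% and 61% rates reported for the two strains) at
  96% array coverage.
- MRM transitions scale with the group's true fold change; S/N is drawn
  so a configurable fraction fails the > 10 filter.
- Stereology phantoms are thresholded smooth Gaussian fields; the
  threshold is the exact quantile, so realized area fraction matches the
  target within 1%.

All randomness flows from a single seed through a splittable
`SeedSequence`, so each table can be regenerated independently and
identical configurations are byte-identical.

What the generator does **not** emulate: retention-time or batch drift,
missing reporter channels, isotopic-envelope structure, peptide-level
ionization biases correlated with sequence, shared peptides between
homologs, or array-platform normalization artifacts.  Passing tests
therefore demonstrate correctness of the analysis logic under the model's
own assumptions, not robustness to every artifact of real instrument
data.

## Numerical and design choices

- Impurity correction uses a dense linear solve per spectrum; negative
  components (possible near zero intensity) are clamped to zero and
  counted, never imputed.
- Zeros propagate: proteins with a zero in a compared channel are
  excluded pairwise from correlations and flagged in ratio tests.
- Normalization equalizes PSM-level medians (protein-level normalization
  was the plausible alternative; PSM level was chosen because
  contamination and loading act per spectrum).  The operation is
  idempotent.
- Fold-change bins close the middle interval: folds of exactly 1.2 or
  1.5 count as "1.2–1.5".
- Exact-test branches are verified against independent brute-force
  oracles (full permutation enumeration for Mann-Whitney; exact-rational
  hypergeometric enumeration for Fisher) in the test suite.
- Default problem sizes in tests and the acceptance script (500 proteins,
  10–20 seeds, 512² phantoms with 200² grids) were chosen as the smallest
  sizes at which the measured rates are stable to well under the asserted
  margins.

## Known limitations

- Protein inference is accession-identity only; no parsimony grouping or
  razor-peptide logic.
- The FDR estimator is the simple ratio form; concatenated vs separate
  decoy search semantics are not modelled.
- The consensus rule's power depends strongly on per-protein PSM counts
  (a protein with 2–3 PSMs per channel can rarely reach p < 0.05 in a
  rank test), so sensitivity claims hold only under adequate sampling
  (≥ 6 PSMs per protein).
- mRNA matching assumes one record per gene per group and a supplied
  protein→gene mapping (identity by default).
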