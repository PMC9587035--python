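# Methods

`refstab` implements the statistical workflow used to select and
validate reference (housekeeping) genes for RT-qPCR in the developing
mouse lung: candidate pre-selection from pooled expression variability,
GeNorm and NormFinder stability analysis of quantification-cycle (Cq)
data under grouped conditions, inter-run plate calibration, microarray
matrix preparation, and single-cell expression profiling. This note
describes the models, the estimators, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Data model

A `CqTable` is a genes × samples matrix of Cq values with per-sample
metadata: postnatal day (`pnd`, days), developmental stage
(`PND2.5` / `PND5.5` / `PND14.5-28.5`), `sex`, inspired oxygen fraction
(`fio2`, 0.21 = room air, 0.8 = hyperoxia), RNA Integrity Number
(`rin`, 1–10, split at 5), and PCR `plate`. Cq values must lie in
(0, 45); non-detects are stored as missing, never imputed to a ceiling
cycle, because downstream analyses either delete listwise or exclude
the gene outright (`drop_undetected_genes`). One Cq cycle corresponds
to a factor of the amplification efficiency *E* in expression; *E* is
fixed at 2.0 (perfect doubling) package-wide and configurable — no
per-gene efficiencies are modeled.

## Candidate pre-selection

Candidates from four sources (literature, reference-gene studies, an
expression-compendium query, a vendor panel) are:

1. **Banded** by log2 signal intensity: high > 13.00,
   medium 10.00–13.00 (closed interval — both boundaries are medium),
   low < 10.00. Boundary assignment is overridable.
2. **Pruned** by rules applied in a fixed precedence order —
   duplicate → pseudogene → ribosomal prefix (`Rpl`/`Rps`, with a
   keep-list for a retained representative) → manual veto — so each
   excluded gene carries exactly one primary reason even when several
   criteria apply.
3. **Ranked** by the pooled variability score
   `sd_overall = sqrt((sd_ref² + sd_array²)/2)`, the square root of
   the unweighted average of the two source variances (log2 scale).
   The average is unweighted even though the two sources have very
   different sample sizes; this is the printed definition and is kept
   as-is. Ties share the lower rank and order alphabetically.
4. **Selected**: the top-*n* lowest-SD genes plus *m* extra genes drawn
   uniformly without replacement from a deeper rank window, seeded for
   reproducibility. The historical panel shipped as a fixture cannot
   be regenerated because the original random draw is unrecoverable.

## GeNorm

Cq is converted to linear relative quantities
`a_gs = E^(min_s Cq_g − Cq_gs)` (per-gene maximum 1). For genes *j*,
*k*, the pairwise variation `V_jk` is the sample SD (n−1 denominator)
of `log2(a_j/a_k)`; the stability measure `M_j` is the mean of `V_jk`
over all partners. Ranking is by iterative exclusion: the gene with
the highest M is removed (ties: the alphabetically last symbol is
removed first) and M recomputed until two genes remain; these form the
final pair, tied at rank 1 (the next gene ranks 3). The reported M is
each gene's M at its removal round, matching classic geNorm output
tables; a first-round M column is also emitted. The V(n/n+1) ladder
between geometric-mean normalization factors of the top-n and
top-(n+1) genes is provided as the standard companion output.

M is invariant under per-sample multiplicative factors (template load,
hence also additive per-sample Cq shifts such as inter-run calibration)
and per-gene constants; both invariances are asserted in tests.
Missing data are handled by listwise deletion within each analysis
subset, with removed samples reported.

## NormFinder

Gene-centered log2 expression `z_igj = y_igj − mean_i y_igj` (with
`y = −log2(E)·Cq`) removes sample-specific effects. The model
decomposes z into a systematic between-group difference `d_ig` and
within-group noise `σ²_ig`. Because centering mixes every gene's noise
into each z, the naive within-group variance is biased; the de-mixing
corrections (for k genes) are:

    v_ig   = sample variance of z_igj
    S_g    = (k/(k−1)) Σ_i v_ig
    σ̂²_ig = max(0, (v_ig − S_g/k²) · k/(k−2))        (needs k ≥ 3)

With G ≥ 2 groups, `d̂_ig = z̄_ig − mean_g z̄_ig` (summing to zero over
genes within each group),

    γ̂² = max(0, Σ d̂²/((G−1)(k−1)) − (1/(Gk)) Σ σ̂²_ig/n_g)

and empirical-Bayes shrinkage `d̃ = d̂·γ̂²/(γ̂² + σ̂²/n_g)`. The
stability value is `SV_i = sqrt(σ̂²_i)` for a single group and

    SV_i = (1/G) Σ_g [ |d̃_ig| + sqrt((σ̂²_ig/n_g)·γ̂²/(γ̂²+σ̂²_ig/n_g)) ]

for grouped analyses; lower is more stable. All variance estimates are
truncated at zero; when `γ̂² = 0` the shrinkage factor is defined as 0
and the grouped SV reduces continuously to zero intergroup
contribution. Correctness is enforced by simulation-recovery tests
(parameter recovery within Monte-Carlo error at large n) and
brute-force-loop oracles rather than parity with any specific software
product.

**Best two-gene combination.** For each pair, the sample-wise mean of
the two genes' log expression acts as a pseudo-gene; the reduced gene
set (pair replaced by pseudo-gene) is re-centered across its k−1 rows
and the grouped SV recomputed. Re-centering matters: it makes the
reduced matrix exactly what centering the raw log expression of the
reduced set would give, so a pair of independent equal-noise genes
approaches SV/√2 (noise halving) and a gene paired with its own
duplicate reproduces the single-gene SV exactly — both are tested.
The published pair summary ("re-calculated SD") has no printed
definition; this pseudo-gene recomputation is the package's documented
choice, validated by the degenerate-pair identity.

## Inter-run calibration

A fixed calibrator cDNA mix is measured for one gene (*Tbp* by
default) on every plate; replicates within a plate are averaged. The
correction is additive in Cq:
`Cq′ = Cq − (cal[plate] − mean_p cal[p])`. The exact published
calibration formula is not printed in the source study; any affine
alternative differs only by a global constant, which the downstream
log-ratio statistics ignore (asserted: M-values are invariant under
calibration). Calibration is idempotent and preserves per-gene means
when plates are balanced. `check_calibrator_quality` flags plates
deviating from the **median** calibrator Cq by more than a tolerance
(default 0.5 cycles); the median is used so a single outlying plate
flags itself instead of dragging the mean.

## Microarray preparation

Intensity matrices pass through: QC filtering (control probes, probes
with vendor quality flags, probes with ≥ 50% missing values — counted
in that precedence), replicate averaging (mean ignoring missing),
sequential KNN imputation, quantile normalization, and log2.

Sequential KNN imputes probes in order of ascending missingness; each
missing entry is the inverse-distance-weighted mean of the k nearest
already-complete probes (root-mean-square distance over mutually
observed arrays, so distances stay comparable across missingness
patterns), and an imputed probe immediately joins the donor pool. A
zero-distance donor is copied exactly. k defaults to 10 and is
configurable, as the upstream study names the method but not its
parameters. Quantile normalization maps each array's values onto the
across-array mean of sorted values; ties receive the mean of their
target quantiles (average ranks with linear interpolation, the
dominant convention).

## Comparison protocol

A stability value strictly below 0.5 marks a reliable reference gene
(a printed value of exactly 0.500 is excluded — the threshold is
strict by design and documented as such). For multi-group
comparisons, genes reliable in *every* group are scored by the
arithmetic mean of their within-group ranks (ties broken by smaller
mean value, then alphabetically); ineligible genes are listed
separately, and an empty eligible set is a valid, reported outcome
(it occurs in the RNA-quality comparison). Two-group designs
additionally run the NormFinder intra/intergroup analysis with best
gene and best pair. The "reliable in ≥ 1 approach" summary is the
union over approach-level reliable sets. `preselection_vs_validation`
reports per-gene rank shifts between the pre-selection ranking and an
RT-qPCR stability ranking plus their Spearman correlation.

## Single-cell profiling

Dot-plot statistics per (gene, cell type, timepoint): the fraction of
cells with expression above the limit of detection and the mean over
all cells of the stratum. The detection limit is expression > 0 by
default (no threshold is stated for the published figure legend this
mirrors) and is configurable. Sparse and dense inputs give exactly
equal summaries. The per-gene variability ranking is the plain SD of
each gene across all cells pooled (two-pass, exact for constant
genes); a variance-stabilizing transform is deliberately *not* applied
— the upstream description of the ranking is the raw per-gene SD, and
the mention of a transform-derived variance elsewhere in that source
is a documented discrepancy. Cell-type mean matrices pool all
timepoints.

## Synthetic data generator

`simulate_cq` draws
`Cq_gs = μ_g + stage/sex/hyperoxia offsets + plate shift + ε`,
`ε ~ N(0, σ_g(1 + λ·[RIN<5]))` — additive Gaussian noise on the Cq
(log2) scale, i.e. multiplicative log-normal expression noise, the
regime in which M and SV are defined. Values above the detection
cutoff (default Cq 35) become non-detects. The default design mirrors
the study sizes: 17 room-air/good-RNA samples over three stages
(6/7/4), 33 room-air/degraded-RNA, 36 hyperoxia, a 21-male split among
good-RNA animals, 4 plates (shift SD 0.4 cycles), λ = 1 (degraded RNA
doubles the noise SD). The default gene panel has 8 genes with noise
SDs 0.05–0.8 and one hyperoxia-regulated gene (+1.5 cycles).

What the generator does **not** emulate: PCR efficiency differences
between genes, amplification-curve artifacts, correlated noise between
genes beyond the shared sample effects, RIN-dependent *systematic*
degradation offsets (available per gene but zero by default), and
realistic biological co-regulation. Passing recovery tests therefore
demonstrate estimator correctness under the assumed model, not
robustness to real-data pathologies.

`simulate_sc` draws sparse negative-binomial counts per cell type ×
timepoint stratum (variance = μ + μ²/size; size → ∞ approaches
Poisson, verified distributionally).

## Simulation sizes and statistical power

Recovery tests run at the study's own sizes where the property is
about the study (k = 8 genes, n = 17 physiologic samples, 100 seeded
replicates). Two power facts shape the suite:

- At n = 17 the sampling SE of a variance estimate exceeds the gap
  between the two least-noisy genes of the default gradient
  (σ 0.05 vs 0.1), so NormFinder's unique top rank lands on the true
  least-noisy gene in only ~3/4 of replicates; GeNorm's two-gene final
  pair contains it in ~98%. This is a property of the estimators at
  that sample size, not an implementation defect, and the acceptance
  suite records it honestly.
- The full GeNorm exclusion order (6 consecutive removals) is only
  reliably recoverable at larger n; the order-recovery property test
  therefore simulates n = 100 samples (200 replicates).

## Numerical choices and edge cases

- Sample SDs use the n−1 denominator throughout.
- Listwise deletion within each analysis subset for both algorithms;
  removed samples are reported.
- k < 3 genes is rejected wherever the NormFinder de-mixing factor
  k/(k−2) or gene-centering would degenerate; ≥ 2 samples per group is
  enforced by `GroupDesign`.
- Rank ties everywhere share the lower rank number and order
  alphabetically for reproducibility.
- All simulations and random draws go through
  `numpy.random.default_rng` with explicit seeds; identical seeds give
  byte-identical outputs.

## Known limitations

- GenEx-software parity is not bit-exact and not targeted; published
  pair SDs are treated as tolerance targets only.
- The packaged stability tables are transcriptions of printed values
  (3 d.p.) whose inputs were rounded upstream; recomputation from the
  2 d.p. columns reproduces the pooled SD only to ~0.002 on a few rows.
- No normalization-factor export for target-gene studies, no PCR
  efficiency estimation, no confidence intervals on M or SV.
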