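# Methods

This note documents the models, estimators and design choices behind each
stage, what the synthetic-data generators do and do not emulate, and the
numerical conventions used at boundaries and in degenerate cases.

## Accessibility footprinting on paired methylation arrays

The assay measures chromatin accessibility on a methylation array by
exposing nuclei to the CpG methyltransferase M.SssI: accessible CpGs gain
methylation in the treated arm, while a no-enzyme (NoE) arm reports native
methylation. Per probe *p* and sample *s*,

    Acc[p, s] = β_SssI[p, s] − β_NoE[p, s]  ∈ [−1, 1]

and methylation is the NoE β alone. Between-condition differences are
means over groups:

    ΔAcc[p] = mean_resistant(Acc) − mean_sensitive(Acc)

and analogously ΔMeth on the NoE arm. Conventions:

- **Sign.** Positive Δ means "higher in the resistant condition". The
  field's verbal descriptions of the subtraction order are inconsistent,
  so the convention is exposed as `sign_convention` ("b_minus_a" default,
  "a_minus_b" negates every delta and mirrors up/down calls).
- **Significance.** |Δ| ≥ 0.15, boundary inclusive. The threshold is a
  fixed β-scale magnitude, not a statistical test; 0.15 is the
  conventional effect size for calling array-level change in this assay.
- **Direction.** A probe is *up* if it has significantly increased
  accessibility and/or significantly decreased methylation with no
  significant opposing signal; *down* is the mirror; opposing significant
  signals are *ambiguous*; otherwise *none*.
- **Missing values.** Probes with any missing β in either arm are dropped
  from delta computation and counted in the result.

Probe QC removes the union of: SNP-overlapping probes, cross-reactive
probes, sex-chromosome probes (contigs "chrX"/"chrY"), and probes with
detection p strictly above 0.01 in *any* sample (the conservative
any-sample convention used by array-QC tools). A probe failing several
rules is removed once but counted under each rule. The exclusion lists
themselves are consumed as manifest flags, never re-derived.

## Differential expression stand-in

The DE stage is a deliberately simple negative-binomial Wald test, fully
specified here so that its behaviour is reproducible without reference to
any external tool. It is *not* a re-implementation of shrinkage-based DE
packages: no dispersion or fold-change shrinkage, no independent
filtering, no outlier refitting.

1. **Normalization** — median-of-ratios size factors over genes expressed
   in every sample, rescaled so the median factor is 1; if no gene is
   expressed everywhere, total-count scaling with a warning.
2. **Dispersion** — method of moments. Per gene and group,
   α̂_g = (s² − m̄)/m̄², combined across the two groups with weights
   n_g − 1. Two modes:
   - `pooled` (default): a single common dispersion from the ratio of
     sums, α̂ = Σ_genes Σ_groups (n_g−1)(s² − m̄) / Σ (n_g−1) m̄²,
     floored at 1e-8. Averaging numerator and denominator separately
     avoids the downward bias of the median of gene-wise ratios (the
     gene-wise sampling distribution is right-skewed). With a common
     dispersion shared by thousands of genes the estimate is effectively
     exact, so the Wald statistic is referred to the **normal**.
   - `per-gene`: each gene keeps its own floored estimate. The plug-in is
     then so noisy that the normal reference is anti-conservative
     (empirically ~12 % rejections at nominal 5 % with n = 3/group), so
     the statistic is referred to a **t** distribution. The reference df
     is n_A + n_B − 1 rather than the naive residual n_A + n_B − 2: the
     Poisson component of the variance, 1/μ, is a known function of the
     mean rather than estimated, so the effective df exceeds the residual
     df; a null-simulation calibration of the tail (rejection-rate ratios
     at α = 0.05…0.001 across 100k null genes) places it at one above.
3. **Statistic** — log2FC = log2(μ̂_B + ½) − log2(μ̂_A + ½) on normalized
   group means (pseudo-count ½ guards zero means), with delta-method SE
   √((1/μ_A + α)/n_A + (1/μ_B + α)/n_B)/ln 2. All-zero genes return
   (log2FC 0, p 1).
4. **Calls** — BH step-up adjustment (delegated to statsmodels), then
   strict thresholds: up ⇔ log2FC > 1 ∧ p_adj < 0.05; down mirror; else ns.

The pooled mode is the default because the synthetic cohorts (and the
test suite) generate counts with a single shared dispersion; on real data
with gene-specific dispersions it would be anti-conservative for
high-dispersion genes, which is exactly the situation the per-gene mode
(and, in practice, a dedicated DE package) addresses. This trade-off is a
known limitation of the stand-in.

## Promoter integration and enrichment

Promoter probes are aggregated per gene: *up* if ≥ 1 promoter probe is up
and none is down, *down* in the mirror case, *ambiguous* if both (an
ambiguous probe alone counts as both), *none* otherwise; genes without
promoter probes are omitted. Overlap with the DE sets uses the DE genes
as denominator — `pct_up = 100·|epi-up ∩ DE-up| / |DE-up|` — with
ambiguous promoters counting as neither direction, and percentages
reported as missing when the DE set is empty.

Over-representation uses the upper-tail hypergeometric probability of the
observed overlap between a query list and each GMT set (sets intersected
with the universe first), BH-adjusted jointly across all sets of all
collections, significant at p_adj < 0.01. The universe defaults to the
genes surviving expression filtering and is exposed as an argument; no
ranked/permutation enrichment is implemented, and collections are always
user-supplied files.

## Variant filter cascade

Candidate acquired-resistance variants per resistant line are: present in
the resistant sample, absent from the background, population-rare, and
protein-disrupting; the final set is the intersection of the two lines'
survivors. Conventions:

- **Background** — union semantics by default: a variant present in
  *either* the parental or the long-term-cultured control is background.
  The strict-conjunction alternative (present in both controls) is
  exposed as `background_mode="intersection"`.
- **Population frequency** — gnomAD AF strictly below 0.001; a missing
  annotation is treated as novel and kept.
- **Impact** — exactly HIGH; a missing impact cannot be certified and is
  removed.
- **Identity** — allele-exact (chrom, pos, ref, alt) after multi-allelic
  splitting and left-trimming; genotype/zygosity are ignored.

The full cascade is equivalent to a single-pass predicate per variant and
is idempotent; AF and impact filters commute. VCF I/O is minimal
VCFv4.2 with `GNOMAD_AF` and `IMPACT` INFO keys (annotations are consumed
upstream products, never computed here).

## BH3 profiling and dose response

Depolarization is expressed on the two-control scale
`100·(DMSO − signal)/(DMSO − FCCP)`: 0 % at the vehicle level, 100 % at
full (FCCP) depolarization. Values are not clamped — readings outside
[−10, 110] % trigger a QC warning instead of being hidden — and the scale
is invariant to rescaling all three signals. Summaries report mean and
SD over replicates per condition × peptide × concentration; single
replicates are flagged with SD 0.

Dose-response tables are fit with a four-parameter logistic on the
log10-dose axis, `r = bottom + (top − bottom)/(1 + (d/IC50)^hill)`,
initialized from the data (bottom = min, top = max, IC50 = dose nearest
the half-range response, Hill = 1) and solved by least squares; flat
curves and optimizer failures return a flagged non-converged result
rather than raising. The normalized AUC is the trapezoidal area over
log10 dose divided by (log-range × response scale), with the scale
auto-detected as 100 for percent responses (max > 1.5) and 1 for
fractions; 1 means no kill anywhere, 0 complete kill.

## Synthetic cohorts

The generators define the study conditions; their defaults are the
analysis conditions, not tuning dials.

- **Epigenome** — baseline methylation U(0.35, 0.55) and accessibility
  U(0, 0.08) per probe, chosen so planted ±0.3 shifts stay inside [0, 1];
  Gaussian noise on the β scale (SD 0.02 by default) followed by clipping
  (noise models for this assay are not published; Gaussian-plus-clip is
  the simplest convention). Planted effects are additive shifts of ±0.3
  in the affected (resistant) group only: accessibility shifts move the
  treated arm alone, methylation shifts move both arms so accessibility
  stays fixed. Flagged (SNP/cross-reactive/sex) probes never carry
  planted signal; promoter-plan probes are kept free of flags so planted
  promoter signal survives QC. Detection failures are Bernoulli per
  entry. The simulator does not emulate array batch structure,
  probe-type chemistry differences or spatially correlated noise, so
  passing recovery tests demonstrate the pipeline's arithmetic and rule
  logic, not robustness to those real-data artifacts.
- **Counts** — NB with mean/dispersion parameterization, constant
  baseline mean 100 (a typical expressed-gene count at bulk depth),
  dispersion 0.05 (a typical cell-line value), size factor 1 for all
  samples (the DE stage estimates its own normalization), 3 replicates
  per group matching the experimental triplicates. Planted genes shift
  the second group's mean by exactly 2^±3 by default. The concordance
  fractions select an exact rounded count of planted DE genes for
  concordant promoter changes, making the planted overlap percentages
  deterministic.
- **Variants** — classes planted by construction: background variants
  (present in controls; half of them rare + HIGH so that only the
  subtraction removes them), resistant-only common variants, resistant-
  only low-impact variants, shared survivors, and per-line private
  survivors. 200 distractors of each failing class accompany the 21
  shared survivors in the acceptance configuration.
- **BH3** — noise-free readouts follow signal = DMSO − f·(DMSO − FCCP)
  exactly; Gaussian noise (default 10 a.u. on a 900 a.u. dynamic range,
  ~1 %) is added on the signal scale. The planted per-condition
  depolarization fractions encode the study's qualitative finding —
  globally reduced priming in the resistant condition, strongest for the
  BCL-2 sensitizer BAD and the activator PUMA.
- **Dose response** — noise-free 4PL curves at the measured venetoclax
  potencies (0.154, 0.055, 17.55, 22.63 µM and the intrinsically
  resistant lines' 5.003 / 6.071 µM) over 8–9 doses spanning
  10⁻³–10² µM.

Every generator is deterministic under its seed; two runs with the same
seed are byte-identical and different seeds differ.

## Problem sizes and runtime

The recovery suite uses the study-scale designs directly (20,000 genes,
~10,000 probes, 3 + 3 samples, ~600 variants per line); each such stage
runs in seconds, and the full orchestrated pipeline completes in well
under a minute on one CPU, so no scaled-down surrogate designs are
needed.

## Known limitations

- The DE stand-in's pooled dispersion assumes a shared dispersion across
  genes (true in the simulations, false in real libraries).
- The epigenome noise model is uncorrelated Gaussian per entry; real
  arrays have probe-type and batch structure.
- ORA treats gene sets as unordered and ignores expression magnitude;
  enriched-pathway identities depend entirely on the supplied
  collections.
- The cascade consumes variant annotations as given; discordant or stale
  population/impact annotations propagate unchecked.
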