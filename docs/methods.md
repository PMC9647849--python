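# Methods

`tmtde` implements the quantitative analysis pipeline of a multi-batch
isobaric-labelling (TMT) case–control proteomics study: five 11-plex
batches covering 45 subjects in three groups (PSP, PD, HC; 15 each), with
one master-pool (MP) reference channel and one pooled QC aliquot per
batch. This note documents the statistical models, the defaults and why
they were chosen, and what the synthetic-data generator does and does not
emulate.

## Normalization chain

Reporter abundances move through a fixed sequence of states, and every
operation asserts its input state:

    raw → mp_ratio → median_ratio → (log2 + z-score) → filter → batch_corrected

1. **MP division** (`mp_normalize`). Every subject/QC channel is divided,
   protein-wise, by its own batch's MP channel. Because the MP is the same
   physical pool in every batch, this bridges batches onto a common
   relative scale; any multiplicative factor common to a whole batch
   cancels exactly (the operation is scale-equivariant per batch). A
   missing or zero MP measurement invalidates that protein's whole batch.
2. **Median scaling** (`median_scale`). Each protein row is divided by the
   median of its non-missing ratios, centring every protein at 1.
3. **log2 + z-score** (`log2_zscore`). Rows are log2-transformed and then
   standardized to mean 0, SD 1 using the sample SD (n−1, the Perseus
   convention). Non-positive values cannot be logged and become missing
   with a warning; constant rows z-score to zeros with a warning.
4. **Missing-value filter** (`filter_missing`). Only proteins quantified
   in every sample are retained — the pipeline never imputes. Because the
   dominant missingness mechanism in multi-batch TMT is a protein escaping
   identification in an entire batch, this effectively keeps the proteins
   observed in all five batches.
5. **Batch correction** (`combat_correct`). Parametric empirical-Bayes
   location/scale adjustment (the ComBat model): per protein i, sample j
   in batch b,

       x_ijb = α_i + X β_i + γ_ib + δ_ib ε_ijb,

   with additive batch shifts γ and multiplicative noise scales δ. Data
   are standardized with the grand model, per-batch/per-protein γ̂ and δ̂²
   are estimated, shrunk toward batch-level priors (normal for γ,
   inverse-gamma for δ², hyperparameters by method of moments) via the
   standard iterative posterior update (tolerance 1e-6, cap 1000
   iterations), and the data adjusted. The implementation was verified
   against Bioconductor `sva::ComBat` (parametric prior), agreeing to
   ~1e-5 on shared inputs; the small residual is the tighter convergence
   tolerance used here.

Design choices that were genuinely open:

- **Group protection.** By default the group factor is included in the
  ComBat covariate design (`preserve_groups=True`), so biological
  differences are not absorbed into the batch terms; the unprotected
  variant is available.
- **Filter before ComBat.** The EB estimation needs a complete matrix, so
  the missing-value filter runs first.
- **QC columns.** QC aliquots travel through normalization (they are the
  raw material of the QC metrics) but are excluded from ComBat estimation
  and dropped from the corrected matrix, which feeds only the DE tests.
- **z-score before ComBat.** Standardizing each protein before the batch
  correction is the pipeline's fixed order; the correction restores the
  grand model, so downstream t- and rank-statistics are unaffected by the
  choice of row scale.
- **Single-batch input** returns unchanged: with one batch there is
  nothing to correct, and the EB machinery degenerates.

Note an interaction worth understanding: a batch shift that is *common to
all proteins* is cancelled already by the MP division (the MP channel
carries the same shift). What ComBat removes on real data are the
protein-specific residual batch effects; in the synthetic model these
enter through the per-batch noise scales and through the interplay of
shift and row standardization.

## QC metrics

- **CV of QC replicates** — SD/mean of the per-batch QC aliquots per
  protein, computed on the linear median-ratio scale (CV of log or
  z-scored data is meaningless because the mean is ~0). Headline summary:
  the fraction of proteins with CV < 30%.
- **S/N ratio** — SD across subjects divided by SD across QC aliquots,
  per protein, computed after log2 (variance-stabilized); a zero QC SD is
  reported as +inf. Headline summary: the fraction of proteins with
  S/N > 1, i.e. biological spread exceeding technical noise.
- **PCA batch check** — samples are projected on the first two principal
  components (proteins as features, centred); `batch_eta2` is the
  between-batch sum of squares over the total sum of squares of the 2-D
  scores. It is near 1 when batches cluster apart and should fall toward
  0 after correction. The 2-D restriction mirrors the usual visual
  argument made with PCA scatter plots.

## Differential expression

Two independent procedures are run per contrast and intersected.

**SAM-style permutation FDR** (`sam_qvalues`). The moderated statistic is
d = (mean_A − mean_B)/(se_pooled + s0), where se_pooled is the pooled-SE
of the two-sample t-test and s0 (default 0.1, a common volcano-plot
default) damps low-variance proteins; s0 = 0 recovers Student's t
exactly. Group labels are randomly reassigned (default 250 relabelings;
if more are requested than distinct relabelings exist, all are
enumerated). At each observed |d| threshold,

    FDR(θ) = median over permutations of #{|d*| ≥ θ} / #{|d| ≥ θ},

clipped to [0, 1]; a protein's q is the minimum FDR over thresholds at or
below its own |d|, which makes q monotone non-increasing in |d|. The
median (rather than mean) null count is the robust default. The curved
volcano boundary is exported as the (log2FC, −log10 p) locus where
|log2FC|/(se + s0) equals the critical d at the q threshold.

**Bootstrap ROC** (`broc_qvalues`). Per protein, the Mann–Whitney AUC
(midrank ties: AUC(A,B) + AUC(B,A) = 1 exactly) is bootstrapped by
resampling each group with replacement (stratified, preserving group
sizes; default 1000 resamples), giving an AUC mean and SD. The null arm
repeats the identical bootstrap after permuting the pooled labels (one
pass by default; more passes are averaged). Proteins split into an
up-list (mean AUC > 0.5) and a down-list (< 0.5); sweeping the threshold
from the extreme inward,

    q(θ) = N_null(θ) / N_obs(θ),

clipped to [0, 1] and made monotone toward 0.5 by suffix minimum; mean
AUC exactly 0.5 gets q = 1. The ratio is deliberately oriented
null-over-observed — the orientation under which small values mean few
null proteins reach the threshold, i.e. an FDR — since that is the only
direction consistent with a q < 0.05 significance cut.

Implementation note: inside `broc_qvalues` the bootstrap resample indices
are drawn once per replicate and shared across proteins. Each protein's
marginal bootstrap distribution is unchanged; only a (irrelevant)
cross-protein correlation is introduced, and the sweep costs one ranking
per replicate instead of one per protein × replicate. The public
`bootstrap_auc(a, b)` draws independently.

**Consensus** (`consensus_select`): significant = q_SAM < 0.05 AND
q_bROC < 0.05, with the three-way Venn counts reported. The intersection
controls the union of the two methods' false-positive mechanisms at the
cost of a little power.

## Overrepresentation

One-sided Fisher exact test (hypergeometric upper tail) of the consensus
DE gene list against each gene set, with the universe defaulting to all
quantified (filter-surviving) proteins mapped to upper-cased gene
symbols. Reported per term: Count (DE ∩ set), PH (set ∩ universe),
percent = 100·Count/PH to one decimal, raw p, and fold enrichment.
DAVID's EASE variant (Count decremented by one) and Benjamini–Hochberg
adjustment are optional flags; raw p-values are the default because
conservative EASE and the choice of background dominate any comparison
across tools.

## Power analysis

`sample_size` solves for the fractional per-group n at which the
two-sided pooled t-test reaches the target power, using the noncentral t
with df = 2n − 2 and noncentrality d·√(n/2), d = delta/sigma, by monotone
root-finding on n ∈ [2, 1e6] (|power − target| < 1e-8 at the solution).
The noncentral t is used exactly; at significance levels like 1e-4 a
normal approximation is visibly biased. Fractional df during solving
mirrors standard power software, and a ceiling field is provided for
design use. Numerical note: the miss-on-the-wrong-side tail
P(T′ < −t_crit) is evaluated as the survival function at +t_crit with
negated noncentrality — identical by symmetry and stable far in the
tail, where a direct CDF evaluation can underflow to NaN. At the study's
design point (alpha 1e-4, power 0.8, sigma 0.208, delta = log2 1.5 =
0.585, d = 2.8125) the solution is n ≈ 9.40 per group.

## Synthetic data

The generator emulates the study design so every stage is testable with
known ground truth. Per protein i and subject j in batch b, on log2:

    x_ij = μ_i + effect_i(group_j) + γ_b + δ_b ε_ij,   ε ~ N(0, σ)

- μ_i ~ N(16, 2²): per-protein baseline, a typical reporter-intensity
  dynamic range on log2.
- Planted effects: with probability `frac_de` a protein carries ±`delta`
  (default 0.585 = log2 1.5) in one group. By default all effects land on
  PSP, so `frac_de` is exactly the expected DE fraction of the PSP-vs-HC
  and PSP-vs-PD contrasts and PD-vs-HC is null; `de_group_weights`
  redistributes.
- σ = 0.208 (default): the between-subject residual SD on log2, the same
  value the power analysis uses.
- Batch effects follow the ComBat generative model: additive shifts
  γ_b ~ N(0, 0.3²) and noise scales δ_b = exp(N(0, 0.1²)). The magnitudes
  are calibration choices (real studies rarely quantify them); they are
  config fields, not measurements.
- MP channel: the linear-scale mean of all 45 subjects' noise-free
  abundances, perturbed by the batch effect only — the defining property
  of an equal-amount pool, and the anchor the MP-division step relies on.
- QC channel: the same pool re-measured with technical noise
  σ_tech = 0.1 (default), chosen so QC CVs sit around 7% and the true
  subject-to-QC S/N is ≈ 2 — a comfortably passing QC surface, matching a
  successful experiment rather than a marginal one.
- Missingness is batch-level: a protein drops out of an entire batch with
  probability 0.05. With the default 8960 proteins this yields ≈ 8500
  observed per batch and ≈ 8960·0.95⁵ ≈ 6900 observed in all five — the
  per-batch vs in-common identification gap typical of 5-batch TMT.
- Channel assignment within each batch is randomized (MP fixed to the
  11th channel), subjects are allocated to batches balanced by group
  (3 PSP + 3 PD + 3 HC per batch), and a single seeded RNG stream drawn
  in a fixed order makes equal seeds bit-identical.

What the generator does **not** emulate: peptide-level quantitation,
ratio compression and co-isolation interference, isotopic impurity,
intensity-dependent missingness, non-normal heavy-tailed residuals, and
correlated proteins (co-regulation). Passing tests therefore demonstrate
the statistical machinery is correct under its stated model, not that
real data meet the model's assumptions.

## Problem sizes used in tests

The test suite and examples run the generator at 250–2000 proteins with
the study's 45-subject design, 250 SAM permutations and 200–500 bootstrap
resamples — sizes chosen so the full suite completes in well under a
minute of simulation time while leaving Monte-Carlo error small relative
to the tested margins (e.g. the type-I bound 0.05 + 2·√(0.05·0.95/n)).
The defaults exposed to users remain the study-scale ones (8960 proteins,
1000 resamples).

## Known limitations

- The EB shrinkage leaves a per-protein residual batch offset of order
  δ/(2√n_b); with 9 subjects per batch this noise floor is visible in
  per-protein batch means even after perfect correction. Systematic
  (across-protein average) offsets are driven to ≈ 0.
- The bootstrap-ROC q-value is a count ratio and therefore granular at
  the extreme tail (small observed counts); with a single permutation
  pass the smallest resolvable q on G proteins is of order 1/G.
- The missing-value filter discards every protein absent from any batch;
  with many batches this is aggressive, and no imputation alternative is
  offered by design.
- `combat_correct` assumes the parametric (normal/inverse-gamma) priors;
  the nonparametric EB variant is not implemented.
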