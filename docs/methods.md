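# Methods

This note documents the models, numerical choices and known limitations
of the package; the statistical machinery is described in the order the
pipelines apply it.

## I-DIRT quantitation model

One peptide × replicate record carries heavy- and light-channel MS1
intensities. The experiment design maps channels to cell lines per
labeling orientation (forward: heavy = tagged; swap: reversed), after
which every quantity is expressed as tagged vs wild-type intensity.

**Evidence filter.** A peptide (within protein × condition ×
orientation) is kept only if its tagged-channel intensity is observed in
at least two replicates (`min_tagged_replicates`, default 2). Peptides
with no tagged evidence — notably light-only contaminants in the forward
orientation — are removed entirely; see *Contaminant handling* below.

**Left-censored imputation (method 3.1).** Applies to wild-type cells of
peptides whose wild-type channel is observed in fewer than two
replicates (for a 4-replicate design: missing in more than two). Each
missing cell is replaced by `2**u`, `u ~ Uniform[μ − 3σ, μ − 2σ]`, where
μ and σ are the mean and SD of all observed log2 intensities within that
replicate (each replicate uses its own μ, σ). The method operates on the
log2 scale: the interval only makes sense as a left-shifted detection
floor there, and raw-scale bounds could go negative. A replicate with no
observed values at all has no defined floor and is an error.

**Partial-missingness imputation (method 4.1).** Applies to the
remaining missing cells (either channel) whose peptide retains ≥ 2
observed values in that channel; cells with fewer observations are
method 3.1's job. Per peptide-channel, the relative range
`Δ = (Int_max − Int_min) / mean(Int_max − Int_min)` is computed over all
eligible peptides (whole-table scope by default; per-condition scope is
a config key). A deviate `Δnew ~ Normal(u_Δ, 2·sd_Δ / mean(corr))` is
drawn once per missing cell, where `mean(corr)` is the average pairwise
Pearson correlation between replicate intensity columns over rows
complete in both columns, and the cell is filled with
`mean(Int_other) · |1 + Δnew|` on the raw intensity scale, exactly as
the formulas are written. Two caveats are intentional consequences of
implementing the printed recipe faithfully:

* `Δ` is non-negative with mean exactly 1 by construction, so
  `|1 + Δnew| ≈ 2` and the imputed value is roughly twice the mean of
  the observed replicates. The package implements the recipe as stated
  and flags the inflation here; supplying `u_delta`/`sd_delta`/
  `mean_corr` up front in `ImputationParams` overrides the estimates.
* A non-positive `mean(corr)` leaves the draw's SD undefined and is an
  error — but only in stochastic mode; `deterministic_mode` replaces the
  draw by its mean `u_Δ` and never touches the scale.

`deterministic_mode` likewise replaces the method-3.1 draw by its
interval midpoint `μ − 2.5σ`, making whole pipelines exactly
reproducible without a seed; stochastic mode records seeds and every
imputed cell in an audit log.

**Ratios.** The per-replicate protein ratio is the median over unique
peptides of `tagged/(tagged + wildtype)`; pairs summing to zero (or with
a residual missing channel) are excluded as undefined rather than
counted as 0/0. The abundance-weighted alternative
`ΣPEP / (ΣPEP + Σpep)` is provided as `protein_level_ratio` purely as a
comparator: a single channel-asymmetric high-intensity peptide (the
simulator plants 1000-fold outliers for this purpose) drags the weighted
ratio toward 0 or 1 while the median barely moves.

## Specificity calling

**Bayes factor.** The study design prescribes a Bayes-factor cutoff of 3
against the bulk-extract null; the package uses the standard
objective-Bayes one-sample test: a Cauchy prior (scale 0.707) on the
standardized effect δ, folded to δ > 0 (the alternative is enrichment
*above* the bulk median), with BF10 computed by numerical integration of
the noncentral-t likelihood over the prior (scipy `quad`, split at the
likelihood peak so sharp peaks are never stepped over). Replicate ratios
are pooled across both orientations by default (8 values in a 4+4
design) against the mean of the two orientation bulk medians; a
per-orientation mode (both BFs must clear the cutoff) is available.
Degenerate zero-variance samples report BF10 = 0 at the null or +inf
away from it, with a flag. Beyond |t| = 40 the BF is evaluated at the
cap: the evidence there is astronomically decisive and the noncentral-t
becomes numerically unreliable; BF10 remains monotone (constant) past
the cap. Ratios enter on the raw [0, 1] scale; a transform hook would be
a one-line change in `call_specific` and was not needed.

**Validation ellipse.** Centred at (1, 1) in the forward-vs-swap
mean-ratio plane with semi-axes `a = 1 − (m + k·s)` per orientation,
where m and s are the median and SD of bulk-extract protein ratios and
k = 3 (config key). This places the ellipse boundary k bulk SDs above
the non-specific cloud; an axis ≤ 0 means the bulk cloud reaches the
corner and is an error suggesting a smaller k. Membership is
`((1−r_f)/a_f)² + ((1−r_s)/a_s)² ≤ 1` on per-protein means of replicate
ratios.

**Categories.** The canonical I-DIRT bands are hardened to closed
boundaries: specific (both ≥ 0.8), intermediate (both in [0.6, 0.8)),
non-specific (both in (0.4, 0.6)), contaminant (forward ≤ 0.2, swap
≥ 0.8). Points outside every band are "unclassified" with the nearest
band centre recorded. All four cut points are config keys.

**Contaminant handling.** Light-only contaminants have no tagged signal
in the forward orientation, so the evidence filter removes their forward
peptides before any ratio exists; their forward mean ratio is undefined
(NaN), which fails ellipse membership — they can never be called
specific — and the category rule reads missing-forward with swap ≥ 0.8
as the contaminant signature.

**Aggregation.** The interactome is the union of proteins specific in at
least one extractant condition, with the per-protein count of conditions
(1–6 in the default design) attached, sorted by that frequency then
accession.

## Differential interactome model

Protein-level log2 abundances from label-free IPs are filtered to ≥ 2
unique peptides, imputed with the same two-method machinery operating on
protein × replicate blocks within each cell line × condition (handed
over as raw `2**log2` intensities so both methods behave exactly as at
peptide level), then normalized to the bait by sample-wise subtraction
on the log2 scale — each value becomes a log2 co-enrichment ratio and
the bait row becomes exactly 0. Imputation precedes normalization, and
the bait itself must be *observed* in every sample (an imputed bait
would inject its noise into every protein); a missing bait is an error
naming the sample.

Contrasts are unpaired two-sample t-tests (pooled variance by default,
Welch by flag) of KO vs WT per protein per condition;
`log2fc = mean(KO) − mean(WT)`. Zero variance in both arms gives p = 1
when the means agree and p = 0 (flagged) when they differ. BH adjustment
is applied within each KO line × condition family — the narrowest
defensible unit for a per-comparison correction; the package defaults to
gating significance on the adjusted p (≤ 0.05) together with
|log2FC| ≥ 1, with a raw-p mode behind a flag for the looser convention.

Profiles average log2FC over the conditions where a protein was
quantified (coverage recorded, absent conditions are not imputed into
the mean) and count significant conditions per KO line. Only proteins in
the caller-supplied in-cell-validated set are profiled. Response groups
come from agglomerative clustering (Euclidean distance, average linkage;
both config keys) of the proteins × KO-lines matrix of average log2FC,
cut at n_groups = 5; labels are assigned 1..5 by ascending cluster
median of the row-mean effect, so Group 1 is always the most decreased
and the labels are stable across linkage implementations and input row
order (proteins are processed in accession order).

## Pre-screen analytics

The condition × protein matrix uses NaN ("NA" on disk) for not-detected,
distinct from zero. Coverage of a condition subset is the detected-union
fraction relative to all conditions; the Monte-Carlo benchmark draws
uniform same-size subsets without replacement and reports the fraction
strictly surpassed (ties do not count). For correlation, not-detected
entries are excluded pairwise and pairs sharing < 3 proteins are
undefined; for clustering distance they are replaced by a floor (matrix
minimum − 1 on the log2 scale), so shared absence groups conditions
together. Condition clustering is Euclidean/average-linkage with
label-order tie-breaking.

## Synthetic data

The I-DIRT generator draws a protein class (default composition: 10%
specific, 5% intermediate, 80% non-specific, 5% contaminant), a
tagged-cell signal fraction per class (specific uniform 0.85–1.0,
intermediate uniform 0.6–0.8, non-specific Normal(0.5, 0.05) truncated
to [0, 1] around the 1:1 mix, contaminants light-only), a base log2
abundance (Normal(20, 2)), and a Poisson unique-peptide count (mean 5,
floor 1). Each peptide's total intensity equals the protein's base
intensity times a shared log-normal ionization-efficiency factor; the
channels split it by the tagged fraction and receive independent
log-normal noise with CV 0.2 (so with zero noise, heavy + light mass
balance is exact). Detection is Bernoulli with logistic probability in
log2 intensity (midpoint 14, slope 1), producing the intensity-dependent
(MNAR) dropout that left-censored imputation presumes; a configurable
fraction of proteins carries one 1000-fold outlier peptide in one random
orientation × replicate (both channels, preserving its fraction — the
channel-asymmetric variant is constructed directly in tests). Bulk-mix
ratios are Normal(0.5, 0.03) truncated to [0, 1], one per protein per
orientation.

The label-free generator plants per-group, per-KO log2 effects
(defaults: Group 1 = −3.4/−3.5/−3.7/−2.6, Group 2 = −1.7/−1.8/−2.0/−1.3,
Group 3 = 0, Group 4 = −0.2/0.2/−0.1/1.0, Group 5 = 1.4/1.7/1.5/2.4 for
TMTC2 / TMTC3 / TMTC2/3 / TMTC1-4), realized per condition with jitter
SD 0.1 and per-sample residual SD 0.3 on the log2 scale; the bait is
planted flat at high abundance. The default has no dropout (the screens
it emulates report none; a logistic-dropout knob exists for imputation
exercises), so at default settings the protein-level imputation pass is
an identity. Noise levels and dropout parameters are conventions chosen
to look like routine IP-MS data, not measured values.

What the generators do **not** emulate: spectrum-level structure (m/z,
charge, retention time), identification FDR, shared-peptide protein
inference, between-run normalization drift, and correlated
peptide-level biases beyond the single-outlier mechanism. Passing
recovery tests therefore demonstrates that the statistical machinery
recovers planted truth under the stated noise model, not that any
particular real dataset would yield the same interactome.

## Problem sizes and tolerances

Recovery tests run at 500 proteins (I-DIRT) and 50 proteins per group ×
6 conditions × 4 replicates × 5 cell lines (label-free), sizes at which
the group-median estimator's sampling error is well below the ±0.3
recovery band used in tests. The BF implementation is checked against an
independent trapezoid-grid integration to 1e-3 relative; BH against a
brute-force step-up transcription to 1e-12; t-tests against the
closed-form CDF to 1e-10; deterministic method-4.1 against a
straight-line transcription of its formulas to 1e-12 relative.

## Known limitations

* The Bayes-factor prior and sidedness, the ellipse axis formula, and
  the imputation scales are documented package decisions; the screening
  design they implement states only the cutoffs (BF > 3, ellipse, |log2FC|
  ≥ 1, p ≤ 0.05).
* Method 4.1's systematic ~2× inflation is inherent to its printed
  formulas (see above).
* The equal-variance t-test default is a convention; Welch is a flag.
* Group labels presume the cut yields exactly n_groups non-empty
  clusters; identical profiles make the cut degenerate and raise.
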