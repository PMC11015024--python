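# Methods

This note documents the statistical model behind the package, the defaults and
why they were chosen, the numerical conventions, and what the synthetic-data
tests do and do not demonstrate about real data.

## Treatment-induced expression change

All patient-level statistics operate on the per-patient, per-gene
treatment-induced change Δ[g, p] = post[g, p] − pre[g, p], a log2 fold change
computed as a subtraction because inputs are assumed log2-normalized
(`value_kind = log2_expression`). A helper applies log2(x + 1) to raw
non-negative input; the pseudocount of 1 keeps zeros at zero. For unpaired
cohorts the surrogate change is the deviation of each sample from the cohort
population baseline, taken as the gene-wise arithmetic mean across samples
(the baseline statistic is not canonical; the mean is the default and the
implementation is a one-line change if a median is preferred). Multiple
biopsies of a patient-timepoint are averaged gene-wise before any statistic.

PCA response scores (used to show that Δ carries the response signal while
baseline expression does not) standardize genes to unit variance before the
fit — expression variances span orders of magnitude and an unscaled PC1 would
be dominated by a handful of high-variance genes. PCA leaves the sign of PC1
undetermined; it is fixed against the labels (AUC ≥ 0.5) when labels are
available, else by making the loading of the lexicographically first retained
gene non-negative, so results are reproducible. AUC is the tie-adjusted
Mann–Whitney statistic.

## Bootstrap DEG selection

Per bootstrap replicate, each response stratum is resampled with replacement
to its own original size (patients, not samples, are the resampling unit), and
a two-sided equal-variance Student's *t* test compares Δ between groups per
gene. Defaults: `n_boot = 100`, `alpha = 0.05`; Welch's test is available via
`equal_var=False`. A gene with p < alpha is a hit, directed R when its mean Δ
is higher in non-responders, S when higher in responders — so a gene is R- or
S-hit in a given replicate, never both, and n_boot × (fraction_R + fraction_S)
is an integer ≤ n_boot. Degenerate draws are handled explicitly: a zero-
variance gene gets p treated as ≥ alpha (never a hit), and a stratum that
collapses to fewer than two distinct patients is redrawn (at most 10 times).

Candidate signatures take the top i% (R) and j% (S) of genes with positive
hit fraction, counting ceil(count × i/100) genes and including all boundary
ties, which makes R_i monotone non-shrinking in i. The (i, j) grid defaults to
{5, 10, …, 50}² — fine enough to span one order of magnitude of signature
sizes without inviting a second layer of selection noise.

## Cross-validation and the (i, j) choice

A stratified leave-out split (default 25% of patients, at least two per class)
is held back first; the remainder undergoes stratified 3-fold CV. Within each
fold, DEG selection runs on the training portion only, and every candidate
(R_i, S_j) is scored on the fold's test patients by the per-patient RS score —
the enrichment of S minus the enrichment of R in the patient's descending-
ranked Δ column. Patient scoring uses the plain enrichment score (ES): it is
permutation-free, and because every patient shares one gene universe, the ES
ordering across patients is what the AUC sees; the NES variant is available
and changes AUCs negligibly.

Core signatures intersect the three folds' candidates at each (i, j); an empty
intersection falls back to genes selected in at least 2 of 3 folds, flagged in
the result. The chosen (i, j) maximizes the mean of the CV AUC and the
leave-out AUC among grid points whose core sizes are balanced
(min/max ≥ 0.5), with ties broken toward smaller signatures — "balanced and
robust" made into a reproducible rule. The entire procedure is a pure function
of (data, grid, seed).

## The pre-ranked enrichment engine

The ES is the weighted Kolmogorov–Smirnov running-sum statistic on a
descending ranked list: a hit at gene g increments the running sum by
|score(g)|^w / Σ_hits |score|^w, a miss decrements it by 1/(N − |S|), and the
ES is the extreme deviation with its sign, so |ES| ≤ 1. Defaults: weight
w = 1 for all signature and shift-ability scoring.

Numerical conventions, each of which matters in practice:

- **Ties in the ranked list** are ordered by ascending gene id and the ES is
  computed on that fixed order — deterministic, and z-score inputs rarely tie.
- **Sign ties.** The positive and negative running-sum extremes can tie
  exactly (a contiguous hit block centered in the list is the simplest case).
  The convention is that the positive extreme wins when the two magnitudes
  agree within 1e-12; without the tolerance, 1e-16 rounding noise would decide
  the sign.
- **Zero hit mass** (every hit carries score 0 under w > 0): hit increments
  fall back to uniform 1/|S|, keeping the statistic defined on degenerate
  columns.
- **Implementation vs oracle.** The running sum changes slope only at hit
  positions, so the implementation evaluates the extremes from the sorted hit
  positions in O(|S|); the test suite checks it against an independent
  explicit full-walk oracle to 1e-12 on 1,000 random instances.

The NES divides the ES by the absolute mean of same-sign null ES values, where
the null is the ES of random gene sets of the same effective size drawn
without replacement from the ranked universe (gene-set permutation — the only
null available for pre-ranked input). The nominal p is the fraction of
same-sign null ES at least as extreme, with a +1 pseudocount on numerator and
denominator so it is never zero; its floor is therefore ≈ 2/n_perm when the
null splits evenly between signs. Null position draws are a pure function of
(seed, N, set size, n_perm), so signatures of equal effective size in one run
share draws automatically, results are independent of evaluation order, and
caching cannot change any value.

A signature is scored only if it retains at least 15 genes **and** at least
50% of its members after intersection with the ranked universe; thinner
overlaps are flagged (`insufficient overlap`), not silently computed. The
floor is a package choice — small enough for desk-scale tests, large enough
that an ES on a handful of surviving genes is not mistaken for signal.

ssGSEA scoring (single-sample immune scores) uses the Barbie-style statistic
with exponent 0.25 on the rank weights: genes are sorted descending (ties by
gene id), the gene at position i carries rank N − i, and the integrated
difference between the rank-weighted in-set ECDF and the uniform out-of-set
ECDF is normalized by the value the same weights would attain with the set
packed at the top — the score lies in [−1, 1] and depends on expression only
through its ordering.

## Shift ability and significance

For each perturbation experiment, shift_ability = NES_S − NES_R on the
experiment's descending-ranked differential profile; the identity holds
exactly on every row by construction, and swapping the signatures negates it.
Note the NES-based score is only approximately antisymmetric under negating
the *profile* (the ES is exactly antisymmetric, but the same-sign null means
need not mirror); observed deviations are a few percent.

Two significance modes:

- **fixed_threshold** (compound screens): significant iff
  shift_ability ≥ 3.5, boundary inclusive.
- **empirical_null** (shRNA screens, where the screen itself provides a
  null): per cell line, the null is the shift abilities of all scored
  experiments in that cell line excluding every experiment of the perturbagen
  under test (leave-one-perturbagen-out); significant iff
  shift_ability ≥ mean + k·sd with k = 2. At least 30 null scores are
  required. By default the null pools all perturbagen types present;
  `null_pert_types=("shRNA",)` restricts it to shRNA experiments when the two
  screens are scored together.

Knockdown success for an shRNA is target differential value ≤ −1 (inclusive)
on the level-5 z-score scale — a conservative reading of "successfully
inhibits its target"; the threshold is a parameter. Direction bookkeeping
calls a perturbation R-suppressing iff NES_R < 0 and S-inducing iff NES_S > 0.
Screen integration retains a gene as a consistent synergy target iff some cell
line has both a significant shRNA experiment targeting it and a significant
experiment of a compound annotated to it; compound→target annotation is an
explicit required input.

## Mechanism clustering

Per compound, each gene's differential values across experiments are mapped to
indicators (+1 if > 1, −1 if < −1, else 0 — strict inequalities, so exactly ±1
maps to 0; the map is odd) and summed into a consensus vector. Compounds are
clustered by Ward linkage on d = 1 − Pearson r between consensus vectors.
Ward is defined for squared Euclidean distances, so pairing it with a
correlation distance is an approximation, adopted as the default for its
scale-invariance; `linkage_space="euclidean"` runs Ward on the raw consensus
vectors instead. The dendrogram is cut at a fixed height (default 12, on the
correlation-distance linkage scale); cut heights are linkage-scale-dependent,
and when a cut leaves a single cluster the implementation falls back to k = 2
with a logged notice — on the synthetic data that fallback path is the tested
contract. A cluster's signature is the gene-wise median of its members'
consensus vectors (arithmetic midpoint for even counts), ranked descending,
and is annotated by pre-ranked GSEA over a gene-set collection (default 1000
permutations) with Benjamini–Hochberg FDR across the tested sets.

Note an FDR resolution limit that is easy to miss: with 1000 permutations the
nominal p is floored at ≈ 2/n_perm, so after BH correction across m sets even
a maximally enriched set cannot reach an FDR below ≈ m × 2/n_perm — with ~50
sets, about 0.1. Collections of that size need more permutations if FDR
thresholds near 0.05 are to be meaningful.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical* structure the method assumes, with
Gaussian noise throughout (the real quantities are z-scores and log-ratios,
for which a Gaussian is the natural desk-scale stand-in):

- **Cohort**: pre ~ N(8, 1) per gene/sample on the log2 scale; post adds
  N(0, noise_sd); planted R genes gain +effect_size·noise_sd on-treatment in
  non-responders, planted S genes the same in responders. Defaults — 5,000
  genes, 200+200 planted, 20+20 patients, effect size 1.5, noise sd 1 — give a
  cohort of roughly the published studies' size with a strong but not trivial
  planted effect (per-gene two-sample t ≈ 4.7 at full n).
- **Perturbations**: null experiments ~ N(0, background_sd = 1) per gene;
  planted experiments add ±2 on 100 up-/down-planted genes; TAS uniform on
  [0.4, 1] with an optional fraction below 0.4 to exercise the quality filter;
  metadata alternates shRNA/compound over 3 round-robin cell lines, and
  planted shRNAs target a planted-down gene so knockdown bookkeeping has a
  consistent truth.
- **Mechanism**: two disjoint templates of 100 genes at +2 and 100 at −2;
  each compound contributes 3 experiments = template + N(0, 0.5), 2,000 genes
  total. Problem sizes (≤ 5,000 genes, ≤ 150 experiments) keep the full suite
  in minutes; scaling to the real 10,174 × 41,321 matrices is an I/O concern,
  not an algorithmic one.

Not emulated: gene–gene correlation, batch effects, dose–response structure,
cell-line identity effects, and non-Gaussian heavy tails. Passing tests
therefore demonstrate that the machinery recovers planted signal and is
calibrated under exchangeable noise — not that the signatures generalize to
any particular clinical cohort.

One property of the bootstrap statistic is worth stating because it is easy to
get wrong: hit fractions are *not* small under the null. Bootstrap replicates
are correlated through the original sample, so a gene with a large chance
separation in the observed cohort is a hit in most replicates, and the maximum
hit fraction over thousands of null genes routinely exceeds 0.9. The null
guarantees are exchangeability (planted genes behave exactly like background
when the effect is zero) and near-chance downstream AUC — not an absolute cap
on individual fractions. Similarly, a single 3-fold CV AUC on ~30 patients has
Monte-Carlo sd ≈ 0.1, so null-calibration statements are made about the AUC
averaged over replicate seeds.

## Known limitations

- Gene identifiers are opaque case-sensitive strings; any symbol mapping must
  happen upstream.
- The GCTX path is read-only and expects the standard HDF5 layout; GCT 1.3
  text is the canonical interchange format.
- The empirical-null mode needs ≥ 30 scored experiments per cell line and is
  sensitive to contamination of the null by true shifters (a mean + 2·sd rule
  tolerates a few, as the tests show, but a heavily planted cell line would
  inflate the cut).
- No batch correction, raw-count normalization, survival analysis, or
  downloading clients; cohort and perturbation matrices arrive preprocessed.
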