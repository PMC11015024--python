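# shiftability

Screening perturbation transcriptomes for their ability to shift tumor cells
from an anti-PD-1–**resistant** to an anti-PD-1–**sensitive** expression state.

Anti-PD-1 checkpoint blockade helps only a minority of patients, and a central
question in chemo-immunotherapy is which drugs (or gene knockdowns) push a
tumor's transcriptional program toward the state seen in responders. This
package implements that screen end to end for computational biologists working
with paired patient transcriptomes and Connectivity-Map-style (L1000 level-5)
perturbation profiles:

1. **Signature construction.** From paired pre/on-treatment tumor expression
   with known response labels, the per-gene treatment-induced change
   Δg = log2(post) − log2(pre) is computed per patient. Stratified bootstrap
   resampling with a two-sided Student's *t* test yields a per-gene, per-direction
   *DEG selection score*

       DEGselection_R(S)(g) = (1/T) Σ_t hit_R(S),t(g),   hit = 1{p_t < 0.05},

   directed **R** (resistance) when Δg is higher in non-responders and **S**
   (sensitivity) when higher in responders. Candidate signatures R_i / S_j take
   the top *i*% / *j*% of positively scoring genes; (i, j) is chosen by 3-fold
   cross-validated AUC of the per-patient **RS score** (enrichment of S minus
   enrichment of R in the patient's ranked Δ profile), and core signatures are
   the intersection of the three folds' candidates.

2. **Shift-ability screen.** For each perturbation profile (a gene-level
   differential z-score vector), genes are ranked descending and both
   signatures are scored with a from-scratch pre-ranked GSEA engine
   (weighted Kolmogorov–Smirnov running sum, weight 1; NES normalized against
   a random-gene-set permutation null). The screen statistic is

       shift_ability = ΔNES = NES_S − NES_R.

   Large positive values mean the perturbation suppresses the resistance
   program while inducing the sensitivity program. Significance is called
   either against a fixed cut (≥ 3.5, inclusive; compound screens) or an
   empirical per-cell-line null (mean + k·sd, leave-one-perturbagen-out;
   shRNA screens). shRNA and compound screens are integrated into *consistent
   synergy targets*: genes whose genetic and pharmacological inhibition both
   shift R-to-S in the same cell line.

3. **Mechanism clustering.** Each shifting compound's experiments are
   collapsed to a consensus expression-change vector (per-gene {−1, 0, +1}
   indicators at strict ±1 thresholds, summed over experiments); compounds are
   clustered by Ward linkage on 1 − Pearson correlation, and each cluster's
   median consensus signature is annotated by pre-ranked GSEA over a gene-set
   collection with Benjamini–Hochberg FDR.

A `synthetic_data` module generates every input with known ground truth
(paired cohorts with planted R/S genes, level-5-like perturbation matrices
with planted shifting experiments, compound families sharing mechanism
templates), so the whole stack is testable without any external download.
Supported formats: GCT 1.3 text (GCTX read-only), GMT, TSV, JSON.

## Worked example

Score a small synthetic screen (30 null experiments + 3 planted R-to-S
shifters) against the planted truth signatures:

```python
from shiftability import simulate_perturbations, screen_perturbations
from shiftability.synthetic_data import PerturbationSpec

spec = PerturbationSpec(n_genes=1000, n_null_experiments=30,
                        n_planted_experiments=3, n_planted_genes=50, seed=42)
matrix, meta, truth = simulate_perturbations(spec)
table = screen_perturbations(
    matrix, meta,
    sig_R=set(truth["planted_down"]), sig_S=set(truth["planted_up"]),
    n_perm=1000, seed=42, mode="fixed_threshold",
)
print(table.rows.nlargest(5, "shift_ability")[
    ["experiment_id", "pert_type", "cell_line", "nes_R", "nes_S",
     "shift_ability", "significant"]].to_string(index=False))
```

```
experiment_id pert_type cell_line  nes_R  nes_S  shift_ability  significant
    SHIFT0001     shRNA      A375 -3.236  3.258          6.494         True
    SHIFT0003     shRNA       PC3 -3.298  2.993          6.290         True
    SHIFT0002  compound      MCF7 -3.162  3.071          6.233         True
     NULL0010  compound      A375 -1.230  0.853          2.083        False
     NULL0028  compound      A375 -0.861  1.176          2.037        False
```

The three planted experiments suppress the R signature (NES_R ≈ −3.2), induce
the S signature (NES_S ≈ +3.1), and clear the fixed significance cut of 3.5,
while the best null experiment reaches only ΔNES ≈ 2.1.
`table.aggregates()` then rolls experiments up per (perturbagen, cell line):
a perturbagen shows R-to-S shifting in a cell line iff at least one of its
experiments there is significant.

The same pipeline is scriptable from the shell:

```bash
shiftability --seed 1 --out-dir out simulate --kind cohort
shiftability --seed 1 --out-dir out sigbuild \
    --pre out/cohort_pre.tsv --post out/cohort_post.tsv \
    --clinical out/cohort_clinical.tsv
shiftability --seed 1 --out-dir out screen \
    --gct perturbations.gct --signatures out/core_signatures.gmt
```

(`enrich` and `cluster` cover stand-alone pre-ranked GSEA and mechanism
clustering; see `shiftability --help`.)

## Documentation

The model, its assumptions, every tunable parameter, and the known limitations
of the synthetic generators are documented in [docs/methods.md](docs/methods.md).
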