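# pairomics

Analysis pipeline for paired two-arm (placebo/probiotic), two-timepoint
(baseline/endline) multiomics intervention studies, plus a synthetic-cohort
generator with recorded ground truth for validating every stage.

## What it does

- **io_formats** — strict readers/writers for feature tables (TSV,
  features x samples), sample metadata, the immunity-indicator panel and a
  minimal VCF v4.2 subset for SNV calls (QUAL >= 60, depth >= 100 filters,
  SNVs only, multi-allelic records split).
- **synthetic** — generates a complete synthetic cohort (four omics layers,
  69-indicator immunity panel, per-sample VCFs) with planted, recorded
  effects: within-group convergence (centroid shrinkage), common temporal
  drift, arm-specific abundance shifts, feature↔indicator delta
  correlations, and per-host SNV gain/loss with shared plus arm-specific
  components. Fixed seed ⇒ byte-identical output.
- **diversity** — Shannon index, Bray-Curtis dissimilarity, a from-scratch
  permutation PERMANOVA (Anderson's pseudo-F), within-group dissimilarity
  and the convergence rank-sum / signed-rank tests.
- **differential** — metabolite QC (intensity / per-group prevalence / RSD),
  pseudocount + CLR transform, per-group paired signed-rank change tests,
  time-effect subtraction (changes shared by both arms are attributed to
  time and discarded) and the direct-influence count/proportion summary.
- **indirect** — per-subject delta Spearman correlation of omics features
  with immunity indicators, per-group significance, removal of
  (feature, indicator, sign) edges shared across arms, and the
  indirect-influence summary.
- **snv** — within-host temporal SNV changes, >= 30% prevalence filtering,
  placebo subtraction of the cross-arm intersection, per-species
  categorisation (top-k table with dense ranks and mean % relative
  abundance) and SNV-immunity association per indicator category.

## CLI

```sh
pairomics simulate --out cohort/ --seed 1 --n-subjects 45
pairomics diversity    --cohort cohort/ --out results/
pairomics differential --cohort cohort/ --out results/
pairomics indirect     --cohort cohort/ --out results/
pairomics snv          --cohort cohort/ --out results/

# or everything in one deterministic run:
pairomics pipeline --out run/ --seed 1 --n-subjects 20
```

Every threshold (alpha, permutations, VCF quality/depth, metabolite QC
cuts, SNV prevalence, ...) lives in one YAML (`pairomics init-config`) and
is also overridable per flag, e.g. `--alpha 0.01 --snv-direction-scope gained`.

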