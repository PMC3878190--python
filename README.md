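# riskroc

Design and build genetic risk prediction models on the optimal ROC curve.

`riskroc` implements a two-stage workflow for case-control risk prediction
from SNP genotypes (plus categorical environmental predictors):

- **Design stage** — from disease prevalence and per-marker information
  (genotype frequencies in cases/controls, or population frequencies plus
  genotype relative risks), it enumerates multilocus genotype risk groups,
  orders them by likelihood ratio to obtain the *optimal ROC curve*, reports
  the model's theoretical AUC, and computes the sample size / power for
  testing that AUC against a threshold (one-sided asymptotic normal test
  with Hanley–McNeil variance).
- **Build stage** — F-ROC forward selection on a case-control genotype
  table: each step splits the current risk groups by the candidate SNP that
  maximizes the training AUC, optionally re-merging statistically
  indistinguishable LR-adjacent groups. Stratified k-fold cross-validation
  provides internal validation and can choose the model size; an independent
  table can be scored for external validation. Missing genotypes are either
  their own category or imputed with the per-SNP mode.
- **Simulator** — retrospective case-control sampling of unlinked biallelic
  SNPs under a multiplicative penetrance model (MAFs, genotype relative
  risks, prevalence, optional pairwise epistatic multipliers, MCAR
  missingness), with the exact generating distributions and theoretical AUC
  available for testing.

## CLI

```sh
# design: AUC estimate + required sample size from a YAML/JSON spec
riskroc design --spec design.yaml --out out_design/

# simulate a case-control genotype table with known truth
riskroc simulate --config sim.yaml --out data.tsv --seed 7

# build: F-ROC fit with CV, optional external validation
riskroc build --train data.tsv --validate valid.tsv \
    --max-predictors 5 --kfold 10 --seed 1 --alpha-merge 0.05 \
    --missing own --out out_build/
```

Each run writes a JSON report, TSV ROC-point tables, a PNG/SVG ROC plot and
(for `build`) a per-step AUC table plus the risk-group structure as Graphviz
DOT. Outputs are deterministic given identical inputs and seed.

A design spec looks like:

```yaml
prevalence: 0.0004
alpha: 0.05
power: 0.95
auc0: 0.60
ratio: 1
snps:
  - id: rs0001
    mode: conditional
    freq_case: [0.30, 0.50, 0.20]
    freq_control: [0.40, 0.45, 0.15]
  - id: rs0002
    mode: population_rr
    allele_freq: 0.2      # expanded under HWE; or give freq_pop: [..,..,..]
    rr: [1, 1.5, 2.2]
```

Genotype tables are TSV/CSV with a header, a `phenotype` column (0 =
control, 1 = case), an optional `id` column and genotype columns coded
0/1/2 (`NA`/`-9`/empty = missing); PLINK `.raw` files are auto-detected
(PHENOTYPE 1/2 remapped to 0/1).

## Python API

```python
from riskroc import (
    SnpDesignInfo, DesignConfig, run_design,      # design stage
    fit_froc, apply_model, cross_validated_auc,    # build stage
    SimConfig, simulate_case_control, truth_spec,  # simulation
)
```

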