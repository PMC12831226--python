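# transmrs

Trans-tissue methylation risk score (MRS) analysis: run a case–control
discovery EWAS on one tissue's DNA-methylation data, build effect-weighted
MRSs at a ladder of discovery p-value thresholds (P_T ∈ {0.001, 0.01, 0.05,
0.1, 0.2, 0.5, 1}), and test their association with diagnosis in a second
tissue via covariate-adjusted logistic regression with incremental
Nagelkerke pseudo-R².

The pipeline covers:

- **synthdata** — paired two-tissue simulator with known ground truth:
  bimodal β baselines, cell-type mixtures (Dirichlet), 2-kb co-methylated
  CpG blocks (Gaussian copula), planted diagnosis effects with partial
  cross-tissue sharing, slide batch shifts, detection/bead failures,
  sex-chromosome signal, confounder phenotypes, and a 450K⊂EPIC-style
  platform-universe subset.
- **qc** — sample/probe filters on detection p and bead counts (strict
  \>10% rules), sex prediction from the X/Y mean-M contrast with outlier
  and mismatch flagging, sex-chromosome exclusion, β↔M transforms.
- **covariates** — reference-based cell deconvolution (constrained least
  squares, proportions ≥ 0 and summing to 1), Mann–Whitney admission of
  cell types that differ between groups, slide-associated principal
  components (one-way ANOVA screen), and residual-PCA surrogate variables
  with permutation-based auto-selection.
- **ewas** — vectorized per-CpG OLS of M-values on phenotype + covariates,
  genome-wide significance calling at p < 9.0×10⁻⁸.
- **scoring** — discovery/target site intersection, co-methylation pruning
  (2-kb window, Spearman |ρ| ≥ 0.3, transitive closure, smallest-p
  representative), thresholded effect-weighted scores, and lead-SNP
  ±100 kb locus include/exclude subsets.
- **assoc** — IRLS logistic regression with separation detection,
  Nagelkerke R² / ΔR², covariate-corrected z-standardized scores, Pearson
  χ² (2×2, no continuity correction), Mann–Whitney U with tie correction.
- **pipeline_cli** — end-to-end orchestration of both discovery→target
  directions, three GWS-locus subset modes, and a confounder-MRS battery,
  from one YAML config with a shipped JSON Schema; deterministic under a
  fixed seed and stamped with a config hash.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: the printed
contingency statistics, trans-tissue power/type-I/asymmetry simulations,
oracle equivalences (brute-force pruning, Newton logistic, exact
permutation Mann–Whitney), algebraic invariants, and parameter-recovery
checks. The full suite takes ~8 minutes on one CPU.

## CLI

```bash
transmrs simulate --seed 3 --out data/            # paired datasets + panel + loci
transmrs qc --in data/tissueA --out qc/tissueA
transmrs covariates --in qc/tissueA --panel data/panel.tsv --out cov/tissueA
transmrs ewas --in qc/tissueA --phenotype diagnosis --out ewasA.tsv.gz
transmrs score --target qc/tissueB --discovery ewasA.tsv.gz --mode all --out mrs.tsv
transmrs assoc --mrs mrs.tsv --meta qc/tissueB/samples.tsv --out assoc.tsv
transmrs run --config run.yaml --seed 5 --out runout/   # end-to-end, both directions
transmrs report --in runout/report.json
```

Matrices are gzipped TSV (CpGs × samples, first column `cpg`); loci are
6-column BED (0-based half-open, converted internally to 1-based
inclusive) or a `chrom`/`pos` lead TSV; reports are JSON + TSV.

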