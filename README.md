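# phytoscreen

Network-pharmacology screening of botanical-drug formulas from
prescription data, with retrospective-cohort validation statistics.

Multi-herb prescriptions from hospital EMRs encode which botanical
drugs clinicians actually combine for a disease — here, hypertensive
nephropathy (HN) — but not which of their hundreds of compounds do the
work. `phytoscreen` implements the full in-silico chain that turns
EMR-style tables and a drug–compound–target knowledge base into a
ranked, testable formula:

* **co-prescription mining** — weighted drug/symptom co-occurrence
  networks; core drugs by weighted k-core (s-core) peeling; disease-
  specific drugs by relative risk on the 2×2 of case vs. other
  prescriptions; symptom communities by fast unfolding (Louvain);
* **network propagation** — random walk with restart on a
  confidence-filtered protein–protein interaction network,
  r = (1−c)·W·r + c·e with c = 0.75, seeded by the disease genes, to
  score compound–disease proximity and derive training labels;
* **compound features** — oral bioavailability (OB), mean Jaccard
  overlap with disease/symptom gene sets (Jac), Wang-method GO
  semantic similarity with best-match-average aggregation (GoSim), and
  Manhattan compactness of the community-regulation profile (Man);
* **effectiveness screen** — a kernel KNN classifier under stratified
  10-fold cross-validation, ROC analysis with the closest-to-corner
  operating threshold, and SVM/GBDT/naive-Bayes baselines on identical
  folds;
* **formula selection** — per-drug effective-compound counts across
  symptom modules, Ward hierarchical clustering, and a permutation
  test for the selected cluster;
* **enrichment** — hypergeometric over-representation with
  Benjamini–Hochberg FDR (Q < 0.05) and MCODE complex detection;
* **cohort statistics** — two-proportion sample size, CKD-EPI eGFR and
  KDIGO staging, logistic propensity scores, stabilized IPTW and 1:1
  caliper matching, standardized mean differences, balance-table t and
  χ² tests, and risk/odds ratios with 95% CIs.

A seeded synthetic-data module (`phytoscreen.synthdata`) generates
every input — EMR tables, knowledge base, interactome, ontology,
cohort — with planted ground truth, so the whole pipeline runs and can
be scored end to end without any download. See `docs/methods.md` for
the models, defaults and generator design.

## Worked example

```python
from phytoscreen import run_pipeline

result = run_pipeline(seed=1, with_baselines=True)
print(result.summary())
```

```
Botanical formula screening pipeline
  core drugs (network extraction): H09, H07, H08, H01, H04, H06, H03, H02, H05
  symptom communities: 5 (Q = 0.469)
Kernel KNN effectiveness screen
  compounds: 633   k=7 kernel=inverse_distance folds=10
  out-of-fold AUC: 0.983 (per-fold mean 0.983)
  operating threshold: 1.000 at (fpr, tpr) = (0.000, 0.969)
  compounds called effective: 154
  baseline svm: AUC 0.972
  baseline gbdt: AUC 0.973
  baseline bayes: AUC 0.985
  OOF AUC vs planted truth: 1.000
  per-module AUCs: M0=0.898, M1=0.881, M2=0.905, M3=0.905, M4=0.899
  selected formula (7 drugs, p = 0.0003): H01, H02, H04, H05, H08, H11, H12
  planted effective drugs: H01, H02, H04, H05, H08, H11, H12
  cohort IPTW OR = 2.094 (95% CI 1.494-2.936); naive OR = 3.330; max post-weighting SMD = 0.032
```

Reading the output: the EMR miner recovers the nine planted
co-prescription core drugs; Louvain finds the five planted symptom
communities (modularity Q = 0.47). The KNN screen separates effective
from background compounds (out-of-fold AUC 0.983 against its RWR
labels, 1.000 against the planted truth) and calls 154 of 633
compounds effective at the ROC corner threshold. Ward clustering of
the per-drug effective fractions selects exactly the seven planted
effective drugs (permutation p = 0.0003). On the confounded synthetic
cohort the naive odds ratio (3.33) overstates the planted treatment
effect (2.5); inverse-probability weighting balances the confounders
(all standardized mean differences < 0.04) and pulls the estimate back
to 2.09 with the planted value inside the 95% CI.

The same run is available from the shell:

```sh
phytoscreen pipeline --seed 1 --out out/          # full chain + files
phytoscreen simulate --seed 42 --out data/        # write all inputs as TSV/GMT/CSV
phytoscreen screen --features features.csv --drug-map map.tsv --out screen/
```

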