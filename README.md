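# covariome

Proteogenomic co-variation analysis for cancer cell-line panels.

Deep isobaric-labelling proteomics of a cell-line panel measures thousands
of proteins across tens of genetically distinct samples. Because the
subunits of protein complexes maintain their stoichiometry
post-transcriptionally, the pairwise co-variation of protein abundances
across such a panel ("the co-variome") recapitulates known complexes and
interactions far better than mRNA co-expression does — and it exposes how
somatic alterations propagate: a loss-of-function (LoF) mutation
downregulates its own protein and, through complex membership, its
co-varying partners, at the protein level only. `covariome` packages that
entire analysis for anyone working with panel proteomics:

* **Scaling & QC** — column-total / row-mean intensity scaling onto the
  0–1000 scale, replicate CVs (CV = SD/mean), detectable fold change
  (1 + 2·CV/100), gene-wise mRNA–protein correlation.
* **Co-variation networks** — pairwise Pearson networks on log2
  intensities (pairwise-complete), ROC evaluation against annotated
  complex/interaction pairs (AUC by the Mann–Whitney rank identity),
  complex cohesion and outlier subunits.
* **Weighted modules** — soft-thresholded adjacency `|r|^β`, topological
  overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij),
  average-linkage module detection, module eigengenes (first PCs),
  hypergeometric set enrichment with BH correction, network export at
  weight > 0.02.
* **Net phosphorylation** — per-peptide OLS residuals of log2
  phosphopeptide on log2 parent protein; kinase/phosphatase
  co-phosphorylation networks at BH FDR.
* **Genomic impact** — mutated-vs-wild-type ANOVA scans (F = t²) with a
  pooled-permutation FDR, zygosity stratification (hom < het < 0),
  C-terminus position trends, mRNA/protein regression-out, binary CNA
  scans, LoF propagation subnetworks, linear-regression QTL mapping with
  cross-layer replication.
* **Subtypes & pharmacoproteomics** — consensus k-means subtyping on the
  top-variance proteins with PAC-based class-number selection, Welch-test
  MSI differential analysis, nested-CV elastic-net drug-response models
  per molecular layer (predictive when out-of-fold Pearson r > 0.4), and
  drug-efflux (ABCB1/ABCB11-type) response correction.
* **Synthetic cohorts** — `generate_cohort` / `null_cohort` emit a full
  50-sample multi-omic panel with planted complexes, mRNA coupling,
  zygosity-dependent LoF effects with protein-only propagation, CNA
  dosage, five subtypes, kinase latents and efflux-driven drug resistance,
  plus a ground-truth ledger — so every stage is testable without any
  download.

Supported formats: GCT 1.2/1.3, GMT, TSV edge lists / mutation tables /
IC50 matrices, YAML configuration.

## Worked example

```python
import numpy as np
from covariome import CohortSpec, generate_cohort
from covariome.covariation import (
    pairwise_correlation, interaction_roc, soft_threshold_select,
    adjacency_and_tom, detect_modules,
)
from covariome.genomic import lof_scan

cohort = generate_cohort(CohortSpec(seed=1))       # 2000 proteins, 50 lines

net_p = pairwise_correlation(cohort.protein)       # >=80% quantified, log2
net_m = pairwise_correlation(cohort.mrna)
pairs = cohort.annotations.all_set_pairs()         # planted complex pairs
print("protein AUC", round(interaction_roc(net_p, pairs).auc, 3))
print("mRNA    AUC", round(interaction_roc(net_m, pairs).auc, 3))

power = soft_threshold_select(net_p.r).power
_, tom = adjacency_and_tom(net_p.r, power)
modules = detect_modules(tom, net_p.features)
print("modules", modules.n_modules)

scan = lof_scan(cohort.protein, cohort.mutations, n_perm=500, seed=0)
hits = scan[scan["q"] < 0.1]
print("LoF hits", len(hits), "| all downregulated:", bool((hits.effect < 0).all()))
```

prints

```
protein AUC 0.997
mRNA    AUC 0.751
modules 221
LoF hits 19 | all downregulated: True
```

The protein network separates planted complex pairs almost perfectly and
clearly outperforms the mRNA network (the co-variome is a
post-transcriptional signal); module detection recovers the planted
complexes among 221 modules; and the permutation-FDR scan finds 19 of the
20 planted LoF genes at q < 0.1, every one with the expected negative
effect.

A thin CLI mirrors the library (`covariome simulate`, `preprocess`,
`covary`, `modules`, `phospho`, `mutimpact`, `cnascan`, `propagate`,
`qtl`, `subtype`, `drugfit`); every subcommand takes `--config` (YAML) and
`--seed`.

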