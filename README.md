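# microkeystone

Keystone-taxon discovery for coupled microbiome / transcriptome / behaviour
studies.

Gut microbiome experiments with a small number of treatment groups (here the
canonical design is Control, high-altitude exposure **HA**, probiotic **P**,
and their combination **HAP**, with 10–15 animals per group) routinely ask
three questions: which taxa characterise each condition, which taxa hold the
community together, and how the community relates to host readouts (brain
gene expression, behaviour scores, antioxidant assays). `microkeystone`
implements that full chain as a tested, seedable pipeline, together with a
synthetic-data generator that plants known structure so every stage can be
validated without any sequencing data.

## What it computes

* **Abundance partition** — each feature's per-sample relative abundance
  range against cuts at 0.1% and 1% assigns one of six classes: rare (RT),
  abundant (AT), moderate (MT), conditionally rare (CRT), conditionally
  abundant (CAT), and conditionally rare-or-abundant (CRAT).
* **Prevalence filter and TMM** — features present in ≥20% of at least one
  group's samples with total relative abundance >2.5% are kept; counts are
  normalised by trimmed-mean-of-M-values scaling factors.
* **Diversity and ordination** — observed features and Shannon diversity
  `H = -Σ p_i log p_i`; Bray–Curtis dissimilarity
  `d(x,y) = Σ|x_i−y_i| / Σ(x_i+y_i)`; PCoA by Gower double-centering; one-way
  PERMANOVA (adonis) with a permutation pseudo-F null.
* **Key species** — point-biserial indicator analysis over group
  combinations with a max-statistic permutation null, and
  specificity–occupancy calling (both strictly > 0.7).
* **Keystone nodes** — Spearman co-occurrence networks (`|rho| ≥ 0.6`,
  BH-corrected p < 0.05), degree / betweenness / stress / eigenvector
  centralities, greedy-modularity modules, and argmax keystone reporting.
* **Differential features** — exact conditional negative-binomial or
  permutation tests on TMM-normalised counts; gene dialect
  (`|log2FC| > 1, p < 0.05`) and microbiome dialect (BH `FDR < 0.05`).
* **Integration** — Procrustes `m² = 1 − (Σσ)²` with a PROTEST permutation
  test, and a typed taxa–gene–trait Spearman network
  (taxa–gene edges at `r > 0.8, p < 0.01`).

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Run the whole chain on a synthetic study in which the correlation hub is
also enriched in the HA group:

```python
import microkeystone as mk

report = mk.run_pipeline(
    {"community": {"n_per_group": 10, "hub_group": "HA"},
     "rho_min": 0.85, "network_per_group": False,
     "diff_method": "permutation"},
    seed=7,
)
```

Selected report fields from this exact run:

```
class_counts            {'RT': 127, 'AT': 7, 'MT': 7, 'CRT': 99, 'CAT': 17, 'CRAT': 43}
permanova               pseudo_F = 26.71, R2 = 0.690, p = 0.001 (999 permutations)
pcoa axes               56.8% / 8.7% of positive-eigenvalue variance
key_species (sample)    ASV0180@HA, ASV0187@HAP, ASV0190@P, ASV0199@Control, ...
keystone_degree         ['ASV0229']      # the planted hub
n_significant_genes     25               # includes all 20 planted DE genes
procrustes              m2 = 0.276, p = 0.001 (999 permutations)
omics_network           11 taxa-gene, 48 taxa-trait, 48 gene-trait edges
```

Reading this: the four groups separate strongly (PERMANOVA p = 0.001, the
smallest value 999 permutations can produce), each group's planted
specialists surface as key species in their own group, the planted hub
ASV0229 is the unique degree keystone, the two omics ordinations are
concordant (Procrustes p = 0.001), and the hub's coupled genes appear among
the taxa–gene edges of the integration network.

The same stages are available from the shell:

```bash
mkp synthesize --seed 7 --outdir run/
mkp partition --counts run/counts.tsv --metadata run/metadata.tsv --outdir run/
mkp permanova --counts run/counts.tsv --metadata run/metadata.tsv --seed 7
mkp run-all --seed 7 --outdir run/
```

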