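# cmlcite

A tested, reusable implementation of a single-cell CITE-seq analysis
pipeline for chronic myeloid leukemia (CML) bone marrow, together with a
synthetic-data generator that makes every stage verifiable against known
ground truth.

## The problem

At diagnosis, the Lin−CD34+ compartment of CML bone marrow is a mixture of
leukemic (BCR::ABL1+) and residual normal (BCR::ABL1−) stem and progenitor
cells. Because the fusion transcript itself is rarely captured in 3'
droplet scRNA-seq, leukemic cells must be identified indirectly: by
projecting patient cells onto a normal bone marrow (nBM) reference,
isolating the primitive (stem-like) cluster, and scoring each cell against
published leukemic-stem-cell (LSC) and normal-HSC gene signatures. Surface
antibody tags (ADTs, e.g. CD26, CD25 vs CD35) then validate the calls
immunophenotypically, and reference-derived cluster profiles allow bulk
cohorts to be deconvolved into constituent cell populations.

The package implements that workflow end to end:

| stage | module | what it does |
|---|---|---|
| synthetic data | `cmlcite.synthetic` | NB count generator: 11-cluster hierarchy, two primitive sub-states, hashtags with doublets, bulk mixtures — all with truth tables |
| QC / demux | `cmlcite.qc` | gene-count and mito-fraction filters; per-hashtag Otsu thresholding (log1p, 256 bins, background buffer 0.1, override 0.5); HTO/RNA cluster-overlap doublet exclusion (reciprocal overlap > 70%) |
| graph & embedding | `cmlcite.embed` | HVG selection by NB-residual dispersion, PCA (20 PCs), KNN graph (k = 11), Leiden clustering, UMAP; rank-based marker specificity |
| projection | `cmlcite.projection` | KNN mapping onto a frozen reference (5 neighbors), inverse-distance weighted label transfer with abstention at weight ≤ 0.5, per-reference-cell mapping scores |
| BCR::ABL1 status | `cmlcite.status` | primitive-cell merge across patients (500 HVGs, PCA fitted on patient cells only), coarse Leiden (resolution 0.1), per-cell signature z-scores, deterministic cluster-level status calls |
| differential | `cmlcite.differential` | pseudobulk (3 random replicates) NB Wald test with BH adjustment (padj < 0.01, \|log2FC\| > 1), cluster-specific and pan-CML gene-set logic, CLR normalization, Mann–Whitney ADT testing with Bonferroni |
| gating | `cmlcite.gating` | antilog×1000 scale transform, +/− threshold gates, capture fractions, CD26+CD35− / CD26−CD35+ ratio |
| deconvolution | `cmlcite.deconvolution` | marker-based signature matrix, non-negative least squares with fractions normalized to 1, responder-group comparison |
| driver | `cmlcite.pipeline`, `cmlcite.cli` | config-validated multi-sample runs; `cmlcite` console command |

## Worked example

```python
import numpy as np
from cmlcite import synthetic as syn
from cmlcite.embed import GraphParams, build_graph, leiden_cluster, select_hvgs
from cmlcite.projection import build_reference, map_cells, transfer_labels

profiles = syn.default_reference_profiles()          # 11-cluster hierarchy
rna, adt, truth = syn.generate_reference(profiles, 2000, seed=1)
model = build_reference(rna, truth.cells["cluster"])

query, _, qtruth = syn.generate_reference(profiles, 1000, seed=2,
                                          cell_prefix="q")
labels = transfer_labels(map_cells(model, query, 5), model.labels, 0.5)
assigned = labels != "NA"
print(f"abstention: {(~assigned).mean():.1%}")
print(f"accuracy:   {(labels[assigned] == qtruth.cells.cluster[assigned]).mean():.1%}")
```

prints

```
abstention: 0.0%
accuracy:   100.0%
```

meaning every query cell received a label and all labels match the
generator's ground truth — at the default cluster separation the
reference projection is essentially lossless. Shrinking the marker boost
toward 1 degrades this gracefully toward chance (see the test suite's
zero-separation check).

An end-to-end run on simulated data:

```bash
cmlcite simulate --outdir study --seed 1 --patients 2
cmlcite run --config study/config.yaml --outdir study/out
```

which writes per-sample QC/demux reports, embeddings, transferred labels,
the BCR::ABL1 status table, DE tables, and the gate-capture report under
`study/out/`.

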