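# crossatlas

Tools for comparing two expression atlases of the **same tissue panel**
measured on different platforms — RNA-Seq (FPKM) and hybridization
microarrays (normalized intensities) — the situation that arises when a
legacy array-based atlas is re-profiled by sequencing.  The package grew out
of the maize developmental atlas setting (18 tissues, 3 biological
replicates per tissue, the same RNA hybridized and sequenced), but nothing
in it is maize-specific.

It answers three questions for platform-paired data:

1. **Do the platforms agree globally?**  Detection filters, per-tissue
   Pearson correlations on log values, replicate QC, complete-linkage
   clustering of tissues and k-means + PCA ordination.
2. **Where does resolution differ?**  Shannon-entropy tissue specificity
   (H = −Σ pₜ log₂ pₜ over the normalized profile) compared between
   platforms by a Mann–Whitney test, and paralog-pair correlations against a
   random-pair null with the "> 2 SD above random pairs" rule, which exposes
   microarray cross-hybridization between close duplicates.
3. **Which genes change their co-expression neighborhood?**  Per-platform
   co-expression networks (all-pairs Pearson over tissues, Fisher
   z-transform, z-score normalization of edges), a global network similarity
   R, and per-gene **expression conservation** (EC) — the correlation of a
   gene's edge-weight vector between the two networks.  Significance comes
   from a mixed-platform bootstrap: for each of B replicates a fair coin
   decides, tissue by tissue, which platform's profile enters each of two
   pseudo-networks, giving the distribution of EC expected when platform
   labels carry no information.  Genes whose observed EC falls in the far
   left tail of that null are platform-divergent.

A first-class synthetic-data module generates paired two-platform datasets
from a known latent transcriptome with planted platform artifacts —
microarray saturation at the scanner ceiling, background floor,
mismatch-dependent probe bleed between tissue-specific paralogs, and
negative-binomial RNA-Seq counts with dropout of low-expressed genes — so
every stage of the pipeline can be validated against ground truth.

## Worked example

```python
from crossatlas import (SyntheticConfig, generate_truth, simulate_rnaseq,
                        simulate_microarray, collapse_replicates)
from crossatlas.transforms import platform_transform
from crossatlas.network import (remove_constant_genes, build_network,
                                fisher_normalize, network_similarity)
from crossatlas.conservation import ec_significance

cfg = SyntheticConfig(n_genes=500, n_modules=25, seed=1)
truth = generate_truth(cfg)
rnaseq = collapse_replicates(simulate_rnaseq(truth, cfg))
microarray = collapse_replicates(simulate_microarray(truth, cfg))

ta = platform_transform(microarray)   # log2 with floor 1
tb = platform_transform(rnaseq)       # inverse hyperbolic sine
ta, _ = remove_constant_genes(ta)
tb, _ = remove_constant_genes(tb)
shared = [g for g in ta.gene_ids if g in set(tb.gene_ids)]
ta, tb = ta.subset_genes(shared), tb.subset_genes(shared)

R = network_similarity(fisher_normalize(build_network(ta)),
                       fisher_normalize(build_network(tb)))
print(f"global network similarity R = {R:.3f}")

ec = ec_significance(ta, tb, B=200, seed=1, alpha=0.01)
print(f"genes with divergent co-expression (p < 0.01): {len(ec.flagged)}")
print(f"fraction conserved: {1 - len(ec.flagged)/len(ec.per_gene_ec):.3f}")
recovered = len(ec.flagged & truth.divergent_genes) / len(truth.divergent_genes)
print(f"planted artifact genes recovered: {recovered:.2f}")
```

Output:

```
global network similarity R = 0.720
genes with divergent co-expression (p < 0.01): 34
fraction conserved: 0.932
planted artifact genes recovered: 0.65
```

The two platform networks agree strongly overall (R = 0.72) while a small
set of genes — dominated by the planted saturation, low-count and
probe-bleed artifacts — have significantly divergent neighborhoods.  A
single 500-gene run recovers about two thirds of the planted artifacts; the
acceptance battery below, which pools ten generator seeds, recovers ~86–90%
with a clean-gene false-flag rate near 0.1%.

## Command line

```bash
atlas simulate --n-genes 2000 --seed 1 --out sim/      # paired tables + truth
atlas run --config run.yaml                            # full pipeline
atlas report run_out/report.json                       # pretty-print summary
```

`run.yaml` holds a `RunConfig`: input paths (or a `synthetic:` block),
thresholds (`ma_threshold: 200`, `fpkm_min: 5`, `ci_level: 0.95`,
`alpha: 0.01`, `tau: 2.0`, `boot_reps: 1000`), a seed, and per-stage
toggles.  Every artifact is written with a JSON metadata sidecar and the run
report aggregates all summary statistics.

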