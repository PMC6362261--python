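# seednet

Seeded mutual-information co-expression network analysis for two-group
(tumor/normal) transcriptomes.

Tumor phenotypes such as chronic inflammation in breast cancer emerge from
coordinated deregulation of many genes at once. `seednet` reconstructs that
coordination from a log2 expression matrix: it scores every gene pair by
mutual information, extracts the subnetwork anchored on a seed process (for
instance the Gene Ontology inflammatory-response gene list), decomposes the
subnetwork into hierarchical modules with the map equation, annotates the
modules with gene-set over-representation and differential-expression
status, and quantifies per-sample pathway deregulation with principal-curve
scores. A synthetic-cohort generator with planted ground truth makes every
stage testable without any microarray download.

## The methods in brief

* **Differential expression** — moderated t with empirical-Bayes variance
  shrinkage: `s²_post = (d₀s₀² + df·s²_g)/(d₀ + df)`, prior `(d₀, s₀²)`
  fitted by moments of the log residual variances; genes banded by fold
  change into over (logFC > 1), under (logFC < −1), no-change otherwise.
* **Network inference** — Shannon mutual information on equal-frequency
  (rank) bins with a support-adjusted Miller–Madow bias correction; all
  C(G,2) pairs are ranked descending, no significance filter.
* **Seeded extraction** — keep the top-k ranked edges touching a seed gene,
  collect seeds plus first neighbors, then take the top-k edges of the full
  ranking internal to that gene list.
* **Modules** — minimize the (hierarchical) map equation
  `L(M) = q·H(Q) + Σᵢ p°ᵢ·H(Pᵢ)` over partitions with a seeded multi-trial
  Louvain-style search, recursing into submodules while the codelength
  drops; modules are labeled by their highest-PageRank member.
* **Enrichment** — per-module hypergeometric upper tail in log space,
  Benjamini–Hochberg within module, with both a q ≤ 0.05 screen and a
  strict p ≤ 1e−5 regime.
* **Overlay** — inter-module edges joining two overexpressed genes are red,
  two underexpressed blue, everything else gray; inter-module flow is
  reported as link counts and MI-weight sums.
* **Deregulation** — Pathifier-style pathway deregulation score (PDS): a
  principal curve is fitted through samples in pathway-expression space,
  each sample scored by normalized arc length from the normal-sample end;
  two pathway scores classify samples into both / adaptive-only /
  inflammation-only / neither at PDS > 0.4.

## Worked example

```python
import seednet as sn

design = sn.default_design(rng_seed=1)           # 1,000 genes, 64 tumors, 16 normals
expr, truth = sn.generate_expression(design)
ranked = sn.all_pairs_mi(expr)                   # 499,500 ranked MI edges
net = sn.extract_network(ranked, truth.planted["gene"], k_seed=3000, k_final=3000)
tree = sn.detect_modules(net, n_trials=10, rng_seed=13)
sn.label_modules(tree, sn.pagerank(net))
summary = sn.hierarchy_summary(tree)
print("network:", net.number_of_nodes(), "genes,", net.number_of_edges(), "edges")
print("codelength:", round(tree.codelength_bits, 3), "bits")
print("modules per level:", summary["modules_per_level"])
```

prints

```
network: 265 genes, 3000 edges
codelength: 5.776 bits
modules per level: {1: 12, 2: 10}
```

meaning the seeded extraction kept 265 genes joined by the 3,000 strongest
internal MI edges, and a random walk on that network is described most
compactly (5.776 bits/step) by 12 first-level modules, 10 of which carry
second-level substructure — the planted submodules and a few small
background fragments. The four-group percentage report works directly from
counts as well; the 641-tumor cohort split (395/210/22/14) gives

```
            group  count  percentage
             both    395        61.6
    adaptive_only    210        32.8
inflammation_only     22         3.4
          neither     14         2.2
```

The same stages are available from the shell: `seednet simulate`,
`seednet de`, `seednet mi`, `seednet extract`, `seednet modules`,
`seednet enrich`, `seednet overlay`, `seednet pds`, and `seednet run
--config cfg.yaml` for the whole pipeline with a manifest.

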