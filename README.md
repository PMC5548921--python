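# tastecells

Analysis pipeline for single-cell transcriptomics of physiologically
identified taste-bud cells.

Mouse taste buds contain distinct cell types that cannot all be told apart by
a reporter gene: *Tas1r3*⁺ type II (sweet/umami receptor) cells fluoresce in
Tas1r3-GFP mice, but type III (presynaptic, sour/salt) cells are identified
functionally — by a depolarization-evoked calcium response to 50 mM KCl.
`tastecells` implements the full chain such a study needs, for anyone
analysing small cohorts of physiologically sorted single cells:

- **`tastecells.calcium`** — classify cells from fura-2 F340/F380 traces: a
  responder shows a rise > 10 baseline SDs sustained ≥ 10 s, with baseline
  statistics from the 120 s before stimulus onset, on irregularly sampled
  traces.
- **`tastecells.counts`** — count-matrix I/O (TSV/MatrixMarket),
  median-of-ratios size factors, detected-gene thresholds (1–50 normalized
  counts), log2(x+1) transform, top-variance PCA, Euclidean hierarchical
  clustering with newick export, 100-quantile gene-body coverage.
- **`tastecells.de`** — two-group negative-binomial differential expression:
  method-of-moments dispersions shrunk to a 1/μ trend, delta-method Wald
  statistic with log2FC = log2((μ_B + ½)/(μ_A + ½)) (type III over
  *Tas1r3*⁺), Student-t p-values, Benjamini–Hochberg FDR with independent
  filtering of low-mean genes, and the standard gene-list filters
  (|FC| ≥ 2, mean ≥ 10 counts, FDR ≤ 0.05).
- **`tastecells.enrich`** — GO-style gene-set enrichment by 2×2 Pearson
  chi-square against a background universe (screen at p < 10⁻³), plus a
  gene-overlap redundancy summarizer.
- **`tastecells.coexpress`** — double-label immunostaining co-expression
  percentages with the published table's exact formatting, including the
  packaged published count fixture.
- **`tastecells.simulate`** — generators for all of the above with recorded
  ground truth: stepped calcium traces on the rig's variable sampling
  schedule, NB count matrices (9 vs 14 cells, dispersion 0.5, depth
  variation, dropout, marker genes at |log2FC| 5–15), and annotations with
  planted enriched terms.

## Worked example

Simulate a cohort with 17 true responders and 9 non-responders, classify it,
then run differential expression on a simulated marker-bearing count matrix:

```sh
$ tastecells simulate-traces --n-responders 17 --n-nonresponders 9 --seed 1 --out-dir sim
wrote 26 traces to sim
$ tastecells detect-responses --traces sim/traces.csv --events sim/events.csv --out calls.tsv
17 of 26 cells labelled TypeIII
$ tastecells simulate-counts --n-genes 2000 --de-fraction 0.05 --markers --seed 1 --out-dir simc
wrote 2000 genes x 23 cells to simc
$ tastecells de --counts simc/counts.tsv --groups simc/cell_groups.tsv --out-dir dedir
108 DE genes pass the filters (42 up in A, 66 up in B)
```

The 17/26 count reproduces the simulated cohort's truth exactly: every cell
with a 40-SD KCl response is labelled type III, every flat cell is not. In
the DE run, group A is *Tas1r3*⁺ and group B type III, so "up in B" genes
(positive log2FC, e.g. the planted Snap25 and Pkd2l1 markers) are type III
genes; `dedir/de_results.tsv` holds per-gene means, log2FC, Wald statistic,
p-value and FDR (NA where independent filtering removed a low-mean gene).

The published co-expression counts ship with the package:

```sh
$ tastecells coexpress --out table2.tsv
    marker   target coexpressed_over_target coexpressed_over_marker
...
       5HT    CPLX2         173/183 (94.5%)         173/174 (99.4%)
...
```

meaning 94.5% of CPLX2-immunopositive taste cells carry the type III marker
5-HT, and 99.4% of 5-HT cells express CPLX2 — the synaptic protein is
essentially confined to, and ubiquitous in, type III cells.

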