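# ifnsynergy

Tools for dissecting how two STAT1-containing transcription factors divide
the labor of the type I interferon response in epithelial cells.

IFN-β signaling activates the trimeric factor **ISGF3** (STAT1–STAT2–IRF9),
which binds interferon-stimulated response elements (**ISRE**, consensus
`AGTTTC nn TTTC`), and — at high doses only — the STAT1 homodimer **GAF**,
which binds gamma-activated sequences (**GAS**, consensus `TTC n{2–4} GAA`).
The two factors bind distinct genomic sites with distinct kinetics (GAF early,
ISGF3 late), and while GAF binding alone does not activate nearby genes in
lung epithelial cells, the joint activation of both factors super-additively
enhances the expression of a subset of interferon-stimulated genes (ISGs).

`ifnsynergy` implements the downstream analysis that quantifies this:

* **Motif classification** — compile GAS/ISRE consensus models (including the
  Irf1-promoter GAS variant `GATTTCCCCGAATG`), scan peak sequences on both
  strands, and categorize each ChIP-seq peak as GAS / ISRE / BOTH / NO_MOTIF;
  an alternative classifier categorizes binding events by TF presence across
  genotypes (GAF vs ISGF3).
* **Binding kinetics** — inducible peaks (≥ 2-fold over basal signal in ≥ 2
  timepoints), k-means clustering of row-scaled log2 time courses with
  silhouette-based choice of k, and one-sided rank-sum tests for dose
  sensitivity (the GAF "dose gate").
* **Peak→gene linkage** — nearest expressed gene by TSS distance, strand-aware
  promoter calls (−1000..+100 bp), unique per-gene link tables, distance
  distributions by motif category.
* **Expression analysis** — CPM/RPKM with TMM effective library sizes, the
  2 CPM expression filter, ISG calling (FDR < 0.05 and fold > 2 vs
  unstimulated, 1 RPKM pseudocount), induced fractions per linked category.
* **Enhancement scores** — from a mixing experiment (low-dose IFN-β, low-dose
  IFN-γ, their mixture):

  ```
  ES = (RPKM_mixed + 1) / ((RPKM_β + 1) + (RPKM_γ + 1))
  ```

  so the additive null maps to ES ≈ 1 and synergy to ES > 1; quartile
  partitions (TOP/BOTTOM, q = ⌈n/4⌉) and comparisons of basal expression,
  promoter GC content (−300..+300 bp) and promoter-peak presence.
* **Synthetic data** — a fully seeded generator that plants all of the above
  (motif instances in a motif-free background genome, kinetic classes, the
  dose gate, ISGs, multiplicative synergy) so every stage is testable against
  known ground truth, with an epithelial/macrophage mode toggle for the
  cell-context contrast.
* **Core statistics** — self-contained Wilcoxon rank-sum (exact enumeration at
  small n, tie-corrected normal approximation otherwise), Fisher's exact test
  (exact rational hypergeometric enumeration) and Benjamini–Hochberg FDR,
  each verified against brute-force oracles.

## Worked example

Simulate a dataset the size of the motivating experiment (723 peaks, 5000
genes, 179 planted ISGs) and run every stage:

```
$ ifnsynergy run-all --outdir demo --seed 7 --simulate
manifest written to demo/manifest.json
n_peaks: 723
n_inducible: 653
chosen_k: 2
n_expressed: 4995
n_linked_genes: 574
n_promoter_linked: 197
n_distal_linked: 377
n_isgs: 180
```

The manifest records, among other things:

```json
"category_counts_all": {"GAS": 280, "ISRE": 201, "BOTH": 155, "NO_MOTIF": 87},
"chosen_k": 2,
"cluster_sizes": {"1": 306, "2": 347},
"enhancement": {
  "quartile_size": 45,
  "es_threshold_top": 1.82,
  "es_threshold_bottom": 0.97,
  "es_both_vs_isre_p": 2.0e-08
}
```

Reading this: the 723 peaks split into the four motif categories in the
planted proportions; 653 are called inducible; the silhouette criterion picks
k = 2 kinetic clusters (early/GAF-like vs late/ISGF3-like); 574 genes are
uniquely linked to inducible motif-bearing peaks; 180 ISGs are called, so the
TOP and BOTTOM Enhancement-score quartiles hold ⌈180/4⌉ = 45 genes each; and
genes whose promoter peak carries BOTH motifs have significantly higher
Enhancement scores than genes with ISRE-only promoter peaks (one-sided
rank-sum p ≈ 2e-8) — the planted synergy recovered from raw counts.

The same stages are available as a library (`ifnsynergy.simulate_all`,
`classify_peaks`, `find_inducible`, `cluster_kinetics`, `link_peaks`,
`call_isgs`, `enhancement_score`, ...) and as individual subcommands
(`simulate`, `classify-peaks`, `inducible`, `link`, `isg`,
`induced-fraction`, `enhance`).

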