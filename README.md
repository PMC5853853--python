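# pamptx

A tested, reusable pipeline for genetically dissecting elicitor-induced
transcriptional responses in a wild type / phosphatase mutant / phosphatase-
kinase double mutant design sampled at 0, 30 and 90 minutes. The package
covers:

* **Synthetic data** (`pamptx.simulate`) — expression matrices with planted
  dependency categories and temporal archetypes, gene→term maps with planted
  enriched terms, and qPCR amplification curves with planted efficiencies;
  everything downstream is testable against known ground truth.
* **Differential testing** (`pamptx.differential`) — a transparent stand-in
  for alignment-based DE tools: Welch's t on log2(FPKM + pseudocount),
  fold changes on pseudocounted means, Benjamini–Hochberg q-values per
  contrast. Deliberately *not* a reimplementation of any tool's
  negative-binomial model; it honours the same table contract.
* **Genetic classification** (`pamptx.classify`) — per-timepoint calls:
  responsive (|log2FC| ≥ 1, q ≤ 0.01 in wild type *or* single mutant vs
  time 0), dependent (≥1.5-fold, q ≤ 0.01 wild type vs single mutant), and
  the q-only subdivision of dependent transcripts into fully
  kinase-dependent / kinase-independent / partial categories.
* **Temporal clustering** (`pamptx.clustering`) — short time-series model
  profiles (bounded integer step shapes), correlation-based gene assignment,
  exact timepoint-permutation significance, and grouping of non-flat
  profiles into eight archetypes (induced/repressed × transient, late,
  sustained, amplified).
* **Enrichment** (`pamptx.enrichment`) — one-sided Fisher's exact singular
  enrichment against flat term maps with BH FDR, supporting both a
  responsive-set background and a whole-genome background.
* **qPCR quantification** (`pamptx.qpcr`) — window-of-linearity efficiency
  and Ct estimation from raw amplification curves, the E^−ΔCt relative
  expression formula with reference-gene and reference-condition
  normalization, and equal-variance t-tests between genotypes.
* **Reporting** (`pamptx.report`, `pamptx.summary`) — orchestration of all
  stages into a deterministic TSV/JSON report bundle with
  count/percentage summaries and cluster × category cross-tabulations.

## Command line

```sh
pamptx simulate --n-genes 2000 --seed 1 --out-dir run/
pamptx de --matrix run/expression.tsv --out run/diff.tsv
pamptx classify --diff-table run/diff.tsv --out run/calls.tsv --summary-out run/summary.tsv
pamptx cluster --expression run/expression.tsv --responsive-calls run/calls.tsv --out run/clusters.tsv
pamptx enrich --study study.txt --background background.txt --terms terms.tsv --out run/enrichment.tsv
pamptx qpcr --curves curves.tsv --sample-map map.tsv --reference-gene REF \
    --out-levels run/levels.tsv --out-tests run/tests.tsv
pamptx all --seed 1 --out-dir run/            # full pipeline + report bundle
```

`pamptx all` (alias `report`) also accepts `--config FILE` with flat
`key = value` settings; see `pamptx.report.PipelineConfig` for the keys.
Exit codes: 0 success, 1 input error, 2 internal error.

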