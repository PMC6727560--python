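# dimorph

Sex-stratified analysis of cardiac-development transcriptomes, packaged as a
tested, reusable pipeline:

- **core** — annotated FPKM gene × sample matrices, TSV I/O, expression
  filters (FPKM < 1 → not expressed; zero-variance removal; log2(x+1)
  transform for all downstream statistics).
- **sexing** — per-cell sex assignment from the Xist/Eif2s3y expression
  ratio (≥ 1.5 → female, < 1 → male; the uncovered gap [1, 1.5) is called
  ambiguous, double-zero markers unassigned; both excluded from testing).
- **de** — per-stage Welch t tests between sexes on the log2 scale with
  Benjamini–Hochberg FDR and XX/XY/nb bias calls (default alpha 0.05; 0.01
  for the cardiac-precursor bulk comparison).
- **wgcna** — unsigned weighted co-expression networks: |cor|^β adjacency
  with a data-driven soft threshold (scale-free fit over powers 1–20),
  topological overlap, average-linkage clustering, quantile tree cut with
  minimum module size 50, eigengene merging, and module–trait (sex)
  correlation with gene/module significance.
- **trajectory** — gene × stage bias tables (stages ES < CP < E8.5 < E9.5 <
  E10.5 < P1 < Adult) classified into trajectory groups I–V (plus a
  residual "lost" class), conserved-bias counts, X-linkage counts, and
  maintain/lose/acquire/reverse transition summaries. A transcription of the
  published female/male stage-bias tables ships as a fixture
  (`src/dimorph/data/tables_2_3_transcription.tsv`).
- **ppi** — STRING-style edge lists filtered at combined score ≥ 0.7 with
  text-mining-only edges dropped, Louvain community detection, and
  degree/betweenness/closeness centralities with mean-rank aggregation.
- **motifs** — JASPAR PFM parsing, log-odds PWMs, exact p-value score
  thresholds by dynamic programming over the null score distribution
  (default cutoff 1e-5), double-strand scanning, promoter windows
  [−5000, +1000) around the TSS, and hypergeometric (ZOOPS) enrichment.
- **profiles** — bedGraph/BED metaprofiles around anchors with RPM scaling,
  bootstrap bands, and Mann–Whitney group comparison of per-anchor areas.
- **synth** — seeded generators for every input type (bulk panels with
  planted sex effects and a planted sex-correlated module, single-cell
  marker panels with dropout, promoter sets with planted motif instances,
  enriched coverage tracks, planted-partition interaction graphs), each with
  a ground-truth sidecar for parameter-recovery testing.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: worked-example
targets from the transcribed bias tables, exact oracle equivalences (TOM vs
triple loop, threshold DP vs exhaustive enumeration, betweenness vs path
enumeration, modularity vs exhaustive partition search), Monte-Carlo
parameter recovery, null-calibration of the FDR, and determinism/boundary
semantics.

## CLI

```sh
dimorph simulate --kind bulk --seed 1 --out scratch/panel
dimorph sex-cells --matrix cells.tsv --out calls.tsv
dimorph de --matrix panel.tsv --samples panel.samples.tsv --stage ES --alpha 0.05 --out de.tsv
dimorph wgcna --matrix panel.tsv --samples panel.samples.tsv --min-size 50 --out-prefix net
dimorph trajectory --bias-table bias.tsv --summary ES:Adult --out classes.tsv
dimorph ppi --edges edges.tsv --min-score 0.7 --seed 7 --out-prefix ppi
dimorph motif-scan --jaspar motifs.jaspar --fasta promoters.fa --p-cutoff 1e-5 --out hits.bed
dimorph promoters --annotation genes.tsv --genome genome.fa --out promoters.fa
dimorph profile --coverage cov.bedgraph --anchors anchors.bed --flank 2000 --bin 100 --out prof.tsv
dimorph run --seed 3 --out-dir scratch/run   # synthetic end-to-end + manifest
```

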