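# linkmap

Diagnostics and sequence integration for dense genetic linkage maps of
allotetraploid cotton — or any organism with an `A_i`/`D_i`-style
homoeologous chromosome structure.

A high-density linkage map (thousands of SSR/SNP/InDel/REMAP loci over 26
linkage groups) is the bridge between genetics and genome assembly, but
on its own it is just an ordered list of positions. `linkmap` implements
the analysis layer around such a map:

* **Map model** — strict TSV I/O, summary statistics (total length,
  mean inter-locus spacing `L / (n_loci − n_groups)`, loci per group) and
  detection of >10 cM gaps.
* **Segregation distortion** — per-locus Pearson χ² against the 1:1
  expectation of a BC1 population, `χ² = (n₁ − n₃)²/(n₁ + n₃)` on 1 df
  (no continuity correction), skew-direction classification at α = 0.05,
  per-marker-type report tables, and scanning for segregation distortion
  regions: maximal runs of ≥3 adjacent same-direction distorted loci,
  named `SDR<k>_<chromosome>`.
* **Map structure** — locus density in 10-cM bins, cluster calling
  (≥5 loci per sliding 1-cM window; EST-SSR-dense clusters flagged as
  candidate gene islands, REMAP-majority clusters as retrotransposon-rich
  regions), duplicated-locus accounting for multi-locus markers with
  homoeologous / same-chromosome / non-homoeologous classification, and
  duplicated-locus support for candidate reciprocal translocations.
* **In silico PCR** — mismatch-bounded (≤3 substitutions per primer)
  convergent forward–reverse primer-site search over EST/BAC FASTA pools,
  implemented with a pigeonhole k-mer index (provably complete for
  Hamming matching) and verified against naive full scans; product-size
  comparison across species; hash-seeded ungapped X-drop extension for
  anchoring arbitrary query sequences to long templates.
* **Integration** — per-marker anchor clusters, greedy exact-overlap
  unigene selection, assignment of anchored genes to fiber-quality QTL
  (FL/FS/FF/FE/FU) whose flanking-marker interval is ≤20 cM, chromosome ×
  trait summary tables with At/Dt subtotals, and interval-overlap QTL
  clustering.
* **Synthetic data** — seeded generators for every input (map, BC1
  genotypes, primers, template pools, QTL tables) with truth manifests,
  so every detector is scored against known plants.

## Worked example

Simulate a study-shaped bundle and run the full pipeline:

```
linkmap simulate --seed 7 --out-dir demo --loci-per-group 40
linkmap pipeline --in-dir demo --out-dir demo_run
```

which prints (and writes to `demo_run/report.json`):

```json
{
 "map": {
  "n_loci": 1141,
  "n_groups": 26,
  "total_length_cM": 3489.55,
  "mean_interlocus_cM": 3.13,
  "n_gaps_gt10cM": 51
 },
 "segregation": {
  "n_distorted": 87,
  "n_sdrs": 8
 },
 "structure": {
  "n_clusters": 4,
  "n_duplicated_loci": 74
 },
 "anchor": {
  "n_markers": 200,
  "n_with_hits": 127,
  "n_without_hits": 73,
  "n_est_templates_hit": 246,
  "n_bac_templates_hit": 5,
  "success_pct": 63.5
 },
 "integration": {
  "n_qtl_retained": 7,
  "n_assignments": 25
 }
}
```

Reading it: 1,141 loci over 26 groups give a sparse 3.13 cM mean spacing
(the demo plants only 40 background loci per group). 87 loci depart from
1:1 segregation at α = 0.05 — the planted distortion regions plus the
expected ~5% false positives — and 8 of the 12 planted regions survive
the ≥3-consecutive-loci SDR rule at this low map density. The anchoring
stage recovers exactly the 63.5% of markers the generator planted
amplicons for, hitting 246 ESTs and 5 BACs, and 25 anchored markers fall
inside the seven QTL intervals that pass the 20-cM filter (the planted
26-cM interval is excluded). Per-stage outputs (`distortion.tsv`,
`sdrs.tsv`, `clusters.tsv`, `anchors.gff3`, `table2.tsv`, …) land in
`demo_run/`; `demo/truth.json` holds the ground truth for every plant.

Each stage is also available as its own subcommand (`summarize`,
`segregation`, `structure`, `anchor`, `integrate`) and as a library API
(`linkmap.anchor_pool`, `linkmap.scan_sdrs`, …).

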