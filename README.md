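# repeatdensity

Genes whose promoters carry long mononucleotide A/T tracts (poly-dA/dT
runs) can be expressed differently between cell states — for example
between cancer-stem-cell–enriched spheroids and the parental monolayer
cells they came from. `repeatdensity` is a small, tested pipeline for
asking that question with a genome, a one-TSS-per-gene annotation, and two
two-group expression experiments:

1. **Scan** the genome for *perfect* (maximal, mismatch-free) homopolymer
   A and T runs and keep those of 13–27 bp.
2. **Profile** each gene's surroundings in a 200-bin window of 100 bp bins
   anchored at the transcription start site (TSS): bins 1–100 cover the
   10,000 bp upstream in transcription direction, bins 101–200 a
   10,000 bp intragenic stretch. A run's base pairs are split over bins
   proportionally (positionwise), so a run of 12, 13, and 15 bp lying in
   one bin contributes 12 + 13 + 15 = 40 bp there.
3. **Classify** every gene per experiment as up- (Up), down- (Dn) or
   non-regulated (Nu) with a two-sided Student's pooled-variance t-test of
   test vs control replicates at P ≤ 0.05, and **intersect** the Up and Dn
   sets across the two experiments (with an optional hypergeometric
   overlap test and a stricter both-experiment P cut for candidate lists).
4. **Compare** repeat density between classes: each gene contributes its
   whole-window density in bp/Mbp (10⁶ × repeat bp / surveyed bp), and
   Dn-vs-Nu and Up-vs-Nu are tested with Student's t-test, per base and
   per experiment.

A synthetic-data generator emulates all of the inputs with exhaustively
known planted truth (run coordinates, gene classes, expression effects),
so every stage is testable end to end without any downloads.

It is aimed at regulatory-genomics analysts who want the procedure to be
explicit, deterministic, and checkable — not at reproducing any specific
published coordinate set, which would require the full human genome and
the original microarray matrices.

## Worked example

Generate a small fixture with planted structure and run the full pipeline:

```bash
repeatdensity simulate --seed 101 --out demo \
    --config tests/fixtures/demo/sim_config.yaml --force
repeatdensity run --config demo/run_config.yaml --out demo_out
```

Output (this exact text — the pipeline is deterministic given the bundle):

```
report written to demo_out/report.json
experiment1 A Dn-vs-Nu: p=0.00338 (increased)
experiment1 A Up-vs-Nu: p=0.461 (increased)
experiment1 T Dn-vs-Nu: p=0.0173 (increased)
experiment1 T Up-vs-Nu: p=0.985 (reduced)
experiment2 A Dn-vs-Nu: p=0.00518 (increased)
experiment2 A Up-vs-Nu: p=0.786 (increased)
experiment2 T Dn-vs-Nu: p=0.0204 (increased)
experiment2 T Up-vs-Nu: p=0.912 (increased)
```

The demo bundle plants repeat runs at three times the background rate in
the windows of its down-regulated genes, so the Dn-vs-Nu comparisons come
out "increased" at small p for both bases, while Up-vs-Nu stays null (the
experiments differ slightly because each classifies genes from its own
noisy replicates). `demo_out/report.json` carries the full accounting:
runs found per base, Up/Dn/Nu counts per experiment, intersection sizes
with hypergeometric overlap p-values, the density comparisons above, and
a checksum manifest of every emitted table.

The same steps are available as library calls (`scan_genome`,
`classify_genes`, `intersect`, `gene_bin_profile`, `compare_classes`, …)
and as separate subcommands (`scan`, `classify`, `intersect`, `profile`,
`compare`) operating on plain FASTA/BED/TSV/YAML files.

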