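# splicescreen

Analysis pipeline for dual-luciferase splicing-reporter RNAi screens, written
for groups who assay alternative splicing with a two-channel minigene
reporter: Firefly luciferase reports transcription, Renilla luciferase is
produced only when the reporter's alternative exons are spliced in-frame, and
the **R/F ratio** (Renilla/Firefly) therefore reports splicing normalized to
transcription. The package covers the full computational chain of such a
screen — per-well ratios, control-anchored effects, percent-of-control hit
calling with gene-level voting — together with the standard splicing-
efficiency formulas for gel/RT-PCR quantification and an overlap analysis
between screen hits and co-purification proteomics.

## The statistic at the core

For each siRNA, with means taken over log2(R/F) of its replicate wells and
anchored to the controls of the same plate:

    Δ(siRNA) = mean log2(R/F | siRNA) − mean log2(R/F | siNeg)
    m(siRNA) = |Δ(siRNA)| / |Δ(siPos)|

* a **siRNA hit**: m ≥ 0.5 (at least half the positive-control effect,
  boundary inclusive; both R/F increases and decreases count);
* a **gene hit**: ≥ 2 of the gene's siRNAs are hits (direction-concordant by
  default);
* a **triple hit**: every siRNA of a gene with ≥ 3 siRNAs is a hit.

Also implemented, for quantified product intensities: % splicing =
spliced/(unspliced+spliced); post-transcriptional % splicing =
(spliced₁₂₀−spliced₄₅)/(unspliced+(spliced₁₂₀−spliced₄₅)); % inclusion (PSI)
= included/(included+skipped); transcription level relative to a reference
lane set to 100%; Welch or exact-permutation comparison of replicate
fractions; and the hypergeometric tail for hit-list/proteomics overlap.

Because no public accession holds raw screen luminescence, the package ships
a ground-truthed generator (`synthetic_data`) whose defaults reproduce the
published screen design: 375 genes covered by 1155 siRNAs (345 genes × 3 +
30 genes × 4), duplicate wells, 96-well plates with on-plate controls, and a
positive control that halves the R/F ratio.

## Worked example

```python
import splicescreen as ss

sim = ss.generate_screen(ss.ScreenDesign(
    n_genes=20, sirnas_per_gene=3, seed=7, noise_sd=0.1,
    effect_table={"GENE0001": -1.0,               # all 3 siRNAs halve R/F
                  "GENE0005": 1.0,                # all 3 double it
                  "GENE0011": [-1.0, -1.0, 0.0]}  # one inert siRNA
))
calls, summary = ss.run_screen(sim.dataset)
print(f"{summary.n_genes} genes, {summary.n_hit_genes} hit genes, "
      f"{summary.n_triple_hits} triple hits")
for c in calls:
    if c.is_hit:
        print(f"  {c.gene}  n_hits={c.n_hits} direction={c.direction} "
              f"status={c.status}")
m = ss.recovery_metrics(calls, sim.truth)
print(f"sensitivity={m.sensitivity:.2f} FPR={m.false_positive_rate:.2f}")
```

prints

```
20 genes, 3 hit genes, 2 triple hits
  GENE0001  n_hits=3 direction=-1 status=triple_hit
  GENE0005  n_hits=3 direction=+1 status=triple_hit
  GENE0011  n_hits=2 direction=-1 status=hit
sensitivity=1.00 FPR=0.00
```

The two genes whose every siRNA carries a full positive-control-sized effect
come back as triple hits; the gene with one inert siRNA still qualifies as a
hit on the two-siRNA rule; the 17 null genes stay below threshold, so
sensitivity is 1 and the false-positive rate 0 against the generator's truth
table.

The same chain is available from a shell:

```
splicescreen simulate --genes 375 --seed 1 --out-dir sim/
splicescreen validate sim/measurements.csv --library sim/library.csv
splicescreen call-hits sim/measurements.csv --library sim/library.csv --out hits.csv
splicescreen overlap --factors table1.csv --hits hits.csv --universe sim/library.csv
splicescreen quant lanes.csv --mode splicing
```

A transcription of the published co-purification factor table (83 factors in
five functional groups, with unique-peptide, coverage and log(e) evidence)
ships with the package: `ss.load_reference_factor_table()`.

## Layout

```
src/splicescreen/
  screen_io.py       library/measurement readers, validation, hit-table I/O
  hit_calling.py     R/F statistic, control anchoring, hit and gene rules
  splicing_quant.py  % splicing / PT splicing / inclusion / transcription level
  factor_overlap.py  factor-table parsing, grouping, overlap + enrichment
  synthetic_data.py  ground-truthed screen/lane/factor generators
  cli.py             click front end (`splicescreen ...`)
  data/table1_factors.csv   packaged factor-evidence table
docs/methods.md      model, assumptions, defaults, limitations
tests/               pytest suite with independent brute-force oracles
```
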