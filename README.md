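# phagecore

Core-genome identification for nucleus-forming (chimallin-encoding) phages,
plus the fluorescence-microscopy statistics used to characterize phage-nucleus
behavior — as a tested, reusable Python package with a synthetic-data
generator so the entire analysis can be exercised without any downloads.

## The problem

Some jumbo bacteriophages replicate inside a proteinaceous compartment — the
*phage nucleus* — whose shell is built from the protein **chimallin (ChmA)**.
Phages encoding chimallin form a monophyletic family, and the genes they all
share are the best candidates for the machinery of nucleus-based replication.
`phagecore` implements the comparative-genomics procedure that delineates that
family's core genome, and the quantification statistics applied to microscopy
of infected cells:

* **Presence/absence from homology hits.** Tabular (PSI-)BLAST hit tables are
  parsed, filtered at an inclusive E-value cutoff (default 0.05), and
  collapsed through an explicit protein-accession → genome map into a boolean
  genes × genomes detection matrix over an in-group panel (chimallin-encoding
  genomes) and an out-group panel (related phages without chimallin).
* **Core / accessory / intermediate classification.** With per-gene
  conservation frequency *f* (fraction of in-group genomes with a detection),
  a gene is **core** iff *f* > θ_core (default 0.90, i.e. "more than 90%"),
  **accessory** iff *f* ≤ θ_acc (default 0.10), intermediate otherwise.
  A core gene is **unique-core** when it has at most k (default 0) out-group
  detections — the genes specific to nucleus-forming phages.
* **Conserved gene blocks.** Along the reference genome's gene order, maximal
  runs of ≥ b_min (3) core genes tolerating ≤ g_max (3) intervening non-core
  genes, found by greedy merging and verified in the test suite against a
  brute-force maximal-interval oracle. Exported as BED + TSV genome maps.
* **Microscopy quantification.** Nucleus rotation speed = total tracked path
  length / rotation time; angular velocity ω = path / radius per unit time in
  °/s (so ω·r·π/180 equals the linear speed identically); nucleus positioning
  as pole-distance / cell-length with nucleoid context (between two nucleoids
  or not); filament calling at ≥ 2× background fluorescence; and a
  four-parameter Hill fit of filamentation percentage versus inducer
  concentration, `y = bottom + (top − bottom) / (1 + 10^((logEC50 − log c)·h))`,
  iteratively reweighted by binomial standard errors.

## Worked example

Generate a synthetic panel with planted ground truth mirroring the study
conditions (66 in-group genomes, 317 reference genes, 72 core genes in 7
blocks, 21 of them unique to the family), then run the full pipeline:

```console
$ phagecore simulate-panel --out demo --seed 7
panel written to demo: 66 in-group, 6 out-group, 317 genes (72 core, 21 unique, 7 blocks), seed=7

$ phagecore report --hits demo/hits.tsv --accession-map demo/accession_map.tsv \
    --genomes demo/genomes.tsv --gene-order demo/gene_order.tsv --out demo_out
phagecore v0.1.0 core-genome report (config 8e187edb9b33, seed 0)
in-group genomes : 66
reference genes  : 317
core genes       : 72 (23% of genome; frequency > 0.90)
accessory genes  : 245 (77% of genome; frequency <= 0.10)
intermediate     : 0
unique-core genes: 21 (<= 0 out-group detections); 51 core genes shared with out-group
hypothetical core: 72 (100.0% of core genes)
conserved blocks : 7 (>= 3 core genes, gaps <= 3); 0 core genes outside blocks
```

All 72 planted core genes are recovered (72/317 = 23% of the genome), the 21
planted family-unique genes are flagged (zero out-group detections), and the
7 planted syntenic blocks are found. With no annotation table supplied, every
core gene defaults to "hypothetical", hence 100%. `demo_out/` contains the
presence/absence matrix, the per-gene classification, block summary, BED
genome map, conservation histogram and a machine-readable summary, each with
a header recording the version, configuration hash and seed.

The quantification side works the same way:

```console
$ phagecore simulate-quant --out q --seed 7
$ phagecore quant-rotation --tracks q/tracks.csv --meta q/tracks_meta.csv --out rot.tsv
n=25 speed=52.3+/-0.7 nm/s omega=9.98+/-0.13 deg/s
$ phagecore quant-filamentation --data q/dose_response.csv --out fit.tsv
Hill dose-response fit ([agonist] vs. response, 4 parameters)
  status: ok (converged)
  ...
  EC50    =    0.02963
```

25 tracks planted at 10.1 °/s on a 300 nm-radius nucleus with 20 nm
localization noise are recovered at 9.98 ± 0.13 °/s (the small deficit is the
chord-versus-arc geometry of frame-by-frame tracking; see
`docs/methods.md`), and a planted EC50 of 0.03% arabinose is fitted as
0.0296% from binomial counts of 50 cells per concentration.

Everything the CLI does is also available as a library:

```python
from phagecore import RunConfig, run_pipeline, synthetic

truth = synthetic.generate_panel(seed=7, out_dir="demo")
report = run_pipeline(RunConfig(hits="demo/hits.tsv",
                                accession_map="demo/accession_map.tsv",
                                genomes="demo/genomes.tsv",
                                gene_order="demo/gene_order.tsv",
                                out_dir="demo_out"))
report.summary["n_core"], report.summary["n_unique_core"]   # (72, 21)
```

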