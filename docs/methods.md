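# Methods

## Presence/absence model

The unit of evidence is a homology-search hit from a reference-genome protein
(query gene) to a subject protein accession. Hit tables are tab-separated
(BLAST `outfmt 6` order by default; column indices are configurable because
deposited tables vary), with `#` comment lines permitted. A hit qualifies if
its E-value is **≤** the cutoff (default 0.05; "cutoff of 0.05" is read as
inclusive, matching BLAST convention). For PSI-BLAST-style tables that record
a round number, the default `round_policy="last"` keeps only each query's
final recorded iteration — the converged search defines presence — with
`"union"` available since round handling is a genuine judgment call; hits
without a round column are unaffected.

Genome identity comes exclusively from a user-supplied accession → (genome,
panel) map, never from parsing organism names out of accession strings: this
makes presence resolution deterministic and testable. Hits to unmapped
accessions are tallied and reported, never silently dropped and never
counted as presence. A gene is *present* in a genome when at least one
qualifying hit maps there; multiple protein hits in one genome count once
for frequency purposes.

Reference genes with no self-hit row are forced present in the reference
genome (a genome trivially contains its own genes) and flagged in the
report, so an incomplete self-search is visible rather than silently
deflating frequencies by 1/N.

## Classification thresholds

Conservation frequency is the row mean of the boolean gene × in-group-genome
matrix. Class boundaries are deliberately asymmetric at the boundaries:
core requires frequency **strictly greater** than θ_core ("more than 90%"),
accessory requires frequency **≤** θ_acc ("10% or fewer"). θ_core defaults
to 0.90 but is a first-class, always-logged parameter: the source analyses
quote both a 90% and a 95% criterion in different places, and rather than
guessing which produced the deposited gene list, every report embeds the
threshold used (via the configuration hash in each file header).
Unique-core status requires ≤ k_outgroup (default 0) out-group detections;
the tolerance is configurable because "unique" could reasonably admit a
stray false-positive hit. Classification into core/accessory depends only on
in-group frequencies; out-group counts affect only the unique flag (tested
as an invariance).

Percentage conventions: genome-fraction percentages are rounded to the
nearest integer, within-core percentages to one decimal — the precisions at
which such numbers are conventionally reported. The conservation histogram
uses a 0.05 bin width by default (binning is a parameter; the top bin is
closed so frequency 1.0 is counted).

## Block finding

Blocks are runs of core genes along the reference gene order: ≥ b_min (3)
members with ≤ g_max (3) non-core genes between consecutive members, gaps
counted in genes. Greedy left-to-right merging is provably maximal and
deterministic (no tie-breaking can arise); the test suite checks it
exhaustively against an independent brute-force enumeration of maximal valid
intervals for every flag string up to length 16 and for 1000 random strings
up to length 200. Blocks begin and end on core genes; intermediate-frequency
genes count as gaps exactly like accessory genes (the analysis colors only
core genes). `circular=True` lets a run wrap the genome origin — phage
genome maps are circular — but the default is linear, matching how the
block structure is usually drawn; a wrapping run is reported once.

## Rotation statistics

A tracked landmark on the nucleus surface gives a time-ordered point series.
Rotation speed is the summed frame-to-frame Euclidean path length divided by
the rotation time (last minus first timestamp). Angular velocity divides the
same path length by the nucleus radius (half the measured diameter), giving
the swept angle in radians, then by the duration, reported in °/s; both the
total angle and the rate are returned because "angle per time" and "angle
per frame" conventions both appear in practice. The identity
ω · r · π/180 = linear speed holds to machine precision by construction and
is asserted per track.

Chord geometry: sampling a circle every Δt underestimates arc length by
sinc(ωΔt/2) — about 2% at 10.1 °/s and 4-second frames. The measurement on
images is the chord sum, so that is the default; `chord_correction=True`
converts each step to its arc (θ = 2·arcsin(d/2r)), which recovers a planted
noise-free ω to numerical precision. On noisy tracks localization error
inflates chords and roughly offsets the chord deficit at the default
simulation settings (20 nm sd on a 300 nm radius), which is why cohort mean
recovery lands within a few percent with the raw definition.

## Positioning and filamentation

The positioning ratio is pole distance over cell length; the default
`nearer`-pole policy bounds it in [0, 0.5] with 0.5 = midcell and is
symmetric to pole labeling (a `designated`-pole mode exists for time-lapse
consistency). With two nucleoid intervals, "between two nucleoids" requires
the nucleus center strictly inside the inter-nucleoid gap; boundary contact
is scored as not-between. More than two intervals is reported as an
unsupported category rather than guessed at. Filament calling is inclusive:
maximum line intensity ≥ 2× background ("at least double").

The dose-response model is the standard four-parameter log-agonist curve
`y(c) = bottom + (top − bottom)/(1 + 10^((logEC50 − log10 c)·hill))`, fitted
by bounded least squares (`scipy.optimize.curve_fit`). Because responses are
percentages of counted cells, the fit is iteratively reweighted (two
rounds) by the binomial standard error implied by the current curve — the
proper chi-square for proportion data; `weights="none"` gives the plain
unweighted fit. Zero concentrations are mapped to a floor one decade below
the smallest nonzero concentration (log10(0) is undefined; a fixed-decade
floor is standard practice and is recorded in the fit result). Degenerate
inputs — fewer than 4 distinct concentrations, or a flat response — return a
fit object flagged as failed with a diagnostic, never a silent answer.

## Synthetic data: what it emulates, and what it does not

The panel generator plants a gene-family truth table: per-family in-group
conservation frequency (core families ~U(0.93, 1.0), accessory
~U(0, 0.08) — bands that exclude the window between the thresholds so
planted classes are recoverable; an optional intermediate band
U(0.20, 0.80) exists for stress tests), block membership laid out along the
reference gene order with > g_max separation between blocks and occasional
internal gaps, and family-unique flags (zero out-group presence; every
non-unique core family gets ≥ 1 out-group detection). Default sizes mirror
the study: 66 in-group genomes, 6 out-group, 317 reference genes, 72 core
with 21 unique, 7 blocks.

Realization modes: `sampling="exact"` (default) places each family in
round(p·N) genomes chosen at random (always including the reference), with
the count nudged, if rounding would cross a threshold, to stay on the
planted side — recovery is then exact by construction, which is what an
end-to-end correctness test needs. `sampling="binomial"` draws presence
i.i.d. Bernoulli(p) per genome; with N = 66 the realized frequency of a
family planted at 0.93 then falls below the 0.90 threshold ~17% of the
time, so exact class recovery is impossible under i.i.d. sampling and this
mode is used for convergence properties, not recovery tests.

Emitted files are 12-column `outfmt 6` hit tables (one sub-cutoff hit per
present gene/genome pair), an accession map (`GENOME_gNNN` accessions), a
panel definition and a truth table; decoy rows — E-values above the cutoff,
or subjects absent from the map — are added at a low rate (2%) so the
filtering and unmapped-report paths are always exercised. The generator does
not simulate sequence evolution, paralogy, or correlated gene loss:
presence/absence is the unit of truth, exactly as in the hit-table-driven
analysis it feeds. Passing tests therefore validate the bookkeeping and the
classification/synteny logic, not homology-search sensitivity on real
sequences.

Quantification generators: circular tracks with i.i.d. Gaussian localization
noise per coordinate (defaults 300 nm radius, 10.1 °/s, 2-minute lapse at
4-second frames, 20 nm noise — the regimes of the measured cohort); cell
geometries with one or two nucleoid intervals at fixed relative positions
and a nucleus placed mid-cell with the spread calibrated so the planted
between-two-nucleoids probability (default 0.97) is exact; dose-response
counts drawn Binomial(n, p(c)) from a planted Hill curve over a 0–1%
arabinose ladder around an EC50 of 0.03%. With 8 concentrations × 50 cells
the EC50 information content is limited: the median recovery error is ~7%
and roughly a third of random cohorts exceed 10%, so single-cohort EC50
estimates should be read with that precision in mind.

## Problem sizes and numerical choices

Tests and the acceptance script run the full default panel (66 × 317) and
the default quantification cohorts (25 tracks, 858-cell rotating cohort,
103 geometries, 8 × 50 dose-response counts); these are the study's own
cohort sizes and complete in seconds. Seeds: all generators take an explicit
seed and are fully deterministic given (parameters, seed); the test suite
fixes seed 0 throughout. Histogram binning uses half-open bins with a closed
top bin. The BED export is 0-based half-open; without per-gene coordinates,
gene index stands in for position (gene *i* spans [i, i+1)).

## Known limitations

* Presence is whatever the hit table plus accession map say: no orthology
  clustering, no paralog disambiguation, no alignment-quality checks beyond
  the E-value cutoff.
* The pipeline does not run BLAST/PSI-BLAST itself or fetch anything from
  NCBI; it consumes deposited/exported tabular results.
* Cross-genome block order comparison (rearrangement detection between
  genomes) is out of scope; blocks are defined on the reference gene order
  only.
* The angular-velocity statistic assumes the tracked point sits on the
  nucleus equator at the measured radius; off-equator tracking biases ω low
  in real data, and the simulation does not model that.
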