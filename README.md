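# lowhic

A Hi-C contact-map processing toolkit for low-input chromosome-conformation
libraries: from aligned read pairs to balanced contact matrices, insulation
scores and TAD boundaries, A/B compartments, de-novo loop calls, and
case-vs-control detection of structural rearrangements by whole-genome
virtual 4C. A ground-truth simulator is included so that every pipeline
stage can be exercised and validated without external data.

## Features

- **Genome model** — in-silico restriction digestion (MboI, HindIII presets),
  uniform bin tables, 0-based half-open coordinates throughout.
- **Pair processing** — ligation-junction scanning, split-read group
  classification, mapping-quality filtering, fragment assignment,
  ligation-bias filters (site distance > 5 kb, same fragment,
  inward/outward orientation below 10 kb), PCR-duplicate removal with 2 bp
  tolerance, cis/trans QC ratios and library-complexity curves.
- **Matrices** — binning, low-coverage masking (< 10 % of median),
  Knight–Ruiz balancing (Newton inner–outer iteration with Sinkhorn
  fallback), expected-by-distance profiles, observed/expected transform,
  difference matrices, distance-stratified correlations.
- **Tracks** — sliding-square insulation scores (any window list),
  delta-vector TAD boundary calling, compartment eigenvectors from the O/E
  correlation matrix.
- **Aggregates** — aggregate TAD/loop pile-ups with nearest-neighbour
  resampling; TAD-strength and loop-strength ratio statistics.
- **Loop calling** — donut / lower-left / horizontal / vertical local
  neighbourhoods, Poisson enrichment tests, lambda-chunked (or plain)
  Benjamini–Hochberg FDR, and the standard retention filters
  (2.0× donut-or-lower-left, 1.5× horizontal-and-vertical, 1.75× both,
  FDR ≤ 0.1).
- **Rearrangements** — per-bin virtual-4C peak scanning (0.15 × viewpoint
  height, 99.5th percentile, 50-bin cis exclusion, ±7-bin mappability
  guard), case-only call comparison, TAD-intensity difference between
  merged boundary sets.
- **Simulator** — Poisson contact maps with power-law decay, TAD blocks,
  loop foci, compartment checkerboards, masked bins, reciprocal
  translocations with cis-like trans decay, and read-pair libraries with
  planted duplicates / self-ligations / unligated fragments.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(filter exactness, duplicate recovery at 10⁵ pairs, KR vs Sinkhorn oracle,
O/E normalisation, decay-exponent recovery, boundary/compartment/loop/V4C
recovery on planted ground truth, neighbourhood-mask enumeration, and
round-trip I/O).

## Command line

```sh
# simulate a ground-truth map (spec is a small JSON file)
lowhic simulate map --spec map.json --seed 1 --out-prefix sim

# digestion and pair processing
lowhic digest genome.fa --enzyme mboi --out fragments.bed
lowhic pairs reads.sam genome.fa --mapq 3 --site-dist 5000 \
    --orientation-cutoff 10000 --dup-tolerance 2 --out valid.pairs
lowhic stats valid.pairs genome.fa --out qc.tsv

# matrix pipeline
lowhic matrix valid.pairs --chrom-sizes sizes.tsv --resolution 50000 --out-prefix raw
lowhic balance raw --tol 1e-6 --out-prefix bal
lowhic oe bal --out-prefix oe --expected-out expected.tsv

# tracks and features
lowhic insulation bal --windows 100000..1000000:50000 --out-prefix ins
lowhic boundaries bal --delta 7 --min-strength 0.1 --out boundaries.bed
lowhic compartments oe --out-prefix comp
lowhic aggregate tads oe tads.bed --expand 3 --grid 90 --out-prefix agg
lowhic loops bal --p 2 --w 5 --fdr 0.1 --out loops.bedpe

# case-vs-control rearrangement scan
lowhic v4c-scan case_bal --out case_peaks.tsv
lowhic v4c-scan ctrl_bal --out ctrl_peaks.tsv
lowhic compare case_peaks.tsv ctrl_peaks.tsv --tolerance 2 --out calls.tsv
lowhic diff case_bal ctrl_bal --out diff.tsv
lowhic tad-diff case_bal ctrl_bal --out tad_diff.tsv
```

Matrices are stored as plain text: a bin table BED
(`chrom start end index mappable [bias]`) plus an upper-triangle COO TSV
(`bin_i bin_j weight`). Pairs use a 4DN-style 1-based text dialect; all
other outputs are BED / bedGraph / BEDPE / TSV.

## Layout

```
src/lowhic/
  genome.py          chromosomes, digestion, bin tables
  pairs.py           read classification, filters, dedup, QC ratios
  matrix.py          contact matrices, KR balancing, O/E, differences
  tracks.py          insulation, boundaries, compartments
  aggregates.py      pile-ups and strength statistics
  loops.py           neighbourhood-enrichment loop caller
  rearrangements.py  virtual-4C scanning and comparison
  synthetic.py       ground-truth simulator
  qc.py              library QC report
  io.py              text-format readers/writers
  cli.py             `lowhic` entry point
```
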