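# nrcistrome

Integrative cistrome–transcriptome analysis for a nuclear receptor studied
with a knockout × ligand design — the setting where a receptor such as
PPARβ/δ is profiled by ChIP-seq and expression arrays in wild-type and
receptor-null cells, each treated with vehicle or a synthetic agonist.
The package is for computational biologists who want the complete analysis
chain as a tested, reusable library: peak calling with a local binomial
background model, knockout-based artifact filtering, an eight-way
classification of transcriptional responses, nearest-TSS direct-target
integration, genomic-feature enrichment and DR1/PPRE motif analysis.
A bundled simulator plants ground truth (binding sites, artifact peaks,
response types, motif instances) so every stage is verifiable end to end
without any external data.

## The statistics at the core

**Peak calling.** Tag enrichment in a 150 bp target window is gauged
against a 200 kb background window under a binomial model. With *n* the
input-subtracted tag count in the window, *N* the tag count in the
background window, and *p* the ratio of uniquely mappable base pairs
(window over background),

    z = (n − μ) / σ,   μ = N·p,   σ = √(N·p·(1−p))

and windows with *z* > 60 become peaks. Input libraries are scaled to the
ChIP library size first. Peaks overlapping a receptor-null ChIP peak by
more than 1 bp are excluded as non-specific.

**Response types.** Genes are tested in three Welch contrasts on log2
expression (knockout vs wild-type at vehicle; ligand vs vehicle in
wild-type; ligand vs vehicle in knockout), thresholded at fold change
≥ 1.3 and Benjamini–Hochberg FDR ≤ 0.25. Knockout-up means the receptor
*represses* the gene; knockout-down means it *activates* it; a ligand
response counts only if absent in knockout cells. The two calls combine
into eight types:

| type | without ligand | with ligand |
|------|----------------|-------------|
| I    | repression     | –           |
| II   | activation     | –           |
| III  | –              | activation  |
| IV   | –              | repression  |
| V    | repression     | activation  |
| VI   | activation     | repression  |
| VII  | activation     | activation  |
| VIII | repression     | repression  |

**Direct targets.** Peaks are assigned to their nearest transcription
start site; a classified gene with a peak within ±10 kb of its TSS is a
direct target. The without-ligand set A and with-ligand set B obey
|A∩B| = |A| + |B| − |A∪B|.

**Motifs.** A position frequency matrix built from aligned validated
DR1-type response elements (pseudocount 0.25) is scanned as log2-odds
along both strands of 400 bp peak-centered regions; hits score ≥ 80% of
the matrix maximum. Motifs as frequent in receptor-null peak regions as
in wild-type regions are dropped as background. An IUPAC consensus and a
column-correlation similarity tree (average linkage, newick) summarize
matrices.

## Worked example

```python
from nrcistrome import (SimulationConfig, simulate_genome, simulate_tags,
                        call_hotspots, normalize_input, subtract_null_peaks)

config = SimulationConfig(seed=1)
_, genes, mappability, manifest = simulate_genome(config, with_sequence=False)
chip = simulate_tags(mappability, manifest, "chip_wt_veh")
null_chip = simulate_tags(mappability, manifest, "chip_null_veh")
inp = simulate_tags(mappability, manifest, "input_wt")

peaks = call_hotspots(chip, normalize_input(inp, chip.total_tags),
                      mappability, chrom_lengths=manifest.chrom_lengths)
null_peaks = call_hotspots(null_chip, normalize_input(inp, null_chip.total_tags),
                           mappability, chrom_lengths=manifest.chrom_lengths)
filtered = subtract_null_peaks(peaks, null_peaks)
```

Running this (it is `examples/02_call_peaks.py`) prints

```
47 raw peaks, 12 knockout-null peaks, 35 after null subtraction
first peak chr1:23635-23830  z=72.9  n=724 window tags over N=58442 background tags (p=1.34e-03)
planted-site recall: 35/36
```

The 47 raw peaks include the planted sites *and* the simulated
non-specific sites; the knockout-null ChIP recovers the latter, and the
subtraction leaves 35 peaks covering 35 of the 36 planted sites active in
this condition. The peak's z = 72.9 says its window held 724
input-subtracted tags where the 200 kb background predicted
μ = N·p ≈ 78 ± 8.8.

The full chain — simulate → call peaks per condition → subtract → classify
→ integrate → annotate → scan motifs — is one call
(`examples/07_full_pipeline.py`):

```
peaks per condition: {'chip_wt_veh': 36, 'chip_wt_lig': 54}
response types: {'I': 11, 'II': 12, 'III': 10, 'IV': 9, 'V': 7, 'VI': 6, 'VII': 8, 'VIII': 5}
direct targets: without=14 with=33 both=4 union=43
PPRE fraction of peak regions: {'chip_wt_veh': 0.83, 'chip_wt_lig': 0.89}
```

Here 68 of 160 simulated genes are classified into the eight types
(57 of the 64 planted genes recover their planted type at the demo's
modest panel size), 43 of them are direct targets, and 83–89% of peak
regions carry the planted PPRE motif (planting fraction: 0.8). Each
example script in `examples/` isolates one capability and explains its
output; `nrcistrome --help` exposes the same stages as shell subcommands
(`simulate`, `callpeaks`, `classify`, `integrate`, `annotate`,
`scan-motifs`, `run`, `report`).

## Layout

- `src/nrcistrome/intervals.py`, `genes.py`, `tracks.py` — genomic types and BED/GTF/FASTA I/O
- `src/nrcistrome/simulate.py` — planted-truth generator
- `src/nrcistrome/peaks.py` — binomial z-score peak caller and null subtraction
- `src/nrcistrome/expression.py` — contrasts, BH adjustment, eight-way classifier
- `src/nrcistrome/integrate.py` — nearest-TSS assignment and direct-target sets
- `src/nrcistrome/annotate.py` — feature categories and enrichment
- `src/nrcistrome/motifs.py` — PWMs, scanning, co-occurrence, similarity tree
- `src/nrcistrome/pipeline.py`, `cli.py` — orchestration and shell interface
- `src/nrcistrome/benchmarks.py` — the two planted-recovery benchmarks
- `docs/methods.md` — models, parameters, numerical choices and limitations
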