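# Methods

This note documents the models implemented in `nrcistrome`, the defaults
and why they were chosen, what the simulator does and does not emulate,
and the numerical edge-case decisions a maintainer would need.

## Coordinate and data conventions

All coordinates are 0-based half-open (BED native; GTF converted on
read). The TSS of a minus-strand transcript is `tx_end − 1`, symmetric
with the plus strand under half-open coordinates. Sequencing tags are
reduced to single 5′ positions with no fragment-length extension; window
counting is by 5′ position, not by any-overlap of the full read. Tag
strand is read and written in BED6 but does not enter the statistic.

## Peak calling

Candidate 150 bp windows are anchored at each distinct tag-bearing
position (`[pos, pos+150)`) rather than tiled at every base. Shifting a
window start right to its first contained tag never drops tags, so
anchored windows dominate all windows in tag count; the test suite checks
the anchored scorer against an exhaustive every-window oracle on a 10 kb
chromosome (same loci, identical peak z). Anchoring makes the caller
O(#distinct tag positions) per sample.

Per window: `n = max(0, chip − scaled_input)` (negative differences are
floored — the model has no meaning for depletion); the 200 kb background
window is centered on the target window and clipped at chromosome ends,
with `p = mappable(window)/mappable(background)` recomputed from the
clipped extent; `N` is counted from the ChIP track alone (subtracting
input in the background too would correct the same mass twice). Windows
with zero mappable target bp are skipped with a debug log (`p`
undefined); `z = 0` when `N = 0`. Windows with `z` above threshold
(default 60) are merged when they overlap; a merged peak reports the
maximum-z window's `n, N, p, z`. Thresholding happens per window, before
merging.

The normal approximation to the binomial tail is good for `N·p ≥ 5` in
the moderate tail (|z| ≲ 3, checked against the mid-P exact tail within
0.25); at the far tail where calling happens (z > 60) the approximation
understates how extreme the tail is, which only makes the threshold
conservative in p-value terms. Input normalization multiplies the stored
integer counts by `chip_total/input_total` at query time, so the
effective input total matches the ChIP library exactly as a real number.

Null subtraction removes a peak iff it overlaps a receptor-null peak by
**more than 1 bp** (a 1 bp touch is kept, 2 bp removed); the operation is
idempotent and never adds peaks.

## Differential expression and response types

The DE test is Welch's t on log2 values per contrast, with per-contrast
Benjamini–Hochberg adjustment (`bh_adjust` delegates to statsmodels and
is verified against a hand-computed step-up oracle). Thresholds default
to fold change 1.3 and FDR 0.25. Both the test and the adjustment sit
behind one function each and can be swapped. Zero within-group variance
in both groups yields p = 1 when the means agree and p = 0 with a warning
otherwise.

Classification reads the genotype contrast for the constitutive call
(knockout-up ⇒ the receptor represses, type-I component; knockout-down ⇒
activates, type-II component) and the wild-type ligand contrast for the
ligand call, which additionally requires the knockout ligand contrast to
be non-significant: a gene whose ligand response survives receptor loss
is receptor-independent and is assigned no type (flagged
`ligand_independent`). The two calls map onto types I–VIII as in the
README table; genes with neither call are `none`. FDR is controlled per
contrast, not pooled across the three contrasts — with three contrasts of
very different signal density, pooling would let the dense contrast set
the threshold for the sparse ones.

## Integration

Peak-to-gene distance is measured from the peak midpoint to the TSS
(signed by the gene's strand: positive downstream). Each peak gets
exactly one gene — the nearest TSS genome-wide, ties broken by
lexicographic gene id — but a gene may collect many peaks; occupancy is
an OR over a gene's peaks. Peaks on chromosomes without genes carry a
`+inf` sentinel and drop out downstream. Direct-target membership uses
|signed distance| ≤ 10 000 bp (configurable); enlarging the window can
only add genes (tested). Multi-transcript inputs are handled at the
transcript level: the nearest TSS wins, whichever transcript provides it.

## Feature annotation

Feature categories partition the genome exactly once per base:
intragenic precedence 5′UTR > 3′UTR > coding exon > intron; outside
transcripts, strand-aware upstream bins (from the TSS) and downstream
bins (from the transcript 3′ end) out to 3 kb, with a base inside two
genes' flanks going to the nearer anchor; all else intergenic. Exonic
bases of non-coding transcripts (empty CDS) fall in the coding-exon
category, which operationally means "exonic, non-UTR". Peaks are labeled
by their midpoint through the same per-base label array that produces
the genome baseline, so observed and baseline fractions are exactly
comparable and fractions sum to 1 by construction.

Enrichment per category is an exact two-sided binomial test of the
observed peak count against `n_peaks × baseline_fraction`, BH-corrected
across categories. The original analysis tested proportions across
samples by ANOVA with post-hoc tests; with a single peak set per
condition there is no across-sample variance to use, so the exact
binomial against the genome fraction is the defensible substitute. A
zero-baseline category with observed peaks reports an infinite ratio and
is tested against a half-count continuity floor (`0.5/n_peaks`), with a
warning.

## Motifs

PFM probabilities are `(count + 0.25)/(n + 1)` per column (pseudocount
0.25 per base, configurable); `N` in a site sequence contributes 0.25 of
a count to each base. Scores are log2 odds against a uniform background;
`N` in a scanned sequence contributes 0. The hit threshold is a fraction
(default 0.8) of the matrix's maximum attainable score — the sum of
column maxima — which makes thresholds comparable across matrices of
different lengths and information content. Scanning covers both strands;
a minus-strand hit at offset *o* means the reverse complement of the
region substring matches.

The consensus uses a 0.6 major / 0.25 minor threshold: a column yields a
single base at ≥ 0.6 probability, otherwise the IUPAC code over all
bases ≥ 0.25 (N when that is all four). 400 bp regions are centered on
peak midpoints and shifted — never truncated — at chromosome ends, so
region width is always exact.

Background correction of co-occurrence: a motif is kept only if its hit
fraction in the reference (wild-type) group exceeds its fraction in
receptor-null peak regions by a one-sided two-proportion z-test at 0.05;
otherwise it is flagged background and omitted. Motif similarity is
`1 − max Pearson correlation` of aligned probability columns over all
ungapped offsets (minimum overlap 4 columns) and both orientations,
clustered by average linkage and serialized as newick. This is a
column-correlation stand-in for alignment-based motif phylogenies; only
topology-level agreement should be expected from it.

## The simulator

The generator emulates: a multi-chromosome genome with non-overlapping
coding gene models (2–6 kb, 2–5 exons, jittered grid placement);
an unmappable-block mask (1 kb blocks carved away from planted sites)
covering `1 − mappable_fraction` of each chromosome; uniform background
tags over mappable bases at `background_rate` tags/bp with planted 150 bp
sites at `enrichment_factor` times that density in the conditions where
they are active (`veh_only`/`lig_only`/`both`, drawn 0.26/0.61/0.13 to
mirror the relative sizes of published occupancy sets); artifact sites
enriched in *every* ChIP sample including receptor-null ones, so the
null subtraction has real work; library totals drawn multinomially so
configured totals are exact; a log2 expression matrix with
`log2(fold_change)` shifts in the conditions each planted type
prescribes (the ligand never shifts knockout samples, making every
planted ligand response receptor-dependent) and i.i.d. Gaussian
replicate noise; and PPRE instances written into the genome sequence at
80% of planted sites. Planted sites are re-drawn until their midpoint's
nearest TSS is the host gene, so truth and nearest-TSS assignment agree.

It does **not** emulate: read sequences or sequencing error, GC or
fragment-size bias, duplicate reads, copy-number or chromatin-state
structure, probe-level array effects, correlated replicate noise, or
distal (>10 kb) regulation. Passing the planted-recovery tests therefore
demonstrates the pipeline's correctness under its own model assumptions,
not performance on real libraries.

Default scale (demo): 4 × 750 kb chromosomes, 160 genes, 80 planted
sites, 12 artifact sites, background 0.5 tags per mappable bp. The tag
density is far above a real genome-wide ChIP-seq average by design: on a
desk-scale genome it reproduces the background-window counts
(N ≈ 10⁵ per 200 kb) at which a z > 60 threshold separates ~10-fold
enriched sites from background, i.e. the *per-window* regime of the real
analysis rather than its genome-wide average.

## Recovery benchmarks

`benchmarks.site_recall_config` plants 110 all-condition sites at
enrichment factor 10 on 2 × 1.5 Mb chromosomes at background 0.8 tags/bp.
At this operating point the expected site z is ≈ 85 with spread ≈ 3 —
site tag mass inflates N by ~7 sites per background window, which the
calibration accounts for — so recall at z > 60 is limited only by
placement pathologies, not by threshold noise.

`benchmarks.response_recovery_config` plants 100 genes per type plus 200
unregulated genes at fold change 2.0, replicate sd 0.25, 3 replicates.
Composition matters here: with Welch's t at n = 3, the BH(0.25)-implied
p-threshold scales with the fraction of truly regulated genes, so
recovery on a mostly-null genome is threshold-limited no matter how
clean the effects (measured: ~97% recovery at 80–100% planted fraction,
~96% at 50%, ~90% at 33%). The benchmark is therefore defined on a
DE-enriched panel — it measures *assignment accuracy among regulated
genes*, which is the classifier's job, separately from *discovery power
on sparse panels*, which is a property of the n = 3 design itself.

## Reproducibility and problem sizes

All randomness flows from one master seed through
`numpy.random.default_rng`; per-condition tag draws use fixed offsets of
the master seed, and identical configurations produce byte-identical
output files. The bundled benchmark sizes (3 Mb genome / ~3.6 M tags for
site recall; 1 000 genes for response recovery) were chosen as the
smallest scales at which the planted-signal margins above hold with
comfortable seed-to-seed stability.

## Known limitations

- The caller reports merged regions with the best window's statistics;
  it does not re-estimate a region-level z, model peak shape, or
  calibrate FDR across windows.
- Welch's t with 3 replicates is noisy; moderated-variance tests are out
  of scope by design, and users with few replicates should expect the
  composition effects described above.
- The motif tree is a similarity dendrogram, not a phylogeny; branch
  lengths are cophenetic distances from average linkage.
- The feature annotator assumes transcripts fit in memory as per-base
  label arrays (fine up to ~10⁸ bp genomes; a real mammalian genome
  would need an interval-based implementation).
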