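# Methods

This note records the models behind goatcnv, the defaults and why they are
set where they are, what the synthetic data does and does not emulate, and
the choices made where the published workflow left the design open.

## Depth model and CNV ratio

The unit of analysis is the 200-bp sliding window stepped every 100 bp
(`window_size` must be a multiple of `step`; every interior position then
falls in exactly `window_size/step` windows). Reads are assigned to every
window containing their leftmost aligned base; leftmost is the cheapest
deterministic convention, and a midpoint option is provided. Unmapped,
secondary, supplementary and duplicate-flagged reads are excluded
(`min_mapq` defaults to 0: inputs are assumed de-duplicated upstream, so
only flag-based filtering is applied here). Alternatively a per-base depth
TSV can be supplied, in which case the window value is the mean per-base
depth over the window — useful when only a depth table survives from an
earlier pipeline. Trailing bases shorter than one window are dropped.

Coordinates are 0-based half-open internally; the per-base TSV is 1-based,
and BED/bedGraph conventions apply on output.

A sample's **one-fold depth** is the unweighted mean window count over all
windows genome-wide, taken as the depth of the baseline diploid state. The
**CNV ratio** of a window is count / one-fold depth. Per-chromosome means
and SDs (population SD; at genome-scale window counts the sample/population
distinction is far below measurement noise) are kept separately because the
gain rule is judged per chromosome while the loss rule is judged against
the genome-wide average — an asymmetry retained deliberately from the
original workflow. Sequences with fewer than 7 windows (one scanning
frame) are flagged unusable for calling.

## Region calling

Both detectors are k-of-frame scans with k = 5 and frame = 7: a frame of 7
consecutive windows fires when ≥ 5 of its windows qualify. "Five out of
seven **or more** sequential windows" is read as: qualifying frames that
overlap or touch merge into one span (the "or more"), and the called
region is trimmed from the frame bounds to the outermost qualifying
window, so regions are never padded with sub-threshold windows. The
supporting-window count and the mean ratio reported for a region are taken
over its qualifying windows.

* Gain: window count > chromosome mean + 2 × chromosome SD (strict). On a
  degenerate chromosome with SD = 0 the threshold reduces to the mean and
  any window strictly above qualifies.
* Loss: window count < 0.1 × the sample's one-fold depth (strict) **and**
  some other sample's count > 0.5 × its own one-fold depth (strict). The
  cross-sample rescue keeps universally unmappable sequence out of the
  loss set; it also means loss calling is undefined for a single sample
  and is an error. All tracks must share one window grid.
* No cross-sample condition is imposed on gains; only the loss rule has
  one.

`merge_regions` joins same-sample, same-type regions separated by at most
`max_gap` (default: one step). Region counts per 1-Mb non-overlapping bin
use a strict > 800 bp length filter and bin by region start.

## Candidate genes

The gene-level statistic is the **median** CNV ratio of the windows
overlapping the gene span (configurable to mean). Median was chosen
because breakpoint windows carry length-weighted intermediate values that
would bias a mean on short genes. A gene shorter than one window falls
back to its covering window(s) with a warning.

Deletion in the domestic cohort requires (i) overlap with a called CNV
region (the `require_cnv_overlap` switch exists because one could also
read the rule genome-wide; overlap is tested against the union of supplied
regions), (ii) gene ratio < 0.2 in every domestic sample and (iii) ≥ 0.5
in every wild sample. The duplication rule mirrors it with defaults
`dup_high = dup_wild_max = 1.5` — these duplication thresholds are this
package's own formalization of "single copy in one species, multi-copies
in the other", are prominently configurable, and should not be read as
published constants. External presence/absence evidence (e.g. tabulated
protein-search results) only annotates calls unless `require_external` is
set, in which case deletions lacking an "absent" entry are downgraded.

qPCR estimation is the standard ΔΔCt method: ΔCt = mean target Ct − mean
reference-gene Ct per sample, ΔΔCt subtracts the calibrator sample, and
relative copy number = calibrator copies × 2^(−ΔΔCt). The calibrator is
assumed to carry 2 copies (diploid single-copy locus) by default, since
the normalization gene is single-copy per haploid genome.

## Anchoring

Hits (PAF or 8-column TSV; for PAF the alignment block length column is
used as the hit length) are chained per (scaffold, chromosome): successive
hits join while their target-start gap is ≤ 100 kb. "Orphan" filtering is
not defined precisely in the source workflow; here an orphan is a
single-hit chain shorter than `orphan_min` (default 500 bp), configurable.
Chain length for the placement rule is the **sum of member hit lengths**,
not the chain span — robust to sparse chains. The longest chain places the
scaffold only when strictly longer than 2 × the second (a tie at exactly
2.0 × stays ambiguous); chain orientation is the length-weighted majority
strand of its members.

Pseudo-chromosomes concatenate placed scaffolds in position order
(ties broken by name), reverse-complementing minus-strand scaffolds, with
100-N gaps (the gap size between anchored scaffolds is not determined by
the data; AGP type "U" records it honestly as unknown-size). The AGP v2.1
rows describe the emitted FASTA exactly and the package can independently
re-assemble the FASTA from AGP + components, which the tests require to be
byte-identical.

The Y pipeline differs in two ways: hit merging uses end-to-start gaps
with the repeat-aware rule (< 1 kb always; 1–5 kb only when the gap
interval is strictly > 50% repeat-covered; without a repeat track those
merges are declined with a warning), and final ordering follows the contig
order of a related species' Y assembly rather than position on a single
chromosome. Protein evidence is reduced to its filterable artifact — a
coverage table — with a ≥ 60% coverage keep rule (0.59 drops, 0.60 keeps);
running the alignment itself is out of scope.

## Synthetic data

The generator produces what the pipeline consumes, with truth recorded:

* **Depth** is simulated directly at window level: counts are drawn
  independently per window from Poisson (default) or negative binomial
  (overdispersion `r`, variance μ + μ²/r) with mean λ × copy/baseline.
  λ defaults to 30 reads per 200-bp window, matching the ~6–8× short-read
  coverage of the resequenced cohort. Windows partially overlapping an
  event get a length-weighted mean copy number, which makes truth
  well-defined at breakpoints. Read-level simulation (FASTQ, sequencing
  error, GC bias) is deliberately out of scope; consequently the
  correlation between overlapping windows that shared reads would induce
  is absent, as are mappability artifacts — passing tests demonstrate the
  rules and their calibration, not robustness to alignment pathology.
  A per-base depth emission path exists to exercise the TSV reader; it
  requires a non-overlapping tiling (step = window), since overlapping
  windows do not define a unique per-base depth.
* **Fragmented assemblies** partition the reference into contiguous
  scaffolds (random orientation), emit one collinear true hit chain per
  scaffold (inter-hit gaps capped well below the clustering window) plus
  Binomial(n_true, rate) short decoy hits at uniform random loci, and
  record the truth placement table.
* **qPCR** tables follow Ct = base − log_eff(copies) + N(0, σ), with
  efficiency in (1, 2] and a perfect assay at 2.

All generators take a seed and are byte-identical under identical
configuration; per-sample streams are derived from (seed, stream, index)
tuples so adding a sample never perturbs the others.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale problem sizes chosen to make
the Monte-Carlo error of each measured quantity small against its
acceptance band: 50,000-window genomes with 30 + 30 engineered 1.5-kb
events for detector recovery; 50 replicates of a 10,000-window, 20-gene,
six-sample cohort for end-to-end candidate recovery; and 10 replicates of
a 10,000-window genome with four 1.5-kb 4-copy events for ratio
calibration. In the calibration runs events cover ~1.4% of the genome —
realistic for a CNV landscape — so the one-fold depth, which includes
event windows, biases the expected interior ratio only to 2/(1 + f) ≈
1.99.

Degenerate inputs are handled explicitly: empty alignments give an
all-zero track with a warning; a zero one-fold depth makes ratios
undefined and is an error; sequences shorter than one frame are skipped in
calling; malformed hit rows are skipped with a warning; duplicate
placements and overlapping truth events are errors.

## Known limitations

* Window counts are simulated independently; real overlapping windows are
  positively correlated, so real-data false-positive rates will differ
  from the simulated ones.
* The duplication candidate thresholds and the orphan-hit definition are
  package choices, not published constants (both configurable).
* No GC correction, mappability masking or duplicate marking; inputs are
  assumed clean.
* Copy-number genotyping beyond the ratio (e.g. integer CN calls via
  segmentation or HMM) is out of scope.
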