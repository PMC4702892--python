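# Methods

`brehot` detects recurrently rearranged genomic regions ("breakpoint
hotspots") from per-sample somatic structural-alteration breakpoint
profiles, with the filtering that produces such profiles from raw
structural-variant calls, overlap comparison between profiles, and a seeded
simulator that provides ground truth for all of it.

## Coordinates and data model

All coordinates are 0-based, half-open (BED semantics), in files and in
memory alike. The atomic datum is the breakpoint: a single-nucleotide
position where a structural alteration (deletion, insertion, inversion,
tandem duplication, intra-/inter-chromosomal translocation, or a complex
combination) joins or severs DNA. An alteration record carries one or two
breakpoints plus read support: the number of discordant read pairs and of
soft-clipped reads at the junction. For intra-chromosomal events with both
breakpoints, the event size is |pos2 − pos1|; inter-chromosomal
translocations have no size. When expanding real alteration records into a
profile, every defined breakpoint becomes one profile entry (two for an
intra-chromosomal event, one per chromosome side for a translocation); the
simulator instead treats the breakpoint itself as the simulation unit — one
profile entry per simulated event, with a synthetic mate kept on the record
only so the size filter has something to act on.

The profile file dialect is BED-based: `chrom start end event_type
discordant_pairs softclip_reads mate`, one alteration per line, mate as
`chrom:pos` or `.`. Missing support columns parse as zero, which means
support-unannotated inputs are visibly rejected by the default support
filter rather than slipping through. Sample identity defaults to the file
name stem (one file per sample).

## Filtering

The cascade runs support → size → germline → blacklist:

* **Support**: keep records with ≥ `min_discordant` (default 2) discordant
  pairs AND ≥ `min_softclip` (default 2) soft-clipped reads.
* **Size**: drop intra-chromosomal events strictly larger than `max_size`
  (default 10 Mb; an event of exactly 10 Mb survives). Undefined sizes are
  never size-filtered.
* **Germline subtraction**: a cancer record is removed when some pooled-
  normal record has the same event type, the same breakpoint arity, and
  every corresponding breakpoint on the same chromosome within
  `germline_tolerance` bases (default 100 bp). Position-based matching with
  a tolerance is the natural criterion for breakpoint-resolution data; the
  tolerance absorbs alignment jitter. Normals are pooled: the union of all
  provided normal records is subtracted from every cancer sample.
* **Blacklist**: a record is removed when any of its breakpoints falls
  inside a population-variant interval (half-open containment). Containment
  of the breakpoint — not reciprocal overlap of the whole event — is used
  because the breakpoint is the unit of record throughout the package.

Filters only select records, never mutate them, so each stage is idempotent
and raising any threshold can only shrink the survivor set.

## Hotspot detection

1. **Extension**: every breakpoint of every sample becomes the region
   `[pos − flank, pos + flank + 1)` clipped to its chromosome; the default
   flank of 10 kb gives ~20 kb regions.
2. **Boundary segmentation**: per chromosome, the sorted distinct starts
   and ends of all samples' extended regions are the bin boundaries;
   consecutive boundaries form half-open bins of unequal sizes. Within any
   such bin the set of covering samples is constant, so the bin is the
   natural testing unit. Bins covered by no region are dropped.
3. **Scoring**: a bin's enrichment score is the number of DISTINCT samples
   with at least one overlapping extended region (a sample with two regions
   in one bin still counts once).
4. **Permutation null**: bins with score ≥ `min_samples_tested` (default 2
   — recurrence needs more than one genome) are tested. For each of
   `n_perm` permutations (default 10,000; experiments here scale it down),
   every breakpoint of every sample is relocated independently and
   uniformly over the genome — chromosome chosen with probability
   proportional to its length, position uniform on it — preserving
   per-sample counts and event-type labels; positions are re-extended and
   the FIXED observed bins re-scored. The per-bin upper-tail p-value is
   `(1 + #{permutations with permuted score ≥ observed}) / (n_perm + 1)`:
   ties count toward the tail and the +1 pseudocount keeps p off zero.
   Fixed bins (rather than re-segmenting each permutation) make per-bin
   p-values well defined and are the conventional choice. A
   `within_chromosome` placement (preserve chromosome, redraw position) and
   a `pooled_null` variant (compare each observed score against the pooled
   permuted-score distribution over all tested bins) are available.
5. **Correction and selection**: tested bins' p-values are adjusted by
   Benjamini–Hochberg step-up FDR over the tested family (plain Bonferroni
   optional); bins with adjusted p < `alpha` (default 0.05) are hotspots,
   and book-ended significant bins are merged into single reported regions
   by default (a merged region reports the maximum member score and the
   minimum member p/q).

Randomness is governed by one master seed: a `SeedSequence` spawns one
deterministic substream per permutation, so results are bit-reproducible
and independent of any execution-order or parallelization concerns.

## Profile comparison

`overlap_with_intervals` counts query breakpoints inside at least one
interval; `overlap_with_profile` counts query breakpoints with some
same-chromosome target breakpoint within ±`window` bases. Both count each
query breakpoint at most once, so counts are bounded by the query size and
monotone in the window. The default window equals the hotspot flank
(10 kb), consistent with rendering each breakpoint as a ~20 kb bar. The
count is intentionally directional (query vs target), matching "number of
overlapping query breakpoints"; it is not a symmetric similarity.

## Simulator

The simulator emulates the features the analysis consumes: per-sample
breakpoint burden (default 20 samples × 50 background breakpoints on a
3-chromosome 50+30+20 Mb toy genome — large enough for permutation
experiments, small enough for seconds-scale runs), uniform background
placement proportional to chromosome length, planted hotspot loci
(`chrom, center, half_width, penetrance`: each sample independently carries
one breakpoint uniform in the window with probability penetrance), an
event-type mixture (deletion-dominated by default), event sizes from
`size_range` (default 1 kb–1 Mb) and support counts from `support_range`
(default 2–10). `simulate_germline_pair` duplicates a stated fraction of
each sample's records into a pooled normal set with ≤`jitter` bp positional
noise (default 50 bp, i.e. half the default germline tolerance) and labels
every record somatic/germline.

What it does not emulate: real SV size spectra, clustered backgrounds
(fragile sites, replication timing, mappability), event-type–dependent
spatial structure, or read-level evidence. Tests that pass on these
simulations therefore demonstrate the machinery's correctness and
calibration under a uniform null — not that uniform relocation is an
adequate null for real cancer genomes, where covariate-aware nulls are
known to matter.

## Numerical and degenerate-input choices

* Empirical p-values lie in `[1/(n_perm+1), 1]` by construction; permuted
  scores tied with the observed score count as exceedances (conservative).
* BH adjustment is delegated to `statsmodels` (`fdr_bh`) and cross-checked
  in the tests against an independent hand-written step-up; inputs outside
  (0, 1] are rejected.
* Extension and display windows clip at chromosome bounds; a flank of 0
  degenerates to the breakpoint base itself.
* Empty profile files parse to empty record lists; an empty chrom-sizes
  file is an error (an empty coordinate universe is unusable).
* Bins with zero coverage never appear; untested bins carry NaN p/q and are
  excluded from the correction family (`m` = number of tested bins).
* Hotspot calling refuses a single profile: recurrence across samples is
  part of the definition.

## Known limitations

* **Per-bin permutation p-values on data-derived bins are
  anti-conservative.** The tested bins exist exactly where ≥2 samples'
  extended regions happen to overlap, so under a uniform null the selected
  bins' p-values concentrate near the `1/(n_perm+1)` floor rather than
  being uniform — e.g. triple-overlap bins arise by chance about ten times
  per 20×50-breakpoint cohort on the 100 Mb toy genome, each with a per-bin
  null tail of ~2×10⁻³ — and the BH step-up admits such a batch whenever
  enough co-occur. In uniform-background experiments (n_perm = 500,
  alpha = 0.05) roughly a third of replicate cohorts report at least one
  hotspot. This selection effect is inherent to testing fixed, data-derived
  bins against per-bin permutation nulls; re-segmenting per permutation or
  testing the genome-wide count/maximum of scores would remove it but is a
  different statistic and out of scope here. Hotspot lists from this
  procedure should be read as enrichment rankings, with the planted-signal
  experiments showing that strong recurrent loci dominate them.
* Only the breakpoint-containment blacklist mode is implemented;
  reciprocal-overlap filtering is reserved as a future mode.
* The null ignores genomic covariates (mappability, replication timing)
  and per-event-type structure by design.
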