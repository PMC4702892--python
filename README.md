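# brehot

Detection of **somatic breakpoint hotspots** — genomic regions recurrently
hit by structural alterations across cancer genomes — from per-sample
breakpoint profiles, together with the filtering that produces those
profiles and tools to compare them.

Whole-genome sequencing of a tumour/normal pair yields structural
alterations (deletions, insertions, inversions, tandem duplications,
translocations, complex events), each anchored at one or two single-base
**breakpoints**. Given many samples' somatic breakpoint profiles, the
question is where in the genome breakpoints recur more often than chance.
`brehot` answers it with a permutation test on boundary-segmented bins:

1. extend every breakpoint by a flank *f* (default 10 kb) to the region
   [pos − f, pos + f + 1);
2. segment each chromosome into non-overlapping, unequal bins at the sorted
   boundaries of all samples' regions;
3. score each bin by the number of distinct samples whose regions overlap
   it;
4. relocate all breakpoints uniformly over the genome *N* times (default
   10,000; chromosome ∝ length), re-score the fixed bins, and assign each
   tested bin (score ≥ 2) the empirical upper-tail p-value
   (1 + #{perm ≥ obs}) / (N + 1);
5. apply Benjamini–Hochberg step-up FDR over tested bins; bins with
   q < α (default 0.05) are hotspots, book-ended ones merged.

The package also implements the upstream somatic filters (read support
≥ 2 discordant pairs and ≥ 2 soft-clips, event size ≤ 10 Mb, pooled-normal
germline subtraction within a 100 bp tolerance, population-variant
blacklist), overlap comparison of a query profile against hotspot sets and
other profiles, cohort summary tables, and a seeded simulator with ground
truth. See `docs/methods.md` for the full model and its limitations.

## Worked example

```bash
python examples/simulate_and_call_hotspots.py
```

```
simulated 20 profiles, 1018 breakpoints; 18 samples hit the planted locus
1216 scored bins, 227 tested (score >= 2), 19 hotspots at BH alpha 0.05

top hotspots (chrom, start, end, score = distinct samples, q):
  chr1:24985964-25013890  score=18  q=0.01192
  chr1:6307958-6312536  score=3  q=0.01192
  chr1:5738653-5739589  score=3  q=0.01192
```

Twenty simulated samples carry 50 uniform background breakpoints each on a
100 Mb toy genome, and 18 of them carry one extra breakpoint in a planted
10 kb window at chr1:25 Mb. The top hotspot is that window: 18 of 20
distinct samples overlap it, far beyond what uniform relocation produces
(q ≈ 0.01). The score-3 bins behind it illustrate the tail of the
procedure: weakly recurrent background bins can reach significance because
tested bins are placed exactly where samples happen to overlap —
`docs/methods.md` discusses this selection effect and why hotspot lists are
best read as enrichment rankings dominated by strong loci.

The same run from the shell:

```bash
brehot simulate --out-dir sim --n-samples 20 --background 50 \
    --locus chr1:25000000:5000:0.9 --seed 7
brehot hotspots --profiles sim --genome sim/genome.sizes \
    --out-dir out --n-perm 500 --seed 11
```

writes `out/hotspots.bed`, the full scored segmentation `out/bins.tsv`, and
a JSON manifest with the resolved parameters, seed and input digests; the
same seed and inputs reproduce the outputs byte-identically.

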