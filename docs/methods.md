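# Methods

Conventions, algorithms and parameter rationale. Everything here is
deterministic given seeds; all derived seeds are kept below 2^31.

## Read anatomy and orientation

The chemistry initiates reverse transcription at the RNA 3′ end by
template switching, so a cDNA read is, in sequencing order:

```
[adapter stub signal][31-nt DNA adapter][tail, poly(T) in cDNA sense][insert]
```

Orientation rules used throughout:

- The cDNA read runs 3′→5′ relative to the RNA. RNA-sense tails are the
  reverse complement of the cDNA tail with T→U; terminal additions (the
  3′-most RNA bases) therefore *lead* the cDNA tail and *end* the RNA
  tail string.
- A read from a forward-strand transcript aligns on the reverse genomic
  strand. The RNA 3′-end coordinate of an alignment is its half-open
  `ref_end` for reverse-strand alignments and `ref_start` for
  forward-strand alignments; the gene strand is the opposite of the
  alignment strand.
- Coordinates are 0-based half-open internally; SAM (1-based) and GTF
  (1-based closed) are converted at the I/O boundary; BED is native.

## Simulator (`tailcap.simulate`)

- **Standards.** The twelve printed synthetic cDNA standards are embedded
  verbatim: a length series with designed tails of 0/15/30/60/90/120 nt
  and a composition series (terminal U×1/3/5, C×5, G×5 and an
  internally-interrupted tail), all sharing the 31-nt adapter and a common
  insert frame.
- **Pore model.** An additive k-mer model (default k = 5): each k-mer's
  mean current is a position-weighted combination of per-base levels
  (A 118, C 86, G 72, T 100 pA) plus seeded jitter. Adapter k-mers are
  nudged so that both homopolymer tails are at least 2 sd away from every
  adapter k-mer, guaranteeing the boundary is detectable in principle.
- **Squiggle.** A fixed 200-sample stub at 40 pA models the sequencing
  adapter, then one segment per base: level from the k-mer context, dwell
  from a shifted geometric distribution (minimum 3 samples, mean
  `dwell_mean`), Gaussian noise `noise_sd`. Ground truth records the tail
  sample span and true tail length.
- **Alignments.** Reads are simulated per transcript with an integer 3′
  offset drawn uniformly from ±20 nt, optional adapter remnant, a
  tail drawn from user-specified class specs, and uniform substitution
  errors; the adapter+tail is soft-clipped. Truth tables carry the clean
  RNA tail, class label and offset.

## Tail length from signal (`tailcap.tail_length`)

1. **Normalization:** z = (x − median) / (1.4826·MAD), sd fallback when
   the MAD collapses.
2. **Segmentation:** after the stub-to-sequence change-point, skip 75 % of
   the adapter (rate-aware), then mark rolling-variance windows (width 25)
   below an adaptive threshold as homopolymer-like. The threshold is
   max(0.003, 6·σ̂²/5) where σ̂² is the read's high-frequency noise floor
   estimated from the median squared first difference — necessary because
   the robust scale shrinks when the tail dominates the read. Runs at the
   same level (tolerance 0.25 z) separated by ≤ 80 samples (at the nominal
   10 samples/nt; all duration thresholds are rescaled by the read's own
   rate) are merged, which bridges the ~k·dwell disturbance a single-base
   tail interruption causes. Candidates must start within 18 nt of the
   estimated adapter end, span ≥ 90 samples with a ≥ 50-sample contiguous
   core, and sit in the poly(T) level band (−2, 0.6) z; the longest
   anchored candidate wins. Absence of a candidate is a zero-tail call,
   not an error.
3. **Duration ratio:** the translocation rate is the self-consistent
   solution of rate = non-tail samples / non-tail bases, which reduces to
   (total samples − stub) / base-called length. Tail nt = segment
   duration / rate + 2 nt of k-mer context padding (the k−1 transition
   k-mers at each edge do not read as pure homopolymer). Rates outside
   3–50 samples/nt mark the read unreliable.

Defaults were calibrated by parameter recovery on the simulated printed
standards: medians 0/16.8/29.9/60.2/89.4/120.2 nt across the length
series at dwell 10, ≥ 97 % zero-tail specificity, and the interrupted-tail
standard recovered as a single ~29-nt segment.

## Tail composition (`tailcap.tail_composition`)

- **Adapter trimming:** the adapter is edit-distance aligned (infix mode)
  in a window at the clip's outer end; identity = 100·(len −
  dist)/len must reach the 50 % threshold (inclusive) to trim.
- **A-content filter:** tails with A-fraction strictly greater than 80 %
  are kept; the strict inequality drops reads whose adapter was never
  trimmed.
- **Classification (last 30 nt):** pure A → All-A; non-A 3′-terminal base
  X → Term-X (terminal additions take precedence over internal ones);
  otherwise Int-X for the most frequent non-A base, ties broken by
  proximity to the 3′ end.
- **Profiles (last 20 nt):** tails are right-justified at the 3′ terminus;
  shorter tails contribute only to the positions they cover.

## 3′-end filtering and assignment (`tailcap.transcript_assign`)

- A read is complete iff its 3′ end is within ±10 nt (inclusive) of any
  exon end of a gene on the matching strand; binary search over the
  per-(contig, strand) sorted exon-end index.
- Isoform assignment takes the candidate minimizing |read 3′ end −
  annotated 3′ end|; assigned iff the minimum ≤ 10; equal-distance ties
  (including across genes) are ambiguous, never double-counted. Distances
  are signed in transcript orientation (positive = past the annotated
  end).
- RPM = gene count × 10⁶ / assigned reads; sums to 10⁶ exactly.

## Tail statistics (`tailcap.tail_stats`)

- Summaries keep units with strictly more than 10 reads (a unit with
  exactly 10 is excluded).
- Divergence: per-unit Kruskal–Wallis with tie correction; totals ≤ 20
  use an exact (or 200 k-sample Monte-Carlo) permutation p instead of the
  χ² asymptotics; all-identical values give H = 0, p = 1. BH adjustment
  runs across all tested units. Both significance policies — BH q < α and
  raw p < α — are computed and reported; the `policy` flag picks which one
  sets the significant flag, because both conventions are in common use
  for this kind of scan.

## Modification profiling (`tailcap.mod_profile`)

- Pileups count matches, per-base mismatches and drop-offs per reference
  position; soft clips are excluded; zero-coverage positions report a
  missing frequency, never 0. Deletions count as mismatches by default
  (reverse-transcription drop events manifest as deletions); insertions
  are ignored.
- The drop-off of a read is attributed to the position where reverse
  transcription stopped: `ref_start` for reverse-strand alignments,
  `ref_end − 1` for forward-strand ones. Drop-offs sum to the number of
  reads.
- Profile contrast: per-site Δ of mismatch frequencies between two
  populations; positions where both populations are below the 0.1 mask
  threshold (a frequency of exactly 0.1 is retained) are masked; outliers
  are ranked by |Δ|.

## I/O and CLI (`tailcap.io`, `tailcap.cli`, `tailcap.config`)

SAM/BAM via pysam (reverse-strand records converted to cDNA orientation
on read, losslessly round-tripped), FASTA/FASTQ via Biopython with
record-naming errors, minimal GTF reader/writer (out-of-order exons
sorted with a logged warning, malformed lines anchored by line number),
BED 3′-end export, TSV with `#` metadata headers carrying the config
hash, HDF5 signal container via h5py. `RunConfig` validates every
threshold, round-trips through YAML, and hashes for provenance. The CLI
exposes `simulate`, `taillen`, `tailcomp`, `assign`, `stats`,
`modprofile` and `all`; per-read diagnostics go to rejects files.
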