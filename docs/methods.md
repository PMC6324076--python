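# Methods

## Coordinate conventions

All public coordinates are 1-based, inclusive, in transcript space.
`cds_start` is the first nucleotide of the start codon and `cds_stop` the
first nucleotide of the stop codon. The frame of a position `p` is
`(p − 1) mod 3`; the phase of an A-site relative to a CDS is
`(A-site − cds_start) mod 3`. Internal numpy arrays are 0-based but never
cross the API boundary.

## Reference construction

Transcript sequences come from the transcriptome FASTA; CDS coordinates come
from projecting genomic GTF CDS features through the transcript's exon chain
(forward strand: cumulative exon offsets; reverse strand: the walk runs from
high to low genomic coordinates). GTF dialects disagree on whether CDS
features include the stop codon. We handle both: if `stop_codon` features
are present they are unioned with the CDS (Gencode style); otherwise, if the
last three CDS nucleotides form a stop codon in the sequence, the CDS is
taken to include the stop; failing both, the stop codon is assumed to follow
the CDS interval. A CDS span that is not a whole number of codons demotes
the transcript to non-coding with a warning rather than failing the build,
since public annotations contain such records. Gene resolution returns all
of a gene's transcripts and leaves the choice to the caller; there is no
privileged isoform.

## Quantification

A retained alignment must be mapped, forward-strand (antisense alignments
are not footprints of that mRNA), at least `min_length` nucleotides
(default 25 — shorter fragments are not credible ribosome footprints), on a
known transcript, and fully within it. Read length is the aligned query
length, excluding soft-clips: transcriptome alignments of footprints are
unspliced and effectively unclipped, so this equals the footprint length.
The 3′ end is `5′ + length − 1`. A read is *ambiguous* iff the aligner
reported it at more than one location (secondary flags or repeated query
names); each reported location is counted once under the ambiguous flag, and
all analyses default to unambiguous counts with a switch to include both.
No fractional multimapper weighting is attempted — the binary flag keeps the
store exact and lets the analyst decide.

`total_retained_reads` counts retained alignments, so the sum of 5′ records,
the sum of 3′ records, and the total agree by construction; this
conservation is asserted in tests after quantification and after every
merge. Merging requires matching assembly tags and is a record-wise sum.

The on-disk store is a single-file SQLite database: a `counts` table
`(transcript_id, read_length, end, ambiguity, position, count)` and a `meta`
key-value table carrying a format version, so any language with SQLite
bindings can read it. A version mismatch is a hard error rather than a
silent misread.

## Offset inference

The metagene aggregates end counts over all coding transcripts with at least
`window` nt (default 100) on both sides of the anchor, so every contributing
transcript spans the full window and the profile is not length-biased.
Search ranges are `[−window, −1]` for the 5′ peak and `[+1, +window]` for the
3′ peak; ties break toward the smallest absolute distance, which favours the
canonical short-distance geometry and makes the argmax deterministic. The 5′
offset is the peak distance plus 3 and the 3′ offset the peak distance minus
3, per read length: the initiation pile-up marks the P-site, and the A-site
is one codon downstream. Offsets are inferred from unambiguous counts only.
Read lengths with an empty search range, or whose inferred offset falls
outside `(0, L]`, receive a fallback offset (default 15 nt, the canonical
footprint geometry) and a warning, and are marked `fallback` in the output
table.

Downstream analyses use A-site densities by default; a `site="p"` switch
shifts positions 3 nt upstream for P-site work, since either site is a
defensible anchor for initiation-focused analyses.

## Periodicity QC

Phase is computed on offset-adjusted A-sites rather than raw 5′ ends, so the
QC measures the same quantity that gives the frame-coloured profiles their
meaning; a raw-end mode is available for comparison. The CDS interval used
is `[cds_start, cds_stop − 1]` — the stop codon is excluded because
terminating ribosomes are not elongating. The in-frame fraction is the
maximum phase count over the total per read length.

## Profiles

Frame assignment is purely positional; "dominant frame" calls over an
interval are the argmax of per-frame totals. The CSV export contains one row
per transcript position with the nucleotide and the three frame counts, so
the profile can be reconstructed exactly. Comparison profiles scale each
group to reads-per-million of its retained-read total when normalization is
on; RNA-Seq groups use full-read coverage (each read covers
`[5′, 5′+L−1]`) because A-site offsets are a ribosome concept. Read-length
filtering happens before summation across lengths.

## Differential expression

Counts are per-million-normalized per condition by default, transcripts with
a raw count below `min_count` (default 1) in either condition are dropped —
zeros give infinite log ratios and would corrupt bin statistics — and an
optional pseudocount is available instead. Transcripts are sorted by
descending geometric mean with ties broken by transcript id (deterministic
binning), partitioned into consecutive bins of 300, and a final partial bin
of fewer than 30 transcripts is merged into its predecessor so no bin has
unusably small sample statistics. Within-bin standardization uses the
unbiased (n−1) standard deviation; a zero-variance bin yields z = 0 with a
warning. Log ratios are base 2. The procedure applies unchanged to Ribo-Seq
or RNA-Seq stores; translation-efficiency ratios are out of scope.

Binning is non-overlapping by rank. A sliding-window variant would smooth
bin-boundary artefacts at the cost of determinism and independence of bins;
the fixed partition is what the z-score screen defines.

## Simulator

The generator emulates the regimes the analyses target, not sequence realism
(no composition, ligation or nuclease biases beyond the length
distribution):

- Transcripts: uniform 80–200 codon CDS (`ATG` + non-stop codons + stop),
  flanked by 120 nt UTRs — long enough for the default metagene window and
  any read overhang. Layouts rotate through single-exon forward, two-exon
  forward and single-exon reverse so CDS projection is always exercised.
- Footprints: per-transcript expected counts are a mean-one lognormal
  (σ = 0.75) expression level times `n_reads / n_transcripts`, realised as
  Poisson. Read lengths 25–35 follow a unimodal distribution peaked at
  30 nt. The A-site codon is uniform over the CDS except that a 10% share of
  reads is initiation-paused (A-site on codon 2), which creates the metagene
  peak that real offset calibration relies on. Phase error `1 − p` (default
  p = 0.9, a strongly periodic dataset) is split evenly between the two
  off-frames. The 5′ end is the A-site minus the configured per-length
  distance (default 15 nt).
- Nested ORFs are inserted in frame +1 inside the CDS by overwriting an
  `ATG` and a `TAA`; with this shift the overlapped main-frame codons cannot
  become stops, so the main ORF is preserved. A configurable fraction of the
  transcript's reads translates the nested interval.
- The RNG is partitioned per transcript (`default_rng([seed, stream, i])`),
  so growing `n_transcripts` never reshuffles earlier transcripts, and
  expression levels are drawn from a condition-independent stream so that
  between-condition differences come only from fold changes and Poisson
  noise.
- `simulate_differential_counts` is a counts-level shortcut for the
  z-score screen: shared lognormal means (log-mean 4, σ = 1 — a realistic
  dynamic range around ~55 counts), Poisson per condition, optional fold
  changes.

What passing tests on this generator shows: the pipeline's arithmetic,
calibration rule, phase bookkeeping and screen calibration are correct under
exact footprint geometry. What it does not show: robustness to real-data
pathologies — heterogeneous offset geometry within a read length, rRNA
contamination, periodicity decay along the CDS, or overdispersed biological
replicates.

## Problem sizes in tests

The bundled test and acceptance runs use 2–10 transcripts and 4k–50k reads
per simulated library, and 3,000 transcripts for the differential screens —
sizes at which every statistical check (binomial calibration of periodicity,
normal-tail false-positive rate, spike recovery) has the power it needs
while the whole suite runs in seconds.

## Known limitations

- One offset per (read length, end); no per-transcript or fuzzy offsets.
- No dwell-time or pausing model; the P→A shift is the fixed 3 nt.
- The differential screen has no replicate-aware variance model; it is a
  ranking/screening tool and its z-scores are not p-values.
- Multimappers are never weighted fractionally.
- Genome-space analyses (intron retention, novel splicing) are outside the
  transcriptome-aligned design.
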