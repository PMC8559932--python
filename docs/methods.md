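# Methods

This note records the models, conventions and numerical choices behind each
stage, what the synthetic data does and does not emulate, and the design
decisions taken where more than one reasonable convention exists.

## Coordinates and splice sites

All internal coordinates are 0-based half-open; GTF I/O converts to and
from the 1-based closed convention only at the file boundary. A splice
site's *boundary* is the position of the first intronic base (donor) or the
last intronic base (acceptor) on the genomic axis; on the minus strand the
donor of an intron therefore sits at the intron's genomic right edge. Site
identity — and deduplication across transcripts and genes — is the tuple
(chrom, strand, boundary, kind). Non-canonical dinucleotides (anything but
GT/AG) are retained and only flagged: branch-site analyses themselves
report non-A branch nucleotides, so filtering sites by consensus would be
inconsistent. Duplicate transcripts (identical exon chains) are collapsed
with a warning. Sequence windows are always returned on the transcribed
strand and never silently truncated — a window that would cross a
chromosome end raises an error.

## Event extraction and PSI

Events are found by pairwise comparison of a gene's isoforms through their
intron sets: a cassette exon is an exon whose two flanking introns in one
isoform fuse into one intron of the other; a retained intron is an intron
spanned by a single exon of the partner isoform; alternative donors or
acceptors are intron pairs sharing one edge whose variable-edge exons share
their distal boundary (this guard prevents skipped-exon patterns from
masquerading as alternative edges); mutually exclusive exons are two
non-overlapping middle exons sharing both flanks. Events are deduplicated
by (type, chrom, strand, defining coordinates).

PSI is junction-count based without effective-length normalisation:
PSI = I/(I+S), where I and S are sums over the event's inclusion and
skipping junction sets. Retained-intron inclusion evidence is a single
exon–intron boundary-spanning support count (keyed with `^` instead of `-`
in count tables); MXE inclusion is the junction pair of the exclusive exon
that is upstream in transcription order. For multi-junction sets the sum
convention assumes each read supports exactly one junction — the generator
splits an event's inclusion count multinomially across its inclusion
junctions, so the sums are unbiased estimators of the event counts.

The differential screen pools counts within each condition and applies a
two-sided Fisher exact test to the 2×2 table (I_ctrl, S_ctrl; I_mut,
S_mut), then Benjamini–Hochberg correction across all testable events.
This is a deliberate simplification relative to rMATS's hierarchical
likelihood model: the screen's contract is its thresholds
(|ΔPSI| > 0.05, FDR < 0.05, supporting reads ≥ 5), not its likelihood, and
pooled exact tests are exactly calibrated under the null (conservative if
anything), which the null-simulation tests confirm. `supporting_reads` is
the minimum of I+S over individual samples (the strictest of the plausible
readings; per-condition or total interpretations would be laxer).
Events with zero pooled counts in either condition are reported untestable
rather than smoothed.

Distance analysis covers the three types with a single defining distance:
retained-intron length, donor–donor spacing (A5SS), acceptor–acceptor
spacing (A3SS); SE and MXE have no such scalar and are excluded.
Histograms default to 30-nt bins starting at 20 nt, so the biologically
salient 50–80 nt short-intron band is one bin.

## Splice-site usage (USS)

The usage statistic is computed from paired windows of (default) 40 nt
flanking each boundary: for a donor, the last 40 nt of the upstream exon
(count *a*) and the first 40 nt of the intron (count *b*); mirrored for
acceptors. The default formula is the exonic coverage share
USS = a/(a+b), chosen for boundedness ([0, 1]), monotonicity (strictly
decreasing in *b* for fixed *a*) and its clean boundary behaviour
(b = 0 ⇒ USS = 1, a = b ⇒ USS = 0.5). The formula is a named, pluggable
strategy (`exonic_share`, alternative `1 − b/a` clipped to [0, 1]) and is
the module's largest documented assumption — the original Unused-Index
variant it generalises is published separately and not restated here.
Coverage is a read count aggregated over the window; per-base coverage
tracks should be collapsed to window totals before input.

When a flanking exon or intron is shorter than the window (common for the
many sub-40-nt fly introns), the window truncates to the element and the
record is flagged `short_window` but still tested. The flanking exon
length is the maximum over transcripts containing the site, the intron
length the minimum, so a window never crosses the nearest annotated
opposite boundary. The screen mirrors the PSI screen (pooled Fisher + BH)
and reports two flags — FDR < 0.05 (the default) and raw p < 0.05 —
because both appear in practice as screening conventions; both use
|ΔUSS| > 0.01. No pseudocounts: undefined records (a+b = 0) are excluded
rather than smoothed, keeping the estimator unbiased.

Enrichment cross-tabulates, per event type and site kind, usage-changed
sites against sites participating in significant differentially spliced
events of that type (universe = all screened sites), with the sample odds
ratio, an exact p, and BH across the strata.

## Splice-site strength

The native scorer is a per-position log2-odds PWM over {A, C, G, T}
relative to a background composition, on the MaxEntScan window
conventions: 9-nt donors (3 exonic + 6 intronic) and 23-nt acceptors
(20 intronic + 3 exonic). Training uses a pseudocount (default 0.5,
enforced > 0 so weights stay finite); the background defaults to the
training set's overall composition, so a uniform training set against a
uniform background scores everything 0. N bases are excluded from counts
at training and contribute 0 with a flag at scoring. The published
maximum-entropy models are deliberately not re-derived — their training
tables are external — but per-sequence score tables computed by any
external scorer can be loaded in place of the native one. Group summaries
report mean/median/SE and two-sided Mann–Whitney rank tests (BH-corrected);
the rank test is this package's documented choice for comparing score
distributions, not a field-mandated one.

## Branch-point calling

A sense-orientation lariat cDNA read decomposes as
`read[0:k] = intron segment ending at the BP` followed by
`read[k:] = intron prefix from base 1`; the post-jump anchor must start
exactly at intron base 1 because the 2′,5′ bond joins the BP to the
intron's first base — no slack. The caller scores every (orientation,
split k, BP position p) candidate by total matches, equivalently minimal
mismatches. At the BP itself: a reference A read as T is free (the
reverse-transcriptase signature); any other mismatch at the junction base
invalidates the candidate, so calls at non-A branch nucleotides (U/G/C
branch points are real) require an exact junction match and remain
reachable. Validity requires both anchors ≥ `min_anchor` (default 8 nt)
and at most `max_mismatch` (default 1) mismatches outside the BP —
Sanger-quality defaults, both configurable.

Ties between co-optimal candidates are broken toward the longer exact
prefix match of the post-jump anchor against the intron 5′ terminus (the
most informative side, since it is anchored); candidates at distinct BP
positions that survive make the read *ambiguous*, reported with the
3′-most candidate first and all co-optima listed — explicit reporting
rather than a silent choice, since a clone supporting two junction
placements is a real outcome of branch-base repeats. Offsets are
3′-anchored (−1 = last intron base) and labels display T as U
(`-54U` style). Frequencies are computed over called reads (clones),
without quality weighting; ambiguous and unalignable reads are tallied
separately, never silently dropped.

An exhaustive brute-force search over every orientation, split and BP
position — implemented independently in the test suite — agrees with the
production caller on 100% of 1,000 random intron/read pairs.

## Synthetic data: what it emulates, and what it does not

The generator builds toy genomes in which each gene carries exactly one
designed event of a known type, on either strand, with canonical GT/AG
intron ends. Defaults mirror the study design the statistics serve: two
conditions (control and a spliceosome-mutant-like condition); a PSI shift
of magnitude 0.2 with random sign planted in half the events; retained
introns shifted upward drawn from the 50–80 nt band (short introns are
where retention concentrates) and all other introns from 100–300 nt;
acceptor spacings of 6–30 nt and donor spacings of 10–60 nt; usage truth
shifted by 0.2 at the sites of changed events (or, for enrichment
experiments, only at RI donors). Junction totals are Poisson (default 200
reads/event) with binomial inclusion; window totals Poisson (default 600)
split binomially by the inverted usage formula; three replicates per
condition. Replicates are independent and identically distributed.

Lariat reads are built literally from the lariat geometry:
`intron[bp−L1+1..bp] ++ intron[1..L2]`, anchor lengths uniform in 10–16 nt
per side (Sanger traces are trimmed to the informative junction-proximal
segment; short anchors also keep the expected per-read error count within
the single-mismatch tolerance), branch A→T misincorporation at rate 0.7
(the signature is frequent but not universal; the rate is part of truth
metadata and overridable), uniform substitution errors at 0.5%, and 50%
of reads emitted reverse-complemented because TA-cloning orientation is
arbitrary.

Not modelled: positional coverage bias, PCR duplicates, fragment-length
effects, read-level quality profiles, RT enzymes that skip the branch base
entirely (a deletion-at-branch mode would be a natural extension), and
alignment itself — the generator emits counts and short amplicon reads,
not BAMs. Passing tests therefore demonstrate correctness of the
statistics given faithful counts, not robustness to alignment artefacts.

## Numerical choices

Two-sided Fisher p-values are computed by summing hypergeometric point
probabilities not exceeding the observed table's (the probability method),
with a 1e-10 relative guard against floating-point ties; the suite checks
this against scipy's implementation on random tables and against full
integer-arithmetic enumeration on all 164,176 tables with margins ≤ 30
(agreement to < 1e-9). BH correction is NaN-tolerant: untestable records
stay NaN and are excluded from the family. Odds ratios are plain
cross-product ratios, reported as inf/NaN for empty cells rather than
smoothed. The pipeline derives per-stage seeds deterministically from one
global seed via `SeedSequence(seed, spawn_key=(stage,))`, so identical
configurations reproduce byte-identical outputs; every output file's
SHA-256 lands in the run manifest.

Problem sizes used by the test suite and acceptance script — 1,000
intron/read pairs for oracle equivalence, 10,000 clones for frequency
recovery, 1,000 events/sites for calibration and power, 150-gene genomes
for distance and enrichment analyses, 1,000 training windows for PWM
recovery — were chosen so that Monte-Carlo error is small against each
tolerance while the whole suite stays fast on a single CPU.

## Known limitations

- The USS formula is a documented default, not the published original;
  conclusions that depend on the exact functional form should be re-run
  with the alternative strategy (outputs record which was used).
- The PSI screen's pooled Fisher test ignores between-replicate
  overdispersion; with real biological replicates it will be anticonservative
  if replicate variability exceeds binomial noise. A per-replicate mean-PSI
  summary is available for reporting, but the test is pooled.
- Event extraction assumes clean annotation; it discovers no novel
  junctions from reads.
- At Sanger scale (10–12 clones per strain) branch-point frequency
  estimates carry binomial noise of ±0.14 (one sigma at f = 0.5); ranking
  two branch points whose true frequencies differ by 0.2 from a dozen
  clones is unreliable in ~15–20% of replicates no matter the caller, so
  strain-level conclusions should rest on deeper clone counts or pooled
  evidence.
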