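# Methods

This note records the model behind `iespipe`, the parameter choices that
matter, what the synthetic data do and do not emulate, and the numerical
conventions — the things a maintainer would otherwise have to reverse-engineer
from the code.

## Genome model and coordinates

The somatic (MAC) genome is a set of named scaffolds over `A C G T N`. An IES
is anchored by the 1-based position of the junction TA on the MAC scaffold;
its sequence **includes both terminal TA dinucleotides** and is at least 6 bp.
Insertion replaces the single junction TA with the full IES (both TAs come
with it); excision replaces the IES span by a single TA. With this convention
`excise ∘ insert` is the identity and the MAC+IES genome is longer than the
MAC by Σ(IES length − 2). GFF3 carries 1-based inclusive coordinates;
everything internal is 0-based half-open, converted only in the parser and
writer. Junction TAs of distinct IESs may not overlap (positions must differ
by ≥ 2 on a scaffold).

## Junction counting

Counting happens at IES *ends*, never across whole IESs, so the wide IES
length distribution cannot bias counts. For flank width `k`, three probes of
length `2k + 2` are cut per IES:

* `minus` — MAC window `flank(k) + TA + flank(k)` centred on the junction
  (the excised form);
* `plus_left` / `plus_right` — `flank(k) +` first `k + 2` IES bases, and last
  `k + 2` IES bases `+ flank(k)` (the unexcised form's two boundaries).

Matching is exact, on both strands, with one verdict per read: PLUS or MINUS
when all hits point at one IES and one form; a read carrying both boundary
probes of the same IES is PLUS once (a fragment is never double-counted);
any hit on a probe string shared between IESs, any cross-IES mixture, or a
plus/minus conflict is AMBIGUOUS and uncounted. Probes containing N never
match. An IES whose three probes are not pairwise distinct at the chosen `k`
is excluded from counting with a warning — classification would be ambiguous
by construction. In paired mode, mates are classified independently and a
fragment contributes at most one count per IES; mates that contradict each
other about one IES cancel as ambiguous.

The alignment (SAM) mode applies the same spanning rule to aligned
coordinates: a primary, non-supplementary record with MAPQ ≥ 1 is MINUS for
an IES when its aligned bases cover the MAC junction window, PLUS when they
cover either boundary window on the MAC+IES reference. MAPQ 0 records —
multi-mappers, i.e. ambiguous alignments — are ignored. Because the MAC and
MAC+IES references share scaffold names, alignment mode accepts one or more
SAM files and detects per file which reference it was aligned to from the
header scaffold lengths (an explicit override exists). On error-free
simulated libraries, probe mode and alignment mode agree count-for-count;
this equivalence is asserted in the tests.

### Choosing the flank width `k`

`k` trades coverage (small `k` lets short reads span) against probe
specificity. The package default is `k = 5` (probes of 12 bp) — enough to
anchor the TA plus flanks for typical read lengths. But probe uniqueness
must be checked at the catalog scale in use: for two random AT-rich windows
the per-position match probability is about 0.30, so the expected number of
chance collisions among `3·n_IES` probes (both strands) grows as
`match_prob^(2k) · pairs`. On a 200 kb fixture with 300 IESs, 12-mers
produce a handful of collisions — each of which silently ambiguates every
read of the affected IES — while 18-mers (`k = 8`) produce essentially none.
The end-to-end analyses in the test suite and acceptance script therefore
use `k = 8`; `build_probe_index` reports collisions and exclusions so users
can make the same check on their own catalogs.

## Retention score and significance

`RS = IES+ / (IES+ + IES−)`, undefined (NA) when the denominator is zero.
The caller compares each IES's experimental count against the control:

1. exact Clopper–Pearson interval of the control RS at confidence
   `alpha = 0.95` (beta-quantile inversion of the binomial CDF; lower bound
   0 at x = 0, upper bound 1 at x = n);
2. one-sided binomial tail `P(X ≥ x)` for the experimental IES+ count with
   the **upper** control bound as null proportion — a deliberately
   conservative null that absorbs residual excision noise and stray counts
   in the control (a control fully retained, x = n, has upper bound 1 and
   can never yield a call: there is no detectable excess);
3. Benjamini–Hochberg step-up across all *tested* IESs — IESs with zero
   denominator (or below `--min-coverage`, default 1) in either sample are
   reported NA and never enter the BH family;
4. retained ⇔ adjusted p strictly < 0.05.

Result tables print statistics at 6 decimal places so reruns diff cleanly.

Calibration properties verified by the test suite: under the null (r = 0
both samples, 2,000 IESs, coverage 100) the retained fraction stays ≤ 5%
across seeds (in practice it is ~0 — the composite procedure is conservative,
as expected from using the interval bound rather than the point estimate);
with control coverage ~200 and experiment r = 0.4 at coverage 30, power
exceeds 90%; the exact 95% interval around the measured RS covers the true r
for 92–98% of IESs with r ~ U(0, 1).

## Synthetic data: what it emulates, and what not

All generators are pure functions of (configuration, seed); rerunning
produces byte-identical files, and every read id encodes its origin so tests
can check results against truth tables.

* **Genome** — i.i.d. bases with P(A) = P(T) = `at_fraction`/2; default
  `at_fraction = 0.72`, the AT-richness of the *P. tetraurelia* somatic
  genome. No repeats, no genes, no isochores.
* **IES catalog** — junction sites uniform on each scaffold with a minimum
  spacing (default 300 bp, so junction regions of neighbouring IESs cannot
  interact at any read length in use) and an edge margin (default 150 bp,
  keeping probes and reads clear of scaffold ends); a TA is planted at each
  site. Lengths come from a configurable sampler; the default mimics the
  periodic IES size distribution with ~10-bp peaks starting at 26–32 bp and
  weights decaying with peak rank. Internal IES bases are random — real IES
  end consensus and inverted repeats are *not* modelled.
* **DNA libraries** — per IES independently, `N ~ Poisson(coverage)`
  junction fragments, each IES+ with probability `r` else IES−; start
  offsets uniform subject to spanning the junction/boundary with ≥ `k` bases
  on each side; strands symmetric; single-end reads of fixed length (default
  101 nt, matching typical shotgun read lengths; fragment = read). A
  background fraction (default 30% of the library) of non-junction MAC reads
  exercises the NONE/ambiguous paths; background starts exclude windows that
  would contain a full junction probe, so a background-only library counts
  zero up to chance k-mer collisions. Qualities are fixed at `I` — nothing
  downstream reads them. Sequencing errors default off; a uniform
  substitution rate exists to stress exact matching but is off in all
  shipped analyses. Poisson-per-IES coverage (rather than fixed depth) keeps
  the IES+ count exactly Binomial(N, r) conditional on N, which is the model
  the caller assumes.
* **Count-level shortcut** — `simulate_junction_counts` draws
  (N, IES+) directly from the same Poisson–Binomial hierarchy. It is
  distributionally identical to exact-match counting of an error-free
  library and is used for the large calibration runs (2,000 IESs × 5 seeds),
  while the read-level path is used wherever the counting rules themselves
  are under test.
* **sRNA libraries** — reads are exact substrings (20–30 nt, configurable
  length weights) of their source pool, drawn from a four-way category
  mixture; no adapter remnants, no 5′-nucleotide bias, no expression
  structure along the references.
* **Contig coverage** — planted covered/uncovered designs; covered contigs
  get RPKM in (2.5·t, 25·t) and uncovered in [0, 0.75·t) for threshold t,
  with ceil/floor rounding so the design is exactly recoverable at the
  emitted library size.

Passing tests on these fixtures shows the *procedures* are correct
(counting rules, interval inversion, BH bookkeeping, set arithmetic); it
does not validate behaviour under alignment error, repeat-induced
multi-mapping, copy-number differences between old- and new-MAC DNA, or IES
sequence biases — none of which the generators produce.

## sRNA profiling conventions

Pipeline order is fixed: length selection (bounds inclusive), contaminant
subtraction, hierarchical assignment. The first two are per-read filters, so
their order is immaterial (asserted on fixtures). Contaminant matching is
substitution-only (Hamming), infix, both strands, threshold
`max_mismatch = 1`, implemented as a vectorized scan over all reference
windows of the read's length. "Unique location" in tier assignment means
exactly one occurrence across the tier's sequences, both strands, overlaps
counted; a read matching a tier at ≥ 2 locations is discarded as non-unique
and by default *not* passed to later tiers (it did match the earlier
reference — it just cannot be placed); `cascade_nonunique=True` gives the
alternative reading. Normalization is per million reads mapped to any
*Paramecium* tier (target + MAC + IES); the enrichment ratio
`(IES/MAC)_late / (IES/MAC)_early` uses normalized counts, where the library
sizes cancel, and is undefined when a denominator is zero.

## Complexity stage conventions

RPKM = reads / (contig kb) / (mapped Mreads). A contig is covered when RPKM
is strictly above 2 *and* its length strictly above 1 kb. The private
complexity of dataset A versus a control is the summed length of contigs
covered by A but not the control; the headline fraction divides the length
of (experiment-private ∩ reference-private) by reference-private length.
When the counts table holds every mapped read of the library, the library
size defaults to the column sum; otherwise pass it explicitly
(`--library-size`).

## Comparative summaries

Quartiles and bin statistics use linear interpolation between order
statistics (numpy's default, the common "type 7" convention); on
`[1..8]` the quartile edges are `1, 2.75, 4.5, 6.25, 8`. Binned summaries
use half-open bins with a right-closed last bin; empty bins report n = 0
with NA statistics. Rank-sum comparisons use the exact Mann–Whitney null
when both groups have n ≤ 8 without ties, else the tie-corrected normal
approximation with continuity correction; sequential size-group comparisons
(each group against its predecessor) are BH-adjusted before flagging
significance at 0.05, mirroring the retention caller's correction policy.

## CLI and reproducibility

Every stage's randomness derives from one explicit seed (no wall-clock
defaults): stage streams are `default_rng([seed, stage_id])` with fixed
per-stage ids, and the `run` subcommand derives the control/experiment
library seeds as `2·seed + 1` and `2·seed + 2`. `run` writes a manifest with
the package version, the resolved configuration and its hash, SHA-256 of
every produced file, and per-stage row counts; rerunning a config reproduces
byte-identical outputs. Exit codes: 0 success, 2 validation failure (before
any stage runs where detectable), 3 runtime failure, always tagged with the
stage name.

## Problem sizes in the shipped analyses

The test suite and acceptance script run at deliberately small scale chosen
to make every property measurable with sharp planted truth: 300 IESs at
coverage 100 for the end-to-end mixture (retained fraction 50% ± 5 points),
2,000 count-level IESs for interval coverage and null calibration, 1,000 for
power, 10,000-read sRNA mixtures, and 3-contig coverage designs where the
planted private fraction (64%) is exact by construction. Real datasets are
two orders of magnitude larger in IES count; nothing in the implementation
depends on these sizes.

## Known limitations

* Exact matching only in probe mode; a single sequencing error inside a
  probe window drops that read. Error-tolerant counting should go through
  the alignment mode with a real aligner upstream.
* The binomial model treats junction fragments as independent; PCR
  duplicates or copy-number structure between old- and new-MAC DNA would
  violate this and are not modelled.
* `count_from_alignments` requires aligned-base coverage of the full probe
  window; indels inside the window disqualify a read even when the
  alignment is confident.
* The sRNA unique-location rule is per tier by default; genome-wide
  uniqueness (across all tiers at once) is only approximated by the cascade
  flag.
* No plotting; all outputs are tables.
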