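# Methods

## Mapping model

A bisulfite-converted fragment differs from the reference only by
C→T substitutions on its origin strand (unmethylated cytosines).
`bsmapper` makes this difference invisible to the aligner by collapsing
the alphabet: C→T on forward-form reads and on both reference strands,
G→A on reverse-complement-form reads and on the reverse complements of
both reference strands. A read then has an exact (or
error-only-mismatched) image in exactly one of four converted reference
spaces — W_CT, C_CT, RCW_GA, RCC_GA — whose hits map back to Watson
coordinates with a form label (+FW, −FW, +RC, −RC).

Complementation swaps C↔G, so G→A applied to a reverse complement
equals the reverse complement of C→T: `RCW_GA = revcomp(W_CT)` and
`RCC_GA = revcomp(C_CT)`. The implementation therefore builds seed
indexes only over W_CT and C_CT and searches the G/A spaces by aligning
the reverse complement of the G/A-converted read against them,
transforming offsets by `p ↦ L − p − n`. The four logical spaces remain
the external contract; the test suite verifies the identity exhaustively
for all sequences up to length 8. All internal coordinates are 0-based
half-open; 1-based inclusive Watson coordinates appear only in output.

Alignment is **ungapped** (Hamming distance): the mismatch-count
framework the method rests on has no indel notion, and indels are out
of scope.

### Seeding and completeness

`align_read` must return *every* placement within the 3-letter mismatch
ceiling m, because the uniqueness decision is only correct if no
qualifying hit is missed. Completeness is guaranteed by pigeonhole
seeding: the read is cut into m+1 non-overlapping k-mers, so any
placement with ≤ m mismatches contains at least one exact seed. The
effective k is `min(seed_len, read_len // (m+1))` (seed_len default 12),
e.g. k = 9 for 36-mers and k = 7 for 31 genomic bases of a tagged
36-mer at the default m = 3. Reads too short for m+1 seeds fall back to
a complete scan of the space rather than dropping hits. Candidate
verification is vectorised, with a subset-of-positions lower bound
pruning candidates that cannot reach ≤ m mismatches before the full
count. Equivalence with a brute-force sliding-window oracle is asserted
on over a thousand randomized instances.

A read whose pooled hit list exceeds `hit_cap` (default 500) is
discarded as ambiguous without further inspection: a repeat-region read
with hundreds of qualifying placements either has tied best hits or, at
best, a unique placement inside near-identical repeats that should not
be trusted; enumerating past the cap would only confirm the discard.

### Uniqueness, mismatch recounting, quality

Hits from all logical spaces are pooled; let b be the minimum 3-letter
mismatch count. The read is unique iff exactly one hit attains b;
strictly worse hits do not break uniqueness, ties at b discard the read
as ambiguous. Ambiguous reads are never randomly assigned — random
assignment lowers accuracy and biases methylation estimates, since
repeats are not methylation-representative.

Mismatches of the surviving hit are recounted on the original alphabet
against the genome segment oriented as the read is written: for FW
forms, read T over genomic C is a match and read C over genomic T a
mismatch; for RC forms, read A over genomic G matches and read G over
genomic A does not. Read N always mismatches. The count is compared
with `max_mm` (default 2, independent of the 3-letter ceiling m3 = 3;
the two ceilings are deliberately separate parameters since the phase
they act on differs). Recounting applies to the tag-trimmed read only —
the tag is adapter-derived, not genomic, so it is the only
self-consistent choice.

Unmapped reads carry one of four reason codes (no_hit, ambiguous,
low_quality, too_short) and the run report prints totals, unique counts
and per-reason discards, because mapability statements are exactly
these statistics.

### Tags and protocols

Non-directional libraries carry a 5-nt tag in the first bases of each
read, identifying FW vs RC forms. The tag patterns are configuration:
they are chemistry-specific and not something this package should
invent. The shipped defaults (`GATCT` FW / `GATCA` RC — the DpnI
recognition site plus one discriminating base) are synthetic
placeholders that match the bundled simulator; real libraries need
their own pattern file. Tags are trimmed before alignment *even when
unmatched*, since the tag region is never genomic under this protocol;
unmatched reads (class UNKNOWN) are aligned as both FW and RC, i.e. in
all four spaces. Directional-protocol reads are always FW, need no
trimming, and use two alignment passes instead of four.

Base qualities are parsed and passed through but never used in
alignment or filtering: reads are modelled as discrete base calls.

## Methylation calling

For every read position whose origin-strand genome base is C: read C is
a methylated observation, read T unmethylated, anything else (an error)
is excluded. Context (CG / CHG / CHH) is assigned from the *reference*
on the C's strand, never from the read, so errors cannot shift context;
bases past the chromosome end count as H. Sites are keyed by (chrom,
1-based Watson position, strand): the two cytosines of a CG dinucleotide
are distinct sites. Genome-wide rates are pooled over observations
(coverage-weighted), not averaged over sites, which is what makes the
inferred rate of a simulated library converge to the input probability.
Contexts with zero coverage are reported NA, never 0. No smoothing and
no per-site testing are applied; rates are raw. Per-read states are
serialised in a `methylation_string` (one character per written base:
`X/x` CG, `Y/y` CHG, `Z/z` CHH, upper = methylated, `.` uncallable,
`-` not a C); the encoding is context-complete, so downstream
aggregation and evaluation need no second pass over the genome.

## Simulator

The simulator defines the validation conditions:

- **Methylome**: every genomic C on each strand independently
  methylated with its context's probability. Defaults p_CG = 0.72,
  p_CHG = p_CHH = 0 — the CG level of the validation experiments; the
  non-CG contexts are left at zero so that any inferred non-CG signal
  is attributable to mapping or error artefacts.
- **Reads**: origins uniform over (chrom, strand, start) with
  replacement; form uniform over the protocol's allowed forms; 36-mers
  by default. For the tagged protocol the emitted read length includes
  the 5-nt tag (31 genomic bases), matching how tagged libraries are
  sequenced; truth records the genomic fragment's coordinates, so
  evaluation is a pure equality check against the mapper's output.
- **Errors**: a per-cycle substitution probability vector; each error
  replaces the base by one of the other three uniformly. The default
  profile rises linearly from 0.2 % to 2 % across the read — the
  characteristic increase of base-calling error with cycle number. The
  exact error distribution of any particular sequencer run is not
  reproduced; the shape suffices for the qualitative error effects
  (accuracy slightly below 100, spurious non-CG methylation of a few
  tenths of a percent).
- **Test genome** (`synthetic_genome`): i.i.d. backbone at 42 % GC with
  15 % of the genome overwritten by copies of its own segments
  (0.3–3 kb) carrying 2 % divergence. The repeats matter: on a purely
  random genome no read can be uniquely *mis*placed, because an
  error-free read's true origin is always a 0-mismatch hit and any
  equal competitor forces an ambiguous discard. Diverged copies are what
  allow a sequencing error to flip a read onto the wrong copy — the
  mechanism behind sub-100 accuracy on real chromosomes — while leaving
  error-free accuracy provably at 100.

What the simulator does *not* model: indels, quality-score variation,
PCR duplicates, fragment-length distributions, incomplete bisulfite
conversion, and the specific repeat taxonomy of real chromosomes.
Passing tests therefore demonstrate the correctness of the mapping and
calling logic under the stated read model, not performance on any
particular organism; in particular, mapability percentages depend
strongly on repeat structure and are not comparable across genomes.

## Problem sizes and determinism

The validation experiments use a 2 Mb genome with 50,000 reads per
protocol (20,000 for the error-injection run), sizes at which every
property being checked — exact accuracy, rate recovery within three
binomial standard errors (computed with the effective sample size
(Σn)²/Σn², which accounts for repeated observations of one site sharing
a single methylation draw), strictly positive error effects — is
statistically stable. All randomness flows through explicit integer
seeds (numpy PCG64); identical seeds give byte-identical FASTQ, truth,
and mapping outputs.

## Interfaces and serialization

Inputs are standard FASTA and 4-line FASTQ (Sanger qualities,
pass-through). The mapping table is TSV (read_id, strand_code, chrom,
start, read_seq, genome_seq, mismatches_orig, methylation_string);
strand codes `++/+-/-+/--` alias the four forms (origin strand, then
FW/RC). Per-site output is a CGmap-like TSV; optional SAM carries the
form in `XF`, 3-letter mismatches in `X3`, recounted mismatches in
`NM` and the methylation string in `XM`, with reverse-orientation
reads stored reverse-complemented as SAM requires. The serialized
reference set (`index` subcommand) is a versioned `.npz` holding the
validated genome and parameters; converted spaces and seed tables are
deterministic functions of these and are rebuilt on load, which keeps
the format trivial and version-safe at the genome sizes this package
targets. An external aligner can replace `align_read` provided it
honours the same completeness contract.
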