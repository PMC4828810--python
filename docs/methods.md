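# Methods

This note documents the models, parameter choices, and numerical
conventions behind `stemloop`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Read preprocessing

Adapter trimming returns the read prefix before the left-most adapter
occurrence; the adapter may run off the 3' end of the read as long as at
least `min_overlap` (default 6) bases align with at most `max_mismatch`
(default 1) mismatches. Reads without any occurrence are rejected in raw
mode and kept unchanged in pre-trimmed mode (`pre_trimmed: true`), since
both input states occur in practice. "Low quality" is not a standardized
notion for sRNA reads; we drop FASTQ reads containing `N` or with mean
Phred < 20, and skip quality filtering for FASTA input.

ncRNA contaminant removal is exact substring matching against the
reference records and their reverse complements. Exact matching is
deterministic and auditable; it will keep reads that differ from an rRNA
fragment by a sequencing error, which a mismatch-tolerant mapper would
remove. Length filtering retains 15–45 nt inclusive.

TPM denominators are each library's *final clean* totals (after ncRNA
removal), so per-library TPMs sum to 10⁶ over the unique-read set. All
snRNA/snoRNA/rRNA/tRNA removal happens in a single pass; the accounting
table reports one combined "ncRNA removed" row.

## Conserved assignment

Matching is ungapped, end-to-end, and strictly length-matched: a 20-nt
read is never compared to a 21-nt reference. This is the simplest rule
consistent with a plain mismatch bound (≤ 2) and makes every assignment
reproducible by inspection; tolerating length offsets is a plausible
alternative and is deliberately not implemented (a read that is a
shortened variant of a known mature will instead reach the novel-calling
stage, where it must justify itself with a hairpin). Ties are broken
toward the lexicographically smallest reference identifier. Family names
are the `miR` + digits token with letter/suffix modifiers stripped.

## RNA folding engine

The folder is a Zuker-style dynamic program over a compact nearest-neighbor
model (module `fold_params`): Watson–Crick and G:U pairs; a 6×6 stacking
table with Turner-like magnitudes; hairpin/bulge/internal-loop penalties
tabulated for small sizes and extrapolated logarithmically; internal-loop
asymmetry at 0.5 kcal/mol per nt capped at 3; a linear multiloop model
(closing 3.4, per branch 0.4, per unpaired base 0.1 kcal/mol); minimum
hairpin loop 3; interior loops capped at 30 nt; no dangling ends or
terminal-AU terms; exterior loop free. All energies are integers in
centi-kcal/mol, so the DP, its traceback, and the exhaustive-enumeration
oracle compare energies exactly — the oracle shares only the parameter
tables, never the recursions, and the two agree bit-for-bit on every short
sequence tested.

Because the model is self-contained, absolute energies differ from other
folding engines; thresholds stated in kcal/mol (notably the −18 kcal/mol
precursor gate) are configuration values calibrated against this model. An
external folder can be substituted behind the same `fold()` contract.

Co-optimal structures are resolved by a fixed traceback preference —
helix extension, then interior loops by increasing size offsets, then
multiloops, then hairpin closure, smallest indices first — which is
deterministic and biased toward structures with more paired bases. The DP
kernel is numba-compiled; a 420-nt window folds in well under a second.

Hairpin spans are extracted by taking each innermost helix and extending
it outward through nested pairs across bulges and internal loops until a
multiloop or the exterior loop is reached.

## Novel miRNA criteria

A candidate read (20–24 nt, TPM ≥ 5 in at least one library, not assigned
to a reference mature) is mapped perfectly to the unigenes on both strands;
each locus window (±200 nt) is folded and judged on five criteria:

1. **hairpin** — the mature's paired bases lie inside one stem-loop span;
2. **arm** — the duplex pairs all point at the opposite arm, the mature
   never pairs with itself, and the paired extent does not cross the
   terminal loop. The unpaired 2-nt 3' overhang may sit in the fold's
   terminal-loop interval (5p arm) or just past the outermost pair (3p
   arm): Dicer-duplex overhangs are structurally unpaired, so a literal
   "no mature base inside the loop interval" rule would reject essentially
   every genuine 5p precursor;
3. **duplex** — ≤ 4 mature bases without a star partner and no asymmetric
   bulge > 2 nt. Duplex pairs are those on the majority side whose
   pairing register (partner + index, constant along an ungapped duplex)
   is within 6 of the median — stray helices that grab one or two mature
   bases are thereby counted as mismatches instead of corrupting the
   bulge statistic;
4. **star** — a miRNA* recoverable by duplex geometry with 2-nt 3'
   overhangs, requiring ≥ (length − 4) paired duplex bases;
5. **mfe** — the precursor, trimmed to the minimal hairpin-containing
   span, folds at or below `mfe_max` (default −18 kcal/mol).

The MFEI window (default [0.7, 1.5]) is computed and reported but advisory
by default (`mfei_gate: false`): published precursor sets include values
well outside it, and MFEI is a ranking statistic rather than a sharp
boundary. MFEI uses the trimmed *precursor's* GC fraction, which is how the
index is defined; the report table's GC% column describes the mature, per
the conventional table layout.

Overlapping windows of the same mature on one unigene are merged when
their precursor spans overlap ≥ 50%. Novel identifiers are assigned in
lexicographic order of the mature sequence (`miRn01`, `miRn02`, …),
matching the convention of sequence-sorted published tables.

## Differential expression

The Fisher exact test is computed in-package as the sum of hypergeometric
probabilities of all tables with the observed margins no more likely than
the observed table (with the conventional 1 + 10⁻⁷ tie guard); an
independent big-integer enumeration oracle reproduces it to 10⁻¹². The χ²
test is the 1-df closed form without continuity correction (Yates
optional). Adjustment is Benjamini–Hochberg (Bonferroni via config); the
decision rule is fold change ≥ 2 or ≤ 0.5 with adjusted p < 0.05, using
Fisher by default. Zero-TPM entries report ratio 0.000 (female absent) or
`inf` (male absent), leave log2 blank, and remain callable when
significant. Report rounding is fixed — TPM 2 d.p., ratio 3 d.p., log2
4 d.p. — so files are comparable cell for cell. Fold changes and log2
values are computed on unrounded TPMs.

## Degradome analysis

Only perfect sense-strand matches of 20–21 nt reads build profiles (mRNA
decay is sense-strand; antisense matches are ignored). The target-scoring
constants (0 / 0.5 / 1 per position, doubled over miRNA positions 2–13,
cutoff 7.0) follow the plant-target scoring convention; all are
configurable. Cleavage detection is strict at the position opposite miRNA
nucleotide 10 by default, with a configurable `(9, 10, 11)` window for the
known 10th/11th-nucleotide ambiguity. The category median is computed over
*occupied* positions only — including zero-count positions would make the
median degenerate on any long transcript. Categories follow the t-plot
tiers (0 unique maximum, 1 shared maximum, 2 above median, 3 at/below
median, 4 single raw read); a category-4 call requires exactly one raw
read regardless of the rest of the profile.

## Synthetic data generator

The generator emulates the study conditions end to end: a random unigene
reference (default GC 0.42, 300–5000 nt range supported), planted
precursors (mature + 8–12 nt loop + star on either arm and either strand;
the star is the reverse complement of the mature minus its 2-nt overhang
with 0–4 injected non-pairing substitutions, plus its own 2-nt overhang),
multi-locus matures, conserved matures mirrored in the reference set,
ncRNA contaminants (default 40% of each library, matching the proportion
removed in real sRNA libraries), random 15–45 nt noise reads, a 3'
adapter on every read, and degradome reads whose 5' ends sit opposite
miRNA nucleotide 10 of planted perfectly complementary target sites, over
uniform background decay.

`plant_precursor` validates its construct by running the default-threshold
evaluator on the resulting window and re-rolls its internal randomness
(loop, overhang, mismatch placement, position) up to 25 times; random
flanking sequence occasionally pairs into the duplex, and this makes the
generator's contract — planted precursors pass the default criteria —
hold deterministically. The bundled dataset recipe keeps mature GC within
0.45–0.65 and injects at most one star mismatch: low-GC 20–24 nt duplexes
cannot reach −18 kcal/mol under any nearest-neighbor model, and two
mismatches sit exactly at the star-coverage boundary, which would make
recovery depend on fold tie-breaking rather than on the pipeline.

Scale: the default study uses 40 unigenes of 600–1200 nt and ~2,400 raw
reads per library (~1,400 final clean), with planted counts of 20–90 reads
per miRNA and 4-to-12-fold planted expression differences; at these
totals the Fisher test resolves the planted directions decisively while
the whole pipeline runs in a few seconds. Reads are emitted in DNA
alphabet; report surfaces print RNA.

What passing these tests shows: the pipeline recovers exactly what was
planted under its own stated assumptions (exact adapter, perfect mapping,
mismatch-free contaminants, idealized cleavage). What they do not show:
robustness to sequencing errors, quality-score artifacts, isomiR
heterogeneity, RNA editing, or assembly errors in the unigene reference —
none of which the generator simulates.

## Numerical conventions and degenerate inputs

Integer centi-kcal energies throughout the folder; MFE reported as
`int/100`. An unpairable sequence folds to all dots with MFE exactly 0.
`fold()` accepts any length from 1 to 2000 nt (the short-sequence limit
makes the enumeration oracle applicable). GC fraction of an empty
sequence, MFEI at GC = 0, fold change with both TPMs zero, χ² with a zero
margin, and an empty mature reference set all raise `ValueError` rather
than returning sentinels. Every stochastic operation takes an explicit
integer seed, and identical configuration plus seed yields byte-identical
report files.

## Known limitations

- The energy model is deliberately compact; it omits dangles, terminal-AU
  penalties, special hairpin sequences, and coaxial stacking, so absolute
  MFEs differ from full Turner-2004 implementations by a few kcal/mol on
  typical precursors.
- Equal-length conserved matching will miss length-variant orthologs.
- Degradome multi-mapping reads increment every matched position (no
  fractional weighting), which can inflate categories on repetitive
  transcripts.
- The pipeline maps reads by exact string search, which is appropriate at
  unigene scale (tens of Mb) but not for full genomes.
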