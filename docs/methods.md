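# Methods

This note documents the models, parameter choices and numerical behavior
of `rdnakit`, and what the synthetic benchmarks do and do not establish
about real data.

## The setting

A nucleolus organizer region (NOR) is a tandem array of nearly identical
~10 kb rDNA units, each carrying the 18S/5.8S/25S rRNA genes, transcribed
spacers (5'-ETS, ITS1, ITS2, 3'-ETS) and an intergenic region with
promoters and length-polymorphic SalI repeat boxes. Whole-genome assembly
collapses the array, so surveys sequence BAC clones (~7 units each) and
reconstruct array structure from per-unit sequence barcodes. The package
operates downstream of assembly and variant calling: its inputs are
assembled sequences (FASTA), probe sets, per-unit barcode catalogs and
allele-frequency tables.

## Barcodes

The feature code concatenates four markers — promoter count (1–5, core +
spacer), AvaI restriction site presence (reference position 4133), CAT
trinucleotide insertion presence (position 4466), and the 3'-ETS length
variant (1 = long, 3 = short) — plus a suffix letter for large deletions:
A (310 bp, 5'-ETS), B (330 bp, 5'-ETS), C (270 bp, 18S), D (334 bp,
18S–ITS1). Deletion letters and SalI bin letters share glyphs but live in
separate namespaces (suffix position vs. inside the bracketed SalI code).

SalI boxes classify into 50 bp bins (D 200–249 … ρ 1800–1850), both
endpoints inclusive. Lengths falling between bins map to `'?'` with a
warning rather than snapping to the nearest bin: the bin table is treated
as exhaustive for classifiable data and silent snapping would fabricate
classes. SalI letters are ordered 5'→3' as the boxes occur; code
comparison is exact text equality. Greek letters are accepted in UTF-8 and
as ASCII aliases (PSI/LAM/RHO) in text formats.

## Annotation

Reference points come from exact word search (both strands by default;
degenerate IUPAC bases expand to the explicit sequence set; no mismatch
tolerance — probes are short and unique). Anchor matches (one designated
probe per unit) segment the assembly into half-open, head-to-tail unit
spans; mixed-strand anchors violate the head-to-tail assumption and raise
an error, and all-minus assemblies are reverse-complemented to
transcription orientation first.

Edge units: a fragment before the first anchor is flagged partial, as is a
trailing span shorter than 0.8× the median anchor spacing. Because genuine
units legitimately range ~7.4–15 kb (deletions, short 3'-ETS, promoter
count, box count), the annotator additionally attempts a feature call on a
flagged trailing unit and keeps it when every landmark is present and
classifiable — a pure length rule would discard real units.

Feature calling parameters (all in `MotifConfig`, units bp):

* AvaI — recognition-site regex `C[CT]CG[AG]G` searched in a ±50 window
  centered 200 bp downstream of the nearest landmark motif (the position
  homologous to reference 4133, mapped through the local landmark so that
  upstream deletions do not shift the window).
* CAT — presence of the insertion-allele context probe (context + CAT +
  context); the insertion-free context marks an explicit negative call, and
  a unit with neither is unclassifiable rather than silently CAT−.
* 3'-ETS variant — length from the 25S-end marker to the first SalI flank
  (threshold 800) or, for boxless units, to the first promoter motif
  (threshold 1150). Two thresholds because the boxless path includes the
  intergenic spacer.
* Deletions — length deficits of the two landmark-bounded windows (5'-ETS
  nominal 1100; 18S–ITS1 nominal 2300) matched to the class lengths within
  ±20 bp, nearest class on ties. The tolerance is small relative to the
  270–334 bp deletions and larger than any jitter the generator emits.
* Zero promoter matches flag the unit unclassifiable instead of reporting
  promoters = 0 (below the code grammar's range).

Coordinates are 0-based half-open internally and 1-based in all reports.

## Overlap detection and contigs

A fingerprint is the ordered (marker identity, position) sequence of one
assembly; distances are the gaps between neighbors. `find_overlaps`
enumerates every suffix/prefix and containment alignment of two
fingerprints: an alignment is reported when *all* paired identities match
and *all* paired distances agree within the tolerance (default ±35 bp; the
original survey also used a 13 bp setting, exposed as the same flag).
`min_n`/`max_n` (defaults 2 and 30) bound the alignment extent, counted in
anchor-delimited units when an anchor id is available, else in points.
Reversed-fingerprint matching (`try_flip`) is on by default since clones
may enter in either orientation.

Repeat arrays are self-similar, so *all* candidate alignments are
reported. Contig building consumes matches best-first (most matched units,
then smallest residual, then lexicographic ids) and places each assembly
by an affine map (shift + optional flip) in contig coordinates; a match
that contradicts existing placements raises a conflict error in strict
mode or is skipped in the pipeline default. An optional marker-concordance
filter re-checks the full barcodes of matched units, automating the manual
confirmation step such surveys otherwise require. Contig bp length sums
the member-covered inter-element gaps plus one median element extent and
is therefore approximate.

## Neighbor statistics and the shuffle null

Pairs are ordered (left→right in transcription orientation) and never
cross assembly boundaries, so total pair count at offset k equals
Σ max(0, n_a − k). Normalization divides the pair count by the number of
units bearing the paired types: marginal(a) + marginal(b) for a ≠ b and
marginal(a) for self pairs (each qualifying unit counted once); the
doubled self-denominator variant sits behind a switch, as does a
symmetrized display mode. R² between distance classes is the squared
Pearson correlation over the union of pair categories, zero-filled;
zero-variance vectors raise rather than return a value.

The null permutes all unit labels uniformly over all slots in one global
permutation — the strongest exchangeability null that preserves what the
survey design fixes: head-to-tail slot order and per-assembly unit counts.
Marginals are permutation-invariant, so all replicates share one
normalization denominator. Per pair the ensemble records the occurrence
frequency across replicates (retention filter: frequency > 0.90,
configurable), the mean normalized value, and the full per-replicate count
distribution for percentile bands. One root seed spawns per-replicate
child streams (`numpy` SeedSequence), so any replicate is reproducible in
isolation. Replicates default to 1000.

Calibration caveat: with few pair categories the "≥95 % of pairs inside
the central 95 % band" summary is itself a random quantity; at 25
categories its seed-to-seed standard deviation is ~3 percentage points, so
individual runs can report ~92 %.

## Allele attribution

The two-array mixture with default n2 = n4 = 400 (≈800 total units)
quantifies the verbal comparison rule: a variant's BAC AF estimates its
NOR2 frequency, the deconvolved `af_nor4 = (af_wg(n2+n4) − af_bac·n2)/n4`
estimates the NOR4 frequency (clamped to [0,100], clamp reported — a
negative raw value is a NOR2-exclusive signal), and the class goes to
whichever side exceeds the other by the enrichment ratio (default 2,
configurable; the choice of an explicit ratio is this package's own, the
original comparison being visual). Attribution is invariant to joint
scaling of n2 and n4. The AF floor is 100/total_copies percent — the
frequency of a single unit — and is idempotent and monotone in the copy
number.

rRNA-side filtering keeps only variants present in both the rRNA and rDNA
call sets at matching key (position, ref, alt) with both members passing
the quality gate (caller PASS after q>30 read filtering; no re-scoring
here); rRNA-only calls are treated as modification artifacts. The ETS/ITS
fraction is reads on {5'-ETS, ITS1, ITS2, 3'-ETS} over all reads on the
repeat; the ratio between a total-RNA and a ribosome-captured sample
measures enrichment success (≈10× depletion in practice). VCF input reads
the `AF` INFO tag via cyvcf2 (fractions converted to percent); a TSV
fallback (`pos, ref, alt, af, source`) and a BED region map are supported.

## The synthetic generator

The generator defines the conditions under which the pipeline is
verified.

* **Chain**: first-order sticky Markov chain over unit types — with
  probability λ the next unit repeats the current type (feature code and
  SalI combination), else both are drawn fresh. Default λ = 0.6 plants
  clustering comparable to a real array's; λ = 0 gives the exchangeable
  control. Default type frequencies are the observed spectrum of the NOR2
  catalog (2001 38 %, 2003 11 %, 3001 10 %, 3111 8.6 %, deletion classes
  ~0.6 % each, remainder spread over the rarer classes), and SalI
  combinations likewise (EZ 14 %, EU 12.5 %, EV 11 %, EEV 8.5 %, EEU
  8.3 %, FQ 6 %, I 5.8 %, M 5.8 %, remainder over 14 rare combinations
  including boxless units). Box lengths draw uniformly within their bins.
* **Structural identity**: every chain unit carries small fixed length
  offsets on its intergenic-side spacers (IGS ±60, 5.8S-flanking spacer
  ±40, 3'-ETS ±30, promoter gaps ±20 bp), shared by every window covering
  the unit. Real repeat units accumulate indels, which is precisely what
  makes inter-marker distances informative for overlap detection; without
  this, distinct same-type units would be metrically indistinguishable.
  The deletion-calling windows (5'-ETS, 18S–ITS1) stay length-conserved so
  deficits remain exact.
* **Windows**: BAC-sized slices of 2 + Poisson(mean−2) units (mean 7),
  placed disjoint with small gaps or per an explicit overlap plan that
  pins exact shared-unit counts between consecutive windows. The default
  study-scale configuration (600-unit array, 59 windows, ten of them in
  four planted multi-window contigs) emulates a BAC survey's shape.
* **Emission**: each unit renders onto a scrubbed random backbone with the
  canonical motif anatomy; per-window assembly jitter is uniform on
  [−j, +j] bp (default j = 10), drawn once per inter-marker distance.
  Bounded jitter is chosen deliberately: it guarantees that two windows of
  the same genomic unit disagree by at most 2j per distance, hence perfect
  planted-overlap recovery whenever 2j < tolerance — an unbounded noise
  model cannot support that guarantee. Chance AvaI-site regex matches are
  scrubbed from the calling window only. Same seed ⇒ byte-identical FASTA;
  `emit_fingerprints` shares the jitter stream with `emit_fasta`, so the
  fast fingerprint path equals annotation of the emitted sequences.
* **AF tables**: binomial read sampling at a given depth around the true
  NOR2 AF (BAC source) and around the n2/n4 mixture (whole-genome source).

What the benchmarks show — and don't. The noiseless round trip shows the
annotator inverts the emitter exactly; the 50-array benchmark shows the
overlapper is complete and sound *under bounded jitter and an unclustered
array*. On clustered arrays (λ = 0.6) runs of identical barcodes make
alternative alignments genuinely ambiguous; all candidates are reported
and greedy chaining picks the best, which can merge unrelated windows —
the same ambiguity that forces manual confirmation on real data. The
generator does not model sequencing error, polishing artifacts, unit-scale
rearrangements, or probe mismatches; real-data annotation quality is
bounded by probe uniqueness, which the word search assumes.

## Problem sizes and determinism

The test suite and the acceptance script use scaled problem sizes chosen
to exercise every code path with comfortable statistical margins: 50
planted-overlap arrays of 6 windows; 2000-unit catalogs with 1000-replicate
nulls; a 600-unit / 59-window study-scale survey (~410 annotated units,
matching a real survey's ~405); law-of-large-numbers checks at 60 000
units. Every random stage consumes a `numpy` Generator seeded from one
root; reruns with identical configuration are byte-identical, including
file outputs (headers carry version, seed and parameters, never
timestamps).

## Known limitations

* Overlap evidence is marker/distance-based only; no base-level alignment
  of overlapping regions confirms a match.
* Contig bp lengths are approximate (median-extent extrapolation at the
  trailing element).
* The promoter motif of real material must be user-supplied; the packaged
  probes describe the synthetic anatomy.
* `matched_units` equals matched reference points when no anchor marker is
  present in a fingerprint.
* The enrichment-ratio default (2) and the per-array copy numbers
  (400/400) are declared modeling choices, not measured quantities; both
  are parameters everywhere they appear.
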