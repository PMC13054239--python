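# Methods

This note documents the models, rules and numerical choices behind
`wormcoi`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the underlying workflow left a
choice open.

## Trace model

Raw inputs are paired bidirectional Sanger reads per
(specimen, collection-method) sample, represented as FASTQ with
Phred+33 qualities.  Chromatogram-level evidence (peak shape, peak
height, background noise) is approximated throughout by per-base Phred
scores: a decision that in a chromatogram editor would be made by eye
("does the trace support this call?") is made here by quality
thresholds.  An `.ab1` reader would be a drop-in extension — nothing
downstream of `TraceRead` knows the provenance of the qualities.

Internal coordinates are 0-based half-open; report output is 1-based
where positions are shown to users.

## Assembly

* **Primer trimming.** A Hamming scan of the expected primer over the
  leading window of the read (primer length + 30 bp slack); the best
  placement within 3 mismatches is removed together with anything
  upstream of it.  Absence of a primer is legal — reads may arrive
  pre-trimmed.
* **End clipping (modified Mott).** With cutoff `c = 0.05`, the running
  score accumulates `c − 10^(−Q/10)` and is floored at 0; the retained
  segment ends at the all-time maximum and starts after the last floor
  reset.  This is the de facto Sanger standard (phred/Trimmomatic
  lineage); the source workflow names no algorithm, only the operation.
  Lowering the cutoff never lengthens the clipped read (tested as a
  property).
* **Overlap alignment.** The forward read and the reverse-complemented
  reverse read are aligned with free end gaps on both sequences
  (dovetail), match +2 / mismatch −3 / gap open −8 / extend −2.  A
  usable contig requires ≥ 50 bp overlap at ≥ 90% identity; these two
  thresholds *define* "usable" here, since the source workflow reports
  only the failure outcome, not its cutoff.
* **Consensus.** Within the overlap: agreement keeps the base at the
  maximum of the two qualities; disagreement is resolved toward the
  higher-quality base only when the Phred margin is ≥ 10 *and* the
  winning call is at least Q20; any other disagreement becomes `N`,
  with both strand calls recorded so diagnostic sites can later be
  re-annotated with the minimal covering IUPAC code.  Outside the
  overlap, single-strand flank bases are kept only above Q20
  ("reliable non-overlapping regions" — the word "reliable" is given
  this concrete meaning here).  Interior single-strand gap columns
  inside the overlap are alignment artifacts and are dropped.

## Frame QC

* **Genetic code.** Invertebrate mitochondrial (translation table 5):
  stop codons TAA and TAG only.  The source workflow does not name the
  table; earthworm mitochondrial COI leaves no real alternative.
* **Frame placement.** All six frame/strand combinations are scored by
  in-frame stop count; minimum wins, ties break toward the + strand and
  the smallest offset.  A codon containing N or an ambiguity code
  counts as a stop only if *every* IUPAC expansion is a stop (TAR yes,
  TAN no).  This replaces profile-HMM placement: the contract is the
  flagging behaviour, not the HMM.  Caveat: a frameshift close to a
  sequence end can leave a stop-free minimum-stop frame, which is why
  flagging also checks indels (next point).
* **Indel flagging.** A sequence is FLAGGED if its best frame contains
  stops, or if glocal alignment against a packaged reference profile
  implies a net internal length shift not divisible by 3.  For
  alignment-based steps the orientation is chosen by alignment score
  against the profile, not by the stop-minimising strand — the
  stop-minimising frame of a frameshifted sequence is unreliable.
* **Rescue ladder.** Flagged records are first re-assembled with the
  Mott cutoff halved (stricter end-clipping; rescues artifacts confined
  to marginal-quality read ends).  If still flagged, single-base
  insertions relative to the reference profile are candidates for
  deletion: a base is deleted only if its quality is < Q20 *and* the
  deletion restores a stop-free frame, with at most two deletions per
  record.  Because gap placement inside repeats is ambiguous, the
  candidate set is widened to ±8 bases around each reported insertion
  column, ordered by quality; in rare repeat contexts this can delete a
  neighbouring low-quality base rather than the exact artifact base,
  which restores the frame but may leave one substitution.  High-quality
  insertions are never deleted; failure to rescue leaves the record in
  the stop/indel failure category.  Deleted positions are recorded on
  the barcode for audit.

## Taxonomy screen

The packaged reference library (synthetic sequences, taxon labels with
an `earthworm`/`other` group tag) stands in for live NCBI/BOLD queries;
this makes runs deterministic and download-free at the cost of realism
of the subject sequences.  Queries are aligned glocally (query global,
subject end gaps free); identity is matches over aligned non-gap
columns, with columns containing N or an IUPAC code excluded from both
numerator and denominator — so conservative N-masking never changes an
assignment.  Best hit by identity, then aligned length, then
lexicographic taxon.  A non-earthworm top hit means contamination.  For
samples whose contig failed, the individual clipped traces are screened
the same way, but a trace is only called contaminated at ≥ 80% identity
— below that floor a garbage trace matches nothing meaningfully and the
sample stays in the unusable-contig category.  Species assignment uses
an inclusive 97% cutoff (configurable to 98); earthworm hits below the
cutoff are reported as low-confidence with the top taxon retained as
putative, and such barcodes remain functional.

The dual-database consensus question (what happens when two databases
disagree) is not modelled: one library, one top hit.

## Quality criteria and rates

Reference quality requires all five of: length > 500 bp (strict),
ambiguous bases < 1% (strict), non-N bidirectional coverage ≥ 40%
(inclusive), contiguous high-quality bases across > 75% (strict), and
QS > 30 (strict).  Two readings of the fourth criterion exist; this
package computes both (`pct_contiguous_hq`: the longest run of
Phred > 20 bases as a fraction of contig length; `pct_hq_total`: the
overall fraction of such bases) and classifies on the *run*
interpretation.  QS averages the per-base qualities of all called
positions, including positions holding `N`.

Rates are reported as (numerator, denominator, percentage), percentage
rounded half-up to one decimal — so 26/39 prints as 66.7.  Tiers:
amplification success = amplified/attempted; sequencing success =
functional/amplified; recovery overall = reference-quality/attempted;
recovery within primary = reference-quality/functional.  Zero
denominators report as undefined (`None`), never as 0.

Concordance compares normalized binomials (case-insensitive
genus + species, subspecies/lineage suffixes ignored).  A specimen is
concordant only if all of its functional barcodes are.

Sequencing error between two barcodes of one specimen is
`100 × p-distance` on their pairwise alignment (free end gaps — the two
barcodes legitimately differ in terminal coverage).  Pairwise alignment
is used rather than the study-wide MSA because intra-specimen pairs are
near-identical and the error table is defined pairwise.

## Clustering

The MSA is built by reference-anchored stacking: each sequence is
aligned pairwise to a common reference (the longest input by default)
and projected onto reference coordinates; insertions relative to the
reference are dropped.  For barcodes without true indels — the case
here by construction — this is exactly the column-homologous alignment
a progressive aligner would produce, with a fixed column count; it is
*not* a general-purpose MSA for indel-rich data.

Neighbor joining is the canonical Saitou–Nei agglomeration on
p-distances with pairwise deletion.  Q-matrix ties break toward the
lexicographically smallest label pair (the Q matrix is explicitly
symmetrized first, since floating-point evaluation order otherwise
makes exact ties orientation-dependent).  Negative branch lengths are
clamped to zero with the deficit moved to the sister edge, preserving
the pair distance.  Bootstrap resamples alignment columns with
replacement; support is the percentage of replicate trees containing
each original bipartition.  The default is 10,000 replicates; tests and
the packaged examples use 25–200 (documented wherever scaled down).  In
a replicate where a pair loses all comparable columns, its distance is
substituted with 0.75 (the uninformative maximum) rather than aborting
the replicate.

The audit asks: (a) per specimen with ≥ 2 barcodes, whether its
barcodes form a clade — specimens interleaved only with zero-distance
(identical) sequences are reported separately, since identical
sequences have no resolvable order; (b) per method, whether any clade
of ≥ 4 barcodes is method-pure, which would be evidence that the
collection method, not the organism, structures the tree.  The
"supports above 50 are shown" convention applies to rendering only; all
supports are retained.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes:

* One ~658 bp stop-free coding haplotype per specimen (frame offset 1),
  drawn from a packaged pool of eight synthetic "earthworm-like"
  species sequences (an ancestor mutated at ~10–12%, congeners ~4%
  within genus) with 0.5% intraspecific divergence per specimen.  All
  sequences are synthetic; taxon labels are real earthworm binomials
  used as labels only.
* Per-read quality: a Q40 plateau with linear decay to Q8 over the
  first 20 and last 120 bases, mimicking Sanger end degradation; errors
  are substitutions at the Phred-implied rate `10^(−Q/10)`.  No real
  instrument was calibrated against — the profile exists to exercise
  the clipping and consensus thresholds.
* Per-method events, drawn once per sample (amplification failure
  unconditionally; then one of contamination / unusable assembly /
  frameshift, conditional on amplification): the default probabilities
  are the observed per-method failure frequencies of the motivating
  study (e.g. swabs: 1/40, 7/39, 2/39, 4/39).  Contamination replaces
  the template with a draw from a non-earthworm spectrum (nematode,
  fungus, insect, human stand-ins) at ~1% divergence from the library
  entry.  Unusable assembly is simulated by degrading the reverse trace
  below the clipping floor.  Frameshifts insert one base at an interior
  position; at the default insertion quality (Q45) they are
  deliberately unrescuable and end as stop/indel failures, at Q < 20
  they exercise the rescue path instead.
* A truth manifest records every sample's template, injected event and
  expected final status.

Not emulated: chromatogram waveforms, PCR chemistry, heteroplasmy
(assumed rare in earthworm mitochondrial COI), mixed templates within
one trace, and real database subject sequences.  A green end-to-end
test therefore establishes that the pipeline's decision rules recover
the generator's ground truth under Phred-faithful noise — not that the
thresholds are optimal for any particular instrument's chromatograms.

## Determinism

All randomness flows from a single seed (`numpy.random.default_rng`);
the same configuration and inputs produce byte-identical JSON reports,
and bootstrap supports are reproducible for a fixed seed and replicate
count.

## Known limitations

* The stacking MSA drops insertions relative to its reference; it is
  unsuitable for sequence sets with real indels.
* Frame placement by minimum stop count can miss frameshifts within
  ~50 bp of a sequence end when no stop arises; the reference-profile
  length check catches most but not all of these.
* The insertion-rescue window heuristic (±8 bp) can, in repeats, delete
  a low-quality neighbour of the true artifact base (frame restored,
  one residual substitution).
* Identity statistics against the packaged synthetic library are not
  comparable to identities against real reference databases.
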