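# wormcoi

Curation and method-comparison pipeline for earthworm COI Sanger
barcodes.

## The problem

DNA barcoding of earthworms (Lumbricidae and relatives) amplifies the
~658 bp Folmer fragment of mitochondrial *COI* with the LCO1490/HCO2198
primer pair and sequences it bidirectionally on Sanger instruments.
When several DNA collection methods are compared on the same specimens —
here lethal tissue extraction with Chelex or a silica-column kit versus
non-lethal body-surface swabbing — the question is not just whether a
method yields *a* sequence, but whether it yields a **functional
barcode** (usable for species identification) and, stricter still, a
**reference-quality barcode** (fit for deposition in a reference
library). `wormcoi` implements that curation and comparison workflow as
a reusable library with a thin CLI:

1. **Assembly** — primer trimming, modified-Mott quality end-clipping
   (cutoff 0.05 on the per-base error probability), semi-global overlap
   alignment of the forward read against the reverse-complemented
   reverse read, and a quality-based consensus.  Strand conflicts are
   written conservatively as `N`; both strand calls are retained so that
   diagnostic sites can later be re-annotated with IUPAC codes.
2. **Frame QC** — placement into the COI-5P reading frame (invertebrate
   mitochondrial code, translation table 5), stop-codon/indel flagging,
   re-assembly with stricter end-clipping, and conservative
   reference-guided deletion of low-quality (< Q20) single-base
   insertions, capped at two deletions.
3. **Taxonomy screen** — glocal homology search against a packaged,
   taxon-annotated reference library (a deterministic stand-in for live
   NCBI BLAST / BOLD queries).  Top hits outside the earthworm group are
   flagged as contamination; earthworm hits are assigned to species at a
   97% (configurable 97–98%) identity cutoff.
4. **Classification** — every amplified sample ends in exactly one
   status: reference quality, functional low quality, or one of three
   failure categories (unusable contig, stop codons/indels,
   contamination).  Reference quality requires all five criteria:
   length > 500 bp, ambiguous bases < 1%, non-N bidirectional coverage
   ≥ 40%, a contiguous run of Phred > 20 bases spanning > 75% of the
   contig, and mean quality score (QS) > 30.
5. **Statistics** — tiered per-method rates (amplification success,
   sequencing success, reference-quality recovery overall and within the
   primary dataset), genetic-data-vs-morphospecies concordance at the
   barcode and specimen level, per-method identity summaries, and
   intra-specimen sequencing error: `error % = 100 − PID` with
   `PID = (1 − p) × 100`, where `p` is the p-distance under pairwise
   deletion of gaps and ambiguous positions.
6. **Clustering audit** — multiple alignment of the primary dataset,
   Saitou–Nei neighbor joining on p-distances, column bootstrap
   (10,000 replicates by default), and two audit questions: do each
   specimen's barcodes form a clade, and does any sizeable clade consist
   of a single collection method (which would mean the collection method
   biased the sequences)?

A first-class synthetic-study generator (`wormcoi.synthetic_data`)
produces FASTQ trace pairs with Sanger-style end-of-read quality decay,
per-method event probabilities (amplification failure, unusable
assembly, frameshift artifacts, contamination — defaults follow the
observed frequencies of the motivating three-method study), and a
ground-truth manifest for auditing the classifier.

## Worked example

```
wormcoi simulate --n-specimens 40 --seed 1 --out-dir sim
wormcoi run --fastq sim/reads.fastq --metadata sim/metadata.tsv \
            --out-dir out --seed 1 --bootstrap-reps 200
wormcoi report --report out/report.json
```

or equivalently in Python:

```python
from wormcoi import PipelineConfig, SimulationConfig, generate_study, run_pipeline

study = generate_study(SimulationConfig(n_specimens=40, seed=1))
result = run_pipeline(PipelineConfig(study=study, bootstrap_reps=200, seed=1))
```

With seed 1 this prints / reports:

```
sequencing success: 94/116 (81.0%)
primary dataset: 94 barcodes
method clustering detected: False
```

Reading the report: of 120 amplification attempts, 4 swab samples
failed to amplify (36/40 = 90.0% amplification success for swabs, 100%
for both tissue methods).  Of the 116 amplified samples, 22 fell into a
failure category — e.g. for Swab-QIAGEN: 3 unusable contigs, 1 stop/
indel failure and 7 contaminated samples, giving a per-method sequencing
success of 25/36 (69.4%) versus 37/40 (92.5%) for Tissue-Chelex — so
the primary dataset holds 94 functional barcodes.  Mean intra-specimen
sequencing error is ~0.01–0.02% (the generator's residual base-call
noise), genetic/morphospecies concordance is 100% (no misidentification
was simulated), all 36 specimens with two or more barcodes are
monophyletic on the NJ tree, and no method-pure clade of four or more
barcodes exists — the collection methods do not structure the tree.

## Acceptance script

`scripts/acceptance.py` re-runs the package end-to-end from scratch: it
generates a fresh 40-specimen synthetic study with the default
(study-derived) event probabilities, executes the full pipeline —
assembly, frame QC, taxonomy screening, quality classification, rates,
concordance, sequencing error, and the NJ/bootstrap clustering audit
(bootstrap scaled to 200 replicates for runtime) — and writes the JSON
result file:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
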