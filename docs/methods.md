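# Methods

## Model and pipeline

`somaticnet` classifies candidate variants from a tumor sample without a
matched normal into somatic vs non-somatic. The pipeline has three stages.

**Population filtering.** Candidates are matched exactly against a germline
population VCF on normalized `(chrom, pos, ref, alt)` keys (shared allele
suffix trimmed, then shared prefix, keeping one anchor base — the minimal
left-anchored VCF representation; the operation is idempotent and verified
against a brute-force trimming oracle). A candidate is removed when present
with AF above `max_af`; at the default `max_af = 0` every database-present
candidate is removed, including presence-only records without an AF value.
Duplicate database keys keep the maximum AF (the conservative choice for a
filter). There is no fuzzy INDEL matching: filtering stays deterministic and
auditable. Multiallelic records are decomposed per ALT before normalization.
Coordinates are 1-based inclusive at VCF boundaries and 0-based half-open
internally.

**Encoding.** Reads overlapping the variant column (excluding unmapped,
QC-fail and duplicate flags, 0x4|0x200|0x400) become a `14×150×70` tensor:

- channels 0–3: reference one-hot over the 150-bp window, replicated into
  every real read row; all-zero on insertion columns and padding rows;
- channels 4–7: p-hot base qualities — called base `1−e`, others `e/3`,
  `e = 10^(−Q/10)`; the four channels sum to 1 (to float32 machine
  precision) wherever a base is present, and are all-zero on gaps;
- channels 8–13: binary flags 0x2, 0x8, 0x10, 0x20, 0x100, 0x800, constant
  over the read's aligned span.

The variant column is index 75 (`⌊W/2⌋`). Insertions of length k insert k
all-zero reference columns after the anchor; reads lacking the insertion
show gaps there. Alt support is: base equality at the variant column (SNP),
a CIGAR insertion of length k at the anchor (INS), or a CIGAR deletion
spanning the first deleted base (DEL). Soft-clipped bases are never placed.
Pileups deeper than `H = 70` are cropped by removing the (alt, non-alt)
split that minimizes the VAF change — bounded by `1/H` and checked against
a brute-force minimizer; within a class, reads with the least window
overlap go first, then input order, so encoding is deterministic. Rows are
sorted by variant-column symbol in group order A, C, G, T, gap (reads
whose alignment is deleted or absent at the column form the gap group),
padding rows last, stable within groups. Pre-crop VAF and depth are kept
and reported.

**Flanking meta features.** Up to two germline flanking variants per side
qualify by population AF > 10% within ±2 Mbp (the 4-Mbp window is read as a
total span), nearest first; annotation happens before filtering so flanks
that will be removed still contribute. Flank VAF/DP are re-measured from
the tumor BAM with the same read filters — the feature of interest is the
*local sample* allele fraction (which tracks copy-number shifts), not the
population frequency and not a caller's reported value. The meta vector is
`[candidate, L1, L2, R1, R2] × (VAF, DP/H)`; depths are scaled by `1/H` so
all ten entries are O(1). A zero-flanking switch zeroes the eight flanking
entries for ablation runs.

**Classifier.** Four 3×3 convolution layers (channels 14→8→16→32→32, ReLU,
2×2 max-pooling) over the tensor; the output is flattened, concatenated
with the 10-value meta vector, and passed through dense layers 64→32→16→1
with a final sigmoid. Training: binary cross-entropy, AdamW (lr 1e-3,
weight decay 1e-2), mini-batches of 32, 15 epochs then 5 more at lr/10,
minority class upsampled to parity by per-epoch sampling with replacement.
Dropout 0.3 on hidden dense layers curbs the overfitting that a ~2k-tensor
training set otherwise invites. The network is implemented directly on
NumPy: convolutions run as k² shifted GEMMs against contiguous flattened
views in channel-first layout, which is the memory-friendly formulation for
a single CPU; gradients were verified against numerical differentiation.

*Quality-channel conditioning.* Raw p-hot values compress the informative
part of base-quality information into a sliver near 0 and 1 (Q30 vs Q40 is
0.999 vs 0.9999): gradient descent discovers such directions unreliably.
The model input stage therefore maps the four quality channels back into
the Phred (log) domain, `x → 1 + log10(x)/5` clipped to [0, 1] with zeros
preserved, where the same information is linear in Q. This is an internal,
fixed, monotone reparameterization of the model input; the stored tensors
and their invariants are unchanged.

Conv/dense widths, kernel, pooling, dropout and the quality transform are
configuration; the defaults above are the package's own, sized so the
reference experiment trains in minutes on one CPU.

## Evaluation protocol

Per sample (patient): ROC-AUC over post-filter candidates (equal to the
tie-corrected rank statistic; asserted against brute-force pair counting).
The f1-score uses the strict rule "call somatic iff score > t"; its recall
denominator is the number of true somatic variants *before* population
filtering, so filter losses count as misses. The operating threshold is
chosen by maximizing f1 per sample over the observed-score grid (ties →
lowest t, which favors recall), taking the median across non-excluded
samples, and recomputing every sample's f1 there. Samples with fewer than
10 positive or 10 negative post-filter labels are excluded from both the
metrics and the median (the latter is a package decision; the protocol
leaves it open). Somatic-vs-germline and somatic-vs-artifact views subset
the labels and choose separate cutoffs. Cross-validation splits are made at
the sample level with a seeded shuffle, fold sizes differing by at most one.

## Mutational signatures

A mutation class is (3-bp reference context, alternate base): 192 classes
by default — the literal class space without strand collapsing — with a
96-class pyrimidine-centered COSMIC-style collapse as an option. Signatures
are class frequencies over an SNV pool; genome normalization divides each
class by its context's occurrence count in the reference (both strands in
collapsed mode) and renormalizes to a probability vector — renormalization
is required for divergence computations; zero-occurrence contexts get
probability 0 with a warning. Signature distance is the Jensen–Shannon
divergence with base-2 logarithm (symmetric, in [0, 1], 0 iff equal).

## Hard-to-map annotation

A variant is H2M if it (i) sits inside a repeat more than one read length
from *both* repeat edges (the stricter of the two readings of the edge
rule — a read anchored outside the repeat cannot span it), (ii) overlaps a
variant hotspot, (iii) overlaps a mappability interval with score < 1.0
(interval+score BED, converted externally from source tracks), or
(iv) overlaps a problematic-gene interval. Tracks are plain BED (0-based
half-open); any malformed line aborts with its line number.

## Synthetic cohorts

The simulator emulates the statistical structure the classifier exploits,
one contig per sample, sites spaced ≥ 2 read lengths so planted depths are
exact:

- **somatic**: VAF ~ Beta(4, 14) (mean 0.22, the low-VAF clonal regime);
- **germline**: heterozygous (80%) at a per-50-kbp block center drawn from
  N(0.5, 0.06) clipped to [0.3, 0.7] — a stand-in for copy-number driven
  local VAF shifts — or homozygous (20%) at VAF 1; 90% of germline variants
  enter the mock population DB with AF ~ U(0.12, 0.6) (all above the
  flanking cutoff), and 10% of somatic variants with AF ~ U(1e-4, 0.01),
  so filtering removes real somatic mass and the recall denominator
  matters;
- **artifact**: VAF ~ Beta(2.5, 30), alt reads with Phred lowered by 15 and
  reverse-strand probability 0.85 (an error-process caricature in which
  base quality is the discriminating feature).

Alt reads per site are Binomial(depth, VAF), depth ~ Poisson(40), reads
100 bp, base qualities ~ N(36, 3²) clipped to [2, 41], substitution errors
drawn at the Phred-implied rate. SNV contexts are drawn from class-specific
trinucleotide signatures (somatic: CpG C>T; germline: A>G; artifact: G>T;
each mixed with a uniform floor) and written into the reference, so the
drawn signature is exactly recoverable from the FASTA. 10% of somatic and
germline variants are 1–3-bp INDELs. A 2% duplicate-read fraction and 1%
mate-unmapped fraction exercise the flag filters. Reads are fixed-length
and ungapped except at planted INDELs, keeping CIGARs simple while still
exercising INS/DEL encoding.

What the simulator does *not* model: sequencer-specific error profiles,
mapping ambiguity (every read is placed at its true origin), overlapping
read pairs, real CNV segmentation, contamination. Passing tests therefore
demonstrate that the pipeline recovers planted structure under calibrated
noise — not performance on real tumor genomes.

## Reference experiment and problem sizes

The headline experiment (`somaticnet.pipeline.run_experiment`, also run by
`scripts/acceptance.py`) simulates 12 samples × 350 candidates
(120 somatic / 150 germline / 80 artifact), trains on ten samples
(~2 000 post-filter tensors) and evaluates the two held-out samples
(~400 tensors), with the default 15+5 epoch schedule — a deliberate
desk-scale configuration that completes in minutes on one CPU. Expected
outcome: held-out per-sample ROC-AUC ≥ 0.90 driven jointly by VAF (meta
and row counts), base-quality and strand channels, and context signatures.

## Numerical choices and degenerate inputs

- Crop split ties resolve toward fewer alt reads; threshold-grid f1 ties
  toward the lowest threshold.
- Zero-coverage sites produce an all-zero padded tensor flagged
  low-coverage with VAF = DP = 0.
- Single-class score sets make ROC-AUC undefined: an error, not a default.
- All randomness flows from explicit seeds (`numpy.random.default_rng`);
  identical seeds give byte-identical simulator output and bit-identical
  tensors and scores.
- Checkpoints store weights plus model and pileup configuration; predicting
  with a tensor archive whose pileup-configuration hash differs from the
  checkpoint's is refused.

## Known limitations

- The naive candidate enumerator calls every position with ≥ 1 alt read; it
  is maximal-sensitivity by design and unusable without the downstream
  classifier.
- Mate-overlap double counting is not deduplicated (both mates pass the
  stated read filters); documented, matching the filter definition.
- The NumPy network targets desk-scale cohorts; it does not attempt
  GPU-scale training runs or hyperparameter search.
- FILTER-failed VCF records are consumed (and logged): upstream caller
  filters are treated as advisory, since the classifier is the filter here.
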