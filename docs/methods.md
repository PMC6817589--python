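# Methods

## Model

The package treats TCR recognition of a 9-mer peptide–MHC complex as
first-order additive over peptide positions. A replacement scan measures
every single-residue substitution of the epitope at the non-anchor
positions P = {1,3,4,5,6,7,8} in three assays (binding, activation,
killing); per-assay position weight matrices normalize those measurements
to the epitope signal, and a query peptide's score is the normalized sum of
its per-position weights. The model deliberately ignores epistasis between
substitutions: a peptide with several edits is scored as if each edit acted
independently. This is the model's central assumption and its main known
limitation — strongly coupled positions (e.g. residues that repack the
peptide backbone together) are invisible to it.

Anchor positions P2 and P9 bind the HLA-A\*02:01 groove rather than the
TCR. They are held fixed in the scan, excluded from scoring, and not stored
in the PWM at all; storing and ignoring them would invite accidental use.
MHC presentation is handled entirely by the upstream affinity table
(precomputed IC50 predictions supplied as input): recognition scoring and
presentation filtering are orthogonal stages.

## PWM construction details

* Background subtraction is per replicate, before averaging. The
  measurement schema therefore carries one background column per replicate
  row; an assay-wide background is the special case of equal values.
* Normalized weights are clamped to [0, 100] after normalization; the
  replicate values themselves are never clamped.
* The epitope residue at each scored position is pinned to exactly 100,
  which makes the epitope the realized maximum and the score normalization
  exact.
* A non-positive epitope signal after background correction makes the
  normalization undefined and raises rather than producing garbage.
* Unmeasured cells should not occur with a complete 134-peptide library;
  when they do, the default imputes 0 (unmeasured ⇒ treated as not
  recognized, the conservative choice for an off-target screen, since PWM
  weights only ever *add* recognition) with a logged count, and a strict
  mode raises instead.

## Scoring choices

* The score denominator is the theoretical maximum 100·|P| rather than the
  epitope's realized sum. The two coincide for scan-derived PWMs (epitope
  cells are pinned), but the theoretical form also normalizes alanine-mode
  PWMs, where permissive columns put 100 in every row.
* PWM similarity is the plain Pearson correlation over the flattened
  20×|P| cell vectors. Published variants optimized for motif comparison
  differ mainly in column weighting; with identical shapes and a shared
  epitope, plain Pearson is the transparent choice.
* The per-assay scores are fused by arithmetic mean *after* scoring each
  peptide (not by averaging the PWMs first); with a common denominator the
  two orders agree, but score-level fusion keeps the per-assay scores
  reportable.
* The edit-distance reference defaults to the wild-type epitope SLLMWITQC,
  while the scanning epitope is the anchor-optimized SLLMWITQV; these are
  distinct configuration fields because they serve different purposes
  (biological identity vs. assay construct).
* Peptides containing B/J/O/U/X/Z are never scored; the proteome scanner
  skips windows containing them and counts the skips, and the scorer raises
  on them explicitly rather than silently zeroing.

## Classifier

Labels derive from observed activation normalized to the epitope: a
peptide is "activating" when it exceeds 0.75 (configurable). The ROC sweep
uses the rule "positive iff score ≥ threshold" over the unique scores plus
a +∞ sentinel; AUC is the Mann–Whitney statistic with half credit for
ties. Cutoff selection maximizes sensitivity first because a false
negative (a missed off-target peptide) is the costly error in a safety
screen; among max-sensitivity thresholds the one with maximal specificity
is taken, remaining ties resolve to the largest threshold. The positive
call is boundary-inclusive so the selected cutoff is always a realized
score and sensitivity 1 is always attainable.

## Synthetic data

The generator emulates the structure of a real replacement-scan study:

* **Kernel** (`make_kernel`): epitope residues at 100; at *critical*
  positions (default P5 and P8, the motif-defining residues) all other
  residues draw uniform(0, 10); at tolerant positions uniform(10, 90).
* **Measurements**: for each of the 134 library peptides and each assay,
  true signal = background (2% positive cells) + 60% × the kernel-implied
  fraction; each of 3 replicates is multiplied by log-normal noise with
  10% CV (assay read-outs are positive and right-skewed; additive Gaussian
  noise is available as an option), and the background column is drawn per
  replicate the same way. With zero noise, PWM construction inverts the
  simulation exactly.
* **Proteome**: 2,000 uniform-composition proteins of 300 aa (the "small"
  scenario uses 300 proteins), with the scanning epitope and 10 designed
  cross-reactive peptides each embedded once at recorded positions. The
  planted peptides keep the critical residues and substitute one or two
  tolerant positions with the best-tolerated non-epitope residue, so their
  intended scores stay high (≈0.94–0.99) while sequences are distinct.
* **Affinity**: peptides matching the anchor rule (P2 ∈ {L, M},
  P9 ∈ {V, L, C}) draw IC50 log-uniform in (1, 500] nM, others in
  (500, 50000] nM, so ~1.5% of random decoys pass the 500 nM filter.
* **Outcomes**: peptides at or above the scenario's true cutoff (0.85)
  activate strongly (0.85–1.25 of epitope), others weakly (0–0.12), with
  optional label flips.
* All generators are pure functions of (scenario, seed); sub-streams are
  tagged so the proteome, affinities and noise never share a random
  stream. Default seed: 20191022.

What the synthetic data does **not** emulate: realistic amino-acid
composition, proteolytic processing and TAP transport, real HLA binding
energetics, assay-specific systematic biases, or epistasis. Passing tests
on synthetic data demonstrate the pipeline's correctness and end-to-end
recoverability under the stated noise model — not predictive accuracy on
real proteomes, which depends on assay quality and the upstream affinity
predictor.

## Numerical and design choices

* PWM files store entries to 12 significant digits; round-trips reproduce
  them to that precision. Reports use fixed float formats and embed the
  resolved configuration, so identical configs give byte-identical output.
* Ranking ties break lexicographically by sequence; rank order is
  invariant under input permutation.
* Affinity-table duplicate peptides keep the minimum IC50 (the
  conservative, binder-favoring choice for a safety screen) with a logged
  warning; the boundary IC50 equal to the cutoff is retained as a binder.
* Score bins are half-open [lo, hi) with the last bin closed; the default
  edges (0.25, 0.40, 0.55, 0.70, 0.85, 1.00) give five groups matching the
  conventional low (0.25–0.4) and top (0.85–1) motif-analysis bins.
* The alanine-scan permissive threshold defaults to 0.5 of the epitope
  signal; "successful" alanine substitution has no standard quantitative
  definition, so the threshold is an explicit parameter.
* Expression annotation counts a tissue when *any* source gene of the
  peptide exceeds the TPM threshold there (a peptide is a risk if any gene
  presenting it is expressed).

## Problem sizes

The test suite and acceptance script run entirely on generated data: the
default end-to-end scenario scans 2,000 × 300 aa (584,000 windows, ~8,700
predicted binders) and completes in seconds; oracle suites use 1,000
scored peptides × 10 random PWMs and 500 random ROC instances of n ≤ 20.
These sizes were chosen to exercise every code path, including
deduplication and provenance merging, while keeping the suite fast.
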