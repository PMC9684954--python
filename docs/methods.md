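# Methods

This note documents the models and procedures decaykit implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## 1. Consensus half-life from a multi-study compendium

Transcriptome-wide half-life measurements disagree across laboratories and
protocols: pulse-labeling experiments (4sU, BrU, 5EU) and
transcriptional-shutoff experiments (ActD, α-Amanitin) carry systematic,
method-class-level biases, and every study has its own dynamic range,
units, and gene coverage. The `compendium` module harmonizes a sparse
gene × sample matrix in a fixed stage order:

1. **Transform.** Half-lives are log10-transformed after a pseudocount —
   0.1 when the sample's unit is hours, 1 when minutes — chosen so the
   transform is stable near zero on either unit scale. Samples deposited
   as degradation rates are monotonically *decreasing* in half-life; when
   their values are strictly positive they are transformed as
   −log10(v + pseudocount), and when a rate sample contains non-positive
   values it is taken to be on a log scale already and only negated.
   Duplicated gene IDs are averaged after the transform. The log base is
   immaterial: each sample is z-scored later, which removes any constant
   scale factor, and the test suite asserts consensus scores from log10
   and natural-log preprocessing agree to 1e-8.
2. **Filter.** Keep genes with at least `min_samples` non-missing values
   (10 for the human compendium, 5 for mouse — roughly a quarter of the
   respective sample counts).
3. **Standardize.** z-score each sample over its observed entries
   (sample standard deviation, n−1 denominator; the choice is absorbed by
   the later quantile normalization).
4. **Impute.** Missing cells are completed by EM-style iterative PCA:
   initialize with column means, then alternate a rank-`ncp` SVD
   reconstruction of the completed matrix with overwriting of the missing
   cells only, until the largest change on a missing cell falls below
   1e-6 (at most 1000 iterations by default). The retained singular
   values are shrunk by the mean discarded noise variance
   (s ← (s² − σ̄²)/s); this regularized form is the standard variant of
   the procedure, prevents the EM from chasing noise directions, and
   vanishes on exactly low-rank input, so the noiseless rank-1 oracle
   test recovers masked cells to better than 1e-6. `ncp` is chosen over
   0..`ncp_max` (20 human / 10 mouse, always below the sample count) by
   K-fold cross-validation (default K = 5, seed-controlled): a fold of
   *observed* cells is additionally masked, each candidate rank imputes
   it, and the rank with the lowest mean squared error wins. Candidate
   scoring runs at a relaxed step tolerance (1e-4) because only the MSE
   ranking matters. Observed cells are bit-identical to the input.
5. **Quantile-normalize.** Every sample column is mapped onto the mean of
   the column order statistics. Ties receive the average of their tied
   reference quantiles; with continuous data (ties have measure zero) the
   sorted value vector of every column is exactly the reference.
6. **Consensus PC1.** PCA over the normalized matrix with samples as
   variables (columns centered, not scaled). The per-gene PC1 scores are
   the consensus half-life. The PC1 sign is anchored so that scores
   correlate positively with per-gene means — necessary because
   rate-deposited samples make the global orientation ambiguous. A
   consequence worth stating: the anchor follows the data's orientation,
   so feeding a matrix in "rate sense" (all columns negated) yields
   negated scores. PC2 and PC3 are not used as phenotypes.

Two statistical probes quantify what harmonization removed.
`method_bias_test` averages a chosen sample-space PC within
(study, method class) and compares the two classes by an exact two-sided
Wilcoxon rank-sum test; which PC separates the classes depends on the
data set (on the synthetic compendium the shared latent is removed by
gene-centering, so the class bias dominates PC1). `celltype_specificity_test`
computes Pearson correlations for every cross-study sample pair —
same-study pairs are excluded as replicate-inflated — and asks, one-sided,
whether same-cell-type pairs correlate more than different-cell-type pairs;
it accepts either the imputed matrix or a pre-imputation matrix (then using
pairwise-complete genes), because the two variants answer slightly
different questions about where the signal lives.

## 2. Transcript models and feature extraction

One representative mRNA per gene: among annotated coding transcripts, the
longest ORF wins, then the longest 5′UTR, then the longest 3′UTR, and any
residual tie goes to the lexicographically smallest transcript ID for
reproducibility. Coordinates are 0-based half-open internally; GTF input
is 1-based closed and converted on ingestion; minus-strand genes are
reverse-complemented so spliced coordinates always run 5′→3′ in mRNA
sense. Ensembl-style GTFs exclude the stop codon from the CDS, so the
ingester extends the ORF by 3 nt when the next in-frame triplet is a stop
codon; the ORF therefore includes the stop, which is why the
codon-frequency denominator counts stop codons. T is normalized to U;
ambiguity codes other than N are rejected.

Feature groups (single-letter labels compose model codes like "BC3MS"):

* **B — basic (8).** G/C fraction of 5′UTR/ORF/3′UTR (undefined for an
  empty region), log10(x+0.1)-transformed lengths of the three regions
  and of the total intron content, and ORF exon-junction density =
  junctions strictly inside the ORF per kilobase of ORF.
* **C — codons (61).** Non-overlapping codon frequencies over the ORF,
  normalized by the total codon count *including* stops, with the three
  stop codons then dropped. Codons containing N are excluded from both
  numerator and denominator.
* **5/O/3 — k-mers (21,844 per region).** Overlapping k-mer counts for
  k = 1..7, normalized within each k so each k forms a proper
  distribution (a region shorter than k contributes zeros). Windows
  containing N are excluded from numerator and denominator.
* **Windowed predictor scores.** A pluggable scorer is applied to 50-nt
  tiles of a region, each padded with 475 nt (1000-nt input mode) or
  50 nt (150-nt mode) of neighboring *transcript* sequence — N where the
  transcript ends — and per-factor sums are divided by the region length.
* **Peak counts.** Strand-aware ≥1-bp overlap counts of peak calls
  against gene bodies (union span of the gene's transcripts),
  log10(x+1)-transformed; genes without peaks count zero.
* **External score tables** attach with a declared transform — miRNA
  cumulative context++ scores are negated so larger means more
  repression; duplicate gene rows are averaged with a warning.
* **Missing-feature imputation.** Incomplete columns (e.g. RIP-seq
  enrichments covering a gene subset) are regressed on the complete basic
  features with a partial-least-squares linear predictor fit on observed
  rows; observed cells never change, and a column that is exactly linear
  in the anchors is recovered to 1e-6 (OLS oracle in the tests).

## 3. Lasso modeling and nested model comparison

Features and target are concatenated and z-scored globally — the
reproduction-faithful choice; a fold-wise option exists and warns that it
changes the estimator (global scaling leaks means/variances across folds,
a deliberate reproduction-vs-best-practice switch). For each of 10 outer
folds, the penalty λ is selected by inner 10-fold cross-validation over a
grid of 100 log-spaced values spanning four decades down from λ_max (the
smallest penalty with empty support), by minimum mean MSE (a 1-SE rule is
available); the model is refit at the chosen λ and scored by Pearson r on
the held-out fold. Degenerate folds (constant predictions) report r = 0
with a flag rather than NaN.

Nested comparisons test, for each declared (simpler, complex) pair, the
one-sided paired t-test on the 10 per-fold correlations (H1: complex >
simpler), Bonferroni-corrected over the declared number of comparisons.
Identical fold vectors give p = 1 (no evidence); a constant positive
improvement has zero variance and is reported as p = 0 (t → ∞
convention). Interpretation refits on the full data at a CV-chosen λ,
ranks coefficients by magnitude (top 30 by default), and reports, for
each top feature, every feature correlated with it at |r| ≥ 0.8 — lasso
picks one member of a collinear block essentially arbitrarily, so the
block, not the single coefficient, is the interpretable unit.

## 4. Saluki: the sequence model

**Encoding.** Each mRNA becomes an L_max × 6 matrix: one-hot A/C/G/U
(N and padding all-zero), a splice track marking the 5′-most nucleotide
of every non-first exon (junctions only; the transcript start is not
marked), and a codon track marking the first nucleotide of every codon,
which implicitly delimits the UTRs. Sequences longer than L_max keep
their 3′-most L_max nucleotides with all track coordinates shifted;
shorter sequences are zero-padded at the 3′ end.

**Architecture.** A width-5 convolution to C channels and a width-2 max
pool, then six blocks of [layer norm → ReLU → width-5 convolution →
dropout → width-2 max pool] — seven halvings, so at the published
L_max = 12,288 each of the 96 final positions summarizes 128 nt. Layer
normalization (not batch normalization) is used in the tower because the
abundant 3′ zero padding would corrupt batch statistics, whereas layer
norm is computed per position and keeps a zero vector (near) zero. After
a final layer norm + ReLU, a GRU (double-bias formulation, hidden width =
channels) consumes the sequence *backwards*, from the padded 3′ end to
the information-dense 5′ end, and its final hidden state summarizes the
mRNA. A shared dense block (batch norm → ReLU → dense without bias, the
bias being redundant before the following normalization) feeds one head
per species (batch norm → ReLU → dense → 1). At 64 channels the
per-species forward graph has exactly 155,521 trainable parameters; this
count is what fixes the block count at seven convolutions and the GRU
bias convention, both of which the architecture prose alone leaves open.

**Training.** MSE on per-species z-scored consensus values; Adam
(lr 1e-3, β₁ 0.9, β₂ 0.98) on batches of 64 with gradients clipped to
global norm 0.5, L2 weight decay 1e-3 on convolution/GRU/dense kernels
(not biases or normalization parameters), dropout 0.3. Human and mouse
batches strictly alternate through the shared trunk, each species
updating its own head; an epoch ends when the larger species is
exhausted and the smaller recycles. One fold is held out for testing,
the next (cyclically) for validation; early stopping keeps the
parameters with the best validation Pearson r (patience 25 epochs). Five
replicates per test fold give a 10 × 5 ensemble: held-out predictions
average the five replicates of the gene's own test fold, and predictions
for external sequences average all fifty members. A single master seed
fans out to weight initialization, dropout, and batch order, and two
runs with the same seed are bit-identical.

The network stack (convolution, pooling, normalizations, GRU, dense,
Adam, clipping) is implemented in numpy with hand-written backward
passes, verified against central finite differences in the test suite;
the package is self-contained and CPU-oriented.

**Scaled-down profile.** The test suite trains on the default synthetic
transcriptome (3,000 genes) at L_max = 1,024 with 32 channels — sizes
chosen so one member trains in minutes on a single CPU. The published
optimizer settings were themselves selected by validation accuracy at
full scale; re-doing that selection at the small scale favors a
shallower tower (5 pools, i.e. 32-nt final resolution — typical
synthetic mRNAs are ~900 nt, so this keeps roughly the full-scale ratio
of sequence length to pooled positions and leaves the recurrent unit
enough steps to accumulate junction and motif counts that max pooling
would otherwise saturate), learning rate 5e-3, dropout 0.1, and a
gradient-norm ceiling of 5. `decaykit.saluki.scaled_hyperparams()`
records this profile. Under it a single member clears held-out r = 0.5
well within 20 epochs; trained to early-stopping convergence (the same
procedure as at full scale) it reaches held-out r ≈ 0.9 on the synthetic
study, and its insertional probes rank the planted codon weights at
Spearman ρ ≈ 0.9. Interpretation analyses use the converged model, since
half-learned models rank weak effects (individual codons) poorly even
when their overall correlation is respectable.

## 5. Interrogation

All substitution probes preserve transcript length exactly and hold the
splice and codon tracks fixed — even for substitutions that would create
or destroy a stop codon (blanking the downstream codon track is possible
but produces disproportionate effects, so it is not done). Effects are
always Δ = prediction(alt) − prediction(ref): negative = destabilizing.

* **ISM** runs three forward passes per position (the three alternative
  bases; reference N positions yield NaN), batched 512 mutants at a time.
  Positions in the 3′ padding or 5′-truncated out of the window are
  errors. The metagene aggregates |mean-of-3 Δ| into percentile bins
  within each region, with transcripts grouped into quartiles of their
  predicted half-life.
* **Insertional scans** overwrite the reference with a k-mer at the first
  position of each of 50 equal bins per region (anchors whose k-mer would
  overrun the region are skipped); codon insertions anchor at the first
  in-frame codon start inside each ORF bin, and the per-codon mean over
  ORF bins is the quantity comparable to codon stability coefficients.
  The validity filter (5′UTR ≥ 100 nt, ORF ≥ 500 nt, 3′UTR ≥ 500 nt)
  matches real transcriptome scale; the scaled-down synthetic studies
  pass 50/300/150 explicitly, in proportion to their shorter mRNAs.
* **Splice-mark ablation** erases one splice-track mark and measures Δ —
  the direct probe of the junction effect, which nucleotide substitutions
  cannot reach.
* **Variant effects** are single substitutions checked against the
  transcript reference (mismatches are errors naming the observed base);
  per-position effect tracks can be smoothed by a centered moving average
  (window 8, shrinking at the edges).
* **Reporter constructs** splice a fragment into a scaffold's 3′UTR at a
  declared site (junctions downstream shift; an empty fragment reproduces
  the scaffold baseline exactly). The scaffold is a user input with a
  synthetic default, since real vector sequences are not part of this
  package.
* **Matched variant benchmarking** takes positives at fine-mapping
  PIP > 0.9 and matches each, without replacement, to a negative with
  PIP < 0.01 from the same transcript region but a different gene,
  minimizing the gene-expression difference; AUROC of the |Δ| ranking
  uses the midrank convention for ties.

## 6. The synthetic-data generator

`gen_transcriptome` samples region lengths log-normally (5′UTR ~110 nt,
ORF ~170 codons, 3′UTR ~260 nt medians), builds ORFs as AUG + non-stop
codons + stop, places exon junctions uniformly on the spliced sequence
(exon count 1 + Poisson(4)), assigns half the genes to the minus strand,
and emits genome-style FASTA (one contig per gene, introns included) plus
an Ensembl-dialect GTF so the real ingestion path is exercised; the
round trip is asserted to be exact.

`gen_latent_halflives` defines the planted truth on the log scale:

    latent = 0.12 · (ORF junctions per kb)
           + Σ_c w_c · codon frequency_c
           + Σ occurrences of UAUUUAU in the 3′UTR: −0.5 · (2p−1)²
           + Σ occurrences of UGUAAAUA in the 3′UTR: −0.4
           + ε,  ε ~ N(0, 0.1²)

where p is the occurrence's position as a fraction of the 3′UTR (the
U-shaped weight peaks at the region termini) and w is a fixed, seeded
draw with spread 4 (so the codon term's across-gene dispersion is
comparable to the junction and motif terms). Motifs are planted at
Poisson rates (0.8 and 0.5 per gene) *and* the latent is computed by
scanning the final sequence, so chance occurrences count identically and
the latent is a true function of the emitted sequence. Every term and
the noise draw are recorded in a per-gene ledger that reconstructs the
latent exactly.

`gen_compendium_matrix` converts latent values to per-sample
measurements: z-scaled latent + per-study offset (sd 0.2) + a gene-wise
bias vector (sd 0.4 by default) shared by all transcriptional-shutoff
samples + gene × cell-type effects (sd 0.3) + noise (sd 0.5), passed
through a rank-preserving cubic distortion v + b·v³ (b uniform in
[0, 0.1] per sample), mapped to hours as 10^(0.35·v+0.6) and then to the
sample's unit (minutes ×60; degradation rates as ln2/hours), with 30%
of cells dropped (optionally length-biased, mimicking length-dependent
labeling and enrichment biases). Defaults: 20 samples from 10 studies
(one method per study, five per method class, so a strong class bias can
reach exact-test significance), four cell types shared across studies.

**What passing on synthetic data does and does not show.** The generator
emulates additive, sequence-scannable determinants with known effect
signs, batch structure, and monotone distortions. It does not emulate
realistic nucleotide composition beyond a GC knob, RNA structure,
cooperative or saturating motif interactions, expression-coupled
measurement error, or raw-read noise; recovery here demonstrates that the
pipeline and models are implemented correctly and can extract planted
signal at realistic noise levels — not that the learned biology
transfers to real transcriptomes.

## 7. Problem sizes used by the test and acceptance suites

Chosen so the full suite completes comfortably on one CPU: consensus
recovery at 2,000 genes × 20 samples (ncp grid 0..5); network study at
3,000 genes, L_max 1,024, 32 channels, one member, ≤20 epochs;
insertional probes on validity-filtered mRNAs with 10 positional bins
(the probe set size is noted in the relevant tests; per-codon insertion
means are averages over bins × mRNAs, and their ranking stabilizes as
the probe set grows). The deposited-data checks (gene counts after
filtering; PC1 variance fractions) run only when the published
supplementary tables are present under `data/supplementary/`.

## 8. Known limitations

* The numpy network trains on one CPU thread through BLAS; full-scale
  training (12,288-nt windows, 50 members) is out of intended scope.
* `method_bias_test` presumes the caller selects the PC that carries the
  method contrast; it does not search PCs.
* Quantile normalization's exact column-identity property holds for
  tie-free data; ties (measure zero for continuous inputs) are averaged.
* The eQTL-style benchmark implements the matching rule only; assembling
  real fine-mapped variant sets is the caller's responsibility.
* Reporter simulations depend on the user-supplied scaffold; the
  synthetic default is labelled as such.
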