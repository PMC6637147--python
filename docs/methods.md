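# Methods

This note documents the statistical models, algorithms and design choices in
`cpf1screen`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, with which
defaults, and what the built-in synthetic data can and cannot establish.

## Screen data model

A pooled CRISPR dropout screen is represented by three objects:

- **GuideLibrary** — constructs mapping genes to ordered 20-nt protospacers.
  Three architectures are supported: `cas9_mono` and `cpf1_mono` (exactly one
  guide per vector) and `cpf1_multi` (a crRNA array of 1–7 guides, all
  targeting the same gene, processed by Cpf1 itself). Guide order within an
  array is preserved because the cistron position matters for oligo assembly
  and downstream QC. Constructs labelled `NonTargeting` are negative
  controls: retained at construct level, excluded from all gene-level
  statistics.
- **CountMatrix** — integer read counts per construct and sample. Samples
  are labelled `T<k>_R<j>` (timepoint, replicate) plus one reference sample
  `T0_ref_R<j>` per replicate, taken at screen start. The one-reference-
  per-replicate contract is validated at construction. Whether the
  reference is truly per-replicate or shared pre-split is not determined by
  the screen design itself; per-replicate is the default because replicate
  fold changes are then fully independent, and a shared reference can be
  represented by duplicating the column.
- **ReferenceSets** — gold-standard essential / non-essential gene sets,
  validated disjoint and non-empty. The benchmark sets used throughout are
  342 core-essential and 345 non-essential genes; their prevalence
  342/687 = 0.4978 anchors the null precision-recall baseline (below).

File formats are deliberately minimal: tab-separated, UTF-8, one header row,
`#` comments skipped. Ragged multiplexed arrays are stored with trailing
empty cells, never placeholder sequences, and the writer round-trips the
canonical dialect byte-identically.

## Synthetic screen generator

The simulator exists so that every analysis stage has a testable ground
truth. Its generative model, per `SimConfig`:

1. Each gene gets `guides_per_gene` guides; each guide is independently
   functional with probability `p_active_guide` (default 0.32, the
   mono-cistronic AsCpf1 regime). Optionally (`motif_effect > 0`) the
   activity probability is shifted by a planted positional sequence motif —
   T at protospacer position +1 strongly deleterious, G/C favourable — so
   the scoring pipeline has a recoverable target.
2. An active guide targeting an essential gene carries a log2 depletion
   effect per timepoint unit, drawn once from
   Normal(`essential_lfc_mean`, `essential_lfc_sd`) and clipped at 0 (no
   fitness-gain "dropout"). Non-essential targets and inactive guides have
   effect 0. A multiplexed construct's effect is that of its **strongest**
   active guide (the minimum, effects being negative). The max-rule is a
   deliberate conservative choice: it models better sampling of an
   effective guide from the array without asserting any multi-cut synergy,
   whose existence is speculative.
3. Reference abundances are log-normal around `depth_mean` (σ = 0.5 in log2
   units), emulating cloning skew.
4. Counts are negative binomial with mean
   `abundance × 2^(effect × timepoint)` and size parameter `nb_dispersion`
   (variance μ + μ²/size; large size → Poisson). Depletion therefore
   accumulates linearly in log2 space — a constant dropout rate with no
   plateau, which matches the early phase of a real screen but not the
   late-phase saturation.

Everything is deterministic given `seed`. Default study conditions are the
benchmark design: 342 + 345 genes, 3 guides/gene, triplicates, four
timepoints, ~500 reads/construct.

**What the simulator does not model:** lentiviral infection (MOI,
bottlenecking), copy-number cutting toxicity, guide position effects within
the array, PCR amplification bias, or any correlation structure between
replicates beyond shared true effects. Passing tests demonstrate
correctness of the estimators under the stated model, not performance on
real sequencing data.

## Fold change

Each sample column is scaled to a common total (default 10⁷ reads), a
pseudocount (default 0.5) is added, and log2 fold change is taken against
the reference sample of the same replicate. Replicates are averaged only at
reporting time. Both defaults are conventions of essentiality pipelines; no
normalization scheme is canonical for these data.

One consequence worth knowing: per-sample depth normalization makes fold
changes *compositional*. When a large fraction of the library drops out,
every construct — including non-essential targets — receives a common
positive shift equal to log2 of the total-count ratio. Class *differences*
in mean lfc are invariant to this shift and are what the tests check against
the simulator's closed forms.

## Active-construct calling

For each replicate and timepoint, the depletion threshold is the empirical
lower-tail FPR-quantile of the non-essential-targeting constructs' fold
changes: the (k+1)-th order statistic with k = ⌊fpr·n⌋, so exactly k
non-essential constructs fall strictly below it. Calls use strict `<`, so
ties at the threshold count as non-active; the empirical FPR therefore
never exceeds the nominal one. `fpr·n < 1` is an error (threshold
undefined); an all-tied distribution returns the common value and zero
active calls. Thresholds are computed per replicate per timepoint (never
pooled), and the summary reports mean ± s.d. across replicates. The metric
is invariant under any strictly monotone transform of the fold changes.

Under the simulator null (zero essential effect, zero spread) the essential
and non-essential count distributions are exactly exchangeable, and the
called active fraction is calibrated to the nominal FPR within binomial
error — verified at 5/10/20% in the acceptance suite.

## Low Fat BAGEL

Bayes-factor essentiality classification adapted to small libraries.
Classic gene-level resampling overfits when only ~700 reference genes
exist, so resampling is done at the level of individual guides:

- **Observation unit.** One log2 fold-change observation per construct
  (replicate-mean at the endpoint by default; any timepoint or a single
  replicate can be selected). For mono-cistronic libraries a construct is a
  guide; for multiplexed libraries the construct/array is the unit, and
  since each gene has one array, construct-level and gene-level Bayes
  factors coincide.
- **Permutations.** Across `n_permutations` (default 100) rounds, 60%
  (`train_fraction`) of the reference guides — stratified per class,
  without replacement — form the training set. The published description
  calls this "bootstrapping" but describes subsampling ("roughly 60% ...
  randomly selected as a training set"); subsampling without replacement is
  implemented. The same description mentions "the 500 guides" where the
  benchmark reference set contains 2061; all available reference guides are
  used here. Every reference guide is guaranteed to appear in at least one
  test split (splits are re-drawn otherwise). `train_fraction=1.0` is the
  degenerate no-holdout mode used by the oracle-equivalence test.
- **Densities.** Gaussian KDEs (Scott's-rule bandwidth) are fitted to the
  essential and non-essential training fold changes. Evaluation is clamped
  to the interval where both densities are at least the floor (10⁻¹²),
  further bounded to [min(train) − 1, max(train) + 1]; both densities are
  floored before the ratio. This is the standard BAGEL-style numerical
  stabilization; zero-variance training sets are an error.
- **Bayes factors.** BF(x) = log2 f_ess(x*)/f_non(x*) at the clamped x*.
  Per guide, the final BF is the mean over the permutations in which it was
  scored (held-out reference rounds, or every round for non-reference
  guides); the gene BF is the sum of its guides' means — exactly additive,
  so removing a guide removes exactly its contribution.
- **Hit calling.** Genes ranked by BF descending; precision computed over
  reference genes only (essential = TP, non-essential = FP); the threshold
  is the smallest BF at which running precision still meets 1 − FDR
  (default 0.01), and all genes at or above it — reference or not — are
  hits. If precision never reaches the target, the hit set is empty with a
  warning.

**Known small bias.** A held-out guide is absent from its own class's
training KDE, which deflates that class's density at its location: essential
guides are biased slightly down, non-essential slightly up (~0.1 log2 under
a pure null). When real signal is present this is negligible against BFs of
tens of log2 units; under a label-permuted null it is the only structure
left, so null checks are framed as "no usable ranking signal and negligible
BF magnitude" rather than as a location test.

## Precision-recall metrics

- **AUC = average precision** (sum of precision over recall increments, no
  trapezoidal interpolation), computed over reference genes only. Its
  expectation under a uniformly random ranking equals the prevalence of
  positives up to O(1/n) (empirically ≈ 0.502 vs 0.498 for the 342/345
  sets) — the property that makes prevalence the natural null baseline.
  The closed-form null is |essential| / (|essential| + |non-essential|) =
  0.498 for the benchmark sets. Ties are kept in stable input order and the
  whole tie group receives the precision at the group's end (conservative;
  an all-tied ranking scores exactly the prevalence).
- **mAUC / rmAUC.** mAUC_x = AUC_x − null; rmAUC_x = mAUC_x / mAUC_end ×
  100%. By construction rmAUC is 100% at the endpoint and 0% where
  AUC_x equals the null; an endpoint AUC at or below the null is an error
  ("no endpoint separation") since the ratio is then meaningless.
- **Down-sampling.** To compare libraries with different guide counts,
  guides are repeatedly sampled without replacement per gene (default 10
  draws), gene BFs re-summed and the AUC recomputed; genes with too few
  guides are excluded with a warning. Deterministic given a seed.

## Protospacer scoring

Gene-wise pairing controls for gene effects: within each essential gene
with ≥ 3 scored guides (mono-cistronic endpoint, replicate-mean lfc), the
most depleted guide is the high-performing one, the least depleted the
low-performing one, ties broken toward the lower construct index; the
remainder form the held-out validation set. Per bootstrap (default 100),
genes are resampled **with replacement, pairs travelling together, size
preserved**; per-position nucleotide frequencies are computed separately
for the high and low sets and subtracted (high − low). The final 4×20 table
is the bootstrap mean, with per-cell bootstrap s.d. Each column of each
bootstrap table sums to zero exactly (two frequency vectors each summing
to 1), and relabelling high↔low negates the table exactly under the same
seed. Exact bootstrap mechanics (resample size, replacement) are a package
decision — the published description fixes only the count (100) and the
pairing rationale.

A guide's score is the sum of its 20 positional cells; `> 0` predicts
high-performing, `≤ 0` low-performing. Validation on the held-out median
guides reports the Spearman correlation between score and fold change
(negative when the table carries signal: higher score → deeper depletion)
and the mean lfc of predicted-high vs predicted-low with a two-sided
two-sample t statistic. Non-essential-gene guides are never used for
training — their depletion carries no activity signal.

## Library designer

- **PAM scan.** Both strands are scanned for TTTV (V ∈ {A,C,G}); every
  occurrence with a full N-free 20-mer 3′ of it on the PAM strand yields a
  candidate. Coordinates are 0-based half-open on the forward strand;
  reverse-strand candidates carry a strand flag with the PAM start on the
  forward axis, protospacers always in PAM-strand orientation. The scan is
  verified against a brute-force positional oracle on random 10-kb
  sequences (exact set equality).
- **Cloning filters.** A protospacer fails `homopolymer` on a T-run ≥ 4
  (a Pol III terminator) or any other base run ≥ 5, and `bsmbi` on CGTCTC
  or its reverse complement GAGACG anywhere in the protospacer (these would
  break Golden-Gate assembly). Both run thresholds are configurable
  package decisions; only "filtered for homopolymers" is prescribed.
- **Off-targets.** An exhaustive PAM-anchored Hamming scan over every TTTV
  site in the genome, not a read-mapper wrapper: bit-exact, dependency-free
  and the right tool at the toy-genome scales this module targets
  (genome-wide runs are cluster work and out of scope). Two policies:
  `benchmark` counts sites within 1 mismatch over the PAM-adjacent 18 nt
  and excludes guides with > 2 total off-targets; `minihuman` counts sites
  within 1 mismatch anywhere in the 20-mer, excludes guides with any exonic
  or intronic off-target, and ranks survivors by intergenic count. The
  on-target locus never counts. Hits are classified by protospacer
  midpoint with precedence exonic > intronic > intergenic (the published
  procedure does not resolve overlaps; precedence is the package's
  resolution), and unannotated chromosomes fall back to intergenic.
- **Selection.** Surviving candidates are ranked lexicographically:
  transcripts targeted (desc), intergenic off-targets (asc), sequence score
  (desc), distance from approximate cut site to the first exon start (asc).
  "Closest to the first exon" is implemented against the annotated
  `first_exon_start`; the cut site is approximated 18 nt into the
  protospacer (configurable). Top k = 4 guides per gene by default, 3
  tolerated when supply is short; genes below the minimum go to a dropout
  manifest rather than failing the run.
- **Assembly.** Arrays are direct-repeat + guide repeats (DR g1 DR g2 …),
  1–7 guides (the oligo-synthesis limit). The default DR is the 19-nt
  AsCpf1 direct repeat but is configuration, not an assertion of truth.
- **Combinatorial sizing.** For pairwise perturbation of n genes with p
  perturbagens each: n²p² mono-cistronic vectors vs n² multiplexed vectors,
  with ordered pairs and self-pairs included — the interpretation under
  which both printed worked examples (36·10⁶ and 10⁶ for n = 1000, p = 6)
  hold exactly; the unordered reading does not reproduce them.

## Problem sizes and determinism

The test and acceptance workloads are desk-scale by design: benchmark-sized
libraries (687 constructs), simulated screens up to 700 genes × 3 guides ×
3 replicates, 100 permutations/bootstraps, and toy genomes up to 10 kb for
the exact off-target oracles. The entire suite runs in seconds on one CPU.
All stochastic components (simulator, resampling schemes, down-sampling)
take explicit seeds and are bit-reproducible given them.

## Known limitations

- The simulator's independence and linear-in-log2 assumptions are idealized;
  calibration and recovery results bound correctness under the model, not
  expected performance on real screens.
- KDE-based Bayes factors are only as monotone as the training data's
  tails; small non-monotonic wiggles appear near isolated extreme training
  points, and the leave-one-out bias described above affects pure-null
  rankings.
- The designer's off-target engine is exhaustive and exact but quadratic in
  practice; genome-scale design requires an indexed aligner upstream and is
  explicitly out of scope.
- Activity-score transferability across cell lines and chromatin contexts
  is not claimed; the score table is a property of the screen it was
  trained on.
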