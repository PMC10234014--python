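# Methods

This note documents the models and procedures implemented in `breedid`,
the defaults chosen where the design was open, and what the simulation-
based tests do and do not demonstrate.

## Quality control and marker pre-filters

The pipeline assumes biallelic autosomal SNPs with complete genotypes:
neither the informativeness statistics nor the classifiers tolerate
missing values, so `qc_basic` removes any SNP with a missing call rather
than imputing.  Each removed SNP is tallied under the first criterion it
fails (biallelic → missingness → autosome), so the removal counts add up
exactly to the input count; this conservation is asserted on every run.

The minor-allele-frequency filter is computed on all samples pooled (the
reference population as a whole, matching common PLINK usage) with an
exclusive removal rule: MAF *below* the threshold is removed, so a SNP at
exactly 0.05 survives.  The default autosome set is "1"–"29" (cattle);
chromosome names are taken verbatim from the input, and all coordinates
are 1-based.

LD pruning is windowed and greedy: within a window of 50 consecutive
retained SNPs on a chromosome, whenever a pair of retained SNPs has
squared Pearson correlation of genotype codes above 0.2, the
later-positioned SNP is removed (a deterministic tie-break; removal by
missingness or MAF is moot on complete data).  The window slides with a
configurable stride (default 5 SNPs), and the scan is iterated to a fixed
point, so the guarantee on return is strong and stride-independent: no
window of 50 consecutive surviving SNPs contains a pair with r² above the
threshold, at any offset.  The stride and window are configuration knobs
because published pipelines rarely state them.

## Informativeness statistics

All three statistics are per-SNP functions of the breeds × SNPs
alt-allele frequency table, and all three are invariant to breed order
and to swapping the ref/alt labels of a SNP.

- **Delta**: mean absolute frequency difference over all unordered breed
  pairs; 0 when all breeds agree, 1 at a fixed difference (K = 2).
- **Pairwise F_ST**: per pair, `(H_T − H_S)/H_T` with `H_T = 2p̄(1−p̄)` at
  the unweighted mean `p̄` of the two breed frequencies and
  `H_S = p_i(1−p_i) + p_j(1−p_j)`.  Concavity of `2p(1−p)` gives
  `H_S ≤ H_T`, so the statistic is always in [0, 1]; when both breeds are
  fixed for the same allele (`H_T = 0`) it is defined as 0 — such SNPs
  carry no differentiation signal and are removed by the MAF filter in
  the standard pipeline anyway.  The unweighted mean is appropriate for
  the equal-sized reference breeds this package targets; a weighted
  variant would be a small extension.
- **I_n (informativeness for assignment)**: the entropy-based form
  summed over both alleles,
  `Σ_a [−p̄_a log₂ p̄_a + (1/K) Σ_i p_{ia} log₂ p_{ia}]` with
  `0·log₂ 0 = 0` and `p̄_a` the unweighted mean over breeds.  Base-2
  logarithms are used throughout, so the score is in bits and bounded by
  log₂ K (attained at a fixed difference).  Printed renderings of this
  statistic sometimes wrap the expression in a sum over SNPs with
  ambiguous sign placement; the per-SNP convention implemented here is
  the one required for per-SNP ranking and reduces correctly at both
  boundary cases.

Ranking is by descending score with a deterministic tie-break by
ascending (chromosome, position).  All three implementations are tested
against independent brute-force evaluations of the formulas to 1e-12.

## The integrated (DFI) panel

The DFI panel of size M is the set of SNPs common to the three
statistics' expanded top lists.  The per-method depth d starts at M and
grows by ×1.25 steps (rounded up, capped at the SNP count N) until the
three top-d lists share at least M SNPs; the bracketing depth is then
binary-refined to the *smallest* d that works, which is well defined
because the intersection size is monotone in d.  At d = N the
intersection is all SNPs, so the search always terminates.  The
intersection is ordered by summed per-method rank (ties again by genomic
position) and truncated to M; the depth d is recorded on the panel.  In
practice d lands near 1.3–2× M on realistic score correlations.

## Classifiers and the KSR consensus

Features are raw allele counts 0/1/2 at the panel SNPs, unstandardised by
default.  The five learners are scikit-learn estimators with explicit
hyperparameter configs:

| method | defaults |
|---|---|
| knn | k = 5 |
| svm | RBF kernel, cost C = 1, γ = 1/n_features |
| rf  | 500 trees, √p features per split, seeded |
| nb  | Gaussian on allele counts |
| ann | one hidden layer of 10 units, ≤ 200 iterations, no weight decay, L-BFGS, seeded |

These mirror the documented defaults of the classical R implementations
of each method (class::knn, e1071::svm/naiveBayes, randomForest, nnet);
they are deliberate package defaults, not a claim about any particular
published configuration, and every evaluation logs the full resolved
config.  KNN, SVM and NB are deterministic given the data; RF and ANN
take their seed from the replicate index (base_seed + r), so repeated
evaluation provably reproduces deterministic learners bitwise (their
standard error over replicates is exactly 0).

KSR is implemented as per-sample majority vote over the KNN, SVM and RF
calls with KNN as the fallback when all three disagree — the natural
per-sample reading of "intersection of the three methods' results".

Evaluation reports the mean over replicates of `N_T/(N_T+N_F)` in
percent; the "standard error" is the sample standard deviation over
replicates divided by √R (a documented choice; other conventions exist).
Per-breed incorrect counts and full confusion matrices are kept per
replicate, and `Σ per-breed incorrect = N_F` is asserted for each.

## Genomic breed composition

One animal at a time, the genotype vector is fitted by ordinary least
squares with an intercept against the K breed-frequency columns; the
composition is the coefficient ratio `b_k / Σ b_j`, which sums to one by
construction whenever `Σ b` is non-negligible (|Σ b| below 1e-8 × mean
|b| raises an undefined-composition error, as does a rank-deficient
design, which names identical frequency columns when that is the cause).
Negative OLS coefficients are reported as-is and flagged; the optional
`nnls` mode constrains coefficients to be non-negative (solving the
demeaned system so the intercept stays implicit) for users who want
proportions that are individually non-negative.  The residual variance
affects only uncertainty, not the coefficient ratios, and is not
estimated.  The purebred call uses a strict threshold: largest
composition > 0.9.

On noise-free purebred input (y = 2 × breed frequency) OLS recovers the
indicator composition to well under 1% absolute error with a few
thousand SNPs; a simulated F1 cross is recovered at 50 ± 5% per parent
from 50,000 independent SNPs.

## The simulator

Breed allele frequencies follow the Balding–Nichols model: ancestral
frequency p ~ Uniform(0.05, 0.95) per SNP (emulating a MAF-filtered
marker set), breed frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with the
per-breed drift F acting as a single interpretable divergence knob
comparable to the F_ST it induces.  Genotypes are independent
Binomial(2, p_i) draws; crossbreds draw each allele copy from a parental
breed (one from each for an F1).  Chip densities are emulated as uniform
random position subsets.  Everything is reproducible from a single seed.

What the simulator does **not** model: linkage disequilibrium between
loci (the LD-pruning tests therefore plant explicit duplicated /
complementary columns), genotyping or sequencing error, depth variation,
admixed reference breeds, and ascertainment bias of real chip manifests.
Passing the simulation suites therefore demonstrates correctness of the
statistics and the pipeline's behaviour under idealised population
structure, not field performance on real livestock data.

Real cattle breeds sit around pairwise F_ST 0.1–0.3 (the closest pairs
near 0.13), so the test grid spans F = 0.01 (well below, deliberately
hard) to F = 0.2 (typical of distinct breeds).  Default study sizes used
in the tests and reproduction script — 5 breeds, 5,000 SNPs, 30
reference / 50 test animals per breed, panels of 200–1,000 SNPs, F1
composition from 50,000 SNPs over 5 seeds — were chosen as the smallest
designs at which the expected qualitative behaviour (near-perfect
assignment at high divergence, degradation at F = 0.01, accuracy
non-decreasing in panel size) is stable across seeds.

## Numerical notes and limitations

- Zero-variance genotype columns have undefined Pearson correlation;
  LD pruning treats their r² as 0 (they cannot evidence linkage).
- `0·log₂ 0 = 0` is applied exactly (masked evaluation), not via an ε.
- Score ties are broken by genomic position everywhere, making panels
  and ranks fully deterministic.
- The evaluation protocol retrains on the same reference each replicate;
  only learner seeds vary.  Subsampled reference designs (10/20 per
  breed, 3 repeats) are provided by `subsample_reference`.
- GBC assumes the reference breeds span the test animal's ancestry; an
  animal from an unrepresented breed will be forced onto the span of the
  K columns and can show spurious mixtures.
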