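# Methods

## Model and assumptions

The framework treats a cell population as a mixture of a small number of
discrete subpopulations, each with a fixed mean expression profile. Three
observation processes sit on top of that latent structure:

- **Single cells** are multinomial draws at a fixed capture depth from a
  cell's profile, possibly distorted by multiplicative nuisance programs
  (cell-cycle phase, clone of origin, technical batch).
- **Bulk samples** are fraction-weighted sums of subpopulation profiles,
  observed through a gene-wise multiplicative platform distortion
  (single-cell vs bulk chemistry) and multiplicative log-normal noise.
- **Perturbation screens** act on the composition: each
  (perturbagen, concentration, time) condition multiplies the baseline
  composition by a per-subpopulation survival fraction and renormalizes.
  Survival acts on relative composition, not absolute cell number, because
  the deconvolution estimates relative fractions.

All downstream statistics (susceptibility, consistency, killed calls,
cocktail search) are deterministic functions of compositions, so their
accuracy is bounded by the deconvolution error.

## Subpopulation learning

Cells are CPM-normalized, log1p-transformed and embedded by PCA (SVD of the
centered matrix, deterministic sign convention; 10 components by default —
at the fixture's size the leading ~6 components carry the subpopulation
separation and later components are multinomial noise, which dilutes
footprint confidence if included).

**Batch correction** is an iterative soft k-means procedure on the
embedding: soft assignments with a diversity penalty of strength theta
(default 2) that rewards clusters mixing batches, followed by removal of
the soft-weighted per-cluster, per-batch offset; iterated (default 30
rounds, kernel width 0.5 x the median squared centering distance) until
hard assignments stabilize. It removes additive offsets in the embedding,
which is the right model for multiplicative gene programs after the log
transform. It is contract-equivalent to, not a port of, the established
iterative-correction algorithms: batch mixing improves while biological
separation is preserved, which is what the tests assert.

**Archetypal analysis** solves X ~ (XC)S per depth k = 2..k_max (default
30), with C and S column-stochastic: archetypes are convex combinations of
cells and cells convex combinations of archetypes. Each level is fitted by
alternating accelerated projected-gradient steps with exact simplex
projections (objective-change tolerance 1e-6, 50 alternations). Archetypes
pooled across depths are unified by average-linkage clustering of their
cell-usage rows (correlation cut 0.2: redundant archetypes found at
different depths are used by the same cells, usage correlation ~0.6;
distinct states sit near zero or below). Usage rather than coordinate
correlation is deliberate — coordinate correlation is degenerate in low
dimensions. Each family's largest-mass member seeds a final alternating
refit at k = number of families, which pulls coarse-level representatives
back to the hull extremes. Final footprints are recomputed against the
refined set; a cell's maximum weight is its confidence, and cells below
the 0.6 threshold are pruned (a cell at exactly 0.6 is kept).

**Clustering**: k-nearest-neighbour graph (default 50 neighbours,
Euclidean) on footprints, edges weighted by footprint cosine similarity and
pruned below 0.5 so that cells loading on different archetypes stay
disconnected; Leiden community detection (RB-modularity, resolution 1).
Because modularity at resolution 1 fragments large homogeneous populations,
communities sharing a dominant archetype (argmax of the community's mean
footprint, ties to the lowest index) are consolidated into one
subpopulation — a subpopulation is defined by its most influential
archetype. Labels are 1..n by decreasing size.

## Signature and deconvolution

Differential expression per subpopulation is a two-sided one-vs-rest
rank-sum test on CPM values: exhaustive enumeration of the null when both
groups have ≤ 8 cells, otherwise the normal approximation with tie and
continuity corrections; genes with p < 0.01 are kept (no multiple-testing
correction by default, matching the pipeline's convention; a BH step can be
applied externally). The signature is the per-subpopulation mean CPM over
the union of significant genes, after removing genes with mean raw count
< 0.5 across all cells (strictly below; exactly 0.5 is kept). The condition
number is reported and a warning is raised above 1e4.

**Cross-platform (S-mode-style) adjustment.** Artificial mixtures of known
composition are drawn from the labelled cells (flat Dirichlet fractions, 60
mixtures x 200 cells by default — enough for a well-conditioned fraction
design). The platform effect is modelled as a gene-wise multiplicative
factor. Its estimate is anchored at a platform-free estimate of the bulk
cohort's mean composition: all samples' fractions are fitted jointly by
least squares on double-centered log expression, where a gene-wise factor
(per-gene constant in log space) and library-size differences (per-sample
constant) both cancel; fractions are softmax-parameterized and solved by
Levenberg–Marquardt. The factor for gene g is then the ratio of the gene's
observed bulk mean to the signature-side expectation at that composition.
Per-gene moment matching between the two "batches" was evaluated and
rejected: with cohorts of ~20 samples the per-gene moments are dominated by
the cohort's composition sampling noise, and recovery failed at roughly one
fixture seed in four. The adjusted signature is re-solved per gene by
non-negative least squares from the factor-corrected mixtures and their
known fractions, shrunk toward the anchored signature (prior weight 4x the
mixture data) — the anchor carries no mixture-sampling noise, which makes
repeated runs with different mixture draws agree to ~0.002 L1 per sample.

**Per-sample decomposition** follows the established digital-cytometry
convention: the signature matrix is standardized by its global mean and sd
(preserving the relative scale of the columns), each sample standardized
separately; a linear nu-SVR is fitted for nu in {0.25, 0.5, 0.75} and the
lowest-RMSE fit kept; negative coefficients are clamped to zero and the
rest normalized to the simplex. The output is invariant to positive
rescaling of the bulk. Permutation significance shuffles the sample's gene
values and refits; p = (1 + #{null >= observed}) / (n_perm + 1) with 500
permutations by default.

## Susceptibility, consistency, cocktail

The susceptibility statistic averages the normalized difference
(TC − C̄C)/(TC + C̄C) over replicates and scales by 100; each term lies in
[−1, 1], so the statistic is bounded by ±100 %. The degenerate 0/0 term
contributes 0 (the limit along TC = C̄C → 0), which keeps the
TC = C̄C ⇒ 0 % identity exact. Plate-control averages are renormalized to
the simplex; conditions with fewer than 3 replicates are dropped.
Consistency is the median susceptibility of the same drug at strictly
higher doses, same time point by default (an `across_time` flag pools time
points); it is undefined (NaN) at a drug's highest dose. Killed is strictly
below −90 %.

The greedy cocktail search counts, per PCT, the surviving subpopulations
with susceptibility < −90 % and consistency ≤ −80 % (undefined consistency
passes, using the PCT's own susceptibility as surrogate — the highest dose
has no higher-dose evidence against it; `strict_consistency` makes it
failing). Maximum count wins; ties break by lowest concentration, then
shortest time, then lexicographic perturbagen id. The selected drug's other
conditions are removed. Note that this removal can strand a subpopulation
killable only by a removed dose of an already-selected drug, so the union
of credited kill sets is not in general the full killable set; the
guaranteed invariant is that at termination no remaining condition can kill
a residual subpopulation. Greedy cover is within the classical (1 + H(n))
factor of the optimum; minimality is not claimed.

## Synthetic data: what it does and does not emulate

Ground truth draws per-gene base expression from a log-normal law
(log-mean 1, log-sd 1), gives each of 6 subpopulations a disjoint block of
25 marker genes up-regulated 8-fold, a gene-wise log-normal platform shift
(log-sd 0.5), and optional per-batch multiplicative programs on non-marker
genes. Cells are multinomial at depth 5,000 (exact depth conservation, used
by the tests); bulk mixtures add multiplicative log-normal noise (sd 0.1).
Kill rates follow Hill-type survival curves with random EC50 inside the
dose ladder (slope 2, ~35 % of drug-subpopulation pairs resistant), floored
to exactly 0 at ≥ 8x EC50 so screens contain complete kills. The
batch-confound fixture uses four batch labels (emulating clone x cycle
phase combinations) with 100-gene, 8-fold programs — strong enough that
uncorrected clustering groups cells by batch program rather than
subpopulation.

Not modelled: doublets, ambient RNA, zero inflation beyond multinomial
sampling, gene–gene correlation within a subpopulation, probe-level
microarray effects, or dose-dependent transcriptional (as opposed to
compositional) change. Passing tests therefore demonstrate the pipeline's
correctness and its statistical behaviour under the stated noise model, not
robustness to every artifact of real single-cell chemistry.

## Problem sizes and numerical choices

The packaged fixtures use 2,000 cells, 1,000 genes, 20-sample bulk cohorts
and an 8-condition screen with 3 replicates — sizes chosen so the full test
suite and the acceptance script each run in minutes on one CPU while
keeping every estimator in its asymptotic regime. Tolerances: simplex
constraints to 1e-8; archetypal-analysis objective change 1e-6; NNLS is
exact (active set); SVR tolerance 1e-6. Known edge cases: an all-zero
expression column is an error in CPM normalization (named in the message);
a plate without controls is an error naming the plate; pruning everything
raises with a suggestion to lower the threshold; GCT parsing requires the
`#1.3` sentinel and exact dimension agreement.

## Known limitations

- Deconvolution error is ~1–2 % absolute per fraction at the packaged
  noise level; susceptibilities of completely killed subpopulations
  therefore land around −88 to −97 %, and a complete kill can occasionally
  score just above the −90 % threshold (the classifier is exact when the
  true platform factors are supplied).
- The batch correction removes additive embedding offsets only; batch
  effects that destroy within-batch separation cannot be undone.
- Probe-to-gene alias mapping, binary GCTX input and absolute-abundance
  modes are out of scope; inputs are expected as MatrixMarket triplets,
  GCT 1.3 text, or TSV/CSV.
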