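# Methods

This note documents the models implemented in `enterodyn`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic cohorts do and do not demonstrate.

## The synthetic cohort generator

The generator emulates a longitudinal pre-weaning calf cohort at the
level of summary statistics, not sequences.

**Community states.** K enterotype profiles over G genera are built by
`make_profiles`: state k places mass `dominance` (default 0.45) on its
driver genus and spreads the remainder uniformly. The four default
drivers mirror the *Achromobacter*, *Corynebacterium*,
*Bifidobacterium* and *Oscillospiraceae_UCG-005*-dominated states of
the calf hindgut. Default G = 50 genera.

**Trajectories.** Each subject's state sequence is a first-order Markov
chain over the sampling schedule, default ages (0, 7, 35, 56, 70) days.
One chain step corresponds to one schedule interval irrespective of its
calendar length ("subject-independent" transition probabilities). The
default transition matrix keeps the five published-scale probabilities
exactly — P(1→3) = 0.95, P(2→3) = 0.96, P(3→3) = 0.42, P(3→4) = 0.58,
P(4→3) = 0.94 — and assigns the small free mass of rows 1, 2 and 4 to
self-transitions. The initial distribution (0.50, 0.35, 0.10, 0.05)
reflects a birth community dominated by states 1 and 2; those states
are effectively unreachable later, so they appear only at the first
age, as in real cohorts.

**Counts.** Per sample, a composition is drawn from
Dirichlet(θ·mean_k) and counts from a multinomial at a library size
drawn from a normal (mean 46,422, sd 16,249) truncated at 1,000 reads —
matching the read-depth summary of typical 16S runs at this scale
without modelling overdispersion beyond the Dirichlet. θ controls
compositional noise (larger = tighter around the state mean).

*Default θ = 150.* This is a deliberate calibration: the default cohort
must be clusterable — the CH index over PAM/JSD should recover K = 4 —
while remaining visibly noisy. Mapping the recovery region empirically,
the CH scan fails to separate the two small birth states below θ ≈ 100
(it merges them, best k = 2–3), recovers K = 4 in 10/10 seeds at
θ = 150, and becomes near-noiseless above θ ≈ 300. θ = 150 sits at the
low-noise edge of reliable recovery; it is the package's definition of
"clusterable but noisy" for G = 50 and dominance 0.45. Note the small
tail concentrations (θ·(1−dominance)/(G−1) ≈ 1.7) still produce highly
variable minor genera and many zero counts per sample.

**Age-signal preset.** `simulate_age_cohort` generates a
cross-sectional strong-signal cohort: 20 of 50 genera have monotone
age trends (multiplier exp(sᵢ(age/70 − ½)), slopes |sᵢ| ∈ [1, 2],
alternating sign), θ = 2000, 600 samples spread over the schedule. The
preset is defined by its purpose — an age signal strong enough that a
regression forest reaches the OOB R² ≈ 0.99 accuracy regime reported
for real calf cohorts — while keeping MAE ≈ 1.5 days of genuine
residual noise (θ = 5000+ would push R² past 0.998 and demonstrate
nothing).

**Phenotypes.** Birth weight ~ N(40, 3²) kg, 70-day weight ~ N(90, 7²)
kg plus a `phenotype_effect` (default +5 kg) for subjects ending in the
designated (*Bifidobacterium*-type) state; ADG is the weight gain per
day. This reproduces the qualitative enterotype–growth association, not
any particular effect size.

**What the generator does not emulate.** Real genus tables have
hundreds of taxa with long-tailed abundance distributions, phylogenetic
correlation, per-subject random effects, age-dependent richness, and
incomplete longitudinal sampling. Passing the recovery tests therefore
shows the estimators are correct and well-calibrated under the stated
model, not that a real cohort of this size would yield equally clean
CH curves or transition estimates.

## Enterotype discovery

Distances are the square root of the Jensen–Shannon divergence (natural
log), which is a metric and bounded by √ln 2 ≈ 0.8326. Zeros are
replaced by a pseudocount (default 1e-6, the classical enterotyping
convention) and columns re-closed, so the divergence is always finite.

PAM is the deterministic BUILD + SWAP algorithm on the precomputed
distance matrix: BUILD seeds medoids greedily by largest cost
reduction; SWAP repeatedly applies the single best (medoid, non-medoid)
exchange while it strictly lowers the total within-cluster distance to
medoids (tolerance 1e-12); all ties break toward the lowest index, and
there are no random restarts, so results are reproducible. PAM is a
local optimiser: on random 7-point problems it attains the exhaustive
optimum in ~92% of cases and its misses coincide exactly (medoids and
cost) with the reference R `cluster::pam` implementation.

The cluster number is the argmax of the distance-based CH index over
k = 2..10 by default (ties → smallest k), where
W = Σ_c n_c⁻¹ Σ_{i<j∈c} d²ᵢⱼ, T = n⁻¹ Σ_{i<j} d²ᵢⱼ, B = T − W. For
Euclidean distances this equals the classical centroid-based CH
(verified on a hand-computed toy: points {0, 1, 10, 11}, CH = 200).

Signature taxa use a simplified effect-size screen honouring the
conventional cutoffs: a taxon passes when the Kruskal–Wallis p across
clusters is < 0.05 and score = log₁₀(max pairwise |mean abundance
difference| × 10⁶) exceeds 2 strictly (so a 10⁻⁴ difference scores
exactly 2 and is excluded). This is a mean-difference surrogate on the
familiar discriminant-score scale, not a full subclass-bootstrapped
discriminant analysis, which would add machinery without changing what
the synthetic cohorts can test.

## Transition modelling

Transitions pool all adjacent *observed* pairs per subject (missing
time points are skipped; a per-interval stratified mode exists but is
not the default). The MLE P̂ᵢⱼ = Nᵢⱼ/Nᵢ· is exact for the product-
multinomial likelihood; additive smoothing is available but defaults to
0 so the estimates reproduce the printed-probability arithmetic. Rows
with no observations are reported as undefined (NaN) rather than
silently uniform. The stationary distribution is the leading left
eigenvector (power-iteration fallback, tolerance 1e-10), reported only
when the chain restricted to visited states is irreducible and
aperiodic — for the default cohort chain the birth states are
transient, so the full-chain stationary vector is reported as undefined
by design. Bootstrap confidence intervals resample subjects (not
samples) with replacement; percentile intervals at 95% cover the
generating entries at the nominal rate in simulation.

## Diversity and tests

Chao1 uses the bias-corrected form, defined also when no doubletons are
present; Shannon defaults to natural log (configurable base). ANOSIM
follows the rank formulation R = (r̄_between − r̄_within)/(M/2);
PERMANOVA is single-factor (marginal) with the distance-based
sum-of-squares decomposition and R² = 1 − SS_W/SS_T. Both use the
add-one permutation p-value p = (1 + #{stat_perm ≥ stat_obs})/(1 +
n_perm), default 999 permutations, so p ≥ 1/(1+n_perm) and p-values are
never zero. Type-I error of all four group tests is verified to sit in
the 3σ binomial band around α = 0.05 under 1,000-replicate null
simulations. Alpha/beta estimators are cross-checked against
scikit-bio to 1e-9 on random tables.

## Networks

Edges require |Spearman r| > 0.5 AND raw p < 0.05, both strict, with
average-rank ties and the two-sided t-approximation p-value; constant
taxa are excluded and reported. No multiple-testing correction is
applied by default (the convention is raw p), but Benjamini–Hochberg is
available behind a flag. Per-cluster networks restrict taxa to > 20%
within-cluster prevalence to avoid rank-degenerate vectors. Natural
connectivity is computed on the unweighted adjacency spectrum (via
log-sum-exp for stability); correlation magnitudes are discarded after
thresholding because the measure is defined for simple graphs.
Anti-interference curves remove round(f·N) nodes for f ∈ {0, 0.05, …,
0.5} — uniformly at random, averaged over 100 replicates, or
deterministically by descending degree — and the trapezoid area under
the mean curve is the scalar stability score. The exact removal
protocol is a declared package default; no published protocol is being
matched.

## Age regression

The bagging loop and OOB bookkeeping are implemented in the package
(bootstrap indices from the seeded generator, per-tree OOB masks, OOB
prediction = mean over trees not containing the sample); individual
trees are scikit-learn regression trees with mtry = ⌊G/3⌋ features per
split, the standard regression-forest default. Default ntree = 1,000
balances stability against runtime; a flag raises it to 10,000.
Importance is %IncMSE computed on OOB samples only, averaged over 5
permutation repetitions by default. OOB R² is this package's accuracy
definition (it is unbiased without a held-out set); note that with
discrete sampling ages the forest interpolates between few age levels,
which is why a strong compositional signal saturates R² near 0.996
rather than 1. Exact invariance of the fitted ensemble under monotone
feature transforms holds at the level of importance rankings but not
bit-for-bit, due to tie-breaking in the underlying split search.

## Pipeline and reproducibility

A single global seed fans out to per-stage child seeds derived from the
stage name (multiplicative hash + CRC32, kept below 2³¹), so stages are
independently re-runnable. Every stage writes its tables as TSV with a
fixed float format; `manifest.yaml` records the seed, a SHA-256
parameter hash and per-file checksums, and two runs with one
configuration are byte-identical. The acceptance script scales the
recomputation to desk size — 400 subjects (2,000 samples) for the
cluster-number scan, 1,000 subjects for transition recovery, 600
samples for the age model — sizes at which the sampling error of each
target is several times smaller than its tolerance.

## Known limitations

* PAM is quadratic in samples (distance matrix in memory); cohorts
  beyond ~10⁴ samples need a subsampled k-selection.
* The stationary distribution is only reported for irreducible
  aperiodic chains; chains with transient birth states (the default)
  get `None`, by design.
* The signature screen and the network protocol are declared package
  conventions where the field's tooling is heterogeneous; both honour
  the standard cutoffs but are not drop-in replacements for LEfSe or
  Gephi workflows.
* ANOSIM/PERMANOVA assume exchangeability under the null; repeated
  measures within subject violate this, so per-age or per-subject
  aggregation should precede them on longitudinal data.
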