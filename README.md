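# enterodyn

Enterotype structure and temporal dynamics of the early-life calf fecal
microbiome, as a tested, reusable Python pipeline.

During the first weeks of life the calf hindgut community passes through
discrete community states ("enterotypes"), each dominated by one genus —
*Achromobacter*- and *Corynebacterium*-dominated states at birth, a
*Bifidobacterium*-dominated state that takes over within the first week,
and an *Oscillospiraceae_UCG-005*-dominated state that grows towards
weaning. `enterodyn` implements the full statistical workflow used to
characterise such cohorts from genus-level 16S count tables, together
with a synthetic longitudinal-cohort generator that reproduces the
cohort's statistical structure so every stage can be exercised, and its
estimators validated, without access to the raw sequencing data.

It is aimed at microbiome researchers analysing longitudinal amplicon
cohorts (livestock or otherwise) who want the classical enterotyping and
dynamics toolchain as composable, seeded, unit-tested functions rather
than a collection of R snippets.

## What it computes

* **Enterotype discovery.** Pairwise sample distances
  d(a,b) = √JSD(a,b) with JSD(a,b) = ½KL(a‖m) + ½KL(b‖m), m = (a+b)/2
  (natural log; the square root makes it a metric); partitioning around
  medoids (deterministic BUILD + SWAP k-medoids); the number of states
  chosen by maximising the distance-based Calinski–Harabasz index
  CH(k) = [B/(k−1)] / [W/(n−k)] over k; per-cluster driver taxa and an
  effect-size screen for signature taxa (p < 0.05 and score > 2).
* **Temporal dynamics.** Adjacent observed time points of each subject
  are pooled into a K×K count matrix N; the maximum-likelihood
  transition matrix is P̂ᵢⱼ = Nᵢⱼ/ΣⱼNᵢⱼ, with stationary distribution
  πP = π when defined, subject-bootstrap confidence intervals, and
  window-persistence summaries.
* **Diversity and group statistics.** Bias-corrected Chao1
  (S_obs + F₁(F₁−1)/(2(F₂+1))), Shannon entropy, Bray–Curtis distances;
  ANOSIM and single-factor PERMANOVA permutation tests; Kruskal–Wallis
  with Dunn/Bonferroni post-hoc; one-way ANOVA.
* **Co-occurrence networks.** Spearman edges kept at |r| > 0.5 and
  p < 0.05 (strict); natural connectivity λ̄ = ln(N⁻¹ Σᵢ e^{λᵢ}) over
  adjacency eigenvalues; anti-interference robustness curves under
  random or degree-ordered node removal, summarised by the area under
  the curve.
* **Microbiota age regression.** Bagged regression trees with
  out-of-bag (OOB) MAE/R² and permutation importance
  (%IncMSE = 100·(MSE_OOB^perm − MSE_OOB)/MSE_OOB).
* **Synthetic cohorts.** Dirichlet-multinomial genus tables over
  Markov-chain enterotype trajectories with realistic library sizes
  (truncated normal, 46,422 ± 16,249 reads), plus a strong-signal
  age-cohort preset and phenotype (body weight / ADG) simulation.

## Worked example

```python
from enterodyn import synth, enterotype as et, dynamics as dyn
from enterodyn.io import to_relative

cfg = synth.default_cohort_config(seed=1, n_subjects=100)
counts, meta, traj, pheno, profiles = synth.simulate_cohort(cfg)

d = et.jsd_distance(to_relative(counts), pseudocount=1e-6)
scan = et.select_k(d, 2, 8)
print(scan.best_k)            # -> 4

model = dyn.estimate_markov(dyn.count_transitions(traj, K=4))
print(model.P.round(3))
```

Run as `python examples/03_enterotype.py`, the CH scan prints

```
CH index by k:
  k=2:    334.5
  k=3:    300.4
  k=4:    390.8  <-- best
  ...
driver genus per cluster (mean relative abundance):
  cluster 1: Bifidobacterium (0.45)
  cluster 2: Corynebacterium (0.45)
  ...
```

i.e. the CH index peaks at the four community states built into the
generator, and each recovered cluster is dominated by its generating
driver genus. `examples/04_markov_dynamics.py` then recovers the
generating transition matrix — entries (1→3, 2→3, 3→3, 3→4, 4→3) =
(0.95, 0.96, 0.42, 0.58, 0.94) — with a maximum entry error of 0.018 at
1,000 subjects. The other `examples/` scripts demonstrate diversity
testing, network robustness and the age model the same way.

## Command line

The same stages are exposed as a thin CLI over the library:

```bash
enterodyn all --outdir results_run --seed 1          # full pipeline
enterodyn enterotype --counts genus.tsv --metadata meta.tsv --outdir out
```

All intermediate tables are written as TSV and listed with checksums in
`manifest.yaml`; re-running with the same configuration reproduces every
file byte for byte.

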