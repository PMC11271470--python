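"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a pre-weaning calf fecal-microbiome
cohort: ~400 subjects sampled at up to six ages, genus-level count tables
whose samples fall into K enterotype community states each dominated by
one genus (the four defaults mirror *Achromobacter*, *Corynebacterium*,
*Bifidobacterium* and *Oscillospiraceae_UCG-005*-dominated states),
per-subject state trajectories following a first-order Markov chain with
subject-independent transition probabilities, library sizes around
46,422 +/- 16,249 reads, and a body-weight phenotype shifted for subjects
ending in a designated enterotype.

Counts are Dirichlet-multinomial: per sample a composition is drawn from
Dirichlet(theta_k * mean_k) for the sample's state k, then counts from a
multinomial at a truncated-normal library size.  Everything is a pure
function of (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Default driver genera of the four enterotype states, in state order.
DEFAULT_DRIVERS = (
    "Achromobacter",
    "Corynebacterium",
    "Bifidobacterium",
    "Oscillospiraceae_UCG-005",
)

#: Transition matrix of the four-state enterotype chain.  The five printed
#: probabilities (1->3 = 0.95, 2->3 = 0.96, 3->3 = 0.42, 3->4 = 0.58,
#: 4->3 = 0.94) are kept exactly; the free mass of rows 1, 2 and 4 is
#: assigned to self-transitions, reflecting that birth states either move
#: to the Bifidobacterium state or briefly persist.
DEFAULT_TRUE_P = np.array(
    [
        [0.05, 0.00, 0.95, 0.00],
        [0.00, 0.04, 0.96, 0.00],
        [0.00, 0.00, 0.42, 0.58],
        [0.00, 0.00, 0.94, 0.06],
    ]
)

#: Initial state distribution: birth samples are dominated by states 1 and 2.
DEFAULT_INIT_DIST = np.array([0.50, 0.35, 0.10, 0.05])

#: Sampling ages in days (birth, first week, and around/after weaning).
DEFAULT_SCHEDULE = (0, 7, 35, 56, 70)

MISSING = -1  # sentinel for an unobserved time point in a trajectory


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class EnterotypeProfileSet:
    """Per-state mean compositions and Dirichlet concentrations.

    Attributes
    ----------
    taxa : list of str
        Taxon identifiers, length G.
    mean_composition : ndarray, shape (K, G)
        Row k is the mean composition of state k (sums to 1).
    concentration : ndarray, shape (K,)
        Dirichlet concentration theta_k > 0; larger = less compositional
        noise around the state mean.
    dominant_taxon : tuple of str
        Per-state driver taxon (the argmax of the state mean).
    """

    taxa: tuple
    mean_composition: np.ndarray
    concentration: np.ndarray
    dominant_taxon: tuple

    def __post_init__(self):
        mc = np.asarray(self.mean_composition, dtype=float)
        if mc.ndim != 2 or mc.shape[0] < 2:
            raise ConfigurationError("need K >= 2 states")
        if mc.shape[1] != len(self.taxa):
            raise ConfigurationError("mean_composition width != number of taxa")
        if not np.allclose(mc.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("state mean compositions must sum to 1")
        if np.any(np.asarray(self.concentration, dtype=float) <= 0):
            raise ConfigurationError("concentrations must be positive")
        for k, name in enumerate(self.dominant_taxon):
            if self.taxa[int(np.argmax(mc[k]))] != name:
                raise ConfigurationError(
                    f"dominant_taxon of state {k + 1} is not the modal taxon"
                )

    @property
    def n_states(self) -> int:
        return self.mean_composition.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.mean_composition.shape[1]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated longitudinal cohort.

    ``true_P`` is the row-stochastic K x K generating transition matrix and
    ``init_dist`` the state distribution at the first sampling age.
    ``library_mean``/``library_sd`` parameterise the truncated-normal
    per-sample read depth; ``phenotype_effect`` is the body-weight shift
    (kg) for subjects whose final state equals ``designated_state``.
    """

    n_subjects: int = 400
    schedule: tuple = DEFAULT_SCHEDULE
    init_dist: np.ndarray = field(default_factory=lambda: DEFAULT_INIT_DIST.copy())
    true_P: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_P.copy())
    library_mean: float = 46422.0
    library_sd: float = 16249.0
    library_min: int = 1000
    phenotype_effect: float = 5.0
    designated_state: int = 3
    bw_birth_mean: float = 40.0
    bw_birth_sd: float = 3.0
    bw_final_mean: float = 90.0
    bw_final_sd: float = 7.0
    seed: int = 0

    def __post_init__(self):
        P = np.asarray(self.true_P, dtype=float)
        init = np.asarray(self.init_dist, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ConfigurationError("true_P must be square")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("rows of true_P must sum to 1")
        if (P < 0).any() or (init < 0).any():
            raise ConfigurationError("probabilities must be non-negative")
        if init.shape != (P.shape[0],) or not np.isclose(init.sum(), 1.0, atol=1e-9):
            raise ConfigurationError("init_dist must be a length-K probability vector")
        if self.library_mean <= 0:
            raise ConfigurationError("library_mean must be positive")
        if self.n_subjects < 1:
            raise ConfigurationError("need at least one subject")
        if len(self.schedule) < 1 or list(self.schedule) != sorted(set(self.schedule)):
            raise ConfigurationError("schedule must be strictly increasing ages")
        if not 1 <= self.designated_state <= P.shape[0]:
            raise ConfigurationError("designated_state out of range")

    @property
    def n_states(self) -> int:
        return np.asarray(self.true_P).shape[0]


@dataclass(frozen=True)
class TrajectorySet:
    """Per-subject ordered enterotype state sequences.

    ``states[i, t]`` is the state (1..K) of subject i at ``schedule[t]``,
    or ``MISSING`` (-1) when the subject was not observed at that age.
    """

    subjects: tuple
    states: np.ndarray
    schedule: tuple

    def __post_init__(self):
        s = np.asarray(self.states)
        if s.shape != (len(self.subjects), len(self.schedule)):
            raise ConfigurationError("states must be (n_subjects, n_times)")
        observed = s[s != MISSING]
        if observed.size and observed.min() < 1:
            raise ConfigurationError("state labels must be in 1..K (or -1 missing)")

    @property
    def n_states(self) -> int:
        observed = self.states[self.states != MISSING]
        return int(observed.max()) if observed.size else 0

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per observed (subject, age, state)."""
        rows = []
        for i, subj in enumerate(self.subjects):
            for t, age in enumerate(self.schedule):
                if self.states[i, t] != MISSING:
                    rows.append((subj, age, int(self.states[i, t])))
        return pd.DataFrame(rows, columns=["subject", "age", "state"])


def make_profiles(
    G: int,
    K: int,
    dominance: float = 0.45,
    concentration: float = 150.0,
    taxa: Sequence[str] | None = None,
    drivers: Sequence[str] | None = None,
) -> EnterotypeProfileSet:
    """Build K enterotype profiles over G taxa with one driver taxon each.

    State k places mass ``dominance`` on its driver taxon (taxon k) and
    spreads the remaining mass uniformly over the other G - 1 taxa, the
    dominance structure seen in real enterotypes where a single genus
    carries a large share of the community.

    Parameters
    ----------
    G, K : int
        Number of taxa and states; requires G >= K.
    dominance : float in (0, 1)
        Mean relative abundance of each state's driver taxon.
    concentration : float
        Dirichlet concentration theta applied to every state.
    """
    if G < K:
        raise ConfigurationError(f"need at least as many taxa as states (G={G} < K={K})")
    if not 0 < dominance < 1:
        raise ConfigurationError("dominance must lie strictly between 0 and 1")
    if K < 2:
        raise ConfigurationError("need K >= 2 states")
    if taxa is None:
        base = list(DEFAULT_DRIVERS[:K]) if drivers is None else list(drivers)
        if len(base) != K:
            base = [f"driver_{k + 1:02d}" for k in range(K)]
        taxa = base + [f"genus_{i + 1:02d}" for i in range(K, G)]
    taxa = tuple(str(t) for t in taxa)
    if len(taxa) != G or len(set(taxa)) != G:
        raise ConfigurationError("taxa must be G unique identifiers")

    rest = (1.0 - dominance) / (G - 1)
    mc = np.full((K, G), rest)
    for k in range(K):
        mc[k, k] = dominance
    return EnterotypeProfileSet(
        taxa=taxa,
        mean_composition=mc,
        concentration=np.full(K, float(concentration)),
        dominant_taxon=tuple(taxa[k] for k in range(K)),
    )


def simulate_trajectories(cfg: CohortConfig, rng: np.random.Generator | None = None) -> TrajectorySet:
    """Draw per-subject state sequences from the Markov chain in *cfg*.

    The state at the first scheduled age follows ``init_dist``; each later
    state is drawn from the ``true_P`` row of the previous state.  One step
    of the chain corresponds to one interval of the sampling schedule,
    regardless of its calendar length.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    K = cfg.n_states
    n, T = cfg.n_subjects, len(cfg.schedule)
    states = np.empty((n, T), dtype=int)
    states[:, 0] = rng.choice(K, size=n, p=np.asarray(cfg.init_dist, float)) + 1
    P = np.asarray(cfg.true_P, dtype=float)
    cum = np.cumsum(P, axis=1)
    for t in range(1, T):
        u = rng.random(n)
        states[:, t] = (u[:, None] < cum[states[:, t - 1] - 1]).argmax(axis=1) + 1
    subjects = tuple(f"calf{i + 1:04d}" for i in range(n))
    return TrajectorySet(subjects=subjects, states=states, schedule=tuple(cfg.schedule))


def _truncated_normal_libraries(rng, size, mean, sd, minimum):
    """Library sizes ~ Normal(mean, sd) resampled until >= minimum."""
    libs = rng.normal(mean, sd, size=size)
    bad = libs < minimum
    while bad.any():
        libs[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = libs < minimum
    return np.round(libs).astype(np.int64)


def simulate_counts(
    traj: TrajectorySet,
    profiles: EnterotypeProfileSet,
    cfg: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a Dirichlet-multinomial count table for every observed sample.

    Returns
    -------
    counts : DataFrame (taxa x samples)
    metadata : DataFrame indexed by sample with columns
        ``subject``, ``age`` (days), ``state`` (ground-truth enterotype).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    observed = traj.states[traj.states != MISSING]
    if observed.size and observed.max() > profiles.n_states:
        raise ConfigurationError(
            f"trajectory uses state {observed.max()} but profiles define only "
            f"{profiles.n_states} states"
        )
    sample_ids, subjects_col, ages_col, states_col = [], [], [], []
    for i, subj in enumerate(traj.subjects):
        for t, age in enumerate(traj.schedule):
            k = traj.states[i, t]
            if k == MISSING:
                continue
            sample_ids.append(f"{subj}_d{age:02d}")
            subjects_col.append(subj)
            ages_col.append(age)
            states_col.append(int(k))
    n_samples = len(sample_ids)
    libs = _truncated_normal_libraries(
        rng, n_samples, cfg.library_mean, cfg.library_sd, cfg.library_min
    )
    G = profiles.n_taxa
    counts = np.empty((G, n_samples), dtype=np.int64)
    mc = profiles.mean_composition
    theta = np.asarray(profiles.concentration, dtype=float)
    for j in range(n_samples):
        k = states_col[j] - 1
        comp = rng.dirichlet(theta[k] * mc[k])
        counts[:, j] = rng.multinomial(libs[j], comp)
    table = pd.DataFrame(counts, index=list(profiles.taxa), columns=sample_ids)
    meta = pd.DataFrame(
        {"subject": subjects_col, "age": ages_col, "state": states_col},
        index=pd.Index(sample_ids, name="sample"),
    )
    return table, meta


def simulate_phenotypes(
    traj: TrajectorySet,
    cfg: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Body weight and average daily gain per subject.

    Birth weight ~ Normal(bw_birth_mean, bw_birth_sd); final weight ~
    Normal(bw_final_mean, bw_final_sd) plus ``phenotype_effect`` kg when
    the subject's final observed state equals ``designated_state``
    (emulating the better growth of the Bifidobacterium-type calves).
    ADG = (BW_final - BW_birth) / days elapsed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    if len(traj.subjects) == 0:
        raise ConfigurationError("empty trajectory set")
    n = len(traj.subjects)
    final_state = np.empty(n, dtype=int)
    for i in range(n):
        obs = np.nonzero(traj.states[i] != MISSING)[0]
        final_state[i] = traj.states[i, obs[-1]] if obs.size else MISSING
    bw_birth = rng.normal(cfg.bw_birth_mean, cfg.bw_birth_sd, size=n)
    bw_final = rng.normal(cfg.bw_final_mean, cfg.bw_final_sd, size=n)
    bw_final = bw_final + cfg.phenotype_effect * (final_state == cfg.designated_state)
    days = max(traj.schedule) - min(traj.schedule)
    adg = (bw_final - bw_birth) / days if days > 0 else np.zeros(n)
    group = np.where(final_state == cfg.designated_state, "Shared", "Others")
    return pd.DataFrame(
        {
            "final_state": final_state,
            "group": group,
            "bw_birth": bw_birth,
            "bw_final": bw_final,
            "adg": adg,
        },
        index=pd.Index(traj.subjects, name="subject"),
    )


def default_cohort_config(seed: int = 1, n_subjects: int = 400) -> CohortConfig:
    """The default four-enterotype cohort configuration."""
    return CohortConfig(n_subjects=n_subjects, seed=seed)


def simulate_cohort(
    cfg: CohortConfig | None = None,
    G: int = 50,
    dominance: float = 0.45,
    concentration: float = 150.0,
):
    """End-to-end cohort simulation with the default profiles.

    Returns ``(counts, metadata, trajectories, phenotypes, profiles)``.
    """
    if cfg is None:
        cfg = default_cohort_config()
    profiles = make_profiles(G=G, K=cfg.n_states, dominance=dominance,
                             concentration=concentration)
    traj = simulate_trajectories(cfg)
    counts, meta = simulate_counts(traj, profiles, cfg)
    pheno = simulate_phenotypes(traj, cfg)
    return counts, meta, traj, pheno, profiles


def simulate_age_cohort(
    n_samples: int = 600,
    G: int = 50,
    n_informative: int = 20,
    schedule: Sequence[int] = DEFAULT_SCHEDULE,
    concentration: float = 2000.0,
    library_mean: float = 46422.0,
    library_sd: float = 16249.0,
    library_min: int = 1000,
    max_log_fold: float = 2.0,
    seed: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strong-signal cohort for microbiota age regression.

    ``n_informative`` of the G genera have monotone age-dependent mean
    abundances: informative genus i is scaled by
    exp(s_i * (age/max_age - 1/2)) with slopes s_i spread over
    [-max_log_fold, max_log_fold] (alternating sign), then the composition
    is re-closed.  The remaining genera carry no age signal.  Samples are
    spread evenly over the schedule; the high Dirichlet concentration makes
    compositional noise low, so chronological age is recoverable from the
    table to high accuracy.

    Returns ``(counts, metadata)`` with metadata columns ``age`` and
    ``subject`` (one synthetic subject per sample, cross-sectional design).
    """
    if not 0 < n_informative <= G:
        raise ConfigurationError("n_informative must be in 1..G")
    rng = np.random.default_rng(seed)
    ages = np.asarray(schedule, dtype=float)
    max_age = ages.max()
    base = np.full(G, 1.0 / G)
    slopes = np.linspace(1.0, max_log_fold, n_informative)
    slopes[::2] *= -1.0  # half increase, half decrease with age
    sample_ages = np.tile(ages, int(np.ceil(n_samples / len(ages))))[:n_samples]
    sample_ages = np.sort(sample_ages)
    libs = _truncated_normal_libraries(rng, n_samples, library_mean, library_sd, library_min)
    counts = np.empty((G, n_samples), dtype=np.int64)
    for j in range(n_samples):
        mean = base.copy()
        scale = np.exp(slopes * (sample_ages[j] / max_age - 0.5))
        mean[:n_informative] *= scale
        mean /= mean.sum()
        comp = rng.dirichlet(concentration * mean)
        counts[:, j] = rng.multinomial(libs[j], comp)
    taxa = [f"agegenus_{i + 1:02d}" for i in range(n_informative)] + [
        f"genus_{i + 1:02d}" for i in range(G - n_informative)
    ]
    sample_ids = [f"s{j + 1:04d}_d{int(sample_ages[j]):02d}" for j in range(n_samples)]
    table = pd.DataFrame(counts, index=taxa, columns=sample_ids)
    meta = pd.DataFrame(
        {"subject": sample_ids, "age": sample_ages.astype(int)},
        index=pd.Index(sample_ids, name="sample"),
    )
    return table, meta


def simulate_correlated_community(
    n_samples: int = 60,
    G: int = 30,
    block: int = 10,
    strength: float = 1.5,
    concentration: float = 200.0,
    library: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Community with one block of mutually dependent taxa.

    A per-sample latent factor multiplies the first ``block`` taxa by
    exp(strength * z), z ~ N(0, 1), inducing strong positive rank
    correlations within the block while the remaining taxa fluctuate
    independently.  With ``strength = 0`` all taxa are independent (up to
    compositional closure).  Used to study co-occurrence network
    robustness under known dependence structure.
    """
    rng = np.random.default_rng(seed)
    base = np.full(G, 1.0 / G)
    counts = np.empty((G, n_samples), dtype=np.int64)
    for j in range(n_samples):
        mean = base.copy()
        z = rng.normal()
        mean[:block] *= np.exp(strength * z)
        mean /= mean.sum()
        comp = rng.dirichlet(concentration * mean)
        counts[:, j] = rng.multinomial(library, comp)
    taxa = [f"blocktax_{i + 1:02d}" for i in range(block)] + [
        f"freetax_{i + 1:02d}" for i in range(G - block)
    ]
    return pd.DataFrame(counts, index=taxa,
                        columns=[f"s{j + 1:03d}" for j in range(n_samples)])
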