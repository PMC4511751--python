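"""Synthetic-data generators with the statistical structure the pipeline assumes.

Every downstream stage can be exercised without any sequence download:

* a neutral Kingman coalescent with infinite-sites Poisson mutation, for
  diversity statistics (E[S] = theta * a_{n-1}, E[pi * L] = theta);
* a finite island-model structured coalescent with known Nm, for the
  F_ST / migration machinery;
* star-phylogeny haplotype clusters with a Poisson mutation clock, for the
  age-bound calculations;
* noisy preference-trial and titration fixtures for the dose-response fits.

All generators are deterministic under a fixed seed.  Mutations follow the
infinite-sites idealization — at most one mutation per site, enforced by
resampling positions on collision — which is a good approximation whenever
theta per locus is small relative to the sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose import PreferenceTrialSet, TitrationCurve, preference_model, titration_model
from .io import HaplotypeAlignment, PopulationMap, SequenceRecord

__all__ = [
    "CoalescentSpec",
    "IslandSpec",
    "StarSpec",
    "simulate_coalescent_alignment",
    "simulate_island_samples",
    "generate_star_haplotypes",
    "generate_preference_trials",
    "generate_titration_curves",
]

_BASES = np.array(list("ACGT"))


@dataclass
class CoalescentSpec:
    """Panmictic neutral sample: n chromosomes at locus-wide theta = 4*N*mu*L."""

    n_chromosomes: int
    theta: float
    length_bp: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_chromosomes < 2:
            raise ValueError("need >= 2 chromosomes")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")


@dataclass
class IslandSpec:
    """Symmetric island model: d demes, equal sampling, migration Nm per deme."""

    n_demes: int
    sample_size: int
    nm: float
    theta: float
    length_bp: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_demes < 2:
            raise ValueError("need >= 2 demes")
        if self.nm < 0:
            raise ValueError("nm must be >= 0")


@dataclass
class StarSpec:
    """n descendants of one ancestor t years ago, mutation rate mu/site/year."""

    n_chromosomes: int
    length_bp: int
    mu: float
    t_years: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.length_bp) <= 0 or self.mu < 0 or self.t_years < 0:
            raise ValueError("all star-spec parameters must be positive")


# ---------------------------------------------------------------------------
# genealogy machinery
# ---------------------------------------------------------------------------

def _kingman_tree(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Neutral coalescent genealogy: (parent, node_time) for 2n-1 nodes.

    Tips are nodes 0..n-1 at time 0; times are in units of 2N generations.
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active[i] = nxt
        active.pop(j)
        nxt += 1
    return parent, time


def _island_tree(
    n_demes: int, sample_size: int, nm: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Structured coalescent genealogy under the symmetric island model.

    In units of 2N generations (N the diploid deme size) two lineages in the
    same deme coalesce at rate 1 per pair, and each lineage migrates to a
    uniformly chosen other deme at rate 2*Nm.  With Nm = 0 the lineages of
    distinct demes never coalesce, so a vanishing Kingman rate is injected
    once each deme has coalesced to a single lineage (deep divergence limit
    is exercised only with nm > 0 fixtures).
    """
    n = n_demes * sample_size
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    lineage = list(range(n))
    deme = [i // sample_size for i in range(n)]
    t = 0.0
    nxt = n
    mig_rate_per_lineage = 2.0 * nm
    while len(lineage) > 1:
        k = len(lineage)
        per_deme: dict[int, list[int]] = {}
        for idx, d in enumerate(deme):
            per_deme.setdefault(d, []).append(idx)
        coal_rate = sum(len(v) * (len(v) - 1) / 2.0 for v in per_deme.values())
        mig_rate = mig_rate_per_lineage * k
        total = coal_rate + mig_rate
        if total == 0:
            # nm = 0 with every deme down to one lineage: the demes are fully
            # isolated; merge the stragglers in a deeply diverged ancestral
            # panmictic phase (50 x 2N generations back)
            t += 50.0
            deme = [0] * k
            continue
        t += rng.exponential(1.0 / total)
        if rng.uniform() < coal_rate / total:
            demes_w = [(d, len(v) * (len(v) - 1) / 2.0) for d, v in per_deme.items() if len(v) > 1]
            weights = np.array([w for _, w in demes_w])
            d_pick = demes_w[rng.choice(len(demes_w), p=weights / weights.sum())][0]
            members = per_deme[d_pick]
            i, j = sorted(rng.choice(len(members), size=2, replace=False))
            a_idx, b_idx = members[i], members[j]
            a, b = lineage[a_idx], lineage[b_idx]
            parent[a] = parent[b] = nxt
            time[nxt] = t
            lineage[a_idx] = nxt
            deme[a_idx] = d_pick
            lineage.pop(b_idx)
            deme.pop(b_idx)
            nxt += 1
        else:
            idx = int(rng.integers(k))
            others = [d for d in range(n_demes) if d != deme[idx]]
            deme[idx] = int(others[rng.integers(len(others))])
    return parent, time


def _drop_mutations(
    parent: np.ndarray,
    time: np.ndarray,
    n_tips: int,
    theta: float,
    length_bp: int,
    rng: np.random.Generator,
) -> list[tuple[int, np.ndarray]]:
    """Poisson(theta/2 per unit branch length) infinite-sites mutations.

    Returns (site index, boolean carrier mask over tips) per mutation; sites
    are unique (collisions resampled).
    """
    n_nodes = parent.size
    lengths = np.zeros(n_nodes)
    has_parent = parent >= 0
    lengths[has_parent] = time[parent[has_parent]] - time[has_parent]
    total = float(lengths.sum())
    n_mut = rng.poisson(0.5 * theta * total) if total > 0 and theta > 0 else 0
    if n_mut == 0:
        return []
    # descendant tip masks per node
    masks = np.zeros((n_nodes, n_tips), dtype=bool)
    masks[np.arange(n_tips), np.arange(n_tips)] = True
    for v in range(n_nodes):  # children precede parents by construction
        p = parent[v]
        if p >= 0:
            masks[p] |= masks[v]
    branch_idx = rng.choice(n_nodes, size=n_mut, p=lengths / total)
    sites: list[int] = []
    used: set[int] = set()
    if n_mut > length_bp:
        raise ValueError("more mutations than sites; increase length_bp or lower theta")
    for _ in range(n_mut):
        s = int(rng.integers(length_bp))
        while s in used:
            s = int(rng.integers(length_bp))
        used.add(s)
        sites.append(s)
    return [(s, masks[b]) for s, b in zip(sites, branch_idx)]


def _sequences_from_mutations(
    n_tips: int,
    length_bp: int,
    mutations: list[tuple[int, np.ndarray]],
    rng: np.random.Generator,
    prefix: str = "chr",
) -> list[SequenceRecord]:
    root = _BASES[rng.integers(0, 4, size=length_bp)]
    seqs = np.tile(root, (n_tips, 1))
    for site, carriers in mutations:
        anc = root[site]
        derived = rng.choice([b for b in "ACGT" if b != anc])
        seqs[carriers, site] = derived
    width = len(str(n_tips))
    return [
        SequenceRecord(f"{prefix}{i + 1:0{width}d}", "".join(seqs[i]))
        for i in range(n_tips)
    ]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_coalescent_alignment(spec: CoalescentSpec) -> HaplotypeAlignment:
    """Neutral panmictic coalescent sample as an aligned FASTA-ready object."""
    rng = np.random.default_rng(spec.seed)
    parent, time = _kingman_tree(spec.n_chromosomes, rng)
    muts = _drop_mutations(parent, time, spec.n_chromosomes, spec.theta, spec.length_bp, rng)
    return HaplotypeAlignment(
        _sequences_from_mutations(spec.n_chromosomes, spec.length_bp, muts, rng)
    )


def simulate_island_samples(spec: IslandSpec) -> tuple[HaplotypeAlignment, PopulationMap]:
    """Structured island-model sample with deme labels.

    At equilibrium the coalescent-time differentiation of a d-deme island
    model satisfies F_ST = 1/(1 + 4*Nm*(d/(d-1))**2), the finite-d refinement
    of the textbook 1/(1 + 4*Nm).
    """
    rng = np.random.default_rng(spec.seed)
    parent, time = _island_tree(spec.n_demes, spec.sample_size, spec.nm, rng)
    n = spec.n_demes * spec.sample_size
    muts = _drop_mutations(parent, time, n, spec.theta, spec.length_bp, rng)
    records = _sequences_from_mutations(n, spec.length_bp, muts, rng)
    assignments = [
        (records[i].id, f"deme{i // spec.sample_size + 1}") for i in range(n)
    ]
    return HaplotypeAlignment(records), PopulationMap(assignments)


def generate_star_haplotypes(spec: StarSpec) -> HaplotypeAlignment:
    """n copies of one root haplotype, each with Poisson(L*mu*t) private mutations."""
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_chromosomes, spec.length_bp
    counts = rng.poisson(L * spec.mu * spec.t_years, size=n)
    mutations: list[tuple[int, np.ndarray]] = []
    used: set[int] = set()
    if counts.sum() > L:
        raise ValueError("more mutations than sites; increase length_bp")
    for tip, c in enumerate(counts):
        for _ in range(int(c)):
            s = int(rng.integers(L))
            while s in used:
                s = int(rng.integers(L))
            used.add(s)
            mask = np.zeros(n, dtype=bool)
            mask[tip] = True
            mutations.append((s, mask))
    return HaplotypeAlignment(_sequences_from_mutations(n, L, mutations, rng))


def generate_preference_trials(
    ec50: float,
    h: float,
    concentrations: tuple[float, ...] = (1.0, 10.0, 100.0, 250.0, 1000.0),
    trials: int = 6,
    noise_sd: float = 0.05,
    seed: int | None = None,
) -> PreferenceTrialSet:
    """Two-bottle preference trials on the half-logistic curve with noise.

    Defaults mirror the behavioural design: PTC at 1, 10, 100, 250 and
    1000 uM, six trials per concentration.  Trial ratios are the model value
    plus truncated Gaussian noise, clamped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    ratios = []
    for x in conc:
        f = preference_model(x, ec50, h)
        vals = np.clip(f + rng.normal(0.0, noise_sd, size=trials), 0.0, 1.0)
        ratios.append(vals)
    return PreferenceTrialSet(conc, ratios)


def generate_titration_curves(
    i_min: float,
    i_max: float,
    ec50: float,
    h: float,
    concentrations: tuple[float, ...],
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TitrationCurve:
    """Replicate dF/F responses on the increasing 4PL with Gaussian noise.

    Three replicates per point by default, matching a triplicate-measurement
    titration design.
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    responses = []
    for x in conc:
        f = titration_model(x, i_min, i_max, ec50, h)
        responses.append(f + rng.normal(0.0, noise_sd, size=replicates))
    return TitrationCurve(conc, responses)
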