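"""Forward simulation of a new neutral allele with emigration.

The experiment: a single copy of a neutral allele appears in a diploid
Wright-Fisher deme of effective size N (2N chromosomes).  Each generation,
first every allele copy emigrates independently with probability m = Nm/N
(emigrant copies are replaced by non-carrier immigrants, keeping the census
size constant), then the next generation is drawn binomially at the
post-migration frequency.  A replicate ends when the allele is lost, when
its frequency first reaches the target q, or at a safety cap.

Quantities of interest, both conditioned on reaching q:

* the mean first-passage time in units of N generations, and
* the "privacy" probability — the chance that no copy ever emigrated
  before the target frequency was reached.

The diffusion limit of the conditioned first-passage expectation,
t(q) = (4/q)[(1-q)ln(1-q) + q] in units of N generations, serves as the
closed-form cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpansionConfig",
    "ExpansionResult",
    "simulate_expansion_replicate",
    "run_expansion",
    "estimate_first_passage_time",
    "estimate_privacy_probability",
    "diffusion_expected_time",
    "generations_to_years",
]


@dataclass
class ExpansionConfig:
    """Parameters of the drift+migration expansion experiment.

    ``replicates`` counts *successful* (target-reaching) replicates; the
    simulator keeps launching attempts until that many successes accrue and
    reports the attempt count alongside.  ``nm`` is the island-model
    migration parameter (expected emigrant chromosomes per generation is
    2*x*Nm at allele frequency x).
    """

    N: int
    q_target: float
    nm: float = 0.0
    replicates: int = 1000
    seed: int | None = None
    max_generations: int | None = None  # default 100 N

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not (1.0 / (2 * self.N) <= self.q_target <= 1.0):
            raise ValueError("q_target must lie in [1/(2N), 1]")
        if self.nm < 0:
            raise ValueError("nm must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.max_generations is None:
            self.max_generations = 100 * self.N

    @property
    def target_copies(self) -> int:
        return math.ceil(self.q_target * 2 * self.N - 1e-9)

    @property
    def migration_rate(self) -> float:
        """Per-chromosome emigration probability per generation, m = Nm/N."""
        return self.nm / self.N


@dataclass
class ExpansionResult:
    """Outcome of a batch of expansion replicates (successes only retained)."""

    config: ExpansionConfig
    attempts: int
    first_passage_generations: np.ndarray  # one entry per success
    privacy_retained: np.ndarray           # bool per success
    censored: int = 0

    @property
    def successes(self) -> int:
        return int(self.first_passage_generations.size)

    @property
    def mean_time_in_N_units(self) -> float:
        return float(np.mean(self.first_passage_generations)) / self.config.N

    @property
    def time_se_in_N_units(self) -> float:
        g = self.first_passage_generations
        return float(np.std(g, ddof=1) / math.sqrt(g.size)) / self.config.N

    @property
    def privacy_probability(self) -> float:
        return float(np.mean(self.privacy_retained))

    @property
    def privacy_se(self) -> float:
        p = self.privacy_probability
        return math.sqrt(p * (1 - p) / self.privacy_retained.size)


def simulate_expansion_replicate(
    config: ExpansionConfig, rng: np.random.Generator
) -> tuple[bool, int, bool]:
    """One replicate: returns (reached_target, generations, any_emigration).

    The allele starts at 1 copy among 2N chromosomes; migration precedes
    reproduction each generation.  A replicate hitting the generation cap is
    reported as unreached with ``generations`` equal to the cap (callers
    treat it as censored).
    """
    two_n = 2 * config.N
    target = config.target_copies
    m = config.migration_rate
    count = 1
    emigrated = False
    if count >= target:
        return True, 0, False
    for gen in range(1, config.max_generations + 1):
        if m > 0 and count > 0:
            em = rng.binomial(count, m)
            if em:
                emigrated = True
                count -= em
        count = rng.binomial(two_n, count / two_n)
        if count == 0:
            return False, gen, emigrated
        if count >= target:
            return True, gen, emigrated
    return False, config.max_generations, emigrated


def _run_attempt_batch(
    config: ExpansionConfig, size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized batch of attempts; returns (success gens, privacy, censored)."""
    two_n = 2 * config.N
    target = config.target_copies
    m = config.migration_rate
    count = np.ones(size, dtype=np.int64)
    emig = np.zeros(size, dtype=bool)
    gens_out: list[np.ndarray] = []
    priv_out: list[np.ndarray] = []
    censored = 0
    if target <= 1:
        return np.zeros(size, dtype=np.int64), np.ones(size, dtype=bool), 0
    gen = 0
    while count.size:
        gen += 1
        if gen > config.max_generations:
            censored += count.size
            break
        if m > 0:
            em = rng.binomial(count, m)
            newly = em > 0
            if newly.any():
                emig |= newly
                count = count - em
        count = rng.binomial(two_n, count / two_n)
        won = count >= target
        lost = count == 0
        if won.any():
            n_w = int(won.sum())
            gens_out.append(np.full(n_w, gen, dtype=np.int64))
            priv_out.append(~emig[won])
        keep = ~(won | lost)
        count = count[keep]
        emig = emig[keep]
    gens = np.concatenate(gens_out) if gens_out else np.zeros(0, dtype=np.int64)
    priv = np.concatenate(priv_out) if priv_out else np.zeros(0, dtype=bool)
    return gens, priv, censored


def run_expansion(config: ExpansionConfig) -> ExpansionResult:
    """Run attempts until ``config.replicates`` successes are collected.

    Lost replicates count as attempts and are excluded from the time and
    privacy estimates (conditioning on reaching the target); censored
    replicates (generation cap) are excluded with a warning.
    """
    rng = np.random.default_rng(config.seed)
    # success probability of a single new neutral copy is ~ 1/(2 N q)
    p_hit = 1.0 / (2 * config.N * config.q_target)
    gens_all: list[np.ndarray] = []
    priv_all: list[np.ndarray] = []
    attempts = 0
    censored = 0
    successes = 0
    while successes < config.replicates:
        need = config.replicates - successes
        size = int(min(max(need / p_hit * 1.2, 1000), 4_000_000))
        gens, priv, cens = _run_attempt_batch(config, size, rng)
        attempts += size
        censored += cens
        gens_all.append(gens)
        priv_all.append(priv)
        successes += gens.size
        if attempts > 5e8:  # pragma: no cover - pathological configs
            raise RuntimeError("expansion simulation failed to accumulate successes")
    if censored:
        warnings.warn(f"{censored} replicates hit the generation cap and were excluded")
    # keep every success from the attempted batches: within a batch successes
    # surface in generation order, so truncating to a fixed count would keep
    # the fastest trajectories and bias the mean downward
    gens = np.concatenate(gens_all)
    priv = np.concatenate(priv_all)
    return ExpansionResult(config, attempts, gens, priv, censored)


def estimate_first_passage_time(config: ExpansionConfig) -> tuple[float, float]:
    """Mean conditioned first-passage time in N-generation units, with SE."""
    result = run_expansion(config)
    if result.successes == 0:
        raise RuntimeError("no replicate reached the target frequency")
    return result.mean_time_in_N_units, result.time_se_in_N_units


def estimate_privacy_probability(config: ExpansionConfig) -> tuple[float, float]:
    """Probability that no allele copy emigrated before reaching the target."""
    result = run_expansion(config)
    if result.successes == 0:
        raise RuntimeError("no replicate reached the target frequency")
    return result.privacy_probability, result.privacy_se


def diffusion_expected_time(q_target: float) -> float:
    """Diffusion-limit conditioned first-passage time, in N generations.

    For a neutral allele starting from a vanishing frequency, the expected
    time to first reach frequency q, conditional on doing so, tends to
    (4/q)[(1-q)ln(1-q) + q] N generations as N grows.
    """
    if not 0 < q_target < 1:
        raise ValueError("q_target must lie strictly between 0 and 1")
    q = q_target
    return (4.0 / q) * ((1.0 - q) * math.log(1.0 - q) + q)


def generations_to_years(
    time_in_N_units: float, N: float, generation_time: float
) -> float:
    """Convert a time in N-generation units to years: t * N * generation_time."""
    if time_in_N_units < 0 or N <= 0 or generation_time <= 0:
        raise ValueError("all arguments must be positive")
    return time_in_N_units * N * generation_time
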