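"""Star-phylogeny Poisson bounds on the age of an identical-haplotype cluster.

If n chromosomes carry byte-identical haplotypes over L monitored base
pairs and descend from a common ancestor t years ago under a star
phylogeny, the total branch length is n*t years and the number of
mutations is Poisson with mean n*L*mu*t.  Observing zero mutations caps
the age: the survival probability exp(-n*L*mu*t) must stay above the
chosen threshold alpha.  The star assumption is conservative — any real
genealogy has less total branch length, so the true bound can only be
tighter than the one reported here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = ["AgeBound", "poisson_upper_bound", "single_mutation_waiting_time"]


@dataclass(frozen=True)
class AgeBound:
    """Upper bound on cluster age from zero observed mutations.

    ``t_upper_years`` is the largest integer t with exp(-n*L*mu*t) > alpha;
    ``t_continuous_years`` is the real-valued solution -ln(alpha)/(n*L*mu).
    """

    n_chromosomes: int
    length_bp: int
    mu: float
    alpha: float
    rate_per_year: float
    t_upper_years: int
    t_continuous_years: float


def poisson_upper_bound(n: int, length_bp: int, mu: float, alpha: float) -> AgeBound:
    """Largest integer age (years) keeping P(no mutation) above alpha.

    ``n`` identical chromosomes, ``length_bp`` monitored sites, ``mu``
    mutations per site per year.  alpha >= 1 yields t = 0 with a warning.
    """
    if n <= 0 or length_bp <= 0 or mu <= 0:
        raise ValueError("n, length_bp and mu must be positive")
    if not 0 < alpha:
        raise ValueError("alpha must lie in (0, 1)")
    rate = n * length_bp * mu
    if alpha >= 1:
        warnings.warn("alpha >= 1 leaves no admissible age; returning t = 0")
        return AgeBound(n, length_bp, mu, alpha, rate, 0, 0.0)
    continuous = -math.log(alpha) / rate
    t = math.floor(continuous)
    # strict inequality at integer years; back off if floating point landed on it
    while t > 0 and not math.exp(-rate * t) > alpha:
        t -= 1
    return AgeBound(n, length_bp, mu, alpha, rate, t, continuous)


def single_mutation_waiting_time(length_bp: int, mu: float) -> float:
    """Expected years for one mutation on a single lineage: 1/(L*mu)."""
    if length_bp <= 0 or mu <= 0:
        raise ValueError("length_bp and mu must be positive")
    return 1.0 / (length_bp * mu)
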