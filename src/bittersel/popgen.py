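"""Diversity and differentiation statistics.

Implements the classical within-population summaries (nucleotide diversity
pi, Watterson's theta, Tajima's D with a coalescent null), Hudson-style
pairwise F_ST with island-model Nm conversion, haplotype sharing spectra,
and Nei-Gojobori synonymous/nonsynonymous site accounting for a coding
sequence.

All per-site statistics are stored as fractions; the reporting helpers
multiply by 100 to express them as percent, the convention of the field's
summary tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import INDEL, MISSING, HaplotypeAlignment, PopulationMap

__all__ = [
    "DiversitySummary",
    "FstResult",
    "HaplotypeSpectrum",
    "SiteCounts",
    "nucleotide_diversity",
    "segregating_sites",
    "effective_length",
    "watterson_theta",
    "tajimas_d",
    "tajima_d_pvalue",
    "diversity_summary",
    "pairwise_fst",
    "nm_from_fst",
    "fst_from_nm",
    "fst_nm_table",
    "haplotype_spectrum",
    "count_syn_nonsyn_sites",
    "classify_snv",
]


# ---------------------------------------------------------------------------
# within-population diversity
# ---------------------------------------------------------------------------

def _usable_columns(alignment: HaplotypeAlignment) -> list[int]:
    """Columns used for site counting: indel and missing columns excluded."""
    return [i for i, c in enumerate(alignment.site_classes) if c not in (INDEL, MISSING)]


def effective_length(alignment: HaplotypeAlignment, chromosomes: Iterable[str] | None = None) -> int:
    """Number of comparable sites (neither gapped nor missing) in the subset."""
    sub = alignment if chromosomes is None else alignment.subset(chromosomes)
    return len(_usable_columns(sub))


def _seq_matrix(alignment: HaplotypeAlignment) -> np.ndarray:
    return np.array([list(r.sequence) for r in alignment.records])


def segregating_sites(alignment: HaplotypeAlignment, chromosomes: Iterable[str] | None = None) -> int:
    """Count of polymorphic (substitution) columns among comparable sites."""
    sub = alignment if chromosomes is None else alignment.subset(chromosomes)
    return sum(1 for c in sub.site_classes if c == "substitution")


def nucleotide_diversity(
    alignment: HaplotypeAlignment, chromosomes: Iterable[str] | None = None
) -> float:
    """Nucleotide diversity pi per site.

    Mean pairwise difference count over all unordered chromosome pairs,
    divided by the number of comparable sites.  Requires >= 2 chromosomes.
    """
    sub = alignment if chromosomes is None else alignment.subset(chromosomes)
    n = len(sub.records)
    if n < 2:
        raise ValueError("nucleotide diversity requires at least 2 chromosomes")
    cols = _usable_columns(sub)
    if not cols:
        raise ValueError("no comparable sites (all columns gapped or missing)")
    mat = _seq_matrix(sub)[:, cols]
    total = 0
    for i, j in combinations(range(n), 2):
        total += int(np.sum(mat[i] != mat[j]))
    n_pairs = n * (n - 1) // 2
    return total / n_pairs / len(cols)


def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1..k} 1/i (Watterson's denominator uses a_{n-1})."""
    return sum(1.0 / i for i in range(1, k + 1))


def watterson_theta(S: int, n_chromosomes: int, effective_length: int) -> float:
    """Watterson's theta per site: S / (a_{n-1} * L)."""
    if n_chromosomes < 2:
        raise ValueError("Watterson's theta requires n >= 2 chromosomes")
    if effective_length <= 0:
        raise ValueError("effective length must be positive")
    if S == 0:
        return 0.0
    return S / (harmonic_number(n_chromosomes - 1) * effective_length)


def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of Tajima's (1989) variance of pi_total - S/a1."""
    a1 = harmonic_number(n - 1)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(pi: float, S: int, n_chromosomes: int, effective_length: int) -> float:
    """Tajima's D from per-site pi, segregating sites S, n, and length L.

    Returns NaN (undefined) when S = 0.
    """
    n = n_chromosomes
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2 chromosomes")
    if S == 0:
        return math.nan
    a1 = harmonic_number(n - 1)
    e1, e2 = _tajima_constants(n)
    pi_total = pi * effective_length
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:  # n = 2 collapses the variance; D is undefined
        return math.nan
    return (pi_total - S / a1) / math.sqrt(var)


def _simulate_null_d(
    n: int, theta_locus: float, replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of D: neutral coalescent, Poisson mutations at theta.

    For each replicate a Kingman genealogy of n tips is traversed epoch by
    epoch; mutations fall as Poisson(theta/2 x epoch branch length) and each
    hits a uniformly chosen active lineage, whose descendant count gives the
    derived-allele count.  S and total pi follow directly, so no sequences
    are materialised.  Replicates with S = 0 yield NaN (D undefined there).
    """
    out = np.empty(replicates)
    denom_pairs = n * (n - 1) / 2.0
    a1 = harmonic_number(n - 1)
    e1, e2 = _tajima_constants(n)
    for r in range(replicates):
        counts = [1] * n  # descendant tips per active lineage
        S = 0
        pi_sum = 0.0  # sum over mutations of c*(n-c)
        k = n
        while k > 1:
            rate = k * (k - 1) / 2.0
            t = rng.exponential(1.0 / rate)
            n_mut = rng.poisson(0.5 * theta_locus * k * t)
            if n_mut:
                hits = rng.integers(0, k, size=n_mut)
                for h in hits:
                    c = counts[h]
                    pi_sum += c * (n - c)
                S += n_mut
            i, j = rng.choice(k, size=2, replace=False)
            if i > j:
                i, j = j, i
            counts[i] += counts[j]
            counts.pop(j)
            k -= 1
        if S == 0:
            out[r] = math.nan
            continue
        pi_total = pi_sum / denom_pairs
        var = e1 * S + e2 * S * (S - 1)
        out[r] = (pi_total - S / a1) / math.sqrt(var)
    return out


def tajima_d_pvalue(
    d_obs: float,
    n_chromosomes: int,
    theta: float,
    effective_length: int,
    replicates: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided Monte-Carlo p-value for Tajima's D.

    Neutral coalescent replicates are simulated at the observed per-site
    theta (times L), with Poisson mutations along lineages and no
    recombination; p = Pr(|D_sim| >= |d_obs|) among replicates where D is
    defined.  Deterministic given the seed.  theta = 0 returns NaN.
    """
    if replicates < 100:
        raise ValueError("at least 100 replicates required")
    if theta == 0 or math.isnan(d_obs):
        return math.nan
    rng = np.random.default_rng(seed)
    sims = _simulate_null_d(n_chromosomes, theta * effective_length, replicates, rng)
    sims = sims[~np.isnan(sims)]
    if sims.size == 0:
        return math.nan
    return float(np.mean(np.abs(sims) >= abs(d_obs)))


@dataclass
class DiversitySummary:
    """Per-population diversity summary (pi and theta as per-site fractions)."""

    population: str
    n_chromosomes: int
    S: int
    n_haplotypes: int
    pi: float
    theta_w: float
    tajima_d: float
    d_pvalue: float = math.nan

    def as_percent_row(self) -> dict[str, object]:
        """Row formatted like a diversity table: pi, theta in % (3 decimals)."""
        return {
            "population": self.population,
            "n_chromosomes": self.n_chromosomes,
            "S": self.S,
            "h": self.n_haplotypes,
            "pi_percent": round(self.pi * 100, 3),
            "theta_percent": round(self.theta_w * 100, 3),
            "tajima_d": round(self.tajima_d, 2) if not math.isnan(self.tajima_d) else "NA",
            "d_pvalue": round(self.d_pvalue, 4) if not math.isnan(self.d_pvalue) else "NA",
        }


def diversity_summary(
    alignment: HaplotypeAlignment,
    pop_map: PopulationMap | None = None,
    *,
    d_replicates: int = 0,
    seed: int | None = None,
) -> list[DiversitySummary]:
    """Summaries per population (plus pooled "all") from a phased alignment.

    With ``d_replicates`` > 0, a coalescent p-value for Tajima's D is
    attached to each row (expensive for large n).
    """
    groups: list[tuple[str, list[str]]] = [("all", alignment.ids)]
    if pop_map is not None:
        groups = [(p, pop_map.chromosomes(p)) for p in pop_map.populations] + groups
    rows = []
    for name, ids in groups:
        sub = alignment.subset(ids)
        n = len(ids)
        S = segregating_sites(sub)
        L = effective_length(sub)
        pi = nucleotide_diversity(sub)
        theta = watterson_theta(S, n, L)
        d = tajimas_d(pi, S, n, L)
        p = math.nan
        if d_replicates and S > 0:
            p = tajima_d_pvalue(d, n, theta, L, d_replicates, seed)
        h = len({r.sequence for r in sub.records})
        rows.append(DiversitySummary(name, n, S, h, pi, theta, d, p))
    return rows


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Pairwise Hudson F_ST and the island-model migration estimate Nm."""

    pop_a: str
    pop_b: str
    fst: float
    nm: float


def _mean_pairwise_diff(mat: np.ndarray, idx_a: Sequence[int], idx_b: Sequence[int] | None = None) -> float:
    """Mean number of differences per pair, within idx_a or between a and b."""
    if idx_b is None:
        pairs = list(combinations(idx_a, 2))
    else:
        pairs = [(i, j) for i in idx_a for j in idx_b]
    if not pairs:
        return math.nan
    return float(np.mean([np.sum(mat[i] != mat[j]) for i, j in pairs]))


def pairwise_fst(
    alignment: HaplotypeAlignment, pop_map: PopulationMap, pop_a: str, pop_b: str
) -> FstResult:
    """Hudson-Slatkin-Maddison F_ST = 1 - Hw/Hb for two populations.

    Hw is the average of the two within-population mean pairwise differences,
    Hb the between-population mean pairwise difference.  Hb = 0 (identical,
    monomorphic populations) yields NaN.
    """
    ids_a = pop_map.chromosomes(pop_a)
    ids_b = pop_map.chromosomes(pop_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each population needs >= 2 chromosomes")
    sub = alignment.subset(ids_a + ids_b)
    cols = _usable_columns(sub)
    mat = _seq_matrix(sub)[:, cols] if cols else _seq_matrix(sub)[:, :0]
    na = len(ids_a)
    idx_a = list(range(na))
    idx_b = list(range(na, na + len(ids_b)))
    hw = 0.5 * (_mean_pairwise_diff(mat, idx_a) + _mean_pairwise_diff(mat, idx_b))
    hb = _mean_pairwise_diff(mat, idx_a, idx_b)
    fst = math.nan if hb == 0 else 1.0 - hw / hb
    return FstResult(pop_a, pop_b, fst, nm_from_fst(fst) if not math.isnan(fst) else math.nan)


def nm_from_fst(fst: float) -> float:
    """Migration estimate Nm = (1 - F_ST)/(4 F_ST); F_ST <= 0 maps to +inf."""
    if math.isnan(fst):
        return math.nan
    if fst > 1:
        raise ValueError("F_ST cannot exceed 1")
    if fst <= 0:
        return math.inf
    return (1.0 - fst) / (4.0 * fst)


def fst_from_nm(nm: float) -> float:
    """Inverse of :func:`nm_from_fst`: F_ST = 1/(1 + 4 Nm)."""
    if nm < 0:
        raise ValueError("Nm must be non-negative")
    return 1.0 / (1.0 + 4.0 * nm)


def fst_nm_table(alignment: HaplotypeAlignment, pop_map: PopulationMap) -> pd.DataFrame:
    """Matrix with pairwise F_ST below and Nm above the diagonal, plus means.

    Mirrors the layout of a pairwise-migration table: the last column holds
    each population's mean Nm over its pairs, the last row the mean F_ST.
    """
    pops = pop_map.populations
    df = pd.DataFrame("", index=pops + ["mean_fst"], columns=pops + ["mean_nm"], dtype=object)
    nm_vals: dict[str, list[float]] = {p: [] for p in pops}
    fst_vals: dict[str, list[float]] = {p: [] for p in pops}
    for i, a in enumerate(pops):
        for j, b in enumerate(pops):
            if i >= j:
                continue
            res = pairwise_fst(alignment, pop_map, a, b)
            df.loc[b, a] = round(res.fst, 2)
            df.loc[a, b] = round(res.nm, 2) if math.isfinite(res.nm) else "inf"
            for p in (a, b):
                fst_vals[p].append(res.fst)
                nm_vals[p].append(res.nm)
    for p in pops:
        finite = [v for v in nm_vals[p] if math.isfinite(v)]
        df.loc[p, "mean_nm"] = round(float(np.mean(finite)), 2) if finite else "inf"
        df.loc["mean_fst", p] = round(float(np.mean(fst_vals[p])), 2) if fst_vals[p] else ""
    return df


# ---------------------------------------------------------------------------
# haplotype sharing
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSpectrum:
    """Per-population haplotype counts and shared/private chromosome fractions.

    A haplotype is *private* iff it is observed in exactly one population;
    fractions are computed over chromosomes, so in each population
    shared_fraction + private_fraction = 1.
    """

    table: pd.DataFrame  # columns: population, haplotype, count, frequency, private
    shared_fraction: dict[str, float]
    private_fraction: dict[str, float]


def haplotype_spectrum(alignment: HaplotypeAlignment, pop_map: PopulationMap) -> HaplotypeSpectrum:
    """Collapse identical sequences and tabulate sharing across populations."""
    seq_by_id = {r.id: r.sequence for r in alignment.records}
    # stable haplotype labels: by decreasing total count then sequence order
    totals: dict[str, int] = {}
    counts: dict[tuple[str, str], int] = {}
    for chrom, pop in pop_map.assignments:
        seq = seq_by_id[chrom]
        counts[(pop, seq)] = counts.get((pop, seq), 0) + 1
        totals[seq] = totals.get(seq, 0) + 1
    order = sorted(totals, key=lambda s: (-totals[s], s))
    label = {seq: f"H{i + 1}" for i, seq in enumerate(order)}
    pops_of: dict[str, set[str]] = {}
    for (pop, seq) in counts:
        pops_of.setdefault(seq, set()).add(pop)
    rows = []
    shared_fraction: dict[str, float] = {}
    private_fraction: dict[str, float] = {}
    for pop in pop_map.populations:
        pop_counts = {seq: c for (p, seq), c in counts.items() if p == pop}
        n_chrom = sum(pop_counts.values())
        private_chrom = 0
        for seq in sorted(pop_counts, key=lambda s: label[s]):
            c = pop_counts[seq]
            private = len(pops_of[seq]) == 1
            if private:
                private_chrom += c
            rows.append(
                {
                    "population": pop,
                    "haplotype": label[seq],
                    "count": c,
                    "frequency": c / n_chrom,
                    "private": private,
                }
            )
        private_fraction[pop] = private_chrom / n_chrom
        shared_fraction[pop] = 1.0 - private_fraction[pop]
    return HaplotypeSpectrum(pd.DataFrame(rows), shared_fraction, private_fraction)


# ---------------------------------------------------------------------------
# coding-sequence site accounting (Nei & Gojobori style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous and nonsynonymous site counts of a CDS."""

    syn_sites: float
    nonsyn_sites: float


_BASES = "ACGT"


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def count_syn_nonsyn_sites(cds: str) -> SiteCounts:
    """Fractional synonymous/nonsynonymous site counts summed over codons.

    Each codon position contributes (synonymous changes)/3 synonymous sites;
    changes that create a stop codon count as nonsynonymous, so every counted
    codon contributes exactly 3 sites in total.  The terminal stop codon
    itself (any codon translating to a stop) is excluded from counting.
    Empty input gives (0, 0).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    syn = 0.0
    nonsyn = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = _translate(codon)
        if aa == "*":
            continue  # stop codon is not a coding site
        for pos in range(3):
            s = 0
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if _translate(mut) == aa:
                    s += 1
            syn += s / 3.0
            nonsyn += (3 - s) / 3.0
    return SiteCounts(syn, nonsyn)


def classify_snv(cds: str, position: int, alt: str) -> str:
    """Classify a single-nucleotide change in a CDS.

    Returns one of ``synonymous``, ``nonsynonymous``, ``start-loss`` (a
    change in codon 1 destroying the ATG initiator) or ``nonsense`` (a new
    stop codon).  ``position`` is 1-based within the CDS.
    """
    cds = cds.upper()
    alt = alt.upper()
    if not 1 <= position <= len(cds):
        raise ValueError("position outside CDS")
    ref = cds[position - 1]
    if alt == ref:
        raise ValueError("alternate base equals the reference base")
    if alt not in _BASES:
        raise ValueError(f"invalid base {alt!r}")
    codon_idx = (position - 1) // 3
    off = (position - 1) % 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    mut = codon[:off] + alt + codon[off + 1 :]
    if codon_idx == 0 and codon == "ATG" and mut != "ATG":
        return "start-loss"
    aa_ref = _translate(codon)
    aa_mut = _translate(mut)
    if aa_mut == "*" and aa_ref != "*":
        return "nonsense"
    return "synonymous" if aa_mut == aa_ref else "nonsynonymous"
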