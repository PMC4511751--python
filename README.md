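# bittersel

Population-genetic and functional analyses for a recurring question in
molecular ecology: a derived allele is found in exactly one local
population, at a frequency far too high for a typical population-private
variant — did it get there by drift, or by positive selection?

The motivating system is the bitter-taste receptor gene *TAS2R38* in
Japanese macaques, where a loss-of-function allele (a start-codon change,
ATG>ACG) segregates at 29% in a single population while ordinary gene flow
connects that population to its neighbors.  The package implements the full
analysis chain for this kind of inference, with a synthetic-data module so
every stage is testable without any sequence download:

* **Diversity statistics** — nucleotide diversity π, Watterson's
  θ_W = S/(a_{n−1}·L), and Tajima's D with a two-sided p-value from neutral
  coalescent simulations (Poisson mutations along lineages, no
  recombination).
* **Differentiation and migration** — Hudson F_ST = 1 − H_w/H_b per
  population pair and the island-model conversion Nm = (1 − F_ST)/(4·F_ST);
  haplotype sharing spectra (shared vs population-private chromosome
  fractions).
* **Haplotype networks** — Bandelt-style median-joining networks with indel
  events weighted 2× substitutions, and a four-gamete scan that localizes
  recombination between the innermost incompatible site pair.
* **Allele expansion simulation** — forward Wright–Fisher simulation of a
  new neutral allele in a deme of size N with per-copy emigration
  probability Nm/N: conditioned first-passage times to a target frequency
  q (diffusion-limit check: t̄(q) = (4/q)[(1−q)ln(1−q) + q] in units of N
  generations) and the "allele privacy" probability that no copy emigrates
  before q is reached.
* **Haplotype age bounds** — for n identical chromosomes over L bp under a
  star phylogeny, the largest age t with exp(−n·L·μ·t) > α, plus the
  single-lineage mutation waiting time 1/(L·μ).
* **Dose-response fits** — Levenberg–Marquardt fits of the increasing
  four-parameter logistic f(x) = I_min + (I_max − I_min)/(1 + (EC50/x)^h)
  for calcium-imaging titrations (ΔF/F), and of the two-bottle preference
  model f(x) = 0.5/[1 + (x/EC50)^h], whose EC50 is the concentration where
  preference falls to 25% (half the chance level).

## Worked example

```python
import bittersel as b

# how long does a neutral allele need to reach 29%, and would it stay private?
cfg = b.ExpansionConfig(N=1000, q_target=0.29, nm=1.8, replicates=1000, seed=7)
res = b.run_expansion(cfg)
print(f"mean time: {res.mean_time_in_N_units:.2f} N generations")
print(f"privacy probability: {res.privacy_probability:.4f}")
print(f"diffusion check: {b.diffusion_expected_time(0.29):.3f} N generations")
print(f"age bound for 23 identical 10-kb haplotypes: "
      f"{b.poisson_upper_bound(23, 10_000, 1e-9, 0.05).t_upper_years:,} years")
```

prints

```
mean time: 0.62 N generations
privacy probability: 0.0000
diffusion check: 0.646 N generations
age bound for 23 identical 10-kb haplotypes: 13,024 years
```

Read: a neutral allele takes roughly 0.6–0.7·N generations to drift from
one copy to 29% (the no-migration diffusion expectation is 0.646·N), and
with Nm = 1.8 migrants per generation essentially no trajectory reaches
29% without leaking a copy into neighboring demes — so an allele that *is*
still private at 29% did not expand neutrally.  Meanwhile 23 identical
10-kb haplotypes cap the expansion's age at about 13,000 years.

The `examples/` directory has one short script per capability
(`python examples/allele_expansion.py`, `examples/diversity_statistics.py`,
…), each printing its numbers with a line on what they mean.  A thin CLI
mirrors the library: `bittersel stats|fst|network|fourgamete|agebound|simulate|fitdose|synth --help`.

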