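# Methods

This note records the models behind each module, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data tests
do and do not establish about real data.

## Alignments and site classes

Inputs are phased, equal-length haplotype sequences over {A,C,G,T,-,N}.
Each column is classed once, over the full record set: any gap makes the
column an *indel* column, otherwise any N makes it *missing*, otherwise it
is *substitution* or *invariant*.  Indel and missing columns are excluded
from S, π and θ site counts (the convention of standard summary-statistic
software); the effective length L used in per-site statistics is the count
of the remaining columns.  Alignment columns are 1-based in every report;
optional per-column genomic anchors (also 1-based) replace column indices
in labels when provided.  Note a consequence of whole-alignment column
classing: a column gapped in some population is excluded for all
populations, so per-population statistics from one alignment share a
common L.

## Diversity statistics

π is the mean pairwise difference count over all unordered chromosome
pairs divided by L.  Watterson's θ_W is S/(a_{n−1}·L) with a_k the k-th
harmonic number.  Tajima's D uses the 1989 constants
(a1, a2, b1, b2, c1, c2, e1, e2) on π·L and S; it is undefined (NaN) when
S = 0 and when n = 2 (the variance term collapses).  Statistics are stored
as fractions and formatted ×100 to three decimals for percent tables.

The D p-value is Monte-Carlo: neutral Kingman genealogies are simulated at
fixed θ equal to the observed θ_W (per locus), mutations fall as
Poisson(θ/2 per unit of coalescent branch length), and
p = Pr(|D_sim| ≥ |D_obs|), two-sided, among replicates where D is defined.
Fixed-θ conditioning (rather than fixed-S) was chosen because the
simulation is described as Poisson mutation along lineages; the choice
matters little for the moderate θ values involved but is flagged for
sensitivity testing.  The simulation never materializes sequences: each
mutation only needs the descendant count of the branch it hits, so S and
π·L follow from epoch-by-epoch bookkeeping and samples of ~10^3
chromosomes with 10^4 replicates stay desk-scale.

## Differentiation, migration, haplotype sharing

F_ST is the Hudson–Slatkin–Maddison estimator 1 − H_w/H_b, with H_w the
average of the two within-population mean pairwise differences and H_b the
between-population mean — the estimator the common summary software
reports.  Small samples can produce negative values; these are reported as
computed but map to an infinite-Nm flag in the conversion
Nm = (1 − F_ST)/(4·F_ST), whose inverse F_ST = 1/(1 + 4·Nm) round-trips
exactly on (0, 1].  The matrix writer mirrors the usual table layout:
F_ST below the diagonal, Nm above, means in the margins.

A haplotype is *private* iff it occurs in exactly one population;
shared/private fractions are over chromosomes, so the two fractions sum to
one per population.  Identical sequences (including gap characters)
collapse to one haplotype; labels are assigned by descending total count,
ties by sequence, so output is deterministic.

## Synonymous/nonsynonymous site counting

Fractional site counts follow the Nei–Gojobori (1986) accounting: each
position of each codon contributes (number of synonymous single-base
changes)/3 synonymous sites.  Two conventions were open.  This package
counts changes that *create* a stop codon as nonsynonymous (rather than
excluding those paths), and excludes the terminal stop codon itself from
counting.  With this convention every counted codon contributes exactly
3 sites, which is the accounting that reproduces a 1002-bp CDS splitting
into 239 + 760 = 999 sites over its 333 non-stop codons.  Transitions and
transversions are unweighted.  SNV classification is by codon translation
before/after, with two special cases checked first: a change destroying
the initiator ATG is *start-loss*, a change creating a stop is *nonsense*.

## Median-joining networks

Distinct haplotypes are condensed into weighted characters: one character
per substitution column (weight 1) and one per maximal run of indel
columns (event coding, default weight 2 — indels weighted twice as much as
substitutions, and a multi-column gap run counts as a single event so it
renders as one branch).  The construction iterates: build the ε-relaxed
minimum spanning network (an edge is feasible iff its weight is within ε
of the minimax path weight between its endpoints; ε = 0 default), form the
consensus (median) haplotype of every linked triple, and add the medians
of minimal connection cost (within ε); then prune median vectors whose
removal leaves the minimum spanning weight unchanged.  All candidate
orderings are lexicographic by node label, so the network is reproducible;
published median-joining software is order-dependent, so only distance
relations (adjacency, step counts), not the exact median-vector set,
should be compared across implementations.  Rooting with an outgroup is
metadata only: the graph stays undirected and the outgroup node is marked
root-adjacent.

On homoplasy-free (infinite-sites) data with ε = 0 the network's spanning
weight equals the parsimony length of the perfect phylogeny, and on
instances small enough for exhaustive Steiner search (≤ 3 variable sites)
it matches the brute-force optimum; both are enforced by tests.  For
larger, homoplastic data median-joining is a heuristic and optimality is
not guaranteed.

## Four-gamete scan

Only biallelic substitution columns are scanned.  A site pair showing all
four gametes is incompatible with a single tree under infinite sites.  For
a single crossover every incompatible pair spans the breakpoint, so the
reported interval is (max of left members, min of right members) — the
innermost incompatible pair flanking the compatible core.  If that
interval is empty the data need more than one breakpoint; the scan then
reports the narrowest incompatible pair and clears the single-breakpoint
flag rather than attempting multi-breakpoint inference.

## Expansion simulator

A diploid Wright–Fisher deme of size N (2N chromosomes); the focal allele
starts as one copy.  Each generation, in this order: (1) every allele copy
emigrates independently with probability m = Nm/N, and emigrant copies are
replaced by non-carrier immigrants (census size constant; expected
emigrant copies per generation is 2·x·Nm at frequency x); (2) binomial
resampling of 2N chromosomes at the post-migration frequency.  A replicate
ends at loss, at frequency ≥ q (copies ≥ ⌈2Nq⌉), or at the safety cap
(default 100·N generations, censored with a warning).  *Privacy* is the
event that no copy emigrated before the target was reached; a single
emigrant copy ends privacy, and whether emigrants establish elsewhere is
deliberately not modeled (conservative toward privacy).  Migration-then-
reproduction ordering is a documented convention; at these rates the
alternative ordering changes nothing detectable.

Estimates condition on success: lost replicates count as attempts but are
excluded from the time and privacy estimates, and `replicates` in the
configuration is the number of *successes* to accumulate.  The simulator
is vectorized over attempts; all successes from the attempted batches are
kept, because truncating to a fixed success count would preferentially
keep fast trajectories (successes surface in generation order within a
batch) and bias the mean time downward.

The closed-form check is the diffusion limit of the conditioned
first-passage expectation from a vanishing initial frequency,
t̄(q) = (4/q)[(1−q)ln(1−q) + q] in units of N generations (0.646 for
q = 0.29, 0.250 for q = 0.12).  At N = 1000 the discrete-generation
simulation sits a few percent above the limit and approaches it as N
grows; scale invariance (time in N units independent of N) and the
neutral fixation probability 1/(2N) at q = 1 are property-tested.
Conversion to years is the exact product t·N·generation-time; with
t = 0.69, N = 20,000 and 6-year generations this is 82,800 years (a source
rounding this to ≈84,000 is consistent with t ≈ 0.70).

## Age bounds

For n identical chromosomes over L bp under a star phylogeny the total
branch length is n·t years, so zero observed mutations has probability
exp(−n·L·μ·t).  The bound is the largest *integer* t keeping that survival
probability strictly above α (the continuous solution −ln(α)/(n·L·μ) is
also reported): n = 23, L = 10^4, μ = 10⁻⁹/site/yr, α = 0.05 gives
t = 13,024 (continuous 13,024.9).  L = 10^4 is used for the headline bound
(the round "10-kb" monitored region) rather than an exact flanking-region
length.  The star assumption is conservative: a non-star genealogy has
total branch length below n·t, so the bound can only tighten.  The
single-lineage waiting time is 1/(L·μ).  A Monte-Carlo property test
confirms that star-generated clusters at t equal to the bound are
mutation-free with probability ≈ α.

## Dose-response models

The printed four-parameter logistic in this literature is ambiguous about
orientation; the increasing form
f(x) = I_min + (I_max − I_min)/(1 + (EC50/x)^h) is adopted, because an
agonist titration rises with dose.  Preference data use
f(x) = 0.5/[1 + (x/EC50)^h], anchored at the 0.5 indifference level, so
f(EC50) = 0.25 identically — EC50 is *defined* as the concentration where
preference is half the chance level.  Both fits are Levenberg–Marquardt
least squares on per-concentration means (replicate SEs are carried for
reporting only); EC50 is parameterized on the log scale so positivity
needs no bound constraints.  Initialization: observed response extremes,
geometric-mean concentration for EC50, hill = 1.  Degenerate inputs (flat
response; preference means never below 0.5) raise a dedicated error rather
than returning an unstable fit.  An EC50 outside the observed
concentration range is flagged as extrapolated.  Fold differences are
max/min ratios, optionally rounded to the nearest ten.

## Synthetic-data generators

The coalescent generator is a direct Kingman simulation (exponential epoch
times, uniform pair merging) with infinite-sites mutations at rate θ/2 per
unit branch length, placed uniformly over the sequence with collisions
resampled; E[S] = θ·a_{n−1} and E[π·L] = θ are verified over replicates,
and one test cross-checks mean S against msprime as an independent oracle.
The island generator is the structured coalescent of a symmetric d-deme
island model: within-deme pairs coalesce at rate 1 (time in 2N units) and
each lineage migrates at rate 2·Nm; d = 10 by default so the reference
value 1/(1 + 4·Nm·(d/(d−1))²) — the finite-d refinement of 1/(1+4Nm) — is
a good target, and the ratio-of-averages Hudson estimator recovers it
within 20% in tests.  With Nm = 0 and every deme reduced to one lineage,
the remaining lineages are joined in a deeply diverged ancestral phase
(50·2N generations back), which exercises the F_ST → 1 limit without
overflowing the mutation budget.  The star generator gives each of n
chromosomes an independent Poisson(L·μ·t) mutation count.  Behavioural
fixtures add truncated Gaussian noise to the exact model curves (simpler
than binomial volume sampling and sufficient for recovery testing);
titration defaults are triplicate measurements, preference defaults are
six trials at 1, 10, 100, 250 and 1000 μM.

What the passing tests show: the estimators and fits recover the
parameters of data generated by their own assumed models, at the stated
Monte-Carlo tolerances.  What they do not show: robustness to real-data
features the generators omit — recombination within loci, recurrent and
context-dependent mutation, unphased or erroneous genotypes, unequal deme
sizes and non-equilibrium demography, and behavioral noise that is
heteroskedastic across concentrations.

## Problem sizes

Defaults used by the test suite and the acceptance script: expansion
experiments at N = 1000 with 5000 (first-passage) and 1000 (privacy)
successful replicates — comfortably past the ≥2000/≥1000 needed for the
quoted precision; coalescent property checks at n = 8–20 with 10^2–10^3
replicates; island checks with 10 demes × 8 samples over 60 replicates;
D p-values at 10^3–10^4 null replicates.  These sizes were chosen so the
whole suite runs in about a minute on one core while keeping every
Monte-Carlo assertion at ≥3σ margins.
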