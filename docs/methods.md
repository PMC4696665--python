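# Methods

This note records the models, estimator conventions, default parameters
and numerical choices behind `popmito`, and what the synthetic-data
generator does and does not emulate.

## Data model and site handling

An alignment is an equal-length matrix of IUPAC nucleotide characters
with a sample→population map. All site-level statistics use only
unambiguous residues (A/C/G/T): a segregating site carries ≥ 2 distinct
unambiguous bases, a parsimony-informative site carries ≥ 2 bases each
in ≥ 2 sequences, and pairwise difference counts use pairwise deletion
(a column counts for a pair only when both residues are unambiguous).
Per-site diversity keeps the full alignment length in the denominator,
the usual convention when π is reported over the analysed fragment.
Gaps are tolerated but flagged in logs; they never enter site counts.
The transition/transversion ratio is the ratio of *summed* pairwise
transition and transversion counts over all pairs (computed per column
from base counts), not a per-pair mean — the two differ on heterogeneous
data, and the summed form is the one that is exactly computable from
column base counts.

Haplotype identity is exact string identity. Sequences differing only at
an ambiguous base are therefore distinct haplotypes; this is
reproducible and conservative, and matters only for data with missing
calls. Haplotype labels H1…Hk follow first appearance in the input, so
every downstream artefact is deterministic.

## Diversity

Gene diversity h = n(1 − Σp²)/(n − 1) with Nei's (1987) variance
V(h) = (2/(n(n−1)))·{2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)²}; nucleotide
diversity π = k̄/L with V(π) = ((n+1)/(3(n−1)L))π +
(2(n²+n+3)/(9n(n−1)))π². Which variance estimator produced any given
published "±" column is often unstated; these closed forms are the
documented choice here, so reported SDs are comparable across runs of
this package but only approximately to other software.

## Neutrality tests

Tajima's D uses the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂)
with S counted as above and k̄ from pairwise deletion. D is reported as
*undefined* (never 0) when S = 0.

Fu's Fs takes θ̂ = k̄ (the π-based estimator, following Fu 1997 and
common practice in ARLEQUIN/DnaSP-style analyses) and evaluates
S′ = P(K ≥ k_obs | θ̂, n) under the Ewens sampling formula,
P(K = k) ∝ |s(n,k)| θ̂ᵏ, with unsigned Stirling numbers of the first
kind computed exactly as Python big integers via the recurrence
|s(n,k)| = |s(n−1,k−1)| + (n−1)|s(n−1,k)|. The log-odds is computed as
log A − log B where A and B are the upper and lower partial sums of the
allele-count distribution evaluated by log-sum-exp over exact
logarithms; this stays accurate when S′ approaches 0 or 1 and agrees
with exact rational arithmetic to better than 10⁻⁶ relative error (a
test enforces this for n ≤ 40; the construction is exact-log based, so
accuracy does not degrade at n of a few hundred). k_obs = 1 yields the
+∞ sentinel.

Significance is by simulation: neutral constant-size coalescent samples
conditioned on θ̂ = k̄ (optionally on S), with p the lower-tail
proportion of simulated statistics ≤ the observed one — the convention
appropriate when the alternative is expansion. The choice of simulation
(rather than a beta approximation) is deliberate: it makes the null
explicit and seedable.

## AMOVA and Φ-statistics

Molecular distance is the pairwise difference count, used directly as a
squared Euclidean distance (the conventional choice for haplotype
data). SSDs follow the standard decomposition — SSD_total =
(1/N)Σ_{i<j}d²ᵢⱼ, within-population and within-group terms analogous —
and variance components use the Excoffier, Smouse & Quattro (1992)
unequal-sample-size coefficients (n, n′, n″). Negative variance
components are retained, not truncated, so small negative Φ_ST values
can occur for undifferentiated pairs; this mirrors ARLEQUIN behaviour
and keeps the permutation null honest. Permutation schemes: individuals
among populations for Φ_ST, individuals among populations within groups
for Φ_SC, whole populations among groups for Φ_CT, with
P = (#{perm ≥ obs} + 1)/(perms + 1). The pairwise Φ_ST matrix entries
are literally two-population AMOVAs, so the identity between the two
code paths is exact and is asserted in tests. The default permutation
count for full analyses is 10,000; the acceptance script uses 1,000,
which resolves P at the 10⁻³ level it reports.

UPGMA is size-weighted average linkage with deterministic lexicographic
tie-breaking and negative input distances clamped to zero (they arise
from retained negative variance components). scipy's average-linkage
implementation serves as an independent oracle in the tests, not as the
implementation, because the tie-break and Newick conventions here are
part of the contract.

## Distances, trees, lineages

The Tamura (1992) three-parameter distance uses the *alignment-wide*
G+C content θ, not a per-pair average — a deliberate convention (other
software differs subtly); at θ = 0.5 it reduces exactly to the Kimura
two-parameter distance, which the tests assert. Saturated pairs (log
argument ≤ 0) are NaN with a warning; NJ refuses NaN inputs, and the
bootstrap fills replicate NaNs with 1.5× the largest finite distance so
replicate trees remain buildable. NJ itself and tree surgery come from
dendropy; rooting is on the outgroup branch (midpoint of that edge).
The substitution model is fixed to T92 rather than selected, since model
choice is outside this package's scope.

Lineage assignment is configuration, not inference: after outgroup
rooting, the two basal ingroup clades are named so the clade holding the
majority of a configured anchor population (default code "SMR") is
lineage "B". If the ingroup root is not bifurcating the assignment
fails loudly and asks for a manual anchor.

The median-joining network follows Bandelt, Forster & Röhl (1999) with
ε = 0 by default (the common software default). The ε-relaxed minimum
spanning network is computed via minimax path weights on an MST; for
every mutually linked triplet, the per-site majority median vector is a
candidate, added (in lexicographic triplet order, one at a time) when it
strictly reduces the spanning cost; unsampled vectors that stop reducing
cost are pruned. All-distinct sites in a median take the state of the
lexicographically smallest member — any choice gives the same cost, and
this one is deterministic. The network therefore always spans the
observed haplotypes, is connected, and never costs more than the MST
over observed haplotypes (property-tested; a brute-force Steiner
enumeration is the oracle for the canonical three-haplotype example).

## Mismatch distributions and expansion dating

Under sudden expansion (θ₀ → θ₁ at τ mutational units before present)
the default spectrum uses the θ₁ → ∞ simplification: F̂ⱼ is the
convolution of Poisson(τ) with the geometric equilibrium of θ₀. This is
the standard "sudden expansion" expectation and is the right default
when the estimator behind published τ values is undisclosed. The finite
θ₁ three-parameter form is available: the pre-expansion coalescence term
has the closed form geom(θ₁)ⱼ · P(j+1, τ(1+θ₁)/θ₁) with P the
regularized lower incomplete gamma, and it converges to the
simplification as θ₁ → ∞ (tested). Both forms are evaluated in log
space where overflow threatens.

Fitting minimises SSD = Σⱼ(Fⱼ − F̂ⱼ)² over the observed range by
bounded nonlinear least squares from a deterministic multistart
(moment-based τ ≈ spectrum mean minus θ₀, three θ₀ scales). The
goodness-of-fit P is a parametric bootstrap: simulate from the fitted
model, refit, count SSDs ≥ observed (an infinite fitted θ₁ is capped at
1000 for simulation, far above any resolvable value at these sample
sizes). Bimodality is operationalised as ≥ 2 local maxima after a 3-bin
moving average with plateau collapsing — a deliberately simple rule for
a qualitative judgement.

Dating uses τ = 2uT with 2u = 2·r·g·L (r: substitution rate per site
per year; g: generation years; L: sites), so T = τ/(2rgL). Defaults
r = 1.42 × 10⁻⁸/site/yr (the midpoint of the 1.17–1.66 %/Myr divergence
range used for this marker system, read as a per-site rate entering 2u)
and g = 1 yr. With τ = 0.932 and L = 792 this gives 41,435 years — the
identity T = τ/2u is exact arithmetic and is asserted to the year.

## Synthetic data: what it emulates and what it does not

Genealogies come from the Hudson coalescent (msprime, haploid), with
finite-sites JC69 mutations on a discrete genome (multiple hits
allowed — appropriate at L = 792 where real data violate infinite
sites); an optional HKY transition bias can mimic ts/tv ≈ 1. Because
the mutation model draws its own root allele per site, variant alleles
are relabelled by the transposition mapping that allele onto the
chosen ancestral background — distribution-preserving under JC69 (under
HKY it slightly distorts the ts/tv structure of relabelled sites; the
bias option is off by default).

The metapopulation generator draws a root sequence, derives two lineage
ancestors separated by exactly `lineage_divergence` mutational steps
(half on each side) and an outgroup ancestor a further
`outgroup_divergence` steps from the root on disjoint sites — so the
outgroup attaches on the stem between the lineages, which is what makes
outgroup rooting meaningful. Each lineage is a single panmictic
sudden-expansion sample; populations differ only in their lineage
mixture. Defaults are the study conditions: nine populations with the
published per-population lineage counts (202 samples), L = 792,
τ_A = 5.215, τ_B = 0.932, θ₀ = 0.5, θ₁ = 500 (a strong expansion),
lineage divergence 12 steps (which puts pooled π near 0.012 given the
within-lineage levels), two outgroup sequences at 40 steps.

Limitations to keep in mind when reading test results: real populations
have *within*-lineage geographic structure which the generator omits, so
synthetic Φ_ST between same-mixture populations is centred on zero;
real haplotype frequency spectra are more skewed (large shared
haplotypes) than the generator's, so synthetic haplotype counts run
higher and Fu's Fs more negative than the corresponding field values at
the same diversity; and there is no recombination, selection or
migration model — mixture proportions stand in for migration history.
Passing tests on synthetic data therefore demonstrate estimator
correctness and pipeline recovery of known truth, not that any field
dataset satisfies the model.

## Problem sizes and determinism

The test suite and acceptance script are sized to run comfortably on a
single CPU: permutations default to 10,000 in the CLI but 100–1,000 in
tests and the acceptance script; bootstraps 20–100 in tests; simulation
calibrations use 200 replicates (Watterson check) and 20 seeds (τ
recovery, D sign). Every stochastic routine takes an explicit seed and
derives per-stage seeds via `numpy.random.SeedSequence`, so manifests
and FASTA fixtures are byte-identical across reruns with the same seed.
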