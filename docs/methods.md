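# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
numerical and design choices made where the design was genuinely open.

## Geometric morphometrics

**Centroid size.** CS = sqrt of the summed *squared* landmark distances
from the configuration centroid — the standard isometric size measure, and
the definition used by the morphometric software this pipeline emulates.
Informal descriptions of centroid size sometimes omit the word "squared";
we implement the standard quantity, which is also the one validated by its
homogeneity property (scaling a configuration by c scales CS by c).

**GPA.** Configurations are centred, scaled to unit centroid size, and
iteratively rotated to the running consensus (the renormalized mean shape)
until the consensus root-sum-of-squares change is below 1e-14 (at most 1000
iterations; typical datasets converge in fewer than 20).  The tight
tolerance matters: the set of GPA fixpoints is a one-parameter family under
global rotation, and a looser stopping rule leaves ~1e-7 orientation drift
that breaks exact idempotence.  For the same reason the converged solution
is put in a canonical orientation — consensus rotated to its principal
axes, first landmark on the positive x half-plane — so the output is
independent of which configuration happened to seed the iteration.
Reflections are never introduced during alignment; left wings are reflected
to right-wing orientation at input, which removes side as a shape factor.

**Allometry.** Multivariate least squares of the 30 shape variables on raw
centroid size (not log size; sizes here vary over a narrow range where the
two are nearly affine).  The share of shape variance explained is
100·SS(fitted)/SS(total) about the mean shape; significance comes from
permuting sizes against shapes, p = (exceedances + 1)/(n_perm + 1) with
10,000 rounds by default.  Downstream analyses use the residuals, which are
exactly uncorrelated with size by construction.

**CVA.** Shape variables are first projected onto principal components
carrying more than 1e-12 relative variance, capped at rank n − g, which
makes the pooled within-group covariance invertible (2k − 4 = 26 is the
maximum shape rank after GPA).  Canonical variates are eigenvectors of
W⁻¹B computed via the symmetric whitened form; scores have unit pooled
within-group variance.  Group separation is summarized by Mahalanobis
distances in the pooled within-group metric and by Euclidean distances
between group mean shapes in the aligned space (the usual "Procrustes
distance between means" for small shape variation).  Permutation tests
reallocate specimens to groups with sizes preserved (1000 rounds default).
Exact numeric parity with any particular CVA implementation's variance
scaling is not claimed; the Mahalanobis matrix itself is invariant to
invertible linear transforms of the variables, which is the tested
contract.

## Sequence statistics

**Ambiguity handling.** Sites with N or '-' are deleted pairwise for every
distance and difference count.  For haplotype collapsing, sequences
differing only at N positions are merged greedily in input order, the
representative's Ns being resolved as matching sequences arrive; treating N
as a fifth state would inflate haplotype counts.

**Diversity.** Gene diversity H = n(1 − Σp²)/(n − 1) with Nei's sampling
variance; θπ is the mean pairwise difference count with the total
(sampling + evolutionary) variance (n+1)/(3(n−1))·π + 2(n²+n+3)/(9n(n−1))·π²
reported as its s.d.

**Neutrality.** Tajima's D uses the standard a₁…e₂ constants.  Fu's F_S
computes S′ = Pr(K ≥ k_obs) under the Ewens sampling formula with θ = π,
via the unsigned-Stirling-number recurrence evaluated entirely in log
space (numerically exact to n in the hundreds); S′ is clamped to
[1e-12, 1 − 1e-12] before the logit, with a warning at the boundary.
p-values for both statistics come from a built-in Kingman coalescent
simulator, conditioned on the observed number of segregating sites
(mutations multinomial on branches in proportion to length), one-tailed in
the direction of the observed deviation, p = (b + 1)/(m + 1).  This
simulator is deliberately independent of the msprime-based data generator
so each can serve as a check on the other.

**TN93 distances** use alignment-wide base frequencies; terms whose base
class is absent vanish; a non-positive logarithm argument raises a
saturation error naming the pair rather than returning a silent NaN.

**Φ_ST and AMOVA** follow the sums-of-squared-distances decomposition on
squared TN93 distances.  Pairwise Φ_ST = σ²ₐ/(σ²ₐ + σ²_w) with p from
permuting individuals between the two populations.  The hierarchical
design estimates σ²ₐ (among groups), σ²_b (among populations within
groups) and σ²_c (within populations), with the three standard permutation
schemes (populations among groups; individuals among populations within
groups; individuals among all populations).  Negative component estimates
are reported as computed — they are legitimate unbiased estimates — and
flagged when below −5% of the total.

**Mismatch.** Relative-frequency histogram of pairwise differences;
Harpending's raggedness r = Σ(xᵢ − xᵢ₋₁)² including the terminal step to
zero; R2 = sqrt(Σ(Uᵢ − π/2)²/n)/S with Uᵢ the singletons carried by
sequence i.

## Median-joining networks

Each round builds the ε-relaxed minimum spanning network (edge kept when
its cost exceeds the minimax path cost by at most ε; ε = 0 gives exactly
the union of all minimum spanning trees), proposes quasi-medians
(per-site majority consensus, full ties resolved lexicographically) for
every triplet sharing a linked neighbour, and accepts the proposal that
most reduces the minimum-spanning-tree cost of the node set, ties again
lexicographic.  When no proposal reduces cost, median vectors whose
removal leaves the spanning cost unchanged are pruned and the final MSN is
emitted.  The construction is deterministic, its spanning cost never
exceeds that of an MST on the sampled haplotypes, and the ε = 0 network is
empirically a subgraph of the ε = 1 network on the same input.  The
optional exhaustive maximum-parsimony pruning pass is not implemented: its
cost is exponential and no downstream quantity depends on it.  Topological
identity with any particular published network is not claimed (the
original runs' ε and character weights are unknown).

## Geography and IBD

Great-circle distances use the haversine formula with R = 6371 km, a
choice validated by reproducing the published 1,155 km Taipei–Quezon City
separation from the printed DMS coordinates (we obtain 1155.6 km); no
ellipsoidal correction.  The "path" mode places sites on the ordered
Sundaland arc (Taipei → San Pa Tong → Bangkok → Nakhon Si Thammarat →
Penang → Serdang → Lampung → Imus → Quezon City) and measures additive
along-arc separations.  The published 7,586 km Taipei→Quezon City arc
distance corresponds to this arc with the San Pa Tong–Bangkok leg omitted
(the two mainland-Thailand sites treated as one stop); we reproduce it to
the km (7,586.7) via `path_distance_km(..., skip_legs=...)`, while the
default all-legs matrix gives 8,148 km for that pair.

IBD regressions run OLS on the g(g−1)/2 lower-triangle pairs and report
Pearson r, r² (always derived from r, never stored separately) and the
OLS p — plus a Mantel permutation p, which is the defensible inference
because distance pairs are not independent.  MDS uses classical Torgerson
scaling refined by SMACOF majorization, whose raw stress is non-increasing
by construction; negative Φ_ST entries are clamped to 0 on input.

## Synthetic data

`simulate_sequences` draws genealogies with msprime: one haploid deme per
site (size N = θ/2 so that θ is the per-deme scaled mutation rate of the
whole 642-bp locus), stepping-stone migration between path-adjacent demes
only, and an instantaneous expansion by factor `growth` at
`expansion_time` (in units of N generations) before present.  Mutations
are placed with infinite-sites continuous positions under HKY kinetics
(κ = 21, AT-rich COI-like base frequencies), then mapped to discrete
sequence positions with collisions re-drawn, so outputs are plain
fixed-length FASTA.  With migration 0 and several demes, ancient panmixia
at 50N generations keeps coalescence finite while preserving deep
structure.  Defaults (θ = 20, migration 2, growth 100, expansion at 0.1N,
nine sites with per-site n of 12–22 totalling 156) were chosen once to
emulate the study conditions: haplotype-rich samples (≈40–60% as many
haplotypes as sequences), gene diversities mostly above 0.9, within-site
θπ of roughly 1–6, strongly negative total Tajima's D (≈ −2 to −2.6) and
among-site Φ_ST up to ≈0.7.  The generator does **not** emulate
recombination, selection, rate heterogeneity among sites, sequencing
error, or the particular historical migration events of any real dataset —
so passing tests demonstrate that the pipeline recovers known structure
from data satisfying its model assumptions, not that any biological
conclusion is correct.

`simulate_wings` builds each specimen in unit-shape space as
template + displacement·(along-path km)·U + allometry·(CS deviation)·V +
isotropic noise, scaled by a per-specimen centroid size ~N(6, 0.35²), with
U, V fixed orthonormal shape directions and ~10% of specimens flagged (and
stored TPS-reflected) as left wings.  Defaults put ≈5% of shape variance
in the allometric component (the closed-form share a²Var(CS) /
[a²Var(CS) + d²Var(pos) + σ²(2k−4)] is exposed for testing) and produce a
strong shape cline along the arc, mirroring the qualitative pattern the
analysis is designed to detect.  Real wing shape is not Gaussian-isotropic
around a template; the simulator exists to give the pipeline data with
known ground truth, not to mimic fly wings in detail.

## Problem sizes and determinism

Every Monte-Carlo routine takes an explicit seed and is bit-reproducible;
the pipeline manifest records seeds, parameters, per-stage warnings and
output checksums.  Default permutation counts are 10,000 (allometry),
1000 (CVA, Φ_ST, AMOVA, neutrality) and 999 (Mantel); the test suite uses
99–199 rounds and replicate counts of 20–500 per property, sizes at which
the whole suite runs in about a minute.  The acceptance script runs the
full study-scale configuration (156 sequences, 169 wings, full permutation
counts) in well under a minute.

## Known limitations

- Fu's F_S is computed exactly from the Ewens distribution; published
  values from other software can differ noticeably at large n where their
  S′ accumulates rounding, so cross-package agreement is expected for the
  sign and significance, not the third decimal.
- The pooled ts/tv ratio over all pairs has very high sampling variance on
  expansion-shaped data (few transversions); it is a diagnostic, not a
  parameter estimate.
- Exact parity with specific legacy software (distance-matrix AMOVA
  implementations, CVA scalings, network heuristics) is not claimed
  anywhere; the tested contracts are the algebraic definitions above.
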