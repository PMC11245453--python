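# Methods

This note documents the models behind `rhizoasm`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used in edge cases.

## Study design and data model

All analyses operate on a taxa × samples integer count table (`OtuTable`),
sample metadata with two crossed factors — fertilization regime
(CK/CF/OF/CMF: control, chemical, organic, compound-microbial fertilizer)
and season (Apr/Jul/Oct/Jan) — with replicates, a rooted branch-length
phylogeny over the table's taxa, a rank-based taxonomy (kingdom→genus,
empty string = unassigned), and optional function/guild rule tables.
Validation is strict at the boundary: duplicate ids, negative or
non-integer counts and all-zero samples are hard errors that name the
offending cell or sample. Tables are not rarefied by default; a
`rarefy(depth, seed)` hook exists for users who want equal-depth tables
before diversity or null-model analyses, since practice differs between
labs and neither choice is canonical.

## Diversity and factorial statistics

Shannon entropy uses natural logarithms (a `base` switch is provided);
Chao1 is the bias-corrected form S + F₁(F₁−1)/(2(F₂+1)), which stays
defined when doubletons are absent — the classic F₁²/(2F₂) form is
available behind a flag. Bray–Curtis works directly on counts (it is
scale-invariant per sample). PCoA is classical scaling of the
double-centred −D²/2 matrix; axis percentages are computed against the sum
of *positive* eigenvalues only and negative eigenvalues are reported, not
corrected away, so users can see metric violations. ANOSIM is implemented
in-package (average-ranked dissimilarities, label permutations, explicit
seed, p = (hits+1)/(perms+1) so p is never 0); PERMANOVA with the same
permutation scheme is delegated to scikit-bio. Both are offered because
the two tests answer slightly different questions and reports in this
field use the terms loosely. The factorial screen is a type-II two-way
ANOVA with interaction; Tukey HSD letters are computed per factor, pooling
over the other factor, using the insert-and-absorb compact-letter-display
algorithm (two levels share a letter iff not significantly different at
α = 0.05). The Kolmogorov–Smirnov normality p-value is attached as a
screen only — it never gates the ANOVA, mirroring how such screens are
used in practice.

## Function and guild profiling

Functional annotation is deliberately database-free: a rule table
(match_rank, match_value, function_label, trophic_mode) drives the
aggregation, so FAPROTAX- or FUNGuild-derived rules can be supplied
without vendoring either database. With multi-assignment on (bacterial
convention) a taxon credits every matching function in full, so function
totals may exceed 1; with it off (guild convention) the abundance is split
equally among matches and per-sample totals are conserved exactly,
unassigned mass included. Guild→trophic-mode rollup sums member guilds;
a guild mapped to several modes contributes equally to each.

## Co-occurrence networks

Networks are built from all-pairs Spearman correlations (average ranks for
ties, t-approximation p-values with n−2 df; constant taxa are excluded
with a warning) after a prevalence filter. Two thresholding dialects are
supported: a fixed |ρ| cutoff — presets 0.88 (bacteria) and 0.78 (fungi) —
and the joint ρ > 0.6 & p < 0.01 rule. The RMT scan offers a data-driven
cutoff: at each candidate threshold the retained matrix's eigenvalue
spacings are spectrally unfolded (5th-order polynomial fit to the
cumulative spectral function) and tested by χ² against Poisson
(system-specific, modular structure) and GOE/Wigner (noise) forms; the
recommended cutoff is the smallest one whose spacing distribution is
Poisson-consistent (p > 0.05). A threshold that fragments the matrix into
an identity-like spectrum is treated as trivially Poisson-consistent.

Topology conventions (stated because published tables rarely define them):
GD is the mean shortest path over *connected* pairs only; HD is the
harmonic-mean geodesic where disconnected pairs contribute 0 to the
reciprocal sum, hence HD ≤ GD holds on connected graphs but not
necessarily on disconnected ones. Modularity is computed on the unsigned
skeleton (signs are kept as edge attributes); module detection is greedy
(Clauset–Newman–Moore) by default for determinism, with seeded Louvain as
an option; module ids are ordered by size. The power-law R² is an ordinary
least-squares fit on log frequency vs log degree with zero-frequency
degrees omitted. Zi is the within-module degree z-score (Zi = 0 when the
module's degree spread is zero); Pi = 1 − Σ(k_is/k_i)²; roles use the
2.5 / 0.62 quadrant thresholds and a node is a keystone candidate when
Zi ≥ 2.5 **or** Pi ≥ 0.62. The published description of the fourth
quadrant ("Pi ≤ 0.62" for network hubs) contradicts the other three
quadrants and is implemented as Pi ≥ 0.62, the standard scheme. Random
baselines are degree-preserving double-edge-swap rewirings (10 swaps per
link per replicate, 100 replicates); rigid graphs with no legal swap fall
back to G(n, L) Erdős–Rényi draws and the result is flagged.

## Assembly inference

βMNTD is the abundance-weighted mean nearest-taxon patristic distance
between two samples, ½[Σᵢ fᵢ·min_j d(i,j) + Σ_j f_j·min_i d(j,i)]; the
implementation computes all pairs at once via a nearest-taxon matrix and a
single matrix product, which is what makes 999-draw nulls affordable. The
βNTI null shuffles tip labels across the whole regional pool — defined as
*all taxa in the analysed table*, the usual convention; per-group pooling
is available by flag. Pairs with zero null spread (e.g. identical
communities) are NaN and excluded with a count. βNTI is invariant to
uniform branch-length scaling by construction.

RC_bray draws null assemblages per sample: the observed richness of taxa
is selected without replacement with probability proportional to regional
occupancy (implemented by the Gumbel-top-k equivalence, which matches
sequential renormalized sampling exactly), and the observed read total is
then distributed multinomially in proportion to regional relative
abundance. RC = 2·[(#{null BC < obs} + ½·ties)/n_null] − 1 ∈ [−1, 1].

Pair classification follows the published thresholds: βNTI < −2 →
homogeneous selection, βNTI > 2 → variable selection, otherwise
RC > 0.95 → dispersal limitation, RC < −0.95 → homogenizing dispersal,
else undominated drift (drift and "undominated" are reported as one class,
since bar-chart legends in this field conflate them). Boundary values fall
on the non-selection/drift side, matching the strict inequalities.

pNST compares each within-group observed βMNTD (D) with its tip-shuffle
null expectation (E): selection strength is (D−E)/(Dmax−E) when D ≥ E and
(E−D)/E otherwise, with Dmax the largest observed-or-null dissimilarity in
the group; the stochasticity ratio is 1 minus that, averaged over pairs
and clipped to [0, 1], with 0.5 as the stochastic/deterministic boundary.
Because the D < E branch reduces to D/E, pNST under homogeneous selection
is bounded below by the achievable observed-to-null βMNTD ratio; with
Brownian niche traits that ratio rarely falls below ≈ 0.5, so very strong
filtering reads as pNST ≈ 0.3–0.6 rather than ≈ 0. This is a property of
the normalization, not a bug, and it is why the test suite checks the
selection-vs-neutral *contrast* rather than an absolute pNST level under
selection.

Null-draw defaults are 999 everywhere, with 99 (the accepted minimum) used
in the simulation-heavy tests and the acceptance script to keep runtimes
in minutes on one CPU.

## Neutral community model and niche breadth

The Sloan fit is nonlinear least squares over log Nm of
F(p) = 1 − BetaCDF(d; Nm·p, Nm·(1−p)) against per-taxon occurrence
frequencies, with detection limit d defaulting to 1/N̄ (N̄ = mean read
depth) and m = Nm/N̄. The 95 % prediction band is a Wilson score interval
around F(p) at the observed sample count, and taxa are classed
above/within/below it. Known limitation: on data whose detection process
is multinomial read sampling (soft threshold ≈ 1 − e^{−Nx}) rather than
the hard x > d cutoff, the fitted m is biased upward, increasingly so for
very skewed abundance distributions; recovery benchmarks therefore use an
even (σ = 1) log-normal pool where the bias is small (typically < 20 %).

Levins breadth is B = 1/ΣPᵢⱼ² over resource states (individual samples by
default; pooled regime × season cells by flag). The generalist/specialist
test compares observed B against B computed on random tables with the
observed row and column sums held fixed, sampled independently by
Patefield's algorithm — the same null space as swap-based schemes but
without burn-in or mixing diagnostics. Taxa above the null's 97.5th
percentile are generalists, below the 2.5th specialists, otherwise
neutral.

## The synthetic-study generator

The generator emulates the 4-regime × 4-season × 3-replicate soil design:
48 samples per marker, 500 taxa (bacteria-like preset; 150 for the fungal
preset), 10,000 reads/sample, a log-normal species abundance distribution
(σ = 1.5 by default), and a Yule phylogeny (ultrametric by default).
Niche optima evolve along the tree as Brownian motion with an early-burst
clock: per-branch variance is branch length times a rate that decays
e^{−6·(depth/tree depth)}. The decay concentrates trait variance on deep
branches so habitat preference is a clade-level property — tips within a
clade share similar optima and convergence between distant clades is rare.
This mirrors the deep phylogenetic conservation of microbial habitat
association that βNTI fundamentally relies on; with a homogeneous-rate
clock, tips from every clade converge onto any given optimum and
phylogenetic turnover carries little signal even under strong filtering.
Setting `trait_eb_decay=0` recovers plain Brownian motion.

Local communities are sampled from the *stationary* distribution of a
Hubbell-style migration–drift process: relative abundances ~
Dirichlet(N·m·pool), then a multinomial read draw. The stationary form is
used instead of iterating the drift chain so that the migration parameter
m is exactly the m of the Sloan neutral model, making parameter-recovery
benchmarks well-posed. Scenarios modify the sampling weights:
`dispersal_limited` gives each regime × season cell an independently
log-normal-perturbed pool (σ = 1.5), and `selection` multiplies the pool
by exp(−s·(trait − env)²). The default shared optimum sits at +2 trait SD:
an extreme environment selects the clades that drifted toward it, whereas
an optimum at the root value (0) is matched by convergent tips of every
clade. `scenario_preset("selection")` additionally uses small local
communities (500 individuals), low migration (m = 0.1) and a flatter pool
(σ = 1), because environmental filtering is only phylogenetically
detectable when communities are sparse and turnover-rich — in large,
high-immigration communities nearly all taxa are shared between samples
and the filtering signature is masked. `mixed` cycles the three scenarios
across cells and records the truth per sample.

What the generator does **not** emulate: sequencing error and chimeras,
compositional artefacts of varying read depth (every sample has the same
nominal depth), taxon–taxon interactions (network structure in synthetic
data arises only through shared environmental responses), temporal
autocorrelation between seasons, and real taxonomies (lineages are derived
from tree clades). Passing the scenario-recovery tests therefore shows
that the inference machinery is internally consistent and correctly
calibrated against known assembly regimes — not that real soil data meet
the generators' assumptions.

## Numerical conventions and edge cases

Every stochastic routine takes an explicit integer seed and is fully
deterministic given it; study emission is byte-identical across runs.
Zero-variance taxa are excluded from correlation networks with a warning;
empty networks are a warned result, not an error. Tukey letters for a
constant response collapse to a single letter with F = 0. RC ties are
counted at ±10⁻¹² and weighted ½. Chao1's classic form raises when F₂ = 0
rather than returning infinity. PCoA never flips or truncates negative
eigenvalues silently. The NCM optimizer restarts from several initial
values and raises with diagnostics if no start converges.

## Problem sizes used in validation

Unit and property tests run on 6–60-taxon fixtures; scenario-recovery
tests use 20 replicate studies of 48 samples × 500 taxa with 99 null draws
per pair matrix; the acceptance script uses 10 replicate studies per
scenario and 999 draws for its enumeration comparisons. These sizes keep
the full suite and the script each within a few minutes on a single CPU
while leaving the Monte-Carlo errors far smaller than the effect sizes
being checked.
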