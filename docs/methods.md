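# Methods

This note records the models and algorithms `blowphylo` implements, the
defaults it ships, the design choices that were genuinely open, and what
the synthetic-data tests do and do not establish.

## Substitution models and likelihood

All sequence models are reversible CTMCs assembled as Q_ij = s_ij π_j from
symmetric exchangeabilities s and equilibrium frequencies π, with the
diagonal set so rows sum to zero. Unless a model opts out
(`normalize=False`, used by the two-state trait model whose rates are in
absolute units), Q is rescaled so one unit of branch length equals one
expected substitution per site at stationarity. Shipped families: JC and
GTR for nucleotides, Poisson and the empirical LG table for amino acids,
an equal-exchangeability six-state model for Dayhoff-recoded data, and
the Mk2 trait model with gain rate q01 and loss rate q10 (stationary
frequencies (q10, q01)/(q01+q10)).

Among-site rate variation uses the discrete gamma with k = 4 equal-
probability categories by default; the category rate is the analytic mean
of its bin (via the incomplete-gamma identity), renormalized to mean 1.
An optional invariant class enters as a rate-0 category with weight
p_inv, the gamma rates divided by 1 − p_inv so the weighted mean stays 1.

Likelihoods run Felsenstein's pruning over unique site patterns
(columns compressed with weights) with transition matrices from the
symmetric-form eigendecomposition of Q. Numerical underflow is handled by
per-node scaling: at each internal node the partials are divided by their
per-pattern maximum and the logs accumulate separately. Gaps, `N`/`X`,
`?` and the IUPAC degeneracies are total or partial ambiguity; a tip's
partial vector is the 0/1 compatibility row of its symbol, so a fully
ambiguous taxon on a zero-length branch provably leaves the likelihood
unchanged (this is a test). The per-site log-likelihood vector is the
primary product; totals are its sum, so the two are consistent by
construction.

**Branch lengths.** Each branch is optimized by bounded Brent search
(bounds [1e−8, 50], `xatol` 1e−6, at most 20 cycles, convergence when a
full cycle improves ln L by < 1e−6). A cycle first computes inside
partials bottom-up, then walks the tree top-down building outside
partials *with the branch lengths already updated on that walk*, so each
edge is optimized against current ancestor and sibling lengths. This
matters: optimizing all edges against partials frozen at the start of a
cycle makes confounded adjacent branches (e.g. the two halves of a
two-taxon path) overshoot jointly. A cycle that fails to improve the
exact log-likelihood terminates the search at the best state seen, which
guarantees the returned tree never scores below the input.

Model-parameter fitting (`optimize_model_parameters`) covers the gamma
shape (bounded scalar search on [0.02, 100]), frequencies (L-BFGS on
log-ratio coordinates) and the two trait rates (L-BFGS on log rates,
bounds [1e−6, 1e3]); the fitted model is returned only if it does not
score below the input model.

## Per-partition ΔpL

Branch lengths for each hypothesis tree are optimized once on the full
supermatrix; per-gene log-likelihoods are then read off the fixed trees
from the per-site vector, and ΔpLᵢ(A,B) = ln Lᵢ(A) − ln Lᵢ(B) exactly, so
Σᵢ ΔpLᵢ reproduces the total difference to float precision. Per-gene
re-optimization is available (`optimize=False` plus per-gene calls) but
not the default. Gene counts treat |ΔpLᵢ| ≤ 1e−9 as ties and report them
separately rather than allocating them to either side — published
favored-gene counts that do not sum to the gene total imply such an
unallocated category, and making it explicit keeps the bookkeeping
honest.

## Four-cluster likelihood mapping

Quartets draw one taxon per group (exhaustive when the product of group
sizes is within `max_quartets`, otherwise uniform sampling without
replacement under the run seed). Each quartet is scored on its own
columns — the sites where all four taxa carry non-ambiguous data — under
the three resolved topologies with branch lengths optimized per topology
(Brent, `xatol` relaxed to 1e−4; weight triples need far less precision
than 1e−6 branch lengths). Weights are the softmax of the three log-
likelihoods. Quartets with fewer than 10 usable sites are dropped and
tallied. The headline numbers are basin (argmax) percentages, which are
geometry-independent; the 7-region refinement uses: corner j iff
w_j ≥ 2/3; otherwise an edge iff the smallest weight ≤ 1/6 and the two
largest are unambiguous; otherwise center.

When the second cluster is paraphyletic the mapping runs twice: once with
group 2b pruned (clusters 1, 2a, 3, outgroup) and once with 2a pruned
(1, 2b, 3, outgroup). Only the four active clusters supply taxa; the
outgroup cluster defaults to every taxon outside the four groups. Note an
intrinsic feature of the 2b-retaining variant on the shipped fixtures:
under the T3 arrangement only Chrysomyinae — not Phumosiinae — sits with
group 2b, so quartets split deterministically between the
(1+2b) and (1+outgroup) basins and the expected outcome is a co-plurality
rather than a unanimous flip. The tests assert exactly that.

## KH / SH / AU tests

All three tests consume the stored per-site log-likelihood matrix (RELL:
sites are resampled, nothing is re-optimized). KH is the one-sided
pairwise test against the ML tree with a centered null at scale 1; the
best tree is assigned p = 1 by construction. SH uses the joint
centered-maximum null. The AU test resamples at the 10 canonical scales
0.5–1.4, computes bootstrap proportions with ties split fractionally,
clamps them to [1/(2B), 1 − 1/(2B)], probit-transforms, and fits
z(r) = d√r + c/√r by weighted least squares with binomial-variance
weights B·φ(z)²/(bp(1−bp)); p = 1 − Φ(d − c). Scales where a tree won
zero (or all) replicates contribute no curvature information and are
excluded from the fit; a tree with fewer than two informative scales gets
p = 1/(2B) (if it essentially never wins) or 1 − 1/(2B) (if it always
wins), with a `saturated-bp` or `never-best` flag. Replicates default to
1000 and are configurable.

## Parsimony

Fitch counting runs on bitmask state sets (ambiguity sets used directly,
all-missing sites free), on a bifurcating rooted view of the tree —
scores are rooting-invariant, which is property-tested. The search is
steepest-descent hill climbing over NNI neighbors with seeded random
tie-breaking, multi-started (default 10 random-addition topologies) for
the full-data tree. This deliberately replaces heavyweight driven
searches; its adequacy is established only at the ≤ 11-taxon scale the
package targets. Jackknife support deletes each site independently with
probability 0.36 (per-site Poisson-style deletion, the convention tied to
parsimony jackknifing), reruns a single-start search per replicate, and
reports for each split of the best full-data tree the percentage of
replicate trees containing it; all-deleted replicates are redrawn and
logged.

## Quartet-coalescent species tree

The quartet agreement score counts gene-tree-induced four-taxon subtrees
matching the candidate; gene trees may miss taxa (fewer quadruples) and
polytomies contribute nothing. The optimum is found by exhaustive
enumeration of all (2n−5)!! unrooted topologies, capped at 9 taxa
(135,135), with all co-optimal trees returned — exactness at exemplar
scale was chosen over re-implementing a scalable heuristic, because every
result can then be checked against a restriction-based oracle. Gene-set
(not site) bootstrap resampling is assumed for support values: each
replicate collection is searched exactly, and a split counts as recovered
only when every co-optimal tree of that replicate contains it.

## Multispecies-coalescent simulator

One haploid lineage per species; within each species-tree branch
(lengths in coalescent units) the k current lineages coalesce at rate
k(k−1)/2, i.e. exponential(1) per pair, with survivors handed upward and
forced coalescence above the root. Node ages accumulate along the species
tree, which is treated as ultrametric in coalescent units. The simulator
is validated against the closed form for rooted-triple concordance,
1 − (2/3)e^(−t).

## Ancestral states

Mk2 rates are fitted by L-BFGS on log rates (bounds [1e−6, 1e3]) through
the pruning likelihood with the root at the stationary frequencies (a
flat-root option exists; stationarity is the default because it is the
field's standard when a tool's own default is undocumented). Marginal
probabilities come from the exact up–down (inside–outside) pass and are
keyed by each node's descendant tip set; tips are included (observed tips
are 0/1, unknown tips get their marginal), which lets origin counting
work from the result object alone. The Bayesian variant is
Metropolis–Hastings over (log q01, log q10) with independent
exponential(mean 1) priors, Gaussian proposals of SD 0.3 on the log
scale, and node probabilities averaged over retained samples; acceptance
rate and autocorrelation-based effective sample sizes are reported, with
a warning outside [0.05, 0.8] acceptance. Origin counting assigns each
node its higher-probability state (threshold configurable in (0.5, 1];
undecided nodes inherit the parent, an undecided root takes state 0) and
counts 0→1 edges as gains, 1→0 as losses.

One binary character carries little information about its rates, so the
posterior tracks the prior unless the tree is large; the Bayesian-vs-ML
agreement checks therefore use a 64-tip tree with short branches and a
true rate near the prior mean, where tip states pin down the nodes and
the reconstruction is insensitive to residual rate uncertainty. On sparse
trees with long branches the two reconstructions can legitimately differ.

## Synthetic data and fixtures

The supermatrix generator emulates the structure of a transcriptomic
amino-acid supermatrix: per-gene lognormal rate multipliers (σ = 0.5,
mean 1) and whole-gene taxon dropout at probability 0.291, which yields
overall completeness ≈ 0.709 — the published structure of such matrices
(thousands of genes, ~0.71 Ca). Missing data are taxon-by-gene, matching
how transcriptome assemblies actually lose data; there is no indel or
alignment-error model. Backbone fixtures use one exemplar per
subfamily/family (11 taxa), terminal branches 0.2 and internal branches
0.05 substitutions/site by default — realistic signal for a calyptrate
backbone and configurable for power studies. The per-gene rate and
missingness distributions of real matrices are unpublished; these
defaults are plausible, not calibrated, so passing tests demonstrate
correctness of the machinery and qualitative behavior (which hypothesis
wins, how support flips), not quantitative agreement with any particular
empirical matrix.

## Problem sizes and numerical choices

The acceptance-style checks run at: 200 genes × 300 aa (LG+Γ₄, shape 0.8)
for the ΔpL and FcLM analyses; 50 seeded replicate experiments with B =
500 RELL replicates × 10 scales for AU calibration (6-taxon JC trees,
internal branches 0.02 with 1000 sites for the size check, 0.1 with 2000
sites for power); 20 runs × 200 coalescent gene trees for species-tree
recovery; 10,000 loci per point for the MSC concordance curve; 64-tip
trees for rate recovery (50 pooled characters) and BBM agreement. These
sizes were chosen so each property is measured with comfortable
statistical margin while the whole suite stays desk-scale.

Other numerics: branch bounds [1e−8, 50]; ΔpL tie tolerance 1e−9;
bootstrap-proportion clamp 1/(2B); FcLM quartet minimum 10 usable sites;
pattern compression everywhere; zero-length branches are legal inputs
(constraint-satisfying starting trees need them) and degenerate
likelihood states surface as errors naming the offending branch.

## Known limitations

* No tree search over topology space for the likelihood analyses —
  hypotheses are supplied, not discovered (the parsimony NNI search and
  the exact quartet search are the only searches shipped).
* No codon models, model selection, partition merging, or compositional
  heterogeneity tests.
* The exact quartet search is capped at 9 taxa by design.
* The MCMC is a two-parameter random-walk sampler; it is adequate for
  Mk2 rates but not a general phylogenetic MCMC.
* Relaxed-PHYLIP I/O covers the sequential layout Biopython writes.
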