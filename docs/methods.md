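# Methods

`tcnet` implements a temporal coexpression-network analysis for a
three-timepoint treatment design (labels `pre`, `mid`, `post`): a
differential-expression screen defines a shared node set; one undirected
network per timepoint is inferred from first-order Spearman partial
correlations; network topology and hub/bottleneck roles are characterized per
timepoint; and rewiring across the ordered series is quantified. A
synthetic-data generator with planted Gaussian graphical structure supplies
ground truth for every stage.

## The edge test

For genes *i*, *j* at one timepoint with *n* samples, let *r<sub>ij</sub>* be
the Spearman rank correlation (mid-ranks for ties) and, for a third gene *k*,

ρ<sub>ij·k</sub> = (r<sub>ij</sub> − r<sub>ik</sub> r<sub>jk</sub>) / √((1 − r<sub>ik</sub>²)(1 − r<sub>jk</sub>²))

the first-order partial correlation. The pair is linked iff the zero-order
correlation is significant at level α **and** ρ<sub>ij·k</sub> is significant
for *every* other gene *k* in the node set. Conditioning on each single gene
removes pairs whose association is fully explained by one common regulator,
so surviving links are direct correlations up to first order. Significance
of an order-*q* partial uses the t approximation
t = ρ·√((n−2−q)/(1−ρ²)) with n−2−q degrees of freedom, two-sided. The
p-value is strictly decreasing in |ρ| at fixed df, so the sweep over all
conditioners is implemented as an exact |ρ| threshold applied to a vectorized
minimum over correlation-matrix slices; a per-pair reference loop
(`edge_test`) is kept and tested to agree exactly. Conditioners with
|r<sub>ik</sub>| = 1 are skipped (the partial is undefined); a gene constant
across samples gets zero correlations and a logged warning rather than
aborting the run.

Defaults: α = 0.01 per test, no multiplicity correction across pairs — the
level is meant as a per-pair error rate balanced against power, and the
permutation null (below) provides the global check. Both choices are
configurable.

Error structure worth knowing (it drives several design choices below): the
conjunction is conservative for true edges (many false negatives) but admits
two kinds of false positives — chance hits among the ≈α·(#pairs)/2 null pairs
that survive all conditioners, and *structural* hits for pairs connected by
two or more vertex-disjoint paths, which no single conditioner can explain
away. Chance hits do not shrink with sample size (the test is calibrated);
structural hits grow with graph density and with sample size.

## Permutation null

Each replicate independently permutes every gene's values across the
timepoint's samples, destroying all inter-gene association while preserving
margins, rebuilds the network and counts edges. The observed count "exceeds
the null" when it is larger than the maximum of the replicate counts
(default 1000 replicates; each replicate uses an independent RNG stream
spawned from the master seed, so runs are reproducible and parallelizable).

## Differential expression screen

Per gene, the two-group linear model contrasting `pre` vs `post` — identical
to the unpaired pooled-variance t-test — with Benjamini–Hochberg q-values and
selection at FDR 0.05 (default). The groups are treated as independent
samples; no patient pairing is modeled. No empirical-Bayes variance
moderation is applied: at the intended group sizes (tens of samples) the
ordinary estimate is stable, and the node set can be supplied explicitly to
bypass the screen entirely. Degenerate genes (zero pooled variance) get
p = 1 when the effect is also zero, p = 0 otherwise, with a logged warning.

## Topology and roles

Per network: degree sequence (all nodes, including isolates, also used for
the two-sample KS comparison across timepoints, asymptotic two-sided p),
largest connected component (ties broken by lexicographically smallest
member), mean shortest path over unordered pairs *within the LCC only*
(never a sentinel distance across components), and global clustering as the
transitivity ratio 3·triangles/connected-triples (0 when no triples) — not
the mean of local clustering coefficients, which differs numerically.

Betweenness is raw (unnormalized), endpoint-excluded, with fractional credit
for tied shortest paths, computed on the full graph. Hubs are nodes whose
degree exceeds the Tukey upper fence Q3 + 1.5·IQR of their network's degree
distribution (quartiles by linear interpolation); bottlenecks likewise for
betweenness. Crossing the two one-sided criteria yields the four exclusive
categories HB / HNB / NHB / NHNB. The multiplier and quartile method are
configurable since "statistical outlier" has no single convention. Note the
fence is *not* monotone under appending an extreme value at small n (the
interpolated quartile positions shift — e.g. scores {−1,0,0,0} have fence
0.375 but appending 1000 drops it to 0); the properties that do hold, and
are tested, are scale equivariance and monotonicity in the multiplier.

## Rewiring statistics

For each consecutive network pair: conserved links |E<sub>a</sub> ∩
E<sub>b</sub>| with all three candidate denominators (earlier network, later
network, union) reported; the headline fraction is *of the earlier network*,
since "X% of links are conserved" most naturally reads forward in time.
Category transitions are full per-gene triples plus 4×4 flow counts per
transition. Stability lists: *stable* = identical non-NHNB category at all
three timepoints; *always-hub* = {HB, HNB} thrice; *always-bottleneck* =
{HB, NHB} thrice; *transiently prominent* = non-NHNB in exactly one network.
Degree-change patterns label each transition increase / decrease / no change
by the exact integer degree difference (no tolerance band), giving 3×3 = 9
patterns over the two transitions.

## Synthetic data generator

Each timepoint's "truth" is a planted simple graph: star edges for a chosen
number of hub nodes first (guaranteeing a heavy-tailed degree distribution
without committing to a degree-distribution model), then uniform random
fill. Consecutive timepoints share exactly round(overlap·|E|) edges, the
rest resampled from unused pairs.

The graph becomes a Gaussian graphical model through its precision matrix:
off-diagonal −s (s = `partial_strength`) for planted edges, 0 otherwise,
uniform diagonal d = max(1, 1.05·s·λ<sub>max</sub>(A)) where
λ<sub>max</sub>(A) is the adjacency spectral radius, then rescaled to unit
diagonal. Positive definiteness holds for every planted graph (and is
verified by an eigenvalue check); the empty graph maps to the identity and a
single edge to an off-diagonal of exactly −s. The 5% spectral margin is the
smallest uniform diagonal that is comfortably positive definite, which
matters because it *maximizes the realized conditional dependence*: after
normalization an edge's partial correlation is ≈ s/d, so whenever
s·λ<sub>max</sub>(A) > 1 the achievable strength saturates at
≈ 1/(1.05·λ<sub>max</sub>(A)) regardless of s. For a uniform 200-edge graph
on 100 nodes (λ<sub>max</sub> ≈ 5) that cap is ≈ 0.19–0.30 in first-order
terms — close to the α = 0.01 detection threshold of 0.182 at n = 200, which
is why planted-edge recovery at those sizes plateaus near 75% rather than
approaching 100%: a positive-definiteness constraint, not an implementation
artifact. A more conservative diagonal (e.g. full diagonal dominance) would
push realized partials to ≈ 0.09 and make planted structure essentially
undetectable at realistic sample sizes.

Samples are drawn per timepoint from N(0, noise_sd²·Σ) with Σ the inverse
precision; `noise_sd` is a pure scale (expression units) and leaves the
correlation structure — all a rank-based pipeline sees — untouched. The mean
shift `shift_size` is added to the chosen gene subset in post-treatment
samples only, matching the pre-vs-post contrast of the screen.

Defaults (`SimulationConfig`): 58/58/60 samples per timepoint (the
motivating study's design), 100 genes, 200 planted edges, 2 hubs of degree
15, overlap 0.2 between consecutive graphs, s = 0.5, half the genes shifted
by 1.0, noise_sd 1.0. Gene count and edges are desk-scale stand-ins chosen
to keep a full pipeline run under seconds while preserving the density
regime (≈2 links per node) of the networks the method is aimed at.

What the generator does **not** emulate: microarray probe-level artifacts
and normalization, patient pairing across timepoints (sequential biopsies
come from the same subjects; both the generator and the screen treat
timepoints as independent groups), non-Gaussian margins, and any dependence
between the mean shifts and the planted graph. Passing tests therefore
certify the statistical machinery under a known sparse Gaussian truth, not
performance on real tumor expression data. At the study's own sample sizes
(n ≈ 58) the positive-definiteness cap above implies planted-edge power is
low; the recovery and rewiring demonstrations use n = 200–400 so that the
quantity being demonstrated (screening behaviour, conservation recovery) is
not drowned by sampling noise.

## Numerical and procedural choices

- Quantities with exact thresholds (|ρ| vs critical r) are compared strictly;
  ties have probability zero for continuous data.
- Conditioner sweep entries with an invalid conditioner are +inf, so an
  empty valid-conditioner set passes the first-order clause vacuously — the
  same semantics as the pairwise loop's skip-and-log.
- All RNG flows through `numpy.random.default_rng`; multi-replicate
  procedures spawn child `SeedSequence` streams. Identical config + seed
  reproduces every artifact byte for byte.
- The rewiring-fidelity demonstration (planted overlap 0.2 vs 0.8) uses 100
  genes / 100 edges / s = 0.7 / n = 400 and α = 0.001: at α = 0.01 the
  ≈10–30 chance edges among ~5000 null pairs dilute the conserved fraction
  of an ~100-edge network well below a planted overlap of 0.8, so the
  demonstration tightens α to make both chance and structural false
  positives negligible while keeping recovery ≈ 99%.
- KS comparisons of degree sequences are reported but their null p-values
  are conservative on heavily tied integer data; no calibration claim is
  made or tested for them.

## Known limitations

- First-order conditioning cannot remove associations carried by two or more
  vertex-disjoint paths; such structural false positives grow with density.
- Conditioning is restricted to the node set, so confounders outside the
  differentially expressed set are never conditioned on.
- No edge directions, no higher-order partials, no full graphical-model
  estimation (graphical lasso etc.), and no enrichment/annotation of genes.
- Category counts from outlier fences are sensitive to the outlier rule; the
  rule is recorded in every output for auditability.
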