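# Methods

## Model

A pathway network G = (V, E) has proteins as nodes and physical
interactions (PPIs) as undirected edges. Each node carries a normalized
knockdown essentiality p ∈ [0, 1] for the cell line under analysis. The
line graph (dual graph) L(G) has one node per PPI; two dual nodes are
adjacent iff their PPIs share exactly one protein s (in a simple graph two
distinct edges can share at most one endpoint), and that dual edge is
weighted exp(w · p_s). The kernel coefficient w sets how strongly protein
lethality steers the diffusion: at w = 0 all weights are 1 and scores
reduce to a purely topological (line-graph degree) centrality; larger w
trusts the screen more. With p ∈ [0, 1] weights span [1, e^w].

PPI scores are defined as the limit of the smoothed propagation

    e(t+1) = (1 − α) e(t) + α Pᵀ e(t)

with P the row-stochastic matrix of dual-edge weights and α ∈ (0, 1] the
smoothing weight. This is a lazy weighted random walk: the fixed point
satisfies Pᵀe = e regardless of α, so α affects only the convergence path,
and laziness removes the period-2 oscillation a bipartite component would
otherwise sustain. Because the dual graph is undirected with positive
weights, the walk on each connected component is reversible and its
stationary distribution is proportional to node strength
(π_i ∝ Σ_j w_ij); `closed_form_scores` computes this directly and is
required to agree with the iteration elementwise within 1e−8. Total mass
is conserved per iteration, so a disconnected dual graph converges to each
component's stationary distribution scaled by the component's share of the
uniform initial mass; isolated dual nodes keep their initial mass. Final
scores are divided by their maximum, giving range (0, 1] with the top PPI
at exactly 1 (min–max was rejected because it forces an artifactual exact
zero on some PPI).

### The averaging mode

The neighbor-averaging operator e(t+1) = (1 − α) e(t) + α P e(t) is also
provided (`update_mode="averaging"`). On a connected dual graph it is a
consensus iteration: it converges to a constant vector whose value is the
stationary-weighted mean of the start vector, so its limit carries no
ranking information and depends on the initialization. It exists for
comparison only; the mass-propagation operator is the default because it
actually possesses the advertised properties (non-uniform stationary
scores, initialization independence, α-independent ranking).

## Parameters

| parameter | default | meaning |
|---|---|---|
| α (`alpha`) | 0.5 | smoothing weight in (0, 1]; retains (1−α) of the previous score per step. α = 0 is rejected: the update degenerates to the identity and no stationary score is defined by iteration. |
| w | 0.5 | kernel coefficient ≥ 0 on the shared protein's essentiality |
| `tol` | 1e−10 | max-norm successive change at which iteration stops |
| `max_iter` | 10 000 | iteration cap; exceeding it returns `converged=False` with a warning |
| `max_missing_fraction` | 0.2 | cell lines with strictly more missing PPIs are dropped |
| uniformity ε | 1e−12 | PPIs whose non-missing standard deviation is ≤ ε are dropped |
| `n_perm` | 1000 | target-set permutations for the drug-screen FDR (floor 1/n_perm) |
| KS threshold | 0.5 | rank-enrichment gate in the survival screen |

The successive-change stopping rule bounds the distance to the fixed point
only up to the spectral gap; where elementwise 1e−8 agreement with the
closed form is asserted (oracle checks, acceptance script) the iteration is
run at tol = 1e−12.

## Input conventions and normalization

Screen scores follow the pooled-shRNA convention: more negative = more
lethal knockdown. Gene-level scores are the **second most lethal** hairpin
per gene (second order statistic), which suppresses single-hairpin
off-target artifacts; genes with fewer than two hairpins are excluded.
Per cell line, gene scores are mapped to p = (max − x)/(max − min), so the
most lethal gene gets p = 1. The screen literature does not fix a scale
for p; the negated min–max was chosen because it is bounded (keeping the
kernel in [1, e^w]) and matches the "0 = not essential, 1 = completely
essential" reading of the output scores. An all-equal profile maps to
p = 0.5 everywhere so the kernel stays defined. Expression-based gene loss
uses a user-set threshold (default ≤ 0 on a log scale). Homodimer edges
(A–A) are dropped at ingest: the line-graph transform is ill-defined for
self-loops.

## Rankings, MPER and the KS statistic

Within-cell-line comparisons use rank percentiles (rank/n, average ties),
which keeps the maximum at exactly 1 and avoids zero denominators. MPER —
the ratio of a PPI's percentile among PPIs to the percentile of its more
essential partner among proteins — is computed on the percentile scale
rather than raw scores to avoid consistent magnitude biases between the
two kinds of score; MPER > 1 flags interactions more critical than either
partner's knockdown suggests.

The KS rank statistic of a PPI over a cell-line group is the signed
sup-deviation of its percentile sample from the uniform CDF, positive when
ranks concentrate high (sup taken over ECDF jump points, right-limit
convention at 1 so an all-top-ranked sample scores exactly +1). It is a
one-sample statistic; a two-sample variant (group vs all other lines)
would be a natural extension but is not implemented. Note an exactly
uniform grid of size n cannot deviate less than 1/n, so the statistic's
null floor shrinks only as the group grows.

## Validation screens

**Drug screen.** Per compound, the pooled non-missing essentiality values
of PPIs touching a target gene are compared against all other PPIs with a
one-sided rank-sum test (normal approximation, tie-corrected, continuity
correction). The permutation FDR redraws |targets| genes uniformly from
the network's gene universe and reports the fraction of redraws whose
standardized statistic meets or exceeds the observed one, floored at
1/n_perm. Because the pooled values are fixed across redraws, ranks are
computed once and each permutation costs O(N). The comparison of
essentiality values (rather than correlation strengths) per compound is
the primary definition; per-pair Pearson correlation of essentiality with
AUC is available separately (`correlate_drug_sensitivity`).

**Mutation screen.** Per PPI, mutant vs wild-type cell lines are compared
with the unequal-variance (Welch) t test, BH-adjusted across PPIs. PPIs
with fewer than two non-missing values in either group, or with undefined
statistics (zero variance in both groups), are skipped with a warning.

**Survival screen.** A PPI is absent in a patient iff a partner gene
carries a nonsense mutation, frameshift mutation, or homozygous deletion
(missense and other non-truncating classes never remove a PPI; an optional
expression-loss criterion is off by default). The two-group log-rank test
is implemented from the risk-table definition — at each distinct event
time, observed minus hypergeometric-expected events in group 1, variance
d(N₁/N)(1−N₁/N)(N−d)/(N−1), ties handled by simultaneous risk-set
accounting — and is cross-checked against an independent survival library
in the tests. P-values are adjusted with Benjamini–Yekutieli (step-up with
harmonic factor c(m) = Σ 1/k), which remains valid under the arbitrary
dependence induced by overlapping PPI splits. Reported hits must pass both
the nominal log-rank gate and the KS rank gate. Cox proportional-hazards
modeling is deliberately out of scope; the log-rank statistic is the
screen's test.

## Synthetic data

The generator emulates the *shape* of the real inputs, not their marginal
distributions: a union of preferential-attachment pathway subnetworks
overlapping on designated hub genes (hub-heavy degree structure with
per-edge pathway provenance); hairpin-level scores (3 per gene) whose
gene-level means place hubs `essential_hub_bias` screen units more lethal;
per-cell-line loss contexts at `mutation_rate`; one planted compound whose
AUC equals the planted target gene's standardized essentiality plus noise
calibrated for population r ≈ 0.7 (the AUC is planted against the *gene*
essentiality, not against engine-derived PPI scores, so the generator
stays independent of the engine under test); and exponential survival with
hazard multiplied by `hazard_ratio` for patients retaining the planted
PPI, administratively censored at 3000 days (~30% censoring at defaults).
One master seed fans out to five named substreams (network, essentiality,
contexts, drugs, survival) so stages regenerate independently and output
files are byte-identical across runs.

Defaults describe a desk-scale study: 150 proteins, 8 pathways of 12–30
members, 10% hubs, 30 cell lines, bias −2, noise SD 0.3, 5% gene-loss
rate, 200 patients, hazard ratio 3. Passing tests on this fixture show
that the pipeline recovers planted structure under its own assumptions —
hub-driven essentiality, a single drugged target, one prognostic PPI. They
do not show robustness to features of real screens the generator omits:
off-target structure beyond hairpin noise, correlated loss events,
batch effects, non-exponential survival, or pathway annotations that are
themselves wrong.

## Numerical and design notes

- Uniform initialization by default (reproducible); the
  initialization-independence property is verified separately with random
  start vectors of equal total mass.
- No teleportation term: positive weights on an undirected connected
  component already give irreducibility, and laziness (α < 1) gives
  aperiodicity.
- Tie-breaks in ranked outputs are lexicographic on the sorted
  partner-symbol pair; PPI row keys are the sorted symbols joined by `_`,
  and symbols containing `_` are rejected at ingest.
- Missing matrix values serialize as the literal `NaN`.
- In update equations the normalization at a dual node is over the weights
  actually incident to that node.
- The planted-recovery check asks that the top decile of mean essentiality
  consist of hub-touching PPIs and that the planted hub's PPIs average a
  rank percentile above 0.75 — with ~10% of proteins designated hubs, the
  planted hub's own interactions outnumber the decile slots, so "all its
  PPIs in the top decile" is not attainable by construction.

## Limitations

- Undirected, unsigned, simple-graph semantics only; no multigraph or
  directed-interaction support, no homodimers.
- Context rewiring is binary (a gene is present or lost); expression and
  abundance do not otherwise modulate edge weights.
- The permutation FDR's resolution is bounded below by 1/n_perm and, in
  very small networks, by the chance of redrawing the true target set.
- The stationary scores depend on the network only through dual-node
  strength within components; they are a local centrality, and long-range
  network structure enters only via component decomposition.
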