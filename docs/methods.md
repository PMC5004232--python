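# Methods

`metadriver` prioritizes rare candidate driver mutations for distant
metastasis in a two-group tumor cohort — high risk of distant metastasis
(HRM) vs low risk (LRM) — by integrating somatic mutation calls, FPKM
expression profiles, a protein–protein interaction (PPI) network and TF →
target annotations. This note describes the models, the parameters that
matter, the numerical choices, what the synthetic cohorts emulate, and the
known limitations.

## 1. Somatic filtering and group-specific mutations

A mutation is identified by the pair *(gene, protein_change)* — position
and type matter, not just the gene. Four exclusion filters are applied to
tumor calls, in any order (they commute):

1. matched-normal subtraction: the same (sample, gene, protein_change)
   present in that sample's normal;
2. common population variants: population allele frequency strictly
   greater than `af_threshold` (default 0.1);
3. synonymous and unclassifiable SNVs;
4. calls outside exons and splice sites.

A mutation is **HRM-specific** when its HRM carrier fraction is strictly
greater than `min_frac` (default 0.09, i.e. ≥ 2 of 22 carriers) and it has
zero LRM carriers. Mutation burden per sample is the row sum of the binary
sample × mutation incidence matrix; groups are compared with a one-sided
Welch t-test (HRM > LRM). The Welch form was chosen because the group
sizes and variances differ; a pooled test is not exposed because the
burden comparison is descriptive, not a selection step.

## 2. Exclusive coverage (mutation-set selection)

Let A be the binary m × n incidence matrix over HRM samples and
HRM-specific mutations, c_j its column sums, c_ij the number of samples
carrying both mutations i and j, and M = max_j c_j. The model selects
exactly K columns maximizing

    f(S) = (Σ_{j∈S} c_j) / M − (λ/K) · Σ_{i∈S} Σ_{j∈S, j≠i} c_ij / c_i ,

normalized coverage minus a co-occurrence penalty: mutually exclusive
drivers in the same pathway should not co-occur in one patient, so overlap
is penalized, balanced by λ (default 1.0). The λ/K normalization keeps both
terms O(1); two alternative normalizations of the penalty are selectable
via `penalty_mode` because the printed form of this objective is ambiguous.

Three solvers return identical optima where they all apply and break ties
toward the lexicographically smallest key set:

* `solve_exact` — exhaustive enumeration of K-subsets (used when C(n, K)
  is within a 10⁶ budget);
* `solve_milp` — the quadratic terms x_i·x_j are linearized with
  auxiliary binaries u_ij (u ≥ x_i + x_j − 1, u ≤ x_i, u ≤ x_j) and solved
  by HiGHS through `scipy.optimize.milp`; the lexicographic tie-break is
  recovered by iteratively fixing variables subject to an optimality floor;
* `solve_greedy` — marginal-objective heuristic, used only as a fallback
  and as a lower-bound cross-check.

K defaults to the smallest value whose optimal solution covers every
sample that carries at least one candidate mutation (`choose_K`); samples
with no candidate mutation are excluded from the coverage denominator with
a warning.

## 3. DEGs, co-expression modules and signature TFs

DEGs are genes with a two-sided pooled-variance t-test p < 0.01 on raw
FPKM between the groups **and** at least a twofold mean change in either
direction, with fold = (mean_HRM + ε)/(mean_LRM + ε), ε = 0.1 guarding
zero means. The test is run on the raw FPKM scale by default; a log2
option exists (`log2=True`) because heavy-tailed FPKM can inflate the
pooled t, but the default follows the raw-scale convention. No multiple-
testing correction is applied — the DEG set is an intermediate signature,
not an inferential endpoint.

The co-expression network over HRM samples links genes with Pearson
r > 0.7 and p < 0.01 (per pair, uncorrected). The threshold is strict,
except that exactly collinear pairs (r = 1, p = 0) always qualify, so the
r_min = 1.0 boundary keeps precisely the collinear pairs. Modules are
found by greedy cohesiveness maximization in the ClusterONE style:
cohesiveness f(V) = w_in / (w_in + w_bound + penalty·|V|) with edge weight
r and penalty 2; seeds are taken in decreasing order of total incident
weight among unassigned nodes; each candidate grows/shrinks to a local
maximum; candidate pairs with overlap |A∩B|²/(|A||B|) ≥ 0.8 merge; modules
smaller than 3 genes or with edge density < 0.5 are discarded. All
tie-breaks are lexicographic on gene symbols, so detection is
deterministic. The implementation is property-tested (local optimality on
small graphs, density floor, relabeling equivariance), not output-matched
to any particular ClusterONE release.

Enrichment of a gene set (DEGs, or a TF's targets) in a module is the
hypergeometric upper tail P(X ≥ overlap) with the measured genes as the
population — only measured genes can appear in modules, so a genome-wide
universe would overstate significance. A module is a **network signature**
when its DEG enrichment p < 0.01 and at least one TF's targets are
enriched at p < 0.01; those TFs form the sink set of the flow stage.

## 4. Network-flow pathway ILP and ranking

The PPI is restricted to measured genes and each edge {i, j} is weighted
by the Pearson correlation ω_ij of the two genes' HRM expression profiles
(signed by default, since the sign distinguishes coherent from incoherent
links; `weight_network(..., absolute=True)` switches to |r|). For one
candidate mutant gene m and the signature TF set, a dummy source s is
attached to m and a dummy sink t to every TF, all with weight-0 edges.
With binary node variables x_i, binary edge variables y_e and integer
flows z on directed arcs (capacity R+1, no flow into s, none out of t),
the program is

    maximize   Σ_e w_e·y_e − λ·Σ_{internal e} y_e
    subject to y_e ≤ x_i, y_e ≤ x_j            (e = {i,j})
               degree(s) ≥ 1, degree(t) ≥ 1
               Σ_e∋i y_e ≥ 2·x_i               (i internal)
               flow out of s ≤ R+1
               inflow(j) − outflow(j) = x_j    (j internal), = 1 for t
               inflow(j) ≤ (R+1)·x_j
               z_uv + z_vu ≤ (R+1)·y_e .

Each selected node consumes one flow unit and flow travels only on
selected edges, so every selected node — and the sink — is reachable from
the source: the selected subnetwork is connected and contains the mutant
(the forced s-edge) and at least one TF. The flow accounting makes
Σ x ≤ R, so R caps the subnetwork size. Solved with HiGGS/HiGHS via
`scipy.optimize.milp`; infeasibility (mutant absent from the interactome,
or no TF reachable) is reported, not raised — incomplete interactomes
legitimately leave some mutants unlinked.

After solving, the dummy nodes are stripped and all simple paths from the
mutant to each reached TF (length ≤ R) inside the selected subnetwork are
scored by the mean edge weight Pw = Σ w_i / n. A mutant's score is its
maximum Pw, and mutants are ranked by that score (ties lexicographic).

### Parameter defaults and a known limitation of the objective

`lambda_flow` (default 0.01) prices each internal edge; `R` (default 20)
caps the subnetwork's node count. The objective maximizes *total* selected
weight, not path quality. Consequently any chance-rich cluster of
strongly correlated PPI edges is appended to the solution wherever it
attaches most cheaply — often through the sink side — because it raises
the objective while being irrelevant to the mutant under study. This is
harmless while R is slack: the mutant's own best chain has positive net
weight and is always included, and the post-hoc path scoring finds it. But
when R binds, the rider cluster can crowd the mutant's chain out of the
selected subnetwork and the mutant's Pw collapses to whatever accidental
link remains. We therefore treat λ as the sparsity control and keep R a
loose safety cap well above plausible pathway lengths; R should only be
lowered together with a λ large enough to make padding unprofitable.
This behavior is reproducible with the planted-path scenarios in
`metadriver.synth` by lowering R to ~6–10.

## 5. Synthetic planted cohorts

`PlantedScenario` generates a cohort with known ground truth; the defaults
describe the study conditions: 22 HRM / 56 LRM samples; three planted
driver mutations with disjoint HRM carrier sets of sizes (8, 7, 7) that
jointly cover the HRM group; three co-expression modules of 10 genes with
fold change 4 in HRM; driver→TF PPI paths of 3 edges; passenger mutation
rate 0.02; plus contaminant variants that exercise every somatic filter.

Expression is generated from a latent per-module activity z_t ~ N(0, 1):
module genes are base·fold^{HRM} + loading·z_t + N(0, noise_sd) with
base = 10 FPKM, loading = 2 and noise_sd = 0.5, giving within-module HRM
correlations around 0.94 and comfortably detectable fold-4 DEGs at n =
22/56; the module's TF gene, the planted driver gene and the path genes
share the same latent activity (so planted path edges carry high Pearson
weight) but no group shift — planted drivers are deliberately *not*
differentially expressed. Decoy mutant genes are planted in exactly two
HRM samples (passing the group-specific rule) and connected to the TFs
through uncorrelated genes, so their pathways exist but carry chance-level
weights. Decoy TFs have targets disjoint from the modules. The PPI adds
Erdős–Rényi background edges (p = 0.03, mean degree ≈ 4) over all ~117
expressed genes. A single integer seed drives independent substreams per
artifact, so every artifact is reproducible in isolation.

What the generator does **not** emulate: FPKM mean–variance coupling and
zero inflation, correlated passenger hotspots, overlapping regulons,
sample contamination/purity, batch structure, and the scale of a real
exome (tens of thousands of variants) or interactome (~10⁴ nodes).
Passing the planted-recovery tests therefore demonstrates the pipeline's
internal correctness and its behavior under the assumed generative model,
not performance on real cohorts.

## 6. Numerical choices and degenerate inputs

* Strict thresholds throughout (> 0.1 allele frequency, > 9% carriers,
  r > 0.7, p < 0.01), matching their verbal definitions; boundary cases
  are covered by unit tests.
* Correlation p-values use the exact t transform t = r·√((n−2)/(1−r²));
  |r| = 1 maps to p = 0. Zero-variance profiles make correlation
  undefined: scalar calls raise, network builders drop the gene or edge
  with a logged count.
* Clinical-table percentages are rounded half-up to one decimal.
* Both MILPs compare objectives with absolute tolerance 1e−9; binary
  variables are read back at the 0.5 threshold.
* Degenerate burden input (zero variance in both groups, equal means)
  reports t = 0, p = 0.5 and a flag instead of NaN.
* An all-zero row in the incidence matrix (a sample with no candidate
  mutation) is excluded from coverage denominators with a warning;
  all-zero columns are removed at construction.
* Problem sizes in the test suite and acceptance script (random
  oracle-equivalence instances with ≤ 12 nodes / ≤ 14 edges, 20 planted
  scenarios of ~117 genes) are chosen so exhaustive enumeration remains
  exact and the full run completes in minutes on one core.

## 7. Known limitations

* The flow objective's rider-cluster artifact described in §4.
* Hypergeometric enrichment assumes exchangeable genes; co-expressed
  modules violate independence, so enrichment p-values are optimistic —
  acceptable here because enrichment is a screening rule with a fixed
  threshold, not a calibrated error rate.
* Per-pair uncorrected thresholds in the co-expression network mean the
  expected number of false edges grows with the gene count.
* The greedy module detector finds local cohesiveness optima; no
  optimality guarantee beyond the property tests.
* Mutation identity by (gene, protein_change) string equality: no indel
  normalization or transcript-aware matching.
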