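# Methods

This note documents the models, the statistical procedures, the
synthetic study conditions and the numerical choices behind
`priornet`, in the order the pipeline runs them.

## Network model

A network is a simple directed graph over string vertex identifiers.
Edges may carry a semantic label (activation, inhibition, binding,
...) as metadata; every topological computation in the package is
label-blind, and parallel edges differing only in their label count
once. Self-loops are rejected at construction and dropped (with a
logged count) at file ingestion: all pair-connectivity quantities used
downstream are defined over ordered pairs of *distinct* vertices, so a
self-loop can never influence a result, and carrying them would only
complicate the invariants. Serialization (SIF and 2-column edge list)
is lexicographically sorted, so identical networks produce
byte-identical files; single-field lines declare lone vertices, which
makes the file round trip exact even for networks with orphans.

Orphan vertices (degree 0) follow a single rule throughout: they stay
in the universe for enrichment (a detected gene is evidence whether or
not the database knows interactions for it) and are removed before
topological scoring (their removal cannot change connectivity, and
they would dilute the normalization of the disconnectivity index).

## Filtering

Detection is presence-based. A gene counts as detected when at least
one of its platform identifiers (tags) reaches the count threshold;
the default threshold of one tag reflects the qualitative nature of
tag sampling — for sparse libraries a single observed tag is already
evidence of presence — and is configurable for deeper libraries. The
two conditions are combined by union by default: this minimizes
fragmentation, maximizes vertex count, and retains both silenced and
induced genes; intersection and symmetric-difference runs are
available for condition-specific questions.

The strict network is the induced subgraph on the detected vertices;
the k-extended network is the induced subgraph on the detected set
plus k rounds of in- and out-neighbors (the 2-neighborhood is
literally the extension applied twice). Extension is monotone in k
and reaches, as fixpoint, the union of the weak components touched by
the seed — both properties are tested.

## Metabolic network construction

The enzyme-centered metabolic network has one vertex per enzyme
activity and a directed edge E1 → E2 whenever some substrate is
produced by a reaction of E1 and consumed by a reaction of E2.
Substrates participating in more than 100 reactions (counting distinct
reaction records, before any filtering) are treated as currency
metabolites (ATP, water, ...) and excluded from edge construction —
they would otherwise connect nearly every enzyme pair. Reversible
reactions contribute both orientations of their educt/product sets;
ignoring reversibility would orphan a large fraction of enzymes, since
reaction tables routinely store one canonical direction. Raising the
currency threshold can only add edges, and the vertex set never
depends on it; both are tested against a brute-force product/educt
join oracle.

## Enrichment statistics

### Weights

Each universe gene i receives an overall expression value
E_i = Σ_j A_ij, the sum of its spot intensities across the tissue
panel (spots mapping to the same gene are summed). Drawing
probabilities are p_i = E_i / Σ E. Universe members without any
expression row are excluded from the weight universe and reported;
members whose rows are all zero receive the smallest positive E before
normalization — a zero drawing probability would contradict their
observed presence — and the imputation count is recorded.

### The noncentral test

The null hypothesis is that the n filtered genes were drawn from the
universe with probabilities proportional to E_i, so that ubiquitously
expressed genes are more likely to appear than specialized ones. The
univariate noncentral (Fisher) hypergeometric distribution requires a
single odds parameter; the per-gene weights are collapsed to the
two-group mean ratio ω = mean(E, pathway) / mean(E, non-pathway),
computed per pathway — only a scalar odds defines the stated
distribution, and the group-mean ratio is its natural estimate. The
pmf f(x) ∝ C(K,x)·C(N−K,n−x)·ω^x is evaluated in log-space
(log-binomials via the log-gamma function, normalization by
log-sum-exp), which keeps extreme odds and large margins stable; the
one-tailed p-value is the tail sum P(X ≥ k), testing
over-representation only. The central Fisher test is the same code
with ω = 1. The implementation is held against exact rational
enumeration of all margin-preserving tables and against an independent
library implementation of the same distribution in the test suite.

### Monte-Carlo p-values for extended networks

Extension makes pathway overlap a function of a correlated vertex set,
so no closed-form null is available. Instead, T strict-size sets are
redrawn from the weighted null, each is 1-extended in the reference,
and the empirical p-value is (1 + #{o_t ≥ o_obs}) / (1 + T). The
add-one form is never zero — a requirement for downstream FDR input —
and the plain r/T form is available behind a flag. Weighted sampling
without replacement uses exponential race keys (the smallest
Exp(1)/w_i ranks), which is distributionally identical to drawing
sequentially with probability proportional to the remaining weights
and vectorizes over thousands of replicates; which classical urn model
the null should follow is not canonically fixed, and this sequential
(Wallenius-type) reading of "drawing probability E_i/ΣE" is the
package's documented choice. One common sample stream serves all
pathways of a collection, which is both faster and slightly
conservative for between-pathway comparisons (shared sampling noise).
With T = 10⁴ the resolution floor is p = 1/(T+1) ≈ 10⁻⁴.

### FDR control

Storey q-values with a single fixed λ (default 0.5):
π̂₀ = #{p > λ} / (m(1−λ)) clamped to [1/m, 1], then
q_(i) = min_{j≥i} π̂₀ · m · p_(j)/j, clamped to ≤ 1; λ = 0 reduces
exactly to Benjamini–Hochberg (verified against statsmodels). A
spline-smoothed π̂₀ would gain little at m ≈ 137 tests and would add a
tuning surface. The overlap-count p-values are discrete and therefore
stochastically larger than uniform, so the q-values err on the
conservative side; the type-I calibration test confirms a rejection
rate of ~3% at nominal 5% under the weighted null.

Pathways overlapping the filtered network in fewer than two vertices
are excluded from the table *and* from the FDR family (a one-gene
"overlap" is not a pathway-level statement); the family is defined per
run.

## Key-node analysis

For vertex v, with C the set of connected ordered vertex pairs (s, t),
s ≠ t, of the intact network: N₀(v) counts the pairs of C not
involving v, N₋ᵥ the connected pairs after deleting v, and
Dis(v) = (N₀(v) − N₋ᵥ)/N₀(v) (zero when N₀(v) = 0). Excluding pairs
that involve v itself isolates v's mediator role; because the
plain-language reading "fraction of pairs that become disconnected"
admits both conventions, the all-pairs variant (N₀ = |C|) is available
behind a flag and the mediator convention is the documented default.
Deleting a vertex can only destroy connections, so 0 ≤ Dis ≤ 1 always.

Pair counting runs on the condensation: within a strongly connected
component of size s there are s(s−1) ordered pairs, and the
transitive closure of the condensation DAG (computed by a reverse
topological sweep with boolean row unions) supplies the
cross-component pairs. The closure is recomputed from scratch for
every single-vertex deletion — O(V · (V_c² + E)) overall — which costs
a few tens of seconds at the ~1800-vertex reference scale and is
accepted for the sake of exact, oracle-matchable counts (the test
suite demands bit-equal pair counts against a remove-and-recount BFS
oracle).

The Dis-increase ΔDis(v) = Dis_f(v)/max Dis_f − Dis_r(v)/max Dis_r is
computed for the filtered network's vertices; it is antisymmetric
under exchanging the roles and bounded in [−1, 1]. Both maxima must
be positive, otherwise the normalization is undefined and the
comparison raises.

## Bow-tie and differential expression

The largest SCC (ties broken toward the component containing the
lexicographically smallest vertex, for determinism) is the LSCC; IN
reaches it, OUT is reached from it, everything else — including
tube-like vertices qualifying for both sides — is OTHER. A network
whose SCCs are all singletons yields an explicitly flagged degenerate
result instead of an arbitrary one-vertex "core".

Log2 fold-changes aggregate a gene's tag counts, normalize to counts
per million within each library, and add a pseudocount of c = 0.5 CPM
to both numerator and denominator, keeping ratios finite for genes
absent from one condition. The default sign is disease over normal;
it is configurable. Levene's test is implemented in its classical
mean-centered form — appropriate for the roughly symmetric,
moderate-tailed fold-change distributions — as the one-way ANOVA F of
the absolute deviations Z_ij = |Y_ij − Ȳ_i|; a zero numerator gives
W = 0, p = 1 (identical spread), a zero denominator with positive
numerator is flagged degenerate. In the variance-per-compartment
analysis only genes detected in *both* conditions enter: a gene seen
in one condition only yields a pseudocount-dominated fold-change of
about ±log2(cpm/c), i.e. pure detection noise of the same magnitude in
every compartment, which would mask the expression-variance signal the
analysis is after.

## Synthetic study conditions

The generator produces every input from one seed, at the scale of the
study it emulates, and all numbers below are its fixed defaults.

* **Reference network** — 1800 vertices, 3900 edges, with a planted
  bow-tie: a 300-vertex strongly connected core (a random cycle plus
  densification), a 450-vertex IN pool, a 550-vertex OUT pool and a
  500-vertex tendril remainder, proportions mirroring the curated
  signaling network the pipeline targets. Pools are forward-ordered
  and acyclic with anchoring edges, so the LSCC is exactly the planted
  core and the compartments equal the pools — topology tests get
  non-degenerate structure by construction. The free edge budget
  attaches preferentially to high-out-degree sources, giving a
  heavy-tailed out-degree profile.
* **Pathways** — 137 sets, sizes 1 + Poisson(47); each new member is
  drawn from the growing ball's frontier with probability 0.5, else
  uniformly: pathway membership is topologically clustered (as real
  pathways are) without collapsing into pure graph balls.
* **Detection** — baseline rate 0.33 per condition (0.30 in the
  recovery experiments), multiplied by ρ = 3 (capped at 1) for members
  of the planted pathway, in both conditions: enrichment is planted in
  *detection probability* because the pipeline is presence-based. The
  two conditions share an "expressed" state observed through a 0.95
  capture rate, with the expressed probability chosen so the marginal
  per-condition detection rate equals the target exactly; this keeps
  the symmetric difference between conditions small, as it is for two
  libraries from the same tissue.
* **Counts** — negative binomial around a library-scaled log-normal
  abundance (libraries of 50 000 tags), dispersion 1/r = 0.1, in the
  published range for tag-count libraries. The disease condition
  multiplies abundance by 2^δ with δ ~ N(0, σ²), σ = 0.4 (most genes
  within ±1 log2 unit), and σ² inflated fourfold for IN-compartment
  vertices — the topology-correlated expression variability the
  Levene analysis must recover.
* **Tissue matrix** — 84 tissues, log-normal intensities (σ_log = 1),
  one designated breast-like column upweighted ×3 for a random 20% of
  genes; 1–2 spots per gene. Row sums of 84 log-normals concentrate,
  so drawing weights are mildly heterogeneous (CV ≈ 0.35), matching
  the "ubiquitous versus specialized" premise without degenerate
  weights.
* **Reactions** — 120 enzymes with 1–5 reactions each over an
  800-substrate pool capped at 10 uses per ordinary substrate; 5
  currency substrates are spliced into 110 reactions each, i.e. above
  the 100-reaction currency threshold by construction.

What the generator does **not** emulate: real pathway identities and
cross-talk, identifier ambiguity beyond simple many-to-many fan-out,
batch effects or normalization artifacts in the intensity matrix, and
any biological correlation between expression level and network
degree. Passing tests therefore demonstrate that the statistical
machinery recovers planted structure under the stated sampling
assumptions — not that those assumptions hold for any particular real
data set.

## Numerical and testing choices

* Exact-test correctness is anchored to rational-arithmetic
  enumeration (|Δp| < 10⁻¹²) over all margins up to N = 20 and to the
  classical Fisher test at ω = 1 on random tables.
* Monte-Carlo p-values are validated on an edgeless reference, where
  extension is the identity and the exact central hypergeometric tail
  is known; agreement is required within three binomial standard
  errors at T = 10⁴.
* Disconnectivity is validated bit-exactly (integer pair counts)
  against an exhaustive remove-and-recount oracle on random digraphs.
* The planted pathway must attain the smallest q-value (ties allowed,
  since flat stretches of the q-cummin are genuine ties) in ≥ 90% of
  50 replicates in both strict-exact and extended-MC modes; the
  planted IN-compartment variance must be detected (p < 0.05) at the
  same rate.
* All simulations in tests and the acceptance script run at the
  default study scale (1800 vertices); the full suite completes in a
  few minutes on one CPU.

## Known limitations

* The scalar ω collapses the full weight vector; when weights vary
  strongly *within* a pathway the univariate noncentral law is an
  approximation to the multivariate one.
* The sequential weighted sampler and the Fisher-type test are two
  subtly different urn models; with the mild weight heterogeneity the
  tissue-sum weights produce, the mismatch is well inside the test's
  conservative margin (measured type-I ≈ 3% at nominal 5%), but very
  skewed weights would widen it.
* Dis recomputation is exact but quadratic-ish; networks beyond ~10⁴
  vertices would need an incremental or sampled variant.
* Storey's π̂₀ uses one fixed λ; with very few tests the clamp to
  [1/m, 1] dominates and q-values become conservative.
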