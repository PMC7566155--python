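# Methods

## Credal sets and their geometry

A credal set over a variable with `k` ordered states is the polytope of
probability vectors satisfying per-state interval bounds and optional
pairwise orderings `p_a >= p_b`. Declared state order is canonical: it
fixes vector indexing and breaks every tie in the package
(classification argmax, vertex sorting, search scans).

*Coherence* (`sum(l) <= 1 <= sum(u)`) guarantees non-emptiness for pure
interval sets; with orderings, emptiness is decided by a linear program
before any enumeration — an empty polytope is always an error, never an
empty vertex list. *Reachability* tightening uses the closed form
`l_i' = max(l_i, 1 - Σ_{j≠i} u_j)`, `u_i' = min(u_i, 1 - Σ_{j≠i} l_j)`;
it is idempotent, never enlarges an interval, and equals the
per-coordinate LP extrema (asserted against scipy's `linprog` in the
test suite). Orderings are deliberately not folded into the interval
tightening; they remain explicit constraints.

Vertex enumeration solves every choice of `k-1` active inequality
constraints together with the simplex equality and filters for
feasibility. Duplicates are merged at absolute tolerance `1e-9` (double
precision is ample at these dimensions). The number of states per set is
capped at 6 (combinatorial candidate growth); exceeding the cap is an
explicit `SizeGuardError`, not a silent truncation. An independent
H-representation-to-vertex oracle (scipy `HalfspaceIntersection` on the
projected simplex slice) confirms the enumeration on hundreds of random
specs in `tests/test_acceptance.py`.

## Inference under the strong extension

`bayesian_posterior` is plain variable elimination on a point-valued
network: factors are instantiated against the evidence, a greedy
min-weight elimination order is compiled once per query shape, and the
schedule is replayed as a sequence of `einsum` contractions. The
networks of interest are small (~20 variables, 2–4 states), so exact
elimination is always feasible.

`posterior_bounds` optimises that posterior over one extreme point per
(variable, parent-configuration) row. Because the posterior is a ratio
of forms multilinear in the row choices, its extrema are attained at
vertices, making vertex-combination search exact in principle. Three
reductions keep it tractable:

1. **Barren-node pruning** — only ancestors of the target and of
   evidence/do variables are retained.
2. **Evidence-row filtering** — CPT rows whose parent configuration
   contradicts an observed parent value never enter the computation and
   are not search dimensions; likewise, when the row's own variable is
   observed, vertices agreeing on the observed state's probability are
   one and the same choice.
3. **Separable target rows** — when the target is unobserved and
   childless in the pruned graph, the posterior is a convex mixture over
   parent configurations whose weights do not involve the target's own
   rows; each target row therefore independently takes its extreme value
   per side and drops out of the combinatorial search.

If the remaining search space has at most `exact_budget` combinations
(default 20,000 — sized so exact mode stays in the tens of seconds on
one core; configurable), it is enumerated and the result is exact.
Otherwise a steepest-descent over single-vertex swaps runs from
`restarts` random starts (default 8, seeded); rows and vertices are
scanned in fixed order with first-found tie-breaking, so results are
bit-reproducible for a given seed. The search only ever visits
admissible vertex combinations, so the reported interval is an *inner*
approximation — never wider than the truth — and is flagged
`exact=False`.

**Zero-probability evidence.** If every admissible combination gives the
evidence probability zero, the query raises `ConditioningError`. If only
some do, the optimisation runs over the rest (regular-extension
behaviour) and flags `regular_extension=True`; the vacuous `[0, 1]`
alternative would silently destroy every POD query involving rare
evidence.

**Interventions.** `do(X = x)` severs X's incoming arcs and replaces its
table by a point mass; the do-variable then behaves as evidence in the
mutilated net. On root variables, conditioning and intervening agree to
`1e-12` (tested). Both observe- and do-mode are exposed for the impact
statistic because the study does not state which was used; scenario
files record the mode per request.

**Impact.** For a manipulated variable A, the impact on a target state
is `max over ordered state pairs |lower P(t|A=a) − lower P(t|A=a')|`,
reported in percentage points — lower bounds because, in this
imprecise-probability setting, movements of the lower envelope are read
as prevalence shifts. Displayed values round to whole points; raw floats
are retained. Only lower bounds are computed (half the work of a
two-sided query).

## Expert elicitation

Verbal probability terms map to intervals through a seven-term scale
(`impossible [0,0]` … `certain [1,1]`), shipped as an editable JSON
config because any particular vocabulary is a convention, not a fact;
the packaged scale is symmetric and deliberately overlapping. Judgments
compile per CPT row: unjudged states stay vacuous `[0,1]` (silence is
ignorance, not uniformity), interval parts are reachability-tightened,
comparative statements become ordering constraints, and contradictory
sets are rejected with the conflicting constraints named. Compilation is
idempotent and monotone: adding a judgment never enlarges the credal
set. Only per-row judgments are supported; cross-row constraints are out
of scope.

## The place-of-death reference network

Structure (20 variables): cancer treatment gates end-of-life
communication; communication drives patient and family awareness of
dying; patient awareness gates whether the patient's preference gets
assessed; symptom burden and treatment drive hospital days; family
conditions for home care depend on carer availability, family
awareness, patient dependence, symptom burden and economic resources
and determine the family's preference; five service indicators
aggregate into a home-care-network strength; place of death depends on
both preferences, hospital days, the network and the area of residence.
"Not assessed" is an explicit state for the preference, awareness and
family-conditions variables — unknown preferences are a clinical
condition the model must reason about, not a data defect.

The interval tables are **illustrative**: the study's elicited values
were never published, so the shipped numbers are generated by documented
qualitative rules (`scripts/build_reference_model.py` — tempered softmax
scores for the POD table, narrative-consistent interval widths of
0.05–0.2 elsewhere) and every table carries `provenance:
"illustrative"`. They are data files: substituting genuinely elicited
values requires no code change. Design choices within the tables: the
home-care-network rows are point-valued (a near-deterministic tally of
five service indicators — imprecision lives in the service roots and
the POD table); most multi-state rows concentrate their imprecision on
one free state with a complementary partner, which both matches how a
single elicited interval propagates to a row and keeps vertex counts
(hence search neighbourhoods) small. Scenario files annotate the
study's narrative impact figures (`reference_impact_pct`) purely for
side-by-side display; no test asserts them, and the packaged model is
not claimed to reproduce them — only the qualitative ordering (family
preference strongest, patient preference weak, treatment→communication
large) is designed in.

## Classifier

Categorical naive Bayes with Laplace weight `alpha` (default 1,
recorded in the model file): priors `(n_c + α)/(n + αK)`, conditionals
`(n_{f=v,c} + α)/(n_{f observed, c} + αK_f)`. The markers `NA`,
`not_assessed` and `not_available` are missing data for the classifier —
skipped in counting and scoring — because missingness is informative
only in the credal model, where it is an explicit state. Day-count
columns are binned by a configurable discretization (hospital days
0 / 1–14 / >14 — no admission, short, long; assessment interval at its
empirical tertiles). Evaluation reports in-sample accuracy, a per-class
confusion table, the recorded care-team baseline, and leave-one-out
cross-validation (n refits), because the study does not state its
validation split.

## Synthetic cohorts

*Marginal-faithful* mode reproduces the published 116-patient summary
exactly: categorical columns contain exactly the printed counts; integer
day-count columns are built deterministically — fill with the floor of
the mean, place the printed minimum and maximum once each, spread the
residual in ±1 increments round-robin — so printed means are exact, then
each column is shuffled by its own seed-derived generator. Cross-column
joints are therefore random **by design**: the summary table publishes
no joint distribution, and any cross-tabulation quoted in prose is
deliberately not reproduced (and untestable here). Two printed
transcription quirks are handled explicitly: the tumour-site counts sum
to 115, balanced by one explicit `NA` record; and the day-count rows are
taken at face value as means. One column dictionary
(`data/dictionary.json`) is the single source of truth for names and
state vocabularies, shared with the reference network.

*Model-driven* mode selects one point distribution per network row
(rules: lower-corner, upper-corner, midpoint = vertex centroid, or
random-per-table) and ancestrally samples records, returning the chosen
Bayesian network as ground truth. Recovery testing fits the classifier
on a 10,000-record midpoint cohort and compares conditionals to the
generating network's exact values: ±0.03 for classes with at least
2,000 records; the nursing-home class draws only a few hundred records
at that cohort size, so its binomial noise alone exceeds that tolerance
and it gets a 0.08 sanity bound instead.

## Numerical choices and reproducibility

Vertex dedup/feasibility tolerance `1e-9`; Bayesian-reduction agreement
`1e-12`; local-search improvement threshold `1e-14` (guards against
cycling); enumeration cap 6 states per set; exact budget 20,000
combinations; 8 restarts. Every random draw descends from one master
seed via `numpy.random.SeedSequence` spawning — cohort columns, vertex
selection, sampling and search restarts each get their own stream, so
per-column or per-query results are independent of execution order.
Problem sizes in the shipped tests (500 geometry specs, 100 random
networks with ≤5 nodes, 1,000 containment samples per query,
10,000-record recovery cohorts) were chosen so the whole suite runs in
a couple of minutes on one core.

## Limitations

Passing tests certify the machinery — geometry against independent
oracles, bounds against brute force, exact cohort fidelity — not the
clinical numbers: the reference tables are illustrative, and the
marginal-faithful cohort carries no real between-column dependence, so
classifier accuracies quoted on it say nothing about accuracy on real
patients. Credal sets are limited to intervals plus pairwise orderings;
no continuous variables, no MAP/abduction queries, no structure
learning, no naive *credal* classifier. The local-search fallback is an
inner approximation; queries needing guaranteed outer bounds must fit
the exact budget.
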