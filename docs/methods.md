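# Methods

This note documents the models, decision rules, parameters and design
choices behind `lingcurate`, and what the synthetic test bed does and does
not demonstrate about real data.

## Data model

A trait matrix is a dense logical grid: every (taxon, feature) pair has a
cell that is either **coded** with a token from the feature's state space,
**unknown** (`?` — not surveyed, or explicitly coded as unknown in the
source), or **not applicable** (`NA` — logically impossible to fill).
Cells absent from input files are read as unknown, which keeps all
invariants total. The two reserved literals are configurable at the I/O
boundary because input dialects vary.

**Coding density** counts only coded cells; unknown and not-applicable
both count as uncoded. The alternative — excluding `NA` from the
denominator — would make conditioning *raise* density and bias the
densifier toward heavily conditioned features; counting `NA` as uncoded
treats deliberately introduced gaps like any other gap, which is the
reading consistent with densification that avoids penalizing sparsely
coded features.

## Logical curation

Curation is plan-driven: a `RecodePlan` (the machine-readable form of a
decisions log) lists modifications executed strictly in order; cycles and
dangling references are hard errors, because the log is an ordered ledger.
The package never invents curation decisions — which features to exclude,
merge, derive or condition is always input data.

Operator semantics, per taxon:

* **state adaptation** — coded tokens are rewritten through a mapping;
  tokens mapped to `?` are discarded. Excluded states become unknown, not
  `NA`: the taxon has a real value that was dropped, so the cell is
  missing information rather than inapplicable. The adapted feature must
  keep ≥ 2 states.
* **meta-feature derivation** (binary inputs) — any coded `1` → `1`; all
  coded `0` → `0`; anything else → `?`. Transferring unknowns keeps `0`
  meaning *known* absence.
* **conditioning** — condition coded and allowed → target unchanged;
  coded and not allowed → `NA`; unknown → `?` in conservative mode,
  target unchanged in liberal mode; condition `NA` → `NA` in both modes
  (anything conditioned on an inapplicable feature is itself
  inapplicable; the inherited-NA case is our extension of the published
  true/false/uncoded semantics). Conditioning never rewrites a coded
  value to a different coded value.
* **combination merge** — both inputs are mapped into a shared state
  space; agreement wins, conflicts go to the declared priority input, a
  single coded side wins over an uncoded one, and the result is `NA` only
  when both inputs are `NA`.
* **decomposition** is expressed as state adaptations optionally
  conditioned on an earlier part (the presence/position split of a
  compositional feature is the canonical case); no further primitive is
  needed.

Inputs of replacing operations are removed from the matrix; meta-feature
derivation keeps its inputs because they are normally replaced afterwards
by conditioned versions. After the last modification, two automatic
filters run: every feature must have its second-most-frequent state
attested in at least `min_variability` = 3 taxa, and plan-produced
features must be coded for at least `min_coding` = 100 taxa. Both
thresholds are project choices, overridable in `CurationConfig`; small
fixtures can disable the filters.

When more than one feature is liberally conditioned on the same feature,
dependencies can emerge among the conditioned features; the engine treats
this as a situation for the analyst's judgement (a logged diagnostic at
plan level), not an error.

Feature-naming helpers implement both published conventions: suffix-style
ids (`e`, `m`, `drm`, `c`, plus capitalized `C`/`F`/`EO`/`EON` for
statistical modifications) and prefix-style ids (`o_` for originals,
`rec_` plus ordered operation letters, `+`-joined inputs for merges,
numeric suffixes for decomposition parts).

## Diversity sampling

Statistical tests never run on raw language samples: relatedness and
areality would masquerade as universals. A diversity sample draws, per
macroarea, `n_per_area` = 20 distinct lineages (families or isolates)
uniformly without replacement among lineages containing at least one
eligible taxon, then one eligible taxon uniformly per lineage — 120 taxa
under the default six areas. Eligibility can require a minimum number of
coded features (0 for dense inputs; 10 in the sparse multi-source
configuration). Batches derive per-sample seeds from a master seed and are
exactly reproducible.

Design choices: a lineage spanning several macroareas may contribute to
each area it has taxa in — stratification operates on (area, lineage)
pairs given by taxon-level macroarea assignments, so "20 distinct
lineages" is enforced within, not across, areas. Undersized areas are a
hard error (naming the area and shortfall) rather than silently shrunk,
to keep samples comparable across a batch.

## Dependency testing

An expectation declares two (feature, state) sides and a type: `THEN`
(unidirectional implication), `OR` (exclusionary bidirectional) or `AND`
(positive bidirectional). The 2×2 cross-table over both-coded taxa uses
the convention `a` = neither state, `b` = side2 only, `c` = side1 only,
`d` = both, so THEN predicts `c ≪ d`, OR predicts `c ≫ d` and `b ≫ d`,
AND predicts `c ≪ d` and `b ≪ d`.

The pipeline per expectation:

1. **Overlap prefilter** (full matrix, once): coded overlap divided by the
   larger coded set must reach 0.30, otherwise the dependency affects too
   few taxa to act on. Evaluating it once on the full matrix (not per
   sample) matches its role as a feature-level gate.
2. **Applicability per sample**: among taxa bearing the antecedent state,
   the fraction also coded for the other feature; bidirectional types
   compute both directions and use the lower ratio. Samples below 1/3 (or
   with an empty antecedent set, flagged distinctly) are dropped. Fewer
   than 20 surviving samples → the expectation is untestable.
3. **Probabilities per surviving sample**: the conditional probability of
   the unexpected combination (e.g. `P(side2 ≠ s2 | side1 = s1)` for
   THEN) and the corresponding marginal. Both are computed over the
   sample's both-coded taxa — the same universe — so the pair is
   comparable; computing the marginal over all sample taxa would mix
   universes and bias the paired difference.
4. **Aggregation and decision**: with conditional and marginal vectors
   over valid samples, the paired effect size is
   `D = |mean(marg − cond)| / sd(marg − cond)` with the sample (n − 1)
   standard deviation. A direction is *strong* iff `D > 1.3`,
   `μ_cond + σ_cond < 0.2`, and `mean(cond) < mean(marg)` — the last
   guard ensures a large effect in the anti-expected direction never
   triggers action. THEN acts iff its single direction is strong; OR/AND
   act iff both directions are strong; any direction with `D > 1.3` that
   does not act is logged as a known remaining dependency; otherwise no
   action. A zero-spread difference vector yields infinite D (counted as
   `D > 1.3`, flagged as degenerate): a perfectly consistent difference
   is maximal evidence. No multiple-testing correction is applied — the
   procedure uses fixed effect-size thresholds on declared hypotheses,
   not p-values over a search.

The `μ + σ < 0.2` rule has a coverage interpretation: if the conditional
probability is approximately Gaussian across samples, then in
Φ(1) ≈ 84% of samples no more than 20% of languages are exceptions.

## Statistical curation

Acted-on dependencies are resolved by declared actions (the choice between
conditioning and merging, and the direction of conditioning, are analyst
inputs — `ActionSpec` requires them). Conditioning mode is chosen by
prevalence: liberal iff the condition state covers ≥ 90% of coded taxa
(boundary inclusive), else conservative. Merge semantics for two binary
features: `F` keeps the four combination states `11/10/01/00` and is
information-preserving wherever both inputs are coded; `EO` keeps only the
two mutually exclusive states; `EON` adds a `neither` state. Combinations
that contradict an exclusionary merge (both present; for `EO` also both
absent) map to unknown rather than a dedicated state, since only the
exclusive states (plus neither) are meaningful states of the merged
feature. Expectations touching replaced features are re-tested against
the replacements on the *same* diversity samples, so second-round
decisions are comparable to the first round; expectations whose
referenced state no longer exists are logged as inapplicable.

## Densification

Pruning removes one element per step, the minimizer of

    taxon score   = density(taxon)^w_coding × (1 / redundancy)^w_taxonomy
    feature score = density(feature)

with `redundancy` the number of remaining taxa sharing the taxon's
lineage (ties: features before taxa, then lexicographic id). This scoring
formula is this package's concrete realization of a taxonomy-sensitive
density mean: with `w_taxonomy > 0`, members of large families are cheap
to drop, protecting lineage diversity. Default weights are
`taxonomy = 1`, `coding = 0.999`.

Each step records `n_taxa`, `n_features`, `n_data_points` (coded cells),
`coding_density`, `row_coding_density_min` (minimum per-taxon density)
and `taxonomic_index` (retained top-level lineages / input lineages). The
optimal sub-matrix maximizes the product of these terms raised to
user-chosen exponents (default `n_data_points · coding_density ·
row_coding_density_min · taxonomic_index³`); ties resolve to the earliest
(largest) step, and a fully dense input is returned unchanged.

The minimum-variability rule is enforced at the boundaries of the run —
violating features are dropped from the input before step 0, and the
selected sub-matrix is filtered again after selection — but deliberately
*not* inside the pruning loop. A feature that loses variability
mid-trajectory can be arbitrarily densely coded; removing it there would
break the procedure's defining property that overall coding density never
decreases along the trajectory (each step removes the minimum-density
element of its kind, which lies at or below its kind's mean density when
redundancy is uniform). With non-uniform redundancy and a positive
taxonomy weight, density monotonicity is traded against lineage
protection by design.

## Diagnostics

**Local entropy maps.** Taxa with coordinates are assigned to their
nearest point (great-circle distance) of a Fibonacci lattice — a
near-equal-area spherical grid; land-masking is unnecessary because grid
points with no assigned taxa simply drop out. At each point with ≥ 2
taxa, each feature coded for > 50% of the point's taxa contributes its
normalized Shannon entropy `−Σ pᵢ ln pᵢ / ln K` over coded states, with
`K` the feature's *global* state-space size, constant across grid points
for comparability (locally observed state counts would make cells with
different attested subsets incommensurable). The cell value is the
arithmetic mean over contributing features; map differences are taken on
shared grid points.

**Family-aggregated ordination.** The matrix is aggregated per family as
the proportion of coded taxa bearing each state, omitting each feature's
globally most frequent state as redundant (global ties drop the
lexicographically smallest token, a deterministic convention). The
resulting family × state-proportion tables are decomposed by NIPALS PCA —
components fitted one at a time by alternating least squares restricted
to observed cells, with column mean-centering over observed entries and
deflation of observed residuals — and two tables are compared by
per-component absolute score correlations over shared families (absolute,
because component signs are arbitrary). Convergence tolerance 1e−9, at
most 1000 iterations per component, initialized from the
highest-variance column.

## Synthetic data

The generator emulates the statistical structure the workflow must
handle, with defaults chosen as a realistic mid-size configuration:

* six macroareas × 25 lineages each (comfortably above the 20 the sampler
  needs), family sizes from a zipf(α = 2) law truncated at 12 — real
  family sizes are heavily skewed, which is exactly what the
  taxonomy-sensitive densifier must cope with;
* binary features with presence frequencies drawn uniformly from
  [0.2, 0.8] unless pinned; multi-state features with Dirichlet weights;
* planted logical blocks generated meta-first, subordinates following the
  meta either with target semantics (`NA` where absent) or deliberately
  un-conditioned (known absence everywhere) to reproduce the
  similarity-boosting pathology logical curation removes;
* planted dependencies with exception rate ε: for THEN, the consequent
  state holds with probability 1 − ε where the antecedent state holds and
  follows the baseline elsewhere, so ε is directly the conditional
  violation probability (independence corresponds to ε equal to the
  baseline violation rate, e.g. ε = 0.5 for a symmetric consequent);
* missingness applied last: cell-level MCAR plus per-source feature-block
  coverage gaps, because multi-source sparsity is source-structured
  rather than random; planted `NA` semantics survive missingness.

Two bundled fixtures (~230–300 taxa, 40 features) mirror the two input
styles: a dense, mostly binary single-source matrix with an
un-conditioned gender-style block and one strong planted implication
(antecedent frequency 0.4, consequent baseline 0.5, ε = 0.02), and a
sparse multistate matrix with four simulated source databases of
differing coverage.

**What the synthetic bed does not show.** It makes no attempt to mimic
real typological frequencies of specific features, real spatial or
phylogenetic autocorrelation of states, or missingness that depends on
the states themselves. Passing tests therefore demonstrate that the
operators, decision rules and pipelines behave as specified under known
ground truth — not that any particular real-world curation is correct,
which remains an expert judgement encoded in the input plans. Published
full-scale curation counts and densified-dataset statistics depend on the
archived source datasets and manual decision logs and are out of scope
here; the property-based suites stand in for them. Problem sizes in the
test suite (hundreds of taxa, tens of features, 50–100 samples per batch)
were chosen as the smallest scales at which the stochastic decision rules
are stable.

## Numerical and interface conventions

* All randomness flows through `numpy.random.default_rng` seeds; batch
  seeds are drawn below 2³¹ from a master seed.
* CLDF export writes unknown cells as absent value rows and
  not-applicable cells as explicit `NA` values with a per-parameter NA
  code, so the `?`/`NA` distinction survives round-trips; row orders are
  sorted, making output byte-stable.
* `CurationConfig` exposes every threshold (100 / 3 / 0.30 / 1⁄3 / 20 /
  1.3 / 0.2 / 0.90, sample counts and sizes) with the defaults above;
  YAML or JSON config files override any subset.

## Known limitations

* Conditioning chains are executed strictly in plan order; the engine
  does not reorder or parallelize modifications.
* The densifier is a contract-level implementation of taxonomy-sensitive
  pruning; it does not claim internal equivalence with any other
  densification routine's density-mean or index definitions.
* The segment-class predicate table bundled under
  `lingcurate/data/` carries the published design IDs, descriptions and
  origin tags, but its boolean predicates are this package's own
  synthetic realization over a simplified segment-attribute schema.
* `retest_replacements` performs one re-testing round per call; deeply
  chained replacement cascades require iterating until a fixed point.
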