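# lingcurate

Curation of categorical trait matrices — taxa × discrete features with
three-way cell semantics (coded state, unknown `?`, not-applicable `NA`) —
for **feature independence**, as needed before multivariate analyses of
cross-linguistic (Grambank/WALS-style) or comparable character data.

## The problem

Typological databases were rarely designed so that their features are
independent. Two kinds of dependency corrupt analyses that treat features
as independent inputs:

* **Logical dependencies.** One feature's state entails another's (e.g. a
  language with *no gender* necessarily has *no sex-based gender system*),
  or a block of binary manifestation features is not conditioned on the
  presence of the phenomenon they manifest. Taxa lacking the phenomenon
  then share the same "absent" signal many times and appear spuriously
  similar.
* **Statistical dependencies.** Near-exceptionless implicational
  universals (e.g. *prepositions → noun–genitive order*) couple features
  across all families and areas.

`lingcurate` implements a reproducible, fully logged curation workflow:

1. **Logical curation** (`lingcurate.recode`) — a machine-readable plan of
   modifications drives operators for state adaptation, meta-feature
   derivation (any coded `1` → `1`; all coded `0` → `0`; else `?`),
   conservative/liberal conditioning, combination merges and
   decomposition, plus two automatic filters (a feature must be coded for
   ≥ 100 taxa and its second-most-frequent state attested in ≥ 3).
2. **Dependency testing** (`lingcurate.dependencies`) — declared THEN / OR
   / AND expectations are evaluated over genealogically and areally
   stratified **diversity samples** (120 taxa: 20 distinct lineages from
   each of 6 macroareas, one taxon per lineage). Per sample the
   conditional probability of the unexpected state combination is paired
   with the corresponding marginal probability; across samples a paired
   Cohen's D, `D = |mean(marg − cond)| / sd(marg − cond)`, quantifies the
   effect. A dependency is acted on iff `D > 1.3` **and**
   `μ + σ < 0.2` for the conditional probability (per direction), with an
   applicability-ratio gate (≥ 1/3 per sample, ≥ 20 valid samples) and a
   30% coded-overlap prefilter.
3. **Statistical curation** (`lingcurate.statcur`) — acted-on dependencies
   are resolved by conditioning (liberal iff the condition state covers
   ≥ 90% of coded taxa) or by F/EO/EON merges, and affected expectations
   are re-tested on the same samples.
4. **Densification** (`lingcurate.densify`) — taxonomy-sensitive iterative
   pruning raises coding density; the optimal sub-matrix is chosen by a
   composable scoring function over `n_data_points`, `coding_density`,
   `row_coding_density_min` and `taxonomic_index`.
5. **Diagnostics** (`lingcurate.diagnostics`) — grid-based normalized
   entropy maps of local typological diversity, and family-aggregated
   ordination comparison via missing-data-tolerant (NIPALS) PCA.

A synthetic-data module (`lingcurate.synth`) generates taxonomies and
matrices with planted logical and statistical structure so the whole
pipeline is testable end to end, and `lingcurate.io` reads and writes flat
matrix CSVs, the decisions-log / recode-patterns metadata dialect and CLDF
StructureDataset bundles.

## Worked example

```python
import lingcurate as lc

# a bundled synthetic dataset with a planted implication GB010=1 -> GB011=1
m, tax, truth = lc.grambank_like_fixture(seed=7)
print(m, "density: %.3f" % lc.coding_density(m))

samples = lc.generate_samples(100, None, tax, master_seed=11)
e = lc.Expectation("S-DEM-1", "THEN", ("GB010", "1"), ("GB011", "1"))
r = lc.evaluate_expectation(m, e, samples)
agg = r.aggregates[0]
print(f"decision={r.decision}  D={agg['cohens_d']:.2f}  "
      f"mu+sigma={agg['mu_cond'] + agg['sd_cond']:.3f}")

# act on it: condition the consequent on the antecedent state
out, replaced, audit = lc.apply_actions(
    m, [lc.ActionSpec("S-DEM-1", "condition", target="GB011")],
    {"S-DEM-1": e})
retests, _ = lc.retest_replacements(out, [e], replaced, samples)
print("after curation:", retests[0].decision)
```

prints

```
<TraitMatrix 226 taxa x 40 features> density: 0.753
decision=act  D=8.92  mu+sigma=0.053
after curation: none
```

The planted implication is detected (`act`: very strong paired effect,
exception level 5.3% < 20%) and, once the consequent is conditioned on the
antecedent (conservative mode, since the antecedent state covers well
under 90% of taxa), the re-test on the same samples finds nothing left to
act on — the dependency has been removed from the matrix.

The same pipeline is available from the shell:

```sh
lingcurate synth --seed 3 --out demo
lingcurate sample --taxonomy demo/taxonomy.csv --n 100 --seed 11 --out samples.csv
lingcurate test-dependencies --matrix demo/matrix.csv \
    --expectations expectations.csv --samples samples.csv --out results.csv
lingcurate densify --matrix demo/matrix.csv --taxonomy demo/taxonomy.csv --out dense
```

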