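"""Statistical dependency testing of declared implicational expectations.

A candidate dependency between two feature states is declared, never mined:
an :class:`Expectation` names two (feature, state) sides and a type —

* ``THEN`` — unidirectional implication: side1's state (almost) always
  co-occurs with side2's state;
* ``OR``   — exclusionary bidirectional: the two states (almost) never
  co-occur;
* ``AND``  — positive bidirectional: the two states (almost) always
  co-occur in both directions.

Testing runs over genealogically/areally stratified diversity samples so
that shared inheritance and areality cannot masquerade as a universal
tendency. Per sample, conditional probabilities of the *unexpected* state
combination are compared with the corresponding marginal probabilities (to
rule out artefacts of skewed state frequencies); across samples, a paired
Cohen's D of the two probability vectors quantifies the effect, and fixed
thresholds on D and on the exception level (mean + sd of the conditional)
yield the decision: act on the dependency, log it as known-but-remaining,
or leave the features untouched.

Cross-table cell convention (side1 state vs not x side2 state vs not)::

            f2 != s2   f2 == s2
    f1!=s1      a          b
    f1==s1      c          d

so a THEN expectation predicts c << d, OR predicts c >> d and b >> d, and
AND predicts c << d and b << d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CurationConfig, DEFAULT_CONFIG
from .core import RESERVED, TraitMatrix
from .sampling import DiversitySample

ETYPES = ("THEN", "OR", "AND")

DECISIONS = ("act", "log_remaining", "none", "untestable_overlap",
             "untestable_samples")


@dataclass(frozen=True)
class Expectation:
    """A declared THEN/OR/AND dependency hypothesis between feature states."""

    id: str
    etype: str
    side1: tuple[str, str]  # (feature id, state token)
    side2: tuple[str, str]
    motivation: str = ""

    def __post_init__(self) -> None:
        if self.etype not in ETYPES:
            raise ValueError(f"{self.id}: unknown expectation type {self.etype!r}")
        if self.side1[0] == self.side2[0]:
            raise ValueError(f"{self.id}: both sides reference the same feature")

    @property
    def features(self) -> tuple[str, str]:
        return self.side1[0], self.side2[0]


@dataclass(frozen=True)
class CrossTable:
    """2x2 counts over taxa coded for both features (see module docstring)."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SampleStats:
    """Per-sample applicability, conditional and marginal probabilities."""

    applicability: tuple[float, ...]
    conditional: tuple[float, ...]
    marginal: tuple[float, ...]
    n_both_coded: int
    valid: bool
    invalid_reason: str = ""


@dataclass
class ExpectationResult:
    """Aggregated outcome of testing one expectation."""

    expectation: Expectation
    decision: str
    n_valid_samples: int = 0
    overlap_ratio: float = float("nan")
    # per direction: mu/sd of conditional and marginal vectors + Cohen's D
    aggregates: list[dict] = field(default_factory=list)
    per_sample: list[SampleStats] = field(default_factory=list)
    degenerate_d: bool = False

    def summary_row(self) -> dict:
        row = {
            "expectation": self.expectation.id,
            "type": self.expectation.etype,
            "decision": self.decision,
            "n_valid": self.n_valid_samples,
            "overlap_ratio": self.overlap_ratio,
        }
        for i, agg in enumerate(self.aggregates, start=1):
            for k, v in agg.items():
                row[f"{k}_{i}"] = v
        return row


# -- building blocks -------------------------------------------------------


def overlap_prefilter(m: TraitMatrix, f1: str, f2: str,
                      threshold: float = 0.30) -> tuple[bool, float]:
    """Feature-level coded-overlap gate, evaluated on the full matrix.

    ``ratio`` is the coded overlap divided by the larger coded set: the
    better-coded feature must have at least ``threshold`` of its taxa coded
    for the other feature, otherwise a dependency would affect too few taxa
    to be worth acting on.
    """
    coded = m.coded_mask()
    c1, c2 = coded[f1].to_numpy(), coded[f2].to_numpy()
    bigger = max(int(c1.sum()), int(c2.sum()))
    if bigger == 0:
        return False, 0.0
    ratio = float((c1 & c2).sum() / bigger)
    return ratio >= threshold, ratio


def cross_table(m: TraitMatrix, taxa, side1: tuple[str, str],
                side2: tuple[str, str]) -> CrossTable:
    """2x2 cross-table over the given taxa coded for both features."""
    (f1, s1), (f2, s2) = side1, side2
    sub = m.data.loc[list(taxa), [f1, f2]]
    v1, v2 = sub[f1], sub[f2]
    c1, c2 = ~v1.isin(RESERVED), ~v2.isin(RESERVED)
    bc = (c1 & c2).to_numpy()
    e1 = (v1 == s1).to_numpy()[bc]
    e2 = (v2 == s2).to_numpy()[bc]
    return CrossTable(
        a=int((~e1 & ~e2).sum()), b=int((~e1 & e2).sum()),
        c=int((e1 & ~e2).sum()), d=int((e1 & e2).sum()),
    )


def conformity_counts(t: CrossTable, etype: str) -> tuple[int, int]:
    """(conforming, violating) language counts for an expectation type.

    THEN counts only the antecedent-without-consequent cell as violating;
    AND treats both single-sided cells as violations and both-present /
    both-absent as conforming; OR treats co-occurrence as the violation and
    the two exclusive cells as conforming (the neither cell is not counted
    either way).
    """
    if etype == "THEN":
        return t.a + t.b + t.d, t.c
    if etype == "AND":
        return t.a + t.d, t.b + t.c
    if etype == "OR":
        return t.b + t.c, t.d
    raise ValueError(f"unknown expectation type {etype!r}")


def cohens_d_paired(cond, marg) -> tuple[float, bool]:
    """Paired effect size |mean(marg - cond)| / sd(marg - cond), ddof=1.

    Returns (D, degenerate): when the differences have zero spread, D is
    +inf for a consistent nonzero difference (maximal evidence) and 0 for
    identical vectors, and the degenerate flag is set.
    """
    cond = np.asarray(cond, dtype=float)
    marg = np.asarray(marg, dtype=float)
    if cond.shape != marg.shape or cond.size < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    diff = marg - cond
    sd = float(np.std(diff, ddof=1))
    mean = float(np.mean(diff))
    # a spread at rounding-error level is a constant difference
    if sd <= 1e-12 * max(1.0, abs(mean)):
        return (math.inf if abs(mean) > 1e-12 else 0.0), True
    return abs(mean) / sd, False


# -- per-sample machinery --------------------------------------------------


def _direction_stats(e_ant: np.ndarray, coded_cons: np.ndarray,
                     e1b: np.ndarray, e2b: np.ndarray, etype: str,
                     direction: int) -> tuple[float, float | None, float | None]:
    """Applicability + (conditional, marginal) for one direction.

    ``e_ant``/``coded_cons`` live on all sample taxa; ``e1b``/``e2b`` are
    the state-match indicators restricted to both-coded taxa. Direction 1
    conditions on side1's state, direction 2 on side2's.
    """
    n_ant = int(e_ant.sum())
    if n_ant == 0:
        return math.nan, None, None
    app = float((e_ant & coded_cons).sum() / n_ant)
    n = e1b.size
    if n == 0:
        return app, None, None
    ant = e1b if direction == 1 else e2b
    cons = e2b if direction == 1 else e1b
    denom = int(ant.sum())
    if denom == 0:
        return app, None, None
    if etype == "OR":
        # unexpected combination: co-occurrence of the two states
        conditional = float(cons[ant].sum() / denom)
        marginal = float(cons.sum() / n)
    else:
        # THEN / AND: unexpected combination: antecedent without consequent
        conditional = float((~cons[ant]).sum() / denom)
        marginal = float((~cons).sum() / n)
    return app, conditional, marginal


def sample_probabilities(m: TraitMatrix, sample: DiversitySample,
                         e: Expectation,
                         config: CurationConfig = DEFAULT_CONFIG) -> SampleStats:
    """Applicability ratios and probabilities for one diversity sample.

    A sample is invalid for the expectation when its applicability ratio
    (the lower of the two, for bidirectional types) falls below the
    configured threshold, or when a needed denominator is zero.
    """
    (f1, s1), (f2, s2) = e.side1, e.side2
    sub = m.data.loc[sample.taxa, [f1, f2]]
    v1 = sub[f1].to_numpy(dtype=object)
    v2 = sub[f2].to_numpy(dtype=object)
    c1 = ~np.isin(v1, RESERVED)
    c2 = ~np.isin(v2, RESERVED)
    e1, e2 = (v1 == s1) & c1, (v2 == s2) & c2
    bc = c1 & c2
    e1b, e2b = e1[bc], e2[bc]

    directions = (1,) if e.etype == "THEN" else (1, 2)
    apps, conds, margs = [], [], []
    reason = ""
    for d in directions:
        ant = e1 if d == 1 else e2
        coded_cons = c2 if d == 1 else c1
        app, cond, marg = _direction_stats(ant, coded_cons, e1b, e2b,
                                           e.etype, d)
        apps.append(app)
        if math.isnan(app):
            reason = "no taxon bears the antecedent state"
        elif app < config.applicability_ratio:
            reason = "applicability ratio below threshold"
        elif cond is None:
            reason = "conditional denominator zero"
        else:
            conds.append(cond)
            margs.append(marg)
    valid = reason == "" and len(conds) == len(directions)
    return SampleStats(
        applicability=tuple(apps),
        conditional=tuple(conds) if valid else (),
        marginal=tuple(margs) if valid else (),
        n_both_coded=int(bc.sum()),
        valid=valid,
        invalid_reason=reason,
    )


# -- aggregation and decision ----------------------------------------------


def decide(result: ExpectationResult,
           d_threshold: float = 1.3,
           exc_threshold: float = 0.2,
           min_samples: int = 20) -> str:
    """Apply the decision rules to an aggregated result.

    A direction is *strong* iff D > ``d_threshold``, the exception level
    mu + sigma of its conditional probabilities is below ``exc_threshold``,
    and the effect points the expected way (mean conditional below mean
    marginal). All directions strong → ``act``; any direction with
    D > ``d_threshold`` otherwise → ``log_remaining``; else ``none``.
    """
    if result.decision == "untestable_overlap":
        return result.decision
    if result.n_valid_samples < min_samples:
        return "untestable_samples"
    strong, high_d = [], []
    for agg in result.aggregates:
        d_high = agg["cohens_d"] > d_threshold
        high_d.append(d_high)
        strong.append(
            d_high
            and agg["mu_cond"] + agg["sd_cond"] < exc_threshold
            and agg["mu_cond"] < agg["mu_marg"]
        )
    if strong and all(strong):
        return "act"
    if any(high_d):
        return "log_remaining"
    return "none"


def evaluate_expectation(
    m: TraitMatrix,
    e: Expectation,
    samples: list[DiversitySample],
    config: CurationConfig = DEFAULT_CONFIG,
) -> ExpectationResult:
    """Run the full test for one expectation over a batch of samples."""
    f1, f2 = e.features
    proceed, ratio = overlap_prefilter(m, f1, f2, config.overlap_ratio)
    if not proceed:
        return ExpectationResult(e, "untestable_overlap", overlap_ratio=ratio)

    per_sample = [sample_probabilities(m, s, e, config) for s in samples]
    valid = [s for s in per_sample if s.valid]
    result = ExpectationResult(
        e, "none", n_valid_samples=len(valid), overlap_ratio=ratio,
        per_sample=per_sample,
    )
    n_dir = 1 if e.etype == "THEN" else 2
    if len(valid) >= 2:
        for d in range(n_dir):
            cond = np.array([s.conditional[d] for s in valid])
            marg = np.array([s.marginal[d] for s in valid])
            dval, degenerate = cohens_d_paired(cond, marg)
            result.degenerate_d |= degenerate
            result.aggregates.append({
                "mu_cond": float(cond.mean()),
                "sd_cond": float(cond.std(ddof=1)),
                "mu_marg": float(marg.mean()),
                "sd_marg": float(marg.std(ddof=1)),
                "cohens_d": dval,
            })
    result.decision = decide(result, config.d_threshold,
                             config.exception_threshold,
                             config.min_valid_samples)
    return result


def evaluate_expectations(
    m: TraitMatrix,
    expectations: list[Expectation],
    samples: list[DiversitySample],
    config: CurationConfig = DEFAULT_CONFIG,
) -> tuple[list[ExpectationResult], pd.DataFrame]:
    """Test a batch of expectations; return results + summary table."""
    results = [evaluate_expectation(m, e, samples, config) for e in expectations]
    return results, pd.DataFrame([r.summary_row() for r in results])
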