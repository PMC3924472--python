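# Methods

## The prioritisation model

The engine answers one question: *given two everyday activities, which one
should be done first?*  Each activity is described by a small discrete
attribute vector; the default schema has three attributes:

| attribute        | domain (ordered)                                    | meaning |
|------------------|-----------------------------------------------------|---------|
| `deadline_bucket`| overdue, today, within_week, later, none            | deadline urgency |
| `requested_by`   | father, mother, someone_else, nobody                | who asked for it |
| `area`           | academic, personal, family, leisure                 | life area |

Free-form calendar deadlines are discretised by `bucket_deadline` with a
half-open one-week boundary: strictly before the reference date → *overdue*;
equal → *today*; in (reference, reference + 7 days] → *within_week*;
beyond → *later*; absent → *none*.  Five buckets keep the attribute finite
for tree induction while still separating the urgency levels a teenager
actually faces.  Dates are ISO-8601 calendar dates with no time of day.
The schema is configuration (JSON), not code: deployments can add areas,
attributes and values freely.

### ID3 induction

A binary-labeled training table (*priority* / *non-priority*) is turned into
a decision tree by plain ID3: at each node the attribute with maximal
information gain is chosen, where gain is the reduction in Shannon entropy
H(S) = −Σᵢ pᵢ log₂ pᵢ (base 2 throughout, so entropies are in bits).
Recursion stops at pure label sets; exhausted attributes yield the majority
label; empty branches inherit the parent's majority.  Deliberate tie-break
rules make builds deterministic:

* equal gains → lexicographically smaller attribute name wins;
* exact majority ties → *priority* (when the data cannot decide, the
  conservative therapeutic default is to treat the activity as important).

There is no pruning, no gain ratio and no continuous-attribute handling:
domains are tiny and finite by construction, and the trees stay small (the
default tree has 8 leaves).

### Leaf weights and the pairwise rule

Every leaf carries a distinct positive integer weight.  The shipped policy
ranks leaves by (1) label — priority before non-priority, (2) deadline
urgency along the leaf's path, (3) requester precedence along the path,
(4) lexicographic path as the final deterministic tie-break, and assigns
weights n_leaves … 1 down that ranking, so weights are always a permutation
of 1..n.  The policy is a plain callable argument of `assign_weights` and
can be swapped.

`prioritise(a, b)`: if exactly one activity is labelled priority it wins
outright; otherwise (both priority *or* both non-priority) the greater leaf
weight wins and the decision is flagged `tie_break_used`.  Resolving
both-non-priority pairs by weight too means the query tool never refuses to
answer.  Identical leaves fall back to the lexicographically smaller
activity id, also flagged.  At classification time an attribute value the
tree has never seen (possible only after schema drift) routes to the child
that held the training majority and sets a `fallback_used` flag — a hard
error was rejected so an interactive query can never dead-end.

### Default training table

The concrete deployed tree is not recoverable, so the shipped tree is
induced at run time from a programmatic full-grid table (80 rows) labeled by
a transparent rule: overdue/today → priority; within_week → priority iff
somebody asked; otherwise non-priority.  The rule is area-independent on
purpose — the life area drives quiz adaptation, not urgency — and any
deployment can induce from its own CSV instead.

## Quiz adaptation

Per-area attempt/error counts form a `DifficultyProfile`.  Area selection
probability is the normalised Laplace-smoothed error rate
(errors + α)/(attempts + 2α) with α = 1.  Properties: uniform with no
history; strictly positive everywhere (no area is ever starved); monotone in
errors at fixed attempts; flattens back to uniform as α → ∞.  The activity
pair is then drawn uniformly within the chosen area — pair-level difficulty
modelling was rejected as unsupported.  All randomness flows through one
caller-supplied seeded generator, so sessions replay exactly.

Supervisor-injected questions carry `source="supervisor"`, are validated
against the schema on entry, default to the tree's answer as ground truth,
and grade exactly like generated ones.

## Questionnaire scoring

* **SUS**: items 1,3,5,7,9 contribute (value − 1); items 2,4,6,8,10
  contribute (5 − value); total × 2.5.  Scores live on a 2.5 grid in
  [0, 100] and obey the complement identity score(r) + score(6 − r) = 100.
* **TMBQ**: 34 items, four factors (F1 goal/priority setting, F2
  time-management mechanics, F3 preference for disorganisation, F4 perceived
  control of time), scored as per-factor item means on the 1–5 scale.  No
  reverse coding: high F3 already *means* preference for disorganisation, so
  raw scoring is the faithful reading.  The item→factor partition is
  configuration; the shipped split (F1:10, F2:11, F3:8, F4:5) is a synthetic
  placeholder because the validated Spanish assignment is not public.
* **Group statistics**: sample (n−1) standard deviations throughout — the
  convention under which published subgroup statistics pool exactly.  Pooled
  mean/sd come from subgroup triples via the sum-of-squares identity
  SS_total = Σ(n_g−1)s_g² + Σn_g(m_g − m̄)², which equals direct
  recomputation from raw scores to rounding error (tested at 1e-9 relative).
* **Mann–Whitney U**: midranks for ties; p-values are exact (full
  enumeration) for tie-free samples with n_a + n_b ≤ 12, else the normal
  approximation with tie and continuity corrections.  The implementation
  delegates the p-value to `scipy.stats.mannwhitneyu`; the test suite checks
  it against an independent enumeration oracle (|Δp| ≤ 0.05 for groups of
  3–6).

## Synthetic data: what it emulates and what it does not

`synthetic_data` replaces human subjects in tests:

* **Labeled tables** sample the attribute grid uniformly and label via a
  ground-truth tree, flipping each label independently with a configurable
  noise rate.  Noise 0 over the full grid makes induction an exact
  round-trip; noise 1 inverts every label.
* **Quiz sessions** simulate a user with per-area probability of answering
  correctly; the session feeds its own running difficulty profile back into
  question selection, as the real tool would.
* **SUS cohorts** are calibrated in *score space*: a group target mean is
  converted to an integer raw-point total on the 2.5 grid (infeasible
  targets raise a named feasibility error), spread over respondents by
  random sum-preserving unit transfers hill-climbed toward the target sd,
  then inverted item-wise using the alternating item polarity.  Group means
  are exact to 2 dp by construction; achieved sds land within ~0.25 score
  points of their targets (unit transfers change the sum of squares in
  discrete steps, so exact sd matching is generally impossible on an integer
  grid).  The default cohort is 16 respondents split 7/9 with group means
  73.93/82.5 — the unique integer split consistent with a pooled mean of
  78.75 — and target sds 4.97/4.68.
* **TMBQ cohorts** fill each (group, factor) block of cells with integers
  1–5 summing to round(target × cells), jittered by sum-preserving swaps;
  scored factor means land within 0.05 of targets for groups of ≥ 2
  respondents.  Default targets use the published per-group F1/F2 extremes
  (2.98/1.92 younger, 3.44/2.30 older); F3/F4 are not published and default
  to values interpolated inside each group's range (2.5/2.7 and 2.8/3.1).

What passing these tests shows: the scorers, pooling identity, induction and
adaptation logic are correct on data with the *stated marginal statistics*.
What it does not show: anything about real response processes — generated
Likert vectors have no item-level covariance structure, no acquiescence or
fatigue effects, and quiz users have no learning curve (accuracy is
stationary).  Per-factor TMBQ cohort values and the published group
comparison p-value are not reproducible at all without the raw item data,
which was never deposited.

## Numerical choices and degenerate inputs

* Entropy of an all-zero count map, empty example sets, empty groups and
  empty area lists are input errors, not silent zeros.
* Information gain is clamped at 0 against float round-off.
* Selection probabilities renormalise over areas that actually hold ≥ 2
  bank activities (an area needs a pair to pose a question).
* An area with zero attempts reports error rate 0 and is ignored by
  hardest-area selection; hardest-area ties break lexicographically.
* Rounding to two decimals happens only at the reporting layer; all
  computation is full precision.
* Timestamps are stored as ISO-8601 strings (UTC for generated data) and
  validated on record construction.

## Problem sizes in the test suite

Property checks run at sizes chosen to make the statistics sharp but the
suite quick: 200 random tables (≤ 5 attributes × ≤ 3 values × ≤ 40 rows)
for oracle equivalence, 10,000 seeded draws for selection frequencies
(±3 binomial SEs), 500-question sessions for competence recovery (binomial
95% intervals), 1,000 random vectors for the SUS complement identity, and
exhaustive enumeration over the full 80-point default grid for
antisymmetry.  The whole suite runs in well under a minute.

## Known limitations

* Binary labels only; no multi-class priorities, no C4.5-style thresholds,
  no pruning.
* The quiz has no spaced repetition or response-time model.
* The history store is a single-process file log; there is no
  authentication and "supervisor" is an API role, not a user account.
* The shipped TMBQ mapping and the F3/F4 cohort targets are placeholders —
  replace them with validated configuration before interpreting factor
  scores substantively.
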