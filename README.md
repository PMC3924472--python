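# taskbalance

A desk-scale toolkit for task-prioritisation tele-therapy, aimed at
researchers and developers building serious games for health around time
management — for example, training tools for adolescents with (or without)
ADHD who struggle to decide which of two everyday activities to do first.

The toolkit reimplements the adaptive core of such a system as an installable
Python library plus CLI, with no web stack or database: everything is plain
functions, JSON/CSV files and a JSON Lines history log.

## What's inside

* **Decision engine** (`decision_engine`) — an ID3 decision tree over
  discrete activity attributes (deadline urgency, who asked, life area).
  Splits are chosen by information gain using Shannon entropy,
  H(S) = −Σᵢ pᵢ log₂ pᵢ; each leaf carries a label
  (*priority* / *non-priority*) **and a unique positive integer weight**.
  Comparing two activities ("the virtual balance"): a priority label beats a
  non-priority one outright; within the same label class the greater leaf
  weight wins, so the engine always answers.
* **Adaptive quiz** (`quiz_engine`) — poses pairwise prioritisation
  questions and adapts to the user's weak spots: each life area is sampled
  with probability ∝ (errors + α)/(attempts + 2α), a Laplace-smoothed error
  rate (α = 1) that keeps every area reachable from a cold start.
* **Supervisor layer** (`history_store`) — an append-only JSON Lines history
  of queries and quiz answers with timestamps, per-area difficulty reports
  (error rate per area, hardest area), and supervisor-injected custom
  questions.
* **Questionnaire scorers** (`questionnaires`) — exact SUS scoring
  (odd items contribute *value − 1*, even items *5 − value*, the sum × 2.5;
  range 0–100 on a 2.5 grid) and TMBQ scoring (34 Likert items, four factor
  means on the 1–5 scale), plus group summaries pooled by the sum-of-squares
  identity and a Mann–Whitney U comparison.
* **Synthetic data** (`synthetic_data`) — labeled training tables from a
  ground-truth tree, simulated quiz sessions from per-area competence
  profiles, and Likert cohorts calibrated so their *scored* statistics
  reproduce target group means/SDs.

## Worked example

```python
import taskbalance as tb

schema = tb.default_schema()          # deadline_bucket x requested_by x area
tree = tb.default_tree(schema)        # ID3 tree induced from the shipped table

homework = tb.Activity("homework", "maths homework", {
    "deadline_bucket": tb.bucket_deadline("2013-07-15", "2013-07-15"),  # 'today'
    "requested_by": "mother", "area": "academic"})
series = tb.Activity("series", "watch a series", {
    "deadline_bucket": "none", "requested_by": "nobody", "area": "leisure"})

decision = tb.prioritise(tree, homework, series, schema)
print(decision.winner, decision.winner_weight, "vs", decision.loser_weight)
# homework 7 vs 1
print(decision.rationale)
# 'homework' is labelled priority, 'series' is not
```

The default tree has 8 leaves with weights 8..1; `homework` lands on the
*today → priority* leaf (weight 7) while `series` falls to the least urgent
non-priority leaf (weight 1), so `homework` wins on the label alone.

Scoring a usability cohort:

```python
from taskbalance import score_sus, cohort_summary
from taskbalance.synthetic_data import DEFAULT_SUS_COHORT, gen_sus_cohort

cohort = gen_sus_cohort(DEFAULT_SUS_COHORT)      # 7 + 9 calibrated responses
scores = [score_sus(items) for _, items in cohort]
groups, pooled = cohort_summary(scores, [g for g, _ in cohort])
print(round(pooled.mean, 2), round(pooled.sd, 2))
# 78.75 6.39
```

The same operations are available from the shell:

```bash
taskbalance compare homework.json series.json
taskbalance quiz --n 5 --answers answers.txt --history history.jsonl --user kid1
taskbalance report --user kid1 --history history.jsonl
taskbalance score-sus responses.csv
taskbalance simulate --kind sus-cohort --seed 7
```

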