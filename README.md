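# hedline

An event-in-context annotation engine for time-series recordings
(EEG/MEG and similar neuroimaging data organized in BIDS-style layouts).

Answering *"what happened, exactly?"* during a recording takes more than a
list of time-stamped event codes.  `hedline` implements the machinery that
turns flat event logs into searchable, temporally structured descriptions:

* **Hierarchical vocabularies** — terms form *is-a* trees (e.g.
  `Item/Object/Ingestible-object`); every term is globally unique, lookups
  are case-insensitive, and annotators may extend most branches with their
  own child terms (`Ingestible-object/Apple`) without breaking more general
  searches.  Library vocabularies can be merged under any node of a base
  schema.
* **A tag-string grammar** — comma-separated tags with arbitrarily nested
  parenthesized groups expressing association: `(Red, Triangle)` is a red
  triangle; `(Experiment-participant, (Move, (Left, Hand)))` encodes
  subject–predicate–object structure.
* **Event processes** — temporally extended happenings assembled from
  phase markers in `*_events.tsv` files.  `(Duration/0.5 s, (Label/X))`
  opens a process that ends 0.5 s later; `(Def/A, (Label/X), Onset)` opens
  a process anchored by the named definition `A`, closed by a matching
  `(Def/A, Offset)` or by the next `Onset` of the same anchor (contiguous
  chains); `Inset` markers record internal phase transitions.  A
  *Recording* process spans the whole file and carries participant and
  environment context (e.g. `participants.tsv` handedness designations
  `left, l, L, Left, LEFT` normalize to the `Left-handed` tag).
* **Abstraction-aware search** — a query for `2D-shape` finds annotations
  containing `Triangle` *and* user extensions such as `2D-shape/Star`;
  markers can be enriched with the annotations of every process active at
  their time (the ongoing context) before matching.  Query hits convert
  directly to 0/1 factor vectors / design matrices for epoching.
* **Transition graphs** — directed multigraphs of consecutive marker
  labels with edge counts, consolidated across files and scored against a
  task rule set (permitted successors per label); the violation percentage
  is reported to one decimal, rounded half away from zero.
* **Synthetic fixtures** — a seeded SART (sustained-attention go/no-go
  task: respond to every digit except the target) session generator with
  exact ground truth, canonical overlap-pattern timelines, and a 14-term
  fixture vocabulary, so everything here runs without downloading data.

## Worked example

```python
from hedline import api, query, summaries, synth

schema = synth.sart_schema()
cfg = synth.SartConfig(n_trials=200, seed=7)          # p_fa=0.10, p_miss=0.05
table, sidecar, gt = synth.generate_sart(cfg)
af = api.annotate_table(table, sidecar, schema)

print("ground truth:", gt.n_targets, "targets,", gt.n_non_targets,
      "non-targets,", gt.n_false_alarms, "false alarms,", gt.n_misses, "misses")

g = summaries.transition_graph(table)
rules = summaries.TaskRuleSet.from_dict({"allowed": synth.SART_ALLOWED})
rep = summaries.classify(g, rules)
print("transitions:", rep.n_transitions, "violations:", rep.n_violations,
      f"({rep.pct_violations}%)")

print("Sensory-event hits:", len(query.search([af], "Sensory-event", schema)))
```

prints

```
ground truth: 25 targets, 175 non-targets, 1 false alarms, 5 misses
transitions: 370 violations: 6 (1.6%)
Sensory-event hits: 200
```

The 200 trials produce 25 target and 175 non-target presentations; the one
false alarm (a key press after the target digit) and five misses (no press
after a non-target) each contravene the task rules, except that a miss on
the final trial would leave no following transition — here all six errors
are visible as rule-violating edges, 6/370 = 1.6 %.  Every stimulus row
carries a `Sensory-event` tag through its sidecar definition, so the
abstraction search hits exactly the 200 stimulus markers.

The same operations are available from a shell:

```bash
hedline synth sart --n-trials 200 --seed 7 --out session/
hedline transitions session/events.tsv --rules rules.json --consolidate
hedline search --sidecar session/events.json --query "Sensory-event" session/events.tsv
hedline validate --sidecar session/events.json session/events.tsv
```

Exit codes: 0 success, 1 validation findings, 2 usage/I-O error.

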