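# Methods

This note documents the model implemented by `hedline`, the semantics it
commits to where the conventions admit more than one reading, and what the
synthetic fixtures do and do not establish about real data.

## Vocabulary model

A schema is a forest of uniquely named terms; each child is a
specialization (*is-a*) of its parent, so a term is identified both by its
full root-to-leaf path (long form) and, because terms are globally unique,
by its final component (short form).  Schema documents are a plain JSON
dialect defined by this repository (one entry per node: term, parent long
form, `extension_allowed`, `takes_value`, `unit_class`); an importer for
other schema serializations would be a thin additional loader and is not
required by anything here.

Decisions taken where the conventions leave room:

* **Case.** Comparison is case-insensitive everywhere; canonical case is
  preserved for display.
* **Extensions.** Any non-value node accepts user extension components
  except the six structural tags (`Onset`, `Offset`, `Inset`, `Def`,
  `Definition`, `Duration`), which never do.  Extension components are
  free terms: they are not checked for uniqueness against the schema,
  since annotators may coin them per dataset.
* **Values.** A value-taking node is a leaf; its value is the remainder of
  the tag path.  For the `time` unit class the value must be numeric with
  an optional unit (`s`, `ms`, `min`, normalized to seconds); a unitless
  duration is taken as seconds with a warning.  `Label`, `Description`,
  `Def` and `Definition` take free text.
* **is-a test.** `is_descendant(candidate, ancestor)` is a
  component-boundary prefix test, reflexive, with extensions on the
  candidate participating as ordinary components.  This is what makes a
  search for `2D-shape` find both `Triangle` (schema child) and
  `2D-shape/Star` (user extension).

## String grammar

Commas separate siblings; parentheses open groups; whitespace around
separators is ignored.  Groups are semantically *sets* (equality and search
are order-insensitive) but sibling order is preserved for serialization, so
`parse ∘ serialize` is the identity on structure.  Commas inside
`Description`/`Label` free text are not supported — a value runs to the
next separator at its nesting level.  This keeps the grammar regular; text
needing commas belongs in dataset documentation, not in a tag value.

## Definitions

A top-level group beginning with `Definition/Name` declares a template;
`Definition/Name/#` declares a one-placeholder family whose `#` is
substituted by the value of each `Def/Name/value` reference.  Names are
case-insensitive; re-declaring a name with identical content is tolerated,
with different content is an error.  Definition contents may not contain
structural tags, so expansion is a fixpoint after one pass.  Expansion
keeps the `Def` tag alongside the expanded content —
`(Def/A, (Label/Q))` — so a reference both anchors timeline assembly and
exposes its content to search.  A `Def` whose definition is missing is a
hard error during validation but is kept opaque (with a warning) during
search, so partially annotated datasets remain searchable.

Extra tags grouped with a `Def` at onset (e.g. `(Def/A, (Label/X),
Onset)`) persist for the lifetime of the process they open: they are
per-instance modifiers of that process, not of the onset instant alone.

## Tabular I/O

Event tables are tab-separated with `onset`/`duration` in seconds and
`n/a` for missing; rows are stably sorted by onset with original file row
indices retained for diagnostics.  Sidecars map categorical column values
to annotation strings or provide a single-`#` value template; an explicit
`HED` column contributes its cell verbatim.  Row annotations concatenate
column contributions in **header order** — a fixed, platform-independent
rule chosen so assembly is reproducible run to run.  Onsets are seconds
from recording start; no cross-file clock alignment is attempted.  When
recording-level metadata arrives from several files, later sources win and
a warning is emitted (documented order: participants table, then any
extra key→tag map).

## Timeline semantics

* A `Duration` group spawns an anonymous process `[t, t + d]`; such
  processes may overlap arbitrarily and never interact.
* `(Def/X, ..., Onset)` opens a process keyed by definition name plus
  placeholder value — `Def/A/1` and `Def/A/2` are independent concurrent
  processes.  A second `Onset` of the same key closes the first process at
  its own time and opens a new contiguous one; `(Def/X, Offset)` closes;
  `(Def/X, Inset)` records an internal phase transition.  An `Offset` or
  `Inset` without an open process of its key, and an `Onset` group without
  a `Def` anchor, are errors.  `Inset` on an anonymous Duration process has
  no anchor to match and is rejected.
* **Tie rule.** Markers are compared with an absolute tolerance of 1e-9 s;
  at equal times Offsets are applied before Onsets so contiguous chains
  touch without overlap.
* **Half-open context.** `context_at(t)` returns processes with
  `onset ≤ t < offset`, plus the Recording process always; at a contiguity
  boundary only the newly opened process is active.
* Processes still open at the recording end are closed there with a
  warning; the recording end defaults to the latest marker/offset time.
* Preceding-event context is deliberately *not* folded into enrichment:
  `preceding(timeline, marker, k, filter)` exposes it explicitly, because
  ongoing and preceding context answer different questions and silently
  merging them would make enriched hit counts hard to interpret.

The same span can legitimately be annotated as a chain of contiguous
processes or as one process with insets; the engine assembles whichever the
data says and does not convert between the two representations.

## Search

Query surface syntax (defined by this repository): bare terms,
`AND`/`OR`/`NOT` keywords (case-insensitive), parentheses containing a
comma list for group queries, plain parentheses for precedence.  `NOT` is
only legal inside an `AND` conjunction, which rules out match-everything
queries.  A group query requires its sub-queries to be satisfied among one
group's *direct* children (the stricter reading of grouping-as-association;
matching anywhere in a subtree would conflate `(Red, Triangle)` with
`Red, (Blue, Triangle)`).  The whole annotation counts as one implicit
group.  `Description` free text is excluded from matching unless the query
targets `Description` itself.  Enrichment appends the annotation of every
process active at the marker's time, so it can only grow a marker's hit
set.

## Transition graphs and compliance

Nodes are the values of a designated label column (default `event_type`) —
markers, not tags, because succession statistics are about the recorded
event stream.  Consecutive rows in time order (file row order at equal
onsets) contribute one edge each, so a file of *n* rows contributes *n−1*
transitions, and consolidation sums counts edge-wise.  A rule set lists
permitted successors per label; labels without an entry permit everything.
The violation percentage is `100 · violations / transitions`, rounded to
one decimal half away from zero.

## Synthetic SART sessions

The generator emulates a sustained-attention response task: digits 0–9
drawn i.i.d. uniform, target digit 3, stimulus on screen 0.25 s, 1.15 s to
the next onset, response latencies uniform on [0.2, 1.0] s (inside the
trial, so responses interleave correctly).  Error probabilities default to
0.10 for false alarms (responding after the target) and 0.05 for misses
(not responding after a non-target).  A single seeded generator object
drives everything; equal seeds give byte-identical files.  Responses are
separate event rows, as response markers are in real event logs.

What the fixtures do **not** emulate: realistic reaction-time
distributions (uniform, not ex-Gaussian), sequence structure in the digit
stream, fatigue/vigilance drift in the error rates, or any physiological
signal.  Passing tests therefore establish the correctness of parsing,
assembly, search, and counting on well-formed event streams — not
robustness to the messiness of hand-curated real event files.

Default problem sizes in the test suite (2,000 trials for the stochastic
error-rate recovery, 20 random timelines × 1,000 probe times for the
context oracle, 50 sessions for the conservation check) were chosen to make
binomial sampling error small relative to the 3-standard-error acceptance
bands while keeping the whole suite comfortably fast on a laptop.

## Known limitations

* No curly-brace column references or multi-schema tag prefixes in
  annotation strings.
* No cross-file (session-spanning) processes and no clock-drift handling.
* Transition analysis is first-order only; higher-order sequence effects
  need dedicated models.
* The bundled vocabularies are deliberately small fixtures, not a complete
  annotation vocabulary.
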