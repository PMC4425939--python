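# Methods

## The confidence model

`ciotools` models confidence statements about annotations as points in a
small axis space and maintains a bijection between that space and the leaf
terms of the Confidence Information Ontology (CIO).

A statement is either about a **single evidence** line — one of three
ordered levels (*low* < *medium* < *high*), or the *rejected* tag for
retracted/invalidated evidence — or about **multiple evidence lines**,
in which case it fixes:

* a *typality*: **same type** or **multiple types**, with respect to the
  ECO hierarchy;
* a *concordance*: **congruent**, **weakly conflicting** or **strongly
  conflicting**;
* an *overall level*, except for strongly conflicting statements, which by
  design carry none (the evidence does not allow a consensual conclusion).

That yields 4 single-evidence and 2 × (3 + 3 + 1) = 14 multiple-evidence
leaf statements. The built-in ontology (`cio_model.builtin_cio`) adds the
internal grouping terms (root, the two branches, the typality nodes, and a
congruent/conflicting and weak/strong split per typality), 29 terms in
total. Canonical keys are the term labels; numeric ids are attached only
to the two statements whose published ids this package relies on
(CIO:0000003, CIO:0000012) — inventing ids for the others would risk
colliding with the released ontology. Terms without a published id use
their label as their id inside the generic ontology container. When a
released CIO OBO file is supplied, labels are matched case-insensitively
and its ids are honoured on input.

## Evidence typing

Two evidence lines are of the *same type* when their ECO terms are
identical or stand in an ancestor/descendant (subsumption) relation; a
group is of the same type only if every pair is. Subsumption is the
default because it reproduces the canonical calls (two
traceable-author-statement lines: same; sequence alignment vs mutant
phenotype: multiple; two phylogenetic-distribution lines: same; adding a
developmental-similarity line: multiple) while still distinguishing
sibling terms — two different children of "author statement" are *not* the
same type. An `exact` mode (identity only) is provided for conservative
resources; it is strictly stronger, and the granularity question is
genuinely open, which is why it is a policy switch rather than a fixed
rule.

## Aggregation rules and their defaults

Aggregation of one assertion's lines proceeds as:

1. drop `rejected` lines (they must never influence a summary, only
   document retraction);
2. one survivor → pass its single-evidence statement through unchanged:
   the arity axis must reflect the actual evidence count;
3. otherwise: typality over **all** surviving lines (the summary term
   names the whole evidence set, not just a winning side); concordance by
   the conflict predicate — default: both polarities present; strength by
   comparing side maxima — equal best levels ⇒ **strong**, otherwise
   **weak** with the better side winning; overall level =
   `max(level) (+1 if multiple types) (+1 if ≥ promote_count lines) capped at high`,
   computed over all lines when congruent and over the winning side when
   weakly conflicting.

Defaults in `AggregationPolicy`:

| knob | default | rationale |
|---|---|---|
| `promote_count` | 3 | ≥ 2 required; 3 means a pair of equal lines is not yet "repeated confirmation", but many congruent low-confidence lines can climb (4 low same-type → medium; 4 low multi-type → high) |
| `multitype_promotion` | true | independent methods corroborating is the core reason the multiple-types branch exists |
| `weak_conflict_demotion` | false | the ontology provides "weakly conflicting … overall confidence high" as a reachable statement, so winning a weak conflict does not demote by default; demotion is opt-in |
| `legacy_default_level` | medium | the conventional choice when imposing a uniform statement on legacy lines |
| `conflict_predicate` | mixed polarity | what constitutes a conflict is resource-specific (e.g. incompatible terms); the predicate is a pluggable hook |

These are the minimal rules consistent with the canonical outcomes
(medium+medium same-type stays medium; two medium phylogenetic lines plus
a medium developmental-similarity line reach high; high+high of different
types is the ceiling; medium vs NOT-medium is strongly conflicting). The
exact promotion threshold and the weak-conflict level rule are not fixed
by any published guideline — they are documented policy, not claims of
consensus.

Edge cases: an empty group or unlevelled (non-imputed) line is a contract
violation; a group whose lines are all rejected raises
`NoAssessableEvidenceError` at the engine level, and the file pipeline
emits *no* summary row for such an assertion — the retracted lines remain
visible, and no confidence claim is manufactured from them.

## File dialects

**GAF 2.0 dialect.** Standard 17-column GAF with `!` comments, NOT in
column 4, pipe-separated references; GO evidence codes map to ECO ids via
a built-in, extensible table (ISA→ECO:0000200, IMP→ECO:0000015,
TAS→ECO:0000033, IEA→ECO:0000501 — only codes with an established mapping
are built in). GAF has no confidence column, so the dialect appends the
CIO term as column 18 and a SUMMARY marker as column 19; strict GAF
consumers ignore the extension. Summary lines pipe-join evidence codes and
references.

**Bgee similarity TSV.** Seven columns: entity name, qualifier, taxon
name, line type (RAW/SUMMARY), evidence term name, confidence term name,
reference id. On write, SUMMARY rows leave evidence and reference empty —
in this dialect the support of a summary is carried by its RAW rows — so
the in-memory pipe-joined values are dropped at serialization; the
roundtrip identity therefore holds for records as the dialect can
represent them. `—` placeholders read as empty.

Both readers are strict: any malformed non-comment line raises an error
with its line number; nothing is silently skipped.

The pipeline groups RAW records into assertions by (subject, object) —
references are *not* part of the key, since one assertion aggregates
across references — and regenerates, rather than trusts, any pre-existing
SUMMARY rows, so a re-evaluation (e.g. newly rejected evidence)
propagates. This makes `summarize_file` idempotent.

## Synthetic data and the oracle

`fixtures.generate_annotations(seed, …)` emulates a grouped
single-evidence annotation file: per assertion a line count (default
uniform 1–4), per line a polarity (negative with p = 0.2), an evidence
term drawn from the six real-id terms of the toy ECO, a level drawn with
weights (0.25, 0.5, 0.25), and a rejected flag (p = 0.1). The defaults
describe a mostly-positive, medium-heavy curation set with occasional
retractions — typical of the annotation files this workflow targets. The
generator is deterministic per seed and labels every assertion with the
summary the decision-table oracle derives, so end-to-end tests can check
the pipeline against ground truth. What it does **not** emulate: real ECO
breadth (13 terms stand in for thousands), correlated evidence within an
assertion, reference structure, or any relation between the latent truth
label and the evidence — so passing tests demonstrate correctness of the
rules, not calibration of confidence against biological truth.

The **toy ECO** uses real ECO ids only where they are established
(ECO:0000015, ECO:0000058, ECO:0000200, ECO:0000208, ECO:0000033,
ECO:0000501); invented grouping nodes carry a `TOYECO:` prefix so they
cannot be mistaken for real terms. The ERG9 fixture's reference id is a
placeholder token, as no PMID is attached to it here.

`fixtures.decision_table_oracle` restates the aggregation rules as flat,
direct case analysis (explicit side lists, index arithmetic over an
ordered level list) sharing no logic with the engine; tests and the
acceptance script verify engine/oracle agreement on the *exhaustive*
enumeration of all evidence-line multisets of size ≤ 4 over a
20-symbol alphabet (3 levels × 2 polarities × 3 evidence terms including a
parent/child pair, plus 2 rejected variants) — 10 625 groups, repeated
under four policy settings in the test suite.

## Numerical and procedural choices

* Ontology queries run on a `networkx` DiGraph; acyclicity is checked at
  construction and a cycle is a hard parse error. Obsolete terms are
  retained but excluded from ancestor/subsumption results and from root
  and leaf sets.
* The OBO writer emits stanzas in sorted-id order for byte-deterministic
  output; parse∘write is the identity on (id, name, parents, obsolete,
  synonyms).
* Label matching is case-insensitive everywhere (annotation files
  capitalize freely); canonical output labels are lowercase.
* Ties and ordering: group members keep input order; summary evidence and
  reference lists are de-duplicated preserving first appearance;
  permutation invariance of the aggregate is a tested property.
* Problem sizes: the exhaustive oracle enumeration stops at groups of four
  lines (10 625 multisets, seconds of runtime) — beyond four, the rules
  introduce no new case structure, since every decision depends on side
  maxima, side counts and pairwise typality only; the synthetic end-to-end
  run uses 50 assertions.

## Known limitations

* Assigning the *single-evidence* level from raw experimental metrics
  (E-values, replicate counts, …) is out of scope by design: those
  parameters are field-specific and belong to each annotation team.
* No OWL semantics, no provenance capture, no reasoning beyond is_a
  transitive closure; cross-ontology imports are not followed.
* The conflict predicate sees only polarity; incompatible-term conflicts
  (e.g. mutually exclusive localizations) require a custom predicate.
* GAF handling covers the 2.0 layout with the NOT qualifier; GPAD/GAF 2.2
  qualifier vocabularies and annotation extensions (column 16) are not
  interpreted. Unmapped extra Bgee columns are not preserved on rewrite.
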