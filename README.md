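# ciotools

Tools for asserting, validating and aggregating **confidence in biocuration
annotations**, built around the Confidence Information Ontology (CIO).

Curated annotations — a gene product linked to a GO term, an anatomical
structure asserted homologous across a taxon — are supported by *evidence
lines*, each typed by a term of the Evidence and Conclusion Ontology (ECO)
and sourced from a reference. Evidence type alone is a poor proxy for how
much an assertion should be trusted: the same evidence term can cover
experiments of very different quality, and assertions backed by several
independent lines deserve more trust than those backed by one. `ciotools`
is for curation teams who want to attach a standard confidence statement to
each evidence line and generate, automatically, a defensible summary
statement per assertion.

## The model

Each single-evidence annotation carries one of three ordered confidence
levels — *low* < *medium* < *high* — or the special tag *rejected* for
retracted or invalidated evidence (kept for traceability, never
aggregated). For an assertion with several evidence lines, a summary
statement is derived along three axes:

* **typality** — *same type* vs *multiple types*, decided from the ECO
  hierarchy: two lines are of the same type iff their ECO terms are
  identical or one subsumes the other (an exact-identity mode is
  available);
* **concordance** — *congruent* if all lines agree, *conflicting* if both a
  positive and a NOT (negative) annotation are present. Conflicts are
  **strong** when the best level on each side is equal (no consensual
  conclusion; the summary carries no level and no polarity) and **weak**
  otherwise (the better-supported side wins);
* **overall level** — the best level among the contributing lines, promoted
  one step when the types are multiple (independent corroboration) and one
  step when enough lines agree (default threshold 3, so repeated
  confirmation by many low-confidence lines can still reach high), capped
  at *high*.

Every reachable axis combination corresponds to exactly one of the 18 leaf
CIO statements (4 single-evidence, 14 multiple-evidence), e.g.
CIO:0000003 *high confidence from single evidence* or CIO:0000012
*confidence statement from congruent evidence lines of multiple types,
overall confidence high*. The promotion thresholds, the conflict predicate
and a weak-conflict demotion flag are policy knobs
(`AggregationPolicy`), because what counts as a conflict and how individual
confidences combine is deliberately left to each resource.

## Worked example

The package embeds the classic homology-annotation example: two
traceable-author-statement lines of medium confidence, one asserting and
one negating (NOT) that the autopod homology originates in Vertebrata.

```python
from ciotools.fixtures import toy_eco, worked_example_bgee
from ciotools.pipeline import summarize_file
from ciotools.annotation_io import write_bgee_tsv

out = summarize_file(worked_example_bgee(), toy_eco())
print(write_bgee_tsv(out))
```

prints

```
Entity name	Qualifier	Taxon name	Line type	Evidence term name	Confidence term name	Reference ID
Autopod		Vertebrata	RAW	Traceable author statement	Medium confidence from single evidence	PMID:23598338
Autopod	NOT	Vertebrata	RAW	Traceable author statement	Medium confidence from single evidence	PMID:23598338
Autopod		Vertebrata	SUMMARY		confidence statement from strongly conflicting evidence lines of same type	
```

The auto-generated SUMMARY row says: two evidence lines of the same type
(both author statements), equally confident, in direct contradiction — a
strong conflict, so no overall level and no qualifier. Conversely the two
high-confidence ERG9/GO:0051996 annotations (sequence alignment evidence
ECO:0000200 and mutant phenotype evidence ECO:0000015 — different types,
congruent) summarize to CIO:0000012, the highest confidence the ontology
can express:

```python
from ciotools.fixtures import worked_example_gaf
summary = summarize_file(worked_example_gaf(), toy_eco())[-1]
print(summary.confidence)
# confidence statement from congruent evidence lines of multiple types, overall confidence high
```

## Command line

```sh
cio summarize --format bgee annotations.tsv out.tsv     # append SUMMARY rows
cio summarize --format gaf --impute-level medium legacy.gaf out.gaf
cio validate  --format bgee out.tsv                     # guideline checks
cio synth --seed 7 -o synthetic.tsv                     # synthetic test file
```

`--impute-level` integrates legacy files lacking per-line confidence by
imposing a uniform single-evidence statement before summarizing. Exit
codes: 0 ok, 1 validation errors, 2 I/O or format failure.

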