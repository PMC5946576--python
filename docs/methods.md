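# Methods

## The query model

A search model has four layers.

**Structure tree.** A rooted tree of `(namespace, local name)` element
names describing the XML layout of the corpus documents. Sibling
`(namespace, name)` pairs are unique; the same local name may recur under
different namespaces (pathology exports routinely double a `value` tag this
way, so the bundled layout does too). Every concept is bound to exactly one
node; its *location path* is the root-to-node step sequence.

**Terms.** A *simple term* is a set of regex labels over words — typically
a German stem plus `(\w)*` to absorb inflection (`Adenokarzinom(\w)*`
matches "Adenokarzinome", not "Pseudoadenokarzinom"). Each label carries
two flags: `whole_word` (default true) anchors both ends at a word
boundary, with the word class `[\wäöüÄÖÜß]`; `case_sensitive` (default
true — German nouns are capitalized, and case-folding invites false hits on
abbreviations) can be disabled per label. A *composite term* is an ordered
list of ≥ 2 simple terms plus a required `max_distance`: the number of
whitespace-delimited tokens allowed between consecutive part matches.
`max_distance = 0` means the next part immediately follows. `ordered`
defaults to false (both part orders are matched), since word order inside a
noun phrase is not reliable in report prose; no default is supplied for
`max_distance` because a silent default would hide modelling errors.

**Concepts and queries.** A concept binds one term to one structure node
("X in Y") and holds existentially over the node's section elements. A
concept binds exactly *one* term; disjunction over terms is expressed with
OR at the query level, keeping the concept semantics unambiguous. A query
is a finite AND/OR/NOT tree over concepts and is the unit of compilation.

## Compilation to XPath

Each query compiles to one XPath selecting the document root of matching
documents:

```
/ns1:pehr[ <boolean expression> ]
```

A concept becomes the relative location path of its node with a predicate
that is a disjunction of one `matches(normalize-space(string(.)), '…')`
call per label (simple term) or per proximity alternative (composite
term). Composite alternatives enumerate the cross product of the parts'
label lists — and both part orders when unordered — joined by the gap
template `(?:\s[^\s]+){0,d}\s`. The gap counts whitespace-delimited tokens,
so punctuation-bearing tokens such as `2,5` or hyphenated compounds count
as one word. `Not` maps to `not(...)` over the existential path: a negated
concept also holds when the document lacks the section entirely, which is
the intended reading for exclusion phrases ("no evidence of …" must
exclude the document wherever or however often it occurs).

Output is deterministic: labels in authored order, tuples in lexicographic
label-index order with the forward part order before the reversed one, and
namespace prefixes `ns1, ns2, …` assigned to distinct namespaces in
structure-tree preorder (the empty namespace gets no prefix).

### Regex dialect and evaluation

The emitted `matches()` call syntax is XPath 2.0, but evaluation uses lxml
(an XPath 1.0 engine) with a no-prefix `matches` extension function backed
by Python's `re`. Consequences:

* engine, oracle and diagnostics share a single regex dialect, so their
  agreement is exact rather than approximate;
* label patterns are restricted to the subset shared by Python `re` and
  XPath `fn:matches` — character classes, `* + ? {m,n}`, alternation,
  groups. Lookarounds, backreferences, named groups, global inline flags
  and anchor escapes are rejected at compile time;
* the word-boundary wrapper uses fixed-width lookarounds
  (`(?<![\wäöüÄÖÜß])`, `(?![\wäöüÄÖÜß])`) and case folding uses the scoped
  flag group `(?i:…)`. Both are Python-`re` constructs; exporting the
  expressions to a pure XPath 2.0 processor (BaseX, eXist) would require
  rewriting the boundary wrapper, the paths themselves are portable
  verbatim.

Section text is `normalize-space(string(.))` — descendant text
concatenated, XML whitespace collapsed. All token counting (proximity,
alignment, quantity distance) happens on this normalized form with one
shared tokenizer: split on single spaces, punctuation left attached.

## The independent oracle

`oracle.oracle_match` re-decides every (document, query) pair without the
compiler: it walks the document along the structure tree, extracts
normalized section texts, matches raw label patterns at every start
position with neighbour-character boundary checks, verifies composite
proximity by measuring the inter-match substring (must be
whitespace-bounded with ≤ d tokens), and evaluates the boolean tree in
Python. It shares only the model types and the tokenizer with the rest of
the package, which makes compiler-vs-oracle equivalence on randomized
models and corpora the central correctness property (exercised over 200
pairs, ≈ 10⁴ document-query decisions, in the acceptance run).

## Reviewer diagnostics

**Enumeration alignment.** Sections are often numbered item lists; a
retrieval can be existentially correct yet clinically wrong when the two
matches sit in different items. An item starts at a standalone token
matching `\d{1,2}[.)]` (the numbered style; other enumeration styles exist
in the wild and the pattern is a parameter). Every match span gets the
ordinal of the last marker before it. A concept that matches in a
non-enumerated section, or before the first marker, is a wildcard. A
document is flagged when ≥ 2 non-wildcard concepts have item-ordinal sets
with empty intersection. Flagging never removes a document — whether
alignment is a hard filter is the reviewer's decision, so the report is
advisory.

**Quantities.** A quantity is a number token (decimal comma or point)
immediately followed by a unit token matching the requested unit pattern
(trailing punctuation ignored). An optional proximity filter keeps only
quantities within `max_distance` tokens of a match of a given term —
the remedy for unit tokens that refer to some other measurement.
Summaries report n, min, max, arithmetic mean and the *population*
standard deviation (σ, divide by n); the population form is declared
explicitly so tests are deterministic. Empty input yields n = 0 with the
statistics marked undefined.

## Synthetic corpus generator

The generator emulates the phenomena the queries must survive, not
clinical prose: per-document Bernoulli planting of term surface forms into
their sections (prevalences of the default plans are plausible per-section
rates, fixed once), enumerated Material/Macroscopy/interpretation sections
with probability 0.64 per document (the observed share of enumerated
records in the motivating audit), German decimal-comma quantities rendered
at one decimal place and placed within `attach_within` tokens of their
surface form, a fixed exclusion phrase ("ohne Nachweis einer
Barrett-Schleimhaut") at rate 0.15, and two opt-in false-positive
injections: *misalignment* (co-occurring matches forced into pairwise
distinct enumeration items; aligned documents share one item) and *stray
units* (a value-unit pair unrelated to any term). Default weight and size
distributions are normal(18.26, 10.18) g and normal(2.76, 1.42) cm,
truncated at zero by clipping; clipping shifts the mean of the weight
distribution by ≈ +0.15 g, which the moment-recovery tests account for via
the closed-form clipped-normal moments where the sample size makes the
shift visible.

Ground truth is exact by construction: filler vocabulary is screened
against the active model's labels, fragments are inserted as indivisible
token cells so plantings can never be split, and every planted fragment is
checked against all labels of concepts bound to its section (so the cave
phrase registers the contained mucosa term too, and a stray `g` registers
the gram-unit concept). Query truth is the boolean evaluation over the
per-document concept sets. Identical spec + seed reproduce byte-identical
corpora and manifests.

What the generator does **not** emulate — free-running prose, section
boundary noise, OCR errors, exotic enumeration styles, multi-line item
bodies with their own numbers — bounds what passing tests show: they
validate the query semantics, the compiler and the diagnostics, not
recall on real-world records.

## Problem sizes and numerical choices

The acceptance run uses 200 random model/corpus pairs of ≤ 10 concepts and
25 documents each, a 500-document corpus for the five-question replay, 300
documents at 30 % injection for the alignment check and 1100 planted
weights for moment recovery; these sizes give ≈ 10⁴ differential decisions
and standard errors small enough for 3-SE assertions while the whole run
stays in the seconds range. Statistical assertions use 3-standard-error
bands (and a central 99 % binomial interval for the enumeration rate).
Ties and degenerate inputs are pinned down explicitly: empty corpora yield
empty results, malformed XML files are reported per document and skipped,
a query over a missing section is false positively and true negatively,
and `summarize_quantities([])` is the defined n = 0 summary.

## Known limitations

* One concept cannot carry several alternative terms; model it with OR.
* Composite terms do not nest; parts are simple terms only.
* The enumeration detector covers the numbered style `1.` / `12)`;
  lettered or indented styles need a custom item pattern.
* The manifest's by-construction truth covers concepts bound to
  text-bearing sections; concepts bound to inner structure nodes
  (ancestors aggregating several sections) are matched correctly by the
  engine and oracle but are not planted deliberately by the generator.
* Exported XPaths need a `matches()`-capable processor; see the dialect
  notes above.
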