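# Methods

This note documents the models, conventions and numerical choices behind
hedgekit: what each stage computes, which knobs matter, what the synthetic
corpora do and do not emulate, and where the design was genuinely open.

## Corpora and the MEDLINE dialect

A `Corpus` is an ordered, duplicate-free collection of records with a PMID,
title, abstract, MeSH headings and publication year. Parsing accepts the
standard MEDLINE tagged export (4-character tag + `- `, indented continuation
lines joined with single spaces) via Biopython's Medline parser; blocks are
tracked locally only to report line numbers for malformed input. The
publication year is the first 4-digit token of the `DP` field; records
without a parseable year are dropped by any year filter, matching the
behaviour of a date-limited database search. The writer emits unwrapped
lines so that writing followed by parsing is the identity on every corpus;
records are otherwise kept verbatim (no Unicode normalisation beyond UTF-8
decoding with replacement) because tokenisation owns text normalisation.
Year limits are inclusive at both ends. Random corpus sampling is uniform
without replacement under `numpy.random.default_rng(seed)` and bit
reproducible.

## Term mining

The tokeniser lowercases, splits on any non-alphanumeric run, and drops
purely numeric tokens and tokens of length 1. There is deliberately no
stemming and no stopword list: inflectional variants ("nurse", "nurses",
"nursing") are distinct terms a filter may want individually, short
domain acronyms ("rns") survive, and ubiquitous words are removed not by a
list but by the differential filter itself — a word like "patients" that is
common in the relevant class is also common in the population at large and
fails the population ceiling. These defaults are declared package
conventions; prevalence counts depend on them, so they are applied
identically to both corpora of any comparison.

The term–document matrix is binary presence (scikit-learn's
`CountVectorizer(binary=True)` with the package tokeniser as analyzer):
every downstream statistic is a document frequency, so within-document
counts carry no information here. Selection has three parameters:

| parameter | default | meaning |
|---|---|---|
| `min_dev_prevalence` | 0.05 | candidate floor in the development set, inclusive |
| `max_pop_prevalence` | 0.02 | ceiling in the population set, inclusive; absent terms count 0 |
| `top_k` | 25 | number of ranked survivors kept |

Threshold comparisons are inclusive ("at least", "or fewer") and performed
on exact count fractions, not on the 2-decimal values used for reporting.
Ranking is by development-set document count descending; all rankings in the
package break ties alphabetically ascending, a determinism choice made once
(the ordering of tied terms carries no signal). MeSH descriptor ranking is
frequency-only at descriptor level (subheadings ignored, one count per
record); judging a descriptor's topical relevance is inherently a curator's
call and is represented as a manual include-list, not automated.

## The query dialect

Strategies are numbered lines, `#n` referring to earlier lines only, the
highest line being the result. Expressions support `OR`, `AND` and binary
`NOT` (set difference), case-insensitive, with precedence NOT > AND > OR,
left association and parentheses. `[tiab]` terms are single words or
phrases; matching is exact-token and case-insensitive against the title or
abstract token streams, with phrase adjacency checked on the stream (never
across the title/abstract boundary). PubMed's automatic term mapping,
variant expansion and truncation are deliberately not emulated — they are
unspecifiable moving targets, and the bundled strategies already spell out
their variants. `[mh]` terms match a record heading's descriptor
case-insensitively; `Descriptor/qualifier` additionally requires that
heading to carry the qualifier. Explosion (matching descendant descriptors)
requires a two-column tree file and is off by default so the engine runs
tree-free; a per-run flag makes explosion the default to mimic PubMed, and
`[mh:noexp]` opts a term out. A term with no field tag defaults to
`[tiab]`, the least surprising reading for externally supplied strategy
files. Compilation substitutes all `#n` references to yield a single
expression that provably (and, in the tests, empirically) retrieves the
same set as line-wise execution.

The expression parser is a small hand-written tokenizer plus
recursive-descent parser; the dialect is too small to warrant a grammar
toolkit and error messages need the strategy line number.

## Evaluation and reporting

Sensitivity, precision and NNR are computed from the retrieved set and the
gold-standard set, with the relevant-retrieved intersection always
recomputed rather than caller-supplied. Reporting convention: percentages
to 1 decimal, prevalences to 2 decimals, NNR to the nearest integer, all
half-away-from-zero. Zero-denominator metrics raise errors instead of
returning 0/∞ sentinels, so malformed comparisons fail loudly; in a
multi-strategy report a strategy that retrieved nothing shows undefined
precision/NNR explicitly. One documented caveat: when the gold standard is
also the development set and the remaining retrieval is unscreened,
precision and NNR are biased downward (every unscreened retrieved record is
presumed irrelevant); the package computes the conservative value and leaves
the interpretation to the analyst.

## Population-size estimation

With all strategies OR-ed into a joint pool of size N assumed to capture
every relevant record, and k relevant found in a screened uniform sample of
size n, the estimated relevant total is N·k/n. The interval is a binomial
CI for k/n scaled by N and truncated below at zero. Wald
(p̂ ± z·√(p̂(1−p̂)/n)) is the default; Wilson and Clopper–Pearson are
selectable. At small k the three differ materially (k=6, n=2,195, N=35,708:
Wald [19.6, 175.6], Wilson [44.8, 212.5]) and Wald is anti-conservative —
it is the default because it is the field's conventional report, not
because it has the best coverage; for small-k inference prefer Wilson. The
point estimate is method-independent and exactly scale-equivariant in N.

## Synthetic corpora

`CorpusSpec` describes a labelled corpus: a relevant class and a background
class, per-term class-conditional prevalences, a MeSH profile (per
descriptor: class rates, optional subheading with attachment probability),
abstract length range (default 60–120 tokens), a title placement probability
(each present profiled term appears in the title with probability 0.3,
otherwise in the abstract), publication years uniform over the range, and a
seed. Filler vocabulary is pronounceable consonant-vowel nonsense generated
disjoint from the profiled terms — prevalence accounting for profiled terms
is therefore exact by construction, and an explicitly supplied filler
vocabulary that overlaps the profile is rejected.

`nurse_staffing_default_spec()` is the bundled reference condition: 78
relevant and 10,000 background records; the 25 differential terms at their
exact reference count fractions (e.g. "staffing" 49/78 vs 10/10,000); two
deliberately non-differential common terms, "patients" (0.65 vs 0.77) and
"outcomes" (0.60 vs 0.10), the first because it is the canonical example of
a frequent-but-unspecific term, the second because the bundled precise and
balanced strategies use it as an AND-operand; and the MeSH descriptors the
bundled strategies reference, at rates chosen once as plausible for the
domain. "Health Services Administration" is given a 0.95 relevant-class
rate: it is an umbrella descriptor that real records match via tree
explosion of its descendants, which flat synthetic headings cannot
reproduce, so the rate stands in for the exploded match.

What the generator does *not* emulate, and what that means for the tests:
terms are class-conditionally independent Bernoulli draws with no topical
correlation, abstracts are token bags rather than language, and each
profiled term occurs at most once per record. Consequently joint
(AND-ed) background probabilities are far smaller than in real corpora —
synthetic precision is near 100% and NNR near 1, and nothing about database
precision should be read off these corpora. What the tests *do* establish
on them: exact set-algebra correctness of the engine against a naive
truth-evaluation oracle, recovery of the planted differential vocabulary by
the selection pipeline (at least 20 of the 25 profiled terms in the
selected top 25, across 20 seeds), agreement of empirical prevalences with
their generating values at binomial precision, analytic recall of OR-filters
under independence, and unbiasedness of the population estimator.

## Numerical and degenerate-input choices

- Rounding is half-away-from-zero everywhere a reference table convention
  applies (implemented as `floor(x·10^d + 0.5)`; none of the reference
  fractions fall on exact representational ties).
- Empty corpus: matrix construction and evaluation raise; query execution
  returns the empty set.
- A record with empty abstract round-trips as an absent `AB` line; empty
  titles likewise.
- Problem sizes in the test and acceptance runs — 100-record corpora × 1,000
  random strategies for the engine oracle, 20 (tests) / 5 (script) seeds of
  the full 10,078-record reference corpus for recovery, 300 replicate
  samples for estimator bias — were chosen as the smallest sizes at which
  the binomial/Monte-Carlo error bands in the assertions are meaningfully
  narrow.

## Known limitations

- No OVID or PubMed-XML dialects; no automatic term mapping, truncation,
  proximity, `[majr]`/`[tw]`/`[ti]` tags or publication-type filters.
- Multi-word free-text mining is out of scope (single-word terms only;
  phrases are supported in queries, not in mining), as is stemming.
- The explosion model is a plain descendant walk over a user-supplied tree;
  version-dependent subtleties of live MeSH explosion are not modelled.
- The estimator's validity rests on the joint pool actually containing all
  relevant records; a leaky pool biases the estimate downward.
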