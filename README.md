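# hedgekit

Empirical development and evaluation of bibliographic **search filters**
("hedges") on local MEDLINE-format corpora.

## The problem

A search filter is a reusable Boolean combination of free-text terms and
controlled-vocabulary (MeSH) headings designed to retrieve one class of
publications from a database such as PubMed/Medline. For topics with diffuse
terminology — the motivating case is *nurse staffing research*, the study of
how nurse-to-patient ratios relate to nursing and patient outcomes — filters
built by ad-hoc term selection miss much of the literature. hedgekit
implements the empirical alternative end to end:

1. **Term mining.** From a *development set* of known-relevant records and a
   random *population set*, build a binary term–document matrix and compute
   each term's document prevalence in both corpora. Candidate terms must
   reach a prevalence floor in the development set (default ≥ 5%) and stay
   under a ceiling in the population (default ≤ 2%); survivors are ranked by
   development-set document frequency and the top *k* (default 25) become
   the filter vocabulary. MeSH descriptors are ranked by record frequency
   for manual curation.
2. **Query engine.** Parse and execute PubMed-dialect Boolean strategies —
   numbered lines with `#n` back-references, `[tiab]` word/phrase terms,
   `[mh]` descriptors with subheadings and optional tree explosion — as pure
   set algebra over a local corpus, with an equivalent compiled single-line
   form.
3. **Evaluation.** Score a strategy against a gold-standard set:

   - sensitivity (recall) = relevant retrieved / all relevant
   - precision = relevant retrieved / all retrieved
   - NNR (number needed to read) = all retrieved / relevant retrieved = 1/precision

4. **Population estimate.** OR all candidate strategies together, screen a
   random sample of size *n* from the joint pool of size *N*, and estimate
   the total number of relevant records as *N·k/n* with a binomial
   confidence interval (Wald by default; Wilson and Clopper–Pearson
   selectable) scaled by *N*.

A seeded synthetic-corpus generator (`hedgekit.synthetic`) produces labelled
MEDLINE-like corpora with exact class-conditional term and heading
prevalences, so the whole pipeline is testable without any database access.
Three ready-made nurse-staffing strategies (`sensitive`, `precise`,
`balanced`) and the 25-term differential prevalence profile they were built
from are bundled in `hedgekit.strategies` / `hedgekit.synthetic`.

## Worked example

Generate the default labelled corpus (78 relevant + 10,000 background
records carrying the bundled prevalence profile), then evaluate the three
bundled strategies against it:

```python
import hedgekit as hk

labelled = hk.generate(hk.nurse_staffing_default_spec(seed=7))
table = hk.compare_strategies(
    [(n, hk.builtin_strategy(n)) for n in ("sensitive", "precise", "balanced")],
    labelled.corpus,
    labelled.relevant_ids,
)
print(hk.format_comparison(table))
```

```
Strategy                       Retrieved [relevant]  Sens(%)  Prec(%)   NNR
---------------------------------------------------------------------------
sensitive                                   73 [73]     93.6    100.0     1
precise                                     32 [32]     41.0    100.0     1
balanced                                    58 [57]     73.1     98.3     1
```

The sensitivity ordering (sensitive > balanced > precise) mirrors what the
strategies are designed for. Precision is near 100% here because synthetic
background records combine the strategies' AND-ed features essentially never
— see `docs/methods.md` for why synthetic precision is not a forecast of
database precision.

Estimating the number of relevant records in a database from a screened
sample — 6 relevant found in 2,195 records sampled from a joint retrieval of
35,708:

```sh
$ hedgekit estimate 35708 2195 6
estimated_relevant	97.6
ci_low	19.6
ci_high	175.6
ci_level	0.95
ci_method	wald
```

i.e. an expected 97.6 relevant records, with a wide interval reflecting only
6 relevant records in the sample.

The same workflow is available from the shell: `hedgekit simulate` writes a
synthetic corpus as MEDLINE text plus a relevant-PMID list, `hedgekit terms`
mines and reports differential terms from two corpora, and `hedgekit eval`
scores strategy files (or the builtin names) against a labelled corpus.

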