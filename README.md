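# natfreq

Bayesian diagnostic inference with **natural frequency trees**, plus
induction and evaluation of **fast-and-frugal classification trees** from
case-level data.

## The problem

A diagnostic test with known prevalence, sensitivity and false-positive
rate poses a Bayesian question: given a positive result, how likely is the
condition?  The textbook answer combines priors and likelihoods,

```
p(H|D) = p(H) p(D|H) / [ p(H) p(D|H) + p(¬H) p(D|¬H) ]
```

but the same inference becomes a simple ratio of counts when the
information is expressed as *natural frequencies* — a reference population
of N individuals decomposed by hypothesis and then by test result:

```
p(H|D) = f(D & H) / f(D)
```

where `f(·)` are integer counts.  For the classic mammography numbers
(prevalence 1%, sensitivity 80%, false-positive rate 9.6%) the frequency
tree at N = 1000 reads: 10 women with cancer, of whom 8 test positive; 990
without, of whom 95 test positive; so p(cancer | positive) = 8/103 ≈ 7.8%.

`natfreq` treats the two formats as first-class, interconvertible
representations of the same task and extends both beyond the basic
two-hypothesis/one-test case: polychotomous cues (including explicit
"unknown" results), more than two hypotheses, and multiple tests —
conditionally independent or chained through context-dependent likelihood
tables.  When the number of cues makes full trees impractical, the package
induces **fast-and-frugal trees** — classifiers that ask one cue per level
and offer an immediate exit at every level — using the ZigZag recipes
(ranking cues by predictive values or by sensitivity/specificity), and
evaluates them by confusion counts, frugality (mean cues inspected) and
exit-structure ROC points.  Rounding out the toolbox: a naive-Bayes
comparator, Boolean cue merging with pair-comparison cue validity, and
synthetic data generation by natural sampling.

Intended users: researchers and educators in risk communication, medical
decision making and judgment/decision research who need exact worked
Bayesian solutions, frequency-format conversions of probability problems,
or reference implementations of fast-and-frugal tree induction.

## Worked example

`mammography.json` (the task above, in the task-spec JSON schema):

```json
{
  "hypotheses": [
    {"label": "cancer", "prior": 0.01},
    {"label": "no cancer", "prior": 0.99}
  ],
  "cues": [
    {
      "name": "mammogram",
      "categories": ["positive", "negative"],
      "likelihoods": [
        {"hypothesis": "cancer", "distribution": {"positive": 0.80, "negative": 0.20}},
        {"hypothesis": "no cancer", "distribution": {"positive": 0.096, "negative": 0.904}}
      ]
    }
  ]
}
```

```sh
$ natfreq solve mammography.json -e mammogram=positive --as-frequencies --population 1000
p(cancer | evidence) = 7.8%  (8/103 of 1000)
p(no cancer | evidence) = 92.2%  (95/103 of 1000)
```

The posterior probability of cancer given a positive mammogram is 7.8% —
computed once by the probability rule and once as the count ratio 8/103
from the N = 1000 frequency tree (the two agree exactly in rational
arithmetic).  The same library calls:

```python
import natfreq as nf

task = nf.load_task(open("mammography.json").read())
nf.posterior(task, {"mammogram": "positive"}).distribution["cancer"]   # 0.07764
tree = nf.to_frequency_tree(task, 1000)                                # counts 10/8/95...
nf.posterior_from_tree(tree, {"mammogram": "positive"}).as_fraction()  # (8, 103)
```

For classification, the bundled 89-patient chest-pain cohort and its
published fast-and-frugal tree (elevated ST segment → high risk; else no
chest pain → low risk; else any other symptom decides):

```python
cohort = nf.green_mehr_fixture()
ev = nf.evaluate_fft(nf.green_mehr_tree(), cohort)
ev.confusion    # ConfusionCounts(hits=15, misses=0, false_alarms=35, correct_rejections=39)
ev.frugality    # 1.93 cues inspected per patient, instead of 3
```

— 50 patients are classified high risk and 39 low risk, with no misses.

Other subcommands: `natfreq convert` (task → tree JSON or Graphviz DOT),
`natfreq fft build|classify|evaluate|roc`, `natfreq simulate
cases|fixture|environment`, `natfreq score`.  Run any of them with
`--help`.

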