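# lexnorm

Extrapolating lexical norms — valence, arousal, dominance, age of acquisition
(AoA) and concreteness — from word similarity, for researchers in
psycholinguistics and cognitive science who need norm estimates for words no
rating study has covered, or who want to compare how well different data
sources encode these properties.

## The method

Two kinds of count data can stand behind the similarity structure:

* **continued free associations** — each participant produces the first three
  associations to a cue word; pooling all responses gives a cue × response
  count matrix, restricted to responses that also served as cues so it
  becomes a square cue × cue matrix;
* **word–context co-occurrence counts** from a text corpus.

Counts *c<sub>ij</sub>* are weighted by positive pointwise mutual
information,

&nbsp;&nbsp;&nbsp;&nbsp;PPMI(*i*, *j*) = max(0, log [ *p<sub>ij</sub>* /
(*p<sub>i·</sub>* *p<sub>·j</sub>*) ]),

and similarity between words is the cosine of their weighted row vectors.
A word's norm is then predicted as the unweighted mean of the norms of its
*k* nearest rated neighbors (*k*-NN), with *k* swept over 1–50 and 60, 70,
80, 90, 100, and prediction quality measured by the Pearson correlation *r*
between cross-validated predictions and human means (leave-one-out, or a
disjoint train/test split).

The evaluation battery covers everything such comparisons need: Fisher-*z*
confidence intervals; split-half reliability of rater means (random half
splits, Spearman–Brown corrected, averaged over randomizations); correction
for attenuation *r*/√(rel<sub>a</sub>·rel<sub>b</sub>); the incremental *R*²
of one source's predictions on the other source's residuals; Fisher's *z*
for independent correlations; and three tests for dependent overlapping
correlations (Steiger's modified *z*, Meng–Rosenthal–Rubin,
Hittner–May–Silver), reporting the most conservative *p*.

A synthetic-lexicon generator closes the loop: words get latent semantic
vectors, norms are noisy linear projections of that space, association
responses are sampled by semantic proximity (softmax over cosines, 100
participants × 3 responses per cue), raters add Gaussian noise on the
Likert scale, and a co-occurrence channel with an independently tunable,
weaker signal stands in for the text corpus. Every pipeline stage is
therefore testable end to end with no external data.

## Worked example

```python
from lexnorm import GeneratorConfig, generate_lexicon, similarity_from_counts, sweep_k
from lexnorm.synthetic_data import sample_association_responses

cfg = GeneratorConfig(vocab_size=300, seed=42)
lex = generate_lexicon(cfg)
counts = sample_association_responses(lex)          # 90,000 responses
sims = similarity_from_counts(counts)               # PPMI + cosine
sweep = sweep_k(sims, lex.true_norms["valence"].to_dict())
print(sweep.best_r, sweep.best_k)
```

prints (see `examples/02_simulate_and_extrapolate.py`):

```
  k =   1: r = 0.635
  k =   5: r = 0.782
  k =  20: r = 0.817
  k = 100: r = 0.883
best: r = 0.883 at k = 100
```

Each `r` is the correlation between leave-one-out *k*-NN predictions and
the true valence values: a single nearest neighbor is already informative
(*r* = .64), and averaging over larger neighborhoods suppresses sampling
noise in the association counts until neighborhoods become too broad to be
semantically local.

The other scripts in `examples/` demonstrate the remaining capabilities:
worked attenuation/CI arithmetic on published summary values (`01`),
reliability estimation and disattenuation (`03`), the two-channel
comparison with dependent-correlation tests and residual analysis (`04`),
and a full configured study (`05`). A thin CLI wraps the same pipeline:

```bash
lexnorm simulate --seed 1 --vocab-size 200 --out-dir data/
lexnorm run --config study.yaml --out-dir results/
```

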