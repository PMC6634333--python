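# Methods

## Model and procedure

The pipeline estimates lexical norms by similarity-based extrapolation.
Given a nonnegative count matrix of words against contexts — a cue × cue
association matrix or a word × context co-occurrence matrix — each cell is
reweighted by positive pointwise mutual information (PPMI) and word
similarity is the cosine between weighted row vectors. An unrated word's
norm is the unweighted arithmetic mean of the norms of its *k* most similar
rated words. Quality is assessed by correlating cross-validated predictions
with human means across a grid of *k* values (1–50 and 60, 70, 80, 90, 100;
55 values), under three designs: leave-one-out over the full shared
vocabulary, leave-one-out within a fixed-size random subset (emulating
evaluation on a small legacy norm set), and a disjoint train/test split.

Assumptions worth making explicit:

* Norms are locally smooth over the similarity structure — similar words
  have similar valence, AoA, etc. *k*-NN averaging needs nothing stronger;
  it is the weakest model under which extrapolation should work.
* PPMI treats unobserved pairs as uninformative (weight 0), not as negative
  evidence; negative PMI values are clamped to zero.
* Neighbor averaging is unweighted. A similarity-weighted variant would add
  a modeling degree of freedom that the evaluation designs here do not need;
  predictions are convex combinations of training values either way.

## Numerical and procedural choices

* **Logarithm base.** PPMI uses the natural log. The choice is immaterial
  for every downstream quantity: changing base rescales all weights by a
  constant, which cancels in the cosine (covered by a property test).
* **No PMI smoothing.** No context-distribution exponent, no add-*k*. The
  weighting is plain PPMI.
* **Word order and ties.** Vocabularies are fixed in lexicographic order at
  construction. Neighbor ties are broken by descending similarity, then
  lexicographic token order; best-*k* ties on the correlation go to the
  smaller *k*. All tie-breaks are deterministic, so every result is
  bit-reproducible from (inputs, seed).
* **Zero-norm words.** A word whose PPMI vector is all zero carries no
  similarity information: it is retained and flagged but never eligible as
  a neighbor. If a target has fewer than *k* eligible neighbors the
  operation raises rather than silently shrinking *k*.
* **Square restriction.** The cue-by-response matrix keeps only response
  columns that also served as cues; the column set becomes exactly the cue
  set (cues never given as responses get zero columns). Rows left empty are
  dropped together with their columns, iterating to a fixed point so the
  operation is idempotent; all drops are logged with counts.
* **Confidence intervals.** Fisher *z* with standard error 1/√(n−3) and a
  1.96 multiplier. This reproduces the published two-decimal interval for
  the concreteness row (r = .87, n = 2,831 → .86–.88), which is why it was
  fixed as the method.
* **Split-half reliability.** Raters are split into two random halves
  (sizes differing by one for odd counts) without stratification; per-half
  item means are correlated across words, stepped up with Spearman–Brown,
  and the mean over randomizations (default 10,000) is reported. Words with
  an all-missing half are dropped for that randomization and logged.
* **Correction for attenuation.** r/√(rel_a·rel_b), with the reliability of
  model predictions set to 1 by convention. Corrected values above 1 are
  clipped with a warning.
* **Dependent-correlation tests.** Three published statistics for two
  overlapping dependent correlations: Steiger's modified *z* (pooling via
  the mean correlation), Hittner–May–Silver (pooling on the Fisher-*z*
  scale) and Meng–Rosenthal–Rubin. The reported *p* is the maximum across
  methods — a conservative choice; which exact method set other analysts
  pool over varies, so conservative maxima from different sets can differ
  slightly. The correlation between the two prediction vectors, needed by
  these tests, is computed from the vectors themselves.
* **Rounding.** Reported correlations are presented at two decimals, half
  away from zero; raw values are retained in all report objects.
* **Response positions.** First, second and third associations are pooled
  with equal weight (an optional integer weight vector exists for
  sensitivity analyses). Tokens are case-folded and trimmed; multi-word
  responses are kept as single tokens; no lemmatization or spelling
  correction.

## The synthetic lexicon

The generator emulates the statistical structure the analysis assumes, not
the surface statistics of any particular corpus.

* **Latent space.** V words (default 500) get i.i.d. standard-normal
  vectors in D = 10 dimensions. Each property is a unit direction
  (directions mutually orthonormal), and the true norm is the projection
  plus Gaussian noise (sd 0.3 in latent units), mapped affinely so ±3 sd
  spans the rating scale — Likert 1–7, AoA on 2–16 years to mimic its wider,
  deviating scale — then clipped. With projection noise 0.3 the best any
  similarity-based predictor can do against true norms is r ≈ 0.96, leaving
  visible headroom between channels.
* **Association channel.** Each of P = 100 participants per cue produces
  3 distinct responses, drawn without replacement with probability ∝
  exp(β·cos) over latent cosines, β = 6, self excluded (implemented by
  Gumbel-top-k, which is distributionally identical to sequential sampling
  without replacement). This respects the empirical floor of at least 100
  participants and 300 responses per cue.
* **Rater channel.** R = 20 raters add Gaussian noise (sd 1.0 rating units)
  to the true value, clipped to the scale. With the induced true-score
  variance this puts the reliability of the mean rating near .95, in the
  range of published norm sets.
* **Co-occurrence channel.** A multinomial over word pairs with weights ∝
  exp(β_text·cos), diagonal excluded, total counts equal to the
  association-token budget (3·P·V) by default. β_text = 1.5 < β makes the
  text channel carry a genuinely weaker semantic signal: at these settings
  its best leave-one-out correlation sits ~0.06–0.10 below the association
  channel's, mirroring the ordering (and roughly the magnitude) of the
  advantage the method is designed to expose.
* **Randomness.** One seed feeds named substreams (lexicon, associations,
  raters, cooccurrence), so each component can be regenerated independently
  and record-level and count-level samplers agree draw for draw.

What the generator does **not** emulate: Zipfian response marginals,
phonological/clang associations, rater drift or demographic structure, and
polysemy. Passing recovery tests therefore shows the pipeline is correct
and well-calibrated under the model's own assumptions — not that real
association data will reach any particular correlation.

## Problem sizes used in tests and the acceptance script

Test and acceptance runs use the generator at V = 500 (recovery,
reliability) and V = 300 (channel ordering), 10–20 seeds per property,
and 500–1,000 reliability randomizations — sizes chosen so the full
statistical battery exercises the same code paths as a full-scale study
while remaining comfortable on a single desktop CPU. The similarity module
stores counts sparsely and computes PPMI on nonzero cells only, so the
12,566-word scale of a real association lexicon remains tractable.

## Known limitations

* Leave-one-out excludes only the target word; its associates remain in
  the training set, as in standard practice.
* The dependent-correlation "conservative p" depends on the method set
  pooled over (see above).
* Disattenuated correlations treat prediction reliability as 1; to the
  extent predictions are themselves noisy, corrected values understate the
  true-score correlation.
* With strongly clipped scales (extreme noise sds) the parallel-measurements
  closed form for reliability no longer holds exactly; at the defaults
  clipping is rare and the agreement is within 0.01.
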