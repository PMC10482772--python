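# Methods

## Scope and model

`contextsim` scores each token of a passage for its semantic similarity to
the preceding context, given a table of fixed word embeddings.  Six
measures are computed (see README for definitions); the package also
simulates fixation-duration data with a known similarity effect and checks
that the effect can be recovered, which is what its tests rely on instead
of any external eye-tracking corpus.

Heavy downstream statistics — additive mixed models with tensor smooths,
their quantile-regression variants, model ranking — are deliberately not
implemented.  The package's job ends at a tidy analysis table (UTF-8 CSV,
RFC-4180) that such software consumes verbatim, plus one deliberately
simple in-repo estimator for sanity checks.

## Window policies

Each measure is bound to exactly one context-window policy:

* `FIXED_K_ALL` (dynamic measures, `cosine_all`, `euclidean_fixed`): the
  k most recent in-vocabulary preceding tokens of any word class.  Windows
  may cross sentence boundaries within a passage — stimuli are
  multi-sentence passages and restricting to sentences would silently
  shrink coverage — but never passage boundaries.  A window is only
  defined when a full k tokens are found; this keeps the number of summed
  correlation pairs constant (six for k=3) so values are comparable across
  tokens.  The alternative (shrinking windows near passage starts) would
  conflate window size with position.
* `FIXED_K_CONTENT_SENT` (`cosine_content`): up to the k most recent
  in-vocabulary *content* words within the current sentence; defined if at
  least one is found.
* `ALL_PRECEDING_SENT` (`euclidean_sentence`): every in-vocabulary
  preceding token in the current sentence.

Out-of-vocabulary context tokens are skipped and the lookback extends
further left (bounded by the passage start).  Zero-filling was rejected: a
zero vector has undefined Pearson correlation and biases context sums and
means.  Sentence-initial targets, and out-of-vocabulary targets, get
MISSING.

k defaults to 3 everywhere and is a parameter (`--window`).

## Numerical choices

* Pearson correlation is computed across embedding dimensions between two
  word vectors, two-pass, with results clipped to [−1, 1] to absorb
  floating-point overshoot.  Constant vectors raise a degenerate signal
  that becomes MISSING with a logged warning — 0 is a meaningful
  similarity value and must never encode failure.
* No vector length-normalization is applied before any measure.  Pearson
  and cosine are scale-invariant anyway; normalizing would silently change
  the Euclidean values.
* The reciprocal Euclidean distance is unbounded; when the target
  coincides with the context mean (distance < 1e−12) the value saturates
  at 1e12 and the row is flagged (`saturated`), the one documented numeric
  sentinel.
* Correlation matrices are validated for symmetry (1e-12), unit diagonal,
  and entries in [−1, 1].

## Tokenization and word classes

Tokenization is rule-based and deterministic so that token indices are
reproducible against a fixation-by-token join: sentences end at `. ! ?`
plus closing quotes; words are maximal letter runs with internal hyphens
and apostrophes kept; standalone punctuation is dropped.  Normalization of
surface forms to embedding keys is Unicode NFC + casefold + edge
punctuation strip — pretrained word2vec-style vocabularies are
overwhelmingly lower-case, so case-folded matching maximizes the hit rate.

Content vs function classification uses a packaged closed-class list
(determiners, prepositions, conjunctions, pronouns, auxiliaries/modals,
particles, wh-words), overridable by file.  This is a coarse
approximation; no POS tagging is attempted, so e.g. verbal "watch" and
auxiliary-like uses of the same form are not disambiguated.

## Synthetic data

The latent-factor embedding sampler draws word w's vector as
`L @ l_w + noise_scale * eps_w` with `L` (d × m) and `eps_w` standard
normal.  For unit loadings the expected Pearson correlation of two words
is `l_w · l_u / (1 + noise_scale²)`, so pairwise correlation structure can
be dialled in; the calibration is verified by test.  Defaults (1200 words,
d = 300, 8 factors, noise 0.5) give the mildly correlated vocabulary the
measures need without making all windows look alike.

The passage sampler emulates short naturalistic reading stimuli: 55
passages of ~50 words and ~2.5 sentences by default, with function words
drawn at rate 0.4 from the closed-class portion of the vocabulary —
roughly the function-word share of running English text.

Fixation durations follow a linear-additive model per (token,
participant): intercept + word-length and log-frequency effects + a linear
similarity effect + a participant random intercept + residual noise,
truncated below at 1 ms.  Defaults: intercept 214 ms for first fixation
with a +36 ms offset for total fixation (typical first/total fixation
levels), β_len = 5 ms/char, β_freq = −8 ms per log-count unit,
β_sim = −10 ms/unit (words closer to context are read faster), σ_u = 30 ms,
σ_ε = 50 ms, 20 participants.  A linear effect rather than a smooth
surface is intentional: the in-repo estimator is linear, and sign/
magnitude recovery — not smooth-curve replication — is what the tests
assert.  Log-normal duration shape, skips, regressions and other
eye-movement dynamics are not simulated; passing tests therefore show the
pipeline's bookkeeping and estimator are correct under the stated model,
not that real reading data obey it.

The worked-example fixture builds six embedding vectors whose sample
correlations among "the", "smart", "watch", "space" equal the published
illustration's matrix to machine precision, by multiplying orthonormalized
centered Gaussian columns by the Cholesky factor of the target matrix
(which is positive definite; eigenvalues 0.34–2.01).

## Effect recovery

`recover_similarity_effect` participant-mean-centers the response, which
under the additive generative model absorbs the random intercept exactly,
then fits OLS of the centered duration on similarity, word length and log
frequency.  The slope is in ms per similarity unit.  This is a linearized
stand-in for a mixed additive model — adequate for recovering a linear
simulated effect, not a replacement for GAMMs on real data, where
nonlinearity and crossed random effects matter.

Problem sizes used by the test suite and acceptance script: oracle
comparison over ~550 tokens of an 11-passage corpus (300-word vocabulary,
d = 60); effect recovery on ~5000 scored tokens × 20 participants
(800-word vocabulary, d = 120), with 100 re-simulation replicates for the
sign-recovery rate.  At this design the slope standard error is ≈ 0.2
ms/unit, so a −10 ms/unit effect is recovered well within ±20% and the
sign essentially always.

## Known limitations

* Function/content classification is list-based, not POS-tagged.
* Only the text `.vec` dialect is read; no binary word2vec, no subword
  OOV synthesis — out-of-vocabulary words are simply skipped.
* English-oriented tokenization rules.
* The fixation simulator is linear-additive with Gaussian noise; it is a
  test harness, not a cognitive model.
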