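# Methods notes

## Cleaning model

Transcript cleaning is a fixed, deterministic rewriting of each raw text
span:

1. Angle-bracketed spans (`<...>`, bracket plus contents) are deleted
   first, innermost-first, so markup like `<unk>` can never leak tokens.
   An unclosed `<` deletes to the end of the span under the default policy
   (with a warning); a strict mode raises instead.
2. The remainder is lowercased.
3. Every character outside the configured alphabet (default: the 26 ASCII
   letters) is replaced by a space. This single rule implements several
   conventions at once: hyphenated compounds split into their components
   ("teh-o" → "teh", "o"), apostrophes act as punctuation ("doesn't" →
   "doesn", "t"), digits are deleted rather than spelled out, and accented
   or non-Latin characters are removed. The alphabet is configurable for
   varieties where, say, accented letters are contrastive.

The function is idempotent, and tokenization is a plain whitespace split.
One transcript file is one document; contextual diversity is counted over
documents regardless of any corpus-part label (a per-part breakdown is
available but not the default, since the validation models never use it).

## Zipf transform

`zipf_value` uses the exact denominator `n_tokens/1e6 + n_types/1e6`. For
a published table computed with a rounded constant (e.g. 0.05668 for a
corpus with 56,679 types) the difference is below 1e-5 Zipf units —
invisible at the 2-decimal reporting scale — but an explicit-denominator
argument is provided so such tables can be reproduced verbatim. Zipf
values are kept at full precision internally and rounded only at CSV
export. Add-one smoothing makes the value defined at count 0, which is
what lets merged tables carry zero-frequency entries in union mode.

## Neighborhood networks

The neighbor predicate is phoneme-level Levenshtein distance exactly 1
with unit costs and atomic symbol comparison (no feature decomposition;
stress or tone marks, if present in the symbol set, make symbols distinct
unless normalized upstream). Consequences of "exactly 1":

* Homophones — identical pronunciations of different words — are *not*
  neighbors by default (`link_homophones=True` reverses this).
* In the pronunciation network, one pronunciation string shared by
  several words is a single node; each such word inherits that node's
  degree.
* A word never neighbors itself, even when its own pronunciation variants
  are one edit apart (those variants may still be linked to each other in
  the pronunciation network).

Neighbor search hashes each pronunciation's single-deletion variants: an
insertion/deletion pair shares a full form with a deletion variant, and a
substitution pair shares a deletion variant at the same position, so
candidate generation is near-linear in lexicon size; every candidate is
verified with the exact predicate. The quadratic all-pairs construction is
kept as a test oracle and as the `brute_force=True` path.

## Mixed-effects fitters

Both fitters handle exactly the design the validation needs: fixed
effects plus crossed random intercepts for participant and item.

* **Linear (RT)**: profiled maximum likelihood in the style of lme4 — for
  relative covariance factors θ = (θ_participant, θ_item) the fixed
  effects, spherical random effects, and residual variance are solved in
  closed form via penalized least squares, leaving a smooth 2-parameter
  deviance minimized by L-BFGS-B (Nelder–Mead fallback). ML rather than
  REML throughout, because AICs are compared across models with different
  fixed effects, and REML likelihoods are not comparable across
  fixed-effect structures. Verified against statsmodels MixedLM
  (variance-component parameterization) to ~1e-3 in log-likelihood,
  coefficients, SEs, and variance components.
* **Logistic (accuracy)**: Laplace approximation; an inner Newton solve
  for the joint random-effect mode with a dense (P+I)×(P+I) penalized
  Hessian assembled from group-wise sums, and an outer quasi-Newton
  search over fixed effects and log random-intercept SDs. Covariates are
  standardized internally (and estimates mapped back) so one
  finite-difference step size serves all parameters. Verified against
  lme4::glmer (nAGQ=1, the same Laplace objective) to ≲0.05 in
  log-likelihood and ~0.02 in coefficients. Estimates are reported as
  odds ratios with delta-method SEs.

Parameter counts entering AIC = 2k − 2logL: k = p fixed effects + 2
variance components (+1 residual variance for the linear model). This
convention is internally consistent across all compared models; since
every compared model shares the same random-effect structure, any other
convention would shift all AICs by a constant and leave Δ-AIC, weights,
and support ratios unchanged.

Akaike weights are computed in log space (shift-invariant and
underflow-safe); corpus support ratios are differences of
log-sum-exp-summed log weights, so a ratio like 1e300:1 is still exact.
By default the weight set contains only the corpus models (3 corpora ×
{frequency, CD} in the full design) — support ratios involve only corpus
models — with an option to include the covariates-only baseline.

Marginal R² is the Nakagawa–Schielzeth form: var(Xβ̂) / (var(Xβ̂) + Σ
τ₀₀ + residual), with residual σ² for linear fits and π²/3 (the latent
logistic scale) for binomial fits.

## Trial filtering

Exclusions run in order: incorrect responses; RTs outside 200–3000 ms;
then a per-participant 2.5-SD trim seeded with the mean and SD of the
trials surviving the first two steps. The trim is repeated until
self-consistent — every retained trial lies within 2.5 SD of the retained
trials' own mean — which makes the filter a well-defined fixed point
(applying it twice changes nothing). A conventional one-shot trim is
available via `max_passes=1`; on Gaussian RTs it retains on the order of
1% more borderline trials, with no visible effect on the fitted models.
Participants with fewer than two surviving trials have an undefined SD
and are retained with a warning. Accuracy analyses use unfiltered trials.

## Synthetic data: what it emulates, and what it does not

* `gen_corpus` writes messy transcripts (long TextGrid, short TextGrid,
  plain text) whose clean token streams follow a rank–frequency power law
  (default exponent 1.0, the classic Zipfian case, so the Zipf transform
  is exercised over its full dynamic range). Injected noise — attached
  punctuation, standalone digit runs, angle-bracketed names from a
  deliberately disjoint token set, hyphen-joined neighbors, random casing
  — is exactly the noise the cleaning rules remove, so recovered counts
  must equal the generator's ground truth *exactly*. It does not emulate
  disfluencies, code-switching, or semantic coherence.
* `gen_norm_table` draws a multinomial count vector over a Zipfian type
  distribution directly at realistic scale (default ~30M tokens, 50k
  types, 19k documents — the scale of a large speech-corpus norm set),
  because token-level simulation adds nothing when only count structure
  matters. CD counts follow the Poisson-occupancy expectation
  n_docs·(1−exp(−count/n_docs)), which makes CD a smooth monotone
  function of count; real CD carries some independent signal that this
  construction does not reproduce.
* `gen_lexicon` plants single-edit neighbors at a controllable rate and
  computes its ground-truth adjacency by brute force at generation time.
  Pronunciations are random symbol strings, not phonotactically legal
  ones.
* `gen_trials` simulates RT = Xβ + u_participant + u_item + ε and a
  logistic accuracy analogue (accuracy effects applied to item-centered
  covariates, so generator intercepts stay interpretable). Default
  magnitudes follow published trial-level auditory lexical decision
  analyses: frequency slope −14 ms/Zipf, residual SD 217 ms, participant
  intercept SD 84 ms, item SD 64 ms; accuracy odds ratio ~1.24 per Zipf
  with participant/item intercept SDs 0.62/0.95 on the logit scale.
  Items are sampled one-per-stratum on the Zipf value axis, emulating how
  megastudy stimulus lists span the whole frequency range (uniform
  sampling from a Zipfian vocabulary would pile items at the
  low-frequency floor and leave the frequency slope poorly identified).
  Optional outlier injection (one-third below 200 ms, one-third above
  3000 ms, one-third ~6 residual SDs from the participant mean but inside
  the response window) exercises the trial filter. Passing tests on these
  data show the estimators and the selection machinery work under the
  generating model; they cannot show that real RT distributions (skewed,
  heteroscedastic) are equally well behaved.
* Cross-corpus emulation (`add_noisy_predictor`, and the shared-deviation
  construction used in the tests) adds one Gaussian usage deviation per
  *item*, shared between a corpus's frequency and CD measures — corpus
  differences are usage-driven, so a foreign corpus's two measures
  deviate together, not independently. The default deviation SD of 0.8
  Zipf units against an item spread of ~1.2 corresponds to an item-level
  cross-corpus correlation near 0.85, in the range reported between
  frequency databases from related English varieties.

## Problem sizes used in the test suite

The recovery harness runs at 50 participants × 300 items (15,000 trials),
100 replicates for slope sign and CI coverage, and 60 replicates for the
corpus support-ratio check; network oracle equivalence uses 100 random
lexicons of 20–300 words and 10,000 random pronunciation pairs. These
sizes make each check statistically meaningful while a full suite run
stays in the low minutes.

## Known limitations

* No part-of-speech information anywhere in the pipeline (deliberate:
  reliable tagging for colloquial varieties is an open problem).
* Random intercepts only; random slopes are out of scope.
* The logistic fitter's Laplace approximation shares lme4's small-cluster
  bias; with ≥50 observations per participant and item it is negligible.
* The TextGrid reader assumes one value per line (the format Praat
  writes); exotic hand-edited multi-line text fields are rejected with a
  parse error rather than guessed at.
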