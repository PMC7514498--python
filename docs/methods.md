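# Methods

## Data model

A corpus is a three-level hierarchy: phoneme tokens nested in word
tokens nested in breath groups (BGs).  Phoneme and word tokens come from
a forced alignment; each token is `(speaker, label, start, end)` with
duration `t = end − start` in seconds.  Containment is decided by
interval inclusion with a 1 ms tolerance (absorbing aligner rounding); a
phoneme that fits no word interval is an orphan and a hard validation
error.  Type identity is case-folded exact label match — no
lemmatization — and silence/pause labels (`sil`, `sp`, empty, …) are
excluded from token lists while still shaping the gaps used for
segmentation.

BGs are derived, not read: a new BG starts when the gap between
consecutive words of one speaker reaches the pause threshold, or the
speaker changes.  No standard pause criterion exists across corpora, so
the threshold is a parameter; the default of 0.1 s is large enough to
sit above a typical 10 ms annotation grain and small enough to split at
breathing pauses.  Token lists are sorted by start time per speaker on
ingestion; overlapping same-tier intervals (beyond tolerance) are
rejected.

## Generative model

The synthetic corpus emulates the statistical structure the analyses
assume:

- **Phonemes.**  `Y = exp(X)`, `X ~ N(mu, sigma²)`.  Defaults
  `mu = −3.0` (median `exp(−3) ≈ 50` ms, the typical median phoneme
  duration of read speech) and `sigma = 0.6` (the scale reported for
  real phoneme/word duration distributions).
- **Words.**  A vocabulary of `vocab_size` types (default 4000, the
  order of magnitude of word types in a ~50k-token corpus).  Token
  probability `p(r) ∝ r^−zipf_alpha` (default 1.41) and target mean
  duration `ell_r = ell_min + (zipf_alpha/brevity_lambda)·log r`
  (defaults `ell_min = 0.10` s, `brevity_lambda = 24.1` s⁻¹) — the
  size-rank form, so Zipf, brevity and size-rank are jointly consistent
  by construction.  A type's phoneme count is `n_r = max(1,
  round(ell_r/E[Y]))` and its phoneme draws are scaled by
  `ell_r/(n_r·E[Y])` so the type's expected duration is exactly `ell_r`
  despite integer phoneme counts.
- **Phonemes-per-word distribution.**  Truncated geometric on {1..8}
  with mean ≈ 3.7, matching the phoneme:word token ratio of read-speech
  corpora; this is a documented stand-in, as real corpora do not publish
  the empirical distribution.
- **Breath groups.**  Lengths from a truncated geometric on {1..20} with
  mean ≈ 4 words per BG (again the observed token-ratio order of
  magnitude); words are contiguous inside a BG and BGs are separated by
  0.5 s pauses, with BGs distributed round-robin over 4 speakers.
- **Labels.**  Each type's label is its phoneme-symbol sequence over a
  32-symbol inventory with power-law symbol usage; labels only need to
  make type counts and character units meaningful.
- **Coarsening.**  `coarsen(t; precision, tau)` rounds to the nearest
  multiple of `precision` (default 10 ms) then floors at `tau` (default
  30 ms).  Word-level coarsening is applied by coarsening phoneme parts
  and summing, so resolution artifacts propagate up the hierarchy.  The
  operator is idempotent whenever `tau` lies on the grid.

What the generator does **not** emulate: prosody, speaker-specific
rates, within-BG temporal structure, any coupling between BG length and
word durations (so the Menzerath–Altmann relation at the BG scale is
flat in synthetic data and its fit there only exercises the machinery),
and serial correlation of tokens (tokens are i.i.d., so vocabulary
growth curves are smoother than in real discourse).  Passing
recovery tests therefore demonstrates estimator correctness under the
model, not the empirical truth of the laws in any real language.

## Estimators

- **Rescaling.**  `t' = (log t − ⟨log t⟩)/sd(log t)` with *sample* sd
  (ddof = 1); an affine standardization, exact to machine precision.
  The lognormal MLE itself uses the closed form `mu = mean(log t)`,
  `sigma = sd(log t)` with ddof = 0 (the maximum-likelihood
  normalization).  The collapse diagnostic is the KS distance between
  the rescaled sample and N(0,1).
- **Zipf.**  The rank of each token's type is treated as a discrete
  random variable with `p(r) ∝ r^−alpha`.  The likelihood is normalized
  over the finite observed rank support: rank is bounded by the
  vocabulary size, and an unbounded zeta normalization is measurably
  biased upward (≈ +0.05 at 4000 types, α ≈ 1.4) precisely because the
  truncated tail carries a few percent of mass.  `xmin` is selected by
  minimizing the KS distance of the fitted tail over candidate cutoffs
  (capped at rank 50 by default); the MLE equals a brute-force
  likelihood grid search to 10⁻³ on small instances (tested).
- **Yule (phonemes).**  Published phoneme analyses report a
  two-parameter "Yule" fit without pinning the density, and phoneme
  inventories are small with gently decaying rank-frequency curves.  We
  therefore fix the family to the geometric-damped power law
  `p(r) ∝ r^−a · b^r` over ranks (a Yule-distribution form classically
  used for rank-frequency data), fitted by numerical MLE (L-BFGS-B; the
  normalizer converges geometrically for b < 1).  The report prints the
  formula next to the parameters so the parameterization is never
  ambiguous; published (a, b) values under an unknown parameterization
  cannot be targeted numerically.
- **Herdan–Heaps.**  With multiple speakers the growth curve depends on
  concatenation order, so V(L) and V(T) are computed for seeded random
  permutations of speaker order (default `min(100, n_speakers!)`),
  sampled at ~64 log-spaced checkpoints, fitted by OLS on logs, and the
  exponents averaged over permutations.
- **Brevity.**  OLS of log frequency on raw per-type size (no binning;
  frequency-1 types retained); Spearman's rho with average ranks for
  ties is reported alongside, and the fit is flagged uninformative when
  the correlation is not significant at 0.05.  Word physical size is the
  mean token duration of the type (median available as an option).  For
  symbolic units, the optimality exponent is obtained by regressing
  `ℓᵢ` on the optimal code length `−log_D pᵢ` (with intercept) and
  inverting the slope; `D` is the number of distinct symbols at that
  unit.  Values outside (0, 1] are reported with a warning rather than
  clipped.
- **Size-rank.**  OLS of raw per-type size on log rank.  θ is predicted
  from the other two laws as the **ratio** `alpha/lambda`: the published
  exponent tables satisfy the ratio (1.42/23.8 ≈ 0.060) and not a
  literal product, so the ratio form is implemented and the report
  records the formula used.  Rank ties are broken by first occurrence in
  the token stream, which makes rank assignment reproducible.
- **Menzerath–Altmann.**  `y(n) = a n^b exp(−cn)` by Levenberg–
  Marquardt on raw construct-level points, starting at
  `(median(y), −0.1, −0.01)`, with up to 20 jittered restarts (fixed
  internal seed) on non-convergence.  R² is `1 − SS_res/SS_tot` on the
  raw points; for exactly constant data the convention is R² = 1.  The
  extremum `n = b/c` is reported as `inversion_n`.  BG-level constituent
  sizes average over word *tokens* within the BG.

## Problem sizes and simulation design

The recovery experiments use: 50k tokens over 4k types for the Zipf
MLE; 100k draws for the lognormal MLE; `n = 1..40` noiseless points for
the Menzerath fit; 100k words for the collapse/coarsening ordering
(lognormal closure of `Z̃` holds to KS < 0.05 for words of 1–4 phonemes
even at `sigma = 2`).

The brevity-recovery corpus uses 50k tokens over a **100-type**
vocabulary rather than the default 4000.  The regressor is the
*measured* per-type mean duration, so the fit is an errors-in-variables
problem: the between-type spread of true mean durations is fixed at
`(alpha/lambda)²·var(log r) ≈ θ²` regardless of vocabulary size, while
the measurement noise of a type observed `f` times scales as
`(sigma·ell)²/(n_ph·f)`.  With thousands of types most types are seen
once or twice and the OLS slope is attenuated far below the generating
rate; with 100 types every type's expected count is ≳ 25 and the
attenuation is within a few percent.  This is a property of the
estimator the analysis pipeline prescribes (raw per-type least squares),
not of the law, and the condition is chosen once from this analysis.

## Known limitations

- The TextGrid reader covers long-format interval tiers only (the
  format forced aligners emit); point tiers are ignored.
- Unordered input tokens are sorted by start time per speaker rather
  than rejected; genuinely inconsistent timelines still fail the
  overlap/negative-gap checks.
- The Yule family choice is a pinned convention (see above); comparing
  its parameters against published values requires knowing the
  publication's parameterization.
- Two-regime Zipf fitting and inferential cross-language optimality
  comparisons are out of scope; λ_D values are reported as numbers only.
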