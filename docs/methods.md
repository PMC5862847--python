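# Methods

## The scoring model

`rpas` computes a four-part stylistic signature for each text chunk — a
document of N tokens and w distinct types after rule-based tokenization:

**Richness (R).** R = w / √N, Menhinick's diversity index applied to word
types.  The plain type-token ratio w/N is exposed behind
`sqrt_denominator=False` for sensitivity checks, but the square-root
denominator is the default: it is the index's standard form and the only
choice on which richness values for ~2,000–30,000-token chunks land in the
10–20 range where the discriminant analyses operate.  Because richness
still decays once a writer's active vocabulary is exhausted, chunks are
capped at 30,000 tokens by corpus design (a warning, not truncation).

**Personal pronouns (P).** A fixed-coefficient logistic model over the
relative frequencies of the three diagnostic possessives:

    P = logistic(−0.93 − 451.86·f(my) + 322.47·f(her) + 129.83·f(its))

with f(·) = count/N.  The coefficients are taken as given from prior
gender-attribution regressions and are not re-fit here.  Frequencies (not
raw counts) are the only reading under which coefficients of magnitude
10² produce non-saturated logits on real text.  P ≥ 0.5 is labelled
Masculine style, below Feminine; the boundary is inclusive of M.  The
score is clamped to the open interval (0, 1) at the floating-point ulp so
downstream logit transforms stay finite.  An opt-in `neuter_his_as_its`
flag counts "his" toward the f(its) term — the Early Modern neuter
possessive reading, where "his" stood where modern English uses "its";
it is off by default.

**Referential-Activity power (A).** Per particle category k ∈ {article,
conjunctive, preposition, pronoun}:

    A_k = Σ_i ω_i² · ε_i / D

where ω_i is the chunk count of particle i, ε_i its averaged
concreteness/imageability weight from the lexicon file, and D = N.  The
square on ω is part of the definition (it emphasises heavy function-word
use); `ra_power_exponent=1` gives the linear variant for comparison.

**Sensory adjectives (S).** Per modality k ∈ {visual, auditory, haptic,
olfactory, gustatory}:

    S_k = Σ_i φ_i · ϑ_i / D

with φ_i the adjective count and ϑ_i its modality-exclusivity weight.
Unlike A_k the count enters linearly, and an adjective normed in two
modalities contributes to both.

Aggregate A and S (used in the 4- and 8-variable layouts) are the sums of
their components; summation preserves additivity over disjoint term sets
and keeps correlation tables well defined.  Four layouts are supported:
RPAS4 (R, P, A, S), RPAS7 (A expanded), RPAS8 (S expanded — the "VAHOG"
variables), RPAS11 (both expanded).

Useful exact scaling laws (all tested): concatenating a chunk with itself
multiplies R by 1/√2, doubles every A_k ((2ω)²/(2D) = 2ω²/D), and leaves P
and every S_k unchanged; every score is invariant to token order.

## Text preparation

Tokens are maximal runs of letters with internal apostrophes/hyphens; a
leading elision apostrophe is kept so Early Modern forms ("'tis", "fix'd",
"o'er") survive as single tokens; case is folded; digits, punctuation and
symbols are dropped; stop words are deliberately retained (the particle
lexicon is built from them).  Stage directions — ALL-CAPS speaker
prefixes, bracketed actions, Enter/Exit/Exeunt lines — are removed by
configurable regular expressions; editions differ, so the patterns are
configuration, not code.  An optional tagger hook accepts an external
(token, tag) stream for parity experiments with tagger-based pipelines;
the rule-based path is the default and has no external dependency.

Chunking is by title headings (each heading line starts a new chunk and
stays with it, so token counts are conserved), or into fixed-size blocks
for resampling, where the trailing remainder below the block size is
discarded so all blocks are exactly equal — 124,000 tokens at size 2,000
give exactly 62 chunks.

## Lexicons

Lexicon files are `term,category,weight` CSV.  Weights are opaque to the
package: they are not recomputed from the psycholinguistic source norms
(which are not redistributed) and not renormalized on load — scores
inherit the file's scale, and only the division by D controls for chunk
size.  The reference tables have 117 particle entries and 774 sensory
entries (each adjective normed in its two dominant modalities); loading a
file of another size warns but proceeds.  `fixture_lexicons(seed)` builds
small deterministic stand-ins (20 particles, 40 adjectives, synthetic
weights in (0, 1]) with the same structure, used by the test suite and
the synthetic generator.

## Accumulation curves

The frequency-group curve groups types by corpus-wide token frequency
(one group per distinct frequency value) and accumulates type counts over
the first 100 groups.  The ordering of groups is genuinely ambiguous in
the source description; the default orders by ascending group size (types
per group, ties by frequency value), with ordering by frequency value
behind a switch.  The work-ordered curve sorts works largest-first (size
ties broken by manifest order, for determinism) and accumulates types not
seen in any earlier work; x is recorded in raw tokens, with the
conventional thousands-scale left to presentation.  The asymptote locator
replaces an eyeball judgement with a rule: the smallest index from which
every later per-point gain is below `rel_gain` (default 0.001) times the
total type count, returning the last index when the curve never plateaus.

## Multivariate battery

All analyses run on the correlation matrix (standardized variables), the
appropriate default for scale-heterogeneous features.

*Pearson screening* reports r, two-tailed p from the t reference
distribution with n−2 df, and n; zero-variance columns yield flagged NaN
entries rather than silent ones.

*Hierarchical clustering* delegates linkage numerics to scipy: Ward's
minimum-variance method (squared-Euclidean geometry only; the
Ward/cosine combination is rejected) and single linkage
("nearest neighbor") with squared-Euclidean or cosine dissimilarity.
Cut labels are renumbered by first appearance so results are stable for a
given row order; scipy's lowest-index merge rule fixes ties.

*KMO and Bartlett gates.*  KMO is the ratio of summed squared
correlations to that sum plus summed squared anti-image partial
correlations (via the inverse correlation matrix); Bartlett's sphericity
statistic is −(n−1−(2p+5)/6)·ln|R| on p(p−1)/2 df.  A singular
correlation matrix is an error naming the near-duplicate columns.

*Iterative EFA/PCA.*  Each pass extracts principal components of the
correlation matrix, retains eigenvalues > 1 (Kaiser's rule, with a 1e−9
tolerance so an exactly spherical spectrum retains nothing), applies
varimax rotation (the conventional orthogonal default; the source
procedure says only that rotation followed), fixes factor signs by making
each factor's dominant loading positive, and removes the variable whose
largest absolute rotated loading is smallest if it falls below the 0.30
threshold; the loop repeats until all survivors load at or above the
threshold.  Per-factor variance is reported from rotated sums of squared
loadings; the total equals the retained-eigenvalue sum ratio exactly.

*Stepwise LDA.*  Forward selection by Wilks' Λ: the candidate minimizing
Λ enters when its partial F = ((n−g−p)/(g−1))·(Λ_p/Λ_{p+1} − 1) exceeds
F-to-enter (3.84), and entered variables whose partial F drops below
F-to-remove (2.71) leave; the thresholds are the conventional defaults of
the social-science packages this procedure originates from, and a
repeated-state guard terminates enter/remove cycles.  Canonical functions
solve the generalized eigenproblem B·v = λ·W·v, scaled to unit pooled
within-group variance with a positive-dominant-coefficient sign
convention; each function is tested by the chi-square approximation to
Λ.  In-sample classification uses Fisher linear classification functions
with equal priors (cross-checked against scikit-learn's LDA in the test
suite).  When no variable passes entry the result is an empty selection
and all rows fall to the alphabetically first group — which is what makes
the null (identical-author) experiment classify at chance.

*Centroid distances* are Euclidean between group means, by default in the
first three canonical dimensions (or all available, if fewer).

*AtoR map.*  Each chunk's (A, R) pair is flagged when R is at or above
the corpus 90th percentile and A at or below the 10th — the signature of
unusually rich but referentially flat writing.  The percentile rule makes
the eyeballed "spike" criterion explicit; both cut-offs are configurable.

*Contested works* are excluded before discriminant training via a
configured chunk-id list, not code: the disputed set is editorial data.

## Synthetic data

The generator emulates exactly the structure the scores measure, nothing
more: a Zipf-Mandelbrot background vocabulary (exponent 1.1, shift 2.7,
5,000 types by default — values in the typical range for literary
frequency lists), author-specific per-token rates for the three
diagnostic possessives (defaults 0.004/0.003/0.0005, the order of
magnitude observed in narrative English), and author-specific per-token
usage rates for each lexicon category.  Tokens are drawn independently
per position from the mixture; background labels are abstract alphabetic
strings, so no Early Modern surface forms, syntax, burstiness or
discourse structure are imitated.  Passing tests therefore demonstrate
that the pipeline recovers the statistical structure it assumes — not
that real authors satisfy those assumptions.

Partial-synthetic pseudo-works concatenate without-replacement draws of
fixed-size chunks from real (or generated) works; by default the pool is
refreshed between samples, so the five samples are independent draws in
the style of multiple partially-synthetic datasets (a no-reuse mode is
available).  Every generator output is a pure function of (parameters,
seed).

## Problem sizes and numerical choices

The validation experiments use 40 chunks of 2,000 tokens per author —
enough for the 3-SD two-feature effect-size experiment to clear 95%
training accuracy with margin while the whole battery runs in seconds.
The rate separation called "3 SD" is three binomial standard errors of
the base rate at the 2,000-token chunk size.  Scores are exact rational
arithmetic over counts divided by floats, so oracle comparisons use
1e−12 tolerances; KMO/Bartlett hand-computation checks use 1e−10.

## Known limitations

* The pronoun model's coefficients are inherited, not re-estimated; the
  positive coefficient on "her" (pushing toward the Masculine label) is
  implemented as defined, without correction.
* Reported EFA variance and KMO on synthetic corpora depend on the
  fixture lexicon weights and rates; they are not estimates of any real
  corpus's values.
* The unweighted-least-squares factor-analysis variant is not
  implemented; only the iterative PCA/EFA path is.
* No parametric vocabulary extrapolation is provided; accumulation
  curves are descriptive.
* Texts are taken as supplied: no spelling modernization or edition
  reconciliation.
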