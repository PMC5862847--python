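# rpas

Stylometric authorship profiling from weighted-lexicon scores.

`rpas` is for researchers in computational psycholinguistics and forensic
stylometry who want to separate authors — or flag stylistically anomalous
passages — using features that reflect a writer's *self* rather than raw
word statistics.  Each text chunk (a titled section or a fixed-size token
block) gets a four-part signature:

- **Richness** `R = w/√N` — Menhinick's diversity index over word types
  (w types, N tokens);
- **Personal pronouns** `P = logistic(−0.93 − 451.86·f(my) + 322.47·f(her)
  + 129.83·f(its))` — a fixed-coefficient logistic gender-style score on
  possessive-pronoun relative frequencies, in (0, 1), with P ≥ 0.5 labelled
  Masculine style;
- **Referential-Activity power** `A_k = Σ ω_i²·ε_i / D` per particle
  category (articles, conjunctives, prepositions, pronouns), where ω_i is
  the count of function word i and ε_i its averaged
  concreteness/imageability weight;
- **Sensory adjectives** `S_k = Σ φ_i·ϑ_i / D` per perceptual modality
  (visual, auditory, haptic, olfactory, gustatory — "VAHOG"), with ϑ_i a
  modality-exclusivity weight.

Around the scores sits the full analysis pipeline: heading-based chunking
with stage-direction stripping, word-accumulation curves with an
asymptote locator, Pearson screening, hierarchical clustering (Ward and
nearest-neighbor), KMO/Bartlett factorability gates, iterative EFA/PCA
with 0.30-threshold variable removal, forward-stepwise LDA with Wilks' Λ
entry tests, canonical-space centroid distances, the high-richness /
low-RA (AtoR) anomaly map, and a seeded synthetic-corpus generator plus
partial-synthetic resampling for validation.  Lexicon weight tables are
loaded from CSV (`term,category,weight`); deterministic fixture lexicons
are built in when no tables are supplied.

## Worked example

Two synthetic authors identical in every rate except their
auditory-adjective usage (0.02 vs 0.06 per token):

```python
from rpas import (AuthorProfile, fixture_lexicons, generate_corpus,
                  feature_table, stepwise_lda, split_feature_table,
                  TokenizerConfig, chunk_by_heading)

ra_lex, sens_lex = fixture_lexicons(seed=0)
profiles = [
    AuthorProfile("alice", lexicon_rates={"article": 0.06, "preposition": 0.10,
                                          "auditory": 0.02, "haptic": 0.015}),
    AuthorProfile("bob",   lexicon_rates={"article": 0.06, "preposition": 0.10,
                                          "auditory": 0.06, "haptic": 0.015}),
]
works = generate_corpus(profiles, works_per_author=20, tokens_per_work=2000,
                        seed=0, ra_lexicon=ra_lex, sensory_lexicon=sens_lex)
cfg = TokenizerConfig(strip_stage_directions=False)
chunks = [c for w in works for c in chunk_by_heading(w, cfg)]
table = feature_table(chunks, "RPAS11", ra_lex, sens_lex, works=works)
print(table[["author", "N", "w", "R", "P", "S_auditory"]].head(3).round(4))

feats, labels = split_feature_table(table)
result = stepwise_lda(feats, labels.to_numpy())
acc = (result.classification.to_numpy() == labels.to_numpy()).mean()
print("selected:", list(result.selected_variables))
print(f"training accuracy: {acc:.1%}")
```

prints

```
  author     N    w        R       P  S_auditory
0  alice  2000  673  15.0487  0.1856      0.0145
1  alice  2000  675  15.0935  0.0256      0.0161
2  alice  2000  688  15.3841  0.4055      0.0102
selected: ['S_auditory', 'P']
training accuracy: 100.0%
```

Each 2,000-token chunk uses ~675 distinct types (richness ≈ 15); the
stepwise procedure finds the auditory score — the one planted difference
— as the leading discriminator and separates the authors perfectly in
training.

The same pipeline is scriptable from the shell:

```sh
rpas synth --preset two-authors --seed 0 --out-dir corpus/
rpas features --manifest corpus/manifest.csv --layout rpas11 --out features.csv
rpas lda --features features.csv --out lda.csv
```

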