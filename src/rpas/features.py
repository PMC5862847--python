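"""The four per-chunk stylometric scores and their feature-vector layouts.

For a chunk of N tokens with w distinct types:

* Richness ``R = w / sqrt(N)`` — Menhinick's diversity index applied to
  word types; a size-controlled vocabulary-diversity measure.  (The plain
  type-token ratio w/N is available behind ``sqrt_denominator=False`` for
  sensitivity checks.)
* Personal pronouns ``P = logistic(b0 + b1*f(my) + b2*f(her) + b3*f(its))``
  — a logistic gender-style score over the relative frequencies of the
  three diagnostic possessives; always strictly inside (0, 1).
* Referential-Activity power ``A_k = sum_i omega_i^2 * eps_i / D`` per
  particle category k (articles, conjunctives, prepositions, pronouns),
  where omega_i is the chunk count of particle i and eps_i its averaged
  concreteness/imageability weight.  Counts are squared to emphasise
  heavy function-word use; D = N normalizes for chunk size.
* Sensory score ``S_k = sum_i phi_i * theta_i / D`` per modality k
  (visual, auditory, haptic, olfactory, gustatory), phi_i the adjective
  count and theta_i its modality-exclusivity weight.  Unlike A_k the
  count enters linearly; an adjective normed in two modalities
  contributes to both.

Aggregates A and S (for the 4- and 8-variable layouts) are the sums of
their components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import Chunk, Work
from .lexicons import (
    RA_CATEGORIES,
    SENSORY_MODALITIES,
    GenderModel,
    WeightedLexicon,
)

__all__ = [
    "RAComponents",
    "SensoryComponents",
    "RPASVector",
    "LAYOUTS",
    "richness",
    "pronoun_score",
    "gender_category",
    "ra_power",
    "sensory",
    "feature_vector",
    "feature_table",
]

#: Column labels of the four feature-vector layouts.  A is expanded into its
#: four particle categories in RPAS7/RPAS11; S into the five modalities in
#: RPAS8/RPAS11 (the "VAHOG" variables).
LAYOUTS: dict[str, tuple[str, ...]] = {
    "RPAS4": ("R", "P", "A", "S"),
    "RPAS7": ("R", "P") + tuple(f"A_{c}" for c in RA_CATEGORIES) + ("S",),
    "RPAS8": ("R", "P", "A") + tuple(f"S_{m}" for m in SENSORY_MODALITIES),
    "RPAS11": ("R", "P")
    + tuple(f"A_{c}" for c in RA_CATEGORIES)
    + tuple(f"S_{m}" for m in SENSORY_MODALITIES),
}


@dataclass(frozen=True)
class RAComponents:
    """Per-category referential-activity scores A_k and their sum."""

    by_category: Mapping[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.by_category.values()))

    def __getitem__(self, category: str) -> float:
        return self.by_category[category]


@dataclass(frozen=True)
class SensoryComponents:
    """Per-modality sensory scores S_k and their sum."""

    by_modality: Mapping[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.by_modality.values()))

    def __getitem__(self, modality: str) -> float:
        return self.by_modality[modality]


@dataclass(frozen=True)
class RPASVector:
    layout: str
    labels: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.labels != LAYOUTS[self.layout] or len(self.values) != len(self.labels):
            raise ValueError(f"labels/values do not match layout {self.layout}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.values))


def richness(chunk: Chunk, *, sqrt_denominator: bool = True) -> float:
    """Vocabulary richness w/sqrt(N) (or the plain ratio w/N)."""
    if chunk.N <= 0:
        raise ValueError("richness undefined for an empty chunk")
    denom = sqrt(chunk.N) if sqrt_denominator else chunk.N
    return chunk.w / denom


def pronoun_score(
    chunk: Chunk,
    model: GenderModel | None = None,
    *,
    neuter_his_as_its: bool = False,
) -> float:
    """Gender-style score P in (0, 1) from my/her/its relative frequencies.

    ``neuter_his_as_its`` additionally counts "his" toward the its-term —
    the Early Modern neuter-possessive reading, where "his" stood where
    modern English uses "its".  Off by default.
    """
    if chunk.N <= 0:
        raise ValueError("pronoun score undefined for an empty chunk")
    model = model or GenderModel()
    n = chunk.N
    f_its = chunk.count("its")
    if neuter_his_as_its:
        f_its += chunk.count("his")
    return model.score(chunk.count("my") / n, chunk.count("her") / n, f_its / n)


def gender_category(p: float, model: GenderModel | None = None) -> str:
    """Masculine style 'M' iff P >= threshold (boundary inclusive), else 'F'."""
    model = model or GenderModel()
    if not 0.0 < p < 1.0:
        raise ValueError(f"P must lie in (0, 1), got {p}")
    return "M" if p >= model.threshold else "F"


def ra_power(
    chunk: Chunk, lexicon: WeightedLexicon, *, exponent: int = 2
) -> RAComponents:
    """Referential-activity power per particle category.

    ``exponent`` is the power applied to the per-term count (default 2, as
    defined; 1 gives the linear variant for sensitivity checks).
    """
    if chunk.N <= 0:
        raise ValueError("RA power undefined for an empty chunk")
    if lexicon.kind != "ra":
        raise ValueError(f"expected a particle ('ra') lexicon, got {lexicon.kind!r}")
    if len(lexicon) == 0:
        warnings.warn("empty particle lexicon: all RA components are 0", stacklevel=2)
    d = chunk.N
    scores = {
        cat: sum(
            (chunk.count(term) ** exponent) * weight
            for term, weight in lexicon.category_terms(cat).items()
            if term in chunk.freq
        )
        / d
        for cat in lexicon.categories
    }
    return RAComponents(scores)


def sensory(chunk: Chunk, lexicon: WeightedLexicon) -> SensoryComponents:
    """Sensory-adjective score per modality (counts enter linearly)."""
    if chunk.N <= 0:
        raise ValueError("sensory score undefined for an empty chunk")
    if lexicon.kind != "sensory":
        raise ValueError(f"expected a sensory lexicon, got {lexicon.kind!r}")
    if len(lexicon) == 0:
        warnings.warn("empty sensory lexicon: all components are 0", stacklevel=2)
    d = chunk.N
    scores = {
        mod: sum(
            chunk.count(term) * weight
            for term, weight in lexicon.category_terms(mod).items()
            if term in chunk.freq
        )
        / d
        for mod in lexicon.categories
    }
    return SensoryComponents(scores)


def feature_vector(
    chunk: Chunk,
    layout: str,
    ra_lexicon: WeightedLexicon,
    sensory_lexicon: WeightedLexicon,
    model: GenderModel | None = None,
    *,
    neuter_his_as_its: bool = False,
    sqrt_denominator: bool = True,
    ra_power_exponent: int = 2,
) -> RPASVector:
    """Assemble one chunk's scores in the requested layout."""
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {sorted(LAYOUTS)}")
    r = richness(chunk, sqrt_denominator=sqrt_denominator)
    p = pronoun_score(chunk, model, neuter_his_as_its=neuter_his_as_its)
    a = ra_power(chunk, ra_lexicon, exponent=ra_power_exponent)
    s = sensory(chunk, sensory_lexicon)
    pool: dict[str, float] = {"R": r, "P": p, "A": a.total, "S": s.total}
    pool.update({f"A_{c}": a[c] for c in RA_CATEGORIES})
    pool.update({f"S_{m}": s[m] for m in SENSORY_MODALITIES})
    labels = LAYOUTS[layout]
    return RPASVector(layout, labels, tuple(pool[lab] for lab in labels))


def feature_table(
    chunks: Iterable[Chunk],
    layout: str,
    ra_lexicon: WeightedLexicon,
    sensory_lexicon: WeightedLexicon,
    model: GenderModel | None = None,
    works: Sequence[Work] | Mapping[str, str] | None = None,
    **score_options,
) -> pd.DataFrame:
    """One row per chunk: chunk_id, work_id, author, N, w + layout columns.

    ``works`` supplies the work_id -> author mapping (a Work list or a
    plain mapping); authors default to the work_id when absent.
    """
    if works is None:
        authors: Mapping[str, str] = {}
    elif isinstance(works, Mapping):
        authors = works
    else:
        authors = {w.id: w.author for w in works}
    rows = []
    for chunk in chunks:
        vec = feature_vector(
            chunk, layout, ra_lexicon, sensory_lexicon, model, **score_options
        )
        rows.append(
            {
                "chunk_id": chunk.chunk_id,
                "work_id": chunk.work_id,
                "author": authors.get(chunk.work_id, chunk.work_id),
                "N": chunk.N,
                "w": chunk.w,
                **vec.as_dict(),
            }
        )
    return pd.DataFrame(rows)
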