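"""Weighted lexicons and the pronoun gender model.

Two lexicons drive the scoring:

* a function-word ("particle") lexicon — articles, conjunctives,
  prepositions, pronouns — whose weights are averaged concreteness/
  imageability scores (the reference file has 117 entries);
* a sensory-adjective lexicon over the five perceptual modalities
  (visual, auditory, haptic, olfactory, gustatory) whose weights are
  modality-exclusivity scores (the reference file has 774 entries; each
  surface adjective may appear under its two dominant modalities).

Weights are taken as given from the lexicon file and are not renormalized:
the scores divide by document size only.  The reference weight tables are
not redistributed here; :func:`fixture_lexicons` builds small deterministic
stand-ins with the same structure for testing and simulation.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "RA_CATEGORIES",
    "SENSORY_MODALITIES",
    "WeightedLexicon",
    "GenderModel",
    "load_lexicon",
    "write_lexicon",
    "fixture_lexicons",
]

RA_CATEGORIES = ("article", "conjunctive", "preposition", "pronoun")
SENSORY_MODALITIES = ("visual", "auditory", "haptic", "olfactory", "gustatory")

#: Reference entry counts of the supplementary weight tables; a loaded file
#: of a different size triggers a warning, not an error.
EXPECTED_SIZES = {"ra": 117, "sensory": 774}

_KIND_CATEGORIES = {"ra": RA_CATEGORIES, "sensory": SENSORY_MODALITIES}

# Max categories one surface term may occupy (sensory adjectives were normed
# in their two most dominant modalities).
_MAX_CATEGORIES_PER_TERM = {"ra": 1, "sensory": 2}


@dataclass(frozen=True)
class WeightedLexicon:
    """term -> (category, weight) map with a fixed category inventory.

    ``entries`` maps each lower-case term to a tuple of (category, weight)
    pairs — one pair for particle lexicons, up to two for sensory lexicons
    where an adjective was normed in both of its dominant modalities.
    """

    kind: str
    entries: Mapping[str, tuple[tuple[str, float], ...]]
    categories: tuple[str, ...] = field(default=())
    expected_size: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CATEGORIES:
            raise ValueError(f"unknown lexicon kind {self.kind!r}")
        cats = self.categories or _KIND_CATEGORIES[self.kind]
        object.__setattr__(self, "categories", tuple(cats))
        limit = _MAX_CATEGORIES_PER_TERM[self.kind]
        for term, pairs in self.entries.items():
            if term != term.lower():
                raise ValueError(f"lexicon term {term!r} is not lower-case")
            if not 1 <= len(pairs) <= limit:
                raise ValueError(
                    f"term {term!r}: {len(pairs)} categories (max {limit})"
                )
            seen = set()
            for cat, weight in pairs:
                if cat not in self.categories:
                    raise ValueError(
                        f"term {term!r}: unknown category {cat!r} "
                        f"(expected one of {self.categories})"
                    )
                if cat in seen:
                    raise ValueError(f"term {term!r}: duplicate category {cat!r}")
                seen.add(cat)
                if not (weight >= 0 and math.isfinite(weight)):
                    raise ValueError(
                        f"term {term!r}: weight must be finite and >= 0, got {weight}"
                    )

    def __len__(self) -> int:
        """Number of (term, category) entries — the N_k total."""
        return sum(len(pairs) for pairs in self.entries.values())

    def category_terms(self, category: str) -> dict[str, float]:
        """term -> weight for one category."""
        if category not in self.categories:
            raise KeyError(category)
        return {
            term: weight
            for term, pairs in self.entries.items()
            for cat, weight in pairs
            if cat == category
        }

    @classmethod
    def from_rows(
        cls,
        kind: str,
        rows: Iterable[tuple[str, str, float]],
        expected_size: int | None = None,
    ) -> "WeightedLexicon":
        entries: dict[str, list[tuple[str, float]]] = {}
        for term, category, weight in rows:
            entries.setdefault(term, []).append((category, float(weight)))
        lex = cls(
            kind=kind,
            entries={t: tuple(p) for t, p in entries.items()},
            expected_size=expected_size,
        )
        if expected_size is not None and len(lex) != expected_size:
            warnings.warn(
                f"{kind} lexicon has {len(lex)} entries; expected "
                f"{expected_size}",
                stacklevel=2,
            )
        return lex


@dataclass(frozen=True)
class GenderModel:
    """Logistic gender-style model over the three diagnostic pronouns.

    P = logistic(intercept + coef_my*f(my) + coef_her*f(her) + coef_its*f(its))
    with f() the within-chunk relative frequency.  Scores >= ``threshold``
    are labelled Masculine style (M), below it Feminine style (F).
    """

    intercept: float = -0.93
    coef_my: float = -451.86
    coef_her: float = 322.47
    coef_its: float = 129.83
    threshold: float = 0.5

    def logit(self, f_my: float, f_her: float, f_its: float) -> float:
        return (
            self.intercept
            + self.coef_my * f_my
            + self.coef_her * f_her
            + self.coef_its * f_its
        )

    def score(self, f_my: float, f_her: float, f_its: float) -> float:
        z = self.logit(f_my, f_her, f_its)
        # numerically stable logistic; clamps keep the score inside (0, 1)
        if z >= 0:
            p = 1.0 / (1.0 + math.exp(-z))
        else:
            ez = math.exp(z)
            p = ez / (1.0 + ez)
        tiny = math.ulp(0.5)
        return min(max(p, tiny), 1.0 - tiny)


# ---------------------------------------------------------------------------
# CSV I/O — dialect: term,category,weight; UTF-8; '.' decimal separator
# ---------------------------------------------------------------------------


def load_lexicon(path: str | Path, kind: str) -> WeightedLexicon:
    """Load and validate a lexicon CSV (``term,category,weight``).

    Unknown categories and negative weights are hard errors; an entry count
    differing from the reference size (117 particles / 774 sensory
    adjectives) is a warning only, so trimmed or extended lexicons remain
    usable.
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"term", "category", "weight"}
        if required - set(reader.fieldnames or ()):
            raise ValueError(f"{path}: lexicon header must be term,category,weight")
        for i, row in enumerate(reader, start=2):
            rows.append(
                (row["term"].strip().lower(), row["category"].strip().lower(),
                 float(row["weight"]))
            )
    return WeightedLexicon.from_rows(kind, rows, expected_size=EXPECTED_SIZES[kind])


def write_lexicon(lex: WeightedLexicon, path: str | Path) -> Path:
    """Write a lexicon as CSV; ``load_lexicon`` round-trips it bit-exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["term", "category", "weight"])
        for term in sorted(lex.entries):
            for cat, weight in lex.entries[term]:
                writer.writerow([term, cat, repr(weight)])
    return path


# ---------------------------------------------------------------------------
# Deterministic fixture lexicons
# ---------------------------------------------------------------------------

_FIXTURE_RA_TERMS = {
    "article": ("the", "a", "an", "this", "that"),
    "conjunctive": ("and", "but", "or", "yet", "nor"),
    "preposition": ("of", "to", "in", "on", "with"),
    "pronoun": ("he", "she", "it", "they", "we"),
}

_FIXTURE_SENSORY_TERMS = {
    "visual": ("bright", "dark", "shiny", "pale", "vivid", "gleaming", "dim",
               "glowing"),
    "auditory": ("loud", "quiet", "shrill", "melodic", "noisy", "hushed",
                 "ringing", "droning"),
    "haptic": ("rough", "smooth", "soft", "sticky", "slick", "coarse",
               "sharp", "heavy"),
    "olfactory": ("fragrant", "musty", "pungent", "perfumed", "smoky",
                  "stale", "scented", "rancid"),
    "gustatory": ("sweet", "sour", "bitter", "salty", "tangy", "savory",
                  "bland", "spicy"),
}


def fixture_lexicons(seed: int) -> tuple[WeightedLexicon, WeightedLexicon]:
    """Small deterministic (particle, sensory) lexicon pair.

    20 particle terms across the four referential categories and 40 sensory
    adjectives across the five modalities, with seed-dependent weights in
    (0, 1].  Structure mirrors the reference tables; weights are synthetic.
    """
    rng = np.random.default_rng(seed)
    ra_rows = [
        (term, cat, round(float(w), 6))
        for cat, terms in _FIXTURE_RA_TERMS.items()
        for term, w in zip(terms, rng.uniform(0.05, 1.0, size=len(terms)))
    ]
    sensory_rows = [
        (term, cat, round(float(w), 6))
        for cat, terms in _FIXTURE_SENSORY_TERMS.items()
        for term, w in zip(terms, rng.uniform(0.05, 1.0, size=len(terms)))
    ]
    return (
        WeightedLexicon.from_rows("ra", ra_rows),
        WeightedLexicon.from_rows("sensory", sensory_rows),
    )
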