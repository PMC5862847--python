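"""Word-accumulation curves for cross-author vocabulary comparison.

Two constructions are provided.  The frequency-group curve treats every
corpus-wide token frequency as one "word group" (a frequency class), orders
the groups, and accumulates the number of distinct types over the first
``n_groups`` groups — the analogue of a species-accumulation curve on a
type-frequency list.  The work-ordered curve orders whole works from
largest to smallest and accumulates the count of types not seen in any
earlier work.  Both curves rise monotonically with a decelerating slope;
the asymptote locator turns the usual eyeball judgement into a relative
marginal-gain rule.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .corpus import Chunk, TokenizerConfig, Work, strip_stage_directions, tokenize

__all__ = [
    "AccumulationCurve",
    "frequency_group_curve",
    "work_ordered_curve",
    "asymptote_index",
]


@dataclass(frozen=True)
class AccumulationCurve:
    """Monotone point series: x strictly increasing, y cumulative types."""

    kind: str  # "frequency_groups" | "work_ordered"
    points: tuple[tuple[float, int], ...]
    total_types: int

    def __post_init__(self) -> None:
        xs = [p[0] for p in self.points]
        ys = [p[1] for p in self.points]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("x must be strictly increasing")
        if any(b < a for a, b in zip(ys, ys[1:])):
            raise ValueError("y must be non-decreasing")

    @property
    def x(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.points)

    @property
    def y(self) -> tuple[int, ...]:
        return tuple(p[1] for p in self.points)

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready table: index, x, y, new_types."""
        ys = self.y
        gains = [ys[0]] + [b - a for a, b in zip(ys, ys[1:])]
        return pd.DataFrame(
            {
                "index": range(1, len(ys) + 1),
                "x": self.x,
                "y": ys,
                "new_types": gains,
            }
        )


def frequency_group_curve(
    corpus_chunks: Iterable[Chunk | Sequence[str]],
    n_groups: int = 100,
    order: str = "group_size",
) -> AccumulationCurve:
    """Accumulate distinct types over the first ``n_groups`` frequency classes.

    Types are grouped by their corpus-wide token frequency (one group per
    distinct frequency value).  ``order="group_size"`` sorts groups by
    ascending number of types per group (ties broken by ascending
    frequency); ``order="frequency"`` sorts by ascending frequency value.
    x is the 1-based group index; y the cumulative type count.
    """
    freq: Counter[str] = Counter()
    for chunk in corpus_chunks:
        tokens = chunk.tokens if isinstance(chunk, Chunk) else chunk
        freq.update(tokens)
    if not freq:
        raise ValueError("empty corpus")
    group_sizes: Counter[int] = Counter(freq.values())  # frequency -> n types
    if order == "group_size":
        ordered = sorted(group_sizes.items(), key=lambda kv: (kv[1], kv[0]))
    elif order == "frequency":
        ordered = sorted(group_sizes.items())
    else:
        raise ValueError(f"unknown group order {order!r}")
    if len(ordered) < n_groups:
        warnings.warn(
            f"only {len(ordered)} distinct frequencies; curve ends early "
            f"(requested {n_groups} groups)",
            stacklevel=2,
        )
    points = []
    cum = 0
    for i, (_freq_value, n_types) in enumerate(ordered[:n_groups], start=1):
        cum += n_types
        points.append((float(i), cum))
    return AccumulationCurve("frequency_groups", tuple(points), len(freq))


def work_ordered_curve(
    works: Sequence[Work | Chunk],
    config: TokenizerConfig | None = None,
) -> AccumulationCurve:
    """New-type accumulation over works ordered largest-first.

    Works are sorted by token count descending (ties broken by input
    order); each point is (cumulative tokens, cumulative count of types not
    introduced by any earlier work).
    """
    if not works:
        raise ValueError("no works given")
    config = config or TokenizerConfig()
    token_lists = []
    for item in works:
        if isinstance(item, Chunk):
            token_lists.append(list(item.tokens))
        else:
            token_lists.append(
                tokenize(strip_stage_directions(item.raw_text, config), config)
            )
    order = sorted(range(len(works)), key=lambda i: -len(token_lists[i]))
    seen: set[str] = set()
    points = []
    cum_tokens = 0
    for i in order:
        tokens = token_lists[i]
        cum_tokens += len(tokens)
        seen.update(tokens)
        points.append((float(cum_tokens), len(seen)))
    return AccumulationCurve("work_ordered", tuple(points), len(seen))


def asymptote_index(curve: AccumulationCurve, rel_gain: float = 0.001) -> int:
    """Smallest 1-based index from which every later gain is negligible.

    The gain at index i is y[i+1] - y[i]; "negligible" means below
    ``rel_gain`` x total_types.  Returns the last index when the curve
    never plateaus.
    """
    ys = curve.y
    if len(ys) < 2:
        raise ValueError("curve needs at least 2 points")
    threshold = rel_gain * curve.total_types
    gains = [b - a for a, b in zip(ys, ys[1:])]  # gains[i-1] = gain at index i
    idx = len(ys)  # never satisfied -> last index
    for i in range(len(gains), 0, -1):
        if gains[i - 1] >= threshold:
            break
        idx = i
    return idx
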