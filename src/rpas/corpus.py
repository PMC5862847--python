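"""Corpus ingestion: manifests, stage-direction stripping, tokenization, chunking.

Works are plain UTF-8 text files listed in a CSV manifest
(``id,title,author,type,year,path``).  Each work is split into analysis
chunks either at title headings (the corpus-design unit) or into fixed-size
token blocks (the resampling unit).  Tokenization is rule-based: tokens are
maximal runs of letters with internal apostrophes/hyphens, so Early Modern
elisions ("'tis", "fix'd", "o'er") survive as single tokens, and punctuation
and symbols are dropped.  Stop words are deliberately retained — the scoring
lexicons are built from function words.
"""

from __future__ import annotations

import csv
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "Work",
    "TokenizerConfig",
    "Chunk",
    "load_corpus",
    "write_corpus",
    "strip_stage_directions",
    "tokenize",
    "chunk_by_heading",
    "rechunk_fixed",
    "CHUNK_TOKEN_CAP",
]

#: Corpus-design cap on chunk size (active-vocabulary comparison breaks down
#: for much larger documents; richness decays toward 0 as N grows).
CHUNK_TOKEN_CAP = 30_000

WORK_TYPES = ("history", "comedy", "tragedy", "poem", "other")

_TYPE_ALIASES = {
    "h": "history",
    "history": "history",
    "c": "comedy",
    "comedy": "comedy",
    "t": "tragedy",
    "tragedy": "tragedy",
    "p": "poem",
    "poem": "poem",
    "other": "other",
    "": "other",
}

#: Default stage-direction patterns: ALL-CAPS speaker prefixes, bracketed
#: actions, and Enter/Exit/Exeunt lines.  These are configuration, not code:
#: editions differ, and the defaults only cover the common conventions.
DEFAULT_STAGE_DIRECTION_PATTERNS = (
    r"^[ \t]*[A-Z][A-Z'\- ]{1,60}\.[ \t]*",   # "HAMLET. To be, or not"
    r"\[[^\]\n]*\]",                           # "[Exeunt]", "[Aside]"
    r"^[ \t]*(?:Enter|Re-enter|Exit|Exeunt)\b[^\n]*$",
)

#: Default title-heading patterns for chunk_by_heading.
DEFAULT_HEADING_PATTERNS = (
    r"^#[ \t]+\S",                 # explicit markers in prepared texts
    r"^[ \t]*ACT[ \t]+[IVXLC\d]+", # act boundaries in play transcriptions
)

# Tokens: optional leading elision apostrophe, letters, internal
# apostrophes/hyphens.  Trailing apostrophes/hyphens never match.
_TOKEN_RE = re.compile(r"'?[^\W\d_]+(?:['\-][^\W\d_]+)*")
_TOKEN_RE_NO_APOS = re.compile(r"[^\W\d_]+(?:\-[^\W\d_]+)*")


@dataclass(frozen=True)
class Work:
    """One titled text with author metadata."""

    id: str
    title: str
    author: str
    work_type: str = "other"
    year: int | None = None
    raw_text: str = ""

    def __post_init__(self) -> None:
        if not self.raw_text:
            raise ValueError(f"work {self.id!r}: raw_text is empty")
        if self.work_type not in WORK_TYPES:
            raise ValueError(
                f"work {self.id!r}: unknown work_type {self.work_type!r}"
            )


@dataclass(frozen=True)
class TokenizerConfig:
    """Text-preparation settings.

    The defaults reproduce the reference preparation: case-folded tokens,
    stage directions removed, no his->its neutering (the neuter possessive
    substitution is opt-in; see :func:`rpas.features.pronoun_score`).
    """

    lowercase: bool = True
    strip_stage_directions: bool = True
    stage_direction_patterns: tuple[str, ...] = DEFAULT_STAGE_DIRECTION_PATTERNS
    neuter_his_as_its: bool = False
    keep_internal_apostrophes: bool = True

    def __post_init__(self) -> None:
        for pat in self.stage_direction_patterns:
            re.compile(pat)  # raises re.error on a bad pattern

    def with_(self, **kw) -> "TokenizerConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class Chunk:
    """A tokenized analysis unit.

    ``N`` is the token count (the document size D in the weighted-lexicon
    scores), ``w`` the distinct-type count, ``freq`` the type->count table.
    """

    chunk_id: int
    work_id: str
    tokens: tuple[str, ...]
    freq: dict[str, int] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("empty chunk")

    @classmethod
    def from_tokens(
        cls, chunk_id: int, work_id: str, tokens: Sequence[str]
    ) -> "Chunk":
        chunk = cls(chunk_id, work_id, tuple(tokens), dict(Counter(tokens)))
        if chunk.N > CHUNK_TOKEN_CAP:
            warnings.warn(
                f"chunk {work_id}:{chunk_id} has {chunk.N} tokens, above the "
                f"{CHUNK_TOKEN_CAP}-token corpus-design cap",
                stacklevel=2,
            )
        return chunk

    @property
    def N(self) -> int:
        return len(self.tokens)

    @property
    def w(self) -> int:
        return len(self.freq)

    def count(self, term: str) -> int:
        return self.freq.get(term, 0)


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("id", "title", "author", "type", "year", "path")


def load_corpus(manifest_path: str | Path, text_root: str | Path | None = None) -> list[Work]:
    """Load every work listed in a CSV manifest, in row order.

    ``path`` entries are resolved against ``text_root`` (default: the
    manifest's directory).  A missing file or duplicate id is a hard error
    naming the offending row.
    """
    manifest_path = Path(manifest_path)
    root = Path(text_root) if text_root is not None else manifest_path.parent
    works: list[Work] = []
    seen: set[str] = set()
    with manifest_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(
                f"manifest {manifest_path}: missing columns {sorted(missing)}"
            )
        for row in reader:
            wid = row["id"].strip()
            if wid in seen:
                raise ValueError(f"manifest row {wid!r}: duplicate id")
            seen.add(wid)
            text_path = root / row["path"].strip()
            if not text_path.is_file():
                raise FileNotFoundError(
                    f"manifest row {wid!r}: text file not found: {text_path}"
                )
            wtype = _TYPE_ALIASES.get(row["type"].strip().lower())
            if wtype is None:
                raise ValueError(
                    f"manifest row {wid!r}: unknown work type {row['type']!r}"
                )
            year = row["year"].strip()
            works.append(
                Work(
                    id=wid,
                    title=row["title"].strip(),
                    author=row["author"].strip(),
                    work_type=wtype,
                    year=int(year) if year else None,
                    raw_text=text_path.read_text(encoding="utf-8"),
                )
            )
    return works


def write_corpus(works: Iterable[Work], out_dir: str | Path) -> Path:
    """Write works as a manifest + one text file per work.

    The layout round-trips through :func:`load_corpus`; used both by the
    synthetic generator and for corpus snapshots.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with manifest.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for work in works:
            fname = f"{work.id}.txt"
            (out_dir / fname).write_text(work.raw_text, encoding="utf-8")
            writer.writerow(
                [
                    work.id,
                    work.title,
                    work.author,
                    work.work_type,
                    "" if work.year is None else work.year,
                    fname,
                ]
            )
    return manifest


# ---------------------------------------------------------------------------
# Text preparation
# ---------------------------------------------------------------------------


def strip_stage_directions(text: str, config: TokenizerConfig | None = None) -> str:
    """Remove speaker titles, bracketed actions, and entrance/exit lines.

    A no-op when ``config.strip_stage_directions`` is off.  Dialogue and
    verse are untouched; matches are replaced by a space so that no two
    words are accidentally glued together.
    """
    config = config or TokenizerConfig()
    if not config.strip_stage_directions:
        return text
    for pat in config.stage_direction_patterns:
        text = re.sub(pat, " ", text, flags=re.MULTILINE)
    return text


def tokenize(
    text: str,
    config: TokenizerConfig | None = None,
    tagger: Callable[[str], Iterable[tuple[str, str]]] | None = None,
) -> list[str]:
    """Tokenize into word tokens; punctuation and symbols are dropped.

    ``tagger`` is an optional hook for an external POS tagger (text ->
    (token, tag) pairs); when given, its token stream is used and then
    filtered/case-folded under the same rules, for parity experiments.
    """
    config = config or TokenizerConfig()
    if tagger is not None:
        raw = (tok for tok, _tag in tagger(text))
        text = " ".join(raw)
    if config.lowercase:
        text = text.lower()
    pattern = _TOKEN_RE if config.keep_internal_apostrophes else _TOKEN_RE_NO_APOS
    return pattern.findall(text)


def chunk_by_heading(
    work: Work,
    config: TokenizerConfig | None = None,
    heading_patterns: Sequence[str] = DEFAULT_HEADING_PATTERNS,
) -> list[Chunk]:
    """Split a work into chunks at title headings.

    Every line matching a heading pattern starts a new chunk (the heading
    line itself stays with its chunk so that token counts are conserved).
    A work with no headings yields one chunk.  Chunk ids are 1-based and
    sequential; empty segments are dropped.
    """
    config = config or TokenizerConfig()
    compiled = [re.compile(p) for p in heading_patterns]
    segments: list[list[str]] = [[]]
    for line in work.raw_text.splitlines(keepends=True):
        if any(p.match(line) for p in compiled) and segments[-1]:
            segments.append([])
        segments[-1].append(line)
    chunks: list[Chunk] = []
    for seg in segments:
        tokens = tokenize(strip_stage_directions("".join(seg), config), config)
        if tokens:
            chunks.append(Chunk.from_tokens(len(chunks) + 1, work.id, tokens))
    return chunks


def rechunk_fixed(
    source: Work | Chunk | Sequence[Work] | Sequence[Chunk] | Sequence[str],
    size: int,
    config: TokenizerConfig | None = None,
) -> list[Chunk]:
    """Re-chunk a token pool into consecutive blocks of exactly ``size`` tokens.

    ``source`` may be a Work, a Chunk, a list of either, or a raw token
    list; token order is preserved and the trailing remainder (< size) is
    discarded, so the result has floor(total/size) chunks.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    tokens, work_id = _pool_tokens(source, config)
    n_chunks = len(tokens) // size
    return [
        Chunk.from_tokens(i + 1, work_id, tokens[i * size : (i + 1) * size])
        for i in range(n_chunks)
    ]


def _pool_tokens(source, config: TokenizerConfig | None) -> tuple[list[str], str]:
    config = config or TokenizerConfig()
    if isinstance(source, Work):
        return tokenize(strip_stage_directions(source.raw_text, config), config), source.id
    if isinstance(source, Chunk):
        return list(source.tokens), source.work_id
    source = list(source)
    if not source:
        return [], "pool"
    if isinstance(source[0], str):
        return list(source), "pool"  # raw token list
    tokens: list[str] = []
    ids: list[str] = []
    for item in source:
        part, wid = _pool_tokens(item, config)
        tokens.extend(part)
        ids.append(wid)
    work_id = ids[0] if len(set(ids)) == 1 else "pool"
    return tokens, work_id
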