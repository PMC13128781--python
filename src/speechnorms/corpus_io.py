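"""Transcript reading, cleaning, and tokenization.

Speech-corpus transcripts arrive either as Praat TextGrid files (interval
tiers whose ``text`` property holds what was said) or as plain UTF-8 text.
This module extracts the raw text spans, applies the cleaning conventions
used when building spoken-corpus frequency norms — angle-bracketed spans
(speaker names, unintelligible stretches) are deleted outright, hyphenated
compounds are split into their components, and punctuation, digits, and
out-of-alphabet characters are stripped — and emits tokenized
:class:`Document` objects, the unit over which contextual diversity is
counted (one file = one document).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "CleaningConfig",
    "RawTranscript",
    "Document",
    "TextGridParseError",
    "EmptyTranscriptError",
    "parse_textgrid",
    "parse_plaintext",
    "write_textgrid",
    "clean_text",
    "tokenize",
    "to_document",
    "load_documents",
    "write_documents_jsonl",
    "read_documents_jsonl",
]


class TextGridParseError(ValueError):
    """Raised when a TextGrid file cannot be parsed; names the offending line."""


class EmptyTranscriptError(ValueError):
    """Raised when a transcript contains no interval tier or no intervals."""


@dataclass(frozen=True)
class CleaningConfig:
    """Text cleaning policy.

    Parameters
    ----------
    alphabet:
        Characters allowed to survive into tokens. Defaults to the 26 ASCII
        lowercase letters; accented Latin and non-Latin characters are
        treated as out-of-alphabet and replaced by a space.
    unclosed_bracket:
        Policy for a ``<`` with no matching ``>``: ``"drop"`` deletes from
        the ``<`` to the end of the span and emits a warning; ``"error"``
        raises ``ValueError``.
    """

    alphabet: str = "abcdefghijklmnopqrstuvwxyz"
    unclosed_bracket: str = "drop"

    def __post_init__(self) -> None:
        if self.unclosed_bracket not in ("drop", "error"):
            raise ValueError(
                f"unclosed_bracket must be 'drop' or 'error', got {self.unclosed_bracket!r}"
            )
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")


DEFAULT_CONFIG = CleaningConfig()


@dataclass(frozen=True)
class RawTranscript:
    """One transcript file before cleaning: ordered raw text spans."""

    source_id: str
    intervals: tuple[str, ...]


@dataclass(frozen=True)
class Document:
    """One cleaned, tokenized transcript — the contextual-diversity unit."""

    source_id: str
    tokens: tuple[str, ...]
    part_label: str | None = None


# ---------------------------------------------------------------------------
# TextGrid reading / writing
# ---------------------------------------------------------------------------

_QUOTED = re.compile(r'"((?:[^"]|"")*)"')


def _unquote(s: str) -> str:
    # Praat escapes a literal double quote by doubling it.
    return s.replace('""', '"')


def parse_textgrid(path: str | Path) -> RawTranscript:
    """Parse a Praat TextGrid (long or short dialect) into a RawTranscript.

    Only the ``text`` property of intervals on interval tiers is kept;
    times, tier names and point tiers are discarded. The spans of all
    interval tiers are returned in file order.

    Raises
    ------
    TextGridParseError
        If the file is not a well-formed TextGrid (the message names the
        offending line number).
    EmptyTranscriptError
        If the file holds no interval tier or zero intervals.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    stripped = [ln.strip() for ln in lines]
    if not any("ooTextFile" in ln for ln in stripped[:3]):
        raise TextGridParseError(f"{path}: line 1: not an ooTextFile TextGrid header")
    if not any("TextGrid" in ln for ln in stripped[:3]):
        raise TextGridParseError(f"{path}: line 2: object class is not TextGrid")

    is_long = any(ln.startswith("xmin") for ln in stripped[:8])
    spans = _parse_long(path, stripped) if is_long else _parse_short(path, stripped)
    if spans is None:
        raise EmptyTranscriptError(f"{path}: no interval tier found")
    if not spans:
        raise EmptyTranscriptError(f"{path}: interval tier has zero intervals")
    return RawTranscript(source_id=path.stem, intervals=tuple(spans))


def _parse_long(path: Path, stripped: list[str]) -> list[str] | None:
    spans: list[str] = []
    saw_tier = False
    in_interval_tier = False
    for i, ln in enumerate(stripped):
        if ln.startswith("class"):
            m = _QUOTED.search(ln)
            if m is None:
                raise TextGridParseError(f"{path}: line {i + 1}: malformed class line")
            in_interval_tier = _unquote(m.group(1)) == "IntervalTier"
            saw_tier = saw_tier or in_interval_tier
        elif in_interval_tier and ln.startswith("text"):
            m = _QUOTED.search(ln)
            if m is None:
                raise TextGridParseError(f"{path}: line {i + 1}: malformed text line")
            spans.append(_unquote(m.group(1)))
    return spans if saw_tier else None


def _parse_short(path: Path, stripped: list[str]) -> list[str] | None:
    # Short format: after the 2-line header come xmin, xmax, "<exists>",
    # n_tiers, then per tier: "IntervalTier"/"TextTier", name, xmin, xmax,
    # n, then n items (intervals: xmin, xmax, text; points: time, mark).
    body = [ln for ln in stripped[2:] if ln != ""]
    pos = 0

    def take(what: str) -> str:
        nonlocal pos
        if pos >= len(body):
            raise TextGridParseError(f"{path}: unexpected end of file while reading {what}")
        val = body[pos]
        pos += 1
        return val

    def take_num(what: str) -> float:
        val = take(what)
        try:
            return float(val)
        except ValueError:
            raise TextGridParseError(f"{path}: expected number for {what}, got {val!r}") from None

    take_num("global xmin")
    take_num("global xmax")
    take("tiers flag")
    n_tiers = int(take_num("tier count"))
    spans: list[str] = []
    saw_tier = False
    for _ in range(n_tiers):
        klass = _unquote(take("tier class").strip('"'))
        take("tier name")
        take_num("tier xmin")
        take_num("tier xmax")
        n_items = int(take_num("item count"))
        if klass == "IntervalTier":
            saw_tier = True
            for _ in range(n_items):
                take_num("interval xmin")
                take_num("interval xmax")
                text = take("interval text")
                m = _QUOTED.fullmatch(text)
                if m is None:
                    raise TextGridParseError(f"{path}: malformed interval text {text!r}")
                spans.append(_unquote(m.group(1)))
        else:  # point tier: time + mark per item
            for _ in range(n_items):
                take_num("point time")
                take("point mark")
    return spans if saw_tier else None


def write_textgrid(
    path: str | Path,
    intervals: Sequence[str],
    tier_name: str = "words",
    short: bool = False,
) -> None:
    """Write interval texts as a minimal one-tier TextGrid (unit interval times)."""
    path = Path(path)
    n = len(intervals)
    xmax = float(max(n, 1))

    def q(s: str) -> str:
        return '"' + s.replace('"', '""') + '"'

    out: list[str] = []
    if short:
        out += ['File type = "ooTextFile"', 'Object class = "TextGrid"', "",
                "0", str(xmax), "<exists>", "1", '"IntervalTier"', q(tier_name),
                "0", str(xmax), str(n)]
        for i, text in enumerate(intervals):
            out += [str(float(i)), str(float(i + 1)), q(text)]
    else:
        out += ['File type = "ooTextFile"', 'Object class = "TextGrid"', "",
                "xmin = 0", f"xmax = {xmax}", "tiers? <exists>", "size = 1",
                "item []:", "    item [1]:", '        class = "IntervalTier"',
                f"        name = {q(tier_name)}", "        xmin = 0",
                f"        xmax = {xmax}", f"        intervals: size = {n}"]
        for i, text in enumerate(intervals):
            out += [f"        intervals [{i + 1}]:", f"            xmin = {float(i)}",
                    f"            xmax = {float(i + 1)}", f"            text = {q(text)}"]
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


def parse_plaintext(path: str | Path) -> RawTranscript:
    """Read a UTF-8 plain-text transcript; each line becomes one span."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise EmptyTranscriptError(f"{path}: empty transcript")
    return RawTranscript(source_id=path.stem, intervals=tuple(lines))


# ---------------------------------------------------------------------------
# Cleaning and tokenization
# ---------------------------------------------------------------------------

_BRACKET_SPAN = re.compile(r"<[^<>]*>")


def clean_text(raw: str, config: CleaningConfig = DEFAULT_CONFIG) -> str:
    """Apply the cleaning rules to one raw text span.

    Order matters: angle-bracketed spans (bracket plus contents) are deleted
    first, so ``"<unk>"`` cannot leak ``"unk"`` into the token stream. The
    remainder is lowercased and every character outside the configured
    alphabet — punctuation, digits, hyphens, apostrophes, non-English
    letters — is replaced by a space, which means hyphenated compounds
    split into their components and contractions split at the apostrophe
    ("doesn't" -> "doesn t"). The function is idempotent.
    """
    text = raw
    # Innermost-first removal handles (rare) nested brackets.
    while True:
        new = _BRACKET_SPAN.sub(" ", text)
        if new == text:
            break
        text = new
    if "<" in text:
        if config.unclosed_bracket == "error":
            raise ValueError(f"unclosed '<' in span: {raw!r}")
        warnings.warn(f"unclosed '<' in span; dropping tail: {raw!r}", stacklevel=2)
        text = text[: text.index("<")]
    # A stray '>' has no matching '<'; it falls through to character
    # filtering below like any other punctuation.
    text = text.lower()
    allowed = frozenset(config.alphabet)
    return "".join(ch if ch in allowed else " " for ch in text)


def tokenize(cleaned: str) -> tuple[str, ...]:
    """Split cleaned text on whitespace runs, dropping empty tokens."""
    return tuple(cleaned.split())


def to_document(
    raw: RawTranscript,
    config: CleaningConfig = DEFAULT_CONFIG,
    part_label: str | None = None,
) -> Document:
    """Clean and tokenize a transcript into a Document."""
    tokens: list[str] = []
    for span in raw.intervals:
        tokens.extend(tokenize(clean_text(span, config)))
    return Document(source_id=raw.source_id, tokens=tuple(tokens), part_label=part_label)


def _read_any(path: Path) -> RawTranscript:
    if path.suffix.lower() == ".textgrid":
        return parse_textgrid(path)
    return parse_plaintext(path)


def load_documents(
    paths: Iterable[str | Path],
    config: CleaningConfig = DEFAULT_CONFIG,
    part_label: str | None = None,
) -> Iterator[Document]:
    """Stream Documents from TextGrid (*.TextGrid) or plain-text files."""
    for p in paths:
        yield to_document(_read_any(Path(p)), config=config, part_label=part_label)


def write_documents_jsonl(documents: Iterable[Document], path: str | Path) -> int:
    """Write documents as JSON lines ({source_id, part_label, tokens}); returns count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(json.dumps({
                "source_id": doc.source_id,
                "part_label": doc.part_label,
                "tokens": list(doc.tokens),
            }) + "\n")
            n += 1
    return n


def read_documents_jsonl(path: str | Path) -> Iterator[Document]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            yield Document(
                source_id=rec["source_id"],
                tokens=tuple(rec["tokens"]),
                part_label=rec.get("part_label"),
            )
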