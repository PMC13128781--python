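"""Word frequency and contextual diversity norms.

Builds a per-word norm table from a stream of tokenized documents:

* ``raw_count`` — token occurrences in the corpus;
* ``zipf`` — the Zipf-scale standardized frequency,
  ``log10((raw_count + 1) / (n_tokens/1e6 + n_types/1e6)) + 3``,
  a log frequency-per-billion-like scale running roughly 1-7 that is
  comparable across corpora of different sizes and is defined for words
  with zero occurrences;
* ``cd_count`` / ``cd_percent`` — contextual diversity: the number
  (respectively percentage) of distinct documents containing the word.

Also provides cross-corpus machinery: inner joins of norm tables with
overlap (Venn-cell) counts, and pairwise Pearson correlations of Zipf or
log10 CD between corpora.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .corpus_io import Document

__all__ = [
    "CorpusStats",
    "NormTable",
    "MergedNorms",
    "NSC_PART_TOKEN_COUNTS",
    "NSC_PART_DOCUMENT_COUNTS",
    "NSC_STATS",
    "count_norms",
    "zipf_value",
    "merge_tables",
    "cross_corpus_correlation",
    "write_norms_csv",
    "read_norms_csv",
]


@dataclass(frozen=True)
class CorpusStats:
    """Corpus-level totals that parameterize the Zipf transform."""

    n_tokens: int
    n_types: int
    n_documents: int

    def __post_init__(self) -> None:
        if self.n_tokens < self.n_types:
            raise ValueError("n_types cannot exceed n_tokens")
        if self.n_documents < 1:
            raise ValueError("corpus must contain at least one document")

    @property
    def zipf_denominator(self) -> float:
        """Tokens plus types, in millions — the Zipf denominator."""
        return self.n_tokens / 1e6 + self.n_types / 1e6


#: Published token counts of the three conversational parts of Singapore's
#: National Speech Corpus (NSC) used for norm construction, and the totals
#: they imply. Kept here so corpus bookkeeping is checkable without the
#: (licensed) corpus itself.
NSC_PART_TOKEN_COUNTS: Mapping[str, int] = {
    "PART3": 10_050_459,
    "PART5": 10_343_605,
    "PART6": 10_854_628,
}
NSC_PART_DOCUMENT_COUNTS: Mapping[str, int] = {
    "PART3": 911,
    "PART5": 6_000,
    "PART6": 11_982,
}
NSC_STATS = CorpusStats(
    n_tokens=31_248_692,
    n_types=56_679,
    n_documents=sum(NSC_PART_DOCUMENT_COUNTS.values()),
)


def zipf_value(
    raw_count: int | float | np.ndarray,
    stats: CorpusStats,
    denominator: float | None = None,
) -> float | np.ndarray:
    """Zipf-scale frequency for a raw token count under the given corpus totals.

    Parameters
    ----------
    raw_count:
        Token count(s), >= 0. Zero is allowed (unseen words get the corpus's
        floor Zipf value via Laplace-style add-one smoothing).
    stats:
        Corpus totals; the denominator is ``n_tokens/1e6 + n_types/1e6``.
    denominator:
        Optional explicit denominator in millions, overriding the one
        derived from ``stats`` (for reproducing published tables that used
        a rounded constant).
    """
    counts = np.asarray(raw_count, dtype=float)
    if np.any(counts < 0):
        raise ValueError("raw_count must be non-negative")
    denom = stats.zipf_denominator if denominator is None else denominator
    out = np.log10((counts + 1.0) / denom) + 3.0
    return float(out) if np.isscalar(raw_count) or counts.ndim == 0 else out


@dataclass
class NormTable:
    """Per-word norms for one corpus.

    ``frame`` is indexed by lowercase word type with columns
    ``raw_count``, ``zipf``, ``cd_count``, ``cd_percent``.
    """

    label: str
    stats: CorpusStats
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"raw_count", "zipf", "cd_count", "cd_percent"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"norm frame missing columns: {sorted(missing)}")
        if not self.frame.index.is_unique:
            raise ValueError("norm frame has duplicate word types")

    @property
    def words(self) -> frozenset[str]:
        return frozenset(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


def count_norms(documents: Iterable[Document], label: str = "corpus") -> NormTable:
    """Count raw frequency and contextual diversity over a document stream.

    A word's ``cd_count`` is the number of distinct documents (by position
    in the stream, not ``source_id``) in which it occurs at least once;
    ``cd_percent`` scales that by the total number of documents.
    """
    token_counts: Counter[str] = Counter()
    doc_counts: Counter[str] = Counter()
    n_documents = 0
    for doc in documents:
        n_documents += 1
        token_counts.update(doc.tokens)
        doc_counts.update(set(doc.tokens))
    if n_documents == 0:
        raise ValueError("empty document stream")

    words = sorted(token_counts)
    raw = np.array([token_counts[w] for w in words], dtype=np.int64)
    cd = np.array([doc_counts[w] for w in words], dtype=np.int64)
    stats = CorpusStats(
        n_tokens=int(raw.sum()), n_types=len(words), n_documents=n_documents
    )
    frame = pd.DataFrame(
        {
            "raw_count": raw,
            "zipf": zipf_value(raw, stats),
            "cd_count": cd,
            "cd_percent": 100.0 * cd / n_documents,
        },
        index=pd.Index(words, name="word"),
    )
    return NormTable(label=label, stats=stats, frame=frame)


@dataclass
class MergedNorms:
    """Inner join of >= 2 norm tables on word type, with overlap counts.

    ``frame`` has a column ``{label}_{measure}`` per table and measure;
    ``pairwise_overlap`` maps unordered label pairs to shared-type counts;
    ``all_overlap`` is the count of words present in every table.
    """

    labels: tuple[str, ...]
    frame: pd.DataFrame
    pairwise_overlap: dict[frozenset[str], int]
    all_overlap: int


def merge_tables(tables: list[NormTable]) -> MergedNorms:
    """Inner-join norm tables on word; report pairwise and all-way overlaps."""
    if len(tables) < 2:
        raise ValueError("need at least two tables to merge")
    labels = [t.label for t in tables]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate table labels: {labels}")

    word_sets = {t.label: t.words for t in tables}
    pairwise = {
        frozenset((a, b)): len(word_sets[a] & word_sets[b])
        for a, b in itertools.combinations(labels, 2)
    }
    shared = frozenset.intersection(*word_sets.values())

    pieces = []
    for t in tables:
        sub = t.frame.loc[sorted(shared)].copy()
        sub.columns = [f"{t.label}_{c}" for c in sub.columns]
        pieces.append(sub)
    frame = pd.concat(pieces, axis=1)
    return MergedNorms(
        labels=tuple(labels),
        frame=frame,
        pairwise_overlap=pairwise,
        all_overlap=len(shared),
    )


def cross_corpus_correlation(
    merged: MergedNorms, measure: str = "zipf"
) -> dict[tuple[str, str], float]:
    """Pairwise Pearson correlation of a norm measure across corpora.

    ``measure`` is ``"zipf"`` or ``"log10_cd"`` (log10 of the CD count,
    defined because every shared word occurs in >= 1 document per corpus).
    """
    if measure not in ("zipf", "log10_cd"):
        raise ValueError(f"unknown measure {measure!r}")
    if len(merged.frame) < 3:
        raise ValueError("need at least 3 shared words for a correlation")

    def series(label: str) -> np.ndarray:
        if measure == "zipf":
            return merged.frame[f"{label}_zipf"].to_numpy()
        return np.log10(merged.frame[f"{label}_cd_count"].to_numpy(dtype=float))

    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(merged.labels, 2):
        x, y = series(a), series(b)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"zero variance in {measure} for pair ({a}, {b})")
        out[(a, b)] = float(sps.pearsonr(x, y).statistic)
    return out


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def write_norms_csv(
    table: NormTable,
    path: str | Path,
    prefix: str | None = None,
    zipf_decimals: int | None = None,
) -> None:
    """Export a norm table with database-style column names.

    Columns are ``word, {P}_rawcount, {P}_Zipf, {P}_CDcount, {P}_CD`` where
    ``P`` defaults to the table label. ``zipf_decimals`` rounds the Zipf
    column for presentation (internally full precision is kept).
    """
    p = prefix if prefix is not None else table.label
    zipf = table.frame["zipf"]
    if zipf_decimals is not None:
        zipf = zipf.round(zipf_decimals)
    out = pd.DataFrame(
        {
            f"{p}_rawcount": table.frame["raw_count"],
            f"{p}_Zipf": zipf,
            f"{p}_CDcount": table.frame["cd_count"],
            f"{p}_CD": table.frame["cd_percent"],
        },
        index=table.frame.index,
    )
    out.to_csv(path, index_label="word")


def read_norms_csv(
    path: str | Path,
    label: str,
    word_col: str = "word",
    count_col: str | None = None,
    cd_col: str | None = None,
    n_documents: int | None = None,
) -> NormTable:
    """Read an external norm table (word / frequency count / CD count CSV).

    Column names are configurable; by default the database-style names
    ``{label}_rawcount`` and ``{label}_CDcount`` are assumed. Corpus totals
    for the Zipf transform are recovered from the counts themselves
    (n_tokens = sum of counts, n_types = number of rows); ``n_documents``
    must be given to compute CD percentages unless a ``{label}_CD`` column
    exists alongside the counts, otherwise the maximum CD count is used as
    a lower-bound stand-in.
    """
    df = pd.read_csv(path)
    count_col = count_col or f"{label}_rawcount"
    cd_col = cd_col or f"{label}_CDcount"
    for col in (word_col, count_col, cd_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.set_index(word_col)
    raw = df[count_col].to_numpy(dtype=np.int64)
    cd = df[cd_col].to_numpy(dtype=np.int64)
    if n_documents is None:
        cd_pct_col = f"{label}_CD"
        if cd_pct_col in df.columns and (df[cd_pct_col] > 0).any():
            ratio = cd / df[cd_pct_col].to_numpy(dtype=float)
            n_documents = int(round(100.0 * np.nanmedian(np.where(cd > 0, ratio, np.nan))))
        else:
            n_documents = int(cd.max())
    stats = CorpusStats(n_tokens=int(raw.sum()), n_types=len(df), n_documents=n_documents)
    frame = pd.DataFrame(
        {
            "raw_count": raw,
            "zipf": zipf_value(raw, stats),
            "cd_count": cd,
            "cd_percent": 100.0 * cd / n_documents,
        },
        index=df.index.rename("word"),
    )
    return NormTable(label=label, stats=stats, frame=frame)
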