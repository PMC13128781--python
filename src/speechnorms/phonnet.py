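"""Phonological neighborhood networks and neighborhood density (PND).

Two phonological neighbors are pronunciations that differ by exactly one
phoneme addition, deletion, or substitution (phoneme-level Levenshtein
distance 1, phoneme symbols compared as atomic tokens). Two network
variants are built over a pronunciation lexicon:

* **word-based** — nodes are words; an edge joins two distinct words when
  *any* pronunciation of one is a one-phoneme neighbor of *any*
  pronunciation of the other. PND is the word's degree.
* **pronunciation-based** — nodes are distinct pronunciation strings; edges
  join neighboring pronunciations. A word's score is the mean degree of its
  pronunciation nodes, so variants of the same word may be mutually linked.

By default homophones (distance-0 pronunciations of different words) are
*not* neighbors, and a pronunciation shared by several words is a single
node whose degree each such word inherits; both choices are configurable.

Neighbor search uses a deletion-form index (hashing each pronunciation's
single-deletion variants) for near-linear scaling; the quadratic all-pairs
path is retained as an oracle.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Pronunciation",
    "PronLexicon",
    "is_one_phoneme_neighbor",
    "build_word_network",
    "build_pron_network",
    "compute_pnd",
    "write_pnd_csv",
]

#: A pronunciation is an ordered tuple of phoneme symbols, e.g. ("EH", "K", "T").
Pronunciation = tuple[str, ...]


@dataclass(frozen=True)
class PronLexicon:
    """Word -> deduplicated list of pronunciations."""

    entries: Mapping[str, tuple[Pronunciation, ...]]

    def __post_init__(self) -> None:
        for word, prons in self.entries.items():
            if not prons:
                raise ValueError(f"word {word!r} has no pronunciations")
            for p in prons:
                if not p:
                    raise ValueError(f"word {word!r} has an empty pronunciation")

    @staticmethod
    def from_dict(raw: Mapping[str, Iterable[Sequence[str]]]) -> "PronLexicon":
        entries: dict[str, tuple[Pronunciation, ...]] = {}
        for word, prons in raw.items():
            seen: list[Pronunciation] = []
            for p in prons:
                tp = tuple(p)
                if tp not in seen:
                    seen.append(tp)
            entries[word] = tuple(seen)
        return PronLexicon(entries=entries)

    @staticmethod
    def from_file(path: str | Path) -> "PronLexicon":
        """Read a dictionary file: ``word<TAB>PH ON EMES``, one variant per row.

        Lines starting with ``#`` and blank lines are skipped. Multiple rows
        for the same word accumulate as pronunciation variants.
        """
        raw: dict[str, list[Sequence[str]]] = defaultdict(list)
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "\t" not in line:
                    raise ValueError(f"{path}: line {lineno}: expected 'word<TAB>phonemes'")
                word, phon = line.split("\t", 1)
                phonemes = phon.split()
                if not word or not phonemes:
                    raise ValueError(f"{path}: line {lineno}: empty word or pronunciation")
                raw[word].append(phonemes)
        if not raw:
            raise ValueError(f"{path}: empty lexicon")
        return PronLexicon.from_dict(raw)

    @staticmethod
    def from_csv(path: str | Path, word_col: str = "word", pron_col: str = "pronunciation") -> "PronLexicon":
        raw: dict[str, list[Sequence[str]]] = defaultdict(list)
        with open(path, encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                raw[row[word_col]].append(row[pron_col].split())
        if not raw:
            raise ValueError(f"{path}: empty lexicon")
        return PronLexicon.from_dict(raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for word in sorted(self.entries):
                for pron in self.entries[word]:
                    fh.write(f"{word}\t{' '.join(pron)}\n")

    def distinct_pronunciations(self) -> list[Pronunciation]:
        seen: dict[Pronunciation, None] = {}
        for prons in self.entries.values():
            for p in prons:
                seen.setdefault(p)
        return list(seen)

    def __len__(self) -> int:
        return len(self.entries)


def is_one_phoneme_neighbor(p: Sequence[str], q: Sequence[str]) -> bool:
    """True iff p and q differ by exactly one phoneme edit (add/delete/substitute).

    Equivalently, phoneme-level Levenshtein distance with unit costs equals
    exactly 1; identical pronunciations (distance 0) are *not* neighbors.
    """
    p, q = tuple(p), tuple(q)
    lp, lq = len(p), len(q)
    if abs(lp - lq) > 1:
        return False
    if lp == lq:
        return sum(a != b for a, b in zip(p, q)) == 1
    if lp > lq:
        p, q, lp, lq = q, p, lq, lp
    # q is one phoneme longer: neighbor iff deleting one symbol of q gives p
    i = 0
    while i < lp and p[i] == q[i]:
        i += 1
    return p[i:] == q[i + 1:]


def _neighbor_pron_pairs(prons: list[Pronunciation]) -> set[tuple[int, int]]:
    """Index pairs (i < j) of one-phoneme-neighbor pronunciations.

    Deletion-form index: an insertion/deletion pair shares a full form and a
    deletion variant; a substitution pair shares a deletion variant *at the
    same position*. Candidates are verified with the exact predicate.
    """
    exact: dict[Pronunciation, list[int]] = defaultdict(list)
    by_deletion: dict[Pronunciation, list[int]] = defaultdict(list)
    by_pos_deletion: dict[tuple[int, Pronunciation], list[int]] = defaultdict(list)
    for idx, p in enumerate(prons):
        exact[p].append(idx)
        for i in range(len(p)):
            reduced = p[:i] + p[i + 1:]
            by_deletion[reduced].append(idx)
            by_pos_deletion[(i, reduced)].append(idx)

    pairs: set[tuple[int, int]] = set()

    def add(i: int, j: int) -> None:
        if i != j and is_one_phoneme_neighbor(prons[i], prons[j]):
            pairs.add((min(i, j), max(i, j)))

    for idx, p in enumerate(prons):
        # longer neighbors: those with a deletion variant equal to p
        for j in by_deletion.get(p, ()):
            add(idx, j)
        for i in range(len(p)):
            reduced = p[:i] + p[i + 1:]
            # shorter neighbors: full forms equal to a deletion variant of p
            for j in exact.get(reduced, ()):
                add(idx, j)
            # substitution neighbors: same-position deletion variant shared
            for j in by_pos_deletion.get((i, reduced), ()):
                add(idx, j)
    return pairs


def _neighbor_pron_pairs_brute(prons: list[Pronunciation]) -> set[tuple[int, int]]:
    return {
        (i, j)
        for i in range(len(prons))
        for j in range(i + 1, len(prons))
        if is_one_phoneme_neighbor(prons[i], prons[j])
    }


def build_word_network(
    lex: PronLexicon,
    link_homophones: bool = False,
    brute_force: bool = False,
) -> nx.Graph:
    """Word-based phonological network: nodes are words, PND is node degree.

    Two distinct words are linked when any pronunciation of one is a
    one-phoneme neighbor of any pronunciation of the other (all variants of
    a multi-pronunciation word contribute). No self-loops, even when a
    word's own variants are neighbors of each other. With
    ``link_homophones=True``, words sharing an identical pronunciation are
    also linked.
    """
    if not len(lex):
        raise ValueError("empty lexicon")
    prons = lex.distinct_pronunciations()
    pron_index = {p: i for i, p in enumerate(prons)}
    words_of: dict[int, list[str]] = defaultdict(list)
    for word, wprons in lex.entries.items():
        for p in wprons:
            words_of[pron_index[p]].append(word)

    finder = _neighbor_pron_pairs_brute if brute_force else _neighbor_pron_pairs
    g = nx.Graph(kind="word_based")
    g.add_nodes_from(lex.entries)
    for i, j in finder(prons):
        for w1 in words_of[i]:
            for w2 in words_of[j]:
                if w1 != w2:
                    g.add_edge(w1, w2)
    if link_homophones:
        for idx, sharers in words_of.items():
            for a in range(len(sharers)):
                for b in range(a + 1, len(sharers)):
                    g.add_edge(sharers[a], sharers[b])
    return g


def build_pron_network(lex: PronLexicon, brute_force: bool = False) -> nx.Graph:
    """Pronunciation-based network: nodes are distinct pronunciation strings.

    Node labels are space-joined phoneme sequences; edges join one-phoneme
    neighbors. Variants of the same word may be mutually connected here.
    """
    if not len(lex):
        raise ValueError("empty lexicon")
    prons = lex.distinct_pronunciations()
    finder = _neighbor_pron_pairs_brute if brute_force else _neighbor_pron_pairs
    g = nx.Graph(kind="pronunciation_based")
    g.add_nodes_from(" ".join(p) for p in prons)
    for i, j in finder(prons):
        g.add_edge(" ".join(prons[i]), " ".join(prons[j]))
    return g


def compute_pnd(
    lex: PronLexicon,
    word_network: nx.Graph | None = None,
    pron_network: nx.Graph | None = None,
) -> pd.DataFrame:
    """Per-word neighborhood measures from both network variants.

    Returns a frame indexed by word with columns ``pnd_word`` (degree in
    the word network), ``pnd_pron`` (mean degree of the word's
    pronunciation nodes), and ``n_phonemes_mean`` (mean pronunciation
    length across the word's variants).
    """
    if word_network is None:
        word_network = build_word_network(lex)
    if pron_network is None:
        pron_network = build_pron_network(lex)

    words = sorted(lex.entries)
    rows = []
    for word in words:
        if word not in word_network:
            raise KeyError(f"word {word!r} missing from word network")
        prons = lex.entries[word]
        pron_degrees = []
        for p in prons:
            key = " ".join(p)
            if key not in pron_network:
                raise KeyError(f"pronunciation {key!r} of {word!r} missing from network")
            pron_degrees.append(pron_network.degree[key])
        rows.append(
            {
                "pnd_word": word_network.degree[word],
                "pnd_pron": sum(pron_degrees) / len(pron_degrees),
                "n_phonemes_mean": sum(len(p) for p in prons) / len(prons),
            }
        )
    return pd.DataFrame(rows, index=pd.Index(words, name="word"))


def write_pnd_csv(pnd: pd.DataFrame, path: str | Path) -> None:
    """Export with database-style column names (PND_word, PND_pronoun, number_of_phoneme)."""
    out = pnd.rename(
        columns={
            "pnd_word": "PND_word",
            "pnd_pron": "PND_pronoun",
            "n_phonemes_mean": "number_of_phoneme",
        }
    )
    out.to_csv(path, index_label="word")
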