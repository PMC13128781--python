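"""Synthetic transcripts, lexicons, and behavioral trials with known ground truth.

Real speech corpora and lexical-decision megastudies are licensed
downloads, so every pipeline stage is exercised against generated data
whose ground truth is emitted alongside:

* :func:`gen_corpus` — documents of CV-syllable pseudowords whose type
  frequencies follow a rank-frequency power law, rendered into messy
  TextGrid / plain-text transcripts (injected punctuation, digits,
  angle-bracketed speaker names, hyphenated compounds, random casing).
  The generator keeps the clean token lists, so the cleaning pipeline can
  be checked for exact count recovery.
* :func:`gen_lexicon` — a pronunciation lexicon with controllable length
  distribution, multi-pronunciation rate, and planted single-edit
  neighbors; ground-truth neighbor structure is computed by brute force
  during generation.
* :func:`gen_trials` — trial-level lexical decision data simulated from a
  known mixed model (Gaussian reaction times, logistic accuracy, crossed
  participant/item random intercepts), with optional injected RT outliers
  to exercise the trial filter.

All randomness in a generator flows from the single ``seed`` in its spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Document, write_textgrid
from .norms import NormTable
from .phonnet import PronLexicon, Pronunciation, is_one_phoneme_neighbor

__all__ = [
    "CorpusSpec",
    "LexiconSpec",
    "TrialSpec",
    "NormTableSpec",
    "CorpusGroundTruth",
    "LexiconGroundTruth",
    "gen_corpus",
    "gen_lexicon",
    "gen_trials",
    "gen_norm_table",
    "add_noisy_predictor",
]

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
#: Angle-bracket "names" are drawn from a token set disjoint from the
#: CV-syllable vocabulary (they contain 'w'/'x'/'q', which the syllable
#: alphabet never produces), so any bracket leakage is detectable downstream.
_BRACKET_NAMES = ("WXQSPKR", "WXQNAME", "WXQUNK", "WXQHOST")
_PUNCT = ",.!?;:'\""


# ---------------------------------------------------------------------------
# Transcript corpus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of the synthetic transcript corpus.

    ``zipf_exponent`` is the rank-frequency power-law exponent (1.0 gives
    classic Zipfian structure, exercising the full dynamic range of the
    Zipf transform). Messiness rates are per-token probabilities of the
    corresponding noise injection.
    """

    n_documents: int = 40
    vocabulary_size: int = 500
    tokens_per_document: int = 400
    zipf_exponent: float = 1.0
    p_punctuation: float = 0.1
    p_digit: float = 0.05
    p_bracket_name: float = 0.05
    p_hyphen: float = 0.05
    p_capitalize: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_punctuation", "p_digit", "p_bracket_name", "p_hyphen", "p_capitalize"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class CorpusGroundTruth:
    """What the generator actually put into the transcripts."""

    documents: list[Document]             # clean token streams, one per file
    paths: list[Path]                     # written transcript files
    token_counts: dict[str, int]          # type -> raw count over the corpus
    doc_counts: dict[str, int]            # type -> number of documents containing it

    def write_json(self, path: str | Path) -> None:
        payload = {
            "documents": [
                {"source_id": d.source_id, "tokens": list(d.tokens)}
                for d in self.documents
            ],
            "token_counts": self.token_counts,
            "doc_counts": self.doc_counts,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")


def _make_vocabulary(rng: np.random.Generator, size: int) -> list[str]:
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < size:
        n_syll = int(rng.integers(1, 4))
        w = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def _render_messy(tokens: Sequence[str], spec: CorpusSpec, rng: np.random.Generator) -> str:
    """Render clean tokens into noisy transcript text.

    Every injected artifact is one the cleaning rules remove without
    touching the underlying tokens: attached punctuation, standalone digit
    runs, angle-bracketed names, hyphen-joined adjacent tokens, casing.
    """
    out: list[str] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if rng.random() < spec.p_capitalize:
            tok = tok.capitalize()
        if rng.random() < spec.p_hyphen and i + 1 < len(tokens):
            nxt = tokens[i + 1]
            if rng.random() < spec.p_capitalize:
                nxt = nxt.capitalize()
            tok = f"{tok}-{nxt}"
            i += 1
        if rng.random() < spec.p_punctuation:
            tok = tok + _PUNCT[rng.integers(len(_PUNCT))]
        out.append(tok)
        if rng.random() < spec.p_digit:
            out.append(str(rng.integers(0, 10000)))
        if rng.random() < spec.p_bracket_name:
            name = _BRACKET_NAMES[rng.integers(len(_BRACKET_NAMES))]
            out.append(f"<{name}{rng.integers(1, 10)}>")
        i += 1
    return " ".join(out)


def gen_corpus(
    spec: CorpusSpec,
    outdir: str | Path,
    file_format: str = "mixed",
) -> CorpusGroundTruth:
    """Generate transcript files plus their clean ground truth.

    ``file_format`` is ``"textgrid"``, ``"text"``, or ``"mixed"`` (long
    TextGrid, short TextGrid, and plain text in rotation). Type
    frequencies follow ``p(rank) ~ rank^-zipf_exponent``.
    """
    if file_format not in ("textgrid", "text", "mixed"):
        raise ValueError(f"unknown file_format {file_format!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    vocab = _make_vocabulary(rng, spec.vocabulary_size)
    ranks = np.arange(1, len(vocab) + 1, dtype=float)
    probs = ranks ** (-spec.zipf_exponent)
    probs /= probs.sum()

    documents: list[Document] = []
    paths: list[Path] = []
    token_counts: dict[str, int] = {}
    doc_counts: dict[str, int] = {}
    for d in range(spec.n_documents):
        n_tok = max(1, int(rng.poisson(spec.tokens_per_document)))
        idx = rng.choice(len(vocab), size=n_tok, p=probs)
        tokens = tuple(vocab[i] for i in idx)
        source_id = f"doc{d:04d}"
        documents.append(Document(source_id=source_id, tokens=tokens))
        for t in tokens:
            token_counts[t] = token_counts.get(t, 0) + 1
        for t in set(tokens):
            doc_counts[t] = doc_counts.get(t, 0) + 1

        # Split the rendered text into a few interval-sized chunks.
        n_chunks = int(rng.integers(1, 6))
        bounds = np.linspace(0, n_tok, n_chunks + 1).astype(int)
        spans = [
            _render_messy(tokens[a:b], spec, rng) for a, b in zip(bounds[:-1], bounds[1:])
        ]
        kind = {"textgrid": d % 2, "text": 2, "mixed": d % 3}[file_format]
        if kind == 2:
            path = outdir / f"{source_id}.txt"
            path.write_text("\n".join(spans) + "\n", encoding="utf-8")
        else:
            path = outdir / f"{source_id}.TextGrid"
            write_textgrid(path, spans, short=(kind == 1))
        paths.append(path)

    truth = CorpusGroundTruth(
        documents=documents, paths=paths,
        token_counts=token_counts, doc_counts=doc_counts,
    )
    truth.write_json(outdir / "ground_truth.json")
    return truth


# ---------------------------------------------------------------------------
# Pronunciation lexicon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LexiconSpec:
    """Parameters of the synthetic pronunciation lexicon.

    ``planted_neighbor_rate`` is the probability that a new word's first
    pronunciation is a single-edit mutation of an existing one (the
    neighbor-density knob); otherwise pronunciations are drawn fresh from
    the inventory. ``multi_pron_rate`` is the probability of a second
    pronunciation variant (a single-edit mutation of the first).
    """

    n_words: int = 200
    inventory: tuple[str, ...] = (
        "AA", "AE", "AH", "B", "CH", "D", "EH", "F", "G", "IH",
        "K", "L", "M", "N", "P", "R", "S", "T",
    )
    min_length: int = 2
    max_length: int = 6
    multi_pron_rate: float = 0.2
    planted_neighbor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.inventory:
            raise ValueError("phoneme inventory must be non-empty")
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("need 0 < min_length <= max_length")
        for name in ("multi_pron_rate", "planted_neighbor_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class LexiconGroundTruth:
    """Brute-force neighbor structure recorded at generation time."""

    word_neighbors: dict[str, set[str]]          # word-network adjacency
    pron_degrees: dict[str, int]                 # pron string -> degree
    pnd_word: dict[str, int]
    pnd_pron: dict[str, float]
    n_phonemes_mean: dict[str, float]


def _mutate(pron: Pronunciation, inventory: Sequence[str], rng: np.random.Generator) -> Pronunciation:
    """One random phoneme addition, deletion, or substitution."""
    ops = ["sub", "add"] + (["del"] if len(pron) > 1 else [])
    op = ops[rng.integers(len(ops))]
    pos = int(rng.integers(len(pron) + (1 if op == "add" else 0)))
    if op == "add":
        return pron[:pos] + (inventory[rng.integers(len(inventory))],) + pron[pos:]
    if op == "del":
        return pron[:pos] + pron[pos + 1:]
    repl = inventory[rng.integers(len(inventory))]
    if repl == pron[pos]:  # force a real substitution
        repl = inventory[(list(inventory).index(repl) + 1) % len(inventory)]
    return pron[:pos] + (repl,) + pron[pos + 1:]


def gen_lexicon(spec: LexiconSpec) -> tuple[PronLexicon, LexiconGroundTruth]:
    """Generate a lexicon and its brute-force ground-truth neighbor structure."""
    rng = np.random.default_rng(spec.seed)
    if len(spec.inventory) == 1 and spec.min_length == spec.max_length:
        import warnings

        warnings.warn(
            "single-symbol inventory with fixed length yields a degenerate "
            "(fully disconnected or trivially dense) network",
            stacklevel=2,
        )
    inventory = list(spec.inventory)
    words = [f"w{i:04d}" for i in range(spec.n_words)]
    entries: dict[str, list[Pronunciation]] = {}
    all_prons: list[Pronunciation] = []
    for w in words:
        if all_prons and rng.random() < spec.planted_neighbor_rate:
            base = all_prons[rng.integers(len(all_prons))]
            pron = _mutate(base, inventory, rng)
        else:
            length = int(rng.integers(spec.min_length, spec.max_length + 1))
            pron = tuple(inventory[rng.integers(len(inventory))] for _ in range(length))
        prons = [pron]
        if rng.random() < spec.multi_pron_rate:
            variant = _mutate(pron, inventory, rng)
            if variant != pron:
                prons.append(variant)
        entries[w] = prons
        all_prons.extend(prons)

    lex = PronLexicon.from_dict(entries)
    truth = _brute_force_truth(lex)
    return lex, truth


def _brute_force_truth(lex: PronLexicon) -> LexiconGroundTruth:
    words = sorted(lex.entries)
    word_neighbors: dict[str, set[str]] = {w: set() for w in words}
    for i, w1 in enumerate(words):
        for w2 in words[i + 1:]:
            if any(
                is_one_phoneme_neighbor(p, q)
                for p in lex.entries[w1]
                for q in lex.entries[w2]
            ):
                word_neighbors[w1].add(w2)
                word_neighbors[w2].add(w1)

    distinct = lex.distinct_pronunciations()
    pron_degrees = {" ".join(p): 0 for p in distinct}
    for i, p in enumerate(distinct):
        for q in distinct[i + 1:]:
            if is_one_phoneme_neighbor(p, q):
                pron_degrees[" ".join(p)] += 1
                pron_degrees[" ".join(q)] += 1

    pnd_word = {w: len(word_neighbors[w]) for w in words}
    pnd_pron = {
        w: float(np.mean([pron_degrees[" ".join(p)] for p in lex.entries[w]]))
        for w in words
    }
    n_phon = {
        w: float(np.mean([len(p) for p in lex.entries[w]])) for w in words
    }
    return LexiconGroundTruth(
        word_neighbors=word_neighbors,
        pron_degrees=pron_degrees,
        pnd_word=pnd_word,
        pnd_pron=pnd_pron,
        n_phonemes_mean=n_phon,
    )


# ---------------------------------------------------------------------------
# Corpus-scale norm tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormTableSpec:
    """Parameters of a corpus-*scale* synthetic norm table.

    Token-level simulation of a realistically sized speech corpus (tens of
    millions of tokens) is wasteful when only the count structure matters,
    so this generator draws a multinomial count vector over a Zipfian type
    distribution directly. Defaults match the scale of large speech-corpus
    norms (~30M tokens, ~50k types, ~19k documents), which gives the Zipf
    measure its realistic 1.5-7 dynamic range. Contextual-diversity counts
    follow the Poisson-occupancy expectation
    ``n_documents * (1 - exp(-raw/n_documents))`` for a word scattered at
    random over documents.
    """

    n_types: int = 50_000
    n_tokens: int = 30_000_000
    n_documents: int = 19_000
    zipf_exponent: float = 1.0
    seed: int = 0


def gen_norm_table(spec: NormTableSpec, label: str = "synthetic") -> NormTable:
    """Draw a Zipfian norm table at realistic corpus scale."""
    from .norms import CorpusStats, zipf_value

    rng = np.random.default_rng(spec.seed)
    ranks = np.arange(1, spec.n_types + 1, dtype=float)
    probs = ranks ** (-spec.zipf_exponent)
    probs /= probs.sum()
    raw = rng.multinomial(spec.n_tokens, probs)
    keep = raw > 0  # a type that drew zero tokens is not observed
    raw = raw[keep]
    words = np.array([f"syn{r:06d}" for r in np.flatnonzero(keep) + 1])

    expected_cd = spec.n_documents * (1.0 - np.exp(-raw / spec.n_documents))
    cd = np.minimum(
        np.minimum(raw, spec.n_documents),
        np.maximum(1, np.round(expected_cd).astype(np.int64)),
    )
    stats = CorpusStats(
        n_tokens=int(raw.sum()), n_types=int(len(raw)), n_documents=spec.n_documents
    )
    frame = pd.DataFrame(
        {
            "raw_count": raw,
            "zipf": zipf_value(raw, stats),
            "cd_count": cd,
            "cd_percent": 100.0 * cd / spec.n_documents,
        },
        index=pd.Index(words, name="word"),
    )
    return NormTable(label=label, stats=stats, frame=frame)


# ---------------------------------------------------------------------------
# Behavioral trials
# ---------------------------------------------------------------------------

#: Default true fixed effects for reaction time, in ms per unit of each
#: covariate — magnitudes chosen to match typical trial-level auditory
#: lexical decision analyses (frequency slope about -14 ms per Zipf unit).
DEFAULT_RT_BETA: Mapping[str, float] = {
    "intercept": 1103.0,
    "duration": 0.55,
    "n_phonemes": -7.84,
    "familiarity": -56.4,
    "prevalence": -44.0,
    "pnd": 0.82,
    "zipf": -14.0,
}

#: Default true accuracy effects on the log-odds scale, applied to
#: item-mean-centered covariates (an odds ratio of about 1.24 per Zipf unit).
DEFAULT_ACC_BETA: Mapping[str, float] = {
    "intercept": 2.5,
    "duration": 0.0,
    "n_phonemes": 0.2,
    "familiarity": 1.0,
    "prevalence": 0.75,
    "pnd": -0.01,
    "zipf": 0.215,
}


@dataclass(frozen=True)
class TrialSpec:
    """Parameters of the trial generator.

    Reaction times follow ``rt = X beta + u_participant + u_item + eps``
    with Gaussian components whose standard deviations match the scale of
    published trial-level analyses (residual ~217 ms, participant ~84 ms,
    item ~64 ms). Accuracy follows the logistic analogue with its own
    random-intercept SDs. ``outlier_rate`` injects RT outliers (half
    outside the 200-3000 ms response window, half ~6 residual SDs from the
    participant mean but inside the window) to exercise trial filtering.
    """

    n_participants: int = 50
    n_items: int = 300
    rt_beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RT_BETA))
    acc_beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ACC_BETA))
    sd_participant: float = 84.0
    sd_item: float = 64.0
    sd_resid: float = 217.0
    acc_sd_participant: float = 0.62
    acc_sd_item: float = 0.95
    outlier_rate: float = 0.0
    item_sampling: str = "stratified"
    accent: str = "SG"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_participant", "sd_item", "sd_resid",
                     "acc_sd_participant", "acc_sd_item"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if self.item_sampling not in ("stratified", "uniform"):
            raise ValueError("item_sampling must be 'stratified' or 'uniform'")


def gen_trials(
    spec: TrialSpec,
    norms: NormTable,
    pnd: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate lexical-decision trials from a known mixed model.

    Items are drawn (without replacement) from the norm table; their Zipf
    and log10 CD-count values become the frequency predictors (columns
    ``zipf`` and ``log10_cd``). The default ``"stratified"`` item sampling
    draws one item per frequency-rank stratum, emulating how megastudy
    stimulus lists span the whole frequency spectrum (uniform sampling
    from a Zipfian vocabulary would instead concentrate items in the
    low-frequency tail); ``"uniform"`` sampling is available. If a PND frame is given, ``pnd`` and
    ``n_phonemes`` come from it; otherwise they are drawn from simple
    count distributions. Returns the trial frame and a ground-truth dict
    (true coefficients, random effects, injected-outlier trial ids).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_items > len(norms):
        raise ValueError(
            f"requested {spec.n_items} items but norm table has {len(norms)} words"
        )
    if spec.item_sampling == "stratified":
        # One item per bin on the Zipf *value* axis: a Zipfian vocabulary is
        # rank-dominated by rare types, so uniform (or rank-stratified)
        # sampling concentrates items at the low-frequency floor; value
        # strata spread items across the whole frequency scale instead.
        srt = norms.frame.sort_values(["zipf", "raw_count"])
        zvals = srt["zipf"].to_numpy()
        words_sorted = srt.index.to_numpy()
        edges = np.linspace(zvals[0], zvals[-1], spec.n_items + 1)
        chosen: list[int] = []
        used: set[int] = set()
        for k in range(spec.n_items):
            lo = np.searchsorted(zvals, edges[k], side="left")
            hi = np.searchsorted(zvals, edges[k + 1], side="right" if k == spec.n_items - 1 else "left")
            cands = [j for j in range(lo, hi) if j not in used]
            if cands:
                pick = cands[int(rng.integers(len(cands)))]
                chosen.append(pick)
                used.add(pick)
        spare = [j for j in range(len(words_sorted)) if j not in used]
        while len(chosen) < spec.n_items:
            j = spare.pop(int(rng.integers(len(spare))))
            chosen.append(j)
        items = words_sorted[np.array(chosen)]
    else:
        words = np.array(sorted(norms.frame.index))
        items = rng.choice(words, size=spec.n_items, replace=False)

    zipf = norms.frame.loc[items, "zipf"].to_numpy()
    log10_cd = np.log10(norms.frame.loc[items, "cd_count"].to_numpy(dtype=float))
    duration = rng.normal(600.0, 80.0, spec.n_items).clip(150.0, None)
    familiarity = rng.normal(5.0, 1.0, spec.n_items).clip(1.0, 7.0)
    prevalence = rng.normal(2.0, 0.4, spec.n_items)
    if pnd is not None:
        sub = pnd.reindex(items)
        if sub.isna().any().any():
            raise ValueError("some sampled items are missing from the PND frame")
        pnd_vals = sub["pnd_word"].to_numpy(dtype=float)
        n_phon = sub["n_phonemes_mean"].to_numpy(dtype=float)
    else:
        pnd_vals = rng.poisson(10.0, spec.n_items).astype(float)
        n_phon = rng.integers(2, 9, spec.n_items).astype(float)

    item_cov = pd.DataFrame(
        {
            "duration": duration,
            "n_phonemes": n_phon,
            "familiarity": familiarity,
            "prevalence": prevalence,
            "pnd": pnd_vals,
            "zipf": zipf,
            "log10_cd": log10_cd,
        },
        index=pd.Index(items, name="item"),
    )

    u_p = rng.normal(0.0, spec.sd_participant, spec.n_participants)
    u_i = rng.normal(0.0, spec.sd_item, spec.n_items)
    v_p = rng.normal(0.0, spec.acc_sd_participant, spec.n_participants)
    v_i = rng.normal(0.0, spec.acc_sd_item, spec.n_items)

    p_rep = np.repeat(np.arange(spec.n_participants), spec.n_items)
    i_rep = np.tile(np.arange(spec.n_items), spec.n_participants)
    n = len(p_rep)

    covs = ("duration", "n_phonemes", "familiarity", "prevalence", "pnd", "zipf")
    eta_rt_item = spec.rt_beta["intercept"] + sum(
        spec.rt_beta[c] * item_cov[c].to_numpy() for c in covs
    )
    centered = {c: item_cov[c].to_numpy() - item_cov[c].mean() for c in covs}
    eta_acc_item = spec.acc_beta["intercept"] + sum(
        spec.acc_beta[c] * centered[c] for c in covs
    )

    rt = eta_rt_item[i_rep] + u_p[p_rep] + u_i[i_rep] + rng.normal(0.0, spec.sd_resid, n)
    eta_acc = eta_acc_item[i_rep] + v_p[p_rep] + v_i[i_rep]
    accuracy = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta_acc))).astype(int)

    trials = pd.DataFrame(
        {
            "participant": np.char.add("p", np.char.zfill(p_rep.astype(str), 3)),
            "item": items[i_rep],
            "accent": spec.accent,
            "rt": rt,
            "accuracy": accuracy,
        }
    )
    for c in ("duration", "n_phonemes", "familiarity", "prevalence", "pnd", "zipf", "log10_cd"):
        trials[c] = item_cov[c].to_numpy()[i_rep]

    # Outlier injection: only correct trials matter for the RT filter.
    outliers: dict[str, list[int]] = {"range_low": [], "range_high": [], "sd": []}
    if spec.outlier_rate > 0:
        correct_idx = np.flatnonzero(accuracy == 1)
        n_out = int(round(spec.outlier_rate * n))
        chosen = rng.choice(correct_idx, size=min(n_out, len(correct_idx)), replace=False)
        part_mean = trials.loc[trials["accuracy"] == 1].groupby("participant")["rt"].mean()
        for j, t in enumerate(chosen):
            kind = ("range_low", "range_high", "sd")[j % 3]
            if kind == "range_low":
                trials.loc[t, "rt"] = rng.uniform(30.0, 180.0)
            elif kind == "range_high":
                trials.loc[t, "rt"] = rng.uniform(3200.0, 6000.0)
            else:
                pm = part_mean[trials.loc[t, "participant"]]
                sign = 1.0 if rng.random() < 0.5 else -1.0
                val = pm + sign * 6.0 * spec.sd_resid
                if not 200.0 < val < 3000.0:
                    val = pm + 6.0 * spec.sd_resid
                trials.loc[t, "rt"] = min(val, 2990.0)
            outliers[kind].append(int(t))

    truth = {
        "rt_beta": dict(spec.rt_beta),
        "acc_beta": dict(spec.acc_beta),
        "sd_participant": spec.sd_participant,
        "sd_item": spec.sd_item,
        "sd_resid": spec.sd_resid,
        "u_participant": u_p,
        "u_item": u_i,
        "item_covariates": item_cov,
        "outlier_trials": outliers,
        "covariate_means": {c: float(item_cov[c].mean()) for c in covs},
    }
    return trials, truth


def add_noisy_predictor(
    trials: pd.DataFrame,
    source_col: str,
    name: str,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Add an item-consistent noisy copy of a predictor column.

    Emulates the same measure derived from a different corpus: per *item*
    (not per trial) Gaussian noise is added to ``source_col``, so the new
    column correlates with the original the way norms from two corpora do.
    """
    rng = np.random.default_rng(seed)
    items = trials["item"].unique()
    noise = pd.Series(rng.normal(0.0, noise_sd, len(items)), index=items)
    out = trials.copy()
    item_vals = out.groupby("item")[source_col].first()
    out[name] = (item_vals + noise).reindex(out["item"]).to_numpy()
    return out
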