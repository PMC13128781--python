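import numpy as np
import pytest

from speechnorms import synthdata
from speechnorms.phonnet import PronLexicon


@pytest.fixture(scope="session")
def act_lexicon() -> PronLexicon:
    """The canonical worked example: 'a', 'act' (two variants), 'actor'."""
    return PronLexicon.from_dict(
        {
            "a": [["EH"]],
            "act": [["EH", "K"], ["EH", "K", "T"]],
            "actor": [["EH", "K", "T", "AA"]],
        }
    )


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A messy synthetic transcript corpus plus its ground truth."""
    outdir = tmp_path_factory.mktemp("corpus")
    spec = synthdata.CorpusSpec(
        n_documents=24,
        vocabulary_size=300,
        tokens_per_document=150,
        p_punctuation=0.2,
        p_digit=0.1,
        p_bracket_name=0.1,
        p_hyphen=0.1,
        seed=11,
    )
    return synthdata.gen_corpus(spec, outdir)


@pytest.fixture(scope="session")
def norm_table():
    """Corpus-scale Zipfian norm table for behavioral simulations."""
    return synthdata.gen_norm_table(synthdata.NormTableSpec(seed=5))


@pytest.fixture(scope="session")
def small_norm_table():
    """A smaller norm table where fits stay fast."""
    return synthdata.gen_norm_table(
        synthdata.NormTableSpec(n_types=5000, n_tokens=1_000_000, n_documents=2000, seed=5)
    )
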