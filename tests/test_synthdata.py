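import numpy as np
import pandas as pd
import pytest

from speechnorms import corpus_io, norms, phonnet, synthdata


class TestCorpusGenerator:
    def test_same_seed_is_byte_identical(self, tmp_path):
        spec = synthdata.CorpusSpec(n_documents=6, vocabulary_size=100,
                                    tokens_per_document=80, seed=42)
        t1 = synthdata.gen_corpus(spec, tmp_path / "a")
        t2 = synthdata.gen_corpus(spec, tmp_path / "b")
        for p1, p2 in zip(t1.paths, t2.paths):
            assert p1.read_bytes() == p2.read_bytes()

    def test_zero_messiness_cleaning_is_noop(self, tmp_path):
        spec = synthdata.CorpusSpec(
            n_documents=8, vocabulary_size=150, tokens_per_document=100,
            p_punctuation=0.0, p_digit=0.0, p_bracket_name=0.0,
            p_hyphen=0.0, p_capitalize=0.0, seed=1,
        )
        truth = synthdata.gen_corpus(spec, tmp_path)
        docs = list(corpus_io.load_documents(truth.paths))
        for got, want in zip(docs, truth.documents):
            assert got.tokens == want.tokens

    def test_messy_corpus_counts_recover_ground_truth(self, small_corpus):
        # end to end: transcripts -> cleaning -> tokenization -> counting
        docs = list(corpus_io.load_documents(small_corpus.paths))
        tab = norms.count_norms(docs)
        assert dict(zip(tab.frame.index, tab.frame.raw_count)) == small_corpus.token_counts
        assert dict(zip(tab.frame.index, tab.frame.cd_count)) == small_corpus.doc_counts

    def test_bracket_names_never_leak(self, small_corpus):
        docs = list(corpus_io.load_documents(small_corpus.paths))
        for doc in docs:
            assert not any("wxq" in t for t in doc.tokens)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            synthdata.CorpusSpec(p_punctuation=1.5)


class TestLexiconGenerator:
    def test_planted_chain_has_known_degrees(self):
        lex = phonnet.PronLexicon.from_dict(
            {"a": [["AA"]], "ab": [["AA", "B"]], "abc": [["AA", "B", "CH"]]}
        )
        pnd = phonnet.compute_pnd(lex)
        assert list(pnd.loc[["a", "ab", "abc"], "pnd_word"]) == [1, 2, 1]

    def test_pipeline_matches_generator_bruteforce(self):
        lex, truth = synthdata.gen_lexicon(
            synthdata.LexiconSpec(n_words=300, seed=17, planted_neighbor_rate=0.4)
        )
        pnd = phonnet.compute_pnd(lex)
        for w in lex.entries:
            assert pnd.loc[w, "pnd_word"] == truth.pnd_word[w]
            assert pnd.loc[w, "pnd_pron"] == pytest.approx(truth.pnd_pron[w])
            assert pnd.loc[w, "n_phonemes_mean"] == pytest.approx(truth.n_phonemes_mean[w])

    def test_no_multi_pronunciations_equalizes_pnd(self):
        lex, _ = synthdata.gen_lexicon(
            synthdata.LexiconSpec(n_words=100, multi_pron_rate=0.0, seed=2)
        )
        prons = [ps[0] for ps in lex.entries.values()]
        assume_unique = len(set(prons)) == len(prons)
        pnd = phonnet.compute_pnd(lex)
        if assume_unique:
            assert (pnd.pnd_word == pnd.pnd_pron).all()

    def test_degenerate_inventory_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            synthdata.gen_lexicon(
                synthdata.LexiconSpec(
                    n_words=5, inventory=("AA",), min_length=3, max_length=3, seed=0
                )
            )


class TestNormTableGenerator:
    def test_invariants_and_scale(self, norm_table):
        f = norm_table.frame
        assert f.raw_count.sum() == norm_table.stats.n_tokens
        assert (f.cd_count >= 1).all()
        assert (f.cd_count <= np.minimum(f.raw_count, norm_table.stats.n_documents)).all()
        # realistic dynamic range of the Zipf scale
        assert f.zipf.max() - f.zipf.min() > 3.0

    def test_reproducible(self):
        spec = synthdata.NormTableSpec(n_types=2000, n_tokens=200_000, seed=3)
        a = synthdata.gen_norm_table(spec)
        b = synthdata.gen_norm_table(spec)
        pd.testing.assert_frame_equal(a.frame, b.frame)


class TestTrialGenerator:
    def test_same_seed_identical(self, small_norm_table):
        spec = synthdata.TrialSpec(n_participants=5, n_items=40, seed=9)
        t1, _ = synthdata.gen_trials(spec, small_norm_table)
        t2, _ = synthdata.gen_trials(spec, small_norm_table)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_frequency_effect_centers_on_zero(self, small_norm_table):
        from speechnorms.model_compare import fit_rt_model, filter_rt_trials

        beta = dict(synthdata.DEFAULT_RT_BETA, zipf=0.0)
        zs = []
        for rep in range(5):
            spec = synthdata.TrialSpec(
                n_participants=20, n_items=120, rt_beta=beta, seed=100 + rep
            )
            trials, _ = synthdata.gen_trials(spec, small_norm_table)
            fit = fit_rt_model(filter_rt_trials(trials), "zipf")
            zs.append(fit.result.fe_params["zipf"] / fit.result.bse["zipf"])
        assert abs(np.mean(zs)) < 1.5  # standard errors of a null effect

    def test_outliers_marked_and_extreme(self, small_norm_table):
        spec = synthdata.TrialSpec(
            n_participants=10, n_items=60, outlier_rate=0.05, seed=3
        )
        trials, truth = synthdata.gen_trials(spec, small_norm_table)
        marked = truth["outlier_trials"]
        assert sum(len(v) for v in marked.values()) == round(0.05 * len(trials))
        assert (trials.loc[marked["range_low"], "rt"] < 200).all()
        assert (trials.loc[marked["range_high"], "rt"] > 3000).all()
        in_range = trials.loc[marked["sd"], "rt"]
        assert ((in_range > 200) & (in_range < 3000)).all()

    def test_item_covariates_are_item_consistent(self, small_norm_table):
        trials, _ = synthdata.gen_trials(
            synthdata.TrialSpec(n_participants=6, n_items=30, seed=5), small_norm_table
        )
        assert (trials.groupby("item")["zipf"].nunique() == 1).all()
        assert (trials.groupby("item")["duration"].nunique() == 1).all()

    def test_noisy_predictor_is_item_consistent_and_correlated(self, small_norm_table):
        trials, _ = synthdata.gen_trials(
            synthdata.TrialSpec(n_participants=10, n_items=100, seed=5), small_norm_table
        )
        out = synthdata.add_noisy_predictor(trials, "zipf", "b", 0.5, seed=1)
        assert (out.groupby("item")["b"].nunique() == 1).all()
        per_item = out.groupby("item")[["zipf", "b"]].first()
        r = np.corrcoef(per_item.zipf, per_item.b)[0, 1]
        assert 0.5 < r < 1.0

    def test_too_many_items_rejected(self, small_norm_table):
        with pytest.raises(ValueError, match="items"):
            synthdata.gen_trials(
                synthdata.TrialSpec(n_items=10**6), small_norm_table
            )
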