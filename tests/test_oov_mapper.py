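"""Resolution chain: lexicon, crowdsourced lookup, learned matcher."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncochat.oov_mapper import (
    AttributeType,
    Lexicon,
    LexiconError,
    MatchStage,
    MatcherConfig,
    MatcherModel,
    PersonalStore,
    TermEntry,
    UtteranceRecord,
    build_corpus_index,
    crowdsourced_match,
    evaluate_matcher,
    exact_match,
    map_utterance,
    predict_match,
    split_corpus,
    train_matcher,
)
from oncochat.textnorm import normalize_text


def rec(t, v, a=AttributeType.GENE):
    return UtteranceRecord(t, v, a)


class TestLexicon:
    def test_duplicate_value_is_load_error(self):
        with pytest.raises(LexiconError):
            Lexicon(
                [
                    TermEntry("TP53", AttributeType.GENE),
                    TermEntry("tp53.", AttributeType.GENE),
                ]
            )

    def test_synonym_collision_is_load_error(self):
        with pytest.raises(LexiconError):
            Lexicon(
                [
                    TermEntry("TP53", AttributeType.GENE),
                    TermEntry("KRAS", AttributeType.GENE, ("tp53",)),
                ]
            )

    def test_every_value_maps_to_itself(self, tiny_lexicon):
        for entry in tiny_lexicon.entries:
            result = exact_match(normalize_text(entry.value), tiny_lexicon)
            assert result.stage is MatchStage.EXACT
            assert result.value == entry.value
            assert result.confidence == 1.0

    def test_tsv_round_trip(self, tiny_lexicon, tmp_path):
        path = tmp_path / "lexicon.tsv"
        tiny_lexicon.to_tsv(path)
        reloaded = Lexicon.from_tsv(path)
        assert [e.value for e in reloaded.entries] == [e.value for e in tiny_lexicon.entries]
        assert reloaded.lookup("breast").value == "breast cancer"


class TestExactAndCrowdsourced:
    def test_exact_match_examples(self, tiny_lexicon):
        hit = exact_match("tp53", tiny_lexicon)
        assert (hit.value, hit.attribute_type) == ("TP53", AttributeType.GENE)
        hit = exact_match("breast cancer", tiny_lexicon)
        assert (hit.value, hit.attribute_type) == ("breast cancer", AttributeType.CANCER_TYPE)
        assert not exact_match("glorp", tiny_lexicon).resolved

    def test_crowdsourced_unanimous_hit(self):
        corpus = [rec("mick", "MYC"), rec("mick", "MYC"), rec("pick three", "PIK3CA")]
        hit = crowdsourced_match("mick", corpus)
        assert (hit.value, hit.stage, hit.confidence) == ("MYC", MatchStage.CROWDSOURCED, 1.0)

    def test_ambiguous_transcription_falls_through(self):
        corpus = [rec("mick", "MYC"), rec("mick", "MICA")]
        assert not crowdsourced_match("mick", corpus).resolved

    def test_absent_transcription_unresolved(self):
        assert not crowdsourced_match("zorp", [rec("mick", "MYC")]).resolved


class TestPersonalStore:
    def test_round_trip_and_isolation(self, tiny_lexicon, tmp_path):
        store = PersonalStore()
        store.add("alice", "kay rass", "KRAS", AttributeType.GENE, tiny_lexicon)
        hit = map_utterance("kay rass", tiny_lexicon, personal_store=store, user_id="alice")
        assert (hit.value, hit.stage) == ("KRAS", MatchStage.PERSONAL)
        miss = map_utterance("kay rass", tiny_lexicon, personal_store=store, user_id="bob")
        assert not miss.resolved
        path = tmp_path / "personal.json"
        store.save(path)
        assert PersonalStore.load(path).list_user("alice") == store.list_user("alice")

    def test_upsert_overwrites(self, tiny_lexicon):
        store = PersonalStore()
        store.add("u", "em why see", "MYC", AttributeType.GENE, tiny_lexicon)
        store.add("u", "em why see", "TP53", AttributeType.GENE, tiny_lexicon)
        assert store.lookup("u", "em why see").value == "TP53"

    def test_empty_transcription_rejected(self):
        with pytest.raises(ValueError):
            PersonalStore().add("u", "  . ", "TP53", AttributeType.GENE)

    def test_unknown_target_requires_custom_flag(self, tiny_lexicon):
        store = PersonalStore()
        with pytest.raises(ValueError):
            store.add("u", "zed", "NOTAGENE", AttributeType.GENE, tiny_lexicon)
        store.add("u", "zed", "NOTAGENE", AttributeType.GENE, tiny_lexicon, custom=True)
        assert store.lookup("u", "zed").value == "NOTAGENE"


class TestSplitArithmetic:
    @settings(max_examples=100, deadline=None)
    @given(
        n=st.integers(min_value=2, max_value=400),
        f_pct=st.integers(min_value=1, max_value=99),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_floor_split_property(self, n, f_pct, seed):
        corpus = [rec(f"t{i}", f"G{i}") for i in range(n)]
        f = f_pct / 100
        train, test = split_corpus(corpus, f, seed)
        assert len(train) == math.floor(f * n)
        assert len(test) == n - len(train)
        assert {r.transcription for r in train} | {r.transcription for r in test} == {
            r.transcription for r in corpus
        }

    def test_same_seed_same_split(self):
        corpus = [rec(f"t{i}", f"G{i}") for i in range(37)]
        assert split_corpus(corpus, 0.9, 5) == split_corpus(corpus, 0.9, 5)
        assert split_corpus(corpus, 0.9, 5) != split_corpus(corpus, 0.9, 6)


@pytest.fixture(scope="module")
def toy_model():
    """Three-class corpus: each term with several distinctive variants."""
    corpus = []
    variants = {
        "TP53": ["tee pee fifty three", "tp fifty three", "tee p 53", "tp five three",
                 "tee pee five three", "t p 53", "tp53"],
        "MYC": ["mick", "mike", "em why see", "myck", "mic", "m y c", "myc"],
        "KRAS": ["kay rass", "k ras", "kay ras", "cray us", "k rass", "kras gene", "kras"],
    }
    for target, texts in variants.items():
        corpus.extend(rec(t, target) for t in texts)
    model, held = train_matcher(
        corpus, 0.8, seed=3, config=MatcherConfig(n_estimators=50)
    )
    return model, held, corpus


class TestPredictedMatching:
    def test_memorizes_training_transcriptions(self, toy_model):
        model, held, corpus = toy_model
        held_set = set(held)
        train = [r for r in corpus if r not in held_set]
        hits = 0
        for r in train:
            out = predict_match(model, normalize_text(r.transcription), seed=0)
            hits += out.value == r.target_value
        assert hits / len(train) >= 0.9  # forest memorizes almost all of a toy set

    def test_prediction_is_seed_deterministic(self, toy_model):
        model, _, _ = toy_model
        a = predict_match(model, "mik", seed=4)
        b = predict_match(model, "mik", seed=4)
        assert (a.value, a.confidence) == (b.value, b.confidence)
        assert a.stage is MatchStage.PREDICTED
        assert 0 < a.confidence <= 1

    def test_empty_input_unresolved(self, toy_model):
        model, _, _ = toy_model
        assert not predict_match(model, "", seed=0).resolved

    def test_model_file_round_trip(self, toy_model, tmp_path):
        model, _, _ = toy_model
        path = tmp_path / "matcher.joblib"
        model.save(path)
        reloaded = MatcherModel.load(path)
        for text in ["mick", "kay rass", "tp five three"]:
            assert predict_match(reloaded, text, seed=1) == predict_match(model, text, seed=1)

    def test_version_mismatch_errors(self, toy_model, tmp_path):
        import joblib

        model, _, _ = toy_model
        path = tmp_path / "matcher.joblib"
        model.save(path)
        payload = joblib.load(path)
        payload["format_version"] = 999
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="format version"):
            MatcherModel.load(path)


class TestChain:
    def test_exact_wins_over_conflicting_corpus(self, tiny_lexicon):
        corpus = [rec("tp53", "KRAS")]  # poisoned corpus entry
        hit = map_utterance("tp53", tiny_lexicon, corpus)
        assert (hit.value, hit.stage) == ("TP53", MatchStage.EXACT)

    def test_personal_wins_over_exact_for_owner(self, tiny_lexicon):
        store = PersonalStore()
        store.add("u", "tp53", "MYC", AttributeType.GENE, tiny_lexicon)
        hit = map_utterance("tp53", tiny_lexicon, personal_store=store, user_id="u")
        assert (hit.value, hit.stage) == ("MYC", MatchStage.PERSONAL)

    def test_gibberish_without_model_unresolved(self, tiny_lexicon):
        out = map_utterance("zzgh blfm", tiny_lexicon, corpus=[rec("mick", "MYC")])
        assert out.stage is MatchStage.UNRESOLVED
        assert out.value is None

    def test_crowdsourced_stage_reached(self, tiny_lexicon):
        hit = map_utterance("mick", tiny_lexicon, corpus=[rec("mick", "MYC")])
        assert (hit.value, hit.stage) == ("MYC", MatchStage.CROWDSOURCED)


class TestEvaluate:
    def test_perfect_corpus_gives_accuracy_one(self, tiny_lexicon):
        held = [rec(e.value, e.value, e.attribute_type) for e in tiny_lexicon.entries]
        report = evaluate_matcher(None, held, tiny_lexicon)
        assert report.full_chain_accuracy == 1.0
        assert report.exact_only_accuracy == 1.0

    def test_chain_dominates_exact_baseline(self, toy_model, tiny_lexicon):
        model, held, corpus = toy_model
        train = [r for r in corpus if r not in set(held)]
        report = evaluate_matcher(model, held, tiny_lexicon, train, seed=0)
        assert report.full_chain_accuracy >= report.exact_only_accuracy

    def test_empty_held_out_errors(self, tiny_lexicon):
        with pytest.raises(ValueError):
            evaluate_matcher(None, [], tiny_lexicon)

    def test_index_building_normalizes(self):
        index = build_corpus_index([rec("Mick!", "MYC")])
        assert "mick" in index
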