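import math

import numpy as np
import pytest

from conceptvec.augment import (
    ID_TOKEN_RE,
    AugmentCounters,
    PhraseModel,
    apply_phrases,
    augment_corpus,
    format_entity_id,
    join_entities,
    phrase_score,
    substitute_ids,
    train_phrase_model,
)
from conceptvec.errors import ContractViolation
from conceptvec.synthcorpus import SyntheticSpec, generate_corpus
from conceptvec.types import AnnotatedSpan, Sentence


def sent(*tokens: str) -> Sentence:
    ranges = []
    pos = 0
    for t in tokens:
        ranges.append((pos, pos + len(t)))
        pos += len(t) + 1
    return Sentence(list(tokens), ranges)


class TestPhraseModel:
    def test_counts_repeated_bigram(self):
        model = train_phrase_model([sent("chronic", "fatigue")] * 10)
        assert model.bigram_counts[("chronic", "fatigue")] == 10
        assert model.unigram_counts["chronic"] == 10

    def test_single_token_sentence_has_no_bigrams(self):
        model = train_phrase_model([sent("a")])
        assert model.bigram_counts == {}

    def test_empty_corpus_fatal(self):
        with pytest.raises(ContractViolation):
            train_phrase_model([])

    def test_unrepeated_adjacency_scores_below_one(self):
        # every adjacent pair occurs once: score <= 0 whenever delta >= 1
        model = train_phrase_model(
            [sent("a", "b", "c"), sent("d", "e", "f")], delta=1
        )
        for a, b in model.bigram_counts:
            assert phrase_score(model, a, b) <= 0

    def test_save_load_round_trip(self, tmp_path):
        model = train_phrase_model([sent("x", "y")] * 3, delta=2, threshold=4)
        model.save(tmp_path / "p.pkl")
        back = PhraseModel.load(tmp_path / "p.pkl")
        assert back.bigram_counts == model.bigram_counts
        assert back.delta == 2 and back.threshold == 4


class TestPhraseScore:
    def _model(self):
        m = PhraseModel(delta=5.0)
        m.unigram_counts = {f"w{i}": 1 for i in range(98)}
        m.unigram_counts.update({"a": 10, "b": 10})
        m.bigram_counts = {("a", "b"): 8}
        assert m.vocab_size == 100
        return m

    def test_closed_form_value(self):
        # (c_ab - delta) * N / (c_a * c_b) = (8-5)*100/100 = 3.0
        assert phrase_score(self._model(), "a", "b") == pytest.approx(3.0)

    def test_count_at_delta_scores_zero(self):
        m = self._model()
        m.bigram_counts[("a", "b")] = 5
        assert phrase_score(m, "a", "b") == pytest.approx(0.0)

    def test_unknown_token_scores_minus_inf(self):
        assert phrase_score(self._model(), "zz", "b") == -math.inf

    def test_threshold_one_joins_threshold_five_does_not(self):
        m = self._model()
        s = sent("a", "b")
        assert apply_phrases(m, s, threshold=1.0).tokens == ["a_b"]
        assert apply_phrases(m, s, threshold=5.0).tokens == ["a", "b"]


class TestApplyPhrases:
    def _model(self, pairs: dict):
        m = PhraseModel(delta=0.0, threshold=1.0)
        toks = {t for ab in pairs for t in ab}
        m.unigram_counts = {t: 1 for t in toks}
        # with delta=0 and unit unigram counts, score = c_ab * N >= 1 iff seen
        m.bigram_counts = dict(pairs)
        return m

    def test_greedy_join_and_continue(self):
        m = self._model({("chronic", "fatigue"): 1})
        out = apply_phrases(m, sent("chronic", "fatigue", "syndrome"))
        assert out.tokens == ["chronic_fatigue", "syndrome"]
        out.validate()

    def test_identity_when_nothing_scores(self):
        m = self._model({("x", "y"): 1})
        s = sent("chronic", "fatigue")
        assert apply_phrases(m, s).tokens == s.tokens

    def test_greedy_non_overlapping_triple(self):
        m = self._model({("a", "a"): 1})
        assert apply_phrases(m, sent("a", "a", "a")).tokens == ["a_a", "a"]

    def test_underscore_strip_recovers_input(self):
        m = self._model({("a", "b"): 1, ("c", "d"): 1})
        s = sent("a", "b", "x", "c", "d")
        out = apply_phrases(m, s)
        recovered = [p for t in out.tokens for p in t.split("_")]
        assert recovered == s.tokens


class TestJoinEntities:
    def test_full_span_joins_all_tokens(self):
        s = sent("chronic", "fatigue", "syndrome")
        span = AnnotatedSpan(0, 24, "chronic fatigue syndrome", "disease",
                             "MESH:D015673")
        assert join_entities(s, [span]).tokens == ["chronic_fatigue_syndrome"]

    def test_no_spans_is_identity(self):
        s = sent("a", "b")
        assert join_entities(s, []).tokens == s.tokens

    def test_two_disjoint_spans(self):
        s = sent("aa", "bb", "cc", "dd", "ee")
        # tokens at chars 0-2, 3-5, 6-8, 9-11, 12-14
        spans = [
            AnnotatedSpan(0, 5, "aa bb", "gene", "1"),
            AnnotatedSpan(9, 14, "dd ee", "gene", "2"),
        ]
        out = join_entities(s, spans)
        assert out.tokens == ["aa_bb", "cc", "dd_ee"]
        out.validate()

    def test_span_with_no_tokens_counted(self):
        s = sent("aa")
        counters = AugmentCounters()
        out = join_entities(s, [AnnotatedSpan(50, 55, "zzz", "gene", "1")], counters)
        assert out.tokens == ["aa"] and counters.spans_no_token == 1

    def test_overlapping_spans_prefer_longer(self):
        s = sent("aa", "bb", "cc")
        spans = [
            AnnotatedSpan(0, 2, "aa", "gene", "short"),
            AnnotatedSpan(0, 8, "aa bb cc", "disease", "long"),
        ]
        assert join_entities(s, spans).tokens == ["aa_bb_cc"]


class TestFormatEntityId:
    def test_species_taxonomy_id(self):
        assert format_entity_id("species", "9096") == "species_9096"

    def test_mesh_descriptor(self):
        assert format_entity_id("disease", "MESH:D005356") == "disease_mesh_d005356"

    def test_prenormalized_id_passes_through(self):
        assert format_entity_id("gene", "gene_4137") == "gene_4137"

    def test_idempotent(self):
        once = format_entity_id("disease", "MESH:D015673")
        assert format_entity_id("disease", once) == once

    def test_bad_inputs_fatal(self):
        with pytest.raises(ContractViolation):
            format_entity_id("disease", "")
        with pytest.raises(ContractViolation):
            format_entity_id("cellline", "x")

    def test_rendered_form_matches_grammar(self):
        for etype, rid in [
            ("species", "9096"), ("disease", "MESH:D005356"), ("gene", "4137"),
            ("mutation", "tmVar:p|SUB|V|600|E"), ("chemical", "MESH:C025204"),
        ]:
            assert ID_TOKEN_RE.match(format_entity_id(etype, rid))


class TestSubstituteIds:
    def test_cfs_mention_becomes_surrogate_token(self):
        s = sent("chronic", "fatigue", "syndrome")
        span = AnnotatedSpan(0, 24, "chronic fatigue syndrome", "disease",
                             "MESH:D015673")
        assert substitute_ids(s, [span]).tokens == ["disease_mesh_d015673"]

    def test_identity_without_spans(self):
        s = sent("x", "y")
        assert substitute_ids(s, []).tokens == s.tokens

    def test_two_spans_two_id_tokens(self):
        s = sent("human", "has", "fibromyalgia")
        spans = [
            AnnotatedSpan(0, 5, "human", "species", "9096"),
            AnnotatedSpan(10, 22, "fibromyalgia", "disease", "MESH:D005356"),
        ]
        out = substitute_ids(s, spans)
        assert out.tokens == ["species_9096", "has", "disease_mesh_d005356"]


class TestAugmentCorpus:
    def _phrase_model(self):
        m = PhraseModel(delta=0.0, threshold=1.0)
        m.unigram_counts = {"long": 1, "covid": 1}
        m.bigram_counts = {("long", "covid"): 1}
        return m

    def test_three_variants_for_annotated_sentence_with_bigram(self):
        s = sent("long", "covid", "fatigue")
        span = AnnotatedSpan(11, 18, "fatigue", "disease", "MESH:D005221")
        out = list(augment_corpus([(s, [span])], self._phrase_model(), seed=0))
        token_lists = sorted(tuple(x.tokens) for x in out)
        assert len(out) == 3
        assert ("long", "covid", "fatigue") in token_lists
        assert ("long_covid", "fatigue") in token_lists
        assert ("long", "covid", "disease_mesh_d005221") in token_lists

    def test_plain_sentence_emits_base_only(self):
        s = sent("alpha", "beta")
        out = list(augment_corpus([(s, [])], self._phrase_model(), seed=0))
        assert len(out) == 1 and out[0].tokens == ["alpha", "beta"]

    def test_shuffle_is_seeded_permutation(self):
        pairs = [(sent(f"tok{i}", "long", "covid"), []) for i in range(50)]
        a = [s.tokens for s in augment_corpus(list(pairs), self._phrase_model(), seed=4)]
        b = [s.tokens for s in augment_corpus(list(pairs), self._phrase_model(), seed=4)]
        c = [s.tokens for s in augment_corpus(list(pairs), self._phrase_model(), seed=5)]
        assert a == b
        assert a != c
        assert sorted(map(tuple, a)) == sorted(map(tuple, c))

    def test_every_output_token_matches_grammar(self):
        corpus = generate_corpus(SyntheticSpec(n_sentences=300, seed=2))
        pm = train_phrase_model(corpus.as_sentences(), delta=5, threshold=1)
        out = augment_corpus(corpus.annotated_sentences(), pm, seed=2)
        for s in out:
            for tok in s.tokens:
                assert ID_TOKEN_RE.match(tok) or (
                    tok and not any(ch.isspace() for ch in tok)
                )

    def test_expansion_factor_matches_annotation_rate(self):
        # half the sentences annotated with multi-token mentions, no
        # collocations: 1 + 0.5 (joined) + 0.5 (id) = 2.0
        spec = SyntheticSpec(
            n_sentences=2000, seed=9, entity_rate=0.5, n_collocations=0
        )
        corpus = generate_corpus(spec)
        pm = train_phrase_model(corpus.as_sentences(), delta=5, threshold=1)
        counters = AugmentCounters()
        list(augment_corpus(corpus.annotated_sentences(), pm, seed=9,
                            counters=counters))
        assert counters.expansion_factor == pytest.approx(2.0, abs=0.02)

    def test_separate_variants_flag(self):
        s = sent("long", "covid", "fatigue")
        span = AnnotatedSpan(5, 18, "covid fatigue", "disease", "MESH:D005221")
        out = list(
            augment_corpus([(s, [span])], self._phrase_model(), seed=0,
                           separate_variants=True)
        )
        # base + entity-joined + phrase-joined + id variant
        assert len(out) == 4
        token_lists = sorted(tuple(x.tokens) for x in out)
        assert ("long", "covid_fatigue") in token_lists
        assert ("long_covid", "fatigue") in token_lists
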