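import numpy as np
import pytest

from conceptvec.evalharness import (
    concept_benchmark,
    oov_ratio,
    pearson,
    sentence_benchmark,
)
from conceptvec.sentsim import nbow, prepare_sentence, wmd
from conceptvec.types import BenchmarkRecord, PairBenchmark
from conceptvec.vectorstore import cosine
from tests.conftest import make_model


def model_with(tokens, dim=5, seed=0, with_buckets=False):
    rng = np.random.default_rng(seed)
    return make_model(sorted(tokens), rng.normal(size=(len(tokens), dim)),
                      counts=list(range(len(tokens) + 5, 5, -1)),
                      with_buckets=with_buckets, seed=seed)


class TestPearson:
    def test_positive_affine(self):
        x = np.arange(10.0)
        r, defined = pearson(x, 2 * x + 1)
        assert defined and r == pytest.approx(1.0)

    def test_negation(self):
        x = np.arange(10.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.2, 3.4, 0.1, 5.5, 2.2, 9.0, 4.4, 6.6, 7.7, 8.1])
        y = np.array([0.5, 2.9, 1.1, 4.0, 3.3, 8.5, 5.1, 5.9, 6.0, 9.9])
        n = len(x)
        num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
        den = np.sqrt(n * np.sum(x**2) - np.sum(x) ** 2) * np.sqrt(
            n * np.sum(y**2) - np.sum(y) ** 2
        )
        r, defined = pearson(x, y)
        assert defined and abs(r - num / den) < 1e-12

    def test_zero_variance_undefined(self):
        r, defined = pearson([1, 1, 1, 1], [1, 2, 3, 4])
        assert not defined and np.isnan(r)

    def test_too_short_undefined(self):
        r, defined = pearson([1, 2], [2, 1])
        assert not defined

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 30))
        r0, _ = pearson(x, y)
        r1, _ = pearson(3.5 * x + 2, y)
        r2, _ = pearson(x, 0.1 * y - 7)
        assert r0 == pytest.approx(r1) == pytest.approx(r2)


class TestOovRatio:
    def test_all_terms_planted(self):
        model = model_with(["fatigue", "pain", "fever"])
        bench = PairBenchmark(
            [BenchmarkRecord("fatigue", "pain", 1.0),
             BenchmarkRecord("pain", "fever", 2.0)]
        )
        assert oov_ratio(model, bench).ratio_pct == 0.0

    def test_two_of_ten_missing(self):
        present = [f"tok{i}" for i in range(8)]
        model = model_with(present)
        records = []
        terms = present + ["missing1", "missing2"]
        for i in range(0, 10, 2):
            records.append(BenchmarkRecord(terms[i], terms[i + 1], 1.0))
        rep = oov_ratio(model, PairBenchmark(records))
        assert rep.n_distinct_terms == 10
        assert rep.n_oov_terms == 2
        assert rep.ratio_pct == pytest.approx(20.0)

    def test_repeated_term_counted_once(self):
        model = model_with(["alpha", "beta"])
        records = [BenchmarkRecord("alpha", "zzmissing", float(i))
                   for i in range(5)]
        rep = oov_ratio(model, PairBenchmark(records))
        assert rep.n_distinct_terms == 2
        assert rep.n_oov_terms == 1
        assert rep.ratio_pct == pytest.approx(50.0)
        assert rep.n_oov_mentions == 5


class TestConceptBenchmark:
    def _bench_from_cosines(self, model, pairs, transform):
        records = []
        for t1, t2 in pairs:
            c = cosine(model.vectors[model.vocab.index[t1]],
                       model.vectors[model.vocab.index[t2]])
            records.append(BenchmarkRecord(t1, t2, transform(c)))
        return PairBenchmark(records)

    def test_noiseless_linear_scores_give_r_one(self):
        model = model_with([f"t{i:02d}" for i in range(12)])
        toks = model.vocab.tokens
        pairs = [(toks[i], toks[(i + 3) % 12]) for i in range(12)]
        bench = self._bench_from_cosines(model, pairs, lambda c: 5 * c + 1)
        res = concept_benchmark(model, bench)
        assert res.defined and res.pearson_r == pytest.approx(1.0)
        assert res.n_pairs_used == 12 and res.n_pairs_excluded == 0

    def test_negated_scores_give_r_minus_one(self):
        model = model_with([f"t{i:02d}" for i in range(10)])
        toks = model.vocab.tokens
        pairs = [(toks[i], toks[(i + 1) % 10]) for i in range(10)]
        bench = self._bench_from_cosines(model, pairs, lambda c: -c)
        assert concept_benchmark(model, bench).pearson_r == pytest.approx(-1.0)

    def test_oov_pairs_excluded_and_accounted(self):
        model = model_with([f"t{i:02d}" for i in range(6)])
        toks = model.vocab.tokens
        pairs = [(toks[i], toks[i + 1]) for i in range(5)]
        bench = self._bench_from_cosines(model, pairs, lambda c: c)
        bench.records.append(BenchmarkRecord("zzmissing", toks[0], 0.5))
        bench.records.append(BenchmarkRecord("zzmissing", "qqgone", 0.1))
        res = concept_benchmark(model, bench)
        assert res.n_pairs_used == 5
        assert res.n_pairs_excluded == 2
        assert res.n_pairs_used + res.n_pairs_excluded == len(bench)
        assert res.oov_terms == 2

    def test_fewer_than_three_pairs_undefined(self):
        model = model_with(["aa", "bb"])
        bench = PairBenchmark([BenchmarkRecord("aa", "bb", 1.0)])
        res = concept_benchmark(model, bench)
        assert not res.defined and np.isnan(res.pearson_r)

    def test_ontology_mode_with_identity_map_matches_term_mode(self):
        tokens = [f"disease_mesh_d{i:06d}" for i in range(8)]
        model = model_with(tokens)
        toks = model.vocab.tokens
        records = []
        for i in range(8):
            t1, t2 = toks[i], toks[(i + 2) % 8]
            c = cosine(model.vectors[model.vocab.index[t1]],
                       model.vectors[model.vocab.index[t2]])
            records.append(BenchmarkRecord(t1, t2, 2 * c, id1=t1, id2=t2))
        bench = PairBenchmark(records)
        res_term = concept_benchmark(model, bench, id_mode="term")
        res_ont = concept_benchmark(model, bench, id_mode="ontology",
                                    id_map={t: t for t in toks})
        assert res_ont.pearson_r == pytest.approx(res_term.pearson_r)

    def test_unmapped_ontology_id_counts_as_oov(self):
        model = model_with(["disease_mesh_d000001", "disease_mesh_d000002",
                            "disease_mesh_d000003", "disease_mesh_d000004"])
        toks = model.vocab.tokens
        records = [
            BenchmarkRecord("x", "y", 1.0, id1=toks[0], id2=toks[1]),
            BenchmarkRecord("x", "y", 2.0, id1="C999999", id2=toks[1]),
        ]
        res = concept_benchmark(
            model, PairBenchmark(records), id_mode="ontology",
            id_map={t: t for t in toks},  # C999999 deliberately unmapped
        )
        assert res.n_pairs_excluded == 1


class TestSentenceBenchmark:
    def _model(self):
        rng = np.random.default_rng(31)
        words = sorted(["fatigue", "chronic", "syndrome", "covid", "pain",
                        "severe", "patient", "sleep", "fever", "cough"])
        return make_model(words, rng.normal(size=(len(words), 6)),
                          counts=list(range(15, 5, -1)), seed=31)

    def _pairs(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        words = ["fatigue", "chronic", "syndrome", "covid", "pain", "severe",
                 "patient", "sleep", "fever", "cough"]
        out = []
        for _ in range(n):
            s1 = " ".join(rng.choice(words, size=4))
            s2 = " ".join(rng.choice(words, size=4))
            out.append((s1, s2))
        return out

    def test_human_equals_wmd_gives_r_one_after_negation(self):
        model = self._model()
        pairs = []
        for s1, s2 in self._pairs():
            d = wmd(nbow(prepare_sentence(s1, model)),
                    nbow(prepare_sentence(s2, model)))
            pairs.append((s1, s2, d))
        res = sentence_benchmark(model, pairs, method="wmd")
        # human score IS the distance: correlation is -1, negation flips to...
        # the harness negates the model distance, so r = -1 here
        assert res.pearson_r == pytest.approx(-1.0)

    def test_human_equals_similarity_gives_r_one(self):
        # human = negated WMD (a similarity): after negation r = +1
        model = self._model()
        pairs = []
        for s1, s2 in self._pairs(seed=1):
            d = wmd(nbow(prepare_sentence(s1, model)),
                    nbow(prepare_sentence(s2, model)))
            pairs.append((s1, s2, -d))
        res = sentence_benchmark(model, pairs, method="wmd")
        assert res.pearson_r == pytest.approx(1.0)

    def test_sif_perfect_linearity(self):
        from conceptvec.sentsim import sentence_similarity

        model = self._model()
        pairs = []
        for s1, s2 in self._pairs(seed=2):
            score, _ = sentence_similarity(s1, s2, model, method="sif")
            pairs.append((s1, s2, score))
        res = sentence_benchmark(model, pairs, method="sif")
        assert res.pearson_r == pytest.approx(1.0)

    def test_swapping_sentence_order_leaves_r_unchanged(self):
        model = self._model()
        rng = np.random.default_rng(3)
        pairs = [(s1, s2, float(rng.uniform(0, 4)))
                 for s1, s2 in self._pairs(n=50, seed=3)]
        swapped = [(s2, s1, h) for s1, s2, h in pairs]
        r1 = sentence_benchmark(model, pairs, method="wmd").pearson_r
        r2 = sentence_benchmark(model, swapped, method="wmd").pearson_r
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_unresolvable_pairs_excluded(self):
        model = self._model()
        pairs = [("fatigue pain", "covid fever", 1.0),
                 ("fatigue covid", "pain sleep", 2.0),
                 ("chronic pain", "severe fatigue", 3.0),
                 ("", "fatigue pain", 0.5)]
        res = sentence_benchmark(model, pairs, method="wmd")
        assert res.n_pairs_used == 3 and res.n_pairs_excluded == 1
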