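"""Sliding windows, entropy scoring, aggregation, class prediction, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bgclm as bg
from bgclm.detection import DomainScoreTrack
from bgclm.training import _log_softmax


def _track(vocab, n, seed=0):
    rng = np.random.default_rng(seed)
    hits = [bg.DomainHit(f"g{i}", i, vocab.pfam_tokens[int(rng.integers(vocab.n_pfam))],
                         1, 50, 10.0, 1e-9) for i in range(n)]
    return bg.GenomeDomainTrack("G", hits)


class TestWindows:
    def test_200_domain_track_yields_137_windows(self, small_vocab):
        wins = bg.windows(_track(small_vocab, 200), small_vocab, w=64)
        assert len(wins) == 137
        # interior domain scored w times
        count = sum(1 for s, ids in wins if s <= 100 < s + (len(ids) - 1))
        assert count == 64

    def test_track_equal_to_window_gives_one_window(self, small_vocab):
        wins = bg.windows(_track(small_vocab, 64), small_vocab, w=64)
        assert len(wins) == 1 and len(wins[0][1]) == 65

    def test_short_track_gives_single_whole_window(self, small_vocab):
        wins = bg.windows(_track(small_vocab, 10), small_vocab, w=64)
        assert len(wins) == 1
        assert len(wins[0][1]) == 11 and wins[0][1][0] == small_vocab.mask_id

    def test_coverage_sums_to_w_times_windows(self, small_vocab):
        L, w = 150, 64
        wins = bg.windows(_track(small_vocab, L), small_vocab, w=w)
        counts = np.zeros(L, dtype=int)
        for s, ids in wins:
            counts[s: s + len(ids) - 1] += 1
        assert counts.sum() == w * (L - w + 1)
        assert (counts[w - 1: L - w + 1] == w).all()


class TestEntropy:
    def test_closed_forms(self):
        assert bg.entropy(np.ones(8) / 8) == pytest.approx(np.log(8), rel=1e-12)
        assert bg.entropy(np.array([0.0, 1.0, 0.0])) == 0.0
        assert bg.entropy(np.array([0.5, 0.5])) == pytest.approx(0.6931471805, abs=1e-9)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            bg.entropy(np.array([0.7, 0.7]))
        with pytest.raises(ValueError):
            bg.entropy(np.array([-0.1, 1.1]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=10))
    def test_bounded_by_log_support(self, weights):
        p = np.asarray(weights) / np.sum(weights)
        assert -1e-9 <= bg.entropy(p) <= np.log(len(p)) + 1e-9


class TestScoreWindow:
    def test_uniform_stub_closed_forms(self, small_vocab):
        stub = bg.UniformStub(small_vocab, "all")
        stub.vocab = small_vocab
        track = _track(small_vocab, 30)
        win = bg.windows(track, small_vocab, w=16)[0]
        ws = bg.score_window(stub, win)
        V, C = len(small_vocab), small_vocab.n_class
        assert ws.start_entropy == pytest.approx(np.log(C), rel=1e-9)
        assert np.allclose(ws.domain_entropy, np.log(V))
        assert np.allclose(ws.nll, np.log(V))

    def test_full_vocab_start_entropy_flag(self, small_vocab):
        stub = bg.UniformStub(small_vocab, "all")
        stub.vocab = small_vocab
        win = bg.windows(_track(small_vocab, 20), small_vocab, w=8)[0]
        ws = bg.score_window(stub, win, start_entropy_slice="full")
        assert ws.start_entropy == pytest.approx(np.log(len(small_vocab)), rel=1e-9)

    def test_confident_model_scores_approach_zero(self, small_vocab, tiny_model):
        class Echo:
            vocab = small_vocab

            def __call__(self, tokens, pad_mask=None):
                V = len(small_vocab)
                logits = np.full(tokens.shape + (V,), -30.0)
                np.put_along_axis(logits, np.asarray(tokens)[..., None], 30.0, axis=-1)
                return logits

        win = bg.windows(_track(small_vocab, 20), small_vocab, w=8)[0]
        ws = bg.score_window(Echo(), win)
        assert (ws.nll < 1e-6).all() and (ws.domain_entropy < 1e-6).all()

    def test_matches_scalar_loop_on_random_logits(self, small_vocab,
                                                  random_logit_stub):
        track = _track(small_vocab, 25, seed=3)
        win = bg.windows(track, small_vocab, w=12)[2]
        ws = bg.score_window(random_logit_stub, win)

        start, tokens = win
        logits = random_logit_stub(tokens[None, :])[0]
        # scalar re-derivation
        def softmax(z):
            e = np.exp(z - z.max())
            return e / e.sum()

        cls_ids = list(small_vocab.class_range)
        p0_full = softmax(logits[0])
        p0 = np.array([p0_full[i] for i in cls_ids])
        p0 = p0 / p0.sum()
        expected_start = -sum(pi * np.log(pi) for pi in p0 if pi > 0)
        assert ws.start_entropy == pytest.approx(expected_start, rel=1e-5)
        for i in range(1, len(tokens)):
            p = softmax(logits[i])
            ent = -sum(pi * np.log(pi) for pi in p if pi > 0)
            assert ws.domain_entropy[i - 1] == pytest.approx(ent, rel=1e-5)
            assert ws.nll[i - 1] == pytest.approx(-np.log(p[tokens[i]]), rel=1e-5)

    def test_batched_scoring_matches_single(self, small_vocab, tiny_model):
        track = _track(small_vocab, 40, seed=5)
        wins = bg.windows(track, small_vocab, w=16)
        batched = bg.score_windows(tiny_model, wins, batch_size=7)
        for ws, win in zip(batched, wins):
            single = bg.score_window(tiny_model, win)
            assert ws.start_entropy == pytest.approx(single.start_entropy, abs=1e-5)
            assert np.allclose(ws.nll, single.nll, atol=1e-5)


class TestAggregate:
    def test_hand_built_toy(self, small_vocab):
        track = _track(small_vocab, 4)
        scores = [
            bg.WindowScores(0, 1.0, np.array([0.2, 0.4]), np.array([2.0, 4.0])),
            bg.WindowScores(1, 2.0, np.array([0.6, 0.8]), np.array([6.0, 8.0])),
            bg.WindowScores(2, 3.0, np.array([1.0, 1.2]), np.array([10.0, 12.0])),
        ]
        out = bg.aggregate(track, scores, w=2)
        # domain 0: window 0 only -> -(1.0 + 0.2 + 2.0)/3
        assert out.domain_score[0] == pytest.approx(-(1.0 + 0.2 + 2.0) / 3)
        # domain 1: windows 0 and 1 -> -(1+0.4+4 + 2+0.6+6)/6
        assert out.domain_score[1] == pytest.approx(-(1 + 0.4 + 4 + 2 + 0.6 + 6) / 6)
        assert out.domain_score[3] == pytest.approx(-(3 + 1.2 + 12) / 3)
        assert np.array_equal(out.window_count, [1, 2, 2, 1])
        assert np.allclose(out.start_score[:3], [-1.0, -2.0, -3.0])
        assert np.isnan(out.start_score[3])

    def test_uniform_stub_gives_constant_scores_and_chance_auroc(self, small_vocab):
        stub = bg.UniformStub(small_vocab, "all")
        stub.vocab = small_vocab
        track = _track(small_vocab, 80, seed=1)
        st_ = bg.score_track(stub, track, w=16)
        assert np.allclose(st_.domain_score, st_.domain_score[0])
        labels = np.zeros(80, dtype=int)
        labels[10:30] = 1
        # scores are equal up to float rounding; quantize so ties are exact
        assert bg.auroc(np.round(st_.domain_score, 9), labels) == pytest.approx(0.5)

    def test_round_trip_score_file(self, small_vocab, tiny_model, tmp_path):
        track = _track(small_vocab, 30, seed=2)
        st_ = bg.score_track(tiny_model, track, w=8)
        path = tmp_path / "scores.tsv"
        st_.save(path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 30


class TestPredictClass:
    def test_uniform_stub_gives_uniform_simplex(self, small_vocab):
        stub = bg.UniformStub(small_vocab, "all")
        stub.vocab = small_vocab
        p = bg.predict_class(stub, [0, 1, 2])
        assert np.allclose(p, 1.0 / small_vocab.n_class)

    def test_output_is_simplex_for_model(self, tiny_model):
        rng = np.random.default_rng(0)
        for _ in range(5):
            seq = list(rng.integers(0, tiny_model.vocab.n_pfam,
                                    size=int(rng.integers(1, 20))))
            p = bg.predict_class(tiny_model, seq)
            assert p.shape == (tiny_model.vocab.n_class,)
            assert (p >= 0).all() and p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_accepts_accession_strings(self, tiny_model, small_vocab):
        p = bg.predict_class(tiny_model, small_vocab.pfam_tokens[:3])
        q = bg.predict_class(tiny_model, small_vocab.encode(small_vocab.pfam_tokens[:3]))
        assert np.allclose(p, q)

    def test_empty_sequence_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            bg.predict_class(tiny_model, [])


class TestEnsemble:
    def test_identity_and_mixture(self):
        v = np.array([0.2, 0.3, 0.5])
        assert np.allclose(bg.ensemble([v, v, v]), v)
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert np.allclose(bg.ensemble([a, b]), [0.5, 0.5])

    def test_matches_element_loop(self):
        rng = np.random.default_rng(1)
        preds = [rng.dirichlet(np.ones(6)) for _ in range(3)]
        expected = [sum(p[i] for p in preds) / 3 for i in range(6)]
        assert np.allclose(bg.ensemble(preds), expected)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            bg.ensemble([])


class TestMapClasses:
    def test_identity_and_collapse(self):
        classes = ["a", "b", "c"]
        p = np.array([0.2, 0.3, 0.5])
        ident = bg.map_classes(p, classes, {c: c for c in classes}, classes)
        assert np.allclose(ident, p)
        one = bg.map_classes(p, classes, {c: "x" for c in classes}, ["x"])
        assert np.allclose(one, [1.0])

    def test_unmapped_goes_to_other_and_loop_oracle(self):
        rng = np.random.default_rng(2)
        src = [f"s{i}" for i in range(10)]
        dst = ["d0", "d1", "other"]
        mapping = {s: dst[int(rng.integers(2))] for s in src[:7]}  # 3 unmapped
        p = rng.dirichlet(np.ones(10))
        out = bg.map_classes(p, src, mapping, dst)
        expected = np.zeros(3)
        for i, s in enumerate(src):
            expected[dst.index(mapping.get(s, "other"))] += p[i]
        assert np.allclose(out, expected)
        assert out.sum() == pytest.approx(1.0)

    def test_unknown_eval_class_rejected(self):
        with pytest.raises(ValueError):
            bg.map_classes(np.array([1.0]), ["a"], {"a": "zzz"}, ["b"])


class TestMetrics:
    def test_auroc_closed_forms(self):
        assert bg.auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert bg.auroc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5

    def test_auroc_single_class_errors(self):
        with pytest.raises(bg.UndefinedMetricError):
            bg.auroc([1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_auroc_matches_pairwise_count(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30).round(1)  # rounding induces ties
        labels = rng.integers(0, 2, size=30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert bg.auroc(scores, labels) == \
            pytest.approx(wins / (len(pos) * len(neg)), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_auroc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        base = bg.auroc(scores, labels)
        assert bg.auroc(np.exp(scores), labels) == pytest.approx(base, rel=1e-12)
        assert bg.auroc(3 * scores - 7, labels) == pytest.approx(base, rel=1e-12)

    def test_average_precision_closed_forms(self):
        assert bg.average_precision([4, 3, 2, 1], [1, 1, 0, 0]) == 1.0
        # single positive ranked 3rd of 5 -> 1/3
        assert bg.average_precision([5, 4, 3, 2, 1], [0, 0, 1, 0, 0]) == \
            pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_average_precision_matches_curve_walk(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, size=20)
        if labels.sum() == 0:
            labels[0] = 1
        order = np.argsort(-scores)
        ranked = labels[order]
        tp, ap = 0, 0.0
        for k, y in enumerate(ranked, start=1):
            if y:
                tp += 1
                ap += tp / k
        assert bg.average_precision(scores, labels) == \
            pytest.approx(ap / labels.sum(), rel=1e-9)

    def test_average_precision_no_positive_errors(self):
        with pytest.raises(bg.UndefinedMetricError):
            bg.average_precision([1, 2], [0, 0])

    def test_evaluate_detection_requires_labels(self, small_vocab, tiny_model):
        track = _track(small_vocab, 30)
        st_ = bg.score_track(tiny_model, track, w=8)
        with pytest.raises(ValueError):
            bg.evaluate_detection(track, st_)
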