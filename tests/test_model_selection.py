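"""NPMI, coherence, topic-count selection, relevance ranking, pruning."""

import math
from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from citylisten import (
    GeneratorConfig,
    TokenizedDoc,
    build_corpus,
    coherence_cv,
    count_windows,
    fit_lda,
    generate_corpus,
    npmi,
    prune_topics,
    relevance_rank,
)
from citylisten.model_selection import WindowCounts

TS = datetime(2020, 7, 1, tzinfo=timezone.utc)


def brute_force_counts(docs_tokens, wi, wj, window):
    """Independent per-pair window scan (no shared precomputation)."""
    n_win = ci = cj = cij = 0
    for toks in docs_tokens:
        n = len(toks)
        starts = [0] if n <= window else list(range(n - window + 1))
        for s in starts:
            seg = toks[s : s + window] if n > window else toks
            has_i, has_j = wi in seg, wj in seg
            n_win += 1
            ci += has_i
            cj += has_j
            cij += has_i and has_j
    return n_win, ci, cj, cij


def brute_force_npmi(docs_tokens, wi, wj, window):
    n, ci, cj, cij = brute_force_counts(docs_tokens, wi, wj, window)
    if ci == 0 or cj == 0:
        return 0.0
    if cij == 0:
        return -1.0
    p_i, p_j, p_ij = ci / n, cj / n, cij / n
    if p_ij >= 1.0:
        return 1.0
    return math.log(p_ij / (p_i * p_j)) / (-math.log(p_ij))


class TestNpmi:
    def toy_counts(self):
        return WindowCounts(
            n_windows=10,
            counts={"i": 4, "j": 5, "k": 3},
            pair_counts={frozenset(("i", "j")): 2},
        )

    def test_perfect_association(self):
        c = WindowCounts(5, {"a": 2, "b": 2}, {frozenset(("a", "b")): 2})
        assert npmi("a", "b", c) == pytest.approx(1.0, abs=1e-9)

    def test_independent_words_zero(self):
        # P(i,j) = 0.2 = 0.4 * 0.5 = P(i) P(j) exactly
        assert npmi("i", "j", self.toy_counts()) == pytest.approx(0.0, abs=1e-12)

    def test_never_cooccurring_floor(self):
        assert npmi("i", "k", self.toy_counts()) == -1.0

    def test_unobserved_word_zero_with_warning(self):
        with pytest.warns(UserWarning, match="never observed"):
            assert npmi("i", "zz", self.toy_counts()) == 0.0

    def test_symmetric(self):
        c = self.toy_counts()
        assert npmi("i", "j", c) == npmi("j", "i", c)

    def test_matches_brute_force_on_random_corpus(self):
        """200 random word pairs of a 100-doc corpus, against an
        independent per-pair window scan, to 1e-10."""
        rng = np.random.default_rng(5)
        vocab = [f"t{i:02d}" for i in range(30)]
        docs = [
            [vocab[j] for j in rng.integers(0, 30, size=rng.integers(4, 16))]
            for _ in range(100)
        ]
        window = 8  # shorter than many docs, so sliding actually happens
        counts = count_windows(docs, vocab, window=window)
        import warnings

        for _ in range(200):
            wi, wj = (vocab[i] for i in rng.integers(0, 30, size=2))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = npmi(wi, wj, counts)
                want = brute_force_npmi(docs, wi, wj, window)
            assert got == pytest.approx(want, abs=1e-10)


class TestCoherence:
    def repeated_pair_model(self):
        docs = [TokenizedDoc(f"d{i}", ("ham", "eggs"), TS, "C") for i in range(8)]
        model, _ = fit_lda(docs, k=1, alpha=1.0, beta=0.01, n_iters=30,
                           burn_in=10, seed=0)
        return model, docs

    def test_single_repeated_pair_is_one(self):
        model, docs = self.repeated_pair_model()
        assert coherence_cv(model, docs, top_n=2) == pytest.approx(1.0)

    def test_invariant_to_topic_permutation(self, separable):
        model = separable["model"]
        docs = separable["docs"]
        base = coherence_cv(model, docs, top_n=6)
        shuffled = type(model)(
            **{**model.__dict__, "phi_hat": model.phi_hat[::-1].copy()}
        )
        assert coherence_cv(shuffled, docs, top_n=6) == pytest.approx(base, abs=1e-12)

    def test_matches_independent_implementation(self, separable):
        """Cross-check against a from-scratch one-set C_V computed with
        plain dict/loop code on a 20-doc slice."""
        model = separable["model"]
        docs = separable["docs"][:20]
        top_n, window = 5, 110
        got = coherence_cv(model, docs, top_n=top_n, window=window)

        # independent path: sets-of-docs as windows (docs < window size)
        tokens = model.vocab.tokens
        topic_scores = []
        for t in range(model.k):
            order = sorted(range(len(tokens)), key=lambda i: (-model.phi_hat[t, i], tokens[i]))
            words = [tokens[i] for i in order[:top_n]]
            win_sets = [set(d.tokens) for d in docs]
            n_win = len(win_sets)

            def p(ws):
                return sum(1 for s in win_sets if ws <= s) / n_win

            vecs = []
            for wa in words:
                row = []
                for wb in words:
                    pij = p({wa, wb})
                    pi, pj = p({wa}), p({wb})
                    if pi == 0 or pj == 0:
                        row.append(0.0)
                    elif pij == 0:
                        row.append(-1.0)
                    elif pij >= 1.0:
                        row.append(1.0)
                    else:
                        row.append(math.log(pij / (pi * pj)) / (-math.log(pij)))
                vecs.append(row)
            vset = [sum(col) for col in zip(*vecs)]
            sims = []
            for v in vecs:
                num = sum(a * b for a, b in zip(v, vset))
                na = math.sqrt(sum(a * a for a in v))
                nb = math.sqrt(sum(b * b for b in vset))
                sims.append(num / (na * nb) if na > 0 and nb > 0 else 0.0)
            topic_scores.append(sum(sims) / len(sims))
        want = sum(topic_scores) / len(topic_scores)
        assert got == pytest.approx(want, abs=0.05)

    def test_top_n_too_small_rejected(self, separable):
        with pytest.raises(ValueError):
            coherence_cv(separable["model"], separable["docs"], top_n=1)


class TestSweepK:
    def test_report_shape_and_membership(self, recovery_runs):
        rep = recovery_runs[0]["report"]
        assert len(rep.candidates) == 7
        assert rep.selected_k in [k for k, _ in rep.candidates]
        assert all(np.isfinite(s) for _, s in rep.candidates)

    def test_singleton_grid(self, stop_kw):
        cfg = GeneratorConfig(k_true=2, V=150, D=120, alpha=0.1, seed=8)
        records, _ = generate_corpus(cfg)
        docs, _, vocab = build_corpus(records, stopwords=stop_kw)
        from citylisten import sweep_k

        rep = sweep_k(docs, [3], n_iters=50, burn_in=20, seed=0, vocab=vocab)
        assert rep.selected_k == 3


class TestRelevance:
    def toy_model(self):
        docs = [TokenizedDoc("a", ("u", "v", "w"), TS, "C")]
        model, _ = fit_lda(docs, k=1, n_iters=10, burn_in=5, seed=0)
        model.phi_hat = np.array([[0.5, 0.3, 0.2]])
        return model  # vocab sorted: u, v, w

    def test_hand_computed_scores_and_order(self):
        model = self.toy_model()
        p = np.array([0.4, 0.1, 0.5])
        ranking = relevance_rank(model, lambda_=0.6, top_n=3, p_w=p)
        lam = 0.6
        expect = {
            tok: lam * math.log(phi) + (1 - lam) * math.log(phi / pw)
            for tok, phi, pw in zip(["u", "v", "w"], [0.5, 0.3, 0.2], p)
        }
        got = dict(ranking.topic_terms[0])
        for tok in expect:
            assert got[tok] == pytest.approx(expect[tok], abs=1e-12)
        order = [t for t, _ in ranking.topic_terms[0]]
        assert order.index("v") < order.index("w")  # lift pushes v above w

    def test_lambda_one_matches_probability_sort(self, separable):
        model = separable["model"]
        r = relevance_rank(model, lambda_=1.0, top_n=10, corpus=separable["docs"])
        tokens = model.vocab.tokens
        for t in range(model.k):
            order = sorted(range(len(tokens)),
                           key=lambda i: (-model.phi_hat[t, i], tokens[i]))
            assert [tok for tok, _ in r.topic_terms[t]] == [tokens[i] for i in order[:10]]

    def test_lambda_zero_matches_lift_sort(self, separable):
        model = separable["model"]
        docs = separable["docs"]
        from citylisten.model_selection import corpus_word_probabilities

        p = corpus_word_probabilities(docs, model.vocab)
        r = relevance_rank(model, lambda_=0.0, top_n=10, p_w=p)
        tokens = model.vocab.tokens
        lift = model.phi_hat / p[None, :]
        for t in range(model.k):
            order = sorted(range(len(tokens)), key=lambda i: (-lift[t, i], tokens[i]))
            assert [tok for tok, _ in r.topic_terms[t]] == [tokens[i] for i in order[:10]]

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_order_flips_at_most_once_along_lambda(self, pa, pb):
        """Relevance of two words is linear in lambda, so their order can
        change at most once as lambda goes 0 -> 1."""
        phi = np.array([0.6, 0.4])
        p = np.array([0.05 + 0.9 * pa, 0.05 + 0.9 * pb])
        lams = np.linspace(0, 1, 41)
        sign = [
            np.sign(
                (l * np.log(phi[0]) + (1 - l) * np.log(phi[0] / p[0]))
                - (l * np.log(phi[1]) + (1 - l) * np.log(phi[1] / p[1]))
            )
            for l in lams
        ]
        changes = sum(
            1 for a, b in zip(sign, sign[1:]) if a != b and a != 0 and b != 0
        )
        assert changes <= 1


class TestPrune:
    def test_equal_shares_all_retained(self):
        out = prune_topics(4, [0, 1, 2, 3] * 5, min_share=0.2)
        assert all(s.retained for s in out)
        assert sum(s.share for s in out) == pytest.approx(1.0)

    def test_small_topic_flagged(self):
        labels = [0] * 50 + [1] * 49 + [2]
        out = prune_topics(3, labels, min_share=0.05)
        assert [s.retained for s in out] == [True, True, False]

    def test_never_flags_above_threshold(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 5, size=300)
        out = prune_topics(5, labels, min_share=0.1)
        for s in out:
            if s.share >= 0.1:
                assert s.retained

    def test_token_weighted_shares(self):
        # one doc of topic 1 but very long: token share dominates
        out = prune_topics(2, [0, 0, 1], doc_weights=[2, 2, 96], min_share=0.5)
        assert [s.retained for s in out] == [False, True]

    def test_six_topic_fixture_with_two_tiny_topics_retains_four(self, stop_kw):
        """On a 6-topic corpus where two topics carry ~3% of documents, the
        share threshold drops exactly those two."""
        cfg = GeneratorConfig(
            k_true=6, V=500, D=1500, alpha=0.05, block_mass=1.0,
            doc_length_mean=15.0, noise_rate=0.0, marker_rate=0.0,
            topic_weights=[0.235, 0.235, 0.235, 0.235, 0.03, 0.03],
            prevalence_concentration=400.0, seed=202,
        )
        records, _ = generate_corpus(cfg)
        docs, _, vocab = build_corpus(records, stopwords=stop_kw)
        model, _ = fit_lda(docs, k=6, alpha=0.1, n_iters=400, burn_in=200,
                           seed=202, vocab=vocab, n_restarts=4)
        out = prune_topics(
            6, model.theta_hat.argmax(1), min_share=0.05,
            doc_weights=[len(d.tokens) for d in docs],
        )
        assert sum(s.retained for s in out) == 4
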