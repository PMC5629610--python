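"""Network tests, including an independent scalar-loop forward oracle."""

import math

import numpy as np
import pytest

from mednorm import (
    Candidate,
    EmbeddingTable,
    MentionRecord,
    NIL_ID,
    RankerParams,
    WordStats,
    conv_feature_map,
    embed,
    encode,
    morph_features,
    rank_candidates,
    score_pair,
    semantic_similarity,
)
from mednorm.candidates import CandidateSet, TIER_CII, TIER_CIII
from mednorm.ranker import D_MOR, Gradients, _forward, backward


# ---------------------------------------------------------------------------
# Independent forward-pass oracle: explicit python loops, no shared code
# with the implementation beyond parameter/embedding access.
# ---------------------------------------------------------------------------

def oracle_score(m_tokens, c_tokens, params, stats):
    t = params.embeddings.t
    widths = params.bank.widths
    max_c = max(widths)

    def matrix(tokens):
        length = max(len(tokens), max_c)
        x = [[0.0] * length for _ in range(t)]
        for i, tok in enumerate(tokens):
            vec = params.embeddings.get(tok)
            for r in range(t):
                x[r][i] = float(vec[r])
        return x

    def enc(x):
        pooled = []
        for c in widths:
            w = params.bank.weights[c]
            b = params.bank.biases[c]
            for j in range(w.shape[0]):
                best = None
                for i in range(len(x[0]) - c + 1):
                    acc = b[j]
                    for r in range(t):
                        for k in range(c):
                            acc += w[j, r, k] * x[r][i + k]
                    val = acc if acc > 0 else 0.0
                    best = val if best is None or val > best else best
                pooled.append(best)
        return pooled

    x_m, x_y = matrix(m_tokens), matrix(c_tokens)
    v_m, v_y = enc(x_m), enc(x_y)
    p = len(v_m)
    v_sem = 0.0
    for i in range(p):
        for j in range(p):
            v_sem += v_m[i] * params.M[i, j] * v_y[j]
    v_sem /= p
    wm, wy = set(m_tokens), set(c_tokens)
    shared, union = wm & wy, wm | wy
    prop = len(shared) / len(union) if union else 0.0
    num = sum(stats.imf(w) ** 2 for w in shared)
    nm = math.sqrt(sum(stats.imf(w) ** 2 for w in wm))
    ny = math.sqrt(sum(stats.imf(w) ** 2 for w in wy))
    if nm == 0 or ny == 0:
        cos = 1.0 if wm == wy else 0.0
    else:
        cos = num / (nm * ny)
    v_joint = v_m + v_y + [v_sem, prop, cos]
    hidden = params.W_h.shape[0]
    o = []
    for h in range(hidden):
        acc = params.b_h[h]
        for j in range(len(v_joint)):
            acc += params.W_h[h, j] * v_joint[j]
        o.append(acc if acc > 0 else 0.0)
    z0 = sum(o[h] * params.q0[h] for h in range(hidden))
    z1 = sum(o[h] * params.q1[h] for h in range(hidden))
    return math.exp(z1) / (math.exp(z0) + math.exp(z1))


_TOKENS = ["aa", "bb", "cc", "dd", "ee", "ff", "polyps"]


class TestEmbed:
    def test_shape(self, tiny_params):
        x = embed(["aa", "bb", "cc"], tiny_params.embeddings, min_len=3)
        assert x.shape == (5, 3)

    def test_padding(self, tiny_params):
        x = embed(["aa"], tiny_params.embeddings, min_len=3)
        assert x.shape == (5, 3)
        assert np.all(x[:, 1:] == 0.0)

    def test_oov_deterministic(self):
        a = EmbeddingTable(8).get("neverseen")
        b = EmbeddingTable(8).get("neverseen")
        np.testing.assert_array_equal(a, b)


class TestConv:
    def test_zero_input_zero_bias(self):
        s = np.ones((3, 2))
        out = conv_feature_map(np.zeros((3, 4)), s, 0.0)
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_relu_floor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 4))
        out = conv_feature_map(x, rng.normal(size=(3, 2)), -1e9)
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_window_loop_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 4))
        s = rng.normal(size=(4, 2))
        b = 0.3
        out = conv_feature_map(x, s, b)
        assert out.shape == (3,)
        for i in range(3):
            expected = max(float((s * x[:, i:i + 2]).sum()) + b, 0.0)
            assert out[i] == pytest.approx(expected, abs=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(2)
        out = conv_feature_map(rng.normal(size=(5, 6)),
                               rng.normal(size=(5, 3)), rng.normal())
        assert np.all(out >= 0.0)


class TestEncode:
    def test_max_of_single_filter(self, tiny_params):
        bank = tiny_params.bank
        x = embed(["aa", "bb", "cc", "dd"], tiny_params.embeddings, 3)
        v = encode(x, bank)
        assert v.shape == (4,)
        # element 0 equals the max of filter 0's explicit map
        fmap = conv_feature_map(x, bank.weights[2][0], bank.biases[2][0])
        assert v[0] == pytest.approx(fmap.max())

    def test_superset_window_monotonicity(self, tiny_params):
        table = tiny_params.embeddings
        short = embed(["aa", "bb", "cc"], table, 3)
        longer = embed(["aa", "bb", "cc", "aa"], table, 3)
        v_short = encode(short, tiny_params.bank)
        v_long = encode(longer, tiny_params.bank)
        # windows of the longer text are a superset -> pooled never decreases
        assert np.all(v_long >= v_short - 1e-12)

    def test_length_matches_filter_count(self):
        rng = np.random.default_rng(3)
        params = RankerParams.init(t=4, widths=(2, 3), p_per_width=50,
                                   hidden=8, rng=rng)
        x = embed(["aa", "bb", "cc"], params.embeddings, 3)
        assert encode(x, params.bank).shape == (100,)


class TestSemanticSimilarity:
    def test_identity_matrix_is_dot(self):
        rng = np.random.default_rng(4)
        v, w = rng.normal(size=4), rng.normal(size=4)
        assert semantic_similarity(v, w, np.eye(4)) == pytest.approx(v @ w)

    def test_zero_vector(self):
        assert semantic_similarity(np.zeros(4), np.ones(4), np.eye(4)) == 0.0

    def test_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        v, w, M = rng.normal(size=4), rng.normal(size=4), rng.normal(size=(4, 4))
        expected = sum(
            v[i] * M[i, j] * w[j] for i in range(4) for j in range(4)
        )
        assert semantic_similarity(v, w, M) == pytest.approx(expected, abs=1e-12)

    def test_self_similarity_is_squared_norm(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=4)
        out = semantic_similarity(v, v, np.eye(4))
        assert out >= 0.0
        assert out == pytest.approx(np.linalg.norm(v) ** 2)


class TestMorphFeatures:
    def test_identical(self, tiny_stats):
        out = morph_features(["aa", "bb"], ["aa", "bb"], tiny_stats)
        np.testing.assert_allclose(out, [1.0, 1.0])

    def test_disjoint(self, tiny_stats):
        out = morph_features(["aa"], ["cc"], tiny_stats)
        np.testing.assert_allclose(out, [0.0, 0.0])

    def test_hand_computed_pair(self):
        # KB names: colonic polyps / colorectal polyps / polyps -> N=3
        stats = WordStats({"colonic": 1, "colorectal": 1, "polyps": 3}, 3)
        lp = math.log(3 / 4) ** 2    # imf(polyps)^2
        lc = math.log(3 / 2) ** 2    # imf(colonic)^2 = imf(colorectal)^2
        expected_cos = lp / math.sqrt((lc + lp) * (lc + lp))
        out = morph_features(["colonic", "polyps"],
                             ["colorectal", "polyps"], stats)
        assert out[0] == pytest.approx(1 / 3)
        assert out[1] == pytest.approx(expected_cos, abs=1e-12)

    def test_range(self, tiny_stats):
        out = morph_features(["aa", "bb"], ["bb", "cc"], tiny_stats)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)
        assert len(out) == D_MOR


def _cand(name, cid="CX"):
    return Candidate(cid, name, "KB", "partial")


class TestScorePair:
    def test_equal_label_weights_give_half(self, tiny_params, tiny_stats):
        tiny_params.q0 = tiny_params.q1.copy()
        sc = score_pair("aa bb", _cand("cc dd"), tiny_params, tiny_stats)
        assert sc.score == pytest.approx(0.5)

    def test_relu_floored_hidden_gives_half(self, tiny_params, tiny_stats):
        tiny_params.b_h = np.full_like(tiny_params.b_h, -1e9)
        sc = score_pair("aa bb", _cand("cc dd"), tiny_params, tiny_stats)
        assert sc.score == pytest.approx(0.5)

    def test_two_class_scores_sum_to_one(self, tiny_params, tiny_stats):
        from mednorm.ranker import _forward
        from mednorm._text import tokenize

        score, cache = _forward(tokenize("aa bb"), tokenize("bb cc"),
                                tiny_params, tiny_stats)
        o = cache["o_h"]
        z0 = float(o @ tiny_params.q0)
        z1 = float(o @ tiny_params.q1)
        p1 = math.exp(z1) / (math.exp(z0) + math.exp(z1))
        p0 = math.exp(z0) / (math.exp(z0) + math.exp(z1))
        assert p0 + p1 == pytest.approx(1.0)
        assert score == pytest.approx(p1)

    def test_score_in_open_interval(self, tiny_params, tiny_stats):
        sc = score_pair("aa", _cand("bb"), tiny_params, tiny_stats)
        assert 0.0 < sc.score < 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_forward_oracle(self, seed, tiny_stats):
        rng = np.random.default_rng(seed)
        params = RankerParams.init(t=5, widths=(2, 3), p_per_width=2,
                                   hidden=4, rng=rng)
        n_m, n_c = rng.integers(1, 5), rng.integers(1, 5)
        m_toks = list(rng.choice(_TOKENS, n_m))
        c_toks = list(rng.choice(_TOKENS, n_c))
        got = score_pair(
            " ".join(m_toks), _cand(" ".join(c_toks)), params, tiny_stats
        ).score
        want = oracle_score(m_toks, c_toks, params, tiny_stats)
        assert got == pytest.approx(want, abs=1e-10)


class TestGradients:
    def test_finite_differences(self, tiny_stats):
        rng = np.random.default_rng(7)
        params = RankerParams.init(t=5, widths=(2, 3), p_per_width=2,
                                   hidden=4, rng=rng)
        m_toks, c_toks = ["aa", "bb", "cc"], ["bb", "dd"]
        score, cache = _forward(m_toks, c_toks, params, tiny_stats)
        grads = Gradients(params)
        backward(cache, score, 1, params, grads)
        eps = 1e-6

        def loss():
            s, _ = _forward(m_toks, c_toks, params, tiny_stats)
            return -math.log(s)

        def check(array, grad, idx):
            v0 = array[idx]
            array[idx] = v0 + eps
            l1 = loss()
            array[idx] = v0 - eps
            l2 = loss()
            array[idx] = v0
            numeric = (l1 - l2) / (2 * eps)
            assert grad[idx] == pytest.approx(numeric, abs=1e-5)

        check(params.M, grads.M, (0, 1))
        check(params.W_h, grads.W_h, (1, 2))
        check(params.q0, grads.q0, (0,))
        check(params.q1, grads.q1, (3,))
        check(params.b_h, grads.b_h, (2,))
        check(params.bank.weights[2], grads.conv_w[2], (1, 0, 1))
        check(params.bank.weights[3], grads.conv_w[3], (0, 2, 2))
        check(params.bank.biases[3], grads.conv_b[3], (1,))
        row = params.embeddings.lookup("bb")
        check(params.embeddings.vectors, _EmbProxy(grads.emb, row), (row, 2))


class _EmbProxy:
    """Adapter so the finite-difference helper can index embedding grads."""

    def __init__(self, emb, row):
        self.emb = emb
        self.row = row

    def __getitem__(self, idx):
        row, k = idx
        return self.emb[row][k]


class TestRankCandidates:
    def _mention(self, text):
        return MentionRecord("d", 0, len(text), text)

    def test_singleton_short_circuit(self, tiny_stats):
        m = self._mention("tremulous")
        cs = CandidateSet(m, TIER_CII, (_cand("tremulous", "C1"),))
        scored, result = rank_candidates(m, cs, None, tiny_stats)
        assert result.predicted_id == "C1"
        assert result.score == 1.0
        assert scored[0].score == 1.0

    def test_nil_singleton_short_circuit(self, tiny_stats):
        m = self._mention("glorp")
        nil = Candidate(NIL_ID, "<NIL>", "NIL", "nil")
        cs = CandidateSet(m, TIER_CIII, (nil,), nil_included=True)
        _, result = rank_candidates(m, cs, None, tiny_stats)
        assert result.predicted_id == NIL_ID
        assert result.score == 1.0

    def test_empty_set_flags_no_mapping(self, tiny_stats):
        m = self._mention("glorp")
        cs = CandidateSet(m, TIER_CIII, ())
        _, result = rank_candidates(m, cs, None, tiny_stats)
        assert result.predicted_id is None

    def test_planted_morphology_reward(self, tiny_stats):
        # r_h weighting only v_mor: identical candidate must win
        rng = np.random.default_rng(8)
        params = RankerParams.init(t=5, widths=(2, 3), p_per_width=2,
                                   hidden=1, rng=rng)
        joint = params.W_h.shape[1]
        params.W_h = np.zeros((1, joint))
        params.W_h[0, -2:] = 1.0     # the two morphological features
        params.b_h = np.zeros(1)
        params.q0 = np.zeros(1)
        params.q1 = np.ones(1)
        m = self._mention("aa bb")
        cs = CandidateSet(m, TIER_CIII, (
            _cand("cc dd", "C1"), _cand("aa bb", "C2"), _cand("aa ee", "C3"),
        ))
        _, result = rank_candidates(m, cs, params, tiny_stats)
        assert result.predicted_id == "C2"

    def test_order_invariance(self, tiny_params, tiny_stats):
        m = self._mention("aa bb")
        cands = (_cand("cc dd", "C1"), _cand("aa bb", "C2"),
                 _cand("aa ee", "C3"))
        cs1 = CandidateSet(m, TIER_CIII, cands)
        cs2 = CandidateSet(m, TIER_CIII, tuple(reversed(cands)))
        s1, r1 = rank_candidates(m, cs1, tiny_params, tiny_stats)
        s2, r2 = rank_candidates(m, cs2, tiny_params, tiny_stats)
        assert [c.candidate.concept_id for c in s1] == \
            [c.candidate.concept_id for c in s2]
        assert r1.predicted_id == r2.predicted_id

    def test_descending_order(self, tiny_params, tiny_stats):
        m = self._mention("aa bb cc")
        cands = tuple(_cand(f"{w} dd", f"C{i}")
                      for i, w in enumerate(["aa", "bb", "ee", "ff"]))
        scored, _ = rank_candidates(
            m, CandidateSet(m, TIER_CIII, cands), tiny_params, tiny_stats
        )
        values = [sc.score for sc in scored]
        assert values == sorted(values, reverse=True)


class TestCheckpoint:
    def test_roundtrip(self, tiny_params, tiny_stats, tmp_path):
        path = tmp_path / "ckpt.npz"
        # touch some vocabulary first
        score_before = score_pair("aa bb", _cand("bb cc"), tiny_params,
                                  tiny_stats).score
        tiny_params.save(path)
        loaded = RankerParams.load(path)
        score_after = score_pair("aa bb", _cand("bb cc"), loaded,
                                 tiny_stats).score
        assert score_after == pytest.approx(score_before, abs=1e-15)
        np.testing.assert_array_equal(loaded.M, tiny_params.M)
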