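import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contextsim import (
    CorrMatrix,
    DegenerateVectorError,
    EmbeddingTable,
    MeasureId,
    WindowPolicy,
    compute_measure,
    correlation_matrix,
    cosine_measure,
    cosine_vec,
    dynamic_full,
    euclidean_measure,
    extract_window,
    pearson,
    simpler_dynamic,
    tokenize,
)
from contextsim.similarity_measures import MEASURE_POLICY

from .oracle import o_all_measures, o_cosine, o_pearson

finite_vec = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=4, max_size=40
)


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        u = rng.standard_normal(30)
        assert pearson(u, u) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        u = rng.standard_normal(30)
        assert pearson(u, 3.5 * u + 2.0) == pytest.approx(1.0, abs=1e-12)
        assert pearson(u, -2.0 * u + 1.0) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_two_pass_definition(self):
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(
            o_pearson([1, 2, 3, 4], [2, 1, 4, 3]), abs=1e-12
        )

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateVectorError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(u=finite_vec, v=finite_vec)
    def test_bounded_and_symmetric(self, u, v):
        n = min(len(u), len(v))
        u, v = u[:n], v[:n]
        if len(set(u)) < 2 or len(set(v)) < 2:
            return
        try:
            r = pearson(u, v)
        except DegenerateVectorError:
            return
        assert -1.0 <= r <= 1.0
        assert r == pytest.approx(pearson(v, u), abs=1e-12)


class TestCosine:
    def test_scale_invariance_and_orthogonality(self, rng):
        u = rng.standard_normal(300)
        assert cosine_vec(u, 2 * u) == pytest.approx(1.0, abs=1e-12)
        assert cosine_vec([1, 0], [0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_dot_norm_definition(self, rng):
        u, v = rng.standard_normal(300), rng.standard_normal(300)
        assert cosine_vec(u, v) == pytest.approx(o_cosine(list(u), list(v)), abs=1e-12)

    def test_zero_norm_degenerate(self):
        with pytest.raises(DegenerateVectorError):
            cosine_vec([0.0, 0.0], [1.0, 2.0])


class TestCorrelationMatrix:
    def test_identical_words_give_all_ones(self):
        table = EmbeddingTable.from_items({"a": np.array([1.0, 2.0, 5.0, 3.0])})
        p = tokenize("a a a")
        w = extract_window(p, 2, WindowPolicy.FIXED_K_ALL, 2, table)
        m = correlation_matrix(w, table)
        np.testing.assert_allclose(m.values, 1.0)

    def test_reproduces_printed_worked_example(self, fig3, fig3_table):
        passage, printed = fig3
        w = extract_window(passage, 5, WindowPolicy.FIXED_K_ALL, 3, fig3_table)
        m = correlation_matrix(w, fig3_table)
        assert m.labels == ["the", "smart", "watch", "space"]
        np.testing.assert_allclose(m.values, printed.values, atol=1e-12)
        assert m.entry("space", "the") == pytest.approx(0.42, abs=1e-12)

    def test_matches_entrywise_brute_force(self, small_table, small_passages):
        p = small_passages[0]
        w = extract_window(p, 10, WindowPolicy.FIXED_K_ALL, 3, small_table)
        m = correlation_matrix(w, small_table)
        vecs = [small_table.vectors[small_table.vocabulary[l]] for l in m.labels]
        for i in range(4):
            for j in range(4):
                expect = 1.0 if i == j else o_pearson(list(vecs[i]), list(vecs[j]))
                assert m.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CorrMatrix(labels=["a", "b"], values=np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(ValueError):
            CorrMatrix(labels=["a", "b"], values=np.array([[1.0, 1.5], [1.5, 1.0]]))


class TestDynamicSums:
    def test_worked_example_sums(self, fig3):
        _, m = fig3
        assert dynamic_full(m) == pytest.approx(1.98, abs=1e-12)
        assert simpler_dynamic(m) == pytest.approx(0.98, abs=1e-12)

    def test_all_ones_matrix(self):
        m = CorrMatrix(labels=list("abcd"), values=np.ones((4, 4)))
        assert dynamic_full(m) == pytest.approx(6.0)
        assert simpler_dynamic(m) == pytest.approx(3.0)

    def test_full_equals_explicit_index_sum_and_identity(self, rng):
        a = rng.uniform(-1, 1, size=(5, 5))
        vals = (a + a.T) / 2
        np.fill_diagonal(vals, 1.0)
        vals = np.clip(vals, -1, 1)
        m = CorrMatrix(labels=list("abcde"), values=vals)
        explicit = sum(vals[i, j] for i in range(5) for j in range(5) if i > j)
        assert dynamic_full(m) == pytest.approx(explicit, abs=1e-12)
        ctx_pairs = sum(vals[i, j] for i in range(4) for j in range(4) if i > j)
        assert simpler_dynamic(m) == pytest.approx(dynamic_full(m) - ctx_pairs, abs=1e-12)


class TestCosineMeasure:
    def test_single_context_word_identical_to_target(self):
        table = EmbeddingTable.from_items({"a": np.array([1.0, 2.0, 3.0])})
        p = tokenize("a a")
        w = extract_window(p, 1, WindowPolicy.FIXED_K_ALL, 1, table)
        assert cosine_measure(w, table) == pytest.approx(1.0, abs=1e-12)

    def test_zero_sum_context_degenerate(self):
        table = EmbeddingTable.from_items({
            "up": np.array([1.0, 2.0, 3.0]),
            "down": np.array([-1.0, -2.0, -3.0]),
            "it": np.array([1.0, 0.0, 0.0]),
        })
        p = tokenize("up down it")
        w = extract_window(p, 2, WindowPolicy.FIXED_K_ALL, 2, table)
        with pytest.raises(DegenerateVectorError):
            cosine_measure(w, table)


class TestEuclideanMeasure:
    def test_distance_two_gives_half(self):
        table = EmbeddingTable.from_items({
            "a": np.array([0.0, 0.0, 1.0]),
            "b": np.array([2.0, 0.0, 1.0]),
        })
        p = tokenize("a b")
        w = extract_window(p, 1, WindowPolicy.FIXED_K_ALL, 1, table)
        val, saturated = euclidean_measure(w, table)
        assert val == pytest.approx(0.5, abs=1e-12)
        assert not saturated

    def test_target_equal_to_context_mean_saturates(self):
        table = EmbeddingTable.from_items({"a": np.array([1.0, 2.0, 3.0])})
        p = tokenize("a a")
        w = extract_window(p, 1, WindowPolicy.FIXED_K_ALL, 1, table)
        val, saturated = euclidean_measure(w, table)
        assert val == 1e12
        assert saturated


class TestComputeMeasure:
    def test_worked_example_dispatch(self, fig3, fig3_table):
        passage, _ = fig3
        full = compute_measure(passage, 5, MeasureId.DYNAMIC_FULL, 3, fig3_table)
        simp = compute_measure(passage, 5, MeasureId.DYNAMIC_SIMPLER, 3, fig3_table)
        assert full.value == pytest.approx(1.98, abs=1e-9)
        assert simp.value == pytest.approx(0.98, abs=1e-9)

    @pytest.mark.parametrize("measure", list(MeasureId))
    def test_token_zero_missing(self, fig3, fig3_table, measure):
        passage, _ = fig3
        sv = compute_measure(passage, 0, measure, 3, fig3_table)
        assert sv.missing

    def test_constant_vector_yields_missing_with_warning(self):
        table = EmbeddingTable.from_items({
            "flat": np.array([2.0, 2.0, 2.0]),
            "a": np.array([1.0, 2.0, 3.0]),
            "b": np.array([3.0, 1.0, 2.0]),
        })
        p = tokenize("flat a b")
        with pytest.warns(RuntimeWarning):
            sv = compute_measure(p, 2, MeasureId.DYNAMIC_FULL, 2, table)
        assert sv.missing

    @pytest.mark.parametrize("measure", list(MeasureId))
    def test_matches_oracle_on_synthetic_passage(self, small_table, small_passages, measure):
        p = small_passages[1]
        for i in range(len(p.tokens)):
            got = compute_measure(p, i, measure, 3, small_table)
            want = o_all_measures(p, i, 3, small_table)[measure.value]
            if want is None:
                assert got.missing
            else:
                assert got.value == pytest.approx(want, rel=1e-10, abs=1e-10)


class TestInvariances:
    """Order and affine invariances of the measure families."""

    def _window_vectors(self, rng, n=4, d=60):
        return rng.standard_normal((n, d))

    def test_context_order_invariance(self, rng):
        vecs = self._window_vectors(rng)
        for perm in ([1, 0, 2], [2, 1, 0], [2, 0, 1]):
            permuted = np.vstack([vecs[perm], vecs[-1:]])
            m0 = np.corrcoef(vecs)
            m1 = np.corrcoef(permuted)
            lab = list("abcd")
            c0 = CorrMatrix(lab, np.clip((m0 + m0.T) / 2, -1, 1))
            c1 = CorrMatrix(lab, np.clip((m1 + m1.T) / 2, -1, 1))
            assert dynamic_full(c1) == pytest.approx(dynamic_full(c0), abs=1e-10)
            assert simpler_dynamic(c1) == pytest.approx(simpler_dynamic(c0), abs=1e-10)
            assert cosine_vec(vecs[perm].sum(axis=0), vecs[-1]) == pytest.approx(
                cosine_vec(vecs[:3].sum(axis=0), vecs[-1]), abs=1e-12
            )
            assert np.linalg.norm(vecs[-1] - vecs[perm].mean(axis=0)) == pytest.approx(
                np.linalg.norm(vecs[-1] - vecs[:3].mean(axis=0)), abs=1e-12
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.01, max_value=100.0),
        b=st.floats(min_value=-50.0, max_value=50.0),
        which=st.integers(min_value=0, max_value=3),
    )
    def test_affine_invariance_of_dynamic_measures(self, a, b, which):
        rng = np.random.default_rng(42)
        vecs = rng.standard_normal((4, 60))
        transformed = vecs.copy()
        transformed[which] = a * vecs[which] + b
        lab = list("abcd")
        m0 = CorrMatrix(lab, np.clip(np.corrcoef(vecs), -1, 1))
        m1 = CorrMatrix(lab, np.clip(np.corrcoef(transformed), -1, 1))
        assert dynamic_full(m1) == pytest.approx(dynamic_full(m0), abs=1e-10)
        assert simpler_dynamic(m1) == pytest.approx(simpler_dynamic(m0), abs=1e-10)

    def test_positive_scaling_preserves_cosine(self, rng):
        u, v = rng.standard_normal(60), rng.standard_normal(60)
        assert cosine_vec(4.2 * u, v) == pytest.approx(cosine_vec(u, v), abs=1e-12)


def test_measure_policy_binding_is_fixed():
    assert MEASURE_POLICY[MeasureId.COSINE_CONTENT] is WindowPolicy.FIXED_K_CONTENT_SENT
    assert MEASURE_POLICY[MeasureId.EUCLIDEAN_SENTENCE] is WindowPolicy.ALL_PRECEDING_SENT
    for m in (MeasureId.COSINE_ALL, MeasureId.EUCLIDEAN_FIXED,
              MeasureId.DYNAMIC_FULL, MeasureId.DYNAMIC_SIMPLER):
        assert MEASURE_POLICY[m] is WindowPolicy.FIXED_K_ALL
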