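"""Per-gene MLP training, probing, joining and binarization."""

import numpy as np
import pytest

from regnann import (
    CorrelationMatrix,
    GeneRegressor,
    ExpressionMatrix,
    LearningParams,
    ToySpec,
    binarize,
    build_patterns,
    forward,
    generate_toy,
    infer_network,
    interaction_strength,
    majority_vote,
    probe,
    read_correlation,
    rescale_linear,
    train_gene,
    write_correlation,
)
from regnann.inference import _pattern_gradient, hidden_size

from conftest import random_scores


def _linear_pair_expr(m=60, seed=5):
    """Rescaled 2-gene matrix with identical columns (perfect correlation)."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1, 1, m)
    return rescale_linear(ExpressionMatrix(np.column_stack([a, a])))


class TestPatterns:
    def test_pattern_definition(self):
        expr = ExpressionMatrix(
            np.array([[0.2, -0.5, 0.9]]), normalization="linear_rescaled"
        )
        x, t = build_patterns(expr, 1)
        assert x[0] == pytest.approx(-0.5)
        assert np.allclose(t[0], [0.2, 0.9])

    def test_one_pattern_per_sample_and_edge_dimensions(self, rng):
        expr = rescale_linear(ExpressionMatrix(rng.normal(size=(7, 2))))
        x, t = build_patterns(expr, 0)
        assert x.shape == (7,) and t.shape == (7, 1)

    def test_raw_input_rejected_with_rescaling_hint(self, rng):
        expr = ExpressionMatrix(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="rescale"):
            build_patterns(expr, 0)


class TestForward:
    def test_zero_weights_give_zero_outputs(self):
        reg = GeneRegressor(0, np.zeros(3), np.zeros((3, 4)))
        assert (forward(reg, 0.77) == 0).all()
        assert (probe(reg) == 0).all()

    def test_single_unit_closed_form(self):
        reg = GeneRegressor(0, np.array([1.3]), np.array([[-0.7]]))
        x = 0.4
        assert forward(reg, x)[0] == pytest.approx(
            np.tanh(-0.7 * np.tanh(1.3 * x)), abs=1e-15
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_matrix_free_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h, n_out = int(rng.integers(1, 6)), int(rng.integers(1, 9))
        reg = GeneRegressor(0, rng.normal(0, 1, h), rng.normal(0, 1, (h, n_out)))
        x = float(rng.uniform(-1, 1))
        y = forward(reg, x)
        for j in range(n_out):
            acc = 0.0
            for k in range(h):
                acc += reg.w_out[k, j] * np.tanh(reg.w_in[k] * x)
            assert y[j] == pytest.approx(np.tanh(acc), abs=1e-12)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        reg = GeneRegressor(0, rng.normal(0, 5, 4), rng.normal(0, 5, (4, 6)))
        y = forward(reg, 1.0)
        assert (np.abs(y) < 1).all()


class TestGradient:
    @pytest.mark.parametrize("seed", range(50))
    def test_backprop_matches_central_finite_differences(self, seed):
        # the core oracle: analytic gradient vs numeric differentiation
        rng = np.random.default_rng(seed)
        h, n_out = int(rng.integers(1, 5)), int(rng.integers(1, 8))
        reg = GeneRegressor(0, rng.normal(0, 1, h), rng.normal(0, 1, (h, n_out)))
        x = float(rng.uniform(-1, 1))
        target = rng.uniform(-1, 1, n_out)
        g_in, g_out = _pattern_gradient(reg, x, target)

        def err(w_in, w_out):
            y = np.tanh(w_out.T @ np.tanh(w_in * x))
            return 0.5 * np.sum((y - target) ** 2)

        eps = 1e-6
        analytic = np.concatenate([g_in, g_out.ravel()])
        numeric = np.empty_like(analytic)
        k = 0
        for i in range(h):
            wp, wm = reg.w_in.copy(), reg.w_in.copy()
            wp[i] += eps
            wm[i] -= eps
            numeric[k] = (err(wp, reg.w_out) - err(wm, reg.w_out)) / (2 * eps)
            k += 1
        for i in range(h):
            for j in range(n_out):
                wp, wm = reg.w_out.copy(), reg.w_out.copy()
                wp[i, j] += eps
                wm[i, j] -= eps
                numeric[k] = (err(reg.w_in, wp) - err(reg.w_in, wm)) / (2 * eps)
                k += 1
        scale = np.abs(analytic) + np.abs(numeric)
        rel = np.abs(analytic - numeric) / np.maximum(scale, 1e-8)
        assert rel.max() < 1e-5


class TestTraining:
    def test_hidden_size_rule_of_thumb(self):
        assert hidden_size(1) == 1
        assert hidden_size(3) == 2
        assert hidden_size(19) == 5
        assert hidden_size(19, override=7) == 7

    def test_converges_on_perfectly_correlated_pair(self):
        expr = _linear_pair_expr()
        reg = train_gene(expr, 0, LearningParams(seed=9))
        x, t = build_patterns(expr, 0)
        y = np.tanh(np.tanh(np.outer(x, reg.w_in)) @ reg.w_out)
        assert np.mean((y - t) ** 2) < 0.05
        assert probe(reg)[0] > 0.8

    def test_zero_rate_not_representable_and_tiny_rate_is_noop_like(self):
        # eta must be > 0 by contract; the smallest step barely moves weights
        with pytest.raises(ValueError):
            LearningParams(learning_rate=0.0)
        expr = _linear_pair_expr(m=20)
        p_tiny = LearningParams(learning_rate=1e-12, momentum=0.0, epochs=1, seed=3)
        reg = train_gene(expr, 0, p_tiny)
        rng = np.random.default_rng(3)
        w_in0 = rng.uniform(-0.1, 0.1, size=1)
        w_out0 = rng.uniform(-0.1, 0.1, size=(1, 1))
        assert np.allclose(reg.w_in, w_in0, atol=1e-9)
        assert np.allclose(reg.w_out, w_out0, atol=1e-9)

    def test_bit_identical_weights_under_identical_inputs(self):
        expr = _linear_pair_expr()
        p = LearningParams(seed=21)
        r1 = train_gene(expr, 0, p)
        r2 = train_gene(expr, 0, p)
        assert np.array_equal(r1.w_in, r2.w_in)
        assert np.array_equal(r1.w_out, r2.w_out)

    def test_non_finite_weights_raise_naming_the_learning_rate(self):
        # tanh saturation keeps weights finite for any step size, so the
        # divergence guard is exercised with a corrupted input column
        vals = np.column_stack([np.linspace(-1, 1, 10), np.linspace(-1, 1, 10)])
        vals[3, 0] = np.nan
        expr = ExpressionMatrix(vals, normalization="linear_rescaled")
        with pytest.raises(FloatingPointError, match="learning_rate"):
            train_gene(expr, 0, LearningParams(epochs=2, seed=1))


@pytest.fixture(scope="module")
def toy_corr():
    expr, truth = generate_toy(ToySpec("single", seed=6))
    return infer_network(expr, LearningParams(seed=13)), truth


class TestInferNetwork:
    def test_diagonal_forced_zero_and_entries_in_range(self, toy_corr):
        corr, _ = toy_corr
        assert (np.diag(corr.entries) == 0).all()
        off = corr.entries[~np.eye(4, dtype=bool)]
        assert (np.abs(off) < 1).all()

    def test_single_interaction_is_recovered(self, toy_corr):
        corr, _ = toy_corr
        s = interaction_strength(corr)
        iu = np.triu_indices(4, k=1)
        assert s[0, 1] == max(s[iu])

    def test_pipeline_reproducible_and_order_independent(self):
        expr, _ = generate_toy(ToySpec("single", n_samples=30, seed=8))
        p = LearningParams(epochs=30, seed=17)
        c1 = infer_network(expr, p)
        c2 = infer_network(expr, p)
        assert np.array_equal(c1.entries, c2.entries)
        # genes train independently: assembling rows in reverse order
        # reproduces the joined matrix exactly
        rows = {}
        for g in reversed(range(expr.n_genes)):
            v = probe(train_gene(expr, g, p))
            rows[g] = np.insert(v, g, 0.0)
        manual = np.vstack([rows[g] for g in range(expr.n_genes)])
        assert np.array_equal(c1.entries, manual)


class TestBinarize:
    def test_extreme_thresholds(self, rng):
        scores = random_scores(rng, 6)
        assert binarize(scores, 1.0).n_links == 0
        n = scores.n_genes
        assert binarize(scores, 0.0).n_links == n * (n - 1) // 2

    def test_max_rule_uses_the_stronger_direction(self):
        c = np.zeros((2, 2))
        c[0, 1], c[1, 0] = 0.7, 0.2
        adj = binarize(CorrelationMatrix(c), 0.5)
        assert adj.entries[0, 1] == 1

    def test_anticorrelation_counts_as_interaction_unless_disabled(self):
        c = np.zeros((2, 2))
        c[0, 1] = c[1, 0] = -0.9
        assert binarize(CorrelationMatrix(c), 0.5).entries[0, 1] == 1
        assert binarize(CorrelationMatrix(c), 0.5, absolute=False).entries[0, 1] == 0

    def test_threshold_out_of_range_rejected(self, rng):
        scores = random_scores(rng, 4)
        with pytest.raises(ValueError):
            binarize(scores, 1.5)
        with pytest.raises(ValueError):
            binarize(scores, -0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_link_sets_shrink_monotonically_with_threshold(self, seed):
        scores = random_scores(np.random.default_rng(seed), 10)
        prev = None
        for t in np.linspace(0, 1, 11):
            links = set(zip(*np.nonzero(binarize(scores, t).entries)))
            if prev is not None:
                assert links <= prev
            prev = links


class TestMajorityVote:
    def test_single_run_equals_plain_binarize(self):
        expr, _ = generate_toy(ToySpec("single", n_samples=30, seed=2))
        p = LearningParams(epochs=30, seed=5)
        mv = majority_vote(expr, p, n_runs=1, threshold=0.5, vote_fraction=0.0)
        direct = binarize(infer_network(expr, p), 0.5)
        assert (mv.entries == direct.entries).all()

    def test_vote_fraction_is_a_strict_cutoff(self, monkeypatch):
        # stub inference: link 0-1 in 4 of 10 runs, link 2-3 in all runs
        calls = {"n": 0}

        def stub(expr, params):
            c = np.zeros((4, 4))
            if calls["n"] < 4:
                c[0, 1] = c[1, 0] = 0.9
            c[2, 3] = c[3, 2] = 0.9
            calls["n"] += 1
            return CorrelationMatrix(c)

        monkeypatch.setattr("regnann.inference.infer_network", stub)
        expr, _ = generate_toy(ToySpec("single", n_samples=10, seed=1))
        adj = majority_vote(expr, LearningParams(seed=0), 10, 0.5, 0.5)
        assert adj.entries[0, 1] == 0  # 4/10 not > 0.5
        assert adj.entries[2, 3] == 1  # 10/10 > any fraction < 1


def test_correlation_tsv_round_trip(tmp_path, rng):
    scores = random_scores(rng, 5)
    path = tmp_path / "corr.tsv"
    write_correlation(scores, path)
    back = read_correlation(path)
    assert back.labels() == scores.labels()
    assert np.array_equal(back.entries, scores.entries)
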