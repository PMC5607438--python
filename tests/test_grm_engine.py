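"""Unit and property tests for the graded-response-model engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from equiforms import (
    FormScorer,
    ItemBank,
    ItemParameters,
    ResponsePattern,
    category_prob,
    cumulative_prob,
    estimate_theta,
    item_information,
    response_loglik,
    test_information,
)
from equiforms.grm_engine import _bank_arrays, _cat_probs

from conftest import random_item


@st.composite
def grm_items(draw):
    a = draw(st.floats(0.5, 4.0, allow_nan=False))
    base = draw(st.floats(-3.0, 2.0))
    gaps = [draw(st.floats(0.05, 1.5)) for _ in range(3)]
    b = (base, base + gaps[0], base + gaps[0] + gaps[1], base + sum(gaps))
    return ItemParameters("h1", a, b)


# ---------------------------------------------------------------------------
# Domain-type invariants
# ---------------------------------------------------------------------------

class TestItemTypes:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(a=-1.0, b=(-1, 0, 1, 2)),
            dict(a=0.0, b=(-1, 0, 1, 2)),
            dict(a=1.0, b=(0, -1, 1, 2)),
            dict(a=1.0, b=(0, 0, 1, 2)),
            dict(a=1.0, b=(0, 1, 2)),
        ],
    )
    def test_invalid_item_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ItemParameters("bad", **kwargs)

    def test_duplicate_item_ids_rejected(self):
        it = ItemParameters("x", 1.0, (-1, 0, 1, 2))
        with pytest.raises(ValueError, match="duplicate"):
            ItemBank([it, it])

    def test_pairing_must_be_perfect_matching(self):
        items = [ItemParameters(f"i{k}", 1.0, (-1, 0, 1, 2)) for k in range(4)]
        with pytest.raises(ValueError):
            ItemBank(items, pair_of={"i0": "i1", "i1": "i0", "i2": "i3", "i3": "i2", "i4": "i0"})
        with pytest.raises(ValueError):  # not symmetric
            ItemBank(items, pair_of={"i0": "i1", "i1": "i2", "i2": "i3", "i3": "i0"})

    def test_response_pattern_validation(self):
        with pytest.raises(ValueError):
            ResponsePattern(("a", "b"), (0, 5))
        with pytest.raises(ValueError):
            ResponsePattern(("a",), (None,))  # all missing
        with pytest.raises(ValueError):
            ResponsePattern(("a", "b"), (0,))  # length mismatch


# ---------------------------------------------------------------------------
# Probabilities
# ---------------------------------------------------------------------------

class TestProbabilities:
    item = ItemParameters("i", 1.0, (-1.0, 0.0, 1.0, 2.0))

    def test_cumulative_at_threshold_is_half(self):
        steep = ItemParameters("s", 2.7, (-1.0, 0.0, 1.0, 2.0))
        for it in (self.item, steep):
            for k in range(1, 5):
                assert cumulative_prob(it.b[k - 1], it, k) == pytest.approx(0.5)

    def test_cumulative_limits_and_conventions(self):
        assert cumulative_prob(50.0, self.item, 1) == pytest.approx(1.0)
        assert cumulative_prob(-50.0, self.item, 4) == pytest.approx(0.0)
        assert cumulative_prob(0.3, self.item, 0) == 1.0
        assert cumulative_prob(0.3, self.item, 5) == 0.0

    def test_cumulative_logistic_value(self):
        # direct evaluation of the logistic function as oracle
        it = ItemParameters("i", 1.0, (0.0, 1.0, 2.0, 3.0))
        assert cumulative_prob(1.0, it, 1) == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-9)

    def test_category_prob_is_difference_of_logistics(self):
        # P*_1(0) - P*_2(0) for a=1, b=(-1,0,1,2)
        expected = expit(1.0) - expit(0.0)
        assert category_prob(0.0, self.item, 1) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.23105857863, abs=1e-9)

    def test_category_zero_limit(self):
        assert category_prob(-50.0, self.item, 0) == pytest.approx(1.0)

    def test_normalization_and_nonnegativity_random(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            it = random_item(rng)
            theta = rng.uniform(-5, 5)
            probs = [category_prob(theta, it, k) for k in range(5)]
            assert min(probs) >= 0
            assert abs(sum(probs) - 1.0) < 1e-12

    @given(item=grm_items(), t1=st.floats(-5, 5), t2=st.floats(-5, 5))
    @settings(max_examples=100, deadline=None)
    def test_cumulative_monotone_in_theta_and_k(self, item, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        for k in range(1, 5):
            if hi > lo:
                assert cumulative_prob(hi, item, k) >= cumulative_prob(lo, item, k)
        stars = [cumulative_prob(t1, item, k) for k in range(6)]
        assert all(stars[k] >= stars[k + 1] for k in range(5))


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

class TestLoglik:
    def make_bank(self):
        rng = np.random.default_rng(3)
        return ItemBank([random_item(rng) for _ in range(3)])

    def test_matches_term_by_term_sum(self):
        bank = self.make_bank()
        ids = tuple(bank.item_ids)
        pattern = ResponsePattern(ids, (0, 2, 4))
        theta = 0.7
        expected = sum(
            np.log(category_prob(theta, bank[i], r)) for i, r in zip(ids, (0, 2, 4))
        )
        assert response_loglik(pattern, bank, theta) == pytest.approx(expected, abs=1e-12)

    def test_duplication_doubles_loglik(self):
        rng = np.random.default_rng(4)
        items = [random_item(rng) for _ in range(2)]
        clones = [ItemParameters(it.item_id + "_c", it.a, it.b) for it in items]
        bank = ItemBank(items + clones)
        single = ResponsePattern(tuple(i.item_id for i in items), (1, 3))
        doubled = ResponsePattern(tuple(i.item_id for i in items + clones), (1, 3, 1, 3))
        assert response_loglik(doubled, bank, 0.4) == pytest.approx(
            2 * response_loglik(single, bank, 0.4), abs=1e-10
        )

    def test_missing_dropped_and_unknown_item_raises(self):
        bank = self.make_bank()
        ids = tuple(bank.item_ids)
        full = ResponsePattern(ids[:2], (1, 2))
        with_missing = ResponsePattern(ids, (1, 2, None))
        assert response_loglik(with_missing, bank, 0.0) == pytest.approx(
            response_loglik(full, bank, 0.0)
        )
        with pytest.raises(KeyError):
            response_loglik(ResponsePattern(("nope",), (1,)), bank, 0.0)


# ---------------------------------------------------------------------------
# Information
# ---------------------------------------------------------------------------

class TestInformation:
    def test_vanishes_in_tails(self, bank28):
        for it in bank28:
            assert item_information(10.0, it) < 1e-3
            assert item_information(-10.0, it) < 1e-3

    def test_matches_finite_difference_fisher_information(self):
        # I(theta) = sum_k (dP_k/dtheta)^2 / P_k with central-difference dP_k
        rng = np.random.default_rng(6)
        h = 1e-5
        for _ in range(50):
            it = random_item(rng)
            theta = rng.uniform(-3, 3)
            fd = 0.0
            for k in range(5):
                dp = (category_prob(theta + h, it, k) - category_prob(theta - h, it, k)) / (2 * h)
                fd += dp**2 / category_prob(theta, it, k)
            assert item_information(theta, it) == pytest.approx(fd, abs=1e-5)

    def test_doubling_discrimination_quadruples_peak_information(self):
        grid = np.linspace(-4, 4, 801)
        base = ItemParameters("w", 1.2, (-2.5, -0.8, 0.8, 2.5))
        double = ItemParameters("w2", 2.4, base.b)
        peak1 = max(item_information(t, base) for t in grid)
        peak2 = max(item_information(t, double) for t in grid)
        assert peak2 / peak1 == pytest.approx(4.0, rel=0.15)

    def test_test_information_additive(self, bank28, split28):
        grid = np.linspace(-4, 4, 41)
        items = bank28.subset(split28.form_a)
        total = test_information(grid, items)
        per_item = sum(test_information(grid, [it]) for it in items)
        np.testing.assert_allclose(total, per_item, atol=1e-12)

    def test_empty_and_single_item_cases(self):
        grid = np.linspace(-2, 2, 5)
        assert np.all(test_information(grid, []) == 0.0)
        it = ItemParameters("one", 2.0, (-1, 0, 1, 2))
        np.testing.assert_allclose(
            test_information(grid, [it]), [item_information(t, it) for t in grid], atol=1e-12
        )

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            test_information([], [])


# ---------------------------------------------------------------------------
# Maximum-likelihood scoring
# ---------------------------------------------------------------------------

def dense_grid_argmax(resp, items, step=1e-3):
    """Optimiser-independent oracle: dense grid search of the log-likelihood."""
    grid = np.arange(-4.0, 4.0 + step / 2, step)
    a, b = _bank_arrays(items)
    with np.errstate(divide="ignore"):
        logp = np.log(_cat_probs(grid, a, b))
    mask = resp >= 0
    ll = logp[:, np.where(mask)[0], resp[mask]].sum(axis=1)
    return float(grid[int(np.argmax(ll))])


class TestEstimateTheta:
    def test_extreme_patterns_clamped_to_bounds(self, bank28, split28):
        items = tuple(split28.form_a)
        low = estimate_theta(ResponsePattern(items, (0,) * 14), bank28)
        high = estimate_theta(ResponsePattern(items, (4,) * 14), bank28)
        assert low.theta == -4.0 and low.boundary and np.isnan(low.se)
        assert high.theta == 4.0 and high.boundary and np.isnan(high.se)

    def test_matches_dense_grid_search(self, bank28, split28):
        rng = np.random.default_rng(12)
        items = bank28.subset(split28.form_a)
        scorer = FormScorer(items)
        for _ in range(60):
            resp = rng.integers(0, 5, size=14)
            if resp.min() == resp.max():
                continue
            est = scorer.score(resp)
            oracle = dense_grid_argmax(resp, items)
            assert abs(est.theta - oracle) <= 1e-3

    def test_se_is_inverse_root_information(self, bank28, split28):
        items = bank28.subset(split28.form_b)
        est = FormScorer(items).score([0, 1, 2, 3, 2, 1, 0, 2, 3, 1, 2, 0, 1, 2])
        info = float(test_information([est.theta], items)[0])
        assert est.se == pytest.approx(1.0 / np.sqrt(info), rel=1e-9)
        assert not est.boundary

    def test_missing_responses_reduce_items_used(self, bank28, split28):
        items = tuple(split28.form_a)
        resp = [2, None, 1, None, 3] + [2] * 9
        est = estimate_theta(ResponsePattern(items, tuple(resp)), bank28)
        assert est.n_items_used == 12
        # equals the estimate from the 12 observed items alone
        kept = tuple(i for i, r in zip(items, resp) if r is not None)
        est2 = estimate_theta(
            ResponsePattern(kept, tuple(r for r in resp if r is not None)), bank28
        )
        assert est.theta == pytest.approx(est2.theta, abs=1e-9)

    def test_score_many_agrees_with_scalar_path(self, bank28, split28):
        rng = np.random.default_rng(13)
        items = bank28.subset(split28.form_a)
        scorer = FormScorer(items)
        matrix = rng.integers(0, 5, size=(25, 14))
        batch = scorer.score_many(matrix)
        for row, est in zip(matrix, batch):
            assert est.theta == pytest.approx(scorer.score(row).theta, abs=1e-9)

    def test_se_calibrated_against_sampling_sd(self, bank28, split28):
        # the reported SE should match the empirical SD of theta-hat at a
        # fixed true theta, up to finite-test-length approximation error
        from equiforms.synthetic_data import _draw_responses

        rng = np.random.default_rng(15)
        items = bank28.subset(split28.form_a)
        a, b = _bank_arrays(items)
        scorer = FormScorer(items)
        resp = np.array([_draw_responses(rng, 1.0, a, b) for _ in range(1000)])
        ests = [e for e in scorer.score_many(resp) if not e.boundary]
        thetas = np.array([e.theta for e in ests])
        mean_se = np.mean([e.se for e in ests])
        assert np.std(thetas, ddof=1) == pytest.approx(mean_se, rel=0.15)

    def test_recovery_bias_shrinks_with_more_items(self, bank28, split28):
        # consistency: 28 items recover theta with smaller RMSE than 14
        from equiforms.synthetic_data import _draw_responses

        rng = np.random.default_rng(14)
        n = 300
        true = rng.uniform(-2, 3, size=n)
        half = bank28.subset(split28.form_a)
        full = bank28.items
        errors = {}
        for name, items in (("half", half), ("full", full)):
            a, b = _bank_arrays(items)
            scorer = FormScorer(items)
            resp = np.array([_draw_responses(rng, t, a, b) for t in true])
            ests = scorer.score_many(resp)
            ok = np.array([not e.boundary for e in ests])
            errors[name] = np.array([e.theta for e in ests])[ok] - true[ok]
        assert np.sqrt(np.mean(errors["full"] ** 2)) < np.sqrt(np.mean(errors["half"] ** 2))
        assert abs(np.mean(errors["half"])) < 0.1
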