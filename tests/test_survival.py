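"""Interval grids, target encoding, the hazard likelihood loss, KM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imgsurv import (
    DiscreteTargets,
    IntervalGrid,
    SurvivalRecord,
    discrete_survival_loss,
    encode_targets,
    hazards_to_survival,
    kaplan_meier,
    make_interval_grid,
    survival_at,
)
from imgsurv.survival import discrete_survival_loss_gradient

from conftest import random_survival_records


def rec(t, e, sid="s"):
    return SurvivalRecord(sid, t, e)


class TestIntervalGrid:
    def test_median_split(self):
        records = [rec(t, 1, f"s{t}") for t in (100, 200, 300, 400)]
        grid = make_interval_grid(records, 2)
        np.testing.assert_allclose(grid.boundaries, [0, 250, 400])

    def test_duplicate_quantiles_collapse(self):
        records = [rec(180, 1, f"s{i}") for i in range(3)] + [rec(500, 0, "c")]
        grid = make_interval_grid(records, 3)
        np.testing.assert_allclose(grid.boundaries, [0, 500])
        assert grid.n_intervals == 1

    def test_last_boundary_extends_to_max_followup(self):
        records = [rec(100, 1), rec(200, 1, "b"), rec(900, 0, "c")]
        grid = make_interval_grid(records, 2)
        assert grid.boundaries[-1] == 900

    def test_quantile_grid_balances_event_counts(self, rng):
        times = rng.exponential(365.0, 1000)
        records = [rec(float(t), 1, f"s{i}") for i, t in enumerate(times)]
        grid = make_interval_grid(records, 4)
        counts = np.histogram(times, bins=grid.boundaries)[0]
        # quantile boundaries put ~250 events in each of the 4 intervals
        assert np.all(np.abs(counts - 250) <= 2)

    def test_requires_events(self):
        with pytest.raises(ValueError, match="uncensored"):
            make_interval_grid([rec(100, 0)], 3)
        with pytest.raises(ValueError):
            make_interval_grid([rec(100, 1)], 0)


class TestEncodeTargets:
    grid = IntervalGrid([0, 180, 360, 540])

    @pytest.mark.parametrize(
        "time,event,d,r",
        [
            (316, 1, [0, 1, 0], [1, 1, 0]),  # death in the second interval
            (540, 0, [0, 0, 0], [1, 1, 1]),  # survived the whole grid
            (200, 0, [0, 0, 0], [1, 0, 0]),  # censored within interval 2
            (100, 1, [1, 0, 0], [1, 0, 0]),
            (540, 1, [0, 0, 1], [1, 1, 1]),  # event at the final boundary
            (800, 0, [0, 0, 0], [1, 1, 1]),  # follow-up clamped to the grid
        ],
    )
    def test_examples(self, time, event, d, r):
        targets = encode_targets([rec(time, event)], self.grid)
        assert targets.event_flags.tolist() == [d]
        assert targets.atrisk_flags.tolist() == [r]

    def test_censored_midpoint_rule(self):
        targets = encode_targets([rec(300, 0)], self.grid,
                                 censored_midpoint_rule=True)
        assert targets.atrisk_flags.tolist() == [[1, 1, 0]]
        targets = encode_targets([rec(200, 0)], self.grid,
                                 censored_midpoint_rule=True)
        assert targets.atrisk_flags.tolist() == [[1, 0, 0]]

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        times=st.lists(st.floats(1, 1000), min_size=1, max_size=8),
        events=st.data(),
        n_intervals=st.integers(1, 6),
    )
    def test_encoding_invariants(self, times, events, n_intervals):
        flags = [events.draw(st.integers(0, 1)) for _ in times]
        if not any(flags):
            flags[0] = 1
        records = [rec(t, e, f"s{i}") for i, (t, e) in enumerate(zip(times, flags))]
        grid = make_interval_grid(records, n_intervals)
        targets = encode_targets(records, grid)
        d, r = targets.event_flags, targets.atrisk_flags
        assert np.all(d.sum(axis=1) <= 1)
        assert np.all(d <= r)
        # prefix property: once out of view, never back in view
        assert np.all(np.diff(r, axis=1) <= 0)


class TestLoss:
    def test_single_cell_analytic(self):
        targets = DiscreteTargets([[1]], [[1]])
        loss = discrete_survival_loss(np.array([[0.5]]), targets)
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_perfect_prediction_limit(self):
        d = np.array([[0, 1, 0], [0, 0, 0]], dtype=np.int8)
        r = np.array([[1, 1, 0], [1, 1, 1]], dtype=np.int8)
        h = np.where(d == 1, 1.0, 0.0)
        loss = discrete_survival_loss(h, DiscreteTargets(d, r))
        assert 0 <= loss <= 2 * 6 * 1e-6

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(100):
            n, j = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            h = rng.uniform(0.01, 0.99, (n, j))
            r = (np.arange(j) < rng.integers(0, j + 1, (n, 1))).astype(np.int8)
            d = np.zeros((n, j), dtype=np.int8)
            for i in range(n):
                at_risk = np.flatnonzero(r[i])
                if at_risk.size and rng.random() < 0.5:
                    jj = at_risk[-1]
                    d[i, jj] = 1
                    r[i, jj + 1:] = 0
            expected = 0.0  # literal double sum over intervals and subjects
            for jj in range(j):
                for i in range(n):
                    if r[i, jj] and d[i, jj]:
                        expected += -np.log(h[i, jj])
                    elif r[i, jj]:
                        expected += -np.log(1 - h[i, jj])
            loss = discrete_survival_loss(h, DiscreteTargets(d, r))
            assert loss == pytest.approx(expected, abs=1e-12)

    def test_decomposes_over_intervals(self, rng):
        h = rng.uniform(0.05, 0.95, (5, 6))
        r = np.ones((5, 6), dtype=np.int8)
        d = np.zeros((5, 6), dtype=np.int8)
        d[0, 5] = d[3, 5] = 1
        total = discrete_survival_loss(h, DiscreteTargets(d, r))
        parts = sum(
            discrete_survival_loss(
                h[:, [j]], DiscreteTargets(d[:, [j]], r[:, [j]])
            )
            for j in range(6)
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_gradient_matches_central_difference(self, rng):
        n, j = 3, 4
        h = rng.uniform(0.1, 0.9, (n, j))
        r = np.ones((n, j), dtype=np.int8)
        d = np.zeros((n, j), dtype=np.int8)
        d[1, 3] = 1
        r[2, 2:] = 0
        targets = DiscreteTargets(d, r)
        grad = discrete_survival_loss_gradient(h, targets)
        eps = 1e-6
        for i in range(n):
            for jj in range(j):
                hp, hm = h.copy(), h.copy()
                hp[i, jj] += eps
                hm[i, jj] -= eps
                num = (
                    discrete_survival_loss(hp, targets)
                    - discrete_survival_loss(hm, targets)
                ) / (2 * eps)
                assert grad[i, jj] == pytest.approx(num, abs=1e-5)

    def test_per_cell_minimizer_orientation(self):
        # failure cells: loss decreasing in h; survived cells: increasing
        hs = np.linspace(0.05, 0.95, 19)
        fail = [discrete_survival_loss(np.array([[h]]), DiscreteTargets([[1]], [[1]]))
                for h in hs]
        surv = [discrete_survival_loss(np.array([[h]]), DiscreteTargets([[0]], [[1]]))
                for h in hs]
        assert np.all(np.diff(fail) < 0)
        assert np.all(np.diff(surv) > 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            discrete_survival_loss(np.ones((2, 3)) * 0.5,
                                   DiscreteTargets([[1]], [[1]]))


class TestSurvivalCurves:
    def test_cumulative_product(self):
        grid = IntervalGrid([0, 180, 360])
        (curve,) = hazards_to_survival(np.array([[0.1, 0.2]]), grid)
        np.testing.assert_allclose(curve.probabilities, [0.9, 0.72])

    def test_zero_hazard_is_flat(self):
        grid = IntervalGrid([0, 1, 2, 3])
        (curve,) = hazards_to_survival(np.zeros((1, 3)), grid)
        np.testing.assert_allclose(curve.probabilities, 1.0)

    def test_matches_direct_product(self, rng):
        h = rng.uniform(0, 0.5, (4, 6))
        grid = IntervalGrid(np.arange(7.0))
        curves = hazards_to_survival(h, grid)
        for i, c in enumerate(curves):
            assert c.probabilities[-1] == pytest.approx(np.prod(1 - h[i]), rel=1e-12)

    @pytest.mark.parametrize(
        "t,expected", [(0, 1.0), (100, 1.0), (200, 0.9), (360, 0.72)]
    )
    def test_step_evaluation(self, t, expected):
        grid = IntervalGrid([0, 180, 360])
        (curve,) = hazards_to_survival(np.array([[0.1, 0.2]]), grid)
        assert survival_at(curve, t) == pytest.approx(expected)

    def test_no_extrapolation(self):
        grid = IntervalGrid([0, 180])
        (curve,) = hazards_to_survival(np.array([[0.1]]), grid)
        with pytest.raises(ValueError):
            survival_at(curve, 181)


class TestKaplanMeier:
    def test_two_events(self):
        km = kaplan_meier([rec(100, 1, "a"), rec(200, 1, "b")])
        assert survival_at(km, 100) == pytest.approx(0.5)
        assert survival_at(km, 200) == pytest.approx(0.0)

    def test_censoring_does_not_drop_curve(self):
        km = kaplan_meier([rec(100, 1, "a"), rec(150, 0, "b")])
        assert survival_at(km, 100) == pytest.approx(0.5)
        assert survival_at(km, 150) == pytest.approx(0.5)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = np.sort(rng.exponential(100, 50))
        records = [rec(float(t), 1, f"s{i}") for i, t in enumerate(times)]
        km = kaplan_meier(records)
        for t in [times[0], times[24], times[-1]]:
            assert survival_at(km, float(t)) == pytest.approx(
                np.mean(times > t), abs=1e-12
            )

    def test_close_to_exponential_truth(self, rng):
        lam = 1 / 200.0
        times = rng.exponential(1 / lam, 200)
        records = [rec(float(t), 1, f"s{i}") for i, t in enumerate(times)]
        km = kaplan_meier(records)
        grid_t = np.linspace(1, np.quantile(times, 0.95), 40)
        errs = [abs(survival_at(km, t) - np.exp(-lam * t)) for t in grid_t]
        assert max(errs) < 0.1

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        records = random_survival_records(rng, 80)
        km = kaplan_meier(records)
        kmf = KaplanMeierFitter().fit(
            [r.time for r in records], [r.event for r in records]
        )
        for t in np.quantile([r.time for r in records], [0.2, 0.5, 0.8]):
            assert survival_at(km, float(t)) == pytest.approx(
                float(kmf.predict(float(t))), abs=1e-10
            )

    def test_empty_input(self):
        with pytest.raises(ValueError):
            kaplan_meier([])


class TestRecordValidation:
    def test_rejects_bad_records(self):
        with pytest.raises(ValueError):
            SurvivalRecord("a", -1.0, 1)
        with pytest.raises(ValueError):
            SurvivalRecord("a", 10.0, 2)
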