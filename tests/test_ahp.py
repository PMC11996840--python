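"""AHP weight derivation, consistency statistics, the composite score and
the exhaustive grid search."""

import numpy as np
import pytest

from emgmeo import (
    GridSpec,
    ahp_score,
    ahp_score_from_values,
    ahp_weights,
    default_judgment_matrix,
    grid_search,
)
from emgmeo.evaluation import ConfusionCounts, MetricsReport


def report(on_tpr, off_tpr, f1, on_bias, off_bias):
    return MetricsReport(on_tpr, off_tpr, f1, on_bias, off_bias, ConfusionCounts())


class TestAhpWeights:
    def test_canonical_matrix_reproduces_published_values(self):
        w = ahp_weights()
        np.testing.assert_allclose(
            np.round(w.eigenvector, 4), [1.7826, 1.7826, 1.0, 0.561, 0.561]
        )
        np.testing.assert_allclose(
            np.round(w.weights, 4), [0.3134, 0.3134, 0.1758, 0.0986, 0.0986]
        )
        assert round(w.lambda_max, 4) == 5.0133
        assert round(w.ci, 4) == 0.0033
        assert w.ri == 1.11
        assert round(w.cr, 3) == 0.003
        assert w.is_consistent()

    def test_weights_sum_to_one(self):
        assert ahp_weights().weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_perfectly_consistent_matrix_has_zero_ci(self):
        v = np.array([4.0, 2.0, 1.0, 0.5])
        a = v[:, None] / v[None, :]
        w = ahp_weights(a)
        assert w.ci == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(w.weights, v / v.sum())

    def test_two_by_two_geometric_means(self):
        w = ahp_weights(np.array([[1.0, 3.0], [1 / 3, 1.0]]))
        np.testing.assert_allclose(w.weights, [0.75, 0.25])

    def test_non_reciprocal_matrix_rejected(self):
        a = default_judgment_matrix()
        a[0, 1] = 2.0  # breaks reciprocity with a[1, 0] = 1
        with pytest.raises(ValueError, match="reciprocal"):
            ahp_weights(a)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            ahp_weights(np.ones((2, 3)))


class TestAhpScore:
    # Published per-detector metric rows: (onset TPR %, offset TPR %, F1 %,
    # onset bias ms, offset bias ms) -> composite score at 4 decimals.
    ROWS = {
        "TEOTD": ((85.17, 77.67, 82.53, 183, 295), 0.6550),
        "aTEOTD": ((90.23, 88.87, 88.29, 154, 255), 0.7161),
        "MEOTD": ((95.15, 92.27, 91.67, 133, 239), 0.7482),
        "aMEOTD": ((95.16, 92.83, 91.80, 117, 223), 0.7502),
        "MEONND": ((97.31, 93.33, 93.48, 103, 209), 0.7615),
        "aMEONND": ((97.31, 93.58, 93.72, 102, 204), 0.7627),
    }

    @pytest.mark.parametrize("name", list(ROWS))
    def test_published_rows_reproduced(self, name):
        (on, off, f1, ob, fb), expected = self.ROWS[name]
        weights = np.round(ahp_weights().weights, 4)
        score = ahp_score_from_values(on / 100, off / 100, f1 / 100, ob, fb, weights)
        assert round(score, 4) == expected

    def test_all_zero_metrics_score_zero(self):
        assert ahp_score_from_values(0, 0, 0, 0, 0, ahp_weights().weights) == 0.0

    def test_report_interface_rescales_f1(self):
        w = ahp_weights()
        r = report(0.9731, 0.9333, 93.48, 103.0, 209.0)
        direct = ahp_score_from_values(0.9731, 0.9333, 0.9348, 103, 209, w.weights)
        assert ahp_score(r, w) == pytest.approx(direct)

    def test_missing_metric_raises(self):
        with pytest.raises(ValueError, match="missing"):
            ahp_score(report(0.9, None, 90.0, 10.0, 10.0), ahp_weights())

    def test_monotone_in_each_metric(self):
        w = ahp_weights()
        base = ahp_score(report(0.9, 0.9, 90.0, 100.0, 100.0), w)
        assert ahp_score(report(0.95, 0.9, 90.0, 100.0, 100.0), w) > base
        assert ahp_score(report(0.9, 0.95, 90.0, 100.0, 100.0), w) > base
        assert ahp_score(report(0.9, 0.9, 95.0, 100.0, 100.0), w) > base
        assert ahp_score(report(0.9, 0.9, 90.0, 50.0, 100.0), w) > base
        assert ahp_score(report(0.9, 0.9, 90.0, 100.0, 50.0), w) > base


class TestGridSpec:
    def test_default_meonnd_threshold_axis(self):
        grid = GridSpec.meonnd_default()
        assert grid.third == (0.406, 0.426, 0.446, 0.466, 0.486, 0.506)

    def test_default_meotd_axes(self):
        grid = GridSpec.meotd_default()
        assert grid.k == tuple(range(1, 42, 2))
        assert grid.L == tuple(range(3, 84, 2))
        assert grid.third == tuple(range(1, 11))

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            GridSpec((), (3,), (1,), "j")


class TestGridSearch:
    @staticmethod
    def _corpus():
        from emgmeo import generate_recording

        rec = generate_recording(duration=20.0, n_bursts=5, seed=21)
        return [(rec.signal, rec.truth)]

    @staticmethod
    def _factory(k, L, j):
        from emgmeo import DoubleThresholdConfig, meotd_detect

        config = DoubleThresholdConfig(j=j, k_max=k, median_len=L)
        return lambda s: meotd_detect(s, config)

    def test_single_cell_returns_that_cell(self):
        grid = GridSpec((15,), (15,), (5,), "j")
        result = grid_search(self._corpus(), self._factory, grid, ahp_weights())
        assert result.best_params == {"k": 15, "L": 15, "j": 5}

    def test_argmax_contract(self):
        grid = GridSpec((5, 15), (5, 15), (2, 5), "j")
        result = grid_search(self._corpus(), self._factory, grid, ahp_weights())
        scores = result.table["score"].dropna()
        assert result.best_score == pytest.approx(scores.max())

    def test_failing_cell_logged_and_skipped(self, caplog):
        def factory(k, L, j):
            if k == 99:
                raise RuntimeError("boom")
            return self._factory(k, L, j)

        # k=99 exceeds no validation here; make the factory itself fail
        grid = GridSpec((15, 99), (15,), (5,), "j")
        import logging

        with caplog.at_level(logging.WARNING, logger="emgmeo.ahp"):
            result = grid_search(self._corpus(), factory, grid, ahp_weights())
        assert result.best_params["k"] == 15
        assert any("failed" in r.message for r in caplog.records)
        assert result.table["score"].isna().sum() == 1

    def test_dominant_cell_wins(self):
        """A cell strictly better on all five metrics must win (the score
        is monotone in each metric)."""
        from emgmeo import ChangePointSet

        rec = self._corpus()[0]
        truth = rec[1]

        def factory(k, L, j):
            if j == 1:  # perfect detector
                return lambda s: truth
            # degraded: drop the last burst entirely
            events = truth.events[:-2]
            return lambda s: ChangePointSet(events)

        grid = GridSpec((1,), (3,), (1, 2), "j")
        result = grid_search([rec], factory, grid, ahp_weights())
        assert result.best_params["j"] == 1
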