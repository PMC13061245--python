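"""Agreement-metric oracle tests: Pearson/RMSE/peak statistics, correlation
ranking, Bland-Altman limits and grouped summaries."""

import numpy as np
import pytest

from scrumforce.evaluation import (
    EvaluationError,
    agreement,
    bland_altman,
    grouped_report,
    pairing_to_shoulder,
    rank_correlation,
)
from scrumforce.io_preprocess import ShapeError


def oracle_pearson(x, y):
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float(np.sum(x * y) / np.sqrt(np.sum(x * x) * np.sum(y * y)))


def oracle_bland_altman(m, p):
    d = np.asarray(p, float) - np.asarray(m, float)
    bias = d.mean()
    sd = np.sqrt(np.sum((d - bias) ** 2) / (len(d) - 1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


class TestAgreement:
    def test_perfect_prediction(self):
        m = np.array([0.0, 500.0, 1500.0, 2000.0])
        rec = agreement(m, m.copy())
        assert rec.correlation == pytest.approx(1.0)
        assert rec.rmse == 0.0 and rec.peak_diff == 0.0
        assert rec.rank == "excellent"

    def test_constant_offset(self):
        m = np.array([0.0, 500.0, 1500.0, 2000.0])
        rec = agreement(m, m + 100.0)
        assert rec.correlation == pytest.approx(1.0)
        assert rec.rmse == pytest.approx(100.0)
        assert rec.peak_diff == pytest.approx(100.0)
        assert rec.nrmse_pct == pytest.approx(100.0 * 100.0 / 2000.0)

    def test_hand_computed_example(self):
        rec = agreement(np.array([0.0, 1000.0, 2000.0]), np.array([0.0, 2000.0, 1000.0]))
        assert rec.rmse == pytest.approx(np.sqrt((0 + 1000**2 + 1000**2) / 3))
        assert rec.correlation == pytest.approx(oracle_pearson([0, 1000, 2000], [0, 2000, 1000]))
        assert rec.peak_diff == 0.0

    def test_matches_reference_implementations_on_random_curves(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 150))
            m = rng.normal(1000, 300, n)
            p = m + rng.normal(0, 100, n)
            rec = agreement(m, p)
            assert rec.correlation == pytest.approx(oracle_pearson(m, p), abs=1e-9)
            assert rec.rmse == pytest.approx(np.sqrt(np.mean((m - p) ** 2)), abs=1e-9)
            assert rec.peak_diff == pytest.approx(abs(m.max() - p.max()), abs=1e-9)

    def test_percentages_scale_invariant(self, rng):
        m = rng.normal(1000, 200, 101)
        p = m + rng.normal(0, 50, 101)
        a, b = agreement(m, p), agreement(3.7 * m, 3.7 * p)
        assert a.nrmse_pct == pytest.approx(b.nrmse_pct)
        assert a.npeak_pct == pytest.approx(b.npeak_pct)

    def test_constant_measured_rejected(self):
        with pytest.raises(EvaluationError):
            agreement(np.full(10, 5.0), np.arange(10.0))

    def test_shoulder_derived_from_pairing(self):
        rec = agreement(
            np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]), {"pairing": "A2R-B2"}
        )
        assert rec.shoulder == "A2-R"
        assert pairing_to_shoulder("A3R-B1") == "A3-R"


class TestRankCorrelation:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.95, "excellent"),
            (0.9, "good"),
            (0.75, "moderate"),
            (0.5, "poor"),
            (0.49, "poor"),
            (-0.2, "poor"),
            (1.0, "excellent"),
            (-1.0, "poor"),
        ],
    )
    def test_bands(self, r, expected):
        assert rank_correlation(r) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(EvaluationError):
            rank_correlation(1.5)


class TestBlandAltman:
    def test_identical_lists_collapse_to_zero(self):
        res = bland_altman([1000.0, 2000.0, 1500.0], [1000.0, 2000.0, 1500.0])
        assert res.bias == 0.0 and res.loa_lower == 0.0 and res.loa_upper == 0.0

    def test_constant_offset_limits_collapse_to_bias(self):
        res = bland_altman([1000.0, 2000.0], [1100.0, 2100.0])
        assert res.bias == pytest.approx(100.0)  # predicted - measured
        assert res.loa_lower == pytest.approx(100.0)
        assert res.loa_upper == pytest.approx(100.0)

    def test_matches_textbook_oracle_on_random_lists(self, rng):
        for _ in range(200):
            m = rng.normal(2000, 400, 50)
            p = m + rng.normal(50, 150, 50)
            res = bland_altman(m, p)
            bias, lo, hi = oracle_bland_altman(m, p)
            assert res.bias == pytest.approx(bias, abs=1e-9)
            assert res.loa_lower == pytest.approx(lo, abs=1e-9)
            assert res.loa_upper == pytest.approx(hi, abs=1e-9)
            assert res.loa_lower <= res.bias <= res.loa_upper

    def test_half_width_converges_to_1_96_sigma(self, rng):
        mu, sigma, n = 54.3, 300.0, 100_000
        m = rng.normal(2000, 400, n)
        p = m + rng.normal(mu, sigma, n)
        res = bland_altman(m, p)
        half = (res.loa_upper - res.loa_lower) / 2
        assert half == pytest.approx(1.96 * sigma, rel=0.02)
        assert res.bias == pytest.approx(mu, abs=3 * sigma / np.sqrt(n) + 1e-9)

    def test_per_technique_subgroups(self):
        m = [1000.0, 1100.0, 2000.0, 2100.0]
        p = [1050.0, 1160.0, 1980.0, 2090.0]
        labels = ["CTS", "CTS", "PreBind", "PreBind"]
        res = bland_altman(m, p, labels)
        assert set(res.by_group) == {"CTS", "PreBind"}
        assert res.by_group["CTS"].bias == pytest.approx((50 + 60) / 2)
        assert res.by_group["PreBind"].bias == pytest.approx((-20 - 10) / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            bland_altman([1.0, 2.0], [1.0])


class TestGroupedReport:
    def _records(self):
        m1 = np.array([0.0, 1000.0, 2000.0])
        m2 = np.array([0.0, 1500.0, 3000.0])
        r1 = agreement(m1, m1 + 100.0, {"trial_id": "a", "technique": "CTS", "pairing": "A1L-B3"})
        r2 = agreement(m2, m2 + 300.0, {"trial_id": "b", "technique": "CTS", "pairing": "A1L-B3"})
        r3 = agreement(m1, m1 + 50.0, {"trial_id": "c", "technique": "PreBind", "pairing": "A2R-B2"})
        return [r1, r2, r3], [m1, m2, m1]

    def test_identical_records_have_zero_sd(self):
        m = np.array([0.0, 1000.0, 2000.0])
        recs = [
            agreement(m, m + 100.0, {"technique": "CTS", "pairing": "A1L-B3"}) for _ in range(4)
        ]
        (rep,) = grouped_report(recs, "technique", [m] * 4)
        assert rep.correlation_sd == 0.0 and rep.rmse_sd == 0.0
        assert rep.rmse_mean == pytest.approx(100.0)

    def test_hand_built_two_groups(self):
        recs, curves = self._records()
        reports = {r.group: r for r in grouped_report(recs, "technique", curves)}
        cts = reports["CTS"]
        assert cts.n == 2
        assert cts.rmse_mean == pytest.approx((100.0 + 300.0) / 2)
        assert cts.rmse_sd == pytest.approx(np.std([100.0, 300.0], ddof=1))
        # group percentage normalises by the group's max force (3000 N), not per-trial
        assert cts.group_max_force == 3000.0
        assert cts.nrmse_pct_mean == pytest.approx(100 * (100 / 3000 + 300 / 3000) / 2)
        assert reports["PreBind"].group_max_force == 2000.0

    def test_grouping_by_shoulder_cardinality(self):
        m = np.array([0.0, 1000.0, 2000.0])
        pairings = ["A1L-B3", "A1R-B3", "A2L-B3", "A2R-B2", "A3L-B2", "A3R-B1"]
        recs = [agreement(m, m + 10.0, {"technique": "CTS", "pairing": pr}) for pr in pairings]
        reports = grouped_report(recs, "shoulder", [m] * 6)
        assert len(reports) == 6
        assert {r.group for r in reports} == {"A1-L", "A1-R", "A2-L", "A2-R", "A3-L", "A3-R"}

    def test_unknown_group_key_rejected(self):
        recs, curves = self._records()
        with pytest.raises(EvaluationError):
            grouped_report(recs, "referee", curves)
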