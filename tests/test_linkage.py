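"""Correlation screening, responder classification and temporal statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shrubice.linkage import (
    CorrelationScreen,
    benjamini_hochberg,
    classify_responders,
    compare_slopes,
    correlation_screen,
    epoch_contrast,
    kmeans_responders,
    moving_bootstrap_correlation,
)


def _bh_oracle(p):
    """Brute-force step-up: sort, scale by m/i, cumulative min from the back."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBenjaminiHochberg:
    def test_hand_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            m = rng.integers(1, 13)
            p = rng.uniform(0, 1, m)
            np.testing.assert_allclose(benjamini_hochberg(p), _bh_oracle(p), atol=1e-12)


def _years(n, start=1979):
    return pd.Index(np.arange(start, start + n), name="year")


class TestCorrelationScreen:
    def test_self_correlation(self, rng):
        x = pd.Series(rng.normal(0, 1, 30), index=_years(30))
        sc = correlation_screen({"c": x}, {"v": x})
        assert sc.r.loc["c", "v"] == pytest.approx(1.0)
        assert sc.p.loc["c", "v"] < 1e-10

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(2024)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            rej += stats.pearsonr(x, y).pvalue < 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=0.02)

    def test_insufficient_overlap_flagged_missing(self, rng):
        x = pd.Series(rng.normal(0, 1, 30), index=_years(30, 1900))
        y = pd.Series(rng.normal(0, 1, 30), index=_years(30, 2000))
        sc = correlation_screen({"c": x}, {"v": y})
        assert np.isnan(sc.r.loc["c", "v"])

    def test_p_adj_at_least_p(self, rng):
        chron = {f"c{i}": pd.Series(rng.normal(0, 1, 30), index=_years(30)) for i in range(3)}
        ice = {f"v{j}": pd.Series(rng.normal(0, 1, 30), index=_years(30)) for j in range(8)}
        sc = correlation_screen(chron, ice)
        assert (sc.p_adj.to_numpy() >= sc.p.to_numpy() - 1e-12).all()


def _screen_from(r, p):
    rdf = pd.DataFrame(r).T
    pdf = pd.DataFrame(p).T
    return CorrelationScreen(r=rdf, p=pdf, p_adj=pdf.copy())


class TestClassifyResponders:
    def test_labels(self):
        sc = _screen_from(
            {
                "inc": {"a": -0.5, "b": 0.1},
                "dec": {"a": 0.5, "b": -0.1},
                "neu": {"a": 0.2, "b": -0.2},
                "amb": {"a": -0.5, "b": 0.5},
            },
            {
                "inc": {"a": 0.01, "b": 0.8},
                "dec": {"a": 0.01, "b": 0.8},
                "neu": {"a": 0.3, "b": 0.3},
                "amb": {"a": 0.01, "b": 0.01},
            },
        )
        labels = {r.chrono_id: r.label for r in classify_responders(sc)}
        assert labels == {
            "inc": "increaser",
            "dec": "decreaser",
            "neu": "neutral",
            "amb": "ambiguous",
        }

    def test_every_chronology_gets_exactly_one_label(self, rng):
        n = 10
        sc = _screen_from(
            {f"c{i}": {f"v{j}": rng.uniform(-1, 1) for j in range(5)} for i in range(n)},
            {f"c{i}": {f"v{j}": rng.uniform(0, 1) for j in range(5)} for i in range(n)},
        )
        out = classify_responders(sc)
        assert len(out) == n
        assert all(r.label in {"increaser", "decreaser", "neutral", "ambiguous"} for r in out)


class TestKmeansResponders:
    def test_separable_clouds_recovered_at_k2(self, rng):
        a = rng.normal(0.5, 0.05, (8, 6))
        b = rng.normal(-0.5, 0.05, (7, 6))
        prof = pd.DataFrame(np.vstack([a, b]), index=[f"r{i}" for i in range(15)])
        res = kmeans_responders(prof, seed=0)
        assert res["k_best"] == 2
        lab = res["labels"][2]
        assert len(set(lab[:8])) == 1 and len(set(lab[8:])) == 1 and lab[0] != lab[-1]

    def test_identical_rows_zero_wss(self):
        prof = pd.DataFrame(np.ones((6, 4)))
        res = kmeans_responders(prof, k_range=(1, 2, 3), seed=0)
        assert res["wss"][1] == pytest.approx(0.0)

    def test_permutation_invariance_up_to_relabeling(self, rng):
        x = np.vstack([rng.normal(1, 0.1, (5, 3)), rng.normal(-1, 0.1, (5, 3))])
        prof = pd.DataFrame(x, index=[f"r{i}" for i in range(10)])
        perm = rng.permutation(10)
        res1 = kmeans_responders(prof, seed=0)["labels"][2]
        res2 = kmeans_responders(prof.iloc[perm], seed=0)["labels"][2]
        part1 = {frozenset(np.flatnonzero(res1[perm] == k)) for k in set(res1)}
        part2 = {frozenset(np.flatnonzero(res2 == k)) for k in set(res2)}
        assert part1 == part2

    def test_k_exceeding_rows_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_responders(pd.DataFrame(np.ones((3, 2))), k_range=(1, 5))


class TestMovingBootstrapCorrelation:
    def test_full_window_reduces_to_plain_pearson(self, rng):
        x = pd.Series(rng.normal(0, 1, 25), index=_years(25))
        y = pd.Series(rng.normal(0, 1, 25), index=_years(25))
        res = moving_bootstrap_correlation(x, y, window=25, n_boot=200, seed=0)
        assert res.r.size == 1
        assert res.r[0] == pytest.approx(stats.pearsonr(x, y).statistic)

    def test_identity_always_significant(self, rng):
        x = pd.Series(rng.normal(0, 1, 30), index=_years(30))
        res = moving_bootstrap_correlation(x, x, window=20, n_boot=200, seed=0)
        np.testing.assert_allclose(res.r, 1.0)
        assert res.significant.all()

    def test_window_count_29_years_window_20(self, rng):
        x = pd.Series(rng.normal(0, 1, 29), index=_years(29, 1980))
        y = pd.Series(rng.normal(0, 1, 29), index=_years(29, 1980))
        res = moving_bootstrap_correlation(x, y, window=20, n_boot=100, seed=0)
        assert res.r.size == 10
        assert res.window_starts[0] == 1980 and res.window_starts[-1] == 1989

    def test_window_longer_than_series_errors(self, rng):
        x = pd.Series(rng.normal(0, 1, 10), index=_years(10))
        with pytest.raises(ValueError, match="window"):
            moving_bootstrap_correlation(x, x, window=20)

    def test_null_significance_rate_near_alpha(self):
        rng = np.random.default_rng(77)
        flags = []
        for _ in range(60):
            x = pd.Series(rng.normal(0, 1, 20), index=_years(20))
            y = pd.Series(rng.normal(0, 1, 20), index=_years(20))
            res = moving_bootstrap_correlation(x, y, window=20, n_boot=300, seed=int(rng.integers(2**31)))
            flags.append(res.significant[0])
        # percentile pairs-bootstrap is roughly calibrated; generous MC band
        assert np.mean(flags) < 0.18


class TestEpochContrast:
    def test_identical_epochs(self):
        x = pd.Series(np.tile([1.0, 2.0, 3.0], 10)[:30], index=_years(30))
        res = epoch_contrast(x)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_welch_hand_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 5.0, 7.0])
        x = pd.Series(
            np.concatenate([a, b]),
            index=[1979, 1980, 1981, 1982, 1994, 1995, 1996],
        )
        res = epoch_contrast(x)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (b.mean() - a.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        assert res.t == pytest.approx(t, abs=1e-6)
        assert res.df == pytest.approx(df, abs=1e-6)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), df), abs=1e-6)

    def test_shift_detected_with_power(self):
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            early = rng.normal(0, 1, 15)
            recent = rng.normal(1.0, 1, 15)
            x = pd.Series(np.concatenate([early, recent]), index=_years(30))
            hits += epoch_contrast(x).p < 0.05
        assert hits / n_rep >= 0.70

    def test_swapping_epochs_negates_t(self, rng):
        x = pd.Series(rng.normal(0, 1, 30), index=_years(30))
        a = epoch_contrast(x, early=(1979, 1993), recent=(1994, 2008))
        b = epoch_contrast(x, early=(1994, 2008), recent=(1979, 1993))
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_empty_epoch_errors(self, rng):
        x = pd.Series(rng.normal(0, 1, 10), index=_years(10, 1994))
        with pytest.raises(ValueError, match="epoch"):
            epoch_contrast(x)


class TestCompareSlopes:
    def test_equal_slopes(self, rng):
        x = np.arange(10.0)
        y = 2 * x + rng.normal(0, 0.3, 10)
        res = compare_slopes({"g1": (x, y), "g2": (x, y)})
        assert res["slopes"]["g1"] == pytest.approx(res["slopes"]["g2"])
        assert res["slopes"]["g1"] == pytest.approx(2.0, abs=0.2)
        # identical groups: interaction coefficient is exactly zero
        assert res["interaction_p"] > 0.99

    def test_opposite_slopes_detected(self, rng):
        x = np.arange(20.0)
        res = compare_slopes(
            {
                "up": (x, x + rng.normal(0, 0.5, 20)),
                "down": (x, -x + rng.normal(0, 0.5, 20)),
            }
        )
        assert res["interaction_p"] < 0.01

    def test_exact_slope(self):
        x = np.arange(5.0)
        res = compare_slopes({"a": (x, 2 * x + 3), "b": (x, 2 * x + 3)})
        assert res["slopes"]["a"] == pytest.approx(2.0, abs=1e-10)

    def test_constant_x_errors(self):
        with pytest.raises(ValueError, match="singular"):
            compare_slopes({"a": (np.ones(5), np.arange(5.0)), "b": (np.arange(5.0), np.arange(5.0))})
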