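"""Half-life estimation: arithmetic oracles, exact recovery, filters and
condition contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from m6adosage import slamfit

LOG2 = math.log(2.0)


def grid_search_k(times, values, floor=1e-6):
    """Independent least-squares oracle: coarse grid + bounded refinement of
    the residual sum of squares over k."""
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    ok = v > floor
    t, v = t[ok], v[ok]
    logv = np.log(v)

    def rss(k):
        return float(np.sum((logv + k * t) ** 2))

    grid = np.linspace(-2.0, 12.0, 2001)
    k0 = grid[int(np.argmin([rss(k) for k in grid]))]
    res = minimize_scalar(
        rss, bounds=(k0 - 0.02, k0 + 0.02), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def profile_frame(rows):
    return pd.DataFrame(
        rows, columns=["utr_id", "time_h", "condition", "replicate", "t_coverage", "tc_count"]
    )


class TestIncorporationRate:
    def test_basic_arithmetic(self):
        prof = profile_frame([("u1", 0, "control", 1, 500, 5)])
        out = slamfit.incorporation_rate(prof, ["utr_id"])
        assert out.loc[0, "rate"] == pytest.approx(0.01)

    def test_zero_conversions(self):
        prof = profile_frame([("u1", 0, "control", 1, 500, 0)])
        assert slamfit.incorporation_rate(prof, ["utr_id"]).loc[0, "rate"] == 0.0

    def test_zero_coverage_flagged(self):
        prof = profile_frame([("u1", 0, "control", 1, 0, 0)])
        out = slamfit.incorporation_rate(prof, ["utr_id"])
        assert out.loc[0, "undefined"]
        assert np.isnan(out.loc[0, "rate"])

    def test_pooled_rate_equals_summation_oracle(self, rng):
        rows = []
        for u in range(20):
            for r in range(3):
                cov = int(rng.integers(50, 5000))
                rows.append((f"u{u}", 0.0, "c", r, cov, int(rng.integers(0, cov // 10))))
        prof = profile_frame(rows)
        pooled = slamfit.incorporation_rate(prof, None)["rate"].iloc[0]
        # brute force: coverage-weighted mean of per-row rates
        oracle = sum(r.tc_count for r in prof.itertuples()) / sum(
            r.t_coverage for r in prof.itertuples()
        )
        assert pooled == pytest.approx(oracle, abs=0)


class TestCorrectAndNormalize:
    def _labeled(self, series, utr="u1", cond="control"):
        return profile_frame(
            [(utr, t, cond, 1, 100_000, int(round(r * 100_000))) for t, r in series.items()]
        )

    def test_hand_arithmetic_halving_series(self):
        # background 0.001, raw {0: 0.0136, 3: 0.0073, 6: 0.00415}
        labeled = self._labeled({0.0: 0.0136, 3.0: 0.0073, 6.0: 0.00415})
        norm, excl = slamfit.correct_and_normalize(labeled, background=0.001)
        got = norm.set_index("time_h")["norm_value"]
        assert got.loc[0.0] == pytest.approx(1.0, abs=1e-12)
        assert got.loc[3.0] == pytest.approx(0.5, abs=1e-12)
        assert got.loc[6.0] == pytest.approx(0.25, abs=1e-12)
        assert excl.empty

    def test_zero_background_normalizes_by_raw_t0(self):
        labeled = self._labeled({0.0: 0.02, 5.0: 0.01})
        norm, _ = slamfit.correct_and_normalize(labeled, background=0.0)
        got = norm.set_index("time_h")["norm_value"]
        assert got.loc[0.0] == 1.0
        assert got.loc[5.0] == pytest.approx(0.5)

    def test_background_equal_to_rate_excludes_series(self):
        labeled = self._labeled({0.0: 0.001, 3.0: 0.001})
        norm, excl = slamfit.correct_and_normalize(labeled, background=0.001)
        assert norm.empty
        assert excl.loc[0, "reason"] == "nonpositive_t0"

    def test_unlabeled_table_supplies_background(self):
        labeled = self._labeled({0.0: 0.011, 3.0: 0.006})
        unlabeled = profile_frame([("u1", 0.0, "unlabeled", 1, 10_000, 10)])
        norm, _ = slamfit.correct_and_normalize(labeled, unlabeled)
        got = norm.set_index("time_h")["norm_value"]
        assert got.loc[3.0] == pytest.approx(0.005 / 0.010)


class TestFitDecay:
    def test_noise_free_exact_recovery(self):
        fit = slamfit.fit_decay([0, 3, 6, 12], [1.0, 0.5, 0.25, 0.0625])
        assert fit["k"] == pytest.approx(LOG2 / 3, rel=1e-12)
        assert fit["t_half"] == pytest.approx(3.0, rel=1e-12)
        assert fit["residual_se"] == pytest.approx(0.0, abs=1e-12)

    def test_t_half_times_k_is_ln2(self, rng):
        for _ in range(50):
            th = float(rng.uniform(0.5, 20))
            t = np.linspace(0, 12, 8)
            fit = slamfit.fit_decay(t, 2 ** (-t / th))
            assert fit["t_half"] * fit["k"] == pytest.approx(LOG2, rel=1e-12)

    def test_constant_series_infinite_half_life(self):
        fit = slamfit.fit_decay([0, 3, 6], [1.0, 1.0, 1.0])
        assert fit["k"] == pytest.approx(0.0, abs=1e-15)
        assert math.isinf(fit["t_half"])

    def test_too_few_points_unfittable(self):
        fit = slamfit.fit_decay([0, 3], [1.0, 0.5])
        assert not fit["fit_ok"]

    def test_nonpositive_values_dropped_and_counted(self):
        fit = slamfit.fit_decay([0, 2, 4, 6], [1.0, 0.5, 0.0, 0.25])
        assert fit["n_dropped"] == 1
        assert fit["n_timepoints"] == 3

    def test_matches_grid_search_oracle_on_random_series(self, rng):
        for _ in range(100):
            th = float(rng.uniform(0.7, 15))
            t = np.sort(rng.uniform(0.2, 12, size=6))
            t = np.concatenate([[0.0], t])
            v = 2 ** (-t / th) * np.exp(rng.normal(0, 0.1, size=len(t)))
            v[0] = 1.0
            fit = slamfit.fit_decay(t, v)
            assert fit["k"] == pytest.approx(grid_search_k(t, v), abs=1e-6)

    def test_noisy_binomial_recovery_within_ten_percent(self, rng):
        """Binomial sampling of the normalized decay curve at T coverage
        1,000 recovers a 4 h half-life within 10%."""
        t = np.array([0.0, 0.5, 0.75, 1.125, 1.6875, 2.53125, 3.796875, 5.6953125, 8.54296875, 12.0])
        cov = 1000
        v = rng.binomial(cov, 2 ** (-t / 4.0)) / cov
        v = v / v[0]
        fit = slamfit.fit_decay(t, v)
        assert fit["t_half"] == pytest.approx(4.0, rel=0.10)


def _fit_row(utr, cond, t_half, rse=0.05, cov=5000, ok=True):
    k = LOG2 / t_half if np.isfinite(t_half) and t_half > 0 else 0.0
    return {
        "utr_id": utr, "condition": cond, "k": k,
        "t_half": t_half, "residual_se": rse, "n_timepoints": 10,
        "n_dropped": 0, "t_coverage_min": cov, "fit_ok": ok,
    }


class TestFilterFits:
    def fixture_fits(self):
        rows = [
            _fit_row("u1", "control", 3.0),                      # pass
            _fit_row("u1", "treated", 3.2),                      # pass
            _fit_row("u2", "control", 20.0),                     # t_half_high
            _fit_row("u2", "treated", 3.0),                      # pass, dropped later
            _fit_row("u3", "control", 0.5),                      # t_half_low
            _fit_row("u3", "treated", 0.5),                      # t_half_low
            _fit_row("u4", "control", 3.0, cov=80),              # low_coverage
            _fit_row("u4", "treated", 3.0, rse=0.4),             # poor_fit
            _fit_row("u5", "control", math.inf),                 # t_half_high
            _fit_row("u5", "treated", 3.0, rse=0.31),            # poor_fit (rse)
        ]
        return pd.DataFrame(rows)

    def test_fixture_reproduces_thresholds_exactly(self):
        kept, ledger = slamfit.filter_fits(self.fixture_fits())
        assert ledger == {
            "low_coverage": 1,
            "t_half_low": 2,
            "t_half_high": 2,
            "poor_fit": 2,
            "pass": 3,
            "input": 10,
            "dropped_missing_condition": 1,
            "kept": 2,
        }
        assert set(kept["utr_id"]) == {"u1"}

    def test_ledger_conserves_input_count(self):
        _, ledger = slamfit.filter_fits(self.fixture_fits())
        reasons = ["low_coverage", "t_half_low", "t_half_high", "poor_fit", "pass"]
        assert sum(ledger[r] for r in reasons) == ledger["input"]

    @pytest.mark.parametrize("t_half,reason", [(20.0, "t_half_high"), (0.5, "t_half_low")])
    def test_boundary_reasons(self, t_half, reason):
        fits = pd.DataFrame([_fit_row("u", "c", t_half)])
        kept, ledger = slamfit.filter_fits(fits, require_both_conditions=False)
        assert ledger[reason] == 1 and kept.empty

    def test_exact_bounds_are_inclusive(self):
        fits = pd.DataFrame(
            [_fit_row("u1", "c", 0.67), _fit_row("u2", "c", 18.0)]
        )
        kept, _ = slamfit.filter_fits(fits, require_both_conditions=False)
        assert len(kept) == 2

    def test_relaxing_rse_never_shrinks_kept_set(self):
        fits = self.fixture_fits()
        kept_03, _ = slamfit.filter_fits(fits, max_rse=0.3, require_both_conditions=False)
        kept_05, _ = slamfit.filter_fits(fits, max_rse=0.5, require_both_conditions=False)
        assert set(map(tuple, kept_03[["utr_id", "condition"]].values)) <= set(
            map(tuple, kept_05[["utr_id", "condition"]].values)
        )


class TestHalflifeContrast:
    def toy(self):
        # 6 transcripts on 2 chromosomes with hand-computed fold changes
        ctrl = pd.DataFrame(
            [_fit_row(u, "control", th) for u, th in
             [("a", 2.0), ("b", 4.0), ("c", 8.0), ("d", 2.0), ("e", 4.0), ("f", 1.0)]]
        )
        trt = pd.DataFrame(
            [_fit_row(u, "treated", th) for u, th in
             [("a", 4.0), ("b", 4.0), ("c", 16.0), ("d", 1.0), ("e", 4.0), ("f", 4.0)]]
        )
        chrom = pd.Series({"a": "chr1", "b": "chr1", "c": "chr1",
                           "d": "chrX", "e": "chrX", "f": "chrX"})
        m6a = pd.Series({"a": 2, "b": 0, "c": 1, "d": 0, "e": 3, "f": 0})
        return ctrl, trt, m6a, chrom

    def test_per_chromosome_medians_hand_computed(self):
        ctrl, trt, m6a, chrom = self.toy()
        res = slamfit.halflife_contrast(ctrl, trt, m6a, chrom)
        med = res["per_chromosome"].set_index("chrom")["median_log2fc"]
        # chr1 log2fc: {1, 0, 1} -> median 1; chrX: {-1, 0, 2} -> median 0
        assert med["chr1"] == pytest.approx(1.0)
        assert med["chrX"] == pytest.approx(0.0)

    def test_identical_fits_zero_change(self):
        ctrl, _, m6a, chrom = self.toy()
        trt = ctrl.assign(condition="treated")
        res = slamfit.halflife_contrast(ctrl, trt, m6a, chrom)
        g = res["groups"].set_index("group")
        assert g["median_pct_change"].abs().max() == 0.0

    def test_injected_methylated_only_increase_recovered(self):
        """A uniform 8% treated increase on methylated transcripts only."""
        rng = np.random.default_rng(5)
        n = 400
        utrs = [f"u{i}" for i in range(n)]
        m6a = pd.Series({u: (1 if i < n // 2 else 0) for i, u in enumerate(utrs)})
        chrom = pd.Series({u: f"chr{1 + i % 5}" for i, u in enumerate(utrs)})
        base = rng.lognormal(np.log(4), 0.4, size=n)
        ctrl = pd.DataFrame([_fit_row(u, "control", th) for u, th in zip(utrs, base)])
        trt_th = base * np.where(m6a[utrs].to_numpy() > 0, 1.08, 1.0)
        trt = pd.DataFrame([_fit_row(u, "treated", th) for u, th in zip(utrs, trt_th)])
        res = slamfit.halflife_contrast(ctrl, trt, m6a, chrom)
        g = res["groups"].set_index("group")
        assert g.loc["methylated", "median_pct_change"] == pytest.approx(8.0, abs=0.01)
        assert g.loc["unmethylated", "median_pct_change"] == pytest.approx(0.0, abs=0.01)

    def test_empty_group_marked_absent(self):
        ctrl, trt, m6a, chrom = self.toy()
        m6a_all = m6a * 0 + 1  # no unmethylated transcripts
        res = slamfit.halflife_contrast(ctrl, trt, m6a_all, chrom)
        g = res["groups"].set_index("group")
        assert bool(g.loc["unmethylated", "absent"])
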