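"""Merging statistics, CC1/2, resolution limits and decay-model fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smxdose import decay_analysis as da
from smxdose.synthetic_decay import (DecayGroundTruth, generate_series,
                                     reflection_template_from_cell)

CELL = (9.6657, 11.0, 12.3, 90.0, 102.0, 90.0)


def make_record(frame, dose=1.0, scan_id=1):
    return da.ScanRecord(scan_id=scan_id, dose_mgy=dose, reflections=frame)


@pytest.fixture(scope="module")
def noisy_record():
    """One scan of a generated series with enough multiplicity for merging."""
    template = reflection_template_from_cell(CELL, 1.1, seed=11,
                                             multiplicity=4)
    truth = DecayGroundTruth(seed=11, n_scans=2, noise_multiplicative=0.05,
                             noise_additive_sigma=0.5)
    return generate_series(truth, template).scans[0]


class TestLaueMerging:
    def test_friedel_and_twofold_mates_share_an_id(self):
        hkl = np.array([[1, 2, 3], [-1, -2, -3], [-1, 2, -3], [1, -2, 3],
                        [1, 2, 4]])
        ids = da.laue_unique_ids(hkl, "P 21")
        assert len(set(ids[:4])) == 1
        assert ids[4] != ids[0]


class TestScanStatistics:
    def test_hand_rmerge(self):
        """Two observations 90 and 110 of one reflection: Rmerge = 20/200."""
        frame = pd.DataFrame({"h": [1, 1], "k": [0, 0], "l": [0, 0],
                              "d": [2.0, 2.0], "I": [90.0, 110.0],
                              "sigI": [1.0, 1.0]})
        stats = da.scan_statistics(make_record(frame), n_bins=1)
        assert stats["rmerge_overall"] == pytest.approx(0.10)

    def test_identical_equivalents_give_zero(self):
        frame = pd.DataFrame({"h": [1, 1, 2, 2], "k": [0, 0, 1, 1],
                              "l": [0, 0, 1, 1], "d": [2.0, 2.0, 1.5, 1.5],
                              "I": [100.0, 100.0, 40.0, 40.0],
                              "sigI": [1.0] * 4})
        stats = da.scan_statistics(make_record(frame), n_bins=1)
        assert stats["rmerge_overall"] == 0.0

    def test_no_multiples_is_flagged_undefined(self, toy_reflections):
        singles = toy_reflections.iloc[1:]    # breaks the only pair
        stats = da.scan_statistics(make_record(singles), n_bins=1)
        assert stats["rmerge_overall"] is None

    def test_matches_two_pass_oracle(self, noisy_record):
        """Rmerge equals a brute-force two-pass recomputation."""
        stats = da.scan_statistics(noisy_record, n_bins=8)
        refl = noisy_record.reflections.copy()
        refl["uid"] = da.laue_unique_ids(refl[["h", "k", "l"]].to_numpy())
        num = den = 0.0
        for _, grp in refl.groupby("uid"):
            if len(grp) < 2:
                continue
            mean = grp["I"].mean()
            num += (grp["I"] - mean).abs().sum()
            den += grp["I"].sum()
        assert stats["rmerge_overall"] == pytest.approx(num / den, rel=1e-12)

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_rmerge_scale_invariant(self, scale):
        frame = pd.DataFrame({"h": [1, 1, 1], "k": [0, 0, 0], "l": [0, 0, 0],
                              "d": [2.0] * 3, "I": [90.0, 100.0, 110.0],
                              "sigI": [1.0] * 3})
        base = da.scan_statistics(make_record(frame), 1)["rmerge_overall"]
        scaled_frame = frame.assign(I=frame["I"] * scale)
        scaled = da.scan_statistics(make_record(scaled_frame), 1)["rmerge_overall"]
        assert scaled == pytest.approx(base, rel=1e-9)


class TestCCHalf:
    def test_identical_halves_give_unity(self):
        """Duplicate observations: both halves identical, CC1/2 = 1."""
        rng = np.random.default_rng(3)
        n = 60
        intens = rng.exponential(100.0, n)
        frame = pd.DataFrame({
            "h": np.repeat(np.arange(1, n + 1), 2), "k": 0, "l": 0,
            "d": np.repeat(np.linspace(3.0, 1.0, n), 2),
            "I": np.repeat(intens, 2), "sigI": 1.0,
        })
        curve = da.cc_half(make_record(frame), n_bins=3, seed=0, point_group="P 1")
        assert np.allclose(curve["cc_half"], 1.0)

    def test_pure_noise_gives_near_zero(self):
        """Intensities with no signal: CC1/2 scatters about zero."""
        rng = np.random.default_rng(12)
        n = 4000
        frame = pd.DataFrame({
            "h": np.repeat(np.arange(1, n + 1), 2), "k": 0, "l": 0,
            "d": np.repeat(np.linspace(3.0, 1.0, n), 2),
            "I": rng.normal(0.0, 1.0, 2 * n), "sigI": 1.0,
        })
        curve = da.cc_half(make_record(frame), n_bins=4, seed=1, point_group="P 1")
        assert np.all(np.abs(curve["cc_half"]) < 0.15)

    def test_bounded_and_scale_invariant(self, noisy_record):
        curve = da.cc_half(noisy_record, n_bins=8, seed=5)
        defined = curve["cc_half"].dropna()
        assert ((defined >= -1.0) & (defined <= 1.0)).all()
        scaled = noisy_record.reflections.assign(
            I=noisy_record.reflections["I"] * 37.5,
            sigI=noisy_record.reflections["sigI"] * 37.5)
        curve2 = da.cc_half(make_record(scaled), n_bins=8, seed=5)
        assert np.allclose(curve["cc_half"], curve2["cc_half"], equal_nan=True)

    def test_split_is_seed_reproducible(self, noisy_record):
        c1 = da.cc_half(noisy_record, n_bins=6, seed=42)
        c2 = da.cc_half(noisy_record, n_bins=6, seed=42)
        pd.testing.assert_frame_equal(c1, c2)

    def test_damped_data_decays_with_resolution(self):
        """B-damped intensities with additive noise lose correlation in the
        high-resolution shells."""
        template = reflection_template_from_cell(CELL, 0.8, seed=2,
                                                 multiplicity=2)
        truth = DecayGroundTruth(seed=2, n_scans=8, b_rate_a2_per_mgy=2.0,
                                 noise_additive_sigma=2.0)
        series = generate_series(truth, template)
        curve = da.cc_half(series.scans[-1], n_bins=8, seed=0)
        defined = curve.dropna(subset=["cc_half"])
        low = defined["cc_half"].iloc[:3].mean()
        high = defined["cc_half"].iloc[-3:].mean()
        assert high < low


class TestResolutionLimit:
    def test_hand_interpolation_in_reciprocal_d(self):
        """Bins (d=1.0, CC=0.5) and (d=0.8, CC=0.1) cross 0.3 at ~0.89 A."""
        curve = pd.DataFrame({"d_mid": [1.0, 0.8], "d_max": [1.1, 0.9],
                              "d_min": [0.9, 0.7], "cc_half": [0.5, 0.1]})
        assert da.resolution_limit(curve, 0.3) == pytest.approx(0.889, abs=0.005)

    def test_never_crossing_returns_data_edge(self):
        curve = pd.DataFrame({"d_mid": [2.0, 1.0, 0.7],
                              "d_max": [2.5, 1.2, 0.8],
                              "d_min": [1.2, 0.8, 0.6],
                              "cc_half": [0.99, 0.98, 0.95]})
        assert da.resolution_limit(curve) == pytest.approx(0.6)

    def test_monotone_in_curve_level(self):
        """Pointwise-lowering the CC curve never sharpens the limit."""
        base = pd.DataFrame({"d_mid": [2.0, 1.5, 1.0, 0.8],
                             "d_max": [2.5, 1.7, 1.2, 0.9],
                             "d_min": [1.7, 1.2, 0.9, 0.7],
                             "cc_half": [0.9, 0.7, 0.4, 0.2]})
        d0 = da.resolution_limit(base)
        lowered = base.assign(cc_half=base["cc_half"] - 0.15)
        assert da.resolution_limit(lowered) >= d0

    def test_all_undefined_is_an_error(self):
        curve = pd.DataFrame({"d_mid": [1.0], "d_max": [1.1], "d_min": [0.9],
                              "cc_half": [np.nan]})
        with pytest.raises(ValueError):
            da.resolution_limit(curve)


class TestNormalizeIntensity:
    def test_first_scan_is_100_and_scaling(self):
        frame = pd.DataFrame({"scan_id": [1, 2, 3], "dose": [1.0, 2.0, 3.0],
                              "sumI": [400.0, 400.0, 200.0]})
        series = da.ScanSeries.from_summary_frame(frame)
        np.testing.assert_allclose(da.normalize_intensity(series),
                                   [100.0, 100.0, 50.0])

    def test_zero_first_scan_rejected(self):
        frame = pd.DataFrame({"scan_id": [1, 2, 3, 4],
                              "dose": [1.0, 2.0, 3.0, 4.0],
                              "sumI": [0.0, 1.0, 1.0, 1.0]})
        series = da.ScanSeries.from_summary_frame(frame)
        with pytest.raises(ValueError):
            da.normalize_intensity(series)


def summary_series(doses, sums):
    frame = pd.DataFrame({"scan_id": np.arange(1, len(doses) + 1),
                          "dose": doses, "sumI": sums})
    return da.ScanSeries.from_summary_frame(frame)


class TestFits:
    def test_half_dose_exact_on_noiseless_exponential(self):
        doses = np.arange(1, 11) * 0.63
        sums = 100.0 * np.exp(-np.log(2) / 4.4 * doses)
        fit = da.fit_half_dose(summary_series(doses, sums))
        assert fit.derived["D_half_mgy"] == pytest.approx(4.4, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_half_dose_flat_series_flagged(self):
        fit = da.fit_half_dose(summary_series(np.arange(1.0, 6.0),
                                              np.full(5, 80.0)))
        assert fit.derived["flat"]
        assert np.isinf(fit.derived["D_half_mgy"])

    def test_half_dose_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            da.fit_half_dose(summary_series(np.arange(1.0, 6.0),
                                            [10.0, 5.0, 2.0, -1.0, 1.0]))

    def test_resolution_slope_exact_on_noiseless_line(self):
        doses = np.linspace(0.63, 10.0, 12)
        fit = da.fit_resolution_decay(doses, 0.6 + 0.1 * doses)
        assert fit.params["b"] == pytest.approx(0.1, rel=1e-9)
        assert fit.derived["slope_a_per_10mgy"] == pytest.approx(1.0, rel=1e-9)

    def test_cell_expansion_recovery(self):
        doses = np.linspace(0.0, 10.0, 8)
        vols = 1279.19 * (1 + 0.002 * doses)      # 2% per 10 MGy
        fit = da.fit_cell_expansion(doses, vols)
        assert fit.derived["expansion_pct_per_10mgy"] == pytest.approx(2.0,
                                                                       rel=1e-6)

    def test_cell_expansion_constant_is_zero(self):
        fit = da.fit_cell_expansion(np.arange(5.0), np.full(5, 1000.0))
        assert fit.derived["expansion_pct_per_10mgy"] == pytest.approx(0.0)

    def test_cell_expansion_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            da.fit_cell_expansion([-1.0, 1.0, 2.0], [1.0, 1.0, 1.0])

    def test_ueq_growth_exact_recovery(self):
        doses = np.arange(1, 9) * 0.63
        ueq = 0.012 * np.exp(0.05 * doses)
        fit = da.fit_ueq_growth(doses, ueq)
        assert fit.params["k"] == pytest.approx(0.05, rel=1e-6)

    def test_ueq_flat_series(self):
        fit = da.fit_ueq_growth(np.arange(1.0, 6.0), np.full(5, 0.012))
        assert fit.params["k"] == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_3_se(self):
        """Across seeded replicates, fitted slopes land within 3 SE of truth
        at least 95% of the time."""
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            doses = np.arange(1, 17) * 0.63
            dmin = 0.6 + 0.1 * doses + rng.normal(0, 0.02, doses.size)
            fit = da.fit_resolution_decay(doses, dmin)
            if abs(fit.params["b"] - 0.1) <= 3 * fit.stderr["b"]:
                hits += 1
        assert hits / n_rep >= 0.95


class TestCompareMatched:
    def test_identical_scans_give_identical_rows(self):
        doses = [1.0, 2.0]
        frame = pd.DataFrame({"scan_id": [1, 2], "dose": doses,
                              "sumI": [100.0, 100.0], "dmin": [0.6, 0.6],
                              "Rmerge": [0.05, 0.05]})
        series = da.ScanSeries.from_summary_frame(frame)
        table = da.compare_matched(series, [1, 2])
        cols = ["resolution_a", "rmerge", "norm_mean_I"]
        assert table.loc[0, cols].tolist() == table.loc[1, cols].tolist()

    def test_row_count_and_columns(self, noisy_record):
        template = reflection_template_from_cell(CELL, 1.2, seed=4,
                                                 multiplicity=3)
        series = generate_series(DecayGroundTruth(seed=4, n_scans=4,
                                                  noise_additive_sigma=0.5),
                                 template)
        table = da.compare_matched(series, [1, 2, 4], n_bins=5)
        assert len(table) == 3
        for col in ("dose_mgy", "resolution_a", "rmerge", "norm_mean_I",
                    "mean_I_over_sig"):
            assert col in table.columns

    def test_missing_scan_rejected(self):
        frame = pd.DataFrame({"scan_id": [1, 2], "dose": [1.0, 2.0],
                              "sumI": [10.0, 9.0]})
        series = da.ScanSeries.from_summary_frame(frame)
        with pytest.raises(ValueError, match="not in series"):
            da.compare_matched(series, [1, 7])


class TestSeriesValidation:
    def test_nonincreasing_dose_rejected(self):
        frame = pd.DataFrame({"scan_id": [1, 2], "dose": [2.0, 1.0],
                              "sumI": [10.0, 9.0]})
        with pytest.raises(ValueError, match="strictly increasing"):
            da.ScanSeries.from_summary_frame(
                frame.assign(dose=[2.0, 2.0]))
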