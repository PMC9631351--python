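"""Corrections, delta values, replicate statistics and diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isofine.ratio_stats import (
    StandardSet,
    aggregate_replicates,
    correct_exchangeable_h,
    cv_between_replicates,
    delta_value,
    incorporation_regression,
    species_contributions,
    subsample_precision,
    summarize_elements,
    tic_trend,
)


class TestExchangeableCorrection:
    def test_no_exchangeable_is_identity(self):
        assert correct_exchangeable_h(2e-4, 8, 0, 1.5e-4) == 2e-4

    def test_homogeneous_case_unchanged(self):
        for h_exch in (1, 3, 7):
            assert correct_exchangeable_h(150e-6, 8, h_exch, 150e-6) == pytest.approx(
                150e-6, rel=1e-12
            )

    def test_proline_example(self):
        # 8 H total, 1 exchangeable, measured 200 ppm in 150 ppm solvent
        got = correct_exchangeable_h(200e-6, 8, 1, 150e-6)
        assert got * 1e6 == pytest.approx(207.142857, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            correct_exchangeable_h(2e-4, 8, 8, 1.5e-4)
        with pytest.raises(ValueError):
            correct_exchangeable_h(-1e-4, 8, 1, 1.5e-4)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        r_raw=st.floats(1e-6, 1e-2),
        scale=st.floats(0.1, 10.0),
        h_exch=st.integers(0, 7),
    )
    def test_linear_in_raw_ratio(self, r_raw, scale, h_exch):
        solvent = 1.5e-4
        f = lambda r: correct_exchangeable_h(r, 8, h_exch, solvent)
        base, scaled = f(r_raw), f(r_raw * scale)
        # affine in r_raw: increments scale exactly
        expected = base + (scale - 1.0) * r_raw * 8 / (8 - h_exch)
        assert scaled == pytest.approx(expected, rel=1e-9)


class TestDeltaValue:
    def test_reference_points(self):
        assert delta_value(1.0, 1.0) == 0.0
        assert delta_value(2.0, 1.0) == 1000.0

    def test_c3_plant_round_trip(self):
        std = StandardSet()
        r = std.c * (1.0 - 47.8 / 1000.0)
        assert delta_value(r, std.c) == pytest.approx(-47.8, abs=1e-9)
        assert r / std.c == pytest.approx(0.9522, abs=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(r=st.floats(1e-6, 1.0), std=st.floats(1e-6, 1.0))
    def test_round_trips_to_machine_precision(self, r, std):
        delta = delta_value(r, std)
        assert std * (1.0 + delta / 1000.0) == pytest.approx(r, rel=1e-12)


class TestAggregation:
    def test_identical_records(self):
        frame = pd.DataFrame(
            {"sample": "a", "replicate": 1, "species": "Pro", "r_c": [0.011] * 3}
        )
        out = aggregate_replicates(frame, "r_c")
        assert out.loc[0, "n"] == 3
        assert out.loc[0, "mean"] == pytest.approx(0.011, rel=1e-12)
        assert out.loc[0, "median"] == pytest.approx(0.011, rel=1e-12)
        assert out.loc[0, "sd"] == pytest.approx(0.0, abs=1e-15)

    def test_gaussian_sample_mean(self):
        rng = np.random.default_rng(42)
        values = rng.normal(0.011, 1e-4, size=1000)
        frame = pd.DataFrame(
            {"sample": "a", "replicate": 1, "species": "Pro", "r_c": values}
        )
        out = aggregate_replicates(frame, "r_c", mad_k=None)
        assert out.loc[0, "mean"] == pytest.approx(0.011, abs=3 * 1e-4 / np.sqrt(1000))
        assert out.loc[0, "sem"] == pytest.approx(1e-4 / np.sqrt(1000), rel=0.15)

    def test_outlier_trimmed(self):
        values = [0.011] * 20 + [0.5]
        frame = pd.DataFrame(
            {"sample": "a", "replicate": 1, "species": "Pro",
             "r_c": values + np.linspace(0, 1e-6, 21)}
        )
        out = aggregate_replicates(frame, "r_c", mad_k=5.0)
        assert out.loc[0, "n"] == 20

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0.011, 1e-4, 50)
        base = pd.DataFrame(
            {"sample": "a", "replicate": 1, "species": "Pro", "r_c": values}
        )
        shuffled = base.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = aggregate_replicates(base, "r_c")
        b = aggregate_replicates(shuffled, "r_c")
        pd.testing.assert_frame_equal(a, b)

    def test_empty_group_reported_with_reason(self):
        frame = pd.DataFrame(
            {"sample": "a", "replicate": 1, "species": "Pro", "r_c": [np.nan]}
        )
        out = aggregate_replicates(frame, "r_c")
        assert out.loc[0, "n"] == 0
        assert out.loc[0, "reason"] == "no unflagged records"


class TestReplicateCv:
    @staticmethod
    def _summary(means):
        return pd.DataFrame(
            {
                "sample": "a",
                "species": "Pro",
                "element": "C",
                "replicate": range(len(means)),
                "mean": means,
            }
        )

    def test_identical_means_zero(self):
        out = cv_between_replicates(self._summary([0.011, 0.011, 0.011]))
        assert out.loc[0, "cv_pct"] == pytest.approx(0.0, abs=1e-10)

    def test_arithmetic(self):
        out = cv_between_replicates(self._summary([0.0110, 0.0111, 0.0109]))
        assert out.loc[0, "cv_pct"] == pytest.approx(0.909, abs=5e-3)

    def test_scale_invariance(self):
        means = [0.0110, 0.0111, 0.0109]
        a = cv_between_replicates(self._summary(means)).loc[0, "cv_pct"]
        b = cv_between_replicates(
            self._summary([7 * m for m in means])
        ).loc[0, "cv_pct"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="< 2 replicates"):
            cv_between_replicates(self._summary([0.011]))


class TestTicTrend:
    @staticmethod
    def _frame(n, rng, slope=0.0):
        log_tic = rng.uniform(5.0, 7.0, n)
        ratio = 0.011 + slope * log_tic + rng.normal(0, 1e-4, n)
        return pd.DataFrame(
            {"species": "Pro", "tic": 10**log_tic, "r_c": ratio}
        )

    def test_null_shows_no_trend(self):
        frame = self._frame(500, np.random.default_rng(3))
        slope, r, p = tic_trend(frame, "Pro", "C")
        assert abs(r) < 0.1

    def test_planted_dependence_detected(self):
        frame = self._frame(500, np.random.default_rng(4), slope=5e-4)
        slope, r, p = tic_trend(frame, "Pro", "C")
        assert slope > 0 and p < 1e-6

    def test_constant_ratio_gives_zero_slope(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            {"species": "Pro", "tic": 10 ** rng.uniform(5, 7, 50), "r_c": 0.011}
        )
        slope, _, _ = tic_trend(frame, "Pro", "C")
        assert slope == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_tic_spread_rejected(self):
        frame = pd.DataFrame(
            {"species": "Pro", "tic": np.full(50, 1e6), "r_c": 0.011}
        )
        with pytest.raises(ValueError, match="decades"):
            tic_trend(frame, "Pro", "C")


def _shot_noise_records(n_per_rep=600, seed=0):
    """Synthetic shot-noise-limited datapoints, 3 replicates, one species."""
    rng = np.random.default_rng(seed)
    frames = []
    for rep in range(1, 4):
        frames.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "species": "Pro",
                    "r_c": rng.normal(0.011, 0.011 * 0.006, n_per_rep),
                    "r_n": rng.normal(0.0037, 0.0037 * 0.03, n_per_rep),
                    "r_h": rng.normal(1.5e-4, 1.5e-4 * 0.04, n_per_rep),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestSubsamplePrecision:
    def test_full_dataset_single_draw_equals_replicate_cv(self):
        frame = _shot_noise_records()
        curve = subsample_precision(frame, ks=[600], n_draws=1, seed=1)
        summary = summarize_elements(
            frame, elements=("C", "N", "H"),
            group_cols=("replicate", "species"), mad_k=None,
        )
        cv = cv_between_replicates(summary, group_cols=("species", "element"))
        assert curve.mean_cv_pct[0] == pytest.approx(cv["cv_pct"].mean(), rel=1e-9)

    def test_precision_improves_as_sqrt_k(self):
        curve = subsample_precision(
            _shot_noise_records(), ks=[40, 150, 600], n_draws=25, seed=2
        )
        assert curve.mean_cv_pct[0] > curve.mean_cv_pct[1] > curve.mean_cv_pct[2]
        slope = np.polyfit(
            np.log(curve.ks), np.log(curve.mean_cv_pct), 1
        )[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_deterministic_for_fixed_seed(self):
        frame = _shot_noise_records()
        a = subsample_precision(frame, ks=[50, 200], n_draws=5, seed=9)
        b = subsample_precision(frame, ks=[50, 200], n_draws=5, seed=9)
        assert a == b

    def test_oversized_k_names_the_replicate(self):
        with pytest.raises(ValueError, match="fewer than k"):
            subsample_precision(_shot_noise_records(), ks=[601], n_draws=1, seed=0)


class TestIncorporationRegression:
    def test_noiseless_linear_input(self):
        media = np.linspace(150, 1000, 10)
        fit = incorporation_regression(media, 150 + 0.04 * (media - 150))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.incorporation_pct == pytest.approx(4.0, rel=1e-9)

    @pytest.mark.parametrize("slope", [0.04, 0.15])
    def test_planted_slope_recovered_under_noise(self, slope):
        rng = np.random.default_rng(int(slope * 1000))
        media = np.repeat(np.linspace(150, 1000, 10), 3)
        values = 150 + slope * (media - 150) + rng.normal(0, 0.5, media.size)
        fit = incorporation_regression(media, values)
        assert abs(fit.slope - slope) <= 3 * fit.slope_stderr
        assert fit.incorporation_pct == pytest.approx(slope * 100, rel=0.05)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            incorporation_regression([150, 150, 1000], [1, 1, 2])


class TestSpeciesContributions:
    def test_single_species_is_total(self):
        frame = pd.DataFrame({"species": ["Pro"] * 3, "area_m": [1.0, 2.0, 3.0]})
        contrib, r2 = species_contributions(frame)
        assert contrib["Pro"] == 100.0
        assert r2 is None

    def test_r2_against_reference_matches_pearson(self):
        # observed collagen contributions vs a literature composition vector
        frame = pd.DataFrame(
            {
                "species": ["Pro", "Hyp", "Leu/Ile", "Phe"],
                "area_m": [35.0, 22.0, 9.0, 5.0],
            }
        )
        reference = {"Pro": 18.0, "Hyp": 11.0, "Leu/Ile": 7.0, "Phe": 5.0}
        contrib, r2 = species_contributions(frame, reference)
        obs = contrib[list(reference)].to_numpy()
        expected_r2 = np.corrcoef(obs, list(reference.values()))[0, 1] ** 2
        assert r2 == pytest.approx(expected_r2, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            species_contributions(pd.DataFrame(columns=["species", "area_m"]))
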