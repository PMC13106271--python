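"""TOST power, cluster bootstrap, and emotion-task preprocessing."""

import numpy as np
import pandas as pd
import pytest

from camhrv.equivalence import (
    ComponentWindows,
    TOSTSpec,
    cluster_bootstrap_equivalence,
    component_means,
    design_effect,
    hr_change_scores,
    tost_power,
    z_standardize_reference,
)
from camhrv.signals import InstHRSeries


class TestDesignEffect:
    def test_nine_recordings_icc_half(self):
        assert design_effect(9, 0.5) == 5.0

    def test_single_recording_no_inflation(self):
        assert design_effect(1, 0.9) == 1.0

    def test_zero_icc_no_inflation(self):
        assert design_effect(20, 0.0) == 1.0


class TestTOSTPower:
    def test_sdnn_design_unclustered(self):
        spec = TOSTSpec(mu=11.45, sigma=14.34, n=77)
        assert tost_power(spec) == pytest.approx(0.69, abs=0.005)

    def test_rmssd_design_unclustered(self):
        spec = TOSTSpec(mu=11.02, sigma=10.43, n=77)
        assert tost_power(spec) == pytest.approx(0.95, abs=0.005)

    def test_clustered_designs(self):
        sdnn = TOSTSpec(mu=11.45, sigma=14.34, n=77, m=9, icc=0.5)
        rmssd = TOSTSpec(mu=11.02, sigma=10.43, n=77, m=9, icc=0.5)
        assert tost_power(sdnn) == pytest.approx(0.895, abs=0.005)
        assert tost_power(rmssd) == pytest.approx(0.998, abs=0.005)

    def test_vanishing_error_gives_full_power(self):
        spec = TOSTSpec(mu=0.0, sigma=1e-6, n=77)
        assert tost_power(spec) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_n(self):
        powers = [tost_power(TOSTSpec(mu=10.0, sigma=14.0, n=n))
                  for n in (10, 30, 77, 200)]
        assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))

    def test_monotone_in_sigma(self):
        powers = [tost_power(TOSTSpec(mu=10.0, sigma=s, n=77))
                  for s in (5.0, 10.0, 20.0, 40.0)]
        assert all(a >= b - 1e-12 for a, b in zip(powers, powers[1:]))

    def test_mu_on_bound_power_near_alpha(self):
        spec = TOSTSpec(mu=15.0, sigma=10.0, n=77)
        assert tost_power(spec) <= 0.05 + 0.01

    def test_infeasible_design_power_zero(self):
        # SE so large the TOST rejection region is empty
        spec = TOSTSpec(mu=0.0, sigma=500.0, n=3)
        assert tost_power(spec) == 0.0

    def test_noncentral_t_variant_close_to_normal(self):
        spec = TOSTSpec(mu=11.02, sigma=10.43, n=77)
        assert tost_power(spec, method="noncentral_t") == pytest.approx(
            tost_power(spec), abs=0.02
        )


def _simulate_table(rng, n_clusters=50, m=5, slope_offset=0.0, sesoi=15.0):
    """Paired outcomes with identical structure plus small noise."""
    rows = []
    for c in range(n_clusters):
        u = rng.normal(0, 5)
        for _ in range(m):
            x = rng.normal(0, 1)
            base = 50 + 3 * x + u + rng.normal(0, 2)
            rows.append(
                {
                    "participant_id": f"p{c}",
                    "x": x,
                    "outcome_ecg": base + rng.normal(0, 1),
                    "outcome_rppg": base + slope_offset * x + rng.normal(0, 1),
                }
            )
    return pd.DataFrame(rows)


class TestClusterBootstrap:
    def test_identical_outcomes_trivially_equivalent(self, rng):
        df = _simulate_table(rng)
        df["outcome_rppg"] = df["outcome_ecg"]
        res = cluster_bootstrap_equivalence(
            df, "outcome_rppg", "outcome_ecg", ["x"], n_boot=100, seed=1
        )
        assert all(res.equivalent.values())
        assert all(abs(v) < 1e-12 for v in res.mean_delta.values())
        assert all(v == 1.0 for v in res.prop_within_sesoi.values())

    def test_planted_large_slope_offset_not_equivalent(self, rng):
        df = _simulate_table(rng, slope_offset=45.0)  # 3x the 15 ms SESOI
        res = cluster_bootstrap_equivalence(
            df, "outcome_rppg", "outcome_ecg", ["x"], n_boot=200, seed=2
        )
        assert not res.equivalent["x"]

    def test_seed_determinism(self, rng):
        df = _simulate_table(rng)
        a = cluster_bootstrap_equivalence(
            df, "outcome_rppg", "outcome_ecg", ["x"], n_boot=50, seed=3
        )
        b = cluster_bootstrap_equivalence(
            df, "outcome_rppg", "outcome_ecg", ["x"], n_boot=50, seed=3
        )
        assert np.array_equal(a.deltas, b.deltas)

    def test_needs_two_clusters(self, rng):
        df = _simulate_table(rng, n_clusters=1)
        with pytest.raises(ValueError):
            cluster_bootstrap_equivalence(
                df, "outcome_rppg", "outcome_ecg", ["x"], n_boot=10, seed=0
            )


class TestChangeScores:
    def _series(self, hr, fs=30.0):
        return InstHRSeries(t=np.arange(hr.size) / fs, hr_bpm=hr,
                            valid=np.ones(hr.size, bool), fs=fs)

    def test_constant_hr_all_bins_zero(self):
        s = self._series(np.full(600, 70.0))
        _, means = hr_change_scores(s, trial_start_s=5.0)
        assert np.allclose(means, 0.0)

    def test_step_at_trial_start(self):
        hr = np.full(600, 70.0)
        hr[150:] = 75.0  # +5 BPM from t = 5 s (trial start)
        s = self._series(hr)
        mids, means = hr_change_scores(s, trial_start_s=5.0)
        assert np.allclose(means, 5.0)  # whole span is post-step

    def test_linear_ramp_bins_match_window_means(self):
        # HR = 60 + 2t: each half-second bin mean sits 2*0.5 = 1 BPM above
        # the previous one, and the bin at the baseline center is
        # 2*(bin mid - baseline mid) above zero change.
        fs = 30.0
        hr = 60.0 + 2.0 * np.arange(600) / fs
        s = self._series(hr)
        mids, means = hr_change_scores(s, trial_start_s=5.0)
        assert np.allclose(np.diff(means), 1.0, atol=1e-9)
        baseline_mid = 5.0 - 0.5 - 0.5 / (2 * fs)  # discrete window center
        bin_mid_abs = 11.0 + mids[0] - 0.5 / (2 * fs)
        assert means[0] == pytest.approx(2.0 * (bin_mid_abs - baseline_mid))

    def test_missing_baseline_flagged(self):
        s = self._series(np.full(100, 70.0))
        with pytest.raises(ValueError):
            hr_change_scores(s, trial_start_s=0.5)


class TestComponentMeans:
    def test_constant_bins_equal_components(self):
        mids = np.arange(-5.75, 2.0, 0.5)
        out = component_means(mids, np.full(mids.size, 1.5))
        assert all(v == pytest.approx(1.5) for v in out.values())

    def test_triphasic_template_ordering(self):
        mids = np.arange(-5.75, 2.0, 0.5)
        vals = np.empty(mids.size)
        vals[(mids >= -6) & (mids < -4)] = -1.0  # D1 dip
        vals[(mids >= -4) & (mids < -2)] = 0.5  # A1 recovery
        vals[(mids >= -2) & (mids < 0)] = -0.5  # D2 dip
        vals[(mids >= 0) & (mids < 2)] = -2.0  # PDP deeper dip
        out = component_means(mids, vals)
        assert out["D1"] < out["A1"]
        assert out["D2"] < out["A1"]
        assert out["PDP"] < out["D2"]

    def test_boundary_midpoint_joins_later_component(self):
        out = component_means(np.array([-4.0]), np.array([2.0]))
        assert out["A1"] == pytest.approx(2.0)
        assert np.isnan(out["D1"])

    def test_permutation_invariance(self, rng):
        mids = np.arange(-5.75, 2.0, 0.5)
        vals = rng.standard_normal(mids.size)
        perm = rng.permutation(mids.size)
        assert component_means(mids, vals) == component_means(
            mids[perm], vals[perm]
        )


class TestZStandardize:
    def test_reference_mean_maps_to_zero(self):
        assert z_standardize_reference(np.array([5.0]), 5.0, 2.0) == 0.0

    def test_self_standardization_unit_moments(self, rng):
        x = rng.normal(3, 4, 500)
        z = z_standardize_reference(x, x.mean(), x.std())
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_other_dataset_keeps_its_offset(self, rng):
        ecg = rng.normal(0, 1, 500)
        rppg = ecg + 0.7
        z = z_standardize_reference(rppg, ecg.mean(), ecg.std())
        assert z.mean() == pytest.approx(0.7 / ecg.std(), abs=0.05)

    def test_bad_reference_sd(self):
        with pytest.raises(ValueError):
            z_standardize_reference(np.ones(3), 0.0, 0.0)
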