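import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sugarshock as ss
from sugarshock.errors import DataError, StructuralError
from sugarshock.stats import GRID_POINTS, SnapshotDataset, common_grid


def _dataset_from_counts(mapping, species="sgrs", provenance="experimental"):
    frames = []
    for t, counts in mapping.items():
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": np.arange(len(counts)),
                    "time_min": float(t),
                    "species": species,
                    "count": counts,
                }
            )
        )
    return SnapshotDataset(pd.concat(frames, ignore_index=True), provenance)


class TestMeanIqrTrace:
    def test_small_sample_mean_and_quartiles(self):
        ds = _dataset_from_counts({0.0: [1, 2, 3, 4, 5]})
        row = ss.mean_iqr_trace(ds).iloc[0]
        assert (row["mean"], row["q25"], row["q75"]) == (3.0, 2.0, 4.0)

    def test_identical_cells_have_zero_iqr_width(self):
        ds = _dataset_from_counts({0.0: [7] * 20})
        row = ss.mean_iqr_trace(ds).iloc[0]
        assert row["q75"] - row["q25"] == 0.0

    def test_missing_timepoint_error_names_the_timepoint(self):
        table = pd.concat(
            [
                _dataset_from_counts({0.0: [1, 2]}, "sgrs").table,
                _dataset_from_counts({0.0: [3, 4], 2.0: [5, 6]}, "ptsg").table,
            ],
            ignore_index=True,
        )
        ds = SnapshotDataset(table)
        with pytest.raises(DataError, match="2.0"):
            ss.mean_iqr_trace(ds)

    def test_accepts_ensemble_directly(self, wt_ensemble):
        trace = ss.mean_iqr_trace(wt_ensemble)
        assert set(trace["species"]) == {"sgrs", "ptsg"}
        assert len(trace) == 16


class TestKde:
    def test_density_normalizes_over_wide_grid(self, rng):
        counts = rng.integers(0, 51, size=200)
        kde = ss.gaussian_kde(counts, np.linspace(-20, 120, GRID_POINTS))
        assert kde.integral() == pytest.approx(1.0, abs=0.01)

    def test_density_symmetric_for_symmetric_sample(self):
        kde = ss.gaussian_kde([0, 0, 10, 10], np.linspace(-15, 25, 401))
        np.testing.assert_allclose(kde.density, kde.density[::-1], atol=1e-12)

    def test_zero_variance_sample_requires_bandwidth_override(self):
        grid = np.linspace(-5, 15, 101)
        with pytest.raises(DataError, match="bandwidth"):
            ss.gaussian_kde([5, 5, 5], grid)
        kde = ss.gaussian_kde([5, 5, 5], grid, bandwidth=0.5)
        assert kde.integral() == pytest.approx(1.0, abs=0.01)

    def test_kl_between_kdes_of_same_distribution_is_small(self, rng):
        a = rng.poisson(30, size=10_000)
        b = rng.poisson(30, size=10_000)
        grid = common_grid(a, b)
        kl = ss.kl_divergence(ss.gaussian_kde(a, grid), ss.gaussian_kde(b, grid))
        assert -1e-6 <= kl < 0.05

    @given(counts=st.lists(st.integers(0, 60), min_size=5, max_size=60))
    @settings(max_examples=25)
    def test_normalization_property(self, counts):
        counts = np.asarray(counts)
        if counts.std() == 0:
            return
        grid = common_grid(counts)
        assert ss.gaussian_kde(counts, grid).integral() == pytest.approx(
            1.0, abs=0.01
        )


class TestKlDivergence:
    def test_identity_is_zero(self, rng):
        counts = rng.poisson(20, size=500)
        grid = common_grid(counts)
        kde = ss.gaussian_kde(counts, grid)
        assert ss.kl_divergence(kde, kde) == 0.0

    def test_two_point_hand_summation(self):
        # 0.5 ln 2 + 0.5 ln(2/3), cross-checked against scipy.stats.entropy
        assert ss.kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
            0.1438410362, abs=1e-9
        )

    def test_asymmetry(self):
        forward = ss.kl_divergence([0.5, 0.5], [0.25, 0.75])
        reverse = ss.kl_divergence([0.25, 0.75], [0.5, 0.5])
        assert reverse == pytest.approx(0.1308120359, abs=1e-9)
        assert forward != reverse

    def test_floor_keeps_divergence_finite(self):
        kl = ss.kl_divergence([0.5, 0.5], [1.0, 0.0])
        assert np.isfinite(kl) and kl > 0

    def test_mismatched_grids_rejected(self, rng):
        counts = rng.poisson(20, size=100)
        k1 = ss.gaussian_kde(counts, np.linspace(0, 50, 100))
        k2 = ss.gaussian_kde(counts, np.linspace(0, 60, 100))
        with pytest.raises(StructuralError):
            ss.kl_divergence(k1, k2)
        with pytest.raises(StructuralError):
            ss.kl_divergence(k1, [0.5, 0.5])


class TestRelativeError:
    @pytest.mark.parametrize(
        "exp, sim, expected", [(40, 44, 0.1), (7, 7, 0.0), (50, 35, 0.3)]
    )
    def test_values(self, exp, sim, expected):
        assert ss.relative_error(exp, sim) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(DataError):
            ss.relative_error(0, 5)


class TestDecayFit:
    def test_exact_on_noiseless_exponential(self):
        t = np.arange(0, 481, 60, dtype=float)
        fit = ss.fit_decay_rate(t, 100 * np.exp(-0.022 * t))
        assert fit.rate == pytest.approx(0.022, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    @given(rate=st.floats(1e-4, 1.0))
    @settings(max_examples=30)
    def test_exact_recovery_property(self, rate):
        t = np.linspace(0.0, 5.0 / rate, 8)
        fit = ss.fit_decay_rate(t, 50 * np.exp(-rate * t))
        assert fit.rate == pytest.approx(rate, rel=1e-8)

    def test_constant_counts_give_zero_rate(self):
        fit = ss.fit_decay_rate([0.0, 60.0, 120.0], [12.0, 12.0, 12.0])
        assert fit.rate == 0.0

    def test_nonpositive_counts_rejected_with_advice(self):
        with pytest.raises(DataError, match="background"):
            ss.fit_decay_rate([0.0, 60.0], [10.0, 0.0])

    def test_single_timepoint_rejected(self):
        with pytest.raises(DataError):
            ss.fit_decay_rate([0.0, 0.0], [10.0, 10.0])

    def test_ssa_chase_recovers_free_sgrs_decay_rate(self):
        """Transcription-off chase at the hfq-null SgrS decay rate 0.022
        refits the truth within 10% from 500 simulated cells."""
        ds = ss.generate_chase_dataset(
            0.022, 500, (0.0, 0.5, 1.0, 1.5, 2.0, 3.0), seed=21
        )
        fit = ss.chase_decay_fit(ds)
        assert abs(fit.rate - 0.022) / 0.022 < 0.10


class TestUnitConversion:
    def test_hfq_pool_conversion_matches_reported_bulk_rate(self):
        """0.063 1/s at 250 Hfq in 1 fL is 1.5e5 1/(M s) to 2 significant
        figures."""
        k2 = ss.pseudo_to_second_order(0.063, 250, 1e-15)
        assert round(k2 / 1e5, 1) == 1.5

    def test_zero_rate_maps_to_zero(self):
        assert ss.pseudo_to_second_order(0.0, 250, 1e-15) == 0.0

    def test_identity_at_one_molar(self):
        from scipy.constants import N_A

        volume = 1e-15
        assert ss.pseudo_to_second_order(1.0, N_A * volume, volume) == pytest.approx(
            1.0
        )

    @given(
        k1=st.floats(1e-4, 10.0),
        pool=st.integers(1, 10_000),
        volume=st.floats(1e-16, 1e-14),
    )
    @settings(max_examples=30)
    def test_round_trip_property(self, k1, pool, volume):
        k2 = ss.pseudo_to_second_order(k1, pool, volume)
        assert ss.second_order_to_pseudo(k2, pool, volume) == pytest.approx(
            k1, rel=1e-12
        )

    def test_invalid_pool_or_volume(self):
        with pytest.raises(DataError):
            ss.pseudo_to_second_order(0.063, 0, 1e-15)
        with pytest.raises(DataError):
            ss.pseudo_to_second_order(0.063, 250, 0.0)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "mutant, wt, expected",
        [
            (0.033, 0.063, -48),
            (2.1e-4, 3.1e-4, -32),
            (0.003, 0.0018, 67),
            (0.27, 0.22, 23),
            (5.0, 5.0, 0),
        ],
    )
    def test_values(self, mutant, wt, expected):
        assert ss.percent_difference(mutant, wt) == expected

    def test_zero_wild_type_rejected(self):
        with pytest.raises(DataError):
            ss.percent_difference(1.0, 0.0)


class TestSnapshotDataset:
    def test_rejects_negative_or_fractional_counts(self):
        bad = pd.DataFrame(
            {"cell_id": [0], "time_min": [0.0], "species": ["sgrs"], "count": [-1]}
        )
        with pytest.raises(DataError):
            SnapshotDataset(bad)

    def test_rejects_unknown_provenance_and_missing_columns(self):
        good = pd.DataFrame(
            {"cell_id": [0], "time_min": [0.0], "species": ["sgrs"], "count": [1]}
        )
        with pytest.raises(DataError):
            SnapshotDataset(good, "guessed")
        with pytest.raises(DataError):
            SnapshotDataset(good.drop(columns=["count"]))

    def test_csv_round_trip_is_bit_exact(self, tmp_path):
        ds = _dataset_from_counts({0.0: [1, 2, 3], 2.0: [4, 5, 6]})
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        again = SnapshotDataset.read_csv(path)
        assert ds == again
        again.to_csv(tmp_path / "ds2.csv")
        assert (tmp_path / "ds.csv").read_bytes() == (tmp_path / "ds2.csv").read_bytes()
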