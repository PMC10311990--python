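import numpy as np
import pytest

from silentnet import (
    PopulationSpec,
    StimulationProtocol,
    apply_stimulation,
    generate_raster,
    generate_surrogate_recording,
)
from silentnet.population import lognormal_params_from_moments


class TestGenerateRaster:
    def test_zero_rate_neuron_never_spikes(self):
        spec = PopulationSpec(n_total=1, silent_fraction=1.0, silent_rate=0.0)
        raster = generate_raster(spec, n_trials=5, trial_duration=2000.0, seed=3)
        assert raster.occupancy.sum() == 0

    def test_spike_count_matches_binomial_oracle(self):
        # one neuron at 20 Hz over 1e6 ms: count ~ Binomial(1e6, 0.02)
        spec = PopulationSpec(n_total=1, silent_fraction=0.0, active_rate=20.0)
        raster = generate_raster(spec, n_trials=1000, trial_duration=1000.0, seed=11)
        count = int(raster.spike_counts()[0])
        n, p = 1_000_000, 0.02
        assert abs(count - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_subgroup_rates_converge_to_nominal(self):
        spec = PopulationSpec(n_total=200, silent_fraction=0.66)
        raster = generate_raster(spec, n_trials=100, trial_duration=1000.0, seed=5)
        active = raster.rates == 20.0
        assert active.sum() == 68
        p = 0.02
        pooled_bins = active.sum() * raster.total_bins
        se_rate = np.sqrt(p * (1 - p) / pooled_bins) * 1000.0
        assert abs(raster.empirical_rates()[active].mean() - 20.0) < 4 * se_rate

    def test_deterministic_given_seed(self):
        spec = PopulationSpec(n_total=10, silent_fraction=0.5)
        a = generate_raster(spec, n_trials=3, seed=42)
        b = generate_raster(spec, n_trials=3, seed=42)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)

    def test_lognormal_rate_law_positive_rates(self):
        spec = PopulationSpec(n_total=500, rate_law="lognormal")
        raster = generate_raster(spec, n_trials=1, trial_duration=10.0, seed=1)
        assert (raster.rates > 0).all()

    @pytest.mark.parametrize(
        "field,value", [("silent_fraction", 1.5), ("active_rate", -1.0), ("n_total", 0)]
    )
    def test_invalid_spec_names_field(self, field, value):
        spec = PopulationSpec(n_total=10)
        setattr(spec, field, value)
        with pytest.raises(ValueError, match=field):
            generate_raster(spec, n_trials=1)


class TestApplyStimulation:
    def test_zero_stimulations_is_identity(self):
        spec = PopulationSpec(n_total=20, silent_fraction=0.5)
        raster = generate_raster(spec, n_trials=10, seed=2)
        out, sets = apply_stimulation(
            raster, StimulationProtocol(n_stimulations=0, n_stimulated_cells=5), seed=2
        )
        np.testing.assert_array_equal(out.occupancy, raster.occupancy)
        assert sets == []

    def test_stimulated_cells_fire_at_stim_rate_inside_window_only(self):
        spec = PopulationSpec(n_total=200, silent_fraction=0.66)
        raster = generate_raster(spec, n_trials=20, seed=8)
        protocol = StimulationProtocol(n_stimulations=1)
        out, sets = apply_stimulation(raster, protocol, seed=9)
        (cells,) = sets
        assert cells.size == 50
        trial = protocol.epoch_trials(20)[0]
        window = out.occupancy[cells, trial, :200]
        p = 0.06
        se_rate = np.sqrt(p * (1 - p) / window.size) * 1000.0
        assert abs(window.mean() * 1000.0 - 60.0) < 3 * se_rate
        # everything outside the epoch window is bitwise unchanged
        mask = np.ones_like(out.occupancy, dtype=bool)
        mask[cells, trial, :200] = False
        np.testing.assert_array_equal(out.occupancy[mask], raster.occupancy[mask])

    def test_fixed_single_cell_changes_only_that_row(self):
        spec = PopulationSpec(n_total=30, silent_fraction=1.0)
        raster = generate_raster(spec, n_trials=4, seed=3)
        protocol = StimulationProtocol(
            n_stimulations=2,
            n_stimulated_cells=1,
            selection_rule="fixed_subset",
            fixed_cells=np.array([17]),
        )
        out, sets = apply_stimulation(raster, protocol, seed=4)
        assert all(list(s) == [17] for s in sets)
        others = np.arange(30) != 17
        np.testing.assert_array_equal(out.occupancy[others], raster.occupancy[others])
        assert out.occupancy[17].sum() > raster.occupancy[17].sum()

    def test_resampled_coverage_matches_closed_form(self):
        # expected coverage after k epochs of m-of-N resampling: 1-(1-m/N)^k
        n, m, k, reps = 40, 10, 6, 300
        rng_seed = 0
        fracs = []
        spec = PopulationSpec(n_total=n, silent_fraction=1.0, silent_rate=0.0)
        raster = generate_raster(spec, n_trials=k, trial_duration=200.0, seed=1)
        protocol = StimulationProtocol(
            n_stimulations=k, n_stimulated_cells=m, stim_duration=200.0
        )
        for rep in range(reps):
            _, sets = apply_stimulation(raster, protocol, seed=rng_seed + rep)
            fracs.append(len(set(np.concatenate(sets))) / n)
        p = 1 - (1 - m / n) ** k
        se = np.sqrt(p * (1 - p) / (n * reps))
        assert abs(np.mean(fracs) - p) < 4 * se

    def test_epoch_exceeding_trial_raises(self):
        spec = PopulationSpec(n_total=5, silent_fraction=0.0)
        raster = generate_raster(spec, n_trials=2, trial_duration=100.0, seed=0)
        with pytest.raises(ValueError, match="exceeds trial length"):
            apply_stimulation(
                raster,
                StimulationProtocol(n_stimulations=1, n_stimulated_cells=2, stim_duration=200.0),
                seed=0,
            )


class TestSurrogateRecording:
    def test_full_session_dimensions(self):
        rec = generate_surrogate_recording(seed=0)
        assert rec.occupancy.shape == (64, 1, 900_000)

    def test_gain_one_is_stationary(self):
        rec = generate_surrogate_recording(
            n_channels=32, total_duration=120.0, stim_epoch_duration=30.0,
            stim_gain=1.0, seed=5,
        )
        flat = rec.flat()
        epoch = flat[:, :30_000].mean()
        rest = flat[:, 30_000:].mean()
        se = np.sqrt(epoch / flat[:, :30_000].size + rest / flat[:, 30_000:].size)
        assert abs(epoch - rest) < 3 * se

    def test_epoch_rate_ratio_matches_gain(self):
        gain = 3.0
        rec = generate_surrogate_recording(
            n_channels=64, total_duration=120.0, stim_epoch_duration=30.0,
            stim_gain=gain, seed=6,
        )
        flat = rec.flat().astype(float)
        n_epoch = 30_000
        c_epoch = flat[:, :n_epoch].sum(axis=1)
        c_rest = flat[:, n_epoch:].sum(axis=1)
        t_epoch, t_rest = 30.0, 90.0
        keep = c_rest > 20
        ratio = (c_epoch[keep] / t_epoch) / (c_rest[keep] / t_rest)
        # delta-method SE of a ratio of two Poisson rates
        se = ratio * np.sqrt(1 / c_epoch[keep] + 1 / c_rest[keep])
        assert (np.abs(ratio - gain) < 3.5 * se).mean() > 0.9

    def test_invalid_durations_raise(self):
        with pytest.raises(ValueError):
            generate_surrogate_recording(total_duration=-1.0)
        with pytest.raises(ValueError):
            generate_surrogate_recording(total_duration=10.0, stim_epoch_duration=20.0)


def test_lognormal_moment_matching():
    mu, sigma = lognormal_params_from_moments(3.7, 3.5)
    mean = np.exp(mu + sigma**2 / 2)
    var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
    np.testing.assert_allclose([mean, np.sqrt(var)], [3.7, 3.5], rtol=1e-12)
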