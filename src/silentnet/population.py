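"""Presynaptic population spike-train generation and stimulation.

A population is a mixture of "silent" neurons (baseline around one spike
per minute, 0.017 Hz) and responsive neurons (around 20 Hz). Spiking is
modelled as an independent Bernoulli process per 1-ms bin with success
probability ``rate * dt / 1000``, which reproduces the nominal rate in
expectation. Stimulation epochs drive a randomly chosen subset of cells at
an elevated rate (60 Hz for 200 ms by default) by resampling their bins
inside each epoch window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeding import derive_rng
from .raster import SpikeRaster

__all__ = [
    "PopulationSpec",
    "StimulationProtocol",
    "generate_raster",
    "apply_stimulation",
    "generate_surrogate_recording",
    "lognormal_params_from_moments",
]

# chunk size (elements) for Bernoulli fills; keeps float temporaries small
_CHUNK = 8_000_000


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) of a lognormal with given mean and SD.

    The rate distributions are specified by their mean and SD in Hz; the
    underlying normal parameters follow by moment matching:
    ``sigma^2 = ln(1 + sd^2/mean^2)``, ``mu = ln(mean) - sigma^2/2``.
    """
    if mean <= 0 or sd < 0:
        raise ValueError(f"lognormal moments must be positive, got mean={mean}, sd={sd}")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


@dataclass
class PopulationSpec:
    """Composition of a presynaptic population.

    Parameters
    ----------
    n_total : int
        Number of presynaptic spike trains.
    silent_fraction : float
        Proportion of silent neurons (default 0.66).
    silent_rate, active_rate : float
        Baseline rates in Hz for the silent (0.017) and responsive (20)
        subgroups under the ``uniform_fixed`` rate law.
    rate_law : {"uniform_fixed", "lognormal"}
        ``uniform_fixed`` assigns each subgroup its fixed rate;
        ``lognormal`` draws every neuron's rate from a lognormal law
        moment-matched to (lognormal_mean, lognormal_sd).
    """

    n_total: int
    silent_fraction: float = 0.66
    silent_rate: float = 0.017
    active_rate: float = 20.0
    rate_law: str = "uniform_fixed"
    lognormal_mean: float = 3.7
    lognormal_sd: float = 3.5

    def validate(self) -> None:
        if self.n_total < 1:
            raise ValueError(f"n_total must be >= 1, got {self.n_total}")
        if not 0.0 <= self.silent_fraction <= 1.0:
            raise ValueError(
                f"silent_fraction must lie in [0, 1], got {self.silent_fraction}"
            )
        for name in ("silent_rate", "active_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.rate_law not in ("uniform_fixed", "lognormal"):
            raise ValueError(f"unknown rate_law {self.rate_law!r}")
        if self.rate_law == "lognormal" and (
            self.lognormal_mean <= 0 or self.lognormal_sd <= 0
        ):
            raise ValueError("lognormal_mean and lognormal_sd must be positive")

    @property
    def n_silent(self) -> int:
        return int(round(self.n_total * self.silent_fraction))

    def sample_rates(self, rng: np.random.Generator) -> np.ndarray:
        """Draw per-neuron nominal rates (Hz). Silent cells come first."""
        self.validate()
        if self.rate_law == "uniform_fixed":
            rates = np.full(self.n_total, self.active_rate, dtype=float)
            rates[: self.n_silent] = self.silent_rate
            return rates
        mu, sigma = lognormal_params_from_moments(self.lognormal_mean, self.lognormal_sd)
        return rng.lognormal(mu, sigma, size=self.n_total)


def _fill_bernoulli(out: np.ndarray, p: np.ndarray, rng: np.random.Generator) -> None:
    """Fill a (n_neurons, n_cols) uint8 array with Bernoulli(p[i]) rows, chunked."""
    n_neurons, n_cols = out.shape
    cols_per_chunk = max(1, _CHUNK // max(1, n_neurons))
    p_col = p[:, None]
    for start in range(0, n_cols, cols_per_chunk):
        stop = min(start + cols_per_chunk, n_cols)
        out[:, start:stop] = rng.random((n_neurons, stop - start)) < p_col


def generate_raster(
    spec: PopulationSpec,
    n_trials: int,
    trial_duration: float = 1000.0,
    dt: float = 1.0,
    seed: int = 0,
) -> SpikeRaster:
    """Generate a Bernoulli spike raster for a population.

    Each neuron with nominal rate f spikes independently per bin with
    probability ``min(1, f * dt / 1000)``. The returned raster carries the
    sampled per-neuron rates as metadata (silent cells occupy the leading
    rows under the fixed-rate law).
    """
    spec.validate()
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    n_bins_f = trial_duration / dt
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ValueError(
            f"trial_duration {trial_duration} is not divisible by dt {dt}"
        )
    n_bins = int(round(n_bins_f))
    rng = derive_rng(seed, "rates")
    rates = spec.sample_rates(rng)
    p = np.minimum(1.0, rates * dt / 1000.0)
    occ = np.empty((spec.n_total, n_trials * n_bins), dtype=np.uint8)
    _fill_bernoulli(occ, p, derive_rng(seed, "bins"))
    return SpikeRaster(
        occ.reshape(spec.n_total, n_trials, n_bins), dt=dt, rates=rates
    )


@dataclass
class StimulationProtocol:
    """Description of a repeated-stimulation protocol.

    ``n_stimulations`` epochs of ``stim_duration`` ms each drive
    ``n_stimulated_cells`` cells at ``stim_rate`` Hz. Under
    ``resample_each_epoch`` the driven subset is redrawn for every epoch
    (this is what makes cumulative coverage of the population grow);
    ``fixed_subset`` drives the same cells every time, for controlled
    perturbation experiments. Epochs are placed one per designated trial,
    onset at bin 0, with designated trials spread evenly over the raster.
    """

    n_stimulations: int
    n_stimulated_cells: int = 50
    stim_rate: float = 60.0
    stim_duration: float = 200.0
    selection_rule: str = "resample_each_epoch"
    fixed_cells: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> None:
        if self.n_stimulations < 0:
            raise ValueError("n_stimulations must be >= 0")
        if self.n_stimulated_cells < 0:
            raise ValueError("n_stimulated_cells must be >= 0")
        if self.stim_rate < 0 or self.stim_duration <= 0:
            raise ValueError("stim_rate must be >= 0 and stim_duration > 0")
        if self.selection_rule not in ("resample_each_epoch", "fixed_subset"):
            raise ValueError(f"unknown selection_rule {self.selection_rule!r}")

    def epoch_trials(self, n_trials: int) -> np.ndarray:
        """Trial indices hosting one epoch each, spread evenly."""
        if self.n_stimulations > n_trials:
            raise ValueError(
                f"{self.n_stimulations} epochs do not fit one-per-trial into "
                f"{n_trials} trials"
            )
        if self.n_stimulations == 0:
            return np.empty(0, dtype=int)
        return np.floor(
            np.arange(self.n_stimulations) * n_trials / self.n_stimulations
        ).astype(int)


def apply_stimulation(
    raster: SpikeRaster,
    protocol: StimulationProtocol,
    seed: int = 0,
) -> tuple[SpikeRaster, list[np.ndarray]]:
    """Overlay a stimulation protocol on a baseline raster.

    Inside each epoch window the selected cells' bins are regenerated as
    Bernoulli(stim_rate * dt / 1000), replacing baseline spikes; every bin
    outside the epoch windows is returned unchanged. Also returns the
    per-epoch selected neuron-id arrays for coverage accounting.
    """
    protocol.validate()
    if protocol.n_stimulated_cells > raster.n_neurons:
        raise ValueError(
            f"n_stimulated_cells={protocol.n_stimulated_cells} exceeds population "
            f"size {raster.n_neurons}"
        )
    dur_bins = protocol.stim_duration / raster.dt
    if abs(dur_bins - round(dur_bins)) > 1e-9:
        raise ValueError("stim_duration is not divisible by raster dt")
    dur_bins = int(round(dur_bins))
    if dur_bins > raster.n_bins:
        raise ValueError(
            f"stimulation epoch of {dur_bins} bins exceeds trial length "
            f"{raster.n_bins}"
        )
    out = raster.copy()
    out.rates = None if raster.rates is None else np.array(raster.rates)
    trials = protocol.epoch_trials(raster.n_trials)
    p_stim = min(1.0, protocol.stim_rate * raster.dt / 1000.0)
    sel_rng = derive_rng(seed, "select")
    bin_rng = derive_rng(seed, "stim-bins")
    if protocol.selection_rule == "fixed_subset" and protocol.fixed_cells is not None:
        fixed = np.asarray(protocol.fixed_cells, dtype=int)
        if fixed.size != protocol.n_stimulated_cells:
            raise ValueError("fixed_cells length must equal n_stimulated_cells")
    elif protocol.selection_rule == "fixed_subset":
        fixed = sel_rng.choice(
            raster.n_neurons, size=protocol.n_stimulated_cells, replace=False
        )
    else:
        fixed = None
    stimulated_sets: list[np.ndarray] = []
    for trial in trials:
        if fixed is not None:
            cells = fixed
        else:
            cells = sel_rng.choice(
                raster.n_neurons, size=protocol.n_stimulated_cells, replace=False
            )
        out.occupancy[cells, trial, :dur_bins] = (
            bin_rng.random((cells.size, dur_bins)) < p_stim
        ).astype(np.uint8)
        stimulated_sets.append(np.sort(cells))
    return out, stimulated_sets


def generate_surrogate_recording(
    n_channels: int = 64,
    total_duration: float = 900.0,
    stim_epoch_duration: float = 60.0,
    baseline_rates: np.ndarray | None = None,
    stim_gain: float = 3.0,
    dt: float = 1.0,
    seed: int = 0,
) -> SpikeRaster:
    """Synthesize a surrogate multichannel recording.

    Emulates the statistics of a multielectrode-array session: ``n_channels``
    units recorded for ``total_duration`` seconds as a single trial, with
    lognormal baseline rates and an initial global-stimulation epoch of
    ``stim_epoch_duration`` seconds during which every channel's rate is
    multiplied by ``stim_gain``. This is a synthetic stand-in for real
    recordings; real data enter through the same event-list raster format.
    """
    if total_duration <= 0 or stim_epoch_duration <= 0:
        raise ValueError("durations must be positive")
    if stim_epoch_duration > total_duration:
        raise ValueError("stim_epoch_duration exceeds total_duration")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = derive_rng(seed, "surrogate-rates")
    if baseline_rates is None:
        mu, sigma = lognormal_params_from_moments(3.7, 3.5)
        baseline_rates = rng.lognormal(mu, sigma, size=n_channels)
    baseline_rates = np.asarray(baseline_rates, dtype=float)
    if baseline_rates.size != n_channels:
        raise ValueError("baseline_rates length must equal n_channels")
    n_bins = int(round(total_duration * 1000.0 / dt))
    stim_bins = int(round(stim_epoch_duration * 1000.0 / dt))
    occ = np.empty((n_channels, n_bins), dtype=np.uint8)
    bin_rng = derive_rng(seed, "surrogate-bins")
    p_base = np.minimum(1.0, baseline_rates * dt / 1000.0)
    p_stim = np.minimum(1.0, stim_gain * baseline_rates * dt / 1000.0)
    _fill_bernoulli(occ[:, :stim_bins], p_stim, bin_rng)
    _fill_bernoulli(occ[:, stim_bins:], p_base, bin_rng)
    return SpikeRaster(occ[:, None, :], dt=dt, rates=baseline_rates)
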