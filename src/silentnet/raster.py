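"""Spike raster container and I/O.

A :class:`SpikeRaster` holds binary spike occupancy for a population over
trials of discretized time (1-ms bins by default). Two on-disk forms are
supported: a delimited event list (neuron_id, trial, time_ms) for
interoperability with sorted-spike exports, and an HDF5 container holding
the dense occupancy array plus metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["SpikeRaster", "read_events", "write_events"]


@dataclass
class SpikeRaster:
    """Binary spike occupancy over (neuron, trial, time bin).

    Parameters
    ----------
    occupancy : ndarray of uint8, shape (n_neurons, n_trials, n_bins)
        1 where a spike occupies a bin, 0 elsewhere.
    dt : float
        Bin width in milliseconds.
    rates : ndarray, optional
        Nominal per-neuron firing rates in Hz used to generate the raster,
        when known. Carried as metadata; not required for any computation.
    """

    occupancy: np.ndarray
    dt: float = 1.0
    rates: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError(
                f"occupancy must be 3-D (n_neurons, n_trials, n_bins), got {occ.ndim}-D"
            )
        if occ.dtype != np.uint8:
            vals = np.unique(occ)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("occupancy values must be binary (0/1)")
            occ = occ.astype(np.uint8)
        self.occupancy = occ
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    # -- shape helpers -------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_trials(self) -> int:
        return self.occupancy.shape[1]

    @property
    def n_bins(self) -> int:
        """Bins per trial."""
        return self.occupancy.shape[2]

    @property
    def trial_duration(self) -> float:
        """Trial duration in ms."""
        return self.n_bins * self.dt

    @property
    def total_bins(self) -> int:
        return self.n_trials * self.n_bins

    def flat(self) -> np.ndarray:
        """View as (n_neurons, n_trials * n_bins), trials concatenated in order."""
        return self.occupancy.reshape(self.n_neurons, -1)

    # -- statistics ----------------------------------------------------
    def spike_counts(self) -> np.ndarray:
        """Total spikes per neuron."""
        return self.flat().sum(axis=1, dtype=np.int64)

    def empirical_rates(self) -> np.ndarray:
        """Per-neuron firing rate in Hz over the whole raster."""
        total_s = self.total_bins * self.dt / 1000.0
        return self.spike_counts() / total_s

    def copy(self) -> "SpikeRaster":
        return SpikeRaster(
            self.occupancy.copy(),
            dt=self.dt,
            rates=None if self.rates is None else np.array(self.rates),
        )

    # -- event-list round trip ------------------------------------------
    def to_events(self) -> pd.DataFrame:
        """Convert to an event list with columns (neuron_id, trial, time_ms)."""
        neuron, trial, t = np.nonzero(self.occupancy)
        return pd.DataFrame({"neuron_id": neuron, "trial": trial, "time_ms": t})

    @classmethod
    def from_events(
        cls,
        events: pd.DataFrame,
        n_neurons: int,
        n_trials: int,
        n_bins: int,
        dt: float = 1.0,
    ) -> "SpikeRaster":
        occ = np.zeros((n_neurons, n_trials, n_bins), dtype=np.uint8)
        occ[
            events["neuron_id"].to_numpy(dtype=np.int64),
            events["trial"].to_numpy(dtype=np.int64),
            events["time_ms"].to_numpy(dtype=np.int64),
        ] = 1
        return cls(occ, dt=dt)

    # -- HDF5 container --------------------------------------------------
    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("occupancy", data=self.occupancy, compression="gzip")
            f.attrs["dt"] = self.dt
            f.attrs["trial_duration"] = self.trial_duration
            if self.rates is not None:
                f.create_dataset("rates", data=np.asarray(self.rates, dtype=float))

    @classmethod
    def from_hdf5(cls, path: str) -> "SpikeRaster":
        with h5py.File(path, "r") as f:
            occ = f["occupancy"][...]
            dt = float(f.attrs["dt"])
            rates = f["rates"][...] if "rates" in f else None
        return cls(occ, dt=dt, rates=rates)


def write_events(raster: SpikeRaster, path: str) -> None:
    """Write a raster as a delimited event list with a header row."""
    raster.to_events().to_csv(path, index=False)


def read_events(
    path: str, n_neurons: int, n_trials: int, n_bins: int, dt: float = 1.0
) -> SpikeRaster:
    """Read an event-list file back into a dense raster."""
    events = pd.read_csv(path)
    return SpikeRaster.from_events(events, n_neurons, n_trials, n_bins, dt=dt)
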