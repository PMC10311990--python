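"""Forward models of the postsynaptic neuron.

Two models map a presynaptic raster and a weight vector to postsynaptic
spikes:

* the memoryless integrate-and-fire threshold unit — per 1-ms bin, the
  membrane potential is the weighted sum of the spiking inputs,
  ``V = sum_i x_i w_i`` (mV), and a spike is emitted iff V strictly
  exceeds the 20-mV threshold; no state carries between bins;
* the leaky integrate-and-fire (LIF) unit — forward-Euler membrane update
  ``V(t+dt) = V(t) + dt * (-(V - V_e) + I_m R_m) / tau_m`` with a
  threshold-and-reset mechanism, where the membrane current is the sum of
  presynaptic currents ``I_m = I_post * sum_i w_i x_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import lif_trace_kernel
from .raster import SpikeRaster

__all__ = [
    "ThresholdUnitParams",
    "LIFParams",
    "threshold_unit_forward",
    "lif_step",
    "lif_forward",
]


@dataclass(frozen=True)
class ThresholdUnitParams:
    """Memoryless threshold unit: spike iff summed input exceeds threshold."""

    threshold: float = 20.0  # mV
    resting: float = 0.0  # mV

    def __post_init__(self) -> None:
        if self.threshold <= self.resting:
            raise ValueError(
                f"threshold ({self.threshold}) must exceed resting ({self.resting})"
            )


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters.

    Membrane time constant tau_m = C_m * R_m = 1 ms with the default 100 pF
    and 10 MOhm. Threshold and reset voltages are not pinned down by the
    membrane parameters; the defaults (-55 mV threshold, reset to rest at
    -75 mV) are standard LIF values and both are configurable.
    """

    V_e: float = -75.0  # resting potential, mV
    C_m: float = 100.0  # membrane capacitance, pF
    R_m: float = 10.0  # input resistance, MOhm
    I_post: float = 1.0  # unitary postsynaptic current, nA
    V_t: float = -55.0  # spike threshold, mV
    V_reset: float = -75.0  # post-spike reset, mV
    dt: float = 1.0  # integration step, ms

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.V_reset > self.V_t:
            raise ValueError("V_reset must not exceed V_t")

    @property
    def tau_m(self) -> float:
        """Membrane time constant in ms (pF * MOhm = microseconds * 1e3)."""
        return self.C_m * self.R_m * 1e-3


def _as_flat(raster: SpikeRaster | np.ndarray) -> tuple[np.ndarray, int]:
    """Return (n_neurons, total_bins) uint8 view and bins-per-trial."""
    if isinstance(raster, SpikeRaster):
        return raster.flat(), raster.n_bins
    arr = np.asarray(raster, dtype=np.uint8)
    if arr.ndim == 2:
        return arr, arr.shape[1]
    if arr.ndim == 3:
        return arr.reshape(arr.shape[0], -1), arr.shape[2]
    raise ValueError("raster must be 2-D or 3-D")


def weighted_input(raster: SpikeRaster | np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-bin weighted sum of spiking inputs, ``sum_i x_i[t] w_i``.

    Rasters are sparse (a handful of spikes per 1-ms bin even at 20 Hz),
    so the sum is accumulated over spike events rather than by dense
    matrix product.
    """
    x, _ = _as_flat(raster)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.ndim != 1 or weights.shape[0] != x.shape[0]:
        raise ValueError(
            f"weights length {weights.shape} does not match raster with "
            f"{x.shape[0]} neurons"
        )
    total = x.shape[1]
    neuron_idx, bin_idx = np.nonzero(x)
    return np.bincount(bin_idx, weights=weights[neuron_idx], minlength=total)


def threshold_unit_forward(
    raster: SpikeRaster | np.ndarray,
    weights: np.ndarray,
    params: ThresholdUnitParams | None = None,
) -> np.ndarray:
    """Postsynaptic spikes of the memoryless threshold unit.

    Returns a flat uint8 array over all bins (trials concatenated). A spike
    requires the summed input to exceed the threshold strictly; a bin
    summing exactly to the threshold stays silent.
    """
    params = params or ThresholdUnitParams()
    v = weighted_input(raster, weights)
    return (v > params.threshold).astype(np.uint8)


def lif_step(
    V_m: float, I_m: float, params: LIFParams | None = None
) -> tuple[float, int]:
    """One forward-Euler LIF update; returns (next membrane potential, spiked).

    ``I_m`` is the membrane current in nA; ``I_m * R_m`` enters the update
    in mV. If the updated potential strictly exceeds the threshold, the
    neuron spikes and the potential is reset within the same step.
    """
    params = params or LIFParams()
    if not (np.isfinite(V_m) and np.isfinite(I_m)):
        raise ValueError("V_m and I_m must be finite")
    v = V_m + params.dt * (-(V_m - params.V_e) + I_m * params.R_m) / params.tau_m
    if v > params.V_t:
        return params.V_reset, 1
    return v, 0


def lif_forward(
    raster: SpikeRaster | np.ndarray,
    weights: np.ndarray,
    params: LIFParams | None = None,
) -> np.ndarray:
    """Postsynaptic spikes of the LIF unit driven by a weighted raster.

    The membrane current per bin is ``I_post * sum_i w_i x_i[t]``; the
    membrane potential carries across bins within a trial, resets to rest
    at trial boundaries, and resets to ``V_reset`` after each spike.
    Returns a flat uint8 spike array over all bins.
    """
    params = params or LIFParams()
    _, bins_per_trial = _as_flat(raster)
    drive = weighted_input(raster, weights) * params.I_post * params.R_m
    return lif_trace_kernel(
        drive,
        bins_per_trial,
        params.V_e,
        params.V_t,
        params.V_reset,
        params.dt,
        params.tau_m,
    )
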