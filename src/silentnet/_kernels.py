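"""Numba kernels for the sequential inner loops.

The per-bin perceptron update and the leaky integrate-and-fire membrane
recursion are inherently sequential (each bin's prediction depends on the
weights/state left by the previous bin), so they are compiled with numba
rather than vectorized. Spike input is consumed in a per-bin CSR layout:
``indptr[t]:indptr[t+1]`` indexes the neurons spiking in bin ``t``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "lif_trace_kernel",
    "train_threshold_kernel",
    "train_lif_kernel",
]


@njit(cache=True)
def lif_trace_kernel(drive, bins_per_trial, v_e, v_t, v_reset, dt, tau):
    """Advance the LIF membrane over all bins given the synaptic drive.

    ``drive[t]`` is the membrane current times input resistance (mV) in bin
    t. The membrane resets to ``v_reset`` after a spike and to ``v_e`` at
    trial boundaries.
    """
    n = drive.shape[0]
    spikes = np.zeros(n, dtype=np.uint8)
    v = v_e
    for t in range(n):
        if t % bins_per_trial == 0:
            v = v_e
        v = v + dt * (-(v - v_e) + drive[t]) / tau
        if v > v_t:
            spikes[t] = 1
            v = v_reset
    return spikes


@njit(cache=True)
def train_threshold_kernel(
    indptr, indices, y, weights, lr, n_iterations, threshold
):
    """Online perceptron passes with the memoryless threshold-unit forward.

    Per bin: predict y' = [sum of weights of spiking inputs > threshold],
    then apply w_i += lr * (y - y') for every spiking input i. Returns the
    per-iteration error counts and a snapshot of the weights after each
    iteration (for error/RMSE traces).
    """
    n_bins = y.shape[0]
    n_w = weights.shape[0]
    errors = np.zeros(n_iterations, dtype=np.int64)
    snapshots = np.empty((n_iterations, n_w), dtype=np.float64)
    for it in range(n_iterations):
        n_err = 0
        for t in range(n_bins):
            lo = indptr[t]
            hi = indptr[t + 1]
            v = 0.0
            for k in range(lo, hi):
                v += weights[indices[k]]
            y_pred = 1 if v > threshold else 0
            err = y[t] - y_pred
            if err != 0:
                n_err += 1
                delta = lr * err
                for k in range(lo, hi):
                    weights[indices[k]] += delta
        errors[it] = n_err
        snapshots[it] = weights
    return errors, snapshots


@njit(cache=True)
def train_lif_kernel(
    indptr,
    indices,
    y,
    weights,
    lr,
    n_iterations,
    bins_per_trial,
    v_e,
    v_t,
    v_reset,
    dt,
    tau,
    i_post_r_m,
):
    """Online perceptron passes with the LIF forward model.

    The predicted membrane potential carries across bins within a trial and
    resets to ``v_e`` at trial boundaries; a predicted spike resets it to
    ``v_reset``. Weight updates follow the same per-bin rule as the
    threshold-unit variant.
    """
    n_bins = y.shape[0]
    n_w = weights.shape[0]
    errors = np.zeros(n_iterations, dtype=np.int64)
    snapshots = np.empty((n_iterations, n_w), dtype=np.float64)
    for it in range(n_iterations):
        n_err = 0
        v = v_e
        for t in range(n_bins):
            if t % bins_per_trial == 0:
                v = v_e
            lo = indptr[t]
            hi = indptr[t + 1]
            drive = 0.0
            for k in range(lo, hi):
                drive += weights[indices[k]]
            v = v + dt * (-(v - v_e) + i_post_r_m * drive) / tau
            if v > v_t:
                y_pred = 1
                v = v_reset
            else:
                y_pred = 0
            err = y[t] - y_pred
            if err != 0:
                n_err += 1
                delta = lr * err
                for k in range(lo, hi):
                    weights[indices[k]] += delta
        errors[it] = n_err
        snapshots[it] = weights
    return errors, snapshots
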