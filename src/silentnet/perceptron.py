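"""Perceptron derivation of synaptic weights from spike trains.

Given a presynaptic raster and the postsynaptic spike train, connection
weights are derived online with the perceptron learning rule

    dw_i = lr * (y - y') * x_i

where y is the recorded postsynaptic spike in a bin, y' the spike predicted
by the forward model under the current derived weights, and x_i the binary
input of presynaptic cell i in that bin. Bins are visited chronologically
within each trial, trials in order, and the whole data set is swept
``n_iterations`` times.

The learner is exposed as a scikit-learn style estimator
(:class:`PerceptronConnectivity`) so it composes with sklearn tooling;
:func:`train` and :func:`optimize_learning_rate` are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._kernels import train_lif_kernel, train_threshold_kernel
from ._seeding import derive_rng
from .connectivity import WeightVector
from .evaluation import spike_prediction_scores, weight_rmse
from .neurons import LIFParams, ThresholdUnitParams, lif_forward, threshold_unit_forward
from .raster import SpikeRaster

__all__ = [
    "TrainingConfig",
    "PerceptronConnectivity",
    "perceptron_update",
    "train",
    "optimize_learning_rate",
]


def perceptron_update(
    weights: np.ndarray,
    x: np.ndarray,
    y: int,
    y_pred: int,
    lr: float,
) -> np.ndarray:
    """Single application of the perceptron rule; returns updated weights.

    ``w_i <- w_i + lr * (y - y_pred) * x_i`` exactly; entries with x_i = 0
    are untouched.
    """
    weights = np.asarray(weights, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if x.shape != weights.shape:
        raise ValueError(f"x shape {x.shape} does not match weights {weights.shape}")
    if y not in (0, 1) or y_pred not in (0, 1):
        raise ValueError("y and y_pred must be binary")
    return weights + lr * (y - y_pred) * x


@dataclass
class TrainingConfig:
    """Hyperparameters of one weight-derivation run."""

    learning_rate: float = 0.01
    n_iterations: int = 100
    init_weights: str = "zeros"  # or "uniform_small"
    init_scale: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.init_weights not in ("zeros", "uniform_small"):
            raise ValueError(f"unknown init_weights {self.init_weights!r}")


def _to_bin_csr(X) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-bin CSR of spiking-neuron ids.

    Accepts a SpikeRaster (neurons x trials x bins) or an ndarray of shape
    (n_bins, n_neurons) in sklearn sample-major orientation. Returns
    (indptr, indices, n_neurons, bins_per_trial).
    """
    if isinstance(X, SpikeRaster):
        flat = X.flat()  # (neurons, total_bins)
        n_neurons = X.n_neurons
        bins_per_trial = X.n_bins
        neuron_idx, bin_idx = np.nonzero(flat)
        total_bins = flat.shape[1]
    else:
        arr = np.asarray(X)
        if arr.ndim != 2:
            raise ValueError("X must be a SpikeRaster or a 2-D (bins, neurons) array")
        bin_idx, neuron_idx = np.nonzero(arr)
        total_bins = arr.shape[0]
        n_neurons = arr.shape[1]
        bins_per_trial = total_bins
    order = np.argsort(bin_idx, kind="stable")
    indices = neuron_idx[order].astype(np.int64)
    counts = np.bincount(bin_idx, minlength=total_bins)
    indptr = np.zeros(total_bins + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, indices, n_neurons, bins_per_trial


class PerceptronConnectivity(BaseEstimator):
    """Derive synaptic weights with the online perceptron rule.

    Parameters
    ----------
    learning_rate : float, default 0.01
        Step size of the perceptron update, in mV per (spike x error).
    n_iterations : int, default 100
        Full sweeps over the training bins.
    model : {"threshold", "lif"}
        Forward model generating the per-bin prediction: the memoryless
        20-mV threshold unit, or the leaky integrate-and-fire unit whose
        membrane state carries across bins within a trial.
    threshold_params, lif_params : parameter dataclasses, optional
        Forward-model parameters; defaults match the standard models.
    init_weights : {"zeros", "uniform_small"}
        Weight initialization. Zeros make the silent-input invariance exact
        (inputs that never spike keep their initial weight bit-for-bit).
    bins_per_trial : int, optional
        Trial length in bins when X is a plain array (the LIF membrane
        resets at trial boundaries). Taken from the raster when X is a
        SpikeRaster; defaults to the full length otherwise.
    random_state : int, optional
        Seed for the uniform_small initialization.

    Attributes
    ----------
    weights_ : ndarray, shape (n_neurons,)
        Derived weights after the final iteration.
    weights_path_ : ndarray, shape (n_iterations, n_neurons)
        Weight snapshot after each full sweep.
    errors_ : ndarray, shape (n_iterations,)
        Number of misclassified bins in each sweep.
    """

    def __init__(
        self,
        learning_rate: float = 0.01,
        n_iterations: int = 100,
        model: str = "threshold",
        threshold_params: ThresholdUnitParams | None = None,
        lif_params: LIFParams | None = None,
        init_weights: str = "zeros",
        init_scale: float = 0.01,
        bins_per_trial: int | None = None,
        random_state: int | None = None,
    ):
        self.learning_rate = learning_rate
        self.n_iterations = n_iterations
        self.model = model
        self.threshold_params = threshold_params
        self.lif_params = lif_params
        self.init_weights = init_weights
        self.init_scale = init_scale
        self.bins_per_trial = bins_per_trial
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _init_w(self, n_neurons: int) -> np.ndarray:
        if self.init_weights == "zeros":
            return np.zeros(n_neurons, dtype=np.float64)
        if self.init_weights == "uniform_small":
            rng = derive_rng(0 if self.random_state is None else self.random_state, "init")
            return rng.uniform(-self.init_scale, self.init_scale, size=n_neurons)
        raise ValueError(f"unknown init_weights {self.init_weights!r}")

    def fit(self, X, y) -> "PerceptronConnectivity":
        """Derive weights from (presynaptic raster X, postsynaptic train y)."""
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.model not in ("threshold", "lif"):
            raise ValueError(f"unknown model {self.model!r}")
        indptr, indices, n_neurons, bins_per_trial = _to_bin_csr(X)
        if self.bins_per_trial is not None:
            bins_per_trial = int(self.bins_per_trial)
        y = np.asarray(y).ravel().astype(np.int64)
        if y.shape[0] != indptr.shape[0] - 1:
            raise ValueError(
                f"y has {y.shape[0]} bins but X has {indptr.shape[0] - 1}"
            )
        w = self._init_w(n_neurons)
        self._init_weights_ = w.copy()
        if self.model == "threshold":
            params = self.threshold_params or ThresholdUnitParams()
            errors, snapshots = train_threshold_kernel(
                indptr,
                indices,
                y,
                w,
                float(self.learning_rate),
                int(self.n_iterations),
                float(params.threshold),
            )
        else:
            params = self.lif_params or LIFParams()
            errors, snapshots = train_lif_kernel(
                indptr,
                indices,
                y,
                w,
                float(self.learning_rate),
                int(self.n_iterations),
                int(bins_per_trial),
                params.V_e,
                params.V_t,
                params.V_reset,
                params.dt,
                params.tau_m,
                params.I_post * params.R_m,
            )
        self.n_features_in_ = n_neurons
        self.weights_ = w
        self.coef_ = w
        self.weights_path_ = snapshots
        self.errors_ = errors
        self._bins_per_trial_ = bins_per_trial
        return self

    def predict(self, X) -> np.ndarray:
        """Predict the postsynaptic spike train under the derived weights."""
        if not hasattr(self, "weights_"):
            raise AttributeError("estimator is not fitted; call fit first")
        if isinstance(X, SpikeRaster):
            raster = X
        else:
            arr = np.asarray(X, dtype=np.uint8)
            raster = arr.T  # to (neurons, bins)
        if self.model == "threshold":
            return threshold_unit_forward(
                raster, self.weights_, self.threshold_params or ThresholdUnitParams()
            )
        return lif_forward(raster, self.weights_, self.lif_params or LIFParams())

    def score(self, X, y) -> float:
        """Spike-prediction performance, the mean of TPR and PPV."""
        scores = spike_prediction_scores(np.asarray(y).ravel(), self.predict(X))
        return scores.performance

    def error_trace(self, total_bins: int | None = None) -> pd.DataFrame:
        """Per-iteration training trace (error counts and rates)."""
        n_bins = total_bins
        df = pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.errors_) + 1),
                "n_errors": self.errors_,
            }
        )
        if n_bins:
            df["error_rate"] = df["n_errors"] / n_bins
        return df

    def rmse_trace(self, true_weights: np.ndarray) -> np.ndarray:
        """Weight RMSE against a reference after each iteration."""
        tw = np.asarray(true_weights, dtype=float)
        return np.sqrt(((self.weights_path_ - tw[None, :]) ** 2).mean(axis=1))


def train(
    raster: SpikeRaster,
    post_spikes: np.ndarray,
    config: TrainingConfig | None = None,
    model: str = "threshold",
    true_weights: np.ndarray | None = None,
    lif_params: LIFParams | None = None,
    threshold_params: ThresholdUnitParams | None = None,
) -> tuple[WeightVector, pd.DataFrame]:
    """Derive a weight vector and return it with a per-iteration trace.

    The trace holds the training error rate per sweep and, when the
    ground-truth weights are supplied, the weight RMSE after each sweep.
    """
    config = config or TrainingConfig()
    config.validate()
    est = PerceptronConnectivity(
        learning_rate=config.learning_rate,
        n_iterations=config.n_iterations,
        model=model,
        init_weights=config.init_weights,
        init_scale=config.init_scale,
        random_state=config.seed,
        lif_params=lif_params,
        threshold_params=threshold_params,
    ).fit(raster, post_spikes)
    total_bins = raster.total_bins if isinstance(raster, SpikeRaster) else len(post_spikes)
    trace = est.error_trace(total_bins)
    if true_weights is not None:
        trace["rmse"] = est.rmse_trace(
            true_weights.weights if isinstance(true_weights, WeightVector) else true_weights
        )
    return WeightVector(est.weights_), trace


def optimize_learning_rate(
    raster: SpikeRaster,
    post_spikes: np.ndarray,
    candidate_rates: np.ndarray,
    n_iterations: int = 100,
    seed: int = 0,
    true_weights: np.ndarray | None = None,
    model: str = "threshold",
) -> tuple[float, pd.DataFrame]:
    """Scan learning rates and return the best one with the full curve.

    Each candidate trains once for ``n_iterations`` sweeps; the figure of
    merit is the final weight RMSE against the ground truth when available,
    else the final training error rate. Ties go to the smaller rate.
    """
    candidates = np.asarray(candidate_rates, dtype=float)
    if candidates.size == 0:
        raise ValueError("candidate_rates must not be empty")
    if np.any(candidates <= 0):
        raise ValueError("learning rates must be positive")
    scores = np.empty(candidates.size)
    for i, lr in enumerate(candidates):
        config = TrainingConfig(
            learning_rate=float(lr), n_iterations=n_iterations, seed=seed
        )
        derived, trace = train(
            raster, post_spikes, config, model=model, true_weights=true_weights
        )
        if true_weights is not None:
            ref = (
                true_weights.weights
                if isinstance(true_weights, WeightVector)
                else np.asarray(true_weights)
            )
            scores[i] = weight_rmse(derived.weights, ref)
        else:
            scores[i] = trace["error_rate"].iloc[-1]
    curve = pd.DataFrame({"learning_rate": candidates, "rmse": scores})
    best_mask = scores == scores.min()
    best = candidates[best_mask].min()
    return float(best), curve
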