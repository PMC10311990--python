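"""End-to-end experiment pipelines.

Wires the population simulator, ground-truth connectivity, forward models,
perceptron learner and scorers into the study's standard conditions:

* ``hyperactive`` — 200-cell population, every cell at 20 Hz (reference
  case with no silent neurons);
* ``silent_unstimulated`` — 66% of cells silent at 0.017 Hz, no
  stimulation (the realistic failure mode);
* ``silent_stimulated`` — same population rescued by repeated stimulation
  epochs (50 random cells at 60 Hz for 200 ms each);
* recurrent LIF circuits driven by multichannel recordings.

Each experiment runs ``n_replicates`` independent populations and reports
per-replicate scores plus mean and standard error. All randomness derives
from one master seed through per-(replicate, stage) sub-seeds, so any
replicate can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeding import derive_seed
from .connectivity import (
    WeightVector,
    build_feedforward_weights,
    build_recurrent_circuit,
)
from .evaluation import (
    ClassificationScheme,
    EvaluationReport,
    cluster_subpopulations,
    evaluate_run,
)
from .neurons import LIFParams, ThresholdUnitParams, lif_forward, threshold_unit_forward
from .perceptron import PerceptronConnectivity, TrainingConfig
from .population import (
    PopulationSpec,
    StimulationProtocol,
    apply_stimulation,
    generate_raster,
    generate_surrogate_recording,
)
from .raster import SpikeRaster

__all__ = [
    "ExperimentConfig",
    "FeedforwardResult",
    "config_for_condition",
    "run_feedforward_experiment",
    "run_stimulus_sweep",
    "run_circuit_experiment",
    "run_single_silent_perturbation",
]

CONDITIONS = (
    "hyperactive",
    "silent_unstimulated",
    "silent_stimulated",
)

_SCALAR_METRICS = ("rmse_weights", "pearson_r", "tpr", "ppv", "performance")


@dataclass
class ExperimentConfig:
    """Specification of one feedforward experiment family."""

    condition: str
    population: PopulationSpec
    protocol: StimulationProtocol | None = None
    test_protocol: StimulationProtocol | None = None
    training: TrainingConfig = field(default_factory=TrainingConfig)
    scheme: ClassificationScheme = field(default_factory=ClassificationScheme)
    threshold_params: ThresholdUnitParams = field(default_factory=ThresholdUnitParams)
    n_replicates: int = 10
    n_trials: int = 2500
    n_test_trials: int = 2500
    trial_duration: float = 1000.0
    dt: float = 1.0
    n_connected: int = 100
    n_excitatory: int = 80
    weight_range: tuple[float, float] = (-8.0, 8.0)
    evaluate_spikes: bool = True
    master_seed: int = 0

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.population.validate()
        self.training.validate()
        if self.protocol is not None:
            self.protocol.validate()
        if self.test_protocol is not None:
            self.test_protocol.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        """Build a config from a plain mapping (e.g. parsed YAML).

        Sub-sections ``population``, ``protocol``, ``test_protocol``,
        ``training`` and ``scheme`` are mappings with the fields of the
        corresponding dataclasses.
        """
        d = dict(d)
        if "population" in d and isinstance(d["population"], dict):
            d["population"] = PopulationSpec(**d["population"])
        for key in ("protocol", "test_protocol"):
            if isinstance(d.get(key), dict):
                d[key] = StimulationProtocol(**d[key])
        if isinstance(d.get("training"), dict):
            d["training"] = TrainingConfig(**d["training"])
        if isinstance(d.get("scheme"), dict):
            d["scheme"] = ClassificationScheme(**d["scheme"])
        if isinstance(d.get("weight_range"), list):
            d["weight_range"] = tuple(d["weight_range"])
        return cls(**d)


def config_for_condition(
    condition: str,
    n_stimulations: int = 15,
    n_replicates: int = 10,
    n_trials: int = 2500,
    n_test_trials: int = 2500,
    n_iterations: int = 100,
    master_seed: int = 0,
) -> ExperimentConfig:
    """Standard configuration for one of the named study conditions.

    Spike prediction is always evaluated on stimulated-condition test data
    for the silent conditions (weights derived without stimulation are
    tested against the spikes that stimulation reveals); the hyperactive
    reference needs no stimulation anywhere.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    silent_fraction = 0.0 if condition == "hyperactive" else 0.66
    population = PopulationSpec(n_total=200, silent_fraction=silent_fraction)
    stim = StimulationProtocol(n_stimulations=n_stimulations)
    protocol = stim if condition == "silent_stimulated" else None
    test_protocol = None if condition == "hyperactive" else stim
    return ExperimentConfig(
        condition=condition,
        population=population,
        protocol=protocol,
        test_protocol=test_protocol,
        training=TrainingConfig(n_iterations=n_iterations),
        n_replicates=n_replicates,
        n_trials=n_trials,
        n_test_trials=n_test_trials,
        master_seed=master_seed,
    )


@dataclass
class FeedforwardResult:
    """Per-replicate reports plus aggregates of one experiment family."""

    condition: str
    reports: list[EvaluationReport]
    derived: list[WeightVector] = field(repr=False, default_factory=list)
    actual: list[WeightVector] = field(repr=False, default_factory=list)

    def per_replicate(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.reports])

    def aggregate(self) -> pd.DataFrame:
        """Mean and standard error (sample SD / sqrt(n)) over replicates."""
        df = self.per_replicate()
        n = len(df)
        mean = df.mean()
        se = df.std(ddof=1) / np.sqrt(n) if n > 1 else df.std(ddof=0) * np.nan
        return pd.DataFrame({"mean": mean, "se": se})


def _run_one_replicate(
    config: ExperimentConfig, replicate: int
) -> tuple[EvaluationReport, WeightVector, WeightVector]:
    seed = config.master_seed
    actual = build_feedforward_weights(
        n_population=config.population.n_total,
        n_connected=config.n_connected,
        n_excitatory=config.n_excitatory,
        weight_range=config.weight_range,
        seed=derive_seed(seed, "weights", replicate),
    )
    raster = generate_raster(
        config.population,
        config.n_trials,
        config.trial_duration,
        dt=config.dt,
        seed=derive_seed(seed, "train-raster", replicate),
    )
    if config.protocol is not None and config.protocol.n_stimulations >= 0:
        raster, _ = apply_stimulation(
            raster, config.protocol, seed=derive_seed(seed, "train-stim", replicate)
        )
    post = threshold_unit_forward(raster, actual.weights, config.threshold_params)
    training = replace(config.training, seed=derive_seed(seed, "train", replicate))
    est = PerceptronConnectivity(
        learning_rate=training.learning_rate,
        n_iterations=training.n_iterations,
        model="threshold",
        threshold_params=config.threshold_params,
        init_weights=training.init_weights,
        init_scale=training.init_scale,
        random_state=training.seed,
    ).fit(raster, post)
    derived = WeightVector(est.weights_)
    del raster, post

    if not config.evaluate_spikes:
        report = evaluate_run(derived, actual, scheme=config.scheme)
        return report, derived, actual

    test_raster = generate_raster(
        config.population,
        config.n_test_trials,
        config.trial_duration,
        dt=config.dt,
        seed=derive_seed(seed, "test-raster", replicate),
    )
    if config.test_protocol is not None:
        test_raster, _ = apply_stimulation(
            test_raster, config.test_protocol, seed=derive_seed(seed, "test-stim", replicate)
        )
    actual_spikes = threshold_unit_forward(
        test_raster, actual.weights, config.threshold_params
    )
    predicted_spikes = threshold_unit_forward(
        test_raster, derived.weights, config.threshold_params
    )
    report = evaluate_run(
        derived, actual, actual_spikes, predicted_spikes, config.scheme
    )
    return report, derived, actual


def run_feedforward_experiment(config: ExperimentConfig) -> FeedforwardResult:
    """Run all replicates of one feedforward condition.

    Per replicate: build ground-truth weights, generate the training
    raster, overlay the stimulation protocol if any, simulate the actual
    postsynaptic spikes with the threshold unit, derive weights with the
    perceptron rule, then score weight recovery and spike prediction on a
    fresh held-out test set.
    """
    config.validate()
    result = FeedforwardResult(condition=config.condition, reports=[])
    for replicate in range(config.n_replicates):
        report, derived, actual = _run_one_replicate(config, replicate)
        result.reports.append(report)
        result.derived.append(derived)
        result.actual.append(actual)
    return result


def run_stimulus_sweep(
    config: ExperimentConfig,
    stimulus_counts=range(0, 16),
) -> pd.DataFrame:
    """Sweep the number of stimulation epochs with paired replicate seeds.

    Every stimulus count reuses the same per-replicate sub-seeds, so the
    count-0 column reproduces the unstimulated baseline exactly and
    differences across counts are paired. Returns one row per count with
    the aggregate (mean, se) of each metric.
    """
    config.validate()
    rows = []
    for k in stimulus_counts:
        protocol = (
            None
            if k == 0
            else replace(
                config.protocol or StimulationProtocol(n_stimulations=int(k)),
                n_stimulations=int(k),
            )
        )
        cfg_k = replace(config, condition=config.condition, protocol=protocol)
        res = run_feedforward_experiment(cfg_k)
        agg = res.aggregate()
        row: dict = {"n_stimulations": int(k)}
        for metric in agg.index:
            row[f"{metric}_mean"] = agg.loc[metric, "mean"]
            row[f"{metric}_se"] = agg.loc[metric, "se"]
        rows.append(row)
    return pd.DataFrame(rows)


def run_single_silent_perturbation(
    config: ExperimentConfig,
    min_strong_weight: float = 4.0,
) -> pd.DataFrame:
    """Can the derived weights predict the effect of waking one silent cell?

    Per replicate: derive weights twice — from the unstimulated population
    and from the stimulated one — then build a test set in which a single
    strong excitatory *silent* cell (true weight above ``min_strong_weight``)
    is driven at the stimulation rate. The postsynaptic spikes that this
    perturbation adds (bins spiking under the perturbed input but not under
    baseline) are the events of interest; the fraction of them each model
    predicts is its detection rate. Returns one row per replicate with the
    detection rates of both models.
    """
    config.validate()
    protocol = config.protocol or StimulationProtocol(n_stimulations=15)
    rows = []
    for replicate in range(config.n_replicates):
        seed = config.master_seed
        actual = build_feedforward_weights(
            n_population=config.population.n_total,
            n_connected=config.n_connected,
            n_excitatory=config.n_excitatory,
            weight_range=config.weight_range,
            seed=derive_seed(seed, "weights", replicate),
        )
        raster = generate_raster(
            config.population,
            config.n_trials,
            config.trial_duration,
            dt=config.dt,
            seed=derive_seed(seed, "train-raster", replicate),
        )
        post = threshold_unit_forward(raster, actual.weights, config.threshold_params)
        training = replace(config.training, seed=derive_seed(seed, "train", replicate))

        def _fit(x, y):
            return PerceptronConnectivity(
                learning_rate=training.learning_rate,
                n_iterations=training.n_iterations,
                model="threshold",
                threshold_params=config.threshold_params,
                init_weights=training.init_weights,
                random_state=training.seed,
            ).fit(x, y)

        w_unstim = _fit(raster, post).weights_
        stim_raster, _ = apply_stimulation(
            raster, protocol, seed=derive_seed(seed, "train-stim", replicate)
        )
        post_stim = threshold_unit_forward(
            stim_raster, actual.weights, config.threshold_params
        )
        w_stim = _fit(stim_raster, post_stim).weights_

        # pick the strongest excitatory silent cell (silent cells lead the
        # raster under the fixed-rate law)
        n_silent = config.population.n_silent
        silent_w = actual.weights[:n_silent]
        if silent_w.size == 0 or silent_w.max() < min_strong_weight:
            raise ValueError(
                f"replicate {replicate}: no strong excitatory silent cell "
                f"(max silent weight {silent_w.max() if silent_w.size else 'n/a'})"
            )
        target = int(np.argmax(silent_w))

        test = generate_raster(
            config.population,
            config.n_test_trials,
            config.trial_duration,
            dt=config.dt,
            seed=derive_seed(seed, "test-raster", replicate),
        )
        perturb = StimulationProtocol(
            n_stimulations=min(protocol.n_stimulations, config.n_test_trials),
            n_stimulated_cells=1,
            stim_rate=protocol.stim_rate,
            stim_duration=protocol.stim_duration,
            selection_rule="fixed_subset",
            fixed_cells=np.array([target]),
        )
        test_pert, _ = apply_stimulation(
            test, perturb, seed=derive_seed(seed, "test-stim", replicate)
        )
        base_actual = threshold_unit_forward(
            test, actual.weights, config.threshold_params
        )
        pert_actual = threshold_unit_forward(
            test_pert, actual.weights, config.threshold_params
        )
        added = (pert_actual == 1) & (base_actual == 0)
        row = {
            "replicate": replicate,
            "target_cell": target,
            "target_weight": float(actual.weights[target]),
            "n_added_spikes": int(added.sum()),
        }
        for label, w in (("unstimulated", w_unstim), ("stimulated", w_stim)):
            pred = threshold_unit_forward(test_pert, w, config.threshold_params)
            row[f"detection_{label}"] = (
                float(pred[added].mean()) if added.any() else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recurrent circuits driven by multichannel recordings
# ---------------------------------------------------------------------------


def _map_channels_to_slots(
    recording: SpikeRaster, presyn_ids: np.ndarray
) -> np.ndarray:
    """Tile recorded channels onto presynaptic slots (slot s -> channel s mod C)."""
    n_channels = recording.n_neurons
    flat = recording.flat()
    channel_of_slot = np.arange(presyn_ids.size) % n_channels
    return flat[channel_of_slot]


def run_circuit_experiment(
    n_datasets: int = 6,
    input_rasters: list[SpikeRaster] | None = None,
    n_neurons: int = 40,
    in_degree: int = 20,
    n_cells_evaluated: int | None = None,
    training: TrainingConfig | None = None,
    lif_params: LIFParams | None = None,
    recording_duration: float = 900.0,
    stim_epoch_duration: float = 60.0,
    stim_gain: float = 3.0,
    n_subgroups: int = 3,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Derive circuit weights from multichannel input, per subpopulation.

    For each dataset, a recurrent LIF circuit is built with reciprocal-pair
    statistics and a fixed in-degree; each circuit neuron's presynaptic
    slots are filled by recorded channels tiled with replacement. The
    neuron's actual postsynaptic spikes are simulated from the true
    weights, the perceptron rule derives weights from the same input, and
    the weight errors (delta w = derived - actual) are summarised within
    subpopulations found by agglomerative clustering of the true weights
    (strong/mid/weak, excitatory/inhibitory).

    Training is scored twice: on the full recording (stimulation epoch
    included) and on the post-epoch remainder only. Surrogate recordings
    are generated when no input rasters are given.
    """
    training = training or TrainingConfig()
    lif_params = lif_params or LIFParams()
    rows = []
    for d in range(n_datasets):
        if input_rasters is not None:
            recording = input_rasters[d]
        else:
            recording = generate_surrogate_recording(
                total_duration=recording_duration,
                stim_epoch_duration=stim_epoch_duration,
                stim_gain=stim_gain,
                seed=derive_seed(master_seed, "surrogate", d),
            )
        circuit = build_recurrent_circuit(
            n_neurons=n_neurons,
            in_degree=in_degree,
            seed=derive_seed(master_seed, "circuit", d),
        )
        stim_bins = int(round(stim_epoch_duration * 1000.0 / recording.dt))
        n_eval = n_cells_evaluated or n_neurons
        for j in range(n_eval):
            pre = circuit.presynaptic(j)
            actual_w = pre["weight"].to_numpy()
            x_full = _map_channels_to_slots(recording, pre["pre"].to_numpy())
            post_full = lif_forward(x_full, actual_w, lif_params)
            for label, sl in (
                ("with_stimulation", slice(None)),
                ("without_stimulation", slice(stim_bins, None)),
            ):
                x = x_full[:, sl]
                post = post_full[sl]
                est = PerceptronConnectivity(
                    learning_rate=training.learning_rate,
                    n_iterations=training.n_iterations,
                    model="lif",
                    lif_params=lif_params,
                    init_weights=training.init_weights,
                    random_state=derive_seed(master_seed, "train", d, j),
                    bins_per_trial=x.shape[1],
                ).fit(x.T, post)
                dw = est.weights_ - actual_w
                groups = cluster_subpopulations(actual_w, n_groups=n_subgroups)
                for g in np.unique(groups):
                    mask = groups == g
                    rows.append(
                        {
                            "dataset": d,
                            "post_neuron": j,
                            "trained_on": label,
                            "subpopulation": g,
                            "n_members": int(mask.sum()),
                            "mean_dw": float(dw[mask].mean()),
                            "rmse": float(np.sqrt((dw[mask] ** 2).mean())),
                        }
                    )
    return pd.DataFrame(rows)
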