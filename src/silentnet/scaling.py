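"""Stimulation requirements for large populations.

With ``m`` cells redrawn uniformly at random per stimulation epoch from a
population of ``N``, the expected fraction of the population stimulated at
least once after ``k`` epochs is the closed form

    coverage(k) = 1 - (1 - m/N)**k

so the number of epochs needed to reach a coverage target grows close to
linearly with N over the sizes studied (200-2,000). The population firing
rate averaged over the training data likewise grows linearly in the number
of epochs, with a slope that falls off with population size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seeding import derive_rng, derive_seed
from .population import PopulationSpec, StimulationProtocol, apply_stimulation, generate_raster

__all__ = [
    "coverage_curve",
    "stimuli_to_coverage",
    "rate_curve",
    "stimuli_required",
    "ScalingResult",
    "run_scaling_analysis",
]


def coverage_curve(
    n_population: int,
    n_per_epoch: int,
    max_epochs: int,
    mode: str = "analytic",
    seed: int = 0,
    n_replicates: int = 200,
) -> np.ndarray:
    """Expected cumulative coverage after 0..max_epochs resampled epochs.

    Returns an array of length ``max_epochs + 1`` with entry k the coverage
    after k epochs. ``analytic`` evaluates the closed form; ``monte_carlo``
    simulates ``n_replicates`` independent epoch sequences and averages the
    empirical coverage.
    """
    if n_per_epoch > n_population:
        raise ValueError(
            f"n_per_epoch={n_per_epoch} exceeds population size {n_population}"
        )
    if n_per_epoch < 0 or max_epochs < 0:
        raise ValueError("n_per_epoch and max_epochs must be non-negative")
    k = np.arange(max_epochs + 1)
    if mode == "analytic":
        return 1.0 - (1.0 - n_per_epoch / n_population) ** k
    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")
    rng = derive_rng(seed, "coverage-mc")
    acc = np.zeros(max_epochs + 1)
    for _ in range(n_replicates):
        covered = np.zeros(n_population, dtype=bool)
        for epoch in range(1, max_epochs + 1):
            cells = rng.choice(n_population, size=n_per_epoch, replace=False)
            covered[cells] = True
            acc[epoch] += covered.mean()
    return acc / n_replicates


def stimuli_to_coverage(
    n_population: int,
    n_per_epoch: int,
    coverage_target: float = 0.99,
) -> float:
    """Smallest epoch count whose expected coverage reaches the target.

    Closed form ``ceil(log(1 - target) / log(1 - m/N))``. A target of 1 (or
    more) is unreachable for m < N and reported as inf.
    """
    if not 0 < coverage_target:
        raise ValueError("coverage_target must be positive")
    if n_per_epoch > n_population:
        raise ValueError("n_per_epoch exceeds population size")
    if n_per_epoch == n_population:
        return 1.0
    if coverage_target >= 1.0:
        return float("inf")
    return float(
        math.ceil(math.log(1.0 - coverage_target) / math.log(1.0 - n_per_epoch / n_population))
    )


def rate_curve(
    spec: PopulationSpec,
    stimulus_counts,
    n_trials: int = 100,
    trial_duration: float = 1000.0,
    protocol_template: StimulationProtocol | None = None,
    dt: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean population firing rate vs. number of stimulation epochs.

    For each stimulus count k, a fresh raster is generated, k epochs are
    applied, and the rate is total spikes / (neurons x total duration).
    The averaging window is the full training duration (n_trials x
    trial_duration); it is exposed through ``n_trials`` because the
    absolute rate, unlike the slope ordering across population sizes,
    depends on that choice.
    """
    if n_trials <= 0 or trial_duration <= 0:
        raise ValueError("averaging window must be positive")
    template = protocol_template or StimulationProtocol(n_stimulations=0)
    rows = []
    for k in stimulus_counts:
        raster = generate_raster(
            spec, n_trials, trial_duration, dt=dt, seed=derive_seed(seed, "raster", k)
        )
        protocol = StimulationProtocol(
            n_stimulations=int(k),
            n_stimulated_cells=template.n_stimulated_cells,
            stim_rate=template.stim_rate,
            stim_duration=template.stim_duration,
            selection_rule=template.selection_rule,
        )
        stim, _ = apply_stimulation(raster, protocol, seed=derive_seed(seed, "stim", k))
        rows.append({"n_stimulations": int(k), "rate_hz": float(stim.empirical_rates().mean())})
    return pd.DataFrame(rows)


def stimuli_required(
    sizes,
    n_per_epoch: int = 50,
    coverage_target: float = 0.99,
    rate_curves: dict[int, pd.DataFrame] | None = None,
    rate_target: float | None = None,
) -> pd.DataFrame:
    """Epochs needed per population size to hit coverage (and rate) targets.

    Coverage counts come from the closed form; rate counts, when rate
    curves are supplied, are the smallest simulated count reaching the
    target (NaN when unreached; being unreached is a result, not an error).
    """
    rows = []
    for n in sizes:
        row = {
            "n_population": int(n),
            "stimuli_to_coverage": stimuli_to_coverage(n, n_per_epoch, coverage_target),
        }
        if rate_curves is not None and rate_target is not None:
            curve = rate_curves[int(n)]
            reached = curve[curve["rate_hz"] >= rate_target]
            row["stimuli_to_rate"] = (
                float(reached["n_stimulations"].min()) if len(reached) else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ScalingResult:
    """Curves and summary counts of the large-population analysis."""

    sizes: list[int]
    coverage_curves: dict[int, np.ndarray]
    rate_curves: dict[int, pd.DataFrame]
    summary: pd.DataFrame

    def coverage_linearity_r2(self) -> float:
        """R^2 of a linear fit of stimuli-to-coverage against size."""
        x = np.asarray(self.sizes, dtype=float)
        y = self.summary["stimuli_to_coverage"].to_numpy(dtype=float)
        fit = stats.linregress(x, y)
        return float(fit.rvalue**2)


def run_scaling_analysis(
    sizes=(200, 400, 600, 800, 1000, 1200, 1400, 1600, 1800, 2000),
    n_per_epoch: int = 50,
    max_epochs: int = 200,
    coverage_target: float = 0.99,
    rate_stimulus_counts=None,
    n_trials: int = 50,
    silent_fraction: float = 0.66,
    seed: int = 0,
) -> ScalingResult:
    """Coverage and rate scaling across population sizes.

    Rate curves use a reduced trial count (the absolute rate depends on the
    averaging window; the slope ordering across sizes does not).
    """
    sizes = [int(n) for n in sizes]
    coverage_curves = {
        n: coverage_curve(n, n_per_epoch, max_epochs, mode="analytic") for n in sizes
    }
    rate_curves_d: dict[int, pd.DataFrame] = {}
    if rate_stimulus_counts is not None:
        for n in sizes:
            spec = PopulationSpec(n_total=n, silent_fraction=silent_fraction)
            rate_curves_d[n] = rate_curve(
                spec,
                rate_stimulus_counts,
                n_trials=n_trials,
                seed=derive_seed(seed, "rate", n),
            )
    summary = stimuli_required(sizes, n_per_epoch, coverage_target)
    return ScalingResult(
        sizes=sizes,
        coverage_curves=coverage_curves,
        rate_curves=rate_curves_d,
        summary=summary,
    )
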