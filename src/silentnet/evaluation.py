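"""Scoring of derived weights and predicted spike trains.

Weight recovery is scored by the RMSE and Pearson correlation between
derived and actual weight vectors. Spike prediction is scored bin-wise by
sensitivity (TPR: the fraction of actual postsynaptic spike bins that are
predicted) and precision (PPV: the fraction of predicted spike bins that
are actual); "performance" is their mean. Derived weights are additionally
classified into five connection types (strong/weak inhibitory, unconnected,
weak/strong excitatory) with a dead zone of half-width epsilon around zero,
where epsilon is calibrated as the RMSE of derived weights for actually
unconnected cells in high-performance runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from .connectivity import WeightVector

__all__ = [
    "ClassificationScheme",
    "EvaluationReport",
    "SpikeScores",
    "weight_rmse",
    "spike_prediction_scores",
    "classify_weight",
    "classify_weights",
    "classification_accuracy",
    "calibrate_epsilon",
    "cluster_subpopulations",
    "evaluate_run",
]

CLASS_LABELS = (
    "strong_inhibitory",
    "weak_inhibitory",
    "unconnected",
    "weak_excitatory",
    "strong_excitatory",
)


def _as_array(w) -> np.ndarray:
    if isinstance(w, WeightVector):
        return w.weights
    return np.asarray(w, dtype=np.float64)


@dataclass(frozen=True)
class ClassificationScheme:
    """Connection-type intervals over the weight range.

    The five classes partition [-8, 8] mV: strong inhibitory (-8, -4),
    weak inhibitory (-4, -eps), unconnected (-eps, eps), weak excitatory
    (eps, 4), strong excitatory (4, 8). Weights landing exactly on a
    boundary are assigned to the interval on the side toward zero.
    """

    epsilon: float = 0.16
    strong_bound: float = 4.0
    weight_range: tuple[float, float] = (-8.0, 8.0)

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < self.strong_bound:
            raise ValueError("epsilon must lie in (0, strong_bound)")
        low, high = self.weight_range
        if not (low < -self.strong_bound and high > self.strong_bound):
            raise ValueError("weight_range must contain (-strong_bound, strong_bound)")


def classify_weights(
    w, scheme: ClassificationScheme | None = None, clip: bool = False
) -> np.ndarray:
    """Vectorized connection-type classification.

    With ``clip`` (used for derived weights, which the learning rule does
    not confine to the ground-truth range) out-of-range values are clipped
    into the range instead of raising.
    """
    scheme = scheme or ClassificationScheme()
    w = _as_array(w)
    low, high = scheme.weight_range
    if clip:
        w = np.clip(w, low, high)
    elif np.any((w < low) | (w > high)):
        bad = w[(w < low) | (w > high)]
        raise ValueError(f"weights outside {scheme.weight_range}: {bad[:5]}")
    eps, b = scheme.epsilon, scheme.strong_bound
    out = np.full(w.shape, "unconnected", dtype=object)
    out[w < -b] = "strong_inhibitory"
    out[(w >= -b) & (w < -eps)] = "weak_inhibitory"
    out[(w > eps) & (w <= b)] = "weak_excitatory"
    out[w > b] = "strong_excitatory"
    return out


def classify_weight(w: float, scheme: ClassificationScheme | None = None) -> str:
    """Classify one weight (mV) into its connection type."""
    return classify_weights(np.array([w]), scheme)[0]


def weight_rmse(derived, actual, subset: np.ndarray | None = None) -> float:
    """Root mean square error between derived and actual weights (mV)."""
    d = _as_array(derived)
    a = _as_array(actual)
    if d.shape != a.shape:
        raise ValueError(f"length mismatch: {d.shape} vs {a.shape}")
    if subset is not None:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise ValueError("subset must not be empty")
        d = d[subset]
        a = a[subset]
    return float(np.sqrt(np.mean((d - a) ** 2)))


@dataclass(frozen=True)
class SpikeScores:
    tpr: float
    ppv: float

    @property
    def performance(self) -> float:
        return (self.tpr + self.ppv) / 2.0


def spike_prediction_scores(actual: np.ndarray, predicted: np.ndarray) -> SpikeScores:
    """Bin-wise sensitivity and precision of a predicted spike train.

    TPR is one minus the mean absolute mismatch over the bins where the
    actual train spikes (equivalently, the fraction of actual spikes that
    are predicted); PPV is the analogue over predicted-spike bins. When a
    train has no spikes the corresponding score is undefined and reported
    as NaN rather than coerced to 1.
    """
    a = np.asarray(actual).ravel().astype(np.int64)
    p = np.asarray(predicted).ravel().astype(np.int64)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    s_a = a == 1
    s_p = p == 1
    if not s_a.any():
        warnings.warn("no actual spikes: TPR undefined", stacklevel=2)
        tpr = float("nan")
    else:
        tpr = 1.0 - float(np.mean(np.abs(a[s_a] - p[s_a])))
    if not s_p.any():
        warnings.warn("no predicted spikes: PPV undefined", stacklevel=2)
        ppv = float("nan")
    else:
        ppv = 1.0 - float(np.mean(np.abs(a[s_p] - p[s_p])))
    return SpikeScores(tpr=tpr, ppv=ppv)


def classification_accuracy(
    derived, actual, scheme: ClassificationScheme | None = None
) -> dict[str, float]:
    """Per-class probability of correct classification given the actual class.

    For each actual connection type, the fraction of its members whose
    derived weight falls in the same class. Classes with no members are
    reported as NaN.
    """
    scheme = scheme or ClassificationScheme()
    d_cls = classify_weights(derived, scheme, clip=True)
    a_cls = classify_weights(actual, scheme)
    out: dict[str, float] = {}
    for label in CLASS_LABELS:
        members = a_cls == label
        if not members.any():
            warnings.warn(f"no members in class {label}; accuracy undefined", stacklevel=2)
            out[label] = float("nan")
        else:
            out[label] = float(np.mean(d_cls[members] == label))
    return out


def per_class_rmse(
    derived, actual, scheme: ClassificationScheme | None = None
) -> dict[str, float]:
    """Weight RMSE within each actual connection type (NaN when empty)."""
    scheme = scheme or ClassificationScheme()
    d = _as_array(derived)
    a = _as_array(actual)
    a_cls = classify_weights(a, scheme)
    out: dict[str, float] = {}
    for label in CLASS_LABELS:
        members = np.nonzero(a_cls == label)[0]
        out[label] = (
            weight_rmse(d, a, subset=members) if members.size else float("nan")
        )
    return out


def calibrate_epsilon(
    runs,
    performance_threshold: float = 0.99,
) -> float:
    """Pool the unconnected-cell weight RMSE over high-performance runs.

    ``runs`` is an iterable of (derived, actual, performance) triples. Runs
    with performance above the threshold contribute the squared errors of
    their derived weights at the actually-unconnected positions; the pooled
    root mean square is the classification dead-zone half-width epsilon.
    """
    sq_errors: list[np.ndarray] = []
    n_qualifying = 0
    for derived, actual, performance in runs:
        if not performance > performance_threshold:
            continue
        d = _as_array(derived)
        a = _as_array(actual)
        unconnected = a == 0
        if not unconnected.any():
            continue
        n_qualifying += 1
        sq_errors.append((d[unconnected] - a[unconnected]) ** 2)
    if n_qualifying == 0:
        raise ValueError(
            "epsilon calibration requires at least one run with performance "
            f"> {performance_threshold} and unconnected cells"
        )
    return float(np.sqrt(np.concatenate(sq_errors).mean()))


def cluster_subpopulations(weights, n_groups: int = 3) -> np.ndarray:
    """Label weights by sign and strength via 1-D agglomerative clustering.

    Within each sign, weight magnitudes are clustered into ``n_groups``
    groups (Ward linkage) and labelled by decreasing mean magnitude:
    strong, mid, weak for the default three groups. Positive and negative
    weights never share a group; exact zeros are labelled "unconnected".
    """
    w = _as_array(weights)
    if n_groups == 3:
        strength_names = ["strong", "mid", "weak"]
    else:
        strength_names = [f"rank{i}" for i in range(n_groups)]
    labels = np.full(w.shape, "unconnected", dtype=object)
    for sign, sign_name in ((1, "excitatory"), (-1, "inhibitory")):
        idx = np.nonzero(np.sign(w) == sign)[0]
        if idx.size == 0:
            continue
        mags = np.abs(w[idx])
        if np.unique(mags).size < n_groups:
            raise ValueError(
                f"need at least {n_groups} distinct {sign_name} magnitudes, "
                f"got {np.unique(mags).size}"
            )
        clust = AgglomerativeClustering(n_clusters=n_groups, linkage="ward")
        assign = clust.fit_predict(mags[:, None])
        means = np.array([mags[assign == g].mean() for g in range(n_groups)])
        order = np.argsort(-means)  # largest magnitude first
        for rank, g in enumerate(order):
            labels[idx[assign == g]] = f"{strength_names[rank]}_{sign_name}"
    return labels


@dataclass
class EvaluationReport:
    """Scores of one weight-derivation run."""

    rmse_weights: float
    pearson_r: float
    pearson_p: float
    tpr: float = float("nan")
    ppv: float = float("nan")
    per_class_rmse: dict = field(default_factory=dict)
    per_class_accuracy: dict = field(default_factory=dict)

    @property
    def performance(self) -> float:
        return (self.tpr + self.ppv) / 2.0

    def to_dict(self) -> dict:
        out = {
            "rmse_weights": self.rmse_weights,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "tpr": self.tpr,
            "ppv": self.ppv,
            "performance": self.performance,
        }
        for k, v in self.per_class_rmse.items():
            out[f"rmse_{k}"] = v
        for k, v in self.per_class_accuracy.items():
            out[f"accuracy_{k}"] = v
        return out


def evaluate_run(
    derived,
    actual,
    actual_spikes: np.ndarray | None = None,
    predicted_spikes: np.ndarray | None = None,
    scheme: ClassificationScheme | None = None,
) -> EvaluationReport:
    """Score one derivation run: weight recovery and optional spike prediction."""
    scheme = scheme or ClassificationScheme()
    d = _as_array(derived)
    a = _as_array(actual)
    r, p = stats.pearsonr(d, a)
    report = EvaluationReport(
        rmse_weights=weight_rmse(d, a),
        pearson_r=float(r),
        pearson_p=float(p),
        per_class_rmse=per_class_rmse(d, a, scheme),
        per_class_accuracy=classification_accuracy(d, a, scheme),
    )
    if actual_spikes is not None and predicted_spikes is not None:
        scores = spike_prediction_scores(actual_spikes, predicted_spikes)
        report.tpr = scores.tpr
        report.ppv = scores.ppv
    return report
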