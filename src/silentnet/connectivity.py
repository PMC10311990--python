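"""Ground-truth connectivity: feedforward weight vectors and recurrent circuits.

Feedforward networks connect a postsynaptic neuron to 100 of 200 population
spike trains (80 excitatory, 20 inhibitory) with weights drawn uniformly in
[-8, 8] mV. Recurrent circuits wire every neuron with a fixed in-degree
(120 by default), a 4:1 excitatory-to-inhibitory presynaptic split, and a
mixture of unidirectional and reciprocal connections; reciprocal-pair
members are 1.5x stronger than unidirectional draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._seeding import derive_rng, derive_seed
from .population import lognormal_params_from_moments

__all__ = [
    "WeightVector",
    "CircuitGraph",
    "build_feedforward_weights",
    "build_recurrent_circuit",
    "assign_circuit_rates",
]


@dataclass
class WeightVector:
    """Per-presynaptic-cell synaptic weights in mV.

    Sign encodes the role: positive = excitatory, negative = inhibitory,
    exactly zero = unconnected.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 1:
            raise ValueError("weights must be 1-D")

    def __len__(self) -> int:
        return self.weights.shape[0]

    @property
    def roles(self) -> np.ndarray:
        out = np.full(len(self), "unconnected", dtype=object)
        out[self.weights > 0] = "excitatory"
        out[self.weights < 0] = "inhibitory"
        return out

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"neuron_id": np.arange(len(self)), "weight_mV": self.weights}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "WeightVector":
        df = pd.read_csv(path).sort_values("neuron_id")
        return cls(df["weight_mV"].to_numpy())


def build_feedforward_weights(
    n_population: int = 200,
    n_connected: int = 100,
    n_excitatory: int = 80,
    weight_range: tuple[float, float] = (-8.0, 8.0),
    seed: int = 0,
) -> WeightVector:
    """Draw a feedforward ground-truth weight vector.

    ``n_connected`` cells (chosen without replacement) receive nonzero
    weights: the first ``n_excitatory`` of them uniform in (0, high], the
    rest uniform in [low, 0); all other cells are exactly 0.
    """
    if not 0 <= n_connected <= n_population:
        raise ValueError(
            f"n_connected={n_connected} must lie in [0, n_population={n_population}]"
        )
    if not 0 <= n_excitatory <= n_connected:
        raise ValueError(
            f"n_excitatory={n_excitatory} must lie in [0, n_connected={n_connected}]"
        )
    low, high = weight_range
    if not (low < 0 < high):
        raise ValueError(f"weight_range must straddle zero, got {weight_range}")
    rng = derive_rng(seed, "ff-weights")
    weights = np.zeros(n_population, dtype=np.float64)
    connected = rng.choice(n_population, size=n_connected, replace=False)
    exc = connected[:n_excitatory]
    inh = connected[n_excitatory:]
    weights[exc] = high * (1.0 - rng.random(exc.size))  # uniform on (0, high]
    weights[inh] = low * (1.0 - rng.random(inh.size))  # uniform on [low, 0)
    return WeightVector(weights)


@dataclass
class CircuitGraph:
    """Weighted directed circuit with per-edge kind annotations.

    ``edges`` has columns (pre, post, weight, kind) with kind in
    {"unidirectional", "reciprocal"}.
    """

    n_neurons: int
    edges: pd.DataFrame = field(repr=False)

    def adjacency(self) -> np.ndarray:
        """Dense weight matrix A with A[pre, post] = weight."""
        a = np.zeros((self.n_neurons, self.n_neurons), dtype=np.float64)
        a[self.edges["pre"].to_numpy(), self.edges["post"].to_numpy()] = self.edges[
            "weight"
        ].to_numpy()
        return a

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.edges["post"].to_numpy(), minlength=self.n_neurons)

    def presynaptic(self, post: int) -> pd.DataFrame:
        """Edges incoming to one neuron, ordered by pre id."""
        sub = self.edges[self.edges["post"] == post]
        return sub.sort_values("pre").reset_index(drop=True)

    def reciprocal_fraction(self) -> float:
        """Fraction of connected (unordered) pairs that are reciprocal."""
        pairs = set()
        recip = set()
        pre = self.edges["pre"].to_numpy()
        post = self.edges["post"].to_numpy()
        seen = set(zip(pre.tolist(), post.tolist()))
        for i, j in seen:
            key = (min(i, j), max(i, j))
            pairs.add(key)
            if (j, i) in seen:
                recip.add(key)
        return len(recip) / len(pairs) if pairs else float("nan")

    def to_csv(self, path: str) -> None:
        self.edges.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, n_neurons: int) -> "CircuitGraph":
        return cls(n_neurons=n_neurons, edges=pd.read_csv(path))


def build_recurrent_circuit(
    n_neurons: int,
    in_degree: int = 120,
    p_uni: float = 0.13,
    p_rec: float = 0.06,
    rec_strength_factor: float = 1.5,
    ei_ratio: float = 4.0,
    weight_range: tuple[float, float] = (-8.0, 8.0),
    clip_reciprocal: bool = True,
    seed: int = 0,
) -> CircuitGraph:
    """Build a recurrent circuit with fixed in-degree and reciprocal pairs.

    The pairwise wiring probabilities and the fixed in-degree cannot both
    hold exactly for arbitrary circuit size, so the in-degree (which sets
    the postsynaptic drive) is the binding constraint and the probabilities
    only set the reciprocal/unidirectional mixture: among connected pairs
    the expected reciprocal fraction is ``p_rec / (p_uni + p_rec)``.

    Per neuron, ``round(in_degree * ei_ratio/(ei_ratio+1))`` incoming
    weights are excitatory and the rest inhibitory. Magnitudes are uniform
    on (0, high]; both members of a reciprocal pair have their magnitude
    multiplied by ``rec_strength_factor`` and are then clipped back to the
    weight range unless ``clip_reciprocal`` is False.
    """
    if not 0 < in_degree < n_neurons:
        raise ValueError(
            f"in_degree={in_degree} must lie in (0, n_neurons={n_neurons})"
        )
    if not (0 <= p_uni <= 1 and 0 <= p_rec <= 1) or p_uni + p_rec == 0:
        raise ValueError("p_uni and p_rec must be probabilities, not both zero")
    low, high = weight_range
    if not (low < 0 < high):
        raise ValueError(f"weight_range must straddle zero, got {weight_range}")

    # fraction of each neuron's in-edges that belong to reciprocal pairs:
    # a reciprocal pair contributes one in-edge to each member, a
    # unidirectional pair contributes one in-edge to one member.
    q = p_rec / (p_uni + p_rec)
    recip_edge_frac = 2.0 * q / (1.0 + q)
    r = int(round(in_degree * recip_edge_frac))
    if (r * n_neurons) % 2 == 1:
        r -= 1  # undirected r-regular graph needs an even edge-count product
    if r >= n_neurons:
        raise ValueError(
            "reciprocal degree requirement exceeds circuit size; increase "
            "n_neurons or reduce in_degree"
        )

    rng = derive_rng(seed, "circuit")
    pre_list: list[int] = []
    post_list: list[int] = []
    kind_list: list[str] = []

    # reciprocal backbone: random r-regular undirected graph, each undirected
    # edge realized as two directed edges
    if r > 0:
        g = nx.random_regular_graph(r, n_neurons, seed=derive_seed(seed, "regular"))
        for i, j in g.edges():
            pre_list += [i, j]
            post_list += [j, i]
            kind_list += ["reciprocal", "reciprocal"]

    # fill each neuron's remaining in-degree with unidirectional edges,
    # avoiding duplicates and accidental reciprocity
    existing: set[tuple[int, int]] = set(zip(pre_list, post_list))
    for j in range(n_neurons):
        have = sum(1 for (_, p) in existing if p == j)
        need = in_degree - have
        if need < 0:
            raise ValueError("reciprocal backbone exceeded the requested in-degree")
        fresh = [
            i
            for i in range(n_neurons)
            if i != j and (i, j) not in existing and (j, i) not in existing
        ]
        # prefer sources that do not close an accidental reciprocal pair; in
        # dense circuits (in_degree near n-1) fall back to sources with an
        # existing reverse edge, since avoidance is then infeasible
        backfill = [
            i
            for i in range(n_neurons)
            if i != j and (i, j) not in existing and (j, i) in existing
        ]
        if len(fresh) + len(backfill) < need:
            raise ValueError(
                f"cannot reach in-degree {in_degree} for neuron {j}; circuit too small"
            )
        if len(fresh) >= need:
            chosen = [fresh[c] for c in rng.choice(len(fresh), size=need, replace=False)]
        else:
            extra = rng.choice(
                len(backfill), size=need - len(fresh), replace=False
            )
            chosen = fresh + [backfill[c] for c in extra]
        for i in chosen:
            pre_list.append(i)
            post_list.append(j)
            kind_list.append("unidirectional")
            existing.add((i, j))

    pre = np.array(pre_list, dtype=int)
    post = np.array(post_list, dtype=int)
    kind = np.array(kind_list, dtype=object)

    # signs: per postsynaptic neuron, an exact E:I split of its in-edges
    n_exc = int(round(in_degree * ei_ratio / (ei_ratio + 1.0)))
    sign = np.empty(pre.size, dtype=np.float64)
    for j in range(n_neurons):
        idx = np.nonzero(post == j)[0]
        s = np.full(idx.size, -1.0)
        s[: min(n_exc, idx.size)] = 1.0
        rng.shuffle(s)
        sign[idx] = s

    mag = high * (1.0 - rng.random(pre.size))  # uniform on (0, high]
    recip_mask = kind == "reciprocal"
    mag[recip_mask] *= rec_strength_factor
    if clip_reciprocal:
        # cap magnitudes so excitatory weights stay <= high, inhibitory >= low
        mag = np.where(sign > 0, np.minimum(mag, high), np.minimum(mag, -low))
    weight = sign * mag

    edges = pd.DataFrame({"pre": pre, "post": post, "weight": weight, "kind": kind})
    return CircuitGraph(n_neurons=n_neurons, edges=edges)


def assign_circuit_rates(
    graph: CircuitGraph,
    lognormal_mean: float = 0.8703,
    lognormal_sd: float = 0.8749,
    seed: int = 0,
) -> np.ndarray:
    """Draw per-neuron baseline firing rates from a moment-matched lognormal.

    ``lognormal_mean`` and ``lognormal_sd`` are the mean and SD of the rate
    distribution itself, in Hz.
    """
    mu, sigma = lognormal_params_from_moments(lognormal_mean, lognormal_sd)
    rng = derive_rng(seed, "circuit-rates")
    return rng.lognormal(mu, sigma, size=graph.n_neurons)
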