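"""Non-parametric classifiers for taxonomic discrimination.

All three work directly on Euclidean distances in feature space, which
is why per-measurement normalization matters so much upstream:

* **k-NN** — majority vote among the k nearest training samples
  (k = 1 by default, the setting that classifies fluorescence spectra
  best and needs no training at all);
* **SOM** — a fixed 2-D grid of neurons (default 8 x 4 = 32) trained by
  competitive learning, W <- W + alpha * h_c * (x - W), with a Gaussian
  neighbourhood h_c around the best-matching unit;
* **GCS** (growing cell structures) — a self-organizing network that
  starts from a 3-cell triangle and inserts cells where the input
  density is highest, up to the same 32-cell budget.

The maps are unsupervised learners; they are used for supervised
classification by labelling each neuron/cell with the majority class of
the training samples mapped to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KNNModel",
    "SOMConfig",
    "SOMModel",
    "GCSConfig",
    "GCSModel",
    "fit_knn",
    "knn_classify",
    "train_som",
    "som_classify",
    "train_gcs",
    "gcs_classify",
]


# ---------------------------------------------------------------------------
# k nearest neighbours
# ---------------------------------------------------------------------------

@dataclass
class KNNModel:
    """Stored training samples + labels; Euclidean distance."""

    x: np.ndarray
    labels: list[str]
    k: int = 1
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if self.x.shape[0] != len(self.labels):
            raise ValueError("labels must cover every training sample")
        if not (1 <= self.k <= self.x.shape[0]):
            raise ValueError("need 1 <= k <= n_train")
        if not self.classes:
            self.classes = sorted(set(self.labels))

    def to_dict(self) -> dict:
        return {"kind": "knn", "x": self.x.tolist(), "labels": self.labels,
                "k": self.k, "classes": self.classes}

    @classmethod
    def from_dict(cls, d: dict) -> "KNNModel":
        return cls(np.asarray(d["x"], float), list(d["labels"]), int(d["k"]),
                   list(d["classes"]))


def fit_knn(x: np.ndarray, labels: list[str], k: int = 1) -> KNNModel:
    """Build a k-NN model (training is just storing the samples)."""
    return KNNModel(x, list(labels), k)


def knn_classify(model: KNNModel, queries: np.ndarray) -> list[str]:
    """Label each query by majority vote among its k nearest neighbours.

    Vote ties are broken by the smaller mean distance to the tied class's
    neighbours, then by the model's fixed class order.
    """
    q = np.atleast_2d(np.asarray(queries, dtype=float))
    if q.shape[1] != model.x.shape[1]:
        raise ValueError("query feature dimension does not match training")
    if model.x.shape[0] == 0:
        raise ValueError("empty training set")
    d = cdist(q, model.x)
    if model.k == 1:
        nearest = np.argmin(d, axis=1)
        return [model.labels[i] for i in nearest]

    order = np.argsort(d, axis=1)[:, : model.k]
    out = []
    class_pos = {c: i for i, c in enumerate(model.classes)}
    for row, dist_row in zip(order, d):
        votes: dict[str, list[float]] = {}
        for idx in row:
            votes.setdefault(model.labels[idx], []).append(dist_row[idx])
        best = min(
            votes.items(),
            key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])),
                            class_pos[kv[0]]),
        )
        out.append(best[0])
    return out


# ---------------------------------------------------------------------------
# Self-organizing map
# ---------------------------------------------------------------------------

@dataclass
class SOMConfig:
    """SOM shape and training schedules.

    32 nodes on an 8 x 4 grid by default; the learning rate decays
    linearly 0.5 -> 0.01 and the Gaussian neighbourhood radius linearly
    max(rows, cols)/2 -> 1 over the epochs.
    """

    rows: int = 8
    cols: int = 4
    epochs: int = 200
    alpha_start: float = 0.5
    alpha_end: float = 0.01
    radius_start: float | None = None   # default max(rows, cols) / 2
    radius_end: float = 1.0
    seed: int | None = None


@dataclass
class SOMModel:
    """Trained map: one weight vector and one class label per neuron."""

    weights: np.ndarray          # (rows*cols, dim)
    grid_coords: np.ndarray      # (rows*cols, 2) integer grid positions
    neuron_labels: list[str]
    config: SOMConfig
    classes: list[str] = field(default_factory=list)

    def bmu(self, queries: np.ndarray) -> np.ndarray:
        """Index of the best-matching unit for each query."""
        q = np.atleast_2d(np.asarray(queries, dtype=float))
        return np.argmin(cdist(q, self.weights), axis=1)

    def to_dict(self) -> dict:
        return {"kind": "som", "weights": self.weights.tolist(),
                "grid_coords": self.grid_coords.tolist(),
                "neuron_labels": self.neuron_labels,
                "classes": self.classes,
                "config": vars(self.config)}

    @classmethod
    def from_dict(cls, d: dict) -> "SOMModel":
        return cls(np.asarray(d["weights"], float),
                   np.asarray(d["grid_coords"], float),
                   list(d["neuron_labels"]), SOMConfig(**d["config"]),
                   list(d["classes"]))


def _majority_labels(assignments: np.ndarray, labels: list[str],
                     n_units: int, classes: list[str]) -> list[str | None]:
    """Majority class per unit; None for units with no mapped samples."""
    pos = {c: i for i, c in enumerate(classes)}
    out: list[str | None] = [None] * n_units
    for u in range(n_units):
        mapped = [labels[i] for i in np.flatnonzero(assignments == u)]
        if mapped:
            counts = np.zeros(len(classes))
            for l in mapped:
                counts[pos[l]] += 1
            out[u] = classes[int(np.argmax(counts))]
    return out


def train_som(x: np.ndarray, labels: list[str],
              config: SOMConfig | None = None) -> SOMModel:
    """Train a SOM by sequential competitive learning, then label neurons.

    Each training step moves every neuron toward the sample, weighted by
    a Gaussian of its grid distance to the best-matching unit. After
    training each neuron takes the majority label of the samples mapped
    to it; neurons left unlabelled inherit the nearest labelled neuron's
    label (grid distance first, weight distance as tie-break).
    """
    config = config or SOMConfig()
    if config.epochs < 1:
        raise ValueError("need at least one training epoch")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, dim = x.shape
    if n < 1:
        raise ValueError("need at least one training sample")
    n_units = config.rows * config.cols
    rng = np.random.default_rng(config.seed)

    coords = np.array([(r, c) for r in range(config.rows)
                       for c in range(config.cols)], dtype=float)
    # initialise on the data manifold: random training samples
    weights = x[rng.integers(n, size=n_units)].astype(float).copy()

    r0 = (config.radius_start if config.radius_start is not None
          else max(config.rows, config.cols) / 2.0)
    grid_d2 = cdist(coords, coords, "sqeuclidean")

    for epoch in range(config.epochs):
        frac = epoch / max(config.epochs - 1, 1)
        alpha = config.alpha_start + frac * (config.alpha_end
                                             - config.alpha_start)
        radius = r0 + frac * (config.radius_end - r0)
        for i in rng.permutation(n):
            sample = x[i]
            bmu = int(np.argmin(((weights - sample) ** 2).sum(axis=1)))
            h = np.exp(-grid_d2[bmu] / (2.0 * radius ** 2))
            weights += alpha * h[:, None] * (sample - weights)

    classes = sorted(set(labels))
    assign = np.argmin(cdist(x, weights), axis=1)
    neuron_labels = _majority_labels(assign, labels, n_units, classes)
    # unlabelled neurons inherit the nearest labelled neuron's label
    labelled = [u for u, l in enumerate(neuron_labels) if l is not None]
    if not labelled:
        raise ValueError("no neuron received a training sample")
    for u, l in enumerate(neuron_labels):
        if l is None:
            cand = sorted(
                labelled,
                key=lambda v: (grid_d2[u, v],
                               float(((weights[u] - weights[v]) ** 2).sum())),
            )
            neuron_labels[u] = neuron_labels[cand[0]]
    return SOMModel(weights, coords, neuron_labels, config, classes)  # type: ignore[arg-type]


def som_classify(model: SOMModel, queries: np.ndarray) -> list[str]:
    """Label each query with its best-matching unit's label."""
    if model.weights.size == 0 or not model.neuron_labels:
        raise ValueError("untrained SOM")
    return [model.neuron_labels[u] for u in model.bmu(queries)]


# ---------------------------------------------------------------------------
# Growing cell structures
# ---------------------------------------------------------------------------

@dataclass
class GCSConfig:
    """Growth and adaptation settings of the growing-cell-structures net.

    eps_b/eps_n are the winner/neighbour adaptation steps, one new cell
    is inserted every ``lambda_ins`` input signals (splitting the edge
    between the busiest cell and its most distant neighbour), and growth
    stops at ``max_cells`` (32, matching the SOM node budget).
    """

    eps_b: float = 0.06
    eps_n: float = 0.002
    lambda_ins: int = 100
    max_cells: int = 32
    seed: int | None = None


@dataclass
class GCSModel:
    """Trained net: cell weights, triangulated connectivity, labels."""

    weights: np.ndarray            # (n_cells, dim)
    edges: list[set[int]]          # adjacency sets
    tau: np.ndarray                # signal counters
    cell_labels: list[str]
    config: GCSConfig
    classes: list[str] = field(default_factory=list)

    def nearest(self, queries: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(queries, dtype=float))
        return np.argmin(cdist(q, self.weights), axis=1)

    def to_dict(self) -> dict:
        return {"kind": "gcs", "weights": self.weights.tolist(),
                "edges": [sorted(e) for e in self.edges],
                "tau": self.tau.tolist(), "cell_labels": self.cell_labels,
                "classes": self.classes, "config": vars(self.config)}

    @classmethod
    def from_dict(cls, d: dict) -> "GCSModel":
        return cls(np.asarray(d["weights"], float),
                   [set(e) for e in d["edges"]], np.asarray(d["tau"], float),
                   list(d["cell_labels"]), GCSConfig(**d["config"]),
                   list(d["classes"]))


def _insert_cell(weights: list[np.ndarray], edges: list[set[int]],
                 tau: list[float]) -> None:
    """Split the edge between the busiest cell and its farthest neighbour."""
    q = int(np.argmax(tau))
    nbrs = sorted(edges[q])
    f = max(nbrs, key=lambda v: float(((weights[q] - weights[v]) ** 2).sum()))
    r = len(weights)
    weights.append(0.5 * (weights[q] + weights[f]))
    common = edges[q] & edges[f]
    edges[q].discard(f)
    edges[f].discard(q)
    new_edges = {q, f} | common
    edges.append(set(new_edges))
    for v in new_edges:
        edges[v].add(r)
    # redistribute signal counters, preserving the total
    tau.append(0.5 * (tau[q] + tau[f]))
    tau[q] *= 0.5
    tau[f] *= 0.5


def train_gcs(x: np.ndarray, labels: list[str],
              config: GCSConfig | None = None) -> GCSModel:
    """Grow and adapt a cell structure on the training data, then label cells.

    Starts from a triangle of three cells placed at random training
    samples. Each input signal moves the winning cell by eps_b and its
    topological neighbours by eps_n toward the signal and increments the
    winner's counter; every ``lambda_ins`` signals a new cell splits the
    edge between the busiest cell and its most distant neighbour. Growth
    stops at ``max_cells``, a final adaptation pass runs over the data,
    and cells take the majority label of their mapped training samples.
    """
    config = config or GCSConfig()
    if config.max_cells < 3:
        raise ValueError("max_cells must be >= 3")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    if n < 3:
        raise ValueError("need >= 3 training samples")
    rng = np.random.default_rng(config.seed)

    init = rng.choice(n, size=3, replace=False)
    weights = [x[i].astype(float).copy() for i in init]
    edges: list[set[int]] = [{1, 2}, {0, 2}, {0, 1}]
    tau = [0.0, 0.0, 0.0]

    def adapt(sample: np.ndarray) -> None:
        w = np.asarray(weights)
        winner = int(np.argmin(((w - sample) ** 2).sum(axis=1)))
        weights[winner] = weights[winner] + config.eps_b * (
            sample - weights[winner])
        for v in edges[winner]:
            weights[v] = weights[v] + config.eps_n * (sample - weights[v])
        tau[winner] += 1.0

    signals = 0
    while len(weights) < config.max_cells:
        for i in rng.permutation(n):
            adapt(x[i])
            signals += 1
            if signals % config.lambda_ins == 0:
                _insert_cell(weights, edges, tau)
                if len(weights) >= config.max_cells:
                    break
        if len(weights) >= config.max_cells:
            break
    # final adaptation pass at full size
    for i in rng.permutation(n):
        adapt(x[i])

    w = np.asarray(weights)
    classes = sorted(set(labels))
    assign = np.argmin(cdist(x, w), axis=1)
    cell_labels = _majority_labels(assign, labels, len(weights), classes)
    labelled = [u for u, l in enumerate(cell_labels) if l is not None]
    if not labelled:
        raise ValueError("no cell received a training sample")
    for u, l in enumerate(cell_labels):
        if l is None:
            cand = min(labelled,
                       key=lambda v: float(((w[u] - w[v]) ** 2).sum()))
            cell_labels[u] = cell_labels[cand]
    return GCSModel(w, edges, np.asarray(tau), cell_labels, config, classes)  # type: ignore[arg-type]


def gcs_classify(model: GCSModel, queries: np.ndarray) -> list[str]:
    """Label each query with the label of its nearest cell."""
    if model.weights.size == 0 or not model.cell_labels:
        raise ValueError("untrained GCS")
    return [model.cell_labels[u] for u in model.nearest(queries)]
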