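"""Transformation and dimension reduction of spectra.

* finite-difference derivative spectra (configurable band separation),
* principal component analysis on the covariance matrix,
* Levina-Bickel maximum-likelihood intrinsic-dimension estimation,
* genetic-algorithm selection of the most discriminative wavelengths,
  with a cross-validated 1-NN kappa fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .spectra import SpectraSet, Spectrum

__all__ = [
    "PCAModel",
    "GAConfig",
    "GAResult",
    "derivative",
    "fit_pca",
    "pca_project",
    "n_components_for_variance",
    "mle_intrinsic_dimension",
    "ga_select_bands",
]


def derivative(spec: Spectrum, separation: int = 1, order: int = 1) -> Spectrum:
    """Forward-difference derivative with a configurable band separation.

    First order: y(l_k) = (x(l_{k+s}) - x(l_k)) / (s * dl); higher orders
    by repeated application. The output shrinks by ``separation`` points
    per order and keeps the left endpoints of each difference; larger
    separations act as a mild low-pass, giving smoother derivative curves.
    """
    if separation < 1:
        raise ValueError("separation must be >= 1")
    if order < 1:
        raise ValueError("order must be >= 1")
    x = spec.intensities
    grid = spec.wavelengths
    dl = spec.step
    for _ in range(order):
        if x.size <= separation:
            raise ValueError("derivative output would be empty")
        x = (x[separation:] - x[:-separation]) / (separation * dl)
        grid = grid[:-separation]
    out = Spectrum(grid.copy(), x, label=spec.label,
                   growth_index=spec.growth_index)
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Eigendecomposition of the covariance matrix of the measurements."""

    mean: np.ndarray
    components: np.ndarray       # rows = eigenvectors, descending eigenvalue
    eigenvalues: np.ndarray
    percent_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(sset: SpectraSet) -> PCAModel:
    """PCA via eigendecomposition of the (population) covariance matrix.

    Components are sorted by descending eigenvalue, and each component's
    sign is fixed so its largest-magnitude loading is positive.
    """
    if sset.n_measurements < 2:
        raise ValueError("PCA needs >= 2 measurements")
    x = sset.values
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / x.shape[0]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    comps = eigvec[:, order].T
    for k in range(comps.shape[0]):
        idx = np.argmax(np.abs(comps[k]))
        if comps[k, idx] < 0:
            comps[k] = -comps[k]
    total = eigval.sum()
    percent = (eigval / total * 100.0) if total > 0 else np.zeros_like(eigval)
    return PCAModel(mean, comps, eigval, percent)


def pca_project(sset: SpectraSet, model: PCAModel,
                n_components: int) -> np.ndarray:
    """Scores of the measurements on the first ``n_components`` components."""
    if not (1 <= n_components <= model.n_components):
        raise ValueError(f"n_components must be in 1..{model.n_components}")
    return (sset.values - model.mean) @ model.components[:n_components].T


def n_components_for_variance(model: PCAModel,
                              threshold: float = 99.0) -> int:
    """Smallest number of components whose cumulative variance reaches
    ``threshold`` percent (default 99, the usual working point where the
    leading components concentrate essentially all the data variability).
    """
    cum = np.cumsum(model.percent_variance)
    idx = np.searchsorted(cum, threshold - 1e-9)
    return int(min(idx + 1, model.n_components))


# ---------------------------------------------------------------------------
# Intrinsic dimension (Levina-Bickel MLE)
# ---------------------------------------------------------------------------

def mle_intrinsic_dimension(data: SpectraSet | np.ndarray, k_min: int = 6,
                            k_max: int = 12) -> int:
    """Maximum-likelihood intrinsic-dimension estimate from neighbour
    distances (Levina-Bickel).

    For each point x and neighbourhood size k,

        m_k(x) = [ (1/(k-1)) * sum_{j<k} ln( T_k(x) / T_j(x) ) ]^(-1)

    with T_j the Euclidean distance to the j-th nearest neighbour. The
    estimates are averaged over points and over k in [k_min, k_max] and
    rounded to the nearest integer. Points with duplicate (zero-distance)
    neighbours are excluded; if every point is degenerate this raises.
    """
    x = data.values if isinstance(data, SpectraSet) else np.asarray(data, float)
    n = x.shape[0]
    if not (1 < k_min <= k_max):
        raise ValueError("need 1 < k_min <= k_max")
    if n <= k_max + 1:
        raise ValueError(f"need more than k_max + 1 = {k_max + 1} points")
    dist = cdist(x, x)
    np.fill_diagonal(dist, np.inf)
    dist.sort(axis=1)
    t = dist[:, :k_max]          # t[:, j-1] = distance to j-th neighbour

    per_k = []
    for k in range(k_min, k_max + 1):
        valid = t[:, k - 1] > 0
        valid &= np.all(t[:, : k - 1] > 0, axis=1)
        if not valid.any():
            continue
        logratio = np.log(t[valid, k - 1][:, None] / t[valid, : k - 1])
        mk = 1.0 / (logratio.sum(axis=1) / (k - 1))
        per_k.append(mk.mean())
    if not per_k:
        raise ValueError("all points degenerate: zero neighbour distances")
    return int(round(float(np.mean(per_k))))


# ---------------------------------------------------------------------------
# Genetic-algorithm wavelength selection
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    """Settings for the genetic wavelength search.

    The fitness of a candidate wavelength subset is the mean Cohen kappa
    of a 1-NN classifier restricted to those wavelengths, under an
    internal stratified cross-validation.
    """

    population_size: int = 100
    generations: int = 20
    n_bands: int = 5
    elite_fraction: float = 0.2
    mutation_rate: float = 0.1
    cv_folds: int = 3
    knn_k: int = 1
    seed: int | None = None
    initial_population: list[tuple[int, ...]] | None = None


@dataclass
class GAResult:
    """Outcome of the genetic search."""

    wavelengths: np.ndarray          # selected wavelengths, nm, sorted
    indices: tuple[int, ...]         # grid indices of the selection
    fitness: float                   # best cross-validated kappa
    trace: list[float] = field(default_factory=list)  # elite fitness/generation


def _kappa_from_counts(true_idx: np.ndarray, pred_idx: np.ndarray,
                       n_classes: int) -> float:
    cm = np.zeros((n_classes, n_classes))
    np.add.at(cm, (true_idx, pred_idx), 1.0)
    n = cm.sum()
    po = np.trace(cm) / n
    pe = float(cm.sum(axis=1) @ cm.sum(axis=0)) / n ** 2
    if pe >= 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def _cv_knn_kappa(x: np.ndarray, y_idx: np.ndarray, n_classes: int,
                  folds: int, k: int, seed: int) -> float:
    """Mean kappa of k-NN over a seeded stratified CV; the GA fitness."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    kappas = []
    for train, test in skf.split(x, y_idx):
        d = cdist(x[test], x[train])
        if k == 1:
            pred = y_idx[train][np.argmin(d, axis=1)]
        else:
            nearest = np.argsort(d, axis=1)[:, :k]
            pred = np.array([
                np.bincount(y_idx[train][row], minlength=n_classes).argmax()
                for row in nearest])
        kappas.append(_kappa_from_counts(y_idx[test], pred, n_classes))
    return float(np.mean(kappas))


def ga_select_bands(sset: SpectraSet, labels: list[str] | None = None,
                    config: GAConfig | None = None) -> GAResult:
    """Genetic search for the most class-discriminative wavelengths.

    Evolutionary loop: random initial subsets -> fitness (cross-validated
    1-NN kappa on the subset's wavelengths) -> elitist rank selection,
    uniform set-crossover with duplicate repair, per-gene mutation ->
    stop at the generation budget or at perfect fitness. Fitness ties are
    broken toward the lexicographically smaller wavelength set, and all
    randomness flows from the config seed.
    """
    config = config or GAConfig()
    labels = labels if labels is not None else sset.labels
    if labels is None:
        raise ValueError("labelled data required")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    class_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.asarray([class_idx[l] for l in labels])
    x = sset.values
    p = sset.n_wavelengths
    nb = config.n_bands
    if nb > p:
        raise ValueError("n_bands exceeds the number of wavelengths")
    rng = np.random.default_rng(config.seed)
    fit_seed = int(rng.integers(2 ** 31))

    cache: dict[tuple[int, ...], float] = {}

    def fitness(sol: tuple[int, ...]) -> float:
        if sol not in cache:
            cache[sol] = _cv_knn_kappa(x[:, list(sol)], y_idx, len(classes),
                                       config.cv_folds, config.knn_k, fit_seed)
        return cache[sol]

    if nb == p:
        sol = tuple(range(p))
        f = fitness(sol)
        return GAResult(sset.grid.copy(), sol, f, [f])

    def random_solution() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(p, size=nb, replace=False)))

    if config.initial_population is not None:
        population = [tuple(sorted(s)) for s in config.initial_population]
    else:
        population = [random_solution() for _ in range(config.population_size)]

    def sort_key(sol: tuple[int, ...]):
        # descending fitness; ties -> lexicographically smaller index set
        return (-fitness(sol), sol)

    trace: list[float] = []
    n_elite = max(1, int(np.ceil(config.elite_fraction * len(population))))
    for _ in range(config.generations):
        population.sort(key=sort_key)
        elite = population[:n_elite]
        trace.append(fitness(elite[0]))
        if fitness(elite[0]) >= 1.0:
            break
        children: list[tuple[int, ...]] = []
        while len(elite) + len(children) < len(population):
            pa, pb = (elite[rng.integers(len(elite))],
                      elite[rng.integers(len(elite))])
            # uniform set-crossover with duplicate repair
            genes = [pa[g] if rng.random() < 0.5 else pb[g]
                     for g in range(nb)]
            child = set()
            for g in genes:
                while g in child:
                    g = int(rng.integers(p))
                child.add(g)
            # per-gene mutation
            child_list = list(child)
            for gi in range(nb):
                if rng.random() < config.mutation_rate:
                    g = int(rng.integers(p))
                    while g in child_list:
                        g = int(rng.integers(p))
                    child_list[gi] = g
            children.append(tuple(sorted(child_list)))
        population = elite + children

    population.sort(key=sort_key)
    best = population[0]
    if not trace or fitness(best) > trace[-1]:
        trace.append(fitness(best))
    return GAResult(sset.grid[list(best)].copy(), best, fitness(best), trace)
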