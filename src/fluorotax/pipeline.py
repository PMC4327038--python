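"""Config-driven execution of the four-block chain:

    crop band -> denoise -> normalize -> transform -> classify,

evaluated with stratified k-fold cross-validation. Stateless stages
(denoising, Min-Max, SNV, derivative) are applied per spectrum; stateful
stages (GSM/SBN regressions, PCA, GA band selection, SOM/GCS training)
are fitted on the training fold only and applied to the held-out fold,
so no information leaks from test to train.

Every stochastic stage draws its seed deterministically from the chain's
master seed, so a report is byte-identical across repeated runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import classify, denoise, normalize, transform
from .evaluate import CVResult, cross_validate
from .spectra import SpectraSet, crop_band

__all__ = ["ChainConfig", "ChainError", "run_chain", "sweep_combinations",
           "SweepResult"]


class ChainError(ValueError):
    """Invalid or incompatible chain configuration."""


_DENOISE_KEYS = {
    "wma": {"window", "sigma", "span"},
    "savgol": {"window", "order"},
    "wavelet": {"wavelet", "level", "mode"},
}
_NORMALIZE_KEYS = {
    "minmax": {"a", "b"},
    "gsm": {"target_max"},
    "snv": {"mu_tot", "var_tot"},
    "sbn": {"wavelet", "level", "retained", "target_max"},
}
_TRANSFORM_KEYS = {
    "derivative": {"separation", "order"},
    "ga": {"n_bands", "population_size", "generations", "elite_fraction",
           "mutation_rate", "cv_folds"},
    "pca": {"n_components", "variance_threshold"},
}
_CLASSIFIER_KEYS = {
    "knn": {"k"},
    "som": {"rows", "cols", "epochs", "alpha_start", "alpha_end",
            "radius_start", "radius_end"},
    "gcs": {"eps_b", "eps_n", "lambda_ins", "max_cells"},
}


def _check_stage(stage: dict | None, allowed: dict[str, set],
                 name: str) -> dict | None:
    if stage is None:
        return None
    stage = dict(stage)
    method = stage.pop("method", None)
    if method not in allowed:
        raise ChainError(f"{name} method must be one of {sorted(allowed)}, "
                         f"got {method!r}")
    unknown = set(stage) - allowed[method]
    if unknown:
        raise ChainError(f"unknown {name} key(s) for {method!r}: "
                         f"{sorted(unknown)}")
    return {"method": method, **stage}


@dataclass
class ChainConfig:
    """One configuration of the four-block chain.

    Each stage is a mapping with a ``method`` key plus method parameters;
    ``denoise``, ``normalize`` and ``transform`` may be None (stage
    skipped). Unknown keys are rejected fail-fast.
    """

    classifier: dict
    denoise: dict | None = None
    normalize: dict | None = None
    transform: dict | None = None
    band: tuple[float, float] = (630.0, 730.0)
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.denoise = _check_stage(self.denoise, _DENOISE_KEYS, "denoise")
        self.normalize = _check_stage(self.normalize, _NORMALIZE_KEYS,
                                      "normalize")
        self.transform = _check_stage(self.transform, _TRANSFORM_KEYS,
                                      "transform")
        self.classifier = _check_stage(self.classifier, _CLASSIFIER_KEYS,
                                       "classifier")
        if (self.normalize and self.normalize["method"] == "sbn"
                and self.transform
                and self.transform["method"] in ("pca", "ga")):
            # fine: sbn precedes the transform. The reverse ordering is
            # impossible in this chain, so nothing else to check here.
            pass

    @classmethod
    def from_dict(cls, d: dict) -> "ChainConfig":
        d = dict(d)
        known = {"classifier", "denoise", "normalize", "transform", "band",
                 "folds", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ChainError(f"unknown config key(s): {sorted(unknown)}")
        if "classifier" not in d:
            raise ChainError("config must define a classifier")
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        return d

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        offsets = {"cv": 1, "ga": 2, "som": 3, "gcs": 4}
        ss = np.random.SeedSequence([self.seed, offsets[stage]])
        return int(ss.generate_state(1)[0] % (2 ** 31))


def _apply_denoise(cfg: dict | None, sset: SpectraSet) -> SpectraSet:
    if cfg is None:
        return sset
    method = cfg["method"]
    if method == "wma":
        if "sigma" in cfg:
            w = denoise.gaussian_window(cfg["sigma"], cfg.get("span"))
        else:
            w = denoise.square_window(cfg.get("window", 3))
        return sset.map_rows(lambda s: denoise.wma_smooth(s, w))
    if method == "savgol":
        return sset.map_rows(lambda s: denoise.savgol_smooth(
            s, cfg.get("window", 13), cfg.get("order", 2)))
    if method == "wavelet":
        return sset.map_rows(lambda s: denoise.wavelet_denoise(
            s, wavelet=cfg.get("wavelet", denoise.DEFAULT_WAVELET),
            level=cfg.get("level", denoise.DEFAULT_LEVEL),
            mode=cfg.get("mode", "soft")))
    raise ChainError(f"unknown denoise method {method!r}")


def _make_normalizer(cfg: dict | None):
    """Return fit(train) -> apply(set) for the normalization stage."""
    if cfg is None:
        return lambda train: (lambda sset: sset)
    method = cfg["method"]
    if method == "minmax":
        a, b = cfg.get("a", 0.0), cfg.get("b", 1.0)
        return lambda train: (
            lambda sset: sset.map_rows(
                lambda s: normalize.minmax_normalize(s, a, b)))
    if method == "snv":
        mu, var = cfg.get("mu_tot", 0.0), cfg.get("var_tot", 1.0)
        return lambda train: (
            lambda sset: sset.map_rows(
                lambda s: normalize.snv_normalize(s, mu, var)))
    if method == "gsm":
        tmax = cfg.get("target_max", 1.0)

        def fit(train: SpectraSet):
            model = normalize.fit_gsm(train, target_max=tmax)
            return lambda sset: sset.map_rows(
                lambda s: normalize.gsm_normalize(s, model))
        return fit
    if method == "sbn":
        kwargs = dict(
            wavelet=cfg.get("wavelet", denoise.DEFAULT_WAVELET),
            level=cfg.get("level", denoise.DEFAULT_LEVEL),
            retained=tuple(cfg.get("retained", (3, 6))),
            target_max=cfg.get("target_max", 1.0),
        )

        def fit(train: SpectraSet):
            model = normalize.fit_sbn(train, **kwargs)
            return lambda sset: sset.map_rows(
                lambda s: normalize.sbn_normalize(s, model))
        return fit
    raise ChainError(f"unknown normalize method {method!r}")


def _make_transformer(cfg: dict | None, config: ChainConfig, artifacts: dict):
    """Return fit(train) -> apply(set) -> feature matrix."""
    if cfg is None:
        return lambda train: (lambda sset: sset.values)
    method = cfg["method"]
    if method == "derivative":
        sep, order = cfg.get("separation", 1), cfg.get("order", 1)
        return lambda train: (
            lambda sset: np.vstack([
                transform.derivative(s, sep, order).intensities
                for s in sset.spectra()]))
    if method == "pca":
        def fit(train: SpectraSet):
            model = transform.fit_pca(train)
            n = cfg.get("n_components")
            if n is None:
                n = transform.n_components_for_variance(
                    model, cfg.get("variance_threshold", 99.0))
            artifacts.setdefault("n_components", []).append(int(n))
            return lambda sset: transform.pca_project(sset, model, n)
        return fit
    if method == "ga":
        def fit(train: SpectraSet):
            ga_cfg = transform.GAConfig(
                n_bands=cfg.get("n_bands", 5),
                population_size=cfg.get("population_size", 100),
                generations=cfg.get("generations", 20),
                elite_fraction=cfg.get("elite_fraction", 0.2),
                mutation_rate=cfg.get("mutation_rate", 0.1),
                cv_folds=cfg.get("cv_folds", 3),
                seed=config.stage_seed("ga"),
            )
            res = transform.ga_select_bands(train, config=ga_cfg)
            artifacts.setdefault("selected_bands", []).append(
                res.wavelengths.tolist())
            idx = list(res.indices)
            return lambda sset: sset.values[:, idx]
        return fit
    raise ChainError(f"unknown transform method {method!r}")


def _make_classifier(cfg: dict, config: ChainConfig):
    """Return train(features, labels) -> predict(features) -> labels."""
    method = cfg["method"]
    if method == "knn":
        k = cfg.get("k", 1)

        def train(x, labels):
            model = classify.fit_knn(x, labels, k=k)
            return lambda q: classify.knn_classify(model, q)
        return train
    if method == "som":
        som_cfg = classify.SOMConfig(
            rows=cfg.get("rows", 8), cols=cfg.get("cols", 4),
            epochs=cfg.get("epochs", 200),
            alpha_start=cfg.get("alpha_start", 0.5),
            alpha_end=cfg.get("alpha_end", 0.01),
            radius_start=cfg.get("radius_start"),
            radius_end=cfg.get("radius_end", 1.0),
            seed=config.stage_seed("som"),
        )

        def train(x, labels):
            model = classify.train_som(x, labels, som_cfg)
            return lambda q: classify.som_classify(model, q)
        return train
    if method == "gcs":
        gcs_cfg = classify.GCSConfig(
            eps_b=cfg.get("eps_b", 0.06), eps_n=cfg.get("eps_n", 0.002),
            lambda_ins=cfg.get("lambda_ins", 100),
            max_cells=cfg.get("max_cells", 32),
            seed=config.stage_seed("gcs"),
        )

        def train(x, labels):
            model = classify.train_gcs(x, labels, gcs_cfg)
            return lambda q: classify.gcs_classify(model, q)
        return train
    raise ChainError(f"unknown classifier {method!r}")


def run_chain(config: ChainConfig, data: SpectraSet) -> dict:
    """Run the full chain under cross-validation and build a report.

    Returns a JSON-serialisable report with the config echo, the
    fold-averaged confusion matrix, per-fold and averaged kappas, and
    per-stage artifacts (selected bands / component counts per fold).
    """
    if data.labels is None:
        raise ChainError("labelled data required")
    sset = crop_band(data, *config.band)
    sset = _apply_denoise(config.denoise, sset)

    artifacts: dict = {}
    norm_fit = _make_normalizer(config.normalize)
    trans_fit = _make_transformer(config.transform, config, artifacts)
    clf_train = _make_classifier(config.classifier, config)

    def fit_predict(train: SpectraSet, test: SpectraSet):
        apply_norm = norm_fit(train)
        train_n, test_n = apply_norm(train), apply_norm(test)
        apply_trans = trans_fit(train_n)
        x_train, x_test = apply_trans(train_n), apply_trans(test_n)
        predict = clf_train(x_train, train_n.labels)
        return predict(x_test)

    result: CVResult = cross_validate(fit_predict, sset, folds=config.folds,
                                      seed=config.stage_seed("cv"))
    report = {
        "config": config.to_dict(),
        **result.to_dict(),
        "artifacts": artifacts,
    }
    return report


@dataclass
class SweepResult:
    """Kappa grid over chain configurations, Tables-style layout."""

    table: pd.DataFrame            # rows = classifiers, cols = normalizations
    reports: list[dict] = field(default_factory=list)
    errors: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def sweep_combinations(configs: list[ChainConfig],
                       data: SpectraSet) -> SweepResult:
    """Run every chain config; tabulate kappa by classifier x normalization.

    A failing cell is recorded as NaN with its error message; the sweep
    never aborts.
    """
    if not configs:
        raise ChainError("empty config list")
    cells: dict[tuple[str, str], float] = {}
    reports, errors = [], {}
    for cfg in configs:
        row = cfg.classifier["method"]
        col = cfg.normalize["method"] if cfg.normalize else "none"
        try:
            report = run_chain(cfg, data)
            reports.append(report)
            cells[(row, col)] = report["kappa_averaged"]
        except Exception as exc:  # noqa: BLE001 - cell-level fault isolation
            cells[(row, col)] = float("nan")
            errors[f"{row}/{col}"] = f"{type(exc).__name__}: {exc}"
    rows = list(dict.fromkeys(r for r, _ in cells))
    cols = list(dict.fromkeys(c for _, c in cells))
    table = pd.DataFrame(
        [[cells.get((r, c), float("nan")) for c in cols] for r in rows],
        index=rows, columns=cols,
    )
    return SweepResult(table, reports, errors)


def report_to_json(report: dict) -> str:
    """Canonical JSON serialisation (sorted keys) of a chain report."""
    return json.dumps(report, sort_keys=True, indent=1)
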