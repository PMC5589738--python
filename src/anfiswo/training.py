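"""End-to-end training: fitness, search-space bounds, and the full pipeline.

Pipeline: fit a min-max normalizer on the training table; cluster the
normalized features with fuzzy c-means (rule count fixed or auto-selected);
build box bounds over the flat parameter vector; optionally inject the
FCM-initialized vector into the optimizer's starting population; run the
configured metaheuristic minimizing the sum of squared prediction errors on
the normalized scale, independently per target column; decode the best
vectors into per-target models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from anfiswo import anfis
from anfiswo.anfis import ANFISModel, SIGMA_MIN
from anfiswo.data_model import NormalizationTransform, SampleTable, fit_normalizer
from anfiswo.fcm import fcm_cluster, init_anfis_from_fcm, select_rule_count
from anfiswo.optimizer import ObjectiveSpec, OptimizerResult, WOAConfig, minimize

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "fitness_sse",
    "make_bounds",
    "train_anfis_wo",
    "save_trained_model",
    "load_trained_model",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Everything needed to reproduce one training run."""

    rules: int | str = "auto"         # fixed rule count, or "auto" (FCM-selected)
    optimizer: str = "woa"            # one of {"woa", "pso", "ga"}
    optimizer_config: WOAConfig = field(default_factory=WOAConfig)
    rho_margin: float = 0.1           # premise centers bounded to [0-margin, 1+margin]
    sigma_min: float = SIGMA_MIN
    sigma_max: float = 2.0
    consequent_cap: float = 10.0      # |coefficients|, |bias| <= cap (normalized units)
    seed_population_with_fcm: bool = True
    restarts: int = 1                 # independent optimizer runs; best kept
    fcm_fuzzifier: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 200
    rule_candidates: tuple[int, ...] = tuple(range(2, 11))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma_min > 0:
            raise ValueError("sigma_min must be > 0")
        if not self.consequent_cap > 0:
            raise ValueError("consequent_cap must be > 0")
        if isinstance(self.rules, str) and self.rules != "auto":
            raise ValueError("rules must be an integer or 'auto'")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass(frozen=True)
class TrainedModel:
    """One fitted model per target column, plus the fitted normalizer."""

    models: list[ANFISModel]
    transform: NormalizationTransform
    feature_names: list[str]
    target_names: list[str]
    traces: list[np.ndarray]
    config: TrainingConfig

    def __post_init__(self) -> None:
        if len(self.models) != len(self.target_names):
            raise ValueError("one model per target column required")

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predict all targets for raw (unnormalized) feature rows.

        Returns an ``N x m`` matrix on the original measurement scale.
        """
        X = self.transform.apply_features(np.asarray(features, float))
        norm = np.column_stack([anfis.predict_batch(X, mdl) for mdl in self.models])
        return self.transform.invert_targets(norm)


def fitness_sse(
    vector: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    d: int,
    c: int,
) -> float:
    """Sum of squared errors of the decoded model on (X, y), normalized scale.

    Non-finite predictions yield +inf so the optimizer never selects them.
    """
    model = anfis.decode(np.asarray(vector, float), d, c)
    pred = anfis.predict_batch(X, model)
    if not np.all(np.isfinite(pred)):
        return np.inf
    resid = np.asarray(y, float) - pred
    return float(resid @ resid)


def make_bounds(d: int, c: int, config: TrainingConfig) -> tuple[np.ndarray, np.ndarray]:
    """Box bounds over the flat parameter vector, matching the encode layout."""
    lo_rule = np.concatenate([
        np.full(d, 0.0 - config.rho_margin),
        np.full(d, config.sigma_min),
        np.full(d, -config.consequent_cap),
        [-config.consequent_cap],
    ])
    hi_rule = np.concatenate([
        np.full(d, 1.0 + config.rho_margin),
        np.full(d, config.sigma_max),
        np.full(d, config.consequent_cap),
        [config.consequent_cap],
    ])
    return np.tile(lo_rule, c), np.tile(hi_rule, c)


def train_anfis_wo(table: SampleTable, config: TrainingConfig) -> TrainedModel:
    """Train one model per target column on ``table`` (see module docstring)."""
    transform = fit_normalizer(table)
    norm = transform.apply_table(table)
    X = norm.features
    d = table.n_features

    if config.rules == "auto":
        candidates = [c for c in config.rule_candidates if c <= table.n_samples]
        if not candidates:
            raise ValueError("no feasible rule-count candidate for this sample size")
        c = select_rule_count(
            X, candidates, m=config.fcm_fuzzifier,
            tol=config.fcm_tol, max_iter=config.fcm_max_iter, seed=config.seed,
        )
    else:
        c = int(config.rules)
    if c > table.n_samples:
        raise ValueError(f"rule count {c} exceeds sample count {table.n_samples}")

    clustering = fcm_cluster(
        X, c, m=config.fcm_fuzzifier,
        tol=config.fcm_tol, max_iter=config.fcm_max_iter, seed=config.seed,
    )
    init_model = init_anfis_from_fcm(clustering, X)
    init_vector = anfis.encode(init_model)
    lower, upper = make_bounds(d, c, config)

    # one optimizer sub-seed shared by all targets, so results do not depend
    # on target column order (each target is an independent objective)
    opt_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0])

    models: list[ANFISModel] = []
    traces: list[np.ndarray] = []
    for j in range(norm.n_targets):
        y = norm.targets[:, j]
        spec = ObjectiveSpec(
            fn=lambda v, y=y: fitness_sse(v, X, y, d, c),
            lower=lower,
            upper=upper,
        )
        seeds = [init_vector] if config.seed_population_with_fcm else None
        restart_seq = np.random.SeedSequence(opt_seed)
        restart_seeds = [
            int(s.generate_state(1)[0]) for s in restart_seq.spawn(config.restarts)
        ]
        result: OptimizerResult = min(
            (
                minimize(
                    config.optimizer,
                    spec,
                    replace(config.optimizer_config, seed=rs),
                    initial_positions=seeds,
                )
                for rs in restart_seeds
            ),
            key=lambda r: r.best_fitness,
        )
        models.append(anfis.decode(result.best_position, d, c))
        traces.append(result.trace)

    return TrainedModel(
        models=models,
        transform=transform,
        feature_names=list(table.feature_names),
        target_names=list(table.target_names),
        traces=traces,
        config=config,
    )


_FORMAT_VERSION = 1


def save_trained_model(trained: TrainedModel, path) -> None:
    """Serialize to a versioned JSON text file with bit-exact parameters."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "layout": "per-rule:rho*d,sigma*d,coeffs*d,bias",
        "feature_names": trained.feature_names,
        "target_names": trained.target_names,
        "column_min": [v.hex() for v in trained.transform.column_min],
        "column_max": [v.hex() for v in trained.transform.column_max],
        "models": [
            {
                "d": m.n_inputs,
                "c": m.n_rules,
                "parameters": [v.hex() for v in anfis.encode(m)],
            }
            for m in trained.models
        ],
        "config": {
            "rules": trained.config.rules,
            "optimizer": trained.config.optimizer,
            "seed": trained.config.seed,
            "pop": trained.config.optimizer_config.n,
            "max_iter": trained.config.optimizer_config.max_iter,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_trained_model(path) -> TrainedModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format in {path}")
    transform = NormalizationTransform(
        column_min=np.array([float.fromhex(v) for v in payload["column_min"]]),
        column_max=np.array([float.fromhex(v) for v in payload["column_max"]]),
        n_features=len(payload["feature_names"]),
        column_names=payload["feature_names"] + payload["target_names"],
    )
    models = [
        anfis.decode(
            np.array([float.fromhex(v) for v in spec["parameters"]]),
            spec["d"], spec["c"],
        )
        for spec in payload["models"]
    ]
    cfg = payload["config"]
    config = TrainingConfig(
        rules=cfg["rules"],
        optimizer=cfg["optimizer"],
        optimizer_config=WOAConfig(n=cfg["pop"], max_iter=cfg["max_iter"], seed=cfg["seed"]),
        seed=cfg["seed"],
    )
    return TrainedModel(
        models=models,
        transform=transform,
        feature_names=payload["feature_names"],
        target_names=payload["target_names"],
        traces=[np.array([])] * len(models),
        config=config,
    )
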