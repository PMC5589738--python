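"""Error metrics and the two experimental protocols.

Metrics are computed on the original (denormalized) measurement scale:
``rmse = sqrt(mean((pred - actual)^2))`` and
``aapre = (100/N) * sum(|pred - actual| / |actual|)``.

Protocols: repeated seeded 70/30 random splits (per-target metrics averaged
across repeats) and K-fold cross-validation (out-of-fold predictions pooled
per target before computing metrics).  A comparison harness runs several
training configurations under byte-identical splits/folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from anfiswo.data_model import SampleTable, kfold_assign, random_split
from anfiswo.training import TrainingConfig, train_anfis_wo

__all__ = [
    "EvaluationReport",
    "rmse",
    "aapre",
    "run_random_split_experiment",
    "run_kfold_experiment",
    "compare_algorithms",
]

#: actual values with magnitude below this are excluded by the aapre guard
AAPRE_EPS = 1e-9


def rmse(pred: np.ndarray, actual: np.ndarray) -> float:
    """Root mean square error between two equal-length vectors."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {actual.shape}")
    if pred.size == 0:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((pred - actual) ** 2)))


def aapre(
    pred: np.ndarray, actual: np.ndarray, zero_guard: bool = False
) -> float:
    """Average absolute percent relative error, in percent.

    Zero denominators raise unless ``zero_guard`` is set, in which case
    terms with ``|actual| < AAPRE_EPS`` are excluded.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {actual.shape}")
    near_zero = np.abs(actual) < AAPRE_EPS
    if near_zero.any():
        if not zero_guard:
            raise ValueError(
                f"{int(near_zero.sum())} actual value(s) are (near) zero; "
                "pass zero_guard=True to exclude them"
            )
        pred = pred[~near_zero]
        actual = actual[~near_zero]
        if pred.size == 0:
            raise ValueError("all actual values excluded by the zero guard")
    return float(100.0 / pred.size * np.sum(np.abs((pred - actual) / actual)))


@dataclass(frozen=True)
class EvaluationReport:
    """Per-target and aggregate metrics for one protocol run."""

    target_names: list[str]
    rmse_per_target: np.ndarray
    aapre_per_target: np.ndarray
    n_evaluated: int
    protocol: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "rmse_per_target", np.asarray(self.rmse_per_target, float))
        object.__setattr__(self, "aapre_per_target", np.asarray(self.aapre_per_target, float))
        if np.any(self.rmse_per_target < 0) or np.any(self.aapre_per_target < 0):
            raise ValueError("metrics must be nonnegative")

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse_per_target))

    @property
    def mean_aapre(self) -> float:
        return float(np.mean(self.aapre_per_target))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": self.target_names,
                "rmse": self.rmse_per_target,
                "aapre": self.aapre_per_target,
            }
        )

    def write_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# protocol: {self.protocol}\n")
            fh.write(f"# n_evaluated: {self.n_evaluated}\n")
            self.to_frame().to_csv(fh, index=False)


def _metrics_per_target(
    pred: np.ndarray, actual: np.ndarray, zero_guard: bool
) -> tuple[np.ndarray, np.ndarray]:
    m = pred.shape[1]
    r = np.array([rmse(pred[:, j], actual[:, j]) for j in range(m)])
    a = np.array([aapre(pred[:, j], actual[:, j], zero_guard=zero_guard) for j in range(m)])
    return r, a


def run_random_split_experiment(
    table: SampleTable,
    config: TrainingConfig,
    repeats: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
    zero_guard: bool = False,
) -> EvaluationReport:
    """Train/evaluate on ``repeats`` independent seeded random splits.

    Per-target metrics are arithmetic means across the repeats, computed on
    the original measurement scale.
    """
    seed_seq = np.random.SeedSequence(seed)
    split_seeds = [int(s.generate_state(1)[0]) for s in seed_seq.spawn(repeats)]
    rmse_runs, aapre_runs, n_total = [], [], 0
    for r, split_seed in enumerate(split_seeds):
        train, test = random_split(table, train_fraction, split_seed)
        run_config = _reseed(config, split_seed)
        trained = train_anfis_wo(train, run_config)
        pred = trained.predict(test.features)
        rm, aa = _metrics_per_target(pred, test.targets, zero_guard)
        rmse_runs.append(rm)
        aapre_runs.append(aa)
        n_total += test.n_samples
    return EvaluationReport(
        target_names=list(table.target_names),
        rmse_per_target=np.mean(rmse_runs, axis=0),
        aapre_per_target=np.mean(aapre_runs, axis=0),
        n_evaluated=n_total,
        protocol=(
            f"random-split train_fraction={train_fraction} repeats={repeats} "
            f"seed={seed} optimizer={config.optimizer}"
        ),
    )


def run_kfold_experiment(
    table: SampleTable,
    config: TrainingConfig,
    k: int = 10,
    seed: int = 0,
    zero_guard: bool = False,
) -> EvaluationReport:
    """K-fold cross-validation pooling out-of-fold predictions per target."""
    folds = kfold_assign(table.n_samples, k, seed)
    pooled = np.full_like(table.targets, np.nan, dtype=float)
    for fold in range(1, k + 1):
        test_idx = folds.fold_indices(fold)
        train_idx = np.flatnonzero(folds.fold_of != fold)
        trained = train_anfis_wo(table.subset(train_idx), _reseed(config, seed + fold))
        pooled[test_idx] = trained.predict(table.features[test_idx])
    assert not np.any(np.isnan(pooled)), "every sample must be predicted once"
    rm, aa = _metrics_per_target(pooled, table.targets, zero_guard)
    return EvaluationReport(
        target_names=list(table.target_names),
        rmse_per_target=rm,
        aapre_per_target=aa,
        n_evaluated=table.n_samples,
        protocol=f"{k}-fold-cv seed={seed} optimizer={config.optimizer} pooled",
    )


def _reseed(config: TrainingConfig, seed: int) -> TrainingConfig:
    from dataclasses import replace

    return replace(
        config,
        seed=seed,
        optimizer_config=replace(config.optimizer_config, seed=seed),
    )


def compare_algorithms(
    table: SampleTable,
    configs: dict[str, TrainingConfig],
    protocol: str = "split",
    repeats: int = 10,
    train_fraction: float = 0.7,
    k: int = 10,
    seed: int = 0,
    zero_guard: bool = False,
) -> pd.DataFrame:
    """Evaluate several configurations under identical splits/folds.

    Returns a table with one row per target and two metric columns
    (``<name>_rmse``, ``<name>_aapre``) per configuration.  All
    configurations see the same split/fold seeds.
    """
    if not configs:
        raise ValueError("need at least one configuration")
    out = pd.DataFrame({"target": list(table.target_names)})
    reports = {}
    for name, config in configs.items():
        if protocol == "split":
            rep = run_random_split_experiment(
                table, config, repeats=repeats,
                train_fraction=train_fraction, seed=seed, zero_guard=zero_guard,
            )
        elif protocol == "cv":
            rep = run_kfold_experiment(table, config, k=k, seed=seed, zero_guard=zero_guard)
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
        reports[name] = rep
        out[f"{name}_rmse"] = rep.rmse_per_target
        out[f"{name}_aapre"] = rep.aapre_per_target
    out.attrs["protocol"] = {name: rep.protocol for name, rep in reports.items()}
    out.attrs["seed"] = seed
    return out
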