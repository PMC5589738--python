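"""Tabular dataset representation, CSV IO, normalization and partitioning.

A :class:`SampleTable` holds an ``N x d`` feature matrix and an ``N x m``
target matrix with column names.  Normalization is per-column min-max to
``[0, 1]`` fitted on a (training) table; the transform is invertible and is
applied unclipped to unseen data.  Splitting and fold assignment are seeded
and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleTable",
    "NormalizationTransform",
    "FoldAssignment",
    "read_table",
    "write_table",
    "fit_normalizer",
    "random_split",
    "kfold_assign",
]


@dataclass(frozen=True)
class SampleTable:
    """Validated N-sample table of d features and m targets."""

    features: np.ndarray
    targets: np.ndarray
    feature_names: list[str]
    target_names: list[str]

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        targs = np.asarray(self.targets, dtype=float)
        if feats.ndim != 2 or targs.ndim != 2:
            raise ValueError("features and targets must be 2-D arrays")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "targets", targs)
        n, d = feats.shape
        m = targs.shape[1]
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if d < 1 or m < 1:
            raise ValueError("need at least one feature and one target column")
        if targs.shape[0] != n:
            raise ValueError(
                f"feature rows ({n}) != target rows ({targs.shape[0]})"
            )
        if len(self.feature_names) != d:
            raise ValueError("feature_names length mismatch")
        if len(self.target_names) != m:
            raise ValueError("target_names length mismatch")
        for label, arr in (("features", feats), ("targets", targs)):
            if not np.all(np.isfinite(arr)):
                i, j = np.argwhere(~np.isfinite(arr))[0]
                names = self.feature_names if label == "features" else self.target_names
                raise ValueError(
                    f"non-finite value in {label} at row {i + 1}, column '{names[j]}'"
                )

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_targets(self) -> int:
        return self.targets.shape[1]

    def subset(self, indices: np.ndarray) -> "SampleTable":
        """New table containing the given rows (0-based), in the given order."""
        idx = np.asarray(indices, dtype=int)
        return SampleTable(
            self.features[idx], self.targets[idx],
            list(self.feature_names), list(self.target_names),
        )

    def to_frame(self) -> pd.DataFrame:
        data = np.hstack([self.features, self.targets])
        return pd.DataFrame(data, columns=self.feature_names + self.target_names)


def read_table(path, feature_names: list[str], target_names: list[str]) -> SampleTable:
    """Read a CSV file into a validated :class:`SampleTable`.

    Column order follows the given name lists, not the file order.  Raises
    ``ValueError`` naming the offending column or cell on any validation
    failure.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"empty table in {path}")
    wanted = list(feature_names) + list(target_names)
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    sub = df[wanted]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~sub.isna()
    if bad.any().any():
        j = [c for c in wanted if bad[c].any()][0]
        i = int(bad[j].idxmax())
        raise ValueError(
            f"non-numeric cell at row {i + 1}, column '{j}': {sub[j].iloc[i]!r}"
        )
    if numeric.isna().any().any():
        j = [c for c in wanted if numeric[c].isna().any()][0]
        i = int(numeric[j].isna().idxmax())
        raise ValueError(f"missing value at row {i + 1}, column '{j}'")
    return SampleTable(
        numeric[list(feature_names)].to_numpy(float),
        numeric[list(target_names)].to_numpy(float),
        list(feature_names),
        list(target_names),
    )


def write_table(table: SampleTable, path) -> None:
    """Write a table to CSV (comma separator, '.' decimal, header row)."""
    table.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class NormalizationTransform:
    """Per-column min-max scaling to [0, 1], fitted on one table.

    ``column_min``/``column_max`` cover feature columns first, then target
    columns, in table order.  Application is unclipped: values outside the
    fitted range map outside [0, 1].
    """

    column_min: np.ndarray
    column_max: np.ndarray
    n_features: int
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo = np.asarray(self.column_min, dtype=float)
        hi = np.asarray(self.column_max, dtype=float)
        object.__setattr__(self, "column_min", lo)
        object.__setattr__(self, "column_max", hi)
        if np.any(hi <= lo):
            j = int(np.argmax(hi <= lo))
            name = self.column_names[j] if self.column_names else f"#{j}"
            raise ValueError(f"constant column '{name}' cannot be normalized")

    # -- feature block ----------------------------------------------------
    def apply_features(self, X: np.ndarray) -> np.ndarray:
        lo = self.column_min[: self.n_features]
        hi = self.column_max[: self.n_features]
        return (np.asarray(X, float) - lo) / (hi - lo)

    def invert_features(self, X: np.ndarray) -> np.ndarray:
        lo = self.column_min[: self.n_features]
        hi = self.column_max[: self.n_features]
        return np.asarray(X, float) * (hi - lo) + lo

    # -- target block -----------------------------------------------------
    def apply_targets(self, Y: np.ndarray) -> np.ndarray:
        lo = self.column_min[self.n_features:]
        hi = self.column_max[self.n_features:]
        return (np.asarray(Y, float) - lo) / (hi - lo)

    def invert_targets(self, Y: np.ndarray) -> np.ndarray:
        lo = self.column_min[self.n_features:]
        hi = self.column_max[self.n_features:]
        return np.asarray(Y, float) * (hi - lo) + lo

    def apply_table(self, table: SampleTable) -> SampleTable:
        return SampleTable(
            self.apply_features(table.features),
            self.apply_targets(table.targets),
            list(table.feature_names),
            list(table.target_names),
        )


def fit_normalizer(table: SampleTable) -> NormalizationTransform:
    """Fit per-column min-max bounds on ``table`` (features then targets).

    Constant columns are rejected with an error naming the column.
    """
    data = np.hstack([table.features, table.targets])
    names = list(table.feature_names) + list(table.target_names)
    return NormalizationTransform(
        column_min=data.min(axis=0),
        column_max=data.max(axis=0),
        n_features=table.n_features,
        column_names=names,
    )


def random_split(
    table: SampleTable, train_fraction: float, seed: int
) -> tuple[SampleTable, SampleTable]:
    """Seeded random train/test split; train size = round(N * fraction)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = table.n_samples
    n_train = int(round(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"split of N={n} at fraction {train_fraction} leaves one side empty"
        )
    perm = np.random.default_rng(seed).permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return table.subset(train_idx), table.subset(test_idx)


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index (1..K) for each of N samples, produced by a stated seed."""

    fold_of: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fold_of, dtype=int)
        object.__setattr__(self, "fold_of", f)
        if f.min() < 1 or f.max() > self.k:
            raise ValueError("fold indices must lie in 1..K")
        counts = np.bincount(f, minlength=self.k + 1)[1:]
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes differ by more than 1")

    def fold_indices(self, fold: int) -> np.ndarray:
        """0-based sample indices belonging to ``fold`` (1-based)."""
        return np.flatnonzero(self.fold_of == fold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_index": np.arange(1, len(self.fold_of) + 1),
             "fold": self.fold_of}
        )


def kfold_assign(n: int, k: int, seed: int) -> FoldAssignment:
    """Assign N samples to K folds of near-equal size, seeded."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= K <= N, got K={k}, N={n}")
    base = np.arange(n) % k + 1        # sizes differ by at most 1
    rng = np.random.default_rng(seed)
    return FoldAssignment(fold_of=base[rng.permutation(n)], k=k, seed=seed)
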