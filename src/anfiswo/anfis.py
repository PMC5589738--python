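"""Five-layer Sugeno fuzzy inference network with Gaussian memberships.

Layers: (1) per-(rule, input) Gaussian membership ``exp(-((x-rho)/sigma)^2)``
-- note: no factor 2 in the denominator, the width difference is absorbed by
sigma; (2) rule firing strength as the product over inputs; (3) firing
normalization with a uniform fallback below ``EPS_FIRING``; (4) linear
consequents ``dot(coeffs, x) + bias``; (5) weighted sum.

A model with ``c`` rules over ``d`` inputs has ``c * (3d + 1)`` free
parameters and round-trips exactly through a flat vector with per-rule layout
``rho[1..d], sigma[1..d], coeffs[1..d], bias``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SIGMA_MIN",
    "EPS_FIRING",
    "GaussianMF",
    "ANFISModel",
    "membership_degree",
    "rule_firing",
    "normalize_firing",
    "rule_output",
    "forward",
    "encode",
    "decode",
    "predict_batch",
    "save_model",
    "load_model",
]

#: floor for membership widths (normalized input units)
SIGMA_MIN = 1e-3
#: below this total firing, layer 3 falls back to uniform rule weights
EPS_FIRING = 1e-12

_FORMAT_VERSION = 1
_LAYOUT = "per-rule:rho*d,sigma*d,coeffs*d,bias"


@dataclass(frozen=True)
class GaussianMF:
    """Gaussian membership function with center ``rho`` and width ``sigma``."""

    rho: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


def membership_degree(x: float, mf: GaussianMF) -> float:
    """Degree of membership of ``x``, in (0, 1]; equals 1 at ``x == rho``."""
    z = (x - mf.rho) / mf.sigma
    return float(np.exp(-z * z))


@dataclass(frozen=True)
class ANFISModel:
    """Rule base of ``c`` Sugeno rules over ``d`` inputs.

    ``centers``/``widths`` are ``c x d`` premise parameter grids;
    ``coeffs`` is ``c x d`` and ``bias`` length ``c`` (linear consequents).
    """

    centers: np.ndarray
    widths: np.ndarray
    coeffs: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        for name in ("centers", "widths", "coeffs"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "bias", np.atleast_1d(np.asarray(self.bias, float)))
        c, d = self.centers.shape
        if self.widths.shape != (c, d) or self.coeffs.shape != (c, d):
            raise ValueError("premise/consequent shape mismatch")
        if self.bias.shape != (c,):
            raise ValueError("bias must have one entry per rule")
        if np.any(self.widths <= 0):
            raise ValueError("all premise widths must be > 0")

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[1]

    @property
    def n_parameters(self) -> int:
        c, d = self.centers.shape
        return c * (3 * d + 1)

    def premise(self, rule: int, inp: int) -> GaussianMF:
        return GaussianMF(float(self.centers[rule, inp]), float(self.widths[rule, inp]))


def rule_firing(x: np.ndarray, model: ANFISModel) -> np.ndarray:
    """Firing strength of every rule at input ``x``: product of memberships."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_inputs,):
        raise ValueError(f"expected input of length {model.n_inputs}, got {x.shape}")
    z = (x[None, :] - model.centers) / model.widths
    return np.exp(-np.sum(z * z, axis=1))


def normalize_firing(w: np.ndarray) -> np.ndarray:
    """Rescale firing strengths to sum to 1; uniform if total < EPS_FIRING."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("firing strengths must be nonnegative")
    total = w.sum()
    if total < EPS_FIRING:
        return np.full(w.shape, 1.0 / w.size)
    return w / total


def rule_output(x: np.ndarray, coeffs: np.ndarray, bias: float) -> float:
    """Linear Sugeno consequent: dot(coeffs, x) + bias."""
    return float(np.dot(np.asarray(coeffs, float), np.asarray(x, float)) + bias)


def forward(x: np.ndarray, model: ANFISModel) -> float:
    """Full five-layer evaluation; a convex combination of rule outputs."""
    w_bar = normalize_firing(rule_firing(x, model))
    f = model.coeffs @ np.asarray(x, dtype=float) + model.bias
    return float(w_bar @ f)


def _forward_matrix(X: np.ndarray, model: ANFISModel) -> np.ndarray:
    """Vectorized forward pass over rows of ``X`` (N x d) -> length-N vector."""
    X = np.asarray(X, dtype=float)
    z = (X[:, None, :] - model.centers[None, :, :]) / model.widths[None, :, :]
    w = np.exp(-np.sum(z * z, axis=2))                      # N x c
    total = w.sum(axis=1, keepdims=True)
    w_bar = np.where(total < EPS_FIRING, 1.0 / model.n_rules, w / np.maximum(total, EPS_FIRING))
    f = X @ model.coeffs.T + model.bias[None, :]            # N x c
    return np.sum(w_bar * f, axis=1)


def predict_batch(X: np.ndarray, model: ANFISModel) -> np.ndarray:
    """Row-wise forward pass on an ``N x d`` matrix (normalized scale)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_inputs:
        raise ValueError(
            f"expected N x {model.n_inputs} feature matrix, got {X.shape}"
        )
    return _forward_matrix(X, model)


def encode(model: ANFISModel) -> np.ndarray:
    """Flatten a model to a length ``c(3d+1)`` vector (per-rule layout)."""
    blocks = np.hstack(
        [model.centers, model.widths, model.coeffs, model.bias[:, None]]
    )
    return blocks.ravel()


def decode(vector: np.ndarray, d: int, c: int) -> ANFISModel:
    """Rebuild a model from a flat vector; clamps nonpositive widths to SIGMA_MIN."""
    vector = np.asarray(vector, dtype=float)
    expected = c * (3 * d + 1)
    if vector.shape != (expected,):
        raise ValueError(
            f"expected parameter vector of length {expected} for d={d}, c={c}, "
            f"got {vector.shape}"
        )
    blocks = vector.reshape(c, 3 * d + 1)
    widths = blocks[:, d:2 * d]
    if np.any(widths < SIGMA_MIN):
        warnings.warn("clamping premise widths below SIGMA_MIN", stacklevel=2)
        widths = np.maximum(widths, SIGMA_MIN)
    return ANFISModel(
        centers=blocks[:, :d].copy(),
        widths=widths.copy(),
        coeffs=blocks[:, 2 * d:3 * d].copy(),
        bias=blocks[:, 3 * d].copy(),
    )


def save_model(model: ANFISModel, path, extra: dict | None = None) -> None:
    """Serialize a model to a versioned JSON text file (bit-exact round trip)."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "layout": _LAYOUT,
        "d": model.n_inputs,
        "c": model.n_rules,
        "parameters": [v.hex() for v in encode(model)],
    }
    if extra:
        payload.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path) -> ANFISModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format in {path}")
    vector = np.array([float.fromhex(v) for v in payload["parameters"]])
    return decode(vector, payload["d"], payload["c"])
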