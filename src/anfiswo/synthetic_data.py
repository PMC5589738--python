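"""Seeded fixture generator emulating the fish-hydrolysate study design.

Samples are spread over monthly collections across a year.  Temperature
follows a sinusoid over the month index spanning a configurable range
(default 12-38 degC) with optional jitter.  Crude protein is affinely coupled
to temperature; moisture, fat and ash vary around fixed plausible means.

Two ground-truth modes for the targets:

``explicit-anfis``
    Targets are the forward pass of a stored known rule base evaluated on
    min-max normalized features, plus Gaussian noise.  The generating model
    is returned so function-recovery experiments can compare against it.

``peaked-response``
    ``target = scale * exp(-((T - T_opt)/width)^2) * (protein/mean_protein)
    + noise`` — concentration peaks near an optimum temperature and falls at
    the seasonal extremes, scaled by protein content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from anfiswo import anfis
from anfiswo.anfis import ANFISModel
from anfiswo.data_model import SampleTable

__all__ = [
    "SyntheticSpec",
    "FEATURE_NAMES",
    "generate_environment",
    "generate_composition",
    "generate_targets",
    "generate_table",
    "write_fixture",
]

FEATURE_NAMES = ["moisture", "fat", "ash", "crude_protein", "temperature"]

#: plausible proximate-composition means and spreads (percent by mass)
_COMPOSITION_MEANS = {"moisture": 72.0, "fat": 6.0, "ash": 4.5}

# crude protein: affine in temperature, roughly 14-20% over the 12-38 degC range
_PROTEIN_INTERCEPT = 11.0
_PROTEIN_SLOPE = 0.22


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    n_samples: int = 120
    n_months: int = 12
    temp_min: float = 12.0
    temp_max: float = 38.0
    temp_jitter_sd: float = 0.0
    composition_noise_sd: float = 1.0
    mode: str = "peaked-response"     # or "explicit-anfis"
    target_noise_sd: float = 0.0
    target_names: tuple[str, ...] = ("aa_concentration",)
    t_opt: float = 28.0               # peaked mode: optimum temperature (degC)
    t_width: float = 6.0              # peaked mode: response width (degC)
    target_scale: float = 10.0        # peaked mode: peak concentration
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.temp_min < self.temp_max:
            raise ValueError("temp_min must be < temp_max")
        if self.temp_jitter_sd < 0 or self.composition_noise_sd < 0 or self.target_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.mode not in ("peaked-response", "explicit-anfis"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


def generate_environment(spec: SyntheticSpec, rng: np.random.Generator | None = None):
    """Month index (1-based) and temperature columns, length ``n_samples``.

    Temperature is a sinusoid over the month spanning [temp_min, temp_max]
    exactly when jitter is zero, plus Gaussian jitter otherwise.
    """
    rng = rng or np.random.default_rng(spec.seed)
    months = np.arange(spec.n_samples) % spec.n_months + 1
    mid = 0.5 * (spec.temp_min + spec.temp_max)
    amp = 0.5 * (spec.temp_max - spec.temp_min)
    # coldest at month 1, warmest mid-year
    temperature = mid - amp * np.cos(2.0 * np.pi * (months - 1) / spec.n_months)
    if spec.n_months % 2:  # odd cycle never reaches the warm extreme; rescale
        lo, hi = temperature.min(), temperature.max()
        temperature = spec.temp_min + (temperature - lo) * (
            (spec.temp_max - spec.temp_min) / (hi - lo)
        )
    if spec.temp_jitter_sd > 0:
        temperature = temperature + rng.normal(0.0, spec.temp_jitter_sd, spec.n_samples)
    return months, temperature


def generate_composition(
    spec: SyntheticSpec,
    temperature: np.ndarray,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Moisture, fat, ash and crude-protein columns; all strictly positive.

    Crude protein is an exact affine function of temperature when the
    composition noise is zero.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    n = len(temperature)
    sd = spec.composition_noise_sd
    columns = {
        name: np.maximum(mean + rng.normal(0.0, sd, n) if sd > 0 else np.full(n, mean), 1e-6)
        for name, mean in _COMPOSITION_MEANS.items()
    }
    protein = _PROTEIN_INTERCEPT + _PROTEIN_SLOPE * np.asarray(temperature, float)
    if sd > 0:
        protein = protein + rng.normal(0.0, 0.5 * sd, n)
    columns["crude_protein"] = np.maximum(protein, 1e-6)
    return columns


def _generator_model(d: int, rng: np.random.Generator) -> ANFISModel:
    """A random smooth rule base over [0,1]^d normalized features."""
    c = 2
    centers = rng.uniform(0.15, 0.85, size=(c, d))
    widths = rng.uniform(0.25, 0.6, size=(c, d))
    coeffs = rng.uniform(-1.0, 1.0, size=(c, d))
    bias = rng.uniform(0.0, 1.0, size=c)
    return ANFISModel(centers=centers, widths=widths, coeffs=coeffs, bias=bias)


def generate_targets(
    spec: SyntheticSpec,
    features: np.ndarray,
    rng: np.random.Generator | None = None,
):
    """Target columns for the given feature matrix, plus a ground-truth descriptor.

    Returns ``(targets, truth)`` where ``truth`` holds the generating model
    (explicit-anfis mode) or the response parameters (peaked mode) and the
    noiseless target values.
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    m = len(spec.target_names)

    if spec.mode == "explicit-anfis":
        lo = features.min(axis=0)
        hi = features.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        X01 = (features - lo) / span
        models = [_generator_model(features.shape[1], rng) for _ in range(m)]
        clean = np.column_stack([anfis.predict_batch(X01, mdl) for mdl in models])
        truth = {"mode": spec.mode, "models": models, "feature_min": lo,
                 "feature_max": hi, "clean_targets": clean}
    else:
        temperature = features[:, FEATURE_NAMES.index("temperature")]
        protein = features[:, FEATURE_NAMES.index("crude_protein")]
        response = np.exp(-(((temperature - spec.t_opt) / spec.t_width) ** 2))
        base = spec.target_scale * response * (protein / protein.mean())
        clean = np.column_stack([base for _ in range(m)])
        truth = {"mode": spec.mode, "t_opt": spec.t_opt, "t_width": spec.t_width,
                 "scale": spec.target_scale, "clean_targets": clean}

    targets = clean.copy()
    if spec.target_noise_sd > 0:
        targets = targets + rng.normal(0.0, spec.target_noise_sd, size=(n, m))
    return targets, truth


def generate_table(spec: SyntheticSpec):
    """Full synthetic :class:`SampleTable` plus the ground-truth descriptor.

    All randomness flows from ``spec.seed`` through fixed per-stage
    sub-streams, so equal specs yield identical tables.
    """
    months, temperature = generate_environment(spec)
    composition = generate_composition(spec, temperature)
    features = np.column_stack(
        [composition["moisture"], composition["fat"], composition["ash"],
         composition["crude_protein"], temperature]
    )
    targets, truth = generate_targets(spec, features)
    table = SampleTable(
        features=features,
        targets=targets,
        feature_names=list(FEATURE_NAMES),
        target_names=list(spec.target_names),
    )
    truth["months"] = months
    return table, truth


def write_fixture(spec: SyntheticSpec, path, truth_path=None):
    """Write the synthetic table to CSV (and the clean targets as a sidecar).

    Values are written as full-precision ``repr`` floats so regenerating with
    the same spec yields byte-identical files.
    """
    table, truth = generate_table(spec)
    df = table.to_frame()
    df.insert(0, "month", truth["months"])
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    if truth_path is not None:
        clean = pd.DataFrame(
            truth["clean_targets"],
            columns=[f"clean_{t}" for t in spec.target_names],
        )
        clean.to_csv(truth_path, index=False, float_format=lambda v: repr(float(v)))
    return table, truth
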