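"""Synthetic daily-diary data generator with person-specific VAR(1) dynamics.

Each person i receives a mean vector and a lag-1 coefficient matrix drawn
around population values (mutually independent — "orthogonal" — random
effects), then a latent series

    y_t = mu_i + B_i' (y_{t-1} - mu_i) + eps_t,   eps_t ~ N(0, innovation_cov)

is simulated after a burn-in, optionally rounded and clipped onto the Likert
observation range.  ``fixed_temporal[i, j]`` is the effect of variable i at
day t-1 on variable j at day t, so the transition uses the transpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from esmnet.dataset import DEFAULT_VARIABLE_NAMES, EsmDataset

BURN_IN = 100
STATIONARY_RETRY_CAP = 1000


class StationarityError(ValueError):
    """Raised when a temporal coefficient matrix is not stationary."""


@dataclass(frozen=True)
class VarParameters:
    """Ground-truth generative quantities for a multilevel VAR(1) process."""

    fixed_temporal: np.ndarray
    fixed_means: np.ndarray
    random_slope_sd: np.ndarray
    random_mean_sd: np.ndarray
    innovation_cov: np.ndarray
    likert_bounds: tuple[int, int] = (1, 7)
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_temporal", np.asarray(self.fixed_temporal, dtype=float))
        object.__setattr__(self, "fixed_means", np.asarray(self.fixed_means, dtype=float))
        object.__setattr__(self, "random_slope_sd", np.asarray(self.random_slope_sd, dtype=float))
        object.__setattr__(self, "random_mean_sd", np.asarray(self.random_mean_sd, dtype=float))
        object.__setattr__(self, "innovation_cov", np.asarray(self.innovation_cov, dtype=float))
        if not self.variable_names:
            p = self.fixed_temporal.shape[0]
            names = DEFAULT_VARIABLE_NAMES if p == len(DEFAULT_VARIABLE_NAMES) else [f"v{i + 1}" for i in range(p)]
            object.__setattr__(self, "variable_names", list(names))
        self.validate()

    @property
    def n_vars(self) -> int:
        return int(self.fixed_temporal.shape[0])

    def validate(self) -> None:
        p = self.n_vars
        if self.fixed_temporal.shape != (p, p):
            raise ValueError("fixed_temporal must be square")
        for name, arr, shape in (
            ("fixed_means", self.fixed_means, (p,)),
            ("random_slope_sd", self.random_slope_sd, (p, p)),
            ("random_mean_sd", self.random_mean_sd, (p,)),
            ("innovation_cov", self.innovation_cov, (p, p)),
        ):
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
        if spectral_radius(self.fixed_temporal) >= 1.0:
            raise StationarityError(
                f"fixed_temporal spectral radius {spectral_radius(self.fixed_temporal):.4f} >= 1"
            )
        if (self.random_slope_sd < 0).any() or (self.random_mean_sd < 0).any():
            raise ValueError("random-effect SDs must be nonnegative")
        if not np.allclose(self.innovation_cov, self.innovation_cov.T):
            raise ValueError("innovation_cov must be symmetric")
        try:
            np.linalg.cholesky(self.innovation_cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("innovation_cov must be positive definite") from exc
        lo, hi = self.likert_bounds
        if not (float(lo) < float(hi)):
            raise ValueError("likert_bounds must satisfy low < high")
        if len(self.variable_names) != p:
            raise ValueError("variable_names length must match n_vars")

    # -- YAML round-trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "variable_names": list(self.variable_names),
            "fixed_temporal": self.fixed_temporal.tolist(),
            "fixed_means": self.fixed_means.tolist(),
            "random_slope_sd": self.random_slope_sd.tolist(),
            "random_mean_sd": self.random_mean_sd.tolist(),
            "innovation_cov": self.innovation_cov.tolist(),
            "likert_bounds": list(self.likert_bounds),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VarParameters":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            fixed_temporal=np.asarray(payload["fixed_temporal"], dtype=float),
            fixed_means=np.asarray(payload["fixed_means"], dtype=float),
            random_slope_sd=np.asarray(payload["random_slope_sd"], dtype=float),
            random_mean_sd=np.asarray(payload["random_mean_sd"], dtype=float),
            innovation_cov=np.asarray(payload["innovation_cov"], dtype=float),
            likert_bounds=tuple(payload.get("likert_bounds", (1, 7))),
            variable_names=list(payload.get("variable_names", [])),
        )

    @classmethod
    def study_default(cls) -> "VarParameters":
        """An 8-symptom generator echoing the study's reported scale.

        Cross-lagged entries lie in the reported 0.04-0.33 range, with the
        sleep-disturbance row carrying the dominant outgoing effects and
        autocorrelations near 0.15.  Means match the reported per-symptom
        sample means.
        """
        p = 8
        B = np.zeros((p, p))
        np.fill_diagonal(B, [0.15, 0.12, 0.10, 0.10, 0.10, 0.12, 0.10, 0.15])
        # index order: worry, unc_worry, restless, fatigue, concentr, irrit, muscle, sleep
        cross = {
            (0, 1): 0.10, (1, 0): 0.08,                       # worry <-> uncontrollable worry
            (3, 6): 0.05, (6, 3): 0.04,                       # fatigue <-> muscle tension
            (2, 3): 0.08, (3, 2): 0.08,                       # restlessness <-> fatigue
            (2, 4): 0.06, (4, 2): 0.06,                       # restlessness <-> concentrating
            (3, 4): 0.09, (4, 3): 0.08,                       # fatigue <-> concentrating
            (1, 2): 0.06, (4, 5): 0.07, (0, 4): 0.04,
            (7, 0): 0.12, (7, 1): 0.19, (7, 2): 0.12,         # sleep -> everything
            (7, 3): 0.33, (7, 4): 0.23, (7, 5): 0.19, (7, 6): 0.15,
        }
        for (i, j), w in cross.items():
            B[i, j] = w
        means = np.array([3.91, 3.67, 3.43, 4.02, 3.65, 3.03, 2.82, 3.73])
        slope_sd = np.full((p, p), 0.05)
        mean_sd = np.full(p, 0.8)
        cov = 1.5 * (0.7 * np.eye(p) + 0.3 * np.ones((p, p)))
        return cls(B, means, slope_sd, mean_sd, cov, (1, 7))


def spectral_radius(matrix: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(matrix, dtype=float)))))


def discretize_likert(values: np.ndarray, bounds: tuple[int, int]) -> np.ndarray:
    """Round half-away-from-zero, then clip into the inclusive bounds.

    Missing (NaN) entries stay missing.  Total on reals.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy low < high")
    arr = np.asarray(values, dtype=float)
    rounded = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    out = np.clip(rounded, lo, hi)
    out = np.where(np.isnan(arr), np.nan, out)
    return out


def _draw_person_matrix(params: VarParameters, rng: np.random.Generator) -> np.ndarray:
    """Draw one person's temporal matrix, rejecting non-stationary draws."""
    if not params.random_slope_sd.any():
        return params.fixed_temporal.copy()
    for _ in range(STATIONARY_RETRY_CAP):
        B = params.fixed_temporal + params.random_slope_sd * rng.standard_normal(
            (params.n_vars, params.n_vars)
        )
        if spectral_radius(B) < 1.0:
            return B
    raise StationarityError(
        f"no stationary person matrix found in {STATIONARY_RETRY_CAP} draws"
    )


def simulate_dataset(
    params: VarParameters,
    n_persons: int,
    n_days: int,
    seed: int,
    discretize: bool = True,
) -> EsmDataset:
    """Simulate a complete daily panel from the hierarchical VAR(1) model.

    A 100-step burn-in precedes the retained days so the first retained day
    is approximately a draw from each person's stationary distribution.
    Identical ``(params, seed)`` give identical output.
    """
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    params.validate()
    rng = np.random.default_rng(seed)
    p = params.n_vars
    chol = np.linalg.cholesky(params.innovation_cov)

    frames = []
    for person in range(1, n_persons + 1):
        mu = params.fixed_means + params.random_mean_sd * rng.standard_normal(p)
        B_t = _draw_person_matrix(params, rng).T  # y_t = mu + B' (y_{t-1}-mu) + eps
        eps = rng.standard_normal((BURN_IN + n_days, p)) @ chol.T
        dev = np.zeros(p)
        series = np.empty((n_days, p))
        for t in range(BURN_IN + n_days):
            dev = B_t @ dev + eps[t]
            if t >= BURN_IN:
                series[t - BURN_IN] = mu + dev
        if discretize:
            series = discretize_likert(series, params.likert_bounds)
        frame = pd.DataFrame(series, columns=params.variable_names)
        frame.insert(0, "day", np.arange(1, n_days + 1))
        frame.insert(0, "person_id", person)
        frame["attention_pass"] = True
        frames.append(frame)

    data = pd.concat(frames, ignore_index=True)
    bounds = params.likert_bounds if discretize else None
    return EsmDataset(data, list(params.variable_names), bounds)


def inject_missingness(dataset: EsmDataset, rate: float, seed: int) -> EsmDataset:
    """Set each observed symptom cell to missing independently with ``rate``.

    Day rows are never deleted (MCAR at the cell level); reproducible for a
    fixed seed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    values = out.data[out.variable_names].to_numpy(dtype=float)
    mask = rng.random(values.shape) < rate
    values[mask] = np.nan
    out.data[out.variable_names] = values
    return out
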