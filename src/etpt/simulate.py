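"""Labelled zero-inflated benchmark generators.

Four generative models produce nonnegative, equal-length series with known
group structure, each built by zero-truncating a latent process (negative
latent values are replaced by exact zeros), except the count model which is
zero-inflated by construction:

* Model 1 — nonstationary AR(2) whose lag-1 coefficient switches abruptly in
  a middle regime (t = 54..128); the two groups differ only inside that
  regime (phi1 = -0.9 vs 1.6).  About half the observations are zero because
  the latent process is mean-zero Gaussian.
* Model 2 — AR(2) with a slowly varying lag-1 coefficient
  -0.8[1 - a cos(pi t / T)]; the groups differ in the modulation depth a
  (0.7 vs 0.001 in case "a", 0.7 vs 0.1 in the harder case "b").
* Model 3 — noisy block (piecewise-constant) signals with five jumps of
  random heights summing to zero; four groups differ in where the jump
  locations concentrate (xi_j ~ U((g-1)/5, (g+1)/5)).
* Model 4 — zero-inflated Poisson counts: each series has a structural-zero
  probability omega_i ~ U(0.4, 0.7) and a Poisson rate lambda_i drawn from
  N(mu_i, sigma^2), with mu_i ~ U(3, 4) in group 1 and U(2, 10) in group 2.

AR recursions start from zero and discard a 200-step burn-in so the reported
stretch does not depend on initial conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

from .io import TimeSeriesSet

__all__ = [
    "Model1Spec", "Model2Spec", "Model3Spec", "Model4Spec", "SimulationSpec",
    "zero_truncate", "simulate_model", "zero_ratio", "spec_from_key",
]

BURN_IN = 200
_LAMBDA_FLOOR = 0.01


@dataclass(frozen=True)
class Model1Spec:
    """Abrupt-change AR(2); two groups, regime boundaries at t=54 and t=128."""
    n_per_group: int = 100
    t_len: int = 500
    change_points: tuple[int, int] = (54, 128)
    phi1: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.8, -0.9, 0.8), (0.8, 1.6, 0.8))
    phi2: float = -0.81
    noise_sd: float = 1.0


@dataclass(frozen=True)
class Model2Spec:
    """Slowly varying AR(2); modulation depths per group depend on the case."""
    case: Literal["a", "b"] = "a"
    n_per_group: int = 100
    t_len: int = 500
    noise_sd: float = 1.0

    @property
    def modulation(self) -> tuple[float, float]:
        return (0.7, 0.001) if self.case == "a" else (0.7, 0.1)


@dataclass(frozen=True)
class Model3Spec:
    """Noisy blocks; four groups distinguished by jump-location windows."""
    n_per_group: int = 100
    t_len: int = 500
    n_groups: int = 4
    jump_scale: float = 20.0
    noise_sd: float = 3.0


@dataclass(frozen=True)
class Model4Spec:
    """Zero-inflated Poisson counts; two groups differ in the rate's mean range."""
    n_per_group: int = 100
    t_len: int = 500
    sigma: float = 0.1
    mu_range_group1: tuple[float, float] = (3.0, 4.0)
    mu_range_group2: tuple[float, float] = (2.0, 10.0)
    omega_range: tuple[float, float] = (0.4, 0.7)


SimulationSpec = Union[Model1Spec, Model2Spec, Model3Spec, Model4Spec]


def zero_truncate(latent: np.ndarray) -> np.ndarray:
    """Replace negative latent values by exact zeros (elementwise max with 0)."""
    return np.maximum(np.asarray(latent, dtype=float), 0.0)


def _ar2(phi1_path: np.ndarray, phi2: float, n: int, t_len: int,
         noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Simulate n AR(2) paths with a (burn-in extended) lag-1 coefficient path."""
    total = BURN_IN + t_len
    coef = np.concatenate([np.full(BURN_IN, phi1_path[0]), phi1_path])
    y = np.zeros((n, total + 2))
    eps = rng.normal(0.0, noise_sd, size=(n, total))
    for s in range(total):
        y[:, s + 2] = coef[s] * y[:, s + 1] + phi2 * y[:, s] + eps[:, s]
    return y[:, 2 + BURN_IN:]


def _simulate_model1(spec: Model1Spec, rng: np.random.Generator):
    t = np.arange(1, spec.t_len + 1)
    cp1, cp2 = spec.change_points
    groups = []
    for g in range(2):
        a, b, c = spec.phi1[g]
        phi1_path = np.where(t < cp1, a, np.where(t <= cp2, b, c))
        groups.append(_ar2(phi1_path, spec.phi2, spec.n_per_group,
                           spec.t_len, spec.noise_sd, rng))
    return np.vstack(groups), np.repeat([0, 1], spec.n_per_group)


def _simulate_model2(spec: Model2Spec, rng: np.random.Generator):
    t = np.arange(1, spec.t_len + 1)
    groups = []
    for a in spec.modulation:
        phi1_path = -0.8 * (1.0 - a * np.cos(np.pi * t / spec.t_len))
        groups.append(_ar2(phi1_path, -0.81, spec.n_per_group,
                           spec.t_len, spec.noise_sd, rng))
    return np.vstack(groups), np.repeat([0, 1], spec.n_per_group)


def _simulate_model3(spec: Model3Spec, rng: np.random.Generator):
    # One height vector h per dataset and one jump-location vector xi per
    # group: groups share the block heights and differ in where the jumps
    # fall, so every series in a group is the same signal plus noise.
    t_frac = (np.arange(1, spec.t_len + 1) - 1) / spec.t_len
    signs = np.array([-1.0, 1.0, -1.0, 1.0])
    h = np.empty(5)
    h[:4] = signs * rng.uniform(0.0, spec.jump_scale, size=4)
    h[4] = -h[:4].sum()  # enforce sum-to-zero
    rows, labels = [], []
    for g in range(spec.n_groups):
        lo, hi = g / 5.0, (g + 2) / 5.0
        xi = rng.uniform(lo, hi, size=5)
        signal = (h[:, None] * (1.0 + np.sign(t_frac[None, :] - xi[:, None])) / 2.0).sum(axis=0)
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_per_group, spec.t_len))
        rows.append(signal[None, :] + noise)
        labels.extend([g] * spec.n_per_group)
    return np.vstack(rows), np.asarray(labels)


def _simulate_model4(spec: Model4Spec, rng: np.random.Generator):
    rows, labels = [], []
    for g, (lo, hi) in enumerate([spec.mu_range_group1, spec.mu_range_group2]):
        mu = rng.uniform(lo, hi, size=spec.n_per_group)
        lam = np.maximum(rng.normal(mu, spec.sigma), _LAMBDA_FLOOR)
        omega = rng.uniform(*spec.omega_range, size=spec.n_per_group)
        counts = rng.poisson(lam[:, None], size=(spec.n_per_group, spec.t_len))
        structural = rng.random((spec.n_per_group, spec.t_len)) < omega[:, None]
        rows.append(np.where(structural, 0, counts).astype(float))
        labels.extend([g] * spec.n_per_group)
    return np.vstack(rows), np.asarray(labels)


def simulate_model(spec: SimulationSpec, seed: int | None = None,
                   rng: np.random.Generator | None = None
                   ) -> tuple[TimeSeriesSet, np.ndarray]:
    """Generate one labelled dataset from a model spec.

    Returns the zero-truncated (Models 1-3) or ZIP-emitted (Model 4) series
    and the true 0-based group labels.  Deterministic given ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(spec, Model1Spec):
        latent, labels = _simulate_model1(spec, rng)
    elif isinstance(spec, Model2Spec):
        latent, labels = _simulate_model2(spec, rng)
    elif isinstance(spec, Model3Spec):
        latent, labels = _simulate_model3(spec, rng)
    elif isinstance(spec, Model4Spec):
        values, labels = _simulate_model4(spec, rng)
        return TimeSeriesSet(values), labels
    else:
        raise TypeError(f"unknown simulation spec {type(spec).__name__}")
    return TimeSeriesSet(zero_truncate(latent)), labels


def zero_ratio(data: TimeSeriesSet) -> float:
    """Average over series of the fraction of exactly-zero observations."""
    obs = ~data.missing_mask
    per_series = (np.where(obs, data.values == 0.0, False).sum(axis=1)
                  / np.maximum(obs.sum(axis=1), 1))
    return float(per_series.mean())


_MODEL_KEYS = {"1", "2a", "2b", "3", "4"}


def spec_from_key(model: str, n_per_group: int = 100, t_len: int = 500,
                  sigma: float = 0.1) -> SimulationSpec:
    """Build a spec from a short model key: one of 1, 2a, 2b, 3, 4."""
    model = str(model).lower()
    if model == "1":
        return Model1Spec(n_per_group=n_per_group, t_len=t_len)
    if model in {"2a", "2b"}:
        return Model2Spec(case=model[1], n_per_group=n_per_group, t_len=t_len)
    if model == "3":
        return Model3Spec(n_per_group=n_per_group, t_len=t_len)
    if model == "4":
        return Model4Spec(n_per_group=n_per_group, t_len=t_len, sigma=sigma)
    raise ValueError(f"unknown model key {model!r}; expected one of {sorted(_MODEL_KEYS)}")
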