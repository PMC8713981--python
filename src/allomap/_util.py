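"""Shared helpers: deterministic child seeding and input validation."""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive a stage-specific generator from a single root seed.

    The child stream is keyed by a CRC of the stage name so that adding or
    reordering stages never perturbs another stage's draws.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


def check_finite(name: str, *values: float) -> None:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite value {values!r}")


def check_prob(name: str, value: float) -> None:
    check_finite(name, value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} must lie in [0, 1]")


def check_positive(name: str, value: float) -> None:
    check_finite(name, value)
    if value <= 0:
        raise ValueError(f"{name}={value} must be positive")


def nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance mean + dispersion*mean**2.

    Implemented as a gamma-Poisson mixture so the mean array can be arbitrary;
    dispersion 0 degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError(f"dispersion={dispersion} must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)
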