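"""Shared helpers: seed substreams, shifted-lognormal RTs, z-scoring."""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a named, stable substream from a master seed.

    The substream depends only on (master_seed, stage name), so adding a new
    stage to a pipeline never perturbs the draws of existing stages.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.SeedSequence(int(master_seed), spawn_key=(key,))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


@dataclass(frozen=True)
class RTSpec:
    """Target mean/SD (ms) for a shifted-lognormal reaction-time draw.

    ``shift_ms`` is a hard lower bound below which no response can occur
    (neuromotor floor); the lognormal component above it is parameterized to
    hit the requested mean and SD exactly.
    """

    mean_ms: float
    sd_ms: float
    shift_ms: float = 100.0

    def __post_init__(self):
        if not (self.mean_ms > self.shift_ms and self.sd_ms > 0):
            raise ValueError("RTSpec requires mean_ms > shift_ms and sd_ms > 0")


def draw_rts(spec: RTSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw shifted-lognormal RTs with the spec's mean and SD."""
    m = spec.mean_ms - spec.shift_ms
    sigma2 = np.log1p(spec.sd_ms**2 / m**2)
    mu = np.log(m) - sigma2 / 2.0
    return spec.shift_ms + rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def zscore(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    m = np.nanmean(x)
    s = np.nanstd(x, ddof=ddof)
    if not np.isfinite(s) or s == 0:
        raise ValueError("cannot z-score a constant (or empty) vector")
    return (x - m) / s
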