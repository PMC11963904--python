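"""Synthetic blood-gas study generator.

Emulates a study in which the dissociation-curve model is its own ground
truth except for a hidden displacement term

    a4(p) = 0.25 * cos(2 * pi * ln(p)) - 0.55,

so the discrepancy between the a4 = 0 baseline and the data is known exactly.
Observations are the noiseless combined saturations plus additive Gaussian
noise scaled to a stated fraction of the data's standard deviation, and
low-saturation points are excluded to mimic the arterial-range truncation of
real intensive-care data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .sa_model import sa_predict_matrix

__all__ = [
    "SyntheticStudyConfig",
    "SyntheticDataset",
    "ground_truth_a4",
    "sample_inputs",
    "generate_dataset",
]

#: Column order of the shared (n, 5) input matrix.
INPUT_COLUMNS = ("pH", "PCO2", "FMetHb", "T", "p")


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study conditions: sizes, noise ladder, sampling ranges, truncation.

    Input ranges are uniform (log-uniform for p) over clinically plausible
    arterial values; ``low_s_cutoff`` rejects draws whose noiseless combined
    saturation falls below the threshold, since patients with low saturations
    are rarely observed.
    """

    n_train: int = 200
    n_val: int = 50
    noise_levels: Tuple[float, ...] = (0.02, 0.05, 0.10, 0.15)
    seed: int = 0
    low_s_cutoff: float = 0.35
    pH_range: Tuple[float, float] = (7.0, 7.6)
    PCO2_range: Tuple[float, float] = (3.0, 9.0)     # kPa
    FMetHb_range: Tuple[float, float] = (0.0, 0.02)
    T_range: Tuple[float, float] = (35.0, 39.0)      # degC
    p_range: Tuple[float, float] = (2.0, 15.0)       # kPa, sampled log-uniformly

    def __post_init__(self) -> None:
        if self.n_train <= 0 or self.n_val <= 0:
            raise ValueError("n_train and n_val must be positive")
        if any(nl < 0 for nl in self.noise_levels):
            raise ValueError("noise levels must be non-negative")


@dataclass
class SyntheticDataset:
    """Inputs, noiseless and noisy targets, and the hidden a4 values."""

    X: np.ndarray            # (n, 5) inputs [pH, PCO2, FMetHb, T, p]
    s_true: np.ndarray       # noiseless combined saturation
    s_obs: np.ndarray        # noisy observations, clipped into (0, 1)
    a4_true: np.ndarray      # hidden displacement at each row
    noise_sd: float          # the sigma actually used
    split: np.ndarray        # "train" / "val" per row

    @property
    def train_mask(self) -> np.ndarray:
        return self.split == "train"

    @property
    def val_mask(self) -> np.ndarray:
        return self.split == "val"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(INPUT_COLUMNS))
        df["s_obs"] = self.s_obs
        df["s_true"] = self.s_true
        df["a4_true"] = self.a4_true
        df["split"] = self.split
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, noise_sd: float = float("nan")) -> "SyntheticDataset":
        X = df[list(INPUT_COLUMNS)].to_numpy(dtype=float)
        return cls(
            X=X,
            s_true=df["s_true"].to_numpy(dtype=float),
            s_obs=df["s_obs"].to_numpy(dtype=float),
            a4_true=df["a4_true"].to_numpy(dtype=float),
            noise_sd=noise_sd,
            split=df["split"].to_numpy(dtype=str),
        )


def ground_truth_a4(p):
    """Hidden displacement term of the synthetic study: 0.25 cos(2 pi ln p) - 0.55.

    Oscillates in ln p between -0.80 and -0.30; everywhere negative, so the
    a4 = 0 baseline systematically underestimates the observed saturations.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("p must be positive")
    out = 0.25 * np.cos(2.0 * np.pi * np.log(p)) - 0.55
    return float(out) if out.ndim == 0 else out


def sample_inputs(
    config: SyntheticStudyConfig, n: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw n input rows, rejecting those with low noiseless saturation.

    pH, PCO2, FMetHb and T are uniform over their ranges; p is log-uniform.
    Rows whose ground-truth (hidden-a4) saturation falls below
    ``config.low_s_cutoff`` are resampled.  When ``rng`` is omitted a fresh
    generator is built from ``config.seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    n_kept = 0
    total_drawn = 0
    while n_kept < n:
        m = max(n - n_kept, 16)
        batch = np.column_stack(
            [
                rng.uniform(*config.pH_range, m),
                rng.uniform(*config.PCO2_range, m),
                rng.uniform(*config.FMetHb_range, m),
                rng.uniform(*config.T_range, m),
                np.exp(rng.uniform(np.log(config.p_range[0]), np.log(config.p_range[1]), m)),
            ]
        )
        s = sa_predict_matrix(batch, a4_override=ground_truth_a4(batch[:, 4]))
        keep = batch[s >= config.low_s_cutoff]
        rows.append(keep)
        n_kept += len(keep)
        total_drawn += m
        if total_drawn > 100 * n and n_kept < 0.01 * total_drawn:
            raise RuntimeError(
                "rejection rate above 99%; low_s_cutoff is incompatible with the input ranges"
            )
    return np.concatenate(rows, axis=0)[:n]


def generate_dataset(
    config: SyntheticStudyConfig, noise_level: float, seed: int | None = None
) -> SyntheticDataset:
    """Generate one train+validation dataset at the given noise level.

    The noise standard deviation is ``noise_level`` times the standard
    deviation of the noiseless saturations over the whole generated set;
    noisy values are clipped into [1e-3, 1 - 1e-3] so downstream logit
    transforms stay finite.  Pure function of (config, noise_level, seed).
    """
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_train + config.n_val
    X = sample_inputs(config, n, rng)
    a4 = ground_truth_a4(X[:, 4])
    s_true = sa_predict_matrix(X, a4_override=a4)
    noise_sd = float(noise_level * np.std(s_true))
    s_obs = s_true + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else s_true.copy()
    s_obs = np.clip(s_obs, 1e-3, 1.0 - 1e-3)
    split = np.array(["train"] * config.n_train + ["val"] * config.n_val)
    return SyntheticDataset(
        X=X, s_true=s_true, s_obs=s_obs, a4_true=a4, noise_sd=noise_sd, split=split
    )
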