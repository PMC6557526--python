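"""Synthetic uptake datasets with the structure of the Caco-2 experiments.

The wet-lab measurements behind the models are radiotracer uptake
time-series: two sequential 15-min challenges at 20 μM apical iron,
cumulative cell+basolateral uptake sampled at 3, 6, 9, 12 and 15 min, in
triplicate. This module simulates either model through that protocol and
decorates the noise-free curves with replicate measurement noise, so the
fitting, validation and sensitivity stages are testable without the
original data. Multiplicative Gaussian noise with a 20% coefficient of
variation is the default — a stand-in for the (graphically reported)
replicate scatter, not a measured value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import REQUIRED_COLUMNS, UptakeDataset
from .model_core import CellGeometry, ChallengeProtocol
from .simulation import run_protocol, uptake_series

__all__ = [
    "NoiseModel",
    "generate_uptake_dataset",
    "mucosal_block_summary",
    "MucosalBlockSummary",
    "read_uptake_table",
    "write_uptake_table",
]


@dataclass(frozen=True)
class NoiseModel:
    """Replicate measurement noise applied to noise-free uptake values.

    ``multiplicative-gaussian`` scales each value by (1 + cv·N(0,1));
    ``additive-gaussian`` adds sd·N(0,1) pmol. Draws are clamped at zero
    (a radioactivity count cannot be negative).
    """

    kind: str = "multiplicative-gaussian"
    cv: float = 0.20
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative-gaussian", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0 or self.sd < 0:
            raise ValueError("noise magnitude must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, float)
        if self.kind == "multiplicative-gaussian":
            noisy = values * (1.0 + self.cv * rng.standard_normal(values.shape))
        else:
            noisy = values + self.sd * rng.standard_normal(values.shape)
        return np.clip(noisy, 0.0, None)


def generate_uptake_dataset(
    model: str,
    params,
    geometry: CellGeometry,
    protocol: ChallengeProtocol,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> UptakeDataset:
    """Simulate the protocol and sample noisy replicate uptake curves.

    All randomness flows from ``noise.seed``; the same seed reproduces
    the dataset bit-identically. Noise is independent per replicate and
    per (challenge, time) sample.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(noise.seed)

    traj = run_protocol(model, params, geometry, protocol, rtol=rtol, atol=atol)
    rows = []
    for c_idx, challenge in enumerate(protocol, start=1):
        series = uptake_series(traj, geometry, c_idx)
        clean = np.interp(challenge.sampling_times, series.times, series.uptake_pmol)
        for rep in range(n_replicates):
            noisy = noise.apply(clean, rng)
            for t, u in zip(challenge.sampling_times, noisy):
                rows.append(
                    {"challenge": c_idx, "time_min": t, "replicate": rep, "uptake_pmol": u}
                )
    return UptakeDataset(
        pd.DataFrame(rows),
        metadata={
            "provenance": "synthetic",
            "model": model,
            "seed": noise.seed,
            "noise_kind": noise.kind,
            "noise_cv": noise.cv,
            "noise_sd": noise.sd,
            "fe_chg": [c.fe_chg for c in protocol],
        },
    )


@dataclass
class MucosalBlockSummary:
    """Reduction of uptake between the first and a later challenge.

    ``per_time`` holds, per sampling time: the mean cumulative uptake of
    each challenge, reduction% = 100·(u1 − u2)/u1, and fold = u1/u2.
    Because uptake is cumulative, the windowed fold ratio over the first
    w minutes is just the fold at t = w.
    """

    per_time: pd.DataFrame
    challenge_pair: tuple[int, int] = (1, 2)

    def fold(self, time_min: float) -> float:
        row = self.per_time[self.per_time["time_min"] == time_min]
        if row.empty:
            raise KeyError(f"no sampling time {time_min} in summary")
        return float(row["fold"].iloc[0])

    def reduction_pct(self, time_min: float) -> float:
        row = self.per_time[self.per_time["time_min"] == time_min]
        if row.empty:
            raise KeyError(f"no sampling time {time_min} in summary")
        return float(row["reduction_pct"].iloc[0])

    def uptake(self, challenge: int, time_min: float) -> float:
        col = {self.challenge_pair[0]: "mean_first", self.challenge_pair[1]: "mean_second"}[
            challenge
        ]
        row = self.per_time[self.per_time["time_min"] == time_min]
        if row.empty:
            raise KeyError(f"no sampling time {time_min} in summary")
        return float(row[col].iloc[0])


def mucosal_block_summary(
    dataset: UptakeDataset, challenges: tuple[int, int] = (1, 2)
) -> MucosalBlockSummary:
    """Per-time mucosal-block statistics between two challenges."""
    c1, c2 = challenges
    have = set(dataset.challenges())
    if not {c1, c2} <= have:
        raise ValueError(f"dataset lacks challenges {challenges}; has {sorted(have)}")
    means = dataset.means([c1, c2]).pivot(index="time_min", columns="challenge",
                                          values="uptake_pmol")
    means = means.dropna()
    u1 = means[c1].to_numpy()
    u2 = means[c2].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        reduction = np.where(u1 > 0, 100.0 * (u1 - u2) / u1, np.nan)
        fold = np.where(u2 > 0, u1 / u2, np.nan)
    table = pd.DataFrame(
        {
            "time_min": means.index.to_numpy(),
            "mean_first": u1,
            "mean_second": u2,
            "reduction_pct": reduction,
            "fold": fold,
        }
    )
    return MucosalBlockSummary(per_time=table, challenge_pair=challenges)


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------


def write_uptake_table(dataset: UptakeDataset, path: str | Path) -> None:
    """Write the dataset as CSV with the canonical column schema."""
    dataset.data.to_csv(path, index=False)


def read_uptake_table(path: str | Path, format: str | None = None) -> UptakeDataset:
    """Read an uptake table from CSV (or a simple XLSX sheet with the same
    columns). Validation errors name the offending rows."""
    path = Path(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return UptakeDataset(df, metadata={"provenance": "file", "path": str(path)})
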