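"""Validated configuration models for simulation and analysis runs.

All physical constants of the assay live here as defaults: 10 Hz frame
rate, ~200 s traces, donor→acceptor leakage 1.7% and acceptor→donor
leakage 16.5%, two-state FRET boundaries at E = 0.5, dwell-time
partitions at 0.56 s (high-FRET) and 0.32 s (low-FRET), and HMM initial
guesses E = 0.2 / 0.8.  Nothing downstream hard-codes them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator


class LeakageMatrix(BaseModel):
    """Channel cross-talk of the two-color detection path.

    ``l_da`` is the fraction of true donor emission detected in the
    acceptor channel, ``l_ad`` the fraction of true acceptor emission
    detected in the donor channel.  The observed channel pair is
    ``observed = M @ true`` with ``M = [[1-l_da, l_ad], [l_da, 1-l_ad]]``.
    """

    l_da: float = Field(default=0.017, ge=0.0, lt=1.0)
    l_ad: float = Field(default=0.165, ge=0.0, lt=1.0)

    @model_validator(mode="after")
    def _invertible(self) -> "LeakageMatrix":
        if abs(self.l_da + self.l_ad - 1.0) < 1e-12:
            raise ValueError("l_da + l_ad = 1 makes the mixing matrix singular")
        return self

    def matrix(self) -> np.ndarray:
        return np.array(
            [[1.0 - self.l_da, self.l_ad], [self.l_da, 1.0 - self.l_ad]]
        )


class StateBoundaries(BaseModel):
    """Cutpoints partitioning E in [0, 1] into labeled FRET states.

    Two-state default: low = (0, 0.5], high = (0.5, 1].  Three-state
    variants (e.g. cutpoints [0.45, 0.8] or [0.35, 0.7]) add a mid state.
    A fitted state mean E is labeled by the interval it falls in.
    """

    cutpoints: list[float] = Field(default_factory=lambda: [0.5])

    @model_validator(mode="after")
    def _ordered(self) -> "StateBoundaries":
        cp = self.cutpoints
        if not cp:
            raise ValueError("at least one cutpoint required")
        if any(not (0.0 < c < 1.0) for c in cp):
            raise ValueError("cutpoints must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        return self

    @property
    def n_states(self) -> int:
        return len(self.cutpoints) + 1

    @property
    def labels(self) -> list[str]:
        if self.n_states == 2:
            return ["low", "high"]
        if self.n_states == 3:
            return ["low", "mid", "high"]
        return [f"state{i}" for i in range(self.n_states)]

    def label_index(self, efficiency: float) -> int:
        """Index of the state interval containing ``efficiency``."""
        return int(np.searchsorted(self.cutpoints, efficiency, side="left"))

    def label(self, efficiency: float) -> str:
        return self.labels[self.label_index(efficiency)]


class SimulationConfig(BaseModel):
    """Generative model of one smFRET experiment.

    Defaults reproduce the reference assay conditions: a two-state
    conformational cycle between the assembled (E = 0.8) and disassembled
    (E = 0.2) complex at 10 Hz for 200 s, ~0.08 relative intensity noise,
    stochastic two-site labeling, and single-exponential photobleaching.
    Rates are per second; ``rate_matrix`` rows sum to zero.
    """

    n_states: int = Field(default=2, ge=2, le=3)
    state_fret: list[float] = Field(default_factory=lambda: [0.2, 0.8])
    rate_matrix: list[list[float]] = Field(
        default_factory=lambda: [[-0.2, 0.2], [0.1, -0.1]]
    )
    total_intensity: float = Field(default=1000.0, gt=0)
    noise_sigma: float = Field(default=80.0, ge=0)
    leakage: LeakageMatrix = Field(default_factory=LeakageMatrix)
    frame_rate: float = Field(default=10.0, gt=0)
    trace_length: float = Field(default=200.0, gt=0)
    donor_bleach_rate: float = Field(default=0.005, ge=0)
    acceptor_bleach_rate: float = Field(default=0.005, ge=0)
    label_efficiency: float = Field(default=0.9, ge=0.0, le=1.0)
    donor_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    n_molecules_per_field: int = Field(default=500, ge=1)
    n_fields: int = Field(default=3, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _consistent(self) -> "SimulationConfig":
        if len(self.state_fret) != self.n_states:
            raise ValueError("state_fret length must equal n_states")
        if any(not (0.0 <= e <= 1.0) for e in self.state_fret):
            raise ValueError("state_fret values must lie in [0, 1]")
        if any(b <= a for a, b in zip(self.state_fret, self.state_fret[1:])):
            raise ValueError("state_fret must be strictly increasing")
        q = np.asarray(self.rate_matrix, dtype=float)
        if q.shape != (self.n_states, self.n_states):
            raise ValueError("rate_matrix must be n_states x n_states")
        off = q[~np.eye(self.n_states, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.any(np.abs(q.sum(axis=1)) > 1e-9):
            raise ValueError("rate_matrix rows must sum to zero")
        return self

    @property
    def n_frames(self) -> int:
        return int(round(self.trace_length * self.frame_rate))

    def q_matrix(self) -> np.ndarray:
        return np.asarray(self.rate_matrix, dtype=float)


class HmmConfig(BaseModel):
    """Per-molecule hidden-Markov fit settings."""

    n_states: int = Field(default=2, ge=1, le=5)
    init_means: list[float] = Field(default_factory=lambda: [0.2, 0.8])
    tol: float = Field(default=1e-6, gt=0)
    max_iter: int = Field(default=500, ge=1)
    sigma_floor: float = Field(default=1e-3, gt=0)
    min_frames: int = Field(default=20, ge=2)

    @model_validator(mode="after")
    def _consistent(self) -> "HmmConfig":
        if len(self.init_means) != self.n_states:
            raise ValueError("init_means length must equal n_states")
        return self


class AnalysisConfig(BaseModel):
    """Settings for trace classification, idealization, and kinetics."""

    leakage: LeakageMatrix = Field(default_factory=LeakageMatrix)
    boundaries: StateBoundaries = Field(default_factory=StateBoundaries)
    hmm: HmmConfig = Field(default_factory=HmmConfig)

    # classification / bleach detection
    intensity_floor: float = Field(default=1e-6, gt=0)
    total_floor_frac: float = Field(default=0.2, gt=0, lt=1)
    bleach_recovery_frac: float = Field(default=0.3, gt=0, lt=1)
    acceptor_dead_e: float = Field(default=0.5, gt=0, le=1)
    multi_complex_factor: float = Field(default=1.5, gt=1)
    low_signal_frac: float = Field(default=0.5, gt=0, lt=1)
    min_frames: int = Field(default=50, ge=1)
    median_filter_width: int = Field(default=3, ge=1)

    # dwell kinetics
    partition_high_s: float = Field(default=0.56, gt=0)
    partition_low_s: float = Field(default=0.32, gt=0)
    fit_domain_start_s: float = Field(default=0.56, ge=0)
    linear_bin_width_s: float = Field(default=1.0, gt=0)
    log_bin_width: float = Field(default=0.25, gt=0)
    min_fit_dwells: int = Field(default=20, ge=2)

    def default_partition(self, state_label: str) -> float:
        """Reference short/long partition threshold for a state label."""
        return self.partition_high_s if state_label == "high" else self.partition_low_s


class RunConfig(BaseModel):
    """Top-level config file: one simulation and one analysis block."""

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Read a JSON or YAML run config; the format follows the suffix."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    if payload is None:
        payload = {}
    return RunConfig.model_validate(payload)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    payload = cfg.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
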