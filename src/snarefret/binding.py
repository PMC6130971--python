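"""Equilibrium binding arithmetic for the adaptor-protein experiments.

The fraction of surface-tethered SNARE complex occupied by a ligand
(e.g. the adaptor αSNAP) in large excess follows the simple isotherm
``f = L / (Kd + L)``; ligand depletion by the pM-density surface sites
is negligible against µM ligand concentrations.  The competition assay
normalizes the count of labeled ligand spots per field by the count of
surface-tethered complexes; a mutually exclusive single-site competitive
model backs the simulated counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field


class BindingModel(BaseModel):
    """Simple one-site isotherm: dissociation constant and free ligand,
    both in µM."""

    kd: float = Field(gt=0)
    ligand_conc: float = Field(ge=0)


@dataclass
class CompetitionObservation:
    """Spot counts for one field of the competition assay."""

    field_id: str
    n_ligand_spots: int
    n_tether_spots: int
    competitor_conc: float     # µM

    def __post_init__(self) -> None:
        if self.n_ligand_spots < 0 or self.n_tether_spots < 0:
            raise ValueError("spot counts must be non-negative")


def fraction_bound(model: BindingModel) -> float:
    """Equilibrium fraction of complex bound: ``L / (Kd + L)``.

    Strictly increasing in ligand concentration, 0 at zero ligand,
    1/2 at ``L = Kd``, and → 1 in the saturation limit.
    """
    return model.ligand_conc / (model.kd + model.ligand_conc)


def competitive_fraction_bound(kd_ligand: float, kd_competitor: float,
                               ligand_conc: float, competitor_conc: float) -> float:
    """Occupancy of the reporter ligand with a mutually exclusive
    competitor: ``(L/Kd_L) / (1 + L/Kd_L + C/Kd_C)``."""
    if kd_ligand <= 0 or kd_competitor <= 0:
        raise ValueError("dissociation constants must be positive")
    x = ligand_conc / kd_ligand
    c = competitor_conc / kd_competitor
    return x / (1.0 + x + c)


def normalize_competition(
        observations: Sequence[CompetitionObservation]) -> pd.DataFrame:
    """Normalized binding per competitor concentration, mean ± SD over
    fields.

    Each field contributes the ratio (ligand spots)/(tether spots);
    fields with zero tethers are skipped with a warning.  Returns a
    DataFrame with columns ``competitor_conc, mean, sd, n_fields``.
    """
    by_conc: dict[float, list[float]] = {}
    for obs in observations:
        if obs.n_tether_spots == 0:
            warnings.warn(f"field {obs.field_id}: zero tether spots, skipped")
            continue
        by_conc.setdefault(obs.competitor_conc, []).append(
            obs.n_ligand_spots / obs.n_tether_spots)
    rows = []
    for conc in sorted(by_conc):
        vals = np.asarray(by_conc[conc])
        rows.append({
            "competitor_conc": conc,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n_fields": int(vals.size),
        })
    return pd.DataFrame(rows, columns=["competitor_conc", "mean", "sd", "n_fields"])


def simulate_competition(kd_ligand: float, kd_competitor: float,
                         ligand_conc: float,
                         competitor_concs: Sequence[float],
                         n_tethers: int, rng: np.random.Generator,
                         n_fields: int = 3) -> list[CompetitionObservation]:
    """Generative stand-in for the competition assay.

    Each surface tether is independently occupied by the labeled ligand
    with the competitive-binding probability; each occupied tether is
    counted exactly once (no double counting, no extraneous Poisson
    noise).
    """
    if n_tethers <= 0:
        raise ValueError("n_tethers must be positive")
    out: list[CompetitionObservation] = []
    for conc in competitor_concs:
        p = competitive_fraction_bound(kd_ligand, kd_competitor,
                                       ligand_conc, conc)
        for f in range(n_fields):
            n_bound = int(rng.binomial(n_tethers, p))
            out.append(CompetitionObservation(
                field_id=f"c{conc}f{f}", n_ligand_spots=n_bound,
                n_tether_spots=n_tethers, competitor_conc=float(conc)))
    return out
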