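"""Synthetic single-cell fluorescence data with the assumed error structure.

The microscopy data behind the published analysis were never deposited, so
this module generates per-cell tables with the same statistical structure:
a condition-level latent signal from the forward model, a per-picture
additive background, and right-skewed per-cell heterogeneity around the
condition mean. The built-in designs mirror the two published experimental
layouts — a 12-condition main design (pulse-chase drug exposures from 2 to
60 minutes with 2 h / 5 h chases and late-labeling controls, roughly
170–300 cells each) and a 4-condition flat/ruffled validation design
(38–74 cells each).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trafficking import (
    LABEL_MINUTES,
    TreatmentSchedule,
    pulse_chase_schedule,
    simulate,
)

__all__ = [
    "DesignRow", "NoiseModel", "SyntheticDataset",
    "builtin_designs", "schedule_for", "generate",
]

#: flat/ruffled shares used for phenotype-sorted conditions; ruffled cells
#: still contain flat membrane regions, hence the mixed shares
PHENOTYPE_FLAT_SHARE = {"flat": 1.0, "ruffled": 0.60}


@dataclass(frozen=True)
class DesignRow:
    """One experimental condition of a measurement design."""

    condition_id: str
    affibody_timing: str    # 'before_experiment' | 'before_measurement'
    drug_min: float
    chase_min: float
    n_cells: int
    n_pictures: int = 6
    phenotype: str = "mixed"  # 'mixed' | 'flat' | 'ruffled'

    def validate(self) -> "DesignRow":
        if self.n_cells < 1 or self.n_pictures < 1:
            raise ValidationError("n_cells and n_pictures must be >= 1")
        if self.drug_min < 0 or self.chase_min < 0:
            raise ValidationError("durations must be >= 0")
        if self.phenotype not in ("mixed", "flat", "ruffled"):
            raise ValidationError(f"unknown phenotype {self.phenotype!r}")
        return self


@dataclass(frozen=True)
class NoiseModel:
    """Per-cell heterogeneity and per-picture background distribution.

    ``cell_cv`` is the coefficient of variation of the per-cell signal
    around the condition mean (lognormal by default, matching the
    right-skewed single-cell intensity distributions of this kind of
    data); backgrounds are normal with mean ``bg_mean`` and spread
    ``bg_sd`` in luminosity units.
    """

    cell_cv: float = 0.5
    cell_family: str = "lognormal"  # 'lognormal' | 'normal'
    bg_mean: float = 50.0
    bg_sd: float = 10.0
    seed: int = 0

    def validate(self) -> "NoiseModel":
        if self.cell_cv < 0 or self.bg_sd < 0:
            raise ValidationError("cell_cv and bg_sd must be >= 0")
        if self.cell_family not in ("lognormal", "normal"):
            raise ValidationError(f"unknown cell_family {self.cell_family!r}")
        return self


def builtin_designs() -> tuple[tuple[DesignRow, ...], tuple[DesignRow, ...]]:
    """The main (12-condition) and validation (4-condition) designs.

    Conditions labeled ``affbm`` apply the Affibody label in the last ten
    minutes before fixation instead of before the drug pulse.
    """
    main = tuple(DesignRow(cid, timing, drug, chase, n).validate()
                 for cid, timing, drug, chase, n in [
        ("control", "before_experiment", 0, 0, 218),
        ("2min", "before_experiment", 2, 0, 223),
        ("2min_chase", "before_experiment", 2, 120, 185),
        ("5min", "before_experiment", 5, 0, 302),
        ("5min_chase", "before_experiment", 5, 120, 168),
        ("5min_chase_affbm", "before_measurement", 5, 120, 188),
        ("5min_chase5", "before_experiment", 5, 300, 218),
        ("5min_chase5_affbm", "before_measurement", 5, 300, 189),
        ("20min", "before_experiment", 20, 0, 209),
        ("20min_chase", "before_experiment", 20, 120, 202),
        ("60min", "before_experiment", 60, 0, 198),
        ("60min_affbm", "before_measurement", 60, 0, 176),
    ])
    validation = tuple(
        DesignRow(cid, "before_experiment", drug, 0, n,
                  phenotype=pheno).validate()
        for cid, drug, n, pheno in [
            ("control_flat", 0, 38, "flat"),
            ("control_ruffled", 0, 69, "ruffled"),
            ("60min_flat", 60, 66, "flat"),
            ("60min_ruffled", 60, 74, "ruffled"),
        ])
    return main, validation


def schedule_for(row: DesignRow,
                 label_min: float = LABEL_MINUTES) -> TreatmentSchedule:
    """Treatment schedule implementing one design row."""
    return pulse_chase_schedule(row.affibody_timing, row.drug_min,
                                row.chase_min, label_min=label_min,
                                note=row.condition_id)


def _params_for_phenotype(params, model: str, phenotype: str):
    if model != "B" or phenotype == "mixed":
        return params
    return params.with_flat_share(PHENOTYPE_FLAT_SHARE[phenotype])


@dataclass
class SyntheticDataset:
    cells: pd.DataFrame
    backgrounds: pd.DataFrame
    truth: dict

    def write(self, cells_path, backgrounds_path, truth_path) -> None:
        self.cells.to_csv(cells_path, index=False)
        self.backgrounds.to_csv(backgrounds_path, index=False)
        with open(truth_path, "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def generate(true_params, model: str, designs, noise: NoiseModel,
             pictures_per_condition: int | None = None,
             label_min: float = LABEL_MINUTES) -> SyntheticDataset:
    """Draw per-cell and per-picture tables for a measurement design.

    For each condition the trajectory is simulated under the condition's
    schedule, the observable is read at the measurement time, per-picture
    backgrounds are drawn, and each cell's luminosity is drawn with mean
    (observable + background) and the configured heterogeneity. The truth
    record stores every latent value for recovery tests.
    """
    noise.validate()
    rng = np.random.default_rng(noise.seed)
    cell_rows, bg_rows = [], []
    truth = {
        "seed": int(noise.seed),
        "model": model,
        "noise": asdict(noise),
        "parameters": asdict(true_params),
        "conditions": {},
    }
    for row in designs:
        row.validate()
        n_pics = pictures_per_condition or row.n_pictures
        params = _params_for_phenotype(true_params, model, row.phenotype)
        sched = schedule_for(row, label_min=label_min)
        traj = simulate(model, params, sched,
                        output_times=[sched.measurement_time])
        signal = float(traj.observed[-1])

        pic_ids = [f"{row.condition_id}_p{j + 1}" for j in range(n_pics)]
        bgs = np.clip(rng.normal(noise.bg_mean, noise.bg_sd, n_pics), 0, None)
        for pid, b in zip(pic_ids, bgs):
            bg_rows.append({"picture_id": pid, "luminosity": b})

        # cells allocated to pictures round-robin
        pics = np.array([pic_ids[i % n_pics] for i in range(row.n_cells)])
        mean_bg = np.array([bgs[i % n_pics] for i in range(row.n_cells)])
        cell_signal = _draw_cells(rng, signal, row.n_cells, noise)
        areas = 600.0 + rng.lognormal(np.log(1200.0), 0.5, row.n_cells)
        for pid, lum, area in zip(pics, cell_signal + mean_bg, areas):
            cell_rows.append({"condition_id": row.condition_id,
                              "picture_id": pid,
                              "luminosity": lum,
                              "area": area})

        truth["conditions"][row.condition_id] = {
            "signal": signal,
            "measurement_time": float(sched.measurement_time),
            "phenotype": row.phenotype,
            "n_cells": int(row.n_cells),
            "backgrounds": {pid: float(b) for pid, b in zip(pic_ids, bgs)},
        }

    cells = pd.DataFrame(cell_rows,
                         columns=["condition_id", "picture_id",
                                  "luminosity", "area"])
    backgrounds = pd.DataFrame(bg_rows, columns=["picture_id", "luminosity"])
    return SyntheticDataset(cells, backgrounds, truth)


def _draw_cells(rng, mean: float, n: int, noise: NoiseModel) -> np.ndarray:
    if noise.cell_cv == 0 or mean == 0:
        return np.full(n, mean)
    if noise.cell_family == "lognormal":
        sigma2 = np.log1p(noise.cell_cv ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), n)
    return rng.normal(mean, noise.cell_cv * mean, n)
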