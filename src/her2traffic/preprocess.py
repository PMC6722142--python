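"""Background correction of per-cell fluorescence records.

Each microscopy image (picture) carries its own additive background level.
The per-cell mean signal per pixel ("luminosity") of every cell on picture
``p`` under condition ``c`` is modeled as ``s_c + b_p``, and the dedicated
background regions of the same picture measure ``b_p`` directly. A joint
least-squares fit of both record types yields one background-corrected
signal per condition together with a standard error of the mean from the
within-condition spread of corrected cell values.

Input/output tables are plain comma-separated text with headers
``condition_id,picture_id,luminosity,area[,background_local,excluded]``
for cells and ``picture_id,luminosity`` for backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    MissingBackgroundError,
    UnidentifiableDesignError,
    ValidationError,
)

__all__ = [
    "ScreeningRules", "fit_additive_model", "screen_cells",
    "normalize_for_presentation", "read_cell_table", "read_background_table",
]

CELL_COLUMNS = ("condition_id", "picture_id", "luminosity", "area")
BACKGROUND_COLUMNS = ("picture_id", "luminosity")


@dataclass(frozen=True)
class ScreeningRules:
    """Cell-level exclusion criteria applied before fitting.

    Small (below ``min_area_um2``) and flagged cells (spherical or only
    partially captured, encoded in a boolean ``excluded`` column) are
    dropped, mirroring the visual screening of the microscopy analysis.
    """

    min_area_um2: float = 600.0
    use_excluded_flag: bool = True


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cell table is missing columns {sorted(missing)}")
    return df


def read_background_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BACKGROUND_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"background table is missing columns {sorted(missing)}")
    return df


def screen_cells(cells: pd.DataFrame,
                 rules: ScreeningRules = ScreeningRules()) -> pd.DataFrame:
    """Apply the area / exclusion-flag screening to a cell table."""
    if (cells["area"] <= 0).any():
        raise ValidationError("cell areas must be > 0")
    keep = cells["area"] >= rules.min_area_um2
    if rules.use_excluded_flag and "excluded" in cells.columns:
        keep &= ~cells["excluded"].fillna(False).astype(bool)
    return cells.loc[keep].reset_index(drop=True)


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def fit_additive_model(cells: pd.DataFrame, backgrounds: pd.DataFrame,
                       rules: ScreeningRules = ScreeningRules()
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Jointly estimate condition signals and per-picture backgrounds.

    Minimizes the summed squared residuals of the cell records against
    ``s_c + b_p`` and of the background records against ``b_p`` (equal
    weights). Returns ``(signals, picture_backgrounds)`` where ``signals``
    has columns ``condition_id, signal, sem, n_cells`` and the background
    table ``picture_id, background``.

    When a ``background_local`` column with per-cell background values is
    present, the additive model is bypassed and correction is direct
    subtraction per cell.
    """
    cells = screen_cells(cells, rules)
    if cells.empty:
        raise ValidationError("no cells left after screening")

    if "background_local" in cells.columns and \
            cells["background_local"].notna().all():
        corrected = cells["luminosity"] - cells["background_local"]
        signals = _condition_summary(cells["condition_id"], corrected)
        bg = (cells.groupby("picture_id", sort=True)["background_local"]
              .mean().rename("background").reset_index())
        return signals, bg

    conditions = sorted(cells["condition_id"].unique())
    pictures = sorted(set(cells["picture_id"]) | set(backgrounds["picture_id"]))
    missing = set(cells["picture_id"]) - set(backgrounds["picture_id"])
    if missing:
        raise MissingBackgroundError(
            f"pictures with cells but no background record: {sorted(missing)}")

    c_idx = {c: i for i, c in enumerate(conditions)}
    p_idx = {p: len(conditions) + i for i, p in enumerate(pictures)}
    n_unknown = len(conditions) + len(pictures)

    n_rows = len(cells) + len(backgrounds)
    design = np.zeros((n_rows, n_unknown))
    y = np.empty(n_rows)
    rows = np.arange(len(cells))
    design[rows, [c_idx[c] for c in cells["condition_id"]]] = 1.0
    design[rows, [p_idx[p] for p in cells["picture_id"]]] = 1.0
    y[:len(cells)] = cells["luminosity"].to_numpy(float)
    rows_b = len(cells) + np.arange(len(backgrounds))
    design[rows_b, [p_idx[p] for p in backgrounds["picture_id"]]] = 1.0
    y[len(cells):] = backgrounds["luminosity"].to_numpy(float)

    theta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < n_unknown:
        raise UnidentifiableDesignError(
            "signal/background design matrix is rank deficient "
            f"(rank {rank} < {n_unknown} unknowns)")

    b_hat = {p: theta[p_idx[p]] for p in pictures}
    corrected = cells["luminosity"].to_numpy(float) - \
        np.array([b_hat[p] for p in cells["picture_id"]])
    signals = _condition_summary(cells["condition_id"],
                                 pd.Series(corrected),
                                 point_estimates={c: theta[c_idx[c]]
                                                  for c in conditions})
    bg = pd.DataFrame({"picture_id": pictures,
                       "background": [b_hat[p] for p in pictures]})
    return signals, bg


def _condition_summary(condition_ids, corrected, point_estimates=None):
    df = pd.DataFrame({"condition_id": np.asarray(condition_ids),
                       "corrected": np.asarray(corrected, dtype=float)})
    rows = []
    for cond, grp in df.groupby("condition_id", sort=True):
        vals = grp["corrected"].to_numpy()
        signal = point_estimates[cond] if point_estimates is not None \
            else float(vals.mean())
        rows.append({"condition_id": cond, "signal": signal,
                     "sem": _sem(vals), "n_cells": len(vals)})
    return pd.DataFrame(rows)


def normalize_for_presentation(signals: pd.DataFrame, fitted_scale: float,
                               control_prediction: float = 1.0
                               ) -> pd.DataFrame:
    """Scale signals so the predicted control condition maps to one.

    Divides every signal and its standard error by
    ``fitted_scale * control_prediction`` — the fitted fluorescence scale
    times the model's (dimensionless) control observable at time zero.
    """
    divisor = fitted_scale * control_prediction
    if not np.isfinite(divisor) or divisor <= 0:
        raise ValidationError("normalization scale must be finite and > 0")
    out = signals.copy()
    out["signal"] = out["signal"] / divisor
    out["sem"] = out["sem"] / divisor
    return out
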