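"""Structured configuration for the analysis pipeline.

A single YAML file drives all stages: model variant, parameter values
(either the published reference estimates, optionally overridden, or a
full explicit set), treatment schedules, noise settings for the synthetic
generator, and fit options. Schedules may alternatively be loaded from a
delimited table with columns ``condition, compound, action, time_min``
(action ``measure`` marks the fixation time).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .trafficking import (
    Event,
    ModelAParameters,
    ModelBParameters,
    TreatmentSchedule,
    pulse_chase_schedule,
    reference_parameters,
)

__all__ = ["load_config", "params_from_config", "schedules_from_config",
           "schedules_from_table", "config_digest"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg


def config_digest(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def params_from_config(cfg: dict):
    """Build a parameter object from the ``model`` / ``parameters`` keys."""
    model = cfg.get("model", "B")
    overrides = dict(cfg.get("parameters") or {})
    if cfg.get("use_reference", True):
        base = reference_parameters(model)
        if overrides:
            import dataclasses
            base = dataclasses.replace(base, **overrides)
        return model, base.validate()
    cls = ModelAParameters if model == "A" else ModelBParameters
    return model, cls(**overrides).validate()


def schedules_from_config(cfg: dict) -> dict[str, TreatmentSchedule]:
    """Schedules from the ``schedules`` list of pulse-chase descriptions."""
    out = {}
    for row in cfg.get("schedules") or []:
        name = row.get("condition")
        if not name:
            raise ValidationError("each schedule needs a 'condition' name")
        out[name] = pulse_chase_schedule(
            affibody_timing=row.get("affibody_timing", "before_experiment"),
            drug_min=float(row.get("drug_min", 0.0)),
            chase_min=float(row.get("chase_min", 0.0)),
            label_min=float(row.get("label_min", 10.0)),
            affibody_during_drug=bool(row.get("affibody_during_drug", False)),
            note=name)
    return out


def schedules_from_table(table) -> dict[str, TreatmentSchedule]:
    """Schedules from a delimited events table.

    Columns: ``condition, compound, action, time_min`` with actions
    ``on``/``off`` per compound and one ``measure`` row per condition.
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table)
    required = {"condition", "compound", "action", "time_min"}
    if not required <= set(table.columns):
        raise ValidationError(
            f"events table needs columns {sorted(required)}")
    out = {}
    for cond, grp in table.groupby("condition", sort=True):
        measure = grp[grp["action"] == "measure"]
        if len(measure) != 1:
            raise ValidationError(
                f"condition {cond!r} needs exactly one 'measure' row")
        evs = [Event(float(r.time_min), str(r.compound), str(r.action))
               for r in grp.itertuples(index=False) if r.action != "measure"]
        evs.sort(key=lambda ev: ev.time)
        out[str(cond)] = TreatmentSchedule(
            tuple(evs), float(measure["time_min"].iloc[0]),
            str(cond)).validate()
    return out
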