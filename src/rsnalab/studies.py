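"""Replicated simulation studies: the desk-scale analogs of the animal
experiments, used for validation and by ``scripts/acceptance.py``.

Each study generates seeded cohorts with the synthetic generator, runs the
full analysis pipeline on every subject (peak detection through curve
estimation -- never the generator's ground truth), and summarizes
group-level estimates across replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baroreflex import average_curves, descending_slope, plateau_pressure
from .core import DataError, NoPlateauError, SubjectRecord
from .model import RSNAModel
from .synthetic import PRESETS, GroupPreset, generate_cohort, with_overrides

__all__ = [
    "analytic_plateau_mmhg",
    "fit_group",
    "plateau_slope_study",
    "coupling_study",
]


def analytic_plateau_mmhg(preset: GroupPreset, tol_pct: float = 5.0) -> float:
    """Closed-form plateau onset of the generating sigmoid.

    The pressure at which the inverse logistic has fallen to within
    ``tol_pct`` percent of its range above the lower plateau:
    ``p50 + k * ln((1 - f) / f)`` with ``f = tol_pct / 100``.
    """
    f = tol_pct / 100.0
    return preset.sigmoid_p50 + preset.sigmoid_k * math.log((1.0 - f) / f)


@dataclass(frozen=True)
class GroupFit:
    """Group-level baroreflex estimates from one simulated cohort."""

    group: str
    n_subjects: int
    plateau_mmhg: float | None
    slope_pct_per_mmhg: float | None
    curve: object
    subject_results: tuple


def fit_group(records: list[SubjectRecord], tol_pct: float = 5.0) -> GroupFit:
    """Fit every subject, average the curves, estimate slope and plateau."""
    results = [RSNAModel(rec).fit() for rec in records]
    curves = [r.curve for r in results if r.curve is not None]
    if len(curves) < 2:
        raise DataError("fewer than two usable subject curves")
    group_curve = average_curves(curves)
    try:
        plateau = plateau_pressure(group_curve, tol_pct=tol_pct)
    except NoPlateauError:
        plateau = None
    try:
        slope = descending_slope(group_curve).slope
    except DataError:
        slope = None
    return GroupFit(
        group=records[0].group,
        n_subjects=len(records),
        plateau_mmhg=plateau,
        slope_pct_per_mmhg=slope,
        curve=group_curve,
        subject_results=tuple(results),
    )


def plateau_slope_study(
    seeds: list[int],
    n_per_group: int = 10,
    presets: tuple[GroupPreset, GroupPreset] = (PRESETS["WKY"], PRESETS["SHRLN"]),
    tol_pct: float = 5.0,
) -> pd.DataFrame:
    """Replicate-cohort recovery of plateau displacement and slope ordering.

    For each seed, one cohort of ``n_per_group`` subjects per phenotype is
    generated with the standard baroreflex protocol and fitted at group
    level. Columns: per-group plateau and its absolute error versus the
    generating sigmoid's analytic plateau onset, the between-group plateau
    separation, and the group slopes.
    """
    a, b = presets
    rows = []
    for seed in seeds:
        cohort = generate_cohort(
            {a.group_label: n_per_group, b.group_label: n_per_group},
            seed=seed,
            protocol_kind="baroreflex",
            presets={a.group_label: a, b.group_label: b},
        )
        fits = {}
        for preset in (a, b):
            recs = [r for r in cohort if r.group == preset.group_label]
            fits[preset.group_label] = fit_group(recs, tol_pct=tol_pct)
        fa, fb = fits[a.group_label], fits[b.group_label]
        truth_a = analytic_plateau_mmhg(a, tol_pct)
        truth_b = analytic_plateau_mmhg(b, tol_pct)
        rows.append(
            {
                "seed": seed,
                f"plateau_{a.group_label}": fa.plateau_mmhg,
                f"plateau_{b.group_label}": fb.plateau_mmhg,
                f"plateau_err_{a.group_label}": (
                    abs(fa.plateau_mmhg - truth_a) if fa.plateau_mmhg is not None else np.nan
                ),
                f"plateau_err_{b.group_label}": (
                    abs(fb.plateau_mmhg - truth_b) if fb.plateau_mmhg is not None else np.nan
                ),
                "separation": (
                    fb.plateau_mmhg - fa.plateau_mmhg
                    if fa.plateau_mmhg is not None and fb.plateau_mmhg is not None
                    else np.nan
                ),
                f"slope_{a.group_label}": fa.slope_pct_per_mmhg,
                f"slope_{b.group_label}": fb.slope_pct_per_mmhg,
            }
        )
    return pd.DataFrame(rows)


def coupling_study(
    seed: int,
    n: int = 10,
    intact_preset: GroupPreset | None = None,
    altered_preset: GroupPreset | None = None,
    duration: float = 180.0,
) -> dict:
    """Classify RSNA-HR coupling in phase-locked vs decoupled cohorts.

    The 'intact' cohort is the normotensive preset with perfect cardiac
    phase-locking (coupling_jitter = 0); the 'altered' cohort is the severe
    hypertension preset, whose default jitter (>= 0.8) decouples bursting.
    Returns per-cohort counts of subjects classified intact/altered.
    """
    intact_preset = intact_preset or with_overrides(PRESETS["WKY"], coupling_jitter=0.0)
    altered_preset = altered_preset or PRESETS["SHRLN"]
    out = {}
    for name, preset in (("intact", intact_preset), ("altered", altered_preset)):
        cohort = generate_cohort(
            {preset.group_label: n},
            seed=seed if name == "intact" else seed + 10_000,
            protocol_kind="basal",
            presets={preset.group_label: preset},
            duration=duration,
        )
        labels = []
        for rec in cohort:
            res = RSNAModel(rec).fit()
            labels.append(res.coupling.classification if res.coupling else "unknown")
        out[name] = {
            "n": n,
            "intact": sum(1 for x in labels if x == "intact"),
            "altered": sum(1 for x in labels if x == "altered"),
        }
    return out
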