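"""End-to-end glue: cohort -> envelopes -> kinetics -> statistics / models."""

from __future__ import annotations

import logging
import math
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import kinetics as kin
from .cohort import CohortDataset
from .preprocessing import FilterSpec, preprocess
from .stats import RMDataset, bonferroni_pairwise, iqr_outliers, rm_anova, shapiro_wilk
from .training import TrainingConfig, WindowSet, fit_indicator, make_windows

logger = logging.getLogger(__name__)

__all__ = [
    "preprocess_cohort",
    "extract_kinetics",
    "subject_condition_means",
    "rm_matrix",
    "run_condition_stats",
    "windows_for",
    "train_models",
]


def preprocess_cohort(
    ds: CohortDataset,
    spec: Optional[FilterSpec] = None,
    window_ms: float = 50.0,
) -> Dict[tuple, np.ndarray]:
    """Envelope (T, C) arrays keyed by (subject, condition, punch)."""
    return {
        key: preprocess(rec.emg, spec, window_ms).samples
        for key, rec in ds.records.items()
    }


def extract_kinetics(ds: CohortDataset) -> pd.DataFrame:
    """Tidy per-punch indicator table from the force traces."""
    mass = {s.subject_id: s.body_mass for s in ds.subjects}
    rows = []
    for (sid, cond, pi), rec in ds.records.items():
        events = kin.detect_punches(rec.force)
        valid = [e for e in events if e.valid]
        if not valid:
            rows.append({"subject_id": sid, "condition": cond, "punch_index": pi,
                         "valid": False, **{k: math.nan for k in kin.INDICATORS}})
            continue
        params = kin.extract_parameters(rec.force, valid[0], mass[sid])
        rows.append({"subject_id": sid, "condition": cond, "punch_index": pi,
                     "valid": True, **params.as_dict()})
    return pd.DataFrame(rows)


def subject_condition_means(kinetics_df: pd.DataFrame) -> pd.DataFrame:
    """Per-(subject, condition) means of the indicators over valid punches."""
    valid = kinetics_df[kinetics_df.valid]
    return (
        valid.groupby(["subject_id", "condition"])[list(kin.INDICATORS)]
        .mean()
        .reset_index()
    )


def rm_matrix(means: pd.DataFrame, indicator: str, conditions) -> RMDataset:
    """Pivot per-subject means into the n x k repeated-measures matrix."""
    pivot = means.pivot(index="subject_id", columns="condition", values=indicator)
    pivot = pivot[list(conditions)].dropna()
    return RMDataset(pivot.to_numpy(), list(conditions), indicator=indicator)


def run_condition_stats(kinetics_df: pd.DataFrame, conditions=None) -> dict:
    """Outlier screen + normality + RM-ANOVA + Bonferroni per indicator."""
    means = subject_condition_means(kinetics_df)
    conditions = list(conditions or means.condition.unique())
    report = {}
    for ind in kin.INDICATORS:
        try:
            data = rm_matrix(means, ind, conditions)
        except KeyError:
            continue
        if data.values.shape[0] < 3:
            continue
        per_cond = {}
        for j, cond in enumerate(conditions):
            col = data.values[:, j]
            w, p_sw = shapiro_wilk(col)
            per_cond[cond] = {
                "shapiro_w": w,
                "shapiro_p": p_sw,
                "n_outliers": int(iqr_outliers(col).sum()),
            }
        anova = rm_anova(data)
        pairs = bonferroni_pairwise(data)
        report[ind] = {
            "conditions": per_cond,
            "anova": anova,
            "pairwise": pairs,
        }
    return report


def windows_for(
    ds: CohortDataset,
    envelopes: Dict[tuple, np.ndarray],
    kinetics_df: pd.DataFrame,
    indicator: str,
    condition: str,
    downsample: int = 10,
) -> WindowSet:
    return make_windows(envelopes, kinetics_df[kinetics_df.valid], indicator,
                        condition, downsample=downsample)


def train_models(
    windows: WindowSet,
    kinds=("kan", "lstm", "rnn"),
    config: Optional[TrainingConfig] = None,
) -> dict:
    """Fit each requested model kind on the same windows; metrics per kind."""
    config = config or TrainingConfig()
    out = {}
    for kind in kinds:
        res = fit_indicator(windows, kind, config)
        out[kind] = {
            "train": res["train_metrics"],
            "test": res["test_metrics"],
            "n_train": res["n_train"],
            "n_test": res["n_test"],
        }
        logger.info(
            "%s %s %s: test R^2 %.3f RMSE %.3f",
            kind, windows.indicator, windows.condition,
            out[kind]["test"].r2, out[kind]["test"].rmse,
        )
    return out
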