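"""Reading and writing the delimited gaze-exchange formats.

Three plain CSV formats are used throughout:

* gaze file — one row per sample:
  ``trial_id,t_ms,left_x,left_y,left_valid,right_x,right_y,right_valid``
  with validity in {0, 1} and empty coordinate fields for an invalid eye;
* manifest — one row per trial:
  ``trial_id,subject_id,group,cc,rate_hz``;
* cohort feature table — one row per (trial, feature):
  ``subject_id,group,cc,feature_name,value``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CC_LABELS,
    FEATURE_NAMES,
    GROUPS,
    DataError,
    FormatError,
    GazeTrial,
)

GAZE_COLUMNS = ("trial_id", "t_ms", "left_x", "left_y", "left_valid",
                "right_x", "right_y", "right_valid")
MANIFEST_COLUMNS = ("trial_id", "subject_id", "group", "cc", "rate_hz")
COHORT_COLUMNS = ("subject_id", "group", "cc", "feature_name", "value")
EVENT_COLUMNS = ("trial_id", "kind", "index", "t_ms", "x", "y", "contribution")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")


def read_trials(gaze_path, manifest_path) -> list[GazeTrial]:
    """Load gaze streams and their manifest into :class:`GazeTrial` objects.

    One trial is produced per manifest row, in manifest order; the gaze rows
    of each trial keep their file order.  Unknown group or CC labels, missing
    columns, and non-monotonic timestamps are rejected with explicit errors.
    """
    # round_trip parsing: timestamps/coordinates must survive write->read
    # bit-exactly (the default float parser is off by an ulp).
    gaze = pd.read_csv(gaze_path, float_precision="round_trip")
    manifest = pd.read_csv(manifest_path, float_precision="round_trip")
    _require_columns(gaze, GAZE_COLUMNS, gaze_path)
    _require_columns(manifest, MANIFEST_COLUMNS, manifest_path)

    by_trial = {tid: g for tid, g in gaze.groupby("trial_id", sort=False)}
    trials: list[GazeTrial] = []
    for row in manifest.itertuples(index=False):
        tid = str(row.trial_id)
        if tid not in by_trial:
            raise DataError(f"{manifest_path}: trial {tid!r} has no gaze samples in {gaze_path}")
        g = by_trial[tid]
        lv = g["left_valid"].to_numpy()
        rv = g["right_valid"].to_numpy()
        for name, v in (("left_valid", lv), ("right_valid", rv)):
            if not np.isin(v, (0, 1)).all():
                raise FormatError(f"{gaze_path}: trial {tid!r}: {name} must be 0 or 1")
        left = g[["left_x", "left_y"]].to_numpy(dtype=float)
        right = g[["right_x", "right_y"]].to_numpy(dtype=float)
        trials.append(GazeTrial(
            trial_id=tid,
            subject_id=str(row.subject_id),
            group=str(row.group),
            cc=str(row.cc),
            rate_hz=float(row.rate_hz),
            t=g["t_ms"].to_numpy(dtype=float),
            left=left,
            right=right,
            left_valid=lv.astype(bool),
            right_valid=rv.astype(bool),
        ))
    return trials


def write_trials(trials: Iterable[GazeTrial], gaze_path, manifest_path) -> None:
    """Write trials to a gaze CSV + manifest CSV (inverse of :func:`read_trials`)."""
    gaze_rows = []
    manifest_rows = []
    for tr in trials:
        manifest_rows.append((tr.trial_id, tr.subject_id, tr.group, tr.cc, tr.rate_hz))
        left = np.where(tr.left_valid[:, None], tr.left, np.nan)
        right = np.where(tr.right_valid[:, None], tr.right, np.nan)
        gaze_rows.append(pd.DataFrame({
            "trial_id": tr.trial_id,
            "t_ms": tr.t,
            "left_x": left[:, 0],
            "left_y": left[:, 1],
            "left_valid": tr.left_valid.astype(int),
            "right_x": right[:, 0],
            "right_y": right[:, 1],
            "right_valid": tr.right_valid.astype(int),
        }))
    gaze = pd.concat(gaze_rows, ignore_index=True) if gaze_rows else pd.DataFrame(columns=GAZE_COLUMNS)
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    Path(gaze_path).parent.mkdir(parents=True, exist_ok=True)
    Path(manifest_path).parent.mkdir(parents=True, exist_ok=True)
    gaze.to_csv(gaze_path, index=False)
    manifest.to_csv(manifest_path, index=False)


def read_cohort_table(path) -> pd.DataFrame:
    """Load a cohort feature table, validating labels and value signs."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, COHORT_COLUMNS, path)
    bad_feat = set(df["feature_name"]) - set(FEATURE_NAMES)
    if bad_feat:
        raise FormatError(f"{path}: unknown feature names {sorted(bad_feat)}; expected {FEATURE_NAMES}")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise FormatError(f"{path}: unknown groups {sorted(bad_group)}")
    bad_cc = set(df["cc"]) - set(CC_LABELS)
    if bad_cc:
        raise FormatError(f"{path}: unknown color configurations {sorted(bad_cc)}")
    if (df["value"] < 0).any():
        raise DataError(f"{path}: feature values must be non-negative")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


def write_events(df: pd.DataFrame, path) -> None:
    """Write a trigger-event table (drives struggle-localization overlays)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.loc[:, EVENT_COLUMNS].to_csv(path, index=False)


__all__ = [
    "GAZE_COLUMNS", "MANIFEST_COLUMNS", "COHORT_COLUMNS", "EVENT_COLUMNS",
    "read_trials", "write_trials", "read_cohort_table", "write_cohort_table",
    "write_events",
]
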