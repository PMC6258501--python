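"""Canonical tabular interchange for rater-by-video feature matrices.

A feature matrix is a pandas DataFrame with one row per rater x video (or per
simulated score sheet) and columns::

    video_id, rater_id, age_years, label, <30 feature columns>

``label`` is 1 for the affected (ASD) class and 0 otherwise; feature cells
hold ordinal scores in {0,1,2,3} or 8 (unscorable).  Matrices are interchanged
as plain CSV with this documented header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .schema import UNSCORABLE, FeatureSchema

META_COLUMNS = ("video_id", "rater_id", "age_years", "label")
VALID_SCORES = frozenset({0, 1, 2, 3, UNSCORABLE})

AFFECTED = 1
UNAFFECTED = 0


class MatrixValidationError(ValueError):
    """A feature-matrix table violates the interchange contract."""


def feature_columns(schema: FeatureSchema) -> list[str]:
    return list(schema.feature_ids)


def validate_feature_matrix(df: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    """Validate columns, label domain and score domain; returns the frame."""
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise MatrixValidationError(f"missing required column(s): {missing}")
    feat_missing = [c for c in schema.feature_ids if c not in df.columns]
    if feat_missing:
        raise MatrixValidationError(f"missing feature column(s): {feat_missing}")
    bad_label = df.index[~df["label"].isin([AFFECTED, UNAFFECTED])]
    if len(bad_label):
        raise MatrixValidationError(
            f"label must be 0 or 1; first bad row index {bad_label[0]}"
        )
    scores = df[list(schema.feature_ids)].to_numpy()
    valid = np.isin(scores, list(VALID_SCORES))
    if not valid.all():
        r, c = np.argwhere(~valid)[0]
        raise MatrixValidationError(
            f"score {scores[r, c]!r} out of {{0,1,2,3,8}} in row {df.index[r]} "
            f"(column {schema.feature_ids[c]!r})"
        )
    return df


def read_feature_matrix(path: str | Path, schema: FeatureSchema) -> pd.DataFrame:
    """Read and validate a feature-matrix CSV."""
    df = pd.read_csv(path)
    validate_feature_matrix(df, schema)
    df[list(schema.feature_ids)] = df[list(schema.feature_ids)].astype(int)
    return df


def write_feature_matrix(df: pd.DataFrame, path: str | Path, schema: FeatureSchema) -> None:
    """Validate and write a feature matrix as CSV (documented column order)."""
    validate_feature_matrix(df, schema)
    cols = list(META_COLUMNS) + list(schema.feature_ids)
    df[cols].to_csv(path, index=False)
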