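"""Delimited-text I/O for feature tables, metadata, annotations and panels.

Comma- and tab-delimited inputs are autodetected.  Samples are rows and
features columns, with the first column holding the sample id.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .chemometrics import OplsdaModel
from .preprocess import FeatureTable

__all__ = [
    "read_delimited",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_annotations",
    "write_annotations",
    "read_panel",
    "write_panel",
    "save_oplsda",
    "load_oplsda",
]

VALID_GROUPS = {"CON", "DOX", "QC"}


def read_delimited(path, index_col=0) -> pd.DataFrame:
    """Read a comma- or tab-delimited table, sniffing the delimiter."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=None, engine="python", index_col=index_col)


def _require_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(
                f"{path}: non-numeric intensity at row {row!r}, "
                f"column {col!r}: {df.loc[row, col]!r}")
        df[col] = coerced
    return df


def read_feature_table(path, platform: str,
                       internal_standard_id: str | None = None
                       ) -> FeatureTable:
    df = read_delimited(path)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    df = _require_numeric(df, path)
    if internal_standard_id and internal_standard_id not in df.columns:
        raise ValueError(f"{path}: internal standard "
                         f"{internal_standard_id!r} not found")
    return FeatureTable(data=df, platform=platform,
                        internal_standard_id=internal_standard_id)


def write_feature_table(table: FeatureTable, path, sep=",") -> None:
    table.data.to_csv(path, sep=sep, index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    md = read_delimited(path)
    if "group" not in md.columns:
        raise ValueError(f"{path}: metadata needs a 'group' column")
    bad = set(md["group"]) - VALID_GROUPS
    if bad:
        raise ValueError(f"{path}: unknown group label(s) {sorted(bad)}")
    if md.index.duplicated().any():
        dup = md.index[md.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    for col in ("ALT", "AST"):
        if col in md.columns:
            md[col] = pd.to_numeric(md[col], errors="coerce")
    return md


def write_metadata(metadata: pd.DataFrame, path, sep=",") -> None:
    metadata.to_csv(path, sep=sep, index_label="sample_id")


def check_metadata_covers(table: FeatureTable, metadata: pd.DataFrame) -> None:
    missing = [s for s in table.data.index if s not in metadata.index]
    if missing:
        raise ValueError(f"sample(s) missing from metadata: {missing}")


def read_annotations(path) -> pd.DataFrame:
    ann = read_delimited(path, index_col=None)
    needed = {"feature_id", "platform", "metabolite", "msi_level"}
    missing = needed - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: annotation columns missing {sorted(missing)}")
    if ann.duplicated(subset=["feature_id", "platform"]).any():
        raise ValueError(f"{path}: duplicate (feature_id, platform) rows")
    ann["msi_level"] = ann["msi_level"].astype(int)
    return ann


def write_annotations(annotations: pd.DataFrame, path, sep=",") -> None:
    annotations.to_csv(path, sep=sep, index=False)


def read_panel(path) -> pd.DataFrame:
    df = read_delimited(path)
    return _require_numeric(df, path)


def write_panel(panel: pd.DataFrame, path, sep=",") -> None:
    panel.to_csv(path, sep=sep, index_label="sample_id")


def save_oplsda(model: OplsdaModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)


def load_oplsda(path) -> OplsdaModel:
    with open(path) as fh:
        return OplsdaModel.from_dict(json.load(fh))
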