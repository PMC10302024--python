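"""Feature-table preprocessing: imputation, normalization, scaling, QC.

The fixed stage order is impute -> normalize -> transform/scale.  Fold
changes downstream are always computed on normalized, *unscaled* intensities;
scaled matrices feed the multivariate models only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "PreprocessReport",
    "ScalingRecipe",
    "QcReport",
    "impute_missing",
    "normalize",
    "transform_scale",
    "qc_assess",
]


@dataclass
class FeatureTable:
    """Samples x features intensity matrix for one analytical platform."""

    data: pd.DataFrame
    platform: str
    internal_standard_id: str | None = None

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise ValueError(f"duplicate sample ids in {self.platform}")
        if self.data.columns.duplicated().any():
            raise ValueError(f"duplicate feature ids in {self.platform}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.platform,
                            self.internal_standard_id)


@dataclass
class PreprocessReport:
    """Record of what a preprocessing step did to a table."""

    platform: str
    n_imputed_cells: int = 0
    dropped_features: dict[str, str] = field(default_factory=dict)
    normalization: str | None = None
    factors: pd.Series | None = None
    scaling: str | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "platform": self.platform,
            "n_imputed_cells": int(self.n_imputed_cells),
            "dropped_features": dict(self.dropped_features),
            "normalization": self.normalization,
            "factors": (None if self.factors is None
                        else {k: float(v) for k, v in self.factors.items()}),
            "scaling": self.scaling,
            "notes": list(self.notes),
        }


def _study_samples(table: FeatureTable, metadata: pd.DataFrame | None):
    if metadata is None:
        return list(table.data.index)
    qc = set(metadata.index[metadata["group"] == "QC"])
    return [s for s in table.data.index if s not in qc]


def impute_missing(table: FeatureTable, max_missing_fraction: float = 0.5,
                   metadata: pd.DataFrame | None = None
                   ) -> tuple[FeatureTable, PreprocessReport]:
    """Drop sparse features, then half-minimum impute the remaining gaps.

    A feature observed in fewer than ``1 - max_missing_fraction`` of the
    study (non-QC) samples is removed; features missing everywhere are
    removed with a warning (never imputed).  Remaining missing cells are
    replaced by half the minimum observed value of that feature.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    rep = PreprocessReport(platform=table.platform)
    df = table.data.copy()
    study = _study_samples(table, metadata)

    miss_all = df.isna().all(axis=0)
    for fid in df.columns[miss_all]:
        rep.dropped_features[fid] = "missing in all samples"
    if miss_all.any():
        warnings.warn(
            f"{int(miss_all.sum())} feature(s) missing in all samples dropped "
            f"({table.platform})", stacklevel=2)
    df = df.loc[:, ~miss_all]

    frac = df.loc[study].isna().mean(axis=0)
    too_sparse = frac > max_missing_fraction
    for fid in df.columns[too_sparse]:
        rep.dropped_features[fid] = (
            f"missing fraction {frac[fid]:.3f} > {max_missing_fraction}")
    df = df.loc[:, ~too_sparse]

    n_missing = int(df.isna().sum().sum())
    if n_missing:
        half_min = df.min(axis=0, skipna=True) / 2.0
        df = df.fillna(half_min)
    rep.n_imputed_cells = n_missing
    if (df.to_numpy() <= 0).any():
        raise ValueError("non-positive intensities after imputation")
    return FeatureTable(df, table.platform, table.internal_standard_id), rep


def normalize(table: FeatureTable, method: str = "auto"
              ) -> tuple[FeatureTable, PreprocessReport]:
    """Per-sample normalization.

    ``internal_standard``
        divide each sample's row by its internal-standard intensity and drop
        the internal-standard feature from the matrix;
    ``total_sum``
        divide each row by its sum, then rescale by the median row sum so
        intensities keep their original order of magnitude;
    ``auto``
        internal_standard when the table declares one, else total_sum.
    """
    if method == "auto":
        method = ("internal_standard" if table.internal_standard_id
                  else "total_sum")
    rep = PreprocessReport(platform=table.platform, normalization=method)
    df = table.data

    if method == "internal_standard":
        is_id = table.internal_standard_id
        if is_id is None or is_id not in df.columns:
            raise ValueError("internal_standard normalization requires an "
                             "internal-standard feature in the table")
        factors = df[is_id].astype(float)
        if (factors <= 0).any() or factors.isna().any():
            raise ValueError("internal-standard intensity must be > 0 in "
                             "every sample")
        out = df.drop(columns=[is_id]).div(factors, axis=0)
        rep.factors = factors
        rep.dropped_features[is_id] = "internal standard"
        return FeatureTable(out, table.platform, None), rep

    if method == "total_sum":
        sums = df.sum(axis=1)
        if (sums <= 0).any():
            raise ValueError("non-positive row sum encountered")
        factors = sums / sums.median()
        out = df.div(factors, axis=0)
        rep.factors = factors
        return FeatureTable(out, table.platform,
                            table.internal_standard_id), rep

    raise ValueError(f"unknown normalization method {method!r}")


@dataclass
class ScalingRecipe:
    """Stored column transform so new samples can be projected identically."""

    log2: bool
    scaling: str
    means: pd.Series
    divisors: pd.Series
    dropped_features: list[str] = field(default_factory=list)

    def apply(self, data: pd.DataFrame) -> pd.DataFrame:
        df = data.drop(columns=self.dropped_features, errors="ignore")
        df = df[self.means.index]
        if self.log2:
            df = np.log2(df)
        return (df - self.means) / self.divisors


def transform_scale(table, log2: bool = False, scaling: str = "uv"
                    ) -> tuple[pd.DataFrame, ScalingRecipe]:
    """Optional log2 transform followed by column-wise scaling.

    ``uv`` centers and divides by the column sd, ``pareto`` by the square
    root of the sd, ``center`` only centers, ``none`` leaves columns
    untouched.  Zero-variance columns are dropped (with a warning) under
    ``uv``/``pareto`` and recorded in the recipe.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    if scaling not in {"uv", "pareto", "center", "none"}:
        raise ValueError(f"unknown scaling {scaling!r}")
    if log2:
        if (df.to_numpy() <= 0).any():
            raise ValueError("log2 transform requires strictly positive data")
        df = np.log2(df)

    dropped: list[str] = []
    if scaling in {"uv", "pareto"}:
        sd = df.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            dropped = list(df.columns[zero])
            warnings.warn(f"{len(dropped)} zero-variance feature(s) dropped "
                          f"under {scaling} scaling", stacklevel=2)
            df = df.loc[:, ~zero]
            sd = sd[~zero]
        means = df.mean(axis=0)
        divisors = sd if scaling == "uv" else np.sqrt(sd)
        out = (df - means) / divisors
    elif scaling == "center":
        means = df.mean(axis=0)
        divisors = pd.Series(1.0, index=df.columns)
        out = df - means
    else:  # none
        means = pd.Series(0.0, index=df.columns)
        divisors = pd.Series(1.0, index=df.columns)
        out = df.copy()

    recipe = ScalingRecipe(log2=log2, scaling=scaling, means=means,
                           divisors=divisors, dropped_features=dropped)
    return out, recipe


@dataclass
class QcReport:
    assessable: bool
    rsd: pd.Series | None = None            # per-feature RSD over QC samples
    dispersion_ratio: float | None = None   # QC spread / study spread, PC1-2
    n_qc: int = 0

    def to_dict(self) -> dict:
        return {
            "assessable": self.assessable,
            "n_qc": int(self.n_qc),
            "dispersion_ratio": (None if self.dispersion_ratio is None
                                 else float(self.dispersion_ratio)),
            "median_rsd": (None if self.rsd is None
                           else float(self.rsd.median())),
        }


def qc_assess(table: FeatureTable, metadata: pd.DataFrame,
              n_components: int = 2) -> QcReport:
    """Analytical-stability assessment from pooled QC injections.

    Per-feature relative standard deviation is computed on the normalized,
    unscaled intensities of the QC samples.  The dispersion ratio compares
    the mean distance of QC samples to their centroid against the mean
    distance of study samples to theirs, in the first two PCA score
    dimensions of the UV-scaled full table; a ratio < 1 means the QC pool
    clusters more tightly than the biological samples.
    """
    from .chemometrics import fit_pca

    qc_ids = [s for s in table.data.index
              if s in metadata.index and metadata.loc[s, "group"] == "QC"]
    if len(qc_ids) < 3:
        return QcReport(assessable=False, n_qc=len(qc_ids))
    study_ids = [s for s in table.data.index if s not in set(qc_ids)]

    qc = table.data.loc[qc_ids]
    rsd = qc.std(axis=0, ddof=1) / qc.mean(axis=0).abs()

    scaled, _ = transform_scale(table, log2=False, scaling="uv")
    model = fit_pca(scaled, n_components=n_components)
    scores = model.scores.iloc[:, :n_components]
    qc_sc = scores.loc[qc_ids].to_numpy()
    st_sc = scores.loc[study_ids].to_numpy()
    qc_d = np.linalg.norm(qc_sc - qc_sc.mean(axis=0), axis=1).mean()
    st_d = np.linalg.norm(st_sc - st_sc.mean(axis=0), axis=1).mean()
    ratio = float(qc_d / st_d) if st_d > 0 else float("nan")
    return QcReport(assessable=True, rsd=rsd, dispersion_ratio=ratio,
                    n_qc=len(qc_ids))
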