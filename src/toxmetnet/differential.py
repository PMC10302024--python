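"""Differential-metabolite screening: fold change, t-test, VIP/FC rule,
annotation, MSI filtering and multi-platform merge.

Fold changes are arithmetic group-mean ratios (treated over control) of
normalized, unscaled intensities; p-values come from a two-sided
equal-variance Student's t-test on log2 intensities.  The screening rule is
the conjunction VIP > vip_cut AND (FC > fc_cut OR FC < 1/fc_cut), with
strict inequalities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fold_change_and_test",
    "attach_vip",
    "screen_features",
    "annotate_and_filter",
    "merge_platforms",
]


def fold_change_and_test(table, metadata: pd.DataFrame,
                         control: str = "CON", treated: str = "DOX",
                         adjust: str | None = None) -> pd.DataFrame:
    """Per-feature fold change and Student's t p-value.

    Returns a DataFrame indexed by feature id with columns ``fold_change``,
    ``log2_fc``, ``p_value`` and ``flag`` (empty, ``degenerate`` for
    zero-variance features, or ``undefined_fc`` for a zero control mean).
    QC samples are excluded.  ``adjust="bh"`` adds a ``p_adjusted`` column
    with Benjamini-Hochberg corrected values (raw p is the default and is
    always reported).
    """
    from .preprocess import FeatureTable

    df = table.data if isinstance(table, FeatureTable) else table
    con_ids = [s for s in df.index
               if s in metadata.index and metadata.loc[s, "group"] == control]
    dox_ids = [s for s in df.index
               if s in metadata.index and metadata.loc[s, "group"] == treated]
    if len(con_ids) < 2 or len(dox_ids) < 2:
        raise ValueError("need at least 2 samples per group")

    con = df.loc[con_ids].to_numpy(dtype=float)
    dox = df.loc[dox_ids].to_numpy(dtype=float)
    mean_con = con.mean(axis=0)
    mean_dox = dox.mean(axis=0)

    fc = np.full(df.shape[1], np.nan)
    valid = mean_con > 0
    fc[valid] = mean_dox[valid] / mean_con[valid]
    if (~valid).any():
        warnings.warn(f"{int((~valid).sum())} feature(s) with non-positive "
                      "control mean excluded from fold-change", stacklevel=2)

    with np.errstate(divide="ignore", invalid="ignore"):
        lcon, ldox = np.log2(con), np.log2(dox)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tstat, pval = stats.ttest_ind(ldox, lcon, axis=0, equal_var=True)

    var_pooled = lcon.var(axis=0, ddof=1) + ldox.var(axis=0, ddof=1)
    degenerate = var_pooled == 0
    same_mean = np.isclose(lcon.mean(axis=0), ldox.mean(axis=0))
    pval = np.asarray(pval, dtype=float)
    pval[degenerate & same_mean] = 1.0
    pval[degenerate & ~same_mean] = 0.0

    flag = np.where(~valid, "undefined_fc",
                    np.where(degenerate, "degenerate", ""))
    out = pd.DataFrame({
        "fold_change": fc,
        "log2_fc": np.log2(fc),
        "p_value": pval,
        "flag": flag,
    }, index=df.columns.rename("feature_id"))
    if adjust == "bh":
        ok = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        adj[ok.to_numpy()] = stats.false_discovery_control(
            out.loc[ok, "p_value"].to_numpy(), method="bh")
        out["p_adjusted"] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def attach_vip(features: pd.DataFrame, vip: pd.Series) -> pd.DataFrame:
    """Join VIP scores onto the fold-change table (inner on feature id).

    Features without a VIP (e.g. dropped as zero-variance during scaling)
    are excluded.
    """
    out = features.join(vip.rename("vip"), how="inner")
    return out


def screen_features(features: pd.DataFrame, vip_cut: float = 1.0,
                    fc_cut: float = 1.2) -> pd.DataFrame:
    """Apply the VIP/FC screening rule; adds a boolean ``passes`` column.

    A feature passes iff VIP > vip_cut and (FC > fc_cut or FC < 1/fc_cut),
    all strict.  Features with undefined fold change never pass.
    """
    if vip_cut <= 0 or fc_cut <= 0:
        raise ValueError("cutoffs must be positive")
    if "vip" not in features.columns:
        raise ValueError("screen_features requires a 'vip' column "
                         "(see attach_vip)")
    fc = features["fold_change"]
    passes = (features["vip"] > vip_cut) & (
        (fc > fc_cut) | (fc < 1.0 / fc_cut)) & fc.notna()
    out = features.copy()
    out["passes"] = passes.fillna(False)
    return out


def annotate_and_filter(passing: pd.DataFrame, annotations: pd.DataFrame,
                        platform: str, msi_max: int = 2
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach metabolite names, keep identifications at MSI <= msi_max.

    Parameters
    ----------
    passing : DataFrame
        Screened feature table (rows: feature ids that passed).
    annotations : DataFrame
        Columns ``feature_id``, ``platform``, ``metabolite``, ``msi_level``;
        duplicate (feature_id, platform) rows are rejected.
    platform : str
        Platform whose features are being annotated.

    Returns the annotated differential list and a side report of passing
    features that were dropped (unannotated or above the MSI cutoff).
    """
    ann = annotations[annotations["platform"] == platform]
    if ann.duplicated(subset=["feature_id", "platform"]).any():
        raise ValueError("duplicate (feature_id, platform) annotation rows")
    if not ann.empty and not ann["msi_level"].between(1, 4).all():
        raise ValueError("msi_level must be an integer in [1, 4]")
    ann = ann.set_index("feature_id")

    rows, side = [], []
    for fid, rec in passing.iterrows():
        if fid not in ann.index:
            side.append({"feature_id": fid, "platform": platform,
                         "reason": "unannotated"})
            continue
        a = ann.loc[fid]
        if int(a["msi_level"]) > msi_max:
            side.append({"feature_id": fid, "platform": platform,
                         "reason": f"msi_level {int(a['msi_level'])} > {msi_max}"})
            continue
        rows.append({
            "metabolite": a["metabolite"],
            "platform": platform,
            "feature_id": fid,
            "fold_change": rec["fold_change"],
            "log2_fc": rec["log2_fc"],
            "vip": rec["vip"],
            "p_value": rec["p_value"],
            "msi_level": int(a["msi_level"]),
        })
    cols = ["metabolite", "platform", "feature_id", "fold_change", "log2_fc",
            "vip", "p_value", "msi_level"]
    annotated = pd.DataFrame(rows, columns=cols)
    side_report = pd.DataFrame(side, columns=["feature_id", "platform",
                                              "reason"])
    return annotated, side_report


def merge_platforms(platform_lists, qc_rsd: dict[str, pd.Series] | None = None
                    ) -> pd.DataFrame:
    """Merge per-platform annotated differential lists into one set.

    A metabolite found on several platforms is kept once: lower MSI level
    wins, then lower QC RSD, then the lexicographically smallest platform
    name.  The result is sorted by metabolite name, so the merge is
    idempotent and invariant to the order of the input lists.
    """
    frames = [df for df in platform_lists if df is not None and not df.empty]
    if not frames:
        return pd.DataFrame(columns=["metabolite", "platform", "feature_id",
                                     "fold_change", "log2_fc", "vip",
                                     "p_value", "msi_level", "direction"])
    allrows = pd.concat(frames, ignore_index=True)

    def _rsd(row):
        if qc_rsd and row["platform"] in qc_rsd:
            s = qc_rsd[row["platform"]]
            if row["feature_id"] in s.index:
                v = s[row["feature_id"]]
                return float(v) if np.isfinite(v) else np.inf
        return np.inf

    allrows = allrows.assign(_rsd=allrows.apply(_rsd, axis=1))
    allrows = allrows.sort_values(
        ["metabolite", "msi_level", "_rsd", "platform"],
        kind="mergesort").drop_duplicates("metabolite", keep="first")
    allrows = allrows.drop(columns="_rsd").reset_index(drop=True)
    allrows["direction"] = np.where(allrows["fold_change"] < 1.0, "down", "up")
    return allrows.sort_values("metabolite", ignore_index=True)
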