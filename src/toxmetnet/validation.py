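"""Targeted-panel validation statistics for candidate biomarkers.

Group comparison (fold change and Student's t on raw absolute
concentrations) and Pearson correlation of each metabolite against serum
aminotransferase markers over the pooled study samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["targeted_group_stats", "marker_correlation"]


def _group_values(panel: pd.DataFrame, metadata: pd.DataFrame, group: str):
    ids = [s for s in panel.index
           if s in metadata.index and metadata.loc[s, "group"] == group]
    return panel.loc[ids]


def targeted_group_stats(panel: pd.DataFrame, metadata: pd.DataFrame,
                         control: str = "CON", treated: str = "DOX"
                         ) -> pd.DataFrame:
    """Per-metabolite group means, fold change and two-sided t p-value.

    Fold change is mean(treated)/mean(control) on the raw concentrations;
    the equal-variance Student's t is computed on the same scale (panel
    values are absolute concentrations, not MS intensities).  Missing panel
    cells are handled pairwise-complete, with the used counts reported.
    Zero pooled variance is flagged ``degenerate`` (p = 1 for identical
    groups, p = 0 for separated constant groups).
    """
    con = _group_values(panel, metadata, control)
    dox = _group_values(panel, metadata, treated)
    rows = []
    for m in panel.columns:
        a = con[m].dropna().to_numpy(dtype=float)
        b = dox[m].dropna().to_numpy(dtype=float)
        if len(a) < 3 or len(b) < 3:
            raise ValueError(f"metabolite {m!r}: need >= 3 values per group")
        fc = b.mean() / a.mean() if a.mean() != 0 else np.nan
        pooled_var = a.var(ddof=1) + b.var(ddof=1)
        flag = ""
        if pooled_var == 0:
            flag = "degenerate"
            p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        else:
            _, p = stats.ttest_ind(b, a, equal_var=True)
        rows.append({
            "metabolite": m,
            "mean_con": a.mean(), "sd_con": a.std(ddof=1), "n_con": len(a),
            "mean_dox": b.mean(), "sd_dox": b.std(ddof=1), "n_dox": len(b),
            "fold_change": fc, "p_value": float(p), "flag": flag,
        })
    return pd.DataFrame(rows).set_index("metabolite")


def marker_correlation(panel: pd.DataFrame, metadata: pd.DataFrame,
                       markers=("ALT", "AST"), pooled: bool = True,
                       control: str = "CON", treated: str = "DOX"
                       ) -> pd.DataFrame:
    """Pearson correlation of each metabolite with each serum marker.

    Computed over pooled control + treated samples by default (per-group
    rows are added when ``pooled=False``).  Pairs with missing values are
    dropped; fewer than 4 complete pairs yields a ``not assessable`` row.
    """
    rows = []

    def _one(m, marker, ids, label):
        x = panel.loc[ids, m]
        y = metadata.loc[ids, marker]
        ok = x.notna() & y.notna()
        if int(ok.sum()) < 4:
            rows.append({"metabolite": m, "marker": marker, "subset": label,
                         "n": int(ok.sum()), "r": np.nan, "p_value": np.nan,
                         "flag": "not assessable"})
            return
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"metabolite": m, "marker": marker, "subset": label,
                     "n": int(ok.sum()), "r": float(r), "p_value": float(p),
                     "flag": ""})

    study = [s for s in panel.index if s in metadata.index
             and metadata.loc[s, "group"] in (control, treated)]
    for m in panel.columns:
        for marker in markers:
            if marker not in metadata.columns:
                raise ValueError(f"marker {marker!r} missing from metadata")
            if pooled:
                _one(m, marker, study, "pooled")
            else:
                for grp in (control, treated):
                    ids = [s for s in study
                           if metadata.loc[s, "group"] == grp]
                    _one(m, marker, ids, grp)
    return pd.DataFrame(rows)
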