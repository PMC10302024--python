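"""PCA and OPLS-DA with cross-validated Q2, VIP scores and permutation test.

OPLS-DA follows the orthogonal-deflation scheme: orthogonal components are
extracted and removed from X first, then a single predictive component is
fitted on the deflated matrix (a binary response makes additional predictive
components unidentifiable).  For each orthogonal component:

    w   proportional to X'y, unit norm
    t   = X w,     p = X't / (t't)
    w_o proportional to p - (w'p) w, unit norm
    t_o = X w_o,   p_o = X't_o / (t_o't_o)
    X  <- X - t_o p_o'

Model statistics: R2Y is the fitted fraction of response variance, R2X the
fraction of X sum of squares captured by predictive plus orthogonal
components, and Q2 = 1 - PRESS/SS(y) under stratified k-fold cross-validation
with deterministic fold assignment from the seed.  VIP is restricted to the
predictive component, ``VIP_j = sqrt(p) * |w_j|`` with ``||w|| = 1``, so the
mean of squared VIP over retained features is exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PcaModel",
    "OplsdaModel",
    "PermutationResult",
    "fit_pca",
    "fit_oplsda",
    "vip_scores",
    "permutation_diagnostic",
]


# ---------------------------------------------------------------------- #
# PCA
# ---------------------------------------------------------------------- #

@dataclass
class PcaModel:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # features x components
    explained_variance_ratio: np.ndarray
    means: pd.Series


def fit_pca(X, n_components: int = 2) -> PcaModel:
    """Principal component analysis via SVD of the column-centered matrix.

    Explained-variance fraction of component k is the squared k-th singular
    value over the total centered sum of squares.
    """
    df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    means = df.mean(axis=0)
    xc = (df - means).to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s[0] * max(xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; "
                      "truncating", stacklevel=2)
        n_components = max(rank, 1)
    total_ss = float((s ** 2).sum())
    k = n_components
    scores = pd.DataFrame(u[:, :k] * s[:k], index=df.index,
                          columns=[f"PC{i + 1}" for i in range(k)])
    loadings = pd.DataFrame(vt[:k].T, index=df.columns, columns=scores.columns)
    evr = (s[:k] ** 2) / total_ss if total_ss > 0 else np.zeros(k)
    return PcaModel(scores=scores, loadings=loadings,
                    explained_variance_ratio=evr, means=means)


# ---------------------------------------------------------------------- #
# OPLS-DA
# ---------------------------------------------------------------------- #

@dataclass
class OplsdaModel:
    feature_ids: list[str]
    w: np.ndarray                 # predictive weights, unit norm
    t: pd.Series                  # predictive scores
    p: np.ndarray                 # predictive X loadings
    q: float                      # response loading
    w_ortho: np.ndarray           # features x n_ortho
    t_ortho: np.ndarray           # samples x n_ortho
    p_ortho: np.ndarray           # features x n_ortho
    n_ortho: int
    r2x: float
    r2y: float
    q2: float
    y_map: dict[str, float]       # group label -> 0/1 coding
    y_mean: float
    x_means: pd.Series
    cv_folds: int
    seed: int
    vip: pd.Series = field(default=None)

    def predict_scores(self, X: pd.DataFrame) -> pd.Series:
        """Predictive score of new samples after orthogonal filtering."""
        means = self.x_means.reindex(self.feature_ids).to_numpy(dtype=float)
        xc = X[self.feature_ids].to_numpy(dtype=float) - means
        for i in range(self.n_ortho):
            t_o = xc @ self.w_ortho[:, i]
            xc = xc - np.outer(t_o, self.p_ortho[:, i])
        return pd.Series(xc @ self.w, index=X.index, name="t_pred")

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "w": self.w.tolist(),
            "t": {k: float(v) for k, v in self.t.items()},
            "p": self.p.tolist(),
            "q": float(self.q),
            "w_ortho": self.w_ortho.tolist(),
            "t_ortho": self.t_ortho.tolist(),
            "p_ortho": self.p_ortho.tolist(),
            "n_ortho": int(self.n_ortho),
            "r2x": float(self.r2x),
            "r2y": float(self.r2y),
            "q2": float(self.q2),
            "y_map": self.y_map,
            "y_mean": float(self.y_mean),
            "x_means": {k: float(v) for k, v in self.x_means.items()},
            "cv_folds": int(self.cv_folds),
            "seed": int(self.seed),
            "vip": {k: float(v) for k, v in self.vip.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OplsdaModel":
        return cls(
            feature_ids=list(d["feature_ids"]),
            w=np.asarray(d["w"], dtype=float),
            t=pd.Series(d["t"]),
            p=np.asarray(d["p"], dtype=float),
            q=float(d["q"]),
            w_ortho=np.asarray(d["w_ortho"], dtype=float),
            t_ortho=np.asarray(d["t_ortho"], dtype=float),
            p_ortho=np.asarray(d["p_ortho"], dtype=float),
            n_ortho=int(d["n_ortho"]),
            r2x=float(d["r2x"]), r2y=float(d["r2y"]), q2=float(d["q2"]),
            y_map={k: float(v) for k, v in d["y_map"].items()},
            y_mean=float(d["y_mean"]),
            x_means=pd.Series(d["x_means"]).reindex(d["feature_ids"]),
            cv_folds=int(d["cv_folds"]), seed=int(d["seed"]),
            vip=pd.Series(d["vip"]).reindex(d["feature_ids"]),
        )


def _fit_core(x: np.ndarray, y: np.ndarray, n_ortho: int):
    """Deflation loop + single predictive component on centered arrays."""
    xd = x.copy()
    w_os, t_os, p_os = [], [], []
    for _ in range(n_ortho):
        w = xd.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p = xd.T @ t / tt
        w_o = p - float(w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-10 * max(1.0, np.linalg.norm(p)):
            break  # no orthogonal variation left
        w_o /= n_o
        t_o = xd @ w_o
        tt_o = float(t_o @ t_o)
        if tt_o < 1e-12:
            break
        p_o = xd.T @ t_o / tt_o
        xd = xd - np.outer(t_o, p_o)
        w_os.append(w_o)
        t_os.append(t_o)
        p_os.append(p_o)

    w = xd.T @ y
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("degenerate response: X'y vanishes")
    w /= nw
    t = xd @ w
    tt = float(t @ t)
    if tt < 1e-12:
        raise ValueError("degenerate predictive component")
    p = xd.T @ t / tt
    q = float(y @ t) / tt
    stack = (lambda lst, ncol: np.column_stack(lst) if lst
             else np.empty((ncol, 0)))
    return {
        "w": w, "t": t, "p": p, "q": q,
        "w_ortho": stack(w_os, x.shape[1]),
        "t_ortho": stack(t_os, x.shape[0]),
        "p_ortho": stack(p_os, x.shape[1]),
    }


def _stratified_folds(groups: np.ndarray, k: int, seed: int):
    """Deterministic stratified fold assignment (list of index arrays)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2 ** 31), 53]))
    folds = [[] for _ in range(k)]
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.array(sorted(f)) for f in folds if f]


def _cv_q2(x: np.ndarray, y01: np.ndarray, groups: np.ndarray,
           n_ortho: int, k: int, seed: int) -> float:
    press = 0.0
    for test in _stratified_folds(groups, k, seed):
        train = np.setdiff1d(np.arange(len(y01)), test)
        xm = x[train].mean(axis=0)
        ym = y01[train].mean()
        core = _fit_core(x[train] - xm, y01[train] - ym, n_ortho)
        xt = x[test] - xm
        for i in range(core["w_ortho"].shape[1]):
            t_o = xt @ core["w_ortho"][:, i]
            xt = xt - np.outer(t_o, core["p_ortho"][:, i])
        yhat = (xt @ core["w"]) * core["q"] + ym
        press += float(((y01[test] - yhat) ** 2).sum())
    ss = float(((y01 - y01.mean()) ** 2).sum())
    return 1.0 - press / ss


def fit_oplsda(X: pd.DataFrame, groups, n_ortho="auto",
               cv_folds: int = 7, seed: int = 0) -> OplsdaModel:
    """Fit a two-class OPLS-DA model on a scaled matrix.

    Parameters
    ----------
    X : DataFrame
        Scaled (e.g. UV) samples x features matrix, study samples only.
    groups : array-like aligned with ``X.index``
        Exactly two class labels, each with at least 3 samples.
    n_ortho : int or "auto"
        Orthogonal component count; "auto" adds components while Q2 improves
        by at least 0.01 (capped at 5).
    cv_folds : int
        Requested cross-validation folds; reduced to the smaller group size
        when necessary so every fold can be stratified.
    seed : int
        Governs fold assignment (deterministic).
    """
    g = pd.Series(np.asarray(groups), index=X.index)
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    counts = g.value_counts()
    if counts.min() < 3:
        raise ValueError("each group needs at least 3 samples")
    k = min(cv_folds, int(counts.min()))
    if k < cv_folds:
        warnings.warn(f"cv_folds reduced from {cv_folds} to {k} to allow "
                      "stratification", stacklevel=2)
    if k < 2:
        raise ValueError("at least 2 cross-validation folds required")

    y01 = (g == labels[1]).to_numpy(dtype=float)
    garr = g.to_numpy()
    x = X.to_numpy(dtype=float)
    x_means = X.mean(axis=0)
    xc = x - x_means.to_numpy()
    yc = y01 - y01.mean()

    if n_ortho == "auto":
        chosen = 0
        q2 = _cv_q2(x, y01, garr, 0, k, seed)
        while chosen < 5:
            q2_next = _cv_q2(x, y01, garr, chosen + 1, k, seed)
            if q2_next - q2 >= 0.01:
                chosen += 1
                q2 = q2_next
            else:
                break
        n_ortho = chosen
    else:
        n_ortho = int(n_ortho)
        if n_ortho < 0:
            raise ValueError("n_ortho must be >= 0")
        q2 = _cv_q2(x, y01, garr, n_ortho, k, seed)

    core = _fit_core(xc, yc, n_ortho)
    n_ortho_eff = core["w_ortho"].shape[1]
    if n_ortho_eff < n_ortho:
        warnings.warn(f"only {n_ortho_eff} orthogonal component(s) could be "
                      "extracted", stacklevel=2)

    w, t, p, q = core["w"], core["t"], core["p"], core["q"]
    # sign convention: predictive score positively associated with the
    # second (alphabetically later, e.g. DOX) group coding
    if q < 0:
        w, t, p, q = -w, -t, -p, -q
        core["w"], core["t"], core["p"], core["q"] = w, t, p, q

    resid = yc - t * q
    r2y = 1.0 - float(resid @ resid) / float(yc @ yc)
    ss_x = float((xc ** 2).sum())
    modeled = float((np.outer(t, p) ** 2).sum())
    for i in range(n_ortho_eff):
        modeled += float(
            (np.outer(core["t_ortho"][:, i], core["p_ortho"][:, i]) ** 2).sum())
    r2x = modeled / ss_x if ss_x > 0 else 0.0

    model = OplsdaModel(
        feature_ids=list(X.columns),
        w=w, t=pd.Series(t, index=X.index, name="t"), p=p, q=q,
        w_ortho=core["w_ortho"], t_ortho=core["t_ortho"],
        p_ortho=core["p_ortho"], n_ortho=n_ortho_eff,
        r2x=r2x, r2y=r2y, q2=q2,
        y_map={labels[0]: 0.0, labels[1]: 1.0},
        y_mean=float(y01.mean()), x_means=x_means,
        cv_folds=k, seed=seed,
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: OplsdaModel) -> pd.Series:
    """Predictive-component VIP: sqrt(p_count) * |w_j| (mean of VIP^2 is 1)."""
    p_count = len(model.feature_ids)
    return pd.Series(np.sqrt(p_count) * np.abs(model.w),
                     index=model.feature_ids, name="vip")


@dataclass
class PermutationResult:
    observed_r2y: float
    observed_q2: float
    null_r2y: np.ndarray
    null_q2: np.ndarray
    p_value: float


def permutation_diagnostic(X: pd.DataFrame, groups, n_perm: int = 100,
                           seed: int = 0, n_ortho="auto",
                           cv_folds: int = 7) -> PermutationResult:
    """Label-permutation null distribution of (R2Y, Q2).

    The observed model is fitted first; each permutation refits with the same
    orthogonal component count and fold settings on shuffled labels.  The
    empirical p-value is ``(1 + #{null Q2 >= observed Q2}) / (n_perm + 1)``.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    observed = fit_oplsda(X, groups, n_ortho=n_ortho, cv_folds=cv_folds,
                          seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2 ** 31), 211]))
    garr = np.asarray(groups)
    null_r2y = np.empty(n_perm)
    null_q2 = np.empty(n_perm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_perm):
            perm = rng.permutation(garr)
            m = fit_oplsda(X, perm, n_ortho=observed.n_ortho,
                           cv_folds=cv_folds,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
            null_r2y[i] = m.r2y
            null_q2[i] = m.q2
    p = (1.0 + float((null_q2 >= observed.q2).sum())) / (n_perm + 1.0)
    return PermutationResult(observed_r2y=observed.r2y,
                             observed_q2=observed.q2,
                             null_r2y=null_r2y, null_q2=null_q2, p_value=p)
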