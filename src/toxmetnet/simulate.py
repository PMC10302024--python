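"""Synthetic liver-metabolomics cohort generation.

This module fabricates the inputs the analysis pipeline expects — per-platform
feature-intensity tables, sample metadata with serum aminotransferases
(ALT/AST), a feature annotation table, and an optional targeted concentration
panel — together with a :class:`SyntheticTruth` record of every planted
effect, so that parameter-recovery tests can compare estimates against known
ground truth.

The generative model works on the natural-log intensity scale (log-normal
intensities, so planted fold changes act multiplicatively):

``log X_ij = mu_j + kappa_j * z_i + lambda_j * h_i + offset_j(group) + eps_ij``

where

* ``z_i`` is a latent per-animal *injury score*, normal with group means
  ``0`` (CON) and ``injury_separation`` (DOX) and within-group sd
  ``injury_within_sd``;
* ``kappa_j = log(FC_j) / injury_separation`` loads each marker-coupled
  biomarker on the injury score, so the between-group mean difference on the
  log scale is exactly ``log(FC_j)``;
* ``h_i`` is an independent latent *hub factor* shared by a designated hub
  metabolite and its partners, producing a correlated metabolite module;
* ``eps_ij`` is independent feature noise.

Serum ALT and AST are affine functions of the injury score plus independent
noise.  The marker noise and the residual noise of each planted biomarker are
calibrated analytically (exact log-normal mixture moments) so that the
population Pearson correlation between each planted biomarker's raw intensity
and ALT (resp. AST) has exactly the requested magnitude; the sign follows the
direction of the planted fold change (a metabolite depleted with injury is
negatively correlated with a marker that rises with injury).

QC samples emulate a pooled aliquot: the per-feature mean of the study
samples with noise at one fifth of the per-feature study sd.  Missing cells
are introduced completely at random, with doubled dropout probability in the
lowest intensity decile (a light-weight stand-in for detection-limit
censoring).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "PlatformSpec",
    "HubSpec",
    "MarkerCoupling",
    "CohortSpec",
    "SyntheticTruth",
    "generate_cohort",
    "generate_targeted_panel",
    "DEFAULT_METABOLITE_POOL",
]

# Affine anchors for the serum markers (arbitrary units on a U/L-like scale).
ALT_BASE, ALT_GAIN = 100.0, 30.0
AST_BASE, AST_GAIN = 120.0, 35.0

#: Metabolite names used to populate the annotated subset of features.
DEFAULT_METABOLITE_POOL = [
    "phenylalanine", "tyrosine", "tryptophan", "serine", "leucine",
    "glycine", "glutamate", "alanine", "valine", "isoleucine",
    "proline", "threonine", "methionine", "lysine", "histidine",
    "aspartic acid", "glucose 6-phosphate", "malic acid", "succinic acid",
    "citric acid", "fumaric acid", "lactic acid", "pyruvic acid",
    "linoleic acid", "arachidonic acid", "eicosapentaenoic acid",
    "cholic acid", "taurocholic acid", "adenosine monophosphate",
    "N-acetylneuraminic acid",
]

_DEFAULT_PLANTED = {
    "phenylalanine": 0.5,
    "tyrosine": 0.55,
    "tryptophan": 0.6,
    "glutamate": 0.7,
    "linoleic acid": 0.65,
    "arachidonic acid": 0.7,
    "eicosapentaenoic acid": 0.6,
    "glucose 6-phosphate": 1.6,
    "malic acid": 1.5,
    "succinic acid": 1.4,
    "lactic acid": 1.5,
    "N-acetylneuraminic acid": 1.3,
}


@dataclass(frozen=True)
class PlatformSpec:
    """One analytical platform: name, feature count, internal-standard id."""

    name: str
    n_features: int
    internal_standard_id: str | None = None

    @property
    def is_id(self) -> str:
        return self.internal_standard_id or f"{self.name}_IS"


@dataclass(frozen=True)
class HubSpec:
    """A correlated metabolite module: hub name, partner count, hub-partner rho."""

    metabolite: str
    n_partners: int
    rho: float


@dataclass(frozen=True)
class MarkerCoupling:
    """Target Pearson r magnitude between planted biomarkers and ALT / AST."""

    r_alt: float
    r_ast: float


def _default_platforms() -> list[PlatformSpec]:
    return [PlatformSpec("GC-MS", 800), PlatformSpec("LC-MS-pos", 800)]


def _default_hub() -> HubSpec:
    return HubSpec("serine", 8, 0.8)


@dataclass
class CohortSpec:
    """Full description of a synthetic two-group cohort with pooled QC samples.

    Defaults emulate a small-animal hepatotoxicity study: 6 control and 6
    treated animals, 6 pooled-QC injections, two platforms with 800 features
    each, a 28-metabolite annotated subset, ~0.5-0.7 fold-change depletions
    planted on aromatic amino acids and fatty acids (with a few up-regulated
    energy metabolites), an 8-partner correlation hub on serine, and serum
    markers coupled to the planted biomarkers at |r| = 0.9 (ALT) / 0.85 (AST).
    """

    n_con: int = 6
    n_dox: int = 6
    n_qc: int = 6
    platforms: list[PlatformSpec] = field(default_factory=_default_platforms)
    n_annotated: int = 28
    planted_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PLANTED))
    hub: HubSpec | None = field(default_factory=_default_hub)
    marker_coupling: MarkerCoupling | None = MarkerCoupling(-0.9, -0.85)
    baseline_log_mean: float = 13.8
    baseline_log_sd: float = 1.5
    noise_log_sd: float = 0.2
    hub_log_sd: float = 0.3
    injury_separation: float = 6.0
    injury_within_sd: float = 1.0
    missing_rate: float = 0.1
    seed: int = 0

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        if min(self.n_con, self.n_dox, self.n_qc) <= 0:
            raise ValueError("sample counts must be positive")
        if not self.platforms:
            raise ValueError("at least one platform is required")
        for pl in self.platforms:
            if pl.n_features <= 0:
                raise ValueError(f"platform {pl.name!r} needs n_features > 0")
        if any(fc <= 0 for fc in self.planted_effects.values()):
            raise ValueError("planted fold changes must be > 0")
        if not 0.0 <= self.missing_rate < 0.3:
            raise ValueError("missing_rate must lie in [0, 0.3)")
        if self.hub is not None:
            if not abs(self.hub.rho) < 1:
                raise ValueError("|hub partner rho| must be < 1")
            if self.hub.n_partners >= self.n_annotated:
                raise ValueError("hub partner count must be < n_annotated")
        if self.marker_coupling is not None:
            if not (abs(self.marker_coupling.r_alt) < 1
                    and abs(self.marker_coupling.r_ast) < 1):
                raise ValueError("|marker coupling r| must be < 1")
        if self.injury_separation <= 0 or self.injury_within_sd <= 0:
            raise ValueError("injury factor parameters must be positive")
        n_named = len(self._annotated_names())
        if n_named > self.n_annotated:
            raise ValueError(
                "n_annotated too small for planted + hub metabolites "
                f"({n_named} names needed, n_annotated={self.n_annotated})")
        total_annot = sum(1 for _ in self._platform_assignment())
        smallest = min(pl.n_features for pl in self.platforms)
        if total_annot > smallest * len(self.platforms):
            raise ValueError("annotated metabolites exceed available features")

    # ------------------------------------------------------------------ #
    def _hub_members(self) -> list[str]:
        """Hub metabolite followed by its partners (deterministic)."""
        if self.hub is None:
            return []
        taken = [self.hub.metabolite]
        pool = [n for n in DEFAULT_METABOLITE_POOL
                if n not in self.planted_effects and n not in taken]
        # user-planted names outside the pool never become partners
        for name in pool:
            if len(taken) - 1 == self.hub.n_partners:
                break
            taken.append(name)
        if len(taken) - 1 < self.hub.n_partners:
            # extend with generic names when the pool runs dry
            i = 1
            while len(taken) - 1 < self.hub.n_partners:
                cand = f"hub partner {i}"
                if cand not in self.planted_effects:
                    taken.append(cand)
                i += 1
        return taken

    def _annotated_names(self) -> list[str]:
        """Ordered annotated metabolite names: planted, hub members, fill."""
        names = list(self.planted_effects)
        for n in self._hub_members():
            if n not in names:
                names.append(n)
        for n in DEFAULT_METABOLITE_POOL:
            if len(names) >= self.n_annotated:
                break
            if n not in names:
                names.append(n)
        i = 1
        while len(names) < self.n_annotated:
            names.append(f"metabolite {i:03d}")
            i += 1
        return names[: self.n_annotated]

    def _platform_assignment(self):
        """Yield (name, platform_index, secondary_platform_index_or_None)."""
        P = len(self.platforms)
        for i, name in enumerate(self._annotated_names()):
            second = (i + 1) % P if (P > 1 and i % 5 == 0) else None
            yield name, i % P, second


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery testing."""

    seed: int
    fold_change: dict[str, float]
    kappa: dict[str, float]
    hub_metabolite: str | None
    hub_partners: list[str]
    injury_score: pd.Series            # latent z per study sample
    injury_within: pd.Series           # within-group component w per sample
    alt: pd.Series
    ast: pd.Series
    panel_base: dict[str, float]       # absolute base concentration per name
    feature_map: dict[str, list[tuple[str, str]]]  # name -> [(platform, fid)]
    coupling_target: tuple[float, float] | None

    def planted(self) -> list[str]:
        return [m for m, fc in self.fold_change.items() if fc != 1.0]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "fold_change": self.fold_change,
            "kappa": self.kappa,
            "hub_metabolite": self.hub_metabolite,
            "hub_partners": self.hub_partners,
            "injury_score": self.injury_score.to_dict(),
            "injury_within": self.injury_within.to_dict(),
            "alt": self.alt.to_dict(),
            "ast": self.ast.to_dict(),
            "panel_base": self.panel_base,
            "feature_map": {k: [list(t) for t in v]
                            for k, v in self.feature_map.items()},
            "coupling_target": self.coupling_target,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"],
            fold_change=d["fold_change"],
            kappa=d["kappa"],
            hub_metabolite=d["hub_metabolite"],
            hub_partners=d["hub_partners"],
            injury_score=pd.Series(d["injury_score"]),
            injury_within=pd.Series(d["injury_within"]),
            alt=pd.Series(d["alt"]),
            ast=pd.Series(d["ast"]),
            panel_base=d["panel_base"],
            feature_map={k: [tuple(t) for t in v]
                         for k, v in d["feature_map"].items()},
            coupling_target=(tuple(d["coupling_target"])
                             if d["coupling_target"] else None),
        )


# ---------------------------------------------------------------------- #
# coupling calibration: exact log-normal mixture moments
# ---------------------------------------------------------------------- #

def _corr_intensity_injury(kappa: float, extra_var: float,
                           group_means: np.ndarray, probs: np.ndarray,
                           sw: float) -> float:
    """Population Pearson corr between exp(kappa*z + noise) and z.

    ``z`` is a two-component normal mixture with the given group means,
    mixing probabilities and common within sd ``sw``; ``noise`` is
    independent normal with variance ``extra_var``.  All moments are exact
    (log-normal mixture), so the returned correlation is exact as well.
    """
    if kappa == 0.0:
        return 0.0
    sig2 = kappa * kappa * sw * sw + extra_var
    a = kappa * group_means
    e_g = np.exp(a + sig2 / 2.0)
    v_g = e_g ** 2 * math.expm1(sig2)
    c_g = kappa * sw * sw * e_g          # Stein: Cov(e^L, w | g)
    ex = float(probs @ e_g)
    ez = float(probs @ group_means)
    cov = float(probs @ (c_g + (e_g - ex) * (group_means - ez)))
    var_x = float(probs @ (v_g + (e_g - ex) ** 2))
    var_z = sw * sw + float(probs @ (group_means - ez) ** 2)
    return cov / math.sqrt(var_x * var_z)


def _solve_noise_for_corr(kappa: float, base_var: float, target: float,
                          group_means: np.ndarray, probs: np.ndarray,
                          sw: float) -> float:
    """Extra noise variance (beyond ``base_var``) giving |corr| == target."""
    def f(v):
        return abs(_corr_intensity_injury(kappa, v, group_means, probs, sw)) - target

    lo = base_var
    if f(lo) < 0:
        raise ValueError(
            "marker coupling target unattainable for a planted biomarker "
            f"(max |r| = {f(lo) + target:.3f} < {target:.3f}); weaken the "
            "coupling target, the hub loading, or strengthen the fold change")
    hi = max(1.0, 2.0 * lo + 1.0)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - cannot happen for |target|>0
            raise RuntimeError("noise calibration failed to bracket")
    v = brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)
    return float(v - base_var)


# ---------------------------------------------------------------------- #
# cohort generation
# ---------------------------------------------------------------------- #

def generate_cohort(spec: CohortSpec):
    """Generate a synthetic cohort.

    Returns
    -------
    tables : dict[str, FeatureTable]
        One feature table per platform (samples x features, raw intensities
        with missing cells as NaN, internal-standard feature included).
    metadata : pandas.DataFrame
        Indexed by sample id, columns ``group`` / ``ALT`` / ``AST``
        (aminotransferases NaN for QC injections).
    annotations : pandas.DataFrame
        Columns ``feature_id``, ``platform``, ``metabolite``, ``msi_level``.
    truth : SyntheticTruth
    """
    from .preprocess import FeatureTable  # local import avoids cycles

    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    n_study = spec.n_con + spec.n_dox
    con_ids = [f"CON_{i + 1}" for i in range(spec.n_con)]
    dox_ids = [f"DOX_{i + 1}" for i in range(spec.n_dox)]
    qc_ids = [f"QC_{i + 1}" for i in range(spec.n_qc)]
    study_ids = con_ids + dox_ids
    is_dox = np.array([0] * spec.n_con + [1] * spec.n_dox)

    delta, sw = spec.injury_separation, spec.injury_within_sd
    group_means = np.array([0.0, delta])
    probs = np.array([spec.n_con, spec.n_dox], dtype=float) / n_study

    # latent factors -- draw order is fixed for determinism
    w = rng.standard_normal(n_study)                  # within-group injury
    z = group_means[is_dox] + sw * w
    h = rng.standard_normal(n_study)                  # hub factor

    # -------------------- per-metabolite structural parameters ----------
    names = spec._annotated_names()
    hub_members = spec._hub_members()
    hub_set = set(hub_members)
    coupled = spec.marker_coupling is not None

    kappa = {m: 0.0 for m in names}
    offset = {m: 0.0 for m in names}                  # plain DOX log offset
    hub_loading = {m: 0.0 for m in names}
    resid_sd = {m: spec.noise_log_sd for m in names}

    if spec.hub is not None:
        rho = abs(spec.hub.rho)
        r_hub = math.sqrt(rho) if math.sqrt(rho) >= 0.98 else 0.98
        r_part = rho / r_hub
        for m in hub_members:
            r = r_hub if m == spec.hub.metabolite else r_part
            hub_loading[m] = r * spec.hub_log_sd
            resid_sd[m] = spec.hub_log_sd * math.sqrt(max(1.0 - r * r, 0.0))

    planted = {m: fc for m, fc in spec.planted_effects.items() if fc != 1.0}
    for m, fc in planted.items():
        if coupled:
            kappa[m] = math.log(fc) / delta
        else:
            offset[m] = math.log(fc)

    tau_alt = tau_ast = None
    if coupled and planted:
        c_max = {}
        for m in planted:
            base_var = hub_loading[m] ** 2
            c_max[m] = abs(_corr_intensity_injury(
                kappa[m], base_var, group_means, probs, sw))
        c_star = 0.999 * min(c_max.values())
        r_alt = abs(spec.marker_coupling.r_alt)
        r_ast = abs(spec.marker_coupling.r_ast)
        if max(r_alt, r_ast) > c_star:
            raise ValueError(
                f"marker coupling target |r| = {max(r_alt, r_ast):.3f} exceeds "
                f"the attainable maximum {c_star:.3f} for this spec")
        for m in planted:
            extra = _solve_noise_for_corr(
                kappa[m], hub_loading[m] ** 2, c_star, group_means, probs, sw)
            resid_sd[m] = math.sqrt(extra)
        var_z = sw * sw + float(probs @ (group_means - probs @ group_means) ** 2)
        rho_alt = r_alt / c_star
        rho_ast = r_ast / c_star
        tau_alt = ALT_GAIN * math.sqrt(var_z) * math.sqrt(1.0 / rho_alt ** 2 - 1.0)
        tau_ast = AST_GAIN * math.sqrt(var_z) * math.sqrt(1.0 / rho_ast ** 2 - 1.0)

    if tau_alt is None:
        var_z = sw * sw + float(probs @ (group_means - probs @ group_means) ** 2)
        tau_alt = 0.33 * ALT_GAIN * math.sqrt(var_z)
        tau_ast = 0.33 * AST_GAIN * math.sqrt(var_z)

    # panel base concentrations (arbitrary absolute units, e.g. nmol/g)
    base_draw = rng.normal(math.log(100.0), 0.5, size=len(names))
    panel_base = {m: float(np.exp(b)) for m, b in zip(names, base_draw)}

    # -------------------- feature bookkeeping ---------------------------
    feature_map: dict[str, list[tuple[str, str]]] = {m: [] for m in names}
    annot_rows = []
    per_platform_features: dict[str, list[str]] = {
        pl.name: [] for pl in spec.platforms}
    feat_struct: dict[str, dict[str, tuple]] = {
        pl.name: {} for pl in spec.platforms}  # fid -> (kappa, off, lam, sd)

    msi_cycle = [1, 2, 2, 3]
    for i, (name, p_idx, p2_idx) in enumerate(spec._platform_assignment()):
        msi = 1 if (name in planted or name in hub_set) else \
            msi_cycle[i % len(msi_cycle)]
        for idx in filter(lambda j: j is not None, (p_idx, p2_idx)):
            pl = spec.platforms[idx]
            fid = f"{pl.name}_F{len(per_platform_features[pl.name]):04d}"
            per_platform_features[pl.name].append(fid)
            feat_struct[pl.name][fid] = (
                kappa[name], offset[name], hub_loading[name], resid_sd[name])
            feature_map[name].append((pl.name, fid))
            annot_rows.append(
                {"feature_id": fid, "platform": pl.name,
                 "metabolite": name, "msi_level": msi})

    for pl in spec.platforms:
        feats = per_platform_features[pl.name]
        if len(feats) > pl.n_features:
            raise ValueError(
                f"platform {pl.name!r} too small for its annotated features")
        while len(feats) < pl.n_features:
            fid = f"{pl.name}_F{len(feats):04d}"
            feats.append(fid)
            feat_struct[pl.name][fid] = (0.0, 0.0, 0.0, spec.noise_log_sd)

    annotations = pd.DataFrame(
        annot_rows, columns=["feature_id", "platform", "metabolite", "msi_level"])

    # -------------------- intensity matrices ----------------------------
    tables: dict[str, object] = {}
    for pl in spec.platforms:
        feats = per_platform_features[pl.name]
        nf = len(feats)
        mu = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=nf)
        kap = np.array([feat_struct[pl.name][f][0] for f in feats])
        off = np.array([feat_struct[pl.name][f][1] for f in feats])
        lam = np.array([feat_struct[pl.name][f][2] for f in feats])
        sd = np.array([feat_struct[pl.name][f][3] for f in feats])

        eps = rng.standard_normal((n_study, nf)) * sd
        logx = (mu[None, :] + np.outer(z, kap) + np.outer(h, lam)
                + np.outer(is_dox, off) + eps)
        x_study = np.exp(logx)

        # pooled QC: raw study mean with noise at 1/5 of the study log sd
        log_sd_emp = logx.std(axis=0, ddof=1)
        qc_noise = rng.standard_normal((spec.n_qc, nf)) * (log_sd_emp / 5.0)
        x_qc = x_study.mean(axis=0)[None, :] * np.exp(qc_noise)

        x = np.vstack([x_study, x_qc])
        sample_ids = pd.Index(study_ids + qc_ids, name="sample_id")

        # internal standard: 2% CV, never missing
        is_col = np.exp(
            math.log(math.exp(spec.baseline_log_mean))
            + rng.standard_normal(len(sample_ids)) * 0.02)

        if spec.missing_rate > 0:
            p0 = spec.missing_rate / 1.1
            q10 = np.quantile(x, 0.10)
            p_cell = np.where(x < q10, 2.0 * p0, p0)
            mask = rng.random(x.shape) < p_cell
            x = np.where(mask, np.nan, x)

        df = pd.DataFrame(x, index=sample_ids, columns=feats)
        df[pl.is_id] = is_col
        tables[pl.name] = FeatureTable(
            data=df, platform=pl.name, internal_standard_id=pl.is_id)

    # -------------------- serum markers & metadata ----------------------
    alt = ALT_BASE + ALT_GAIN * z + rng.standard_normal(n_study) * tau_alt
    ast = AST_BASE + AST_GAIN * z + rng.standard_normal(n_study) * tau_ast
    metadata = pd.DataFrame({
        "group": ["CON"] * spec.n_con + ["DOX"] * spec.n_dox
                 + ["QC"] * spec.n_qc,
        "ALT": list(alt) + [np.nan] * spec.n_qc,
        "AST": list(ast) + [np.nan] * spec.n_qc,
    }, index=pd.Index(study_ids + qc_ids, name="sample_id"))

    fold_change = {m: float(spec.planted_effects.get(m, 1.0)) for m in names}
    truth = SyntheticTruth(
        seed=spec.seed,
        fold_change=fold_change,
        kappa={m: float(kappa[m]) for m in names},
        hub_metabolite=spec.hub.metabolite if spec.hub else None,
        hub_partners=hub_members[1:] if spec.hub else [],
        injury_score=pd.Series(z, index=study_ids),
        injury_within=pd.Series(sw * w, index=study_ids),
        alt=pd.Series(alt, index=study_ids),
        ast=pd.Series(ast, index=study_ids),
        panel_base=panel_base,
        feature_map=feature_map,
        coupling_target=((spec.marker_coupling.r_alt,
                          spec.marker_coupling.r_ast) if coupled else None),
    )
    return tables, metadata, annotations, truth


# ---------------------------------------------------------------------- #
# targeted panel
# ---------------------------------------------------------------------- #

def generate_targeted_panel(truth: SyntheticTruth, metabolites: list[str],
                            cv: float, seed: int | None = None) -> pd.DataFrame:
    """Absolute-concentration panel for the requested metabolites.

    Concentrations preserve each metabolite's true fold change exactly when
    ``cv == 0`` (the within-group injury coupling is renormalised by its group
    mean so the arithmetic group-mean ratio equals the planted fold change)
    and carry multiplicative log-normal noise with the given coefficient of
    variation otherwise.  Rows are the study samples.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    unknown = [m for m in metabolites if m not in truth.fold_change]
    if unknown:
        raise KeyError(f"unknown metabolite(s): {unknown}")
    if seed is None:
        seed_seq = np.random.SeedSequence([int(truth.seed) % (2 ** 31), 977])
    else:
        seed_seq = np.random.SeedSequence(int(seed) % (2 ** 31))
    rng = np.random.default_rng(seed_seq)

    samples = list(truth.injury_score.index)
    dox = np.array([s.startswith("DOX") for s in samples])
    w = truth.injury_within.to_numpy()
    sigma = math.sqrt(math.log1p(cv * cv)) if cv > 0 else 0.0

    out = {}
    for m in metabolites:
        fc = truth.fold_change[m]
        kap = truth.kappa[m]
        u = np.exp(kap * w)
        for grp_mask in (dox, ~dox):
            u[grp_mask] = u[grp_mask] / u[grp_mask].mean()
        conc = truth.panel_base[m] * np.where(dox, fc, 1.0) * u
        if sigma > 0:
            conc = conc * np.exp(rng.standard_normal(len(samples)) * sigma
                                 - sigma * sigma / 2.0)
        out[m] = conc
    return pd.DataFrame(out, index=pd.Index(samples, name="sample_id"))
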