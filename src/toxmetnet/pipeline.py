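"""Pipeline configuration and end-to-end orchestration.

One config (YAML-serialisable) drives the whole run: synthetic-cohort
generation or file inputs, preprocessing, PCA/OPLS-DA, differential
screening, network construction and targeted validation.  Every output file
is hashed into a manifest so identical config + seed runs are verifiably
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, io, network, simulate, validation
from .chemometrics import fit_oplsda, fit_pca, permutation_diagnostic
from .preprocess import impute_missing, normalize, qc_assess, transform_scale

__all__ = ["PipelineConfig", "RunArtifacts", "read_tables", "run_pipeline"]

log = logging.getLogger("toxmetnet")


@dataclass
class InputPaths:
    feature_tables: list[dict] = field(default_factory=list)
    metadata: str | None = None
    annotations: str | None = None
    panel: str | None = None


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults mirror the published settings
    (VIP > 1, FC > 1.2 or < 1/1.2, MSI <= 2, K = 30, K scan 10-80 step 5,
    7-fold cross-validation)."""

    seed: int = 0
    output_dir: str = "toxmetnet_out"
    synthetic: dict | None = field(default_factory=dict)
    inputs: InputPaths | None = None
    # preprocessing
    max_missing_fraction: float = 0.5
    normalization: str = "auto"
    scaling: str = "uv"
    log2: bool = False
    # modelling
    n_ortho: int | str = "auto"
    cv_folds: int = 7
    n_perm: int = 0
    # screening
    vip_cut: float = 1.0
    fc_cut: float = 1.2
    msi_max: int = 2
    # network
    k: int = 30
    k_mode: str = "fixed"           # fixed | scan
    k_range: tuple[int, int, int] = (10, 80, 5)
    weighted_ec: bool = False
    # validation
    validation_metabolites: list[str] | None = None
    panel_cv: float = 0.1

    def validate(self) -> None:
        if self.vip_cut <= 0 or self.fc_cut <= 0 or self.msi_max < 1:
            raise ValueError("screening cutoffs must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k_mode not in {"fixed", "scan"}:
            raise ValueError("k_mode must be 'fixed' or 'scan'")
        lo, hi, step = self.k_range
        if not (lo <= hi and step > 0):
            raise ValueError("k_range must be ascending with positive step")
        if self.synthetic is None and self.inputs is None:
            raise ValueError("either a synthetic spec or input paths needed")

    # ------------------------------------------------------------------ #
    def k_values(self) -> list[int]:
        lo, hi, step = self.k_range
        return list(range(lo, hi + 1, step))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "inputs" in d and d["inputs"] is not None:
            d["inputs"] = InputPaths(**d["inputs"])
        if "k_range" in d and d["k_range"] is not None:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def cohort_spec_from_dict(d: dict) -> simulate.CohortSpec:
    """Build a CohortSpec from a plain config dictionary."""
    d = dict(d or {})
    if "platforms" in d:
        d["platforms"] = [simulate.PlatformSpec(**p) if isinstance(p, dict)
                          else p for p in d["platforms"]]
    if isinstance(d.get("hub"), dict):
        d["hub"] = simulate.HubSpec(**d["hub"])
    if isinstance(d.get("marker_coupling"), (list, tuple)):
        d["marker_coupling"] = simulate.MarkerCoupling(*d["marker_coupling"])
    elif isinstance(d.get("marker_coupling"), dict):
        d["marker_coupling"] = simulate.MarkerCoupling(**d["marker_coupling"])
    return simulate.CohortSpec(**d)


@dataclass
class RunArtifacts:
    output_dir: Path
    manifest: dict

    def path(self, name: str) -> Path:
        return self.output_dir / name


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_tables(config: PipelineConfig):
    """Load and validate the external input tables named in the config."""
    inp = config.inputs
    if inp is None:
        raise ValueError("config has no input paths")
    tables = {}
    for spec in inp.feature_tables:
        ft = io.read_feature_table(spec["path"], spec["platform"],
                                   spec.get("internal_standard_id"))
        tables[ft.platform] = ft
    metadata = io.read_metadata(inp.metadata)
    for ft in tables.values():
        io.check_metadata_covers(ft, metadata)
    annotations = (io.read_annotations(inp.annotations)
                   if inp.annotations else None)
    panel = io.read_panel(inp.panel) if inp.panel else None
    return tables, metadata, annotations, panel


def run_pipeline(config: PipelineConfig,
                 output_dir: str | Path | None = None) -> RunArtifacts:
    """Execute the full pipeline and return the run manifest.

    Stage order: impute -> normalize -> scale -> QC assessment -> PCA ->
    OPLS-DA (optional permutation diagnostic) -> fold change & t-test ->
    VIP/FC screen -> annotate & MSI filter -> platform merge -> Spearman
    matrix -> density scan -> top-K network -> eigenvector centrality ->
    export -> targeted validation (when a panel is available).
    """
    config.validate()
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    files: dict[str, str] = {}
    stages: list[dict] = []

    def _emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        files[name] = _sha256(path)

    def _stage(name: str, **info) -> None:
        stages.append({"stage": name, **{k: str(v) for k, v in info.items()}})
        log.info("%s %s", name, info)

    try:
        # ------------------------------------------------ inputs
        truth = None
        panel = None
        if config.synthetic is not None:
            spec = cohort_spec_from_dict(
                {**config.synthetic, "seed": config.seed})
            tables, metadata, annotations, truth = simulate.generate_cohort(spec)
            for name, ft in tables.items():
                _emit(f"features_{name}.csv",
                      lambda p, ft=ft: io.write_feature_table(ft, p))
            _emit("metadata.csv", lambda p: io.write_metadata(metadata, p))
            _emit("annotations.csv",
                  lambda p: io.write_annotations(annotations, p))
            _emit("truth.json", lambda p: truth.to_json(p))
            _stage("simulate", platforms=list(tables),
                   n_samples=len(metadata))
            panel_names = (config.validation_metabolites
                           or [m for m in truth.planted()])
            if panel_names:
                panel = simulate.generate_targeted_panel(
                    truth, panel_names, cv=config.panel_cv)
                _emit("panel.csv", lambda p: io.write_panel(panel, p))
        else:
            tables, metadata, annotations, panel = read_tables(config)
            _stage("read_tables", platforms=list(tables))

        study_mask = metadata["group"].isin(["CON", "DOX"])
        study_ids = list(metadata.index[study_mask])

        # ------------------------------------------------ per-platform
        per_platform_diff = []
        qc_rsd: dict[str, pd.Series] = {}
        normalized_tables = {}
        for name, ft in tables.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                imputed, rep_i = impute_missing(
                    ft, config.max_missing_fraction, metadata)
                normalized, rep_n = normalize(imputed, config.normalization)
            normalized_tables[name] = normalized
            _emit(f"normalized_{name}.csv",
                  lambda p, t=normalized: io.write_feature_table(t, p))
            _emit(f"preprocess_{name}.json",
                  lambda p, a=rep_i, b=rep_n: Path(p).write_text(json.dumps(
                      {"impute": a.to_dict(), "normalize": b.to_dict()},
                      indent=1, sort_keys=True)))
            _stage("preprocess", platform=name,
                   imputed=rep_i.n_imputed_cells,
                   dropped=len(rep_i.dropped_features))

            qc_rep = qc_assess(normalized, metadata)
            if qc_rep.assessable:
                qc_rsd[name] = qc_rep.rsd
            _emit(f"qc_{name}.json",
                  lambda p, r=qc_rep: Path(p).write_text(
                      json.dumps(r.to_dict(), indent=1, sort_keys=True)))
            _stage("qc_assess", platform=name,
                   ratio=qc_rep.dispersion_ratio)

            # scaled matrix on study samples only (QC never enters models)
            study_tbl = normalized.data.loc[
                [s for s in normalized.data.index if s in study_ids]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scaled, recipe = transform_scale(
                    study_tbl, log2=config.log2, scaling=config.scaling)
            groups = metadata.loc[scaled.index, "group"]

            pca = fit_pca(scaled, n_components=2)
            _emit(f"pca_scores_{name}.csv",
                  lambda p, m=pca: m.scores.to_csv(p, index_label="sample_id"))

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_oplsda(scaled, groups, n_ortho=config.n_ortho,
                                   cv_folds=config.cv_folds, seed=config.seed)
            _emit(f"oplsda_{name}.json",
                  lambda p, m=model: io.save_oplsda(m, p))
            _stage("oplsda", platform=name, n_ortho=model.n_ortho,
                   r2x=round(model.r2x, 4), r2y=round(model.r2y, 4),
                   q2=round(model.q2, 4))

            if config.n_perm >= 20:
                perm = permutation_diagnostic(
                    scaled, groups, n_perm=config.n_perm, seed=config.seed,
                    n_ortho=model.n_ortho, cv_folds=config.cv_folds)
                _emit(f"permutation_{name}.json",
                      lambda p, r=perm: Path(p).write_text(json.dumps({
                          "observed_q2": r.observed_q2,
                          "observed_r2y": r.observed_r2y,
                          "p_value": r.p_value,
                          "null_q2": list(r.null_q2),
                          "null_r2y": list(r.null_r2y)}, indent=1)))
                _stage("permutation", platform=name, p=perm.p_value)

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fc = differential.fold_change_and_test(
                    normalized.data.loc[scaled.index], metadata)
            feats = differential.attach_vip(fc, model.vip)
            screened = differential.screen_features(
                feats, vip_cut=config.vip_cut, fc_cut=config.fc_cut)
            _emit(f"differential_{name}.csv",
                  lambda p, d=screened: d.to_csv(p, index_label="feature_id"))
            passing = screened[screened["passes"]]
            _stage("screen", platform=name, n_pass=len(passing))

            if annotations is not None:
                annotated, side = differential.annotate_and_filter(
                    passing, annotations, platform=name,
                    msi_max=config.msi_max)
                _emit(f"dropped_{name}.csv",
                      lambda p, d=side: d.to_csv(p, index=False))
                per_platform_diff.append(annotated)
                _stage("annotate", platform=name, n_annotated=len(annotated))

        # ------------------------------------------------ merge + network
        merged = differential.merge_platforms(per_platform_diff, qc_rsd)
        _emit("differential_merged.csv",
              lambda p: merged.to_csv(p, index=False))
        _stage("merge", n_metabolites=len(merged))

        if len(merged) >= 2:
            levels = pd.DataFrame({
                row["metabolite"]:
                    normalized_tables[row["platform"]]
                    .data.loc[study_ids, row["feature_id"]]
                for _, row in merged.iterrows()})
            _emit("metabolite_levels.csv",
                  lambda p: levels.to_csv(p, index_label="sample_id"))

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corr = network.spearman_matrix(levels)
            _emit("scc_matrix.csv",
                  lambda p: corr.scc.to_csv(p, index_label="metabolite"))
            _emit("scc_pvalues.csv",
                  lambda p: corr.p_values.to_csv(p, index_label="metabolite"))

            scan, best_k = network.scan_density(corr, config.k_values())
            _emit("density_scan.csv", lambda p: scan.to_csv(p, index=False))
            k_used = best_k if config.k_mode == "scan" else config.k
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = network.select_top_k(corr, k_used)
            ranking = network.eigenvector_centrality(
                net, weighted=config.weighted_ec)
            _emit("centrality.csv",
                  lambda p: pd.DataFrame({
                      "ec_score": ranking.scores,
                      "in_dominant": ranking.in_dominant})
                  .to_csv(p, index_label="metabolite"))
            _emit("network.sif",
                  lambda p: network.export_network(
                      net, ranking, p, outdir / "network.graphml"))
            files["network.graphml"] = _sha256(outdir / "network.graphml")
            _stage("network", k_used=k_used, density_scan_argmin=best_k,
                   n_nodes=net.n_nodes, n_edges=net.n_edges,
                   density=round(net.density, 4))
        else:
            _stage("network", skipped="fewer than 2 differential metabolites")

        # ------------------------------------------------ validation
        if panel is not None:
            gstats = validation.targeted_group_stats(panel, metadata)
            corr_v = validation.marker_correlation(panel, metadata)
            _emit("validation_groups.csv",
                  lambda p: gstats.to_csv(p, index_label="metabolite"))
            _emit("validation_correlation.csv",
                  lambda p: corr_v.to_csv(p, index=False))
            _stage("validation", n_metabolites=panel.shape[1])
        else:
            _stage("validation", skipped="no panel supplied")

        manifest = {
            "seed": int(config.seed),
            "config": config.to_dict(),
            "stages": stages,
            "files": dict(sorted(files.items())),
        }
        config.to_yaml(outdir / "config_snapshot.yaml")
        files["config_snapshot.yaml"] = _sha256(outdir / "config_snapshot.yaml")
        manifest["files"] = dict(sorted(files.items()))
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return RunArtifacts(output_dir=outdir, manifest=manifest)
    except Exception as err:
        partial = {"error": str(err), "stages": stages,
                   "files": dict(sorted(files.items()))}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(partial, fh, indent=1, sort_keys=True)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
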