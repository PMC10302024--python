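"""Shared fixtures: small synthetic cohorts and preprocessed matrices."""

import warnings

import pandas as pd
import pytest

import toxmetnet as tn


def small_spec(seed=42, **overrides):
    """One-platform cohort small enough for fast unit tests."""
    kwargs = dict(
        seed=seed,
        platforms=[tn.PlatformSpec("GC-MS", 60)],
        n_annotated=28,
        missing_rate=0.05,
    )
    kwargs.update(overrides)
    return tn.CohortSpec(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    spec = small_spec()
    tables, metadata, annotations, truth = tn.generate_cohort(spec)
    return spec, tables, metadata, annotations, truth


@pytest.fixture(scope="session")
def preprocessed(small_cohort):
    _, tables, metadata, _, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        imputed, _ = tn.impute_missing(tables["GC-MS"], 0.5, metadata)
        normalized, _ = tn.normalize(imputed)
        study = [s for s in normalized.data.index
                 if metadata.loc[s, "group"] != "QC"]
        scaled, recipe = tn.transform_scale(
            normalized.data.loc[study], scaling="uv")
    groups = metadata.loc[scaled.index, "group"]
    return normalized, scaled, recipe, groups, metadata


def metabolite_levels(tables, metadata, truth):
    """Normalized per-metabolite level matrix over study samples."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = {}
        for name, ft in tables.items():
            imputed, _ = tn.impute_missing(ft, 0.5, metadata)
            normalized, _ = tn.normalize(imputed)
            study = [s for s in normalized.data.index
                     if metadata.loc[s, "group"] != "QC"]
            for met, locs in truth.feature_map.items():
                for plat, fid in locs:
                    if plat == name and met not in out:
                        out[met] = normalized.data.loc[study, fid]
    return pd.DataFrame(out)
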