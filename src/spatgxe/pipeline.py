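"""Orchestration: tessellate -> assign -> MH map -> model fit -> risk map.

Each stage persists its artifact before the next starts, so a failure
leaves prior outputs intact and names the failing stage. Reruns with an
identical config reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, mh, survival, tessellation

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "fit_records", "fit_to_dict"]


def _load_boundary(path):
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        return shape(gj["features"][0]["geometry"])
    if gj.get("type") == "Feature":
        return shape(gj["geometry"])
    return shape(gj)


def fit_records(records: pd.DataFrame, model: int, **kw) -> survival.SpatialCoxFit:
    """Fit Model 1, 2 or 3 to prepared survival records.

    Records need the standard covariates plus locale_id and log_density
    (added here from locale density if absent).
    """
    spec = survival.model_spec(model)
    fixed = tuple(c for c in spec.fixed if ":" in c or c in records.columns)
    spec = survival.ModelSpec(fixed, spec.random_intercept, spec.random_slope,
                              spec.prs_col, spec.strata_col if spec.strata_col in records.columns else None)
    return survival.fit_variance_components(records, spec, **kw)


def fit_to_dict(fit: survival.SpatialCoxFit) -> dict:
    hr = fit.hazard_ratios
    out = {
        "fixed_effects": {
            name: {
                "coef": float(fit.beta[name]),
                "se": float(fit.se[name]),
                "robust_se": float(fit.robust_se[name]) if fit.robust_se is not None else None,
                "hr": float(hr[name]),
            }
            for name in fit.beta.index
        },
        "loglik_integrated": fit.loglik_integrated,
        "loglik_penalized": fit.loglik_penalized,
        "loglik_fixed": fit.loglik_fixed,
        "converged": fit.converged,
    }
    if fit.spec.n_random_terms:
        out["variance_components"] = {
            k: v for k, v in (
                ("sigma2_E", fit.sigma2_E if fit.spec.random_intercept else None),
                ("sigma2_GxE", fit.sigma2_GxE if fit.spec.random_slope else None),
            ) if v is not None
        }
        out["median_hazard_ratios"] = {
            comp: {m: s.mhr for m, s in d.items()} for comp, d in fit.median_hr().items()
        }
    if "log_density" in fit.beta.index:
        out["urban_rural"] = survival.urban_rural_contrast(fit)
    return out


def run_pipeline(config: io.PipelineConfig) -> dict[str, Path]:
    """Run the full mapping pipeline; returns paths of the five artifacts
    (locales.geojson, assignment.tsv, rr.tsv, fit.json, riskmap.geojson)."""
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "validate"
    try:
        subjects, report = io.validate_subjects(io.read_subjects(config.subjects))

        stage = "tessellate"
        noncases = subjects[subjects["case"] == 0]
        points = tessellation.collapse_to_grid(
            noncases, config.resolution,
            x_col=f"x_{config.which_age}", y_col=f"y_{config.which_age}",
        )
        boundary = _load_boundary(config.boundary) if config.boundary else None
        tess = tessellation.build_tessellation(points, boundary, config.resolution)
        lmap = tessellation.grow_locales(tess, config.n_min)
        p = out_dir / "locales.geojson"
        io.write_geojson(tessellation.locale_map_to_geojson(lmap), p, config)
        artifacts["locales"] = p

        stage = "assign"
        assignment = tessellation.assign_subjects(lmap, subjects, config.which_age)
        adf = pd.DataFrame({"subject_id": subjects["id"], "locale_id": assignment})
        p = out_dir / "assignment.tsv"
        io.write_tsv(adf, p, config)
        artifacts["assignment"] = p

        stage = "mh"
        subjects = subjects.assign(
            weight=1.0 / subjects["samp_prob"].to_numpy(),
            locale_id=assignment.to_numpy(),
        )
        rr = mh.mh_risk_table(subjects, assignment, config.age_band_years,
                              weighted=config.mh_weighted)
        p = out_dir / "rr.tsv"
        io.write_tsv(rr, p, config)
        artifacts["rr"] = p

        stage = "fit"
        dens = {loc.id: loc.population_density for loc in lmap.locales}
        subjects["log_density"] = np.log(
            np.maximum(subjects["locale_id"].map(dens).to_numpy(dtype=float), 1e-12)
        )
        prs = subjects["prs"].to_numpy(dtype=float)
        subjects["prs"] = (prs - prs.mean()) / prs.std()
        fit = fit_records(
            subjects, config.model,
            theta_bounds=config.theta_bounds, objective=config.objective,
        )
        fd = fit_to_dict(fit)
        fd["exclusion_report"] = report
        fd["model"] = config.model
        p = out_dir / "fit.json"
        io.write_json(fd, p, config)
        artifacts["fit"] = p

        stage = "riskmap"
        blups = pd.DataFrame({"locale_id": [loc.id for loc in lmap.locales]})
        if fit.spec.random_intercept:
            blups["blup_E"] = blups["locale_id"].map(fit.blup_E)
            blups["hr_E"] = np.exp(blups["blup_E"])
        if fit.spec.random_slope:
            blups["blup_GxE"] = blups["locale_id"].map(fit.blup_GxE)
            blups["hr_GxE"] = np.exp(blups["blup_GxE"])
        p = out_dir / "blups.tsv"
        io.write_tsv(blups, p, config)
        artifacts["blups"] = p
        gj = survival.export_risk_map(fit, lmap)
        p = out_dir / "riskmap.geojson"
        io.write_geojson(gj, p, config)
        artifacts["riskmap"] = p
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return artifacts
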