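"""End-to-end analysis pipeline.

Ties the stages together the way the study analyses its data: per-image
calibration and segmentation, per-individual spectral contrasts, the morph
discriminant analysis with leave-one-out validation, and the hormone and
colour time-course statistics. Each stage is optional — whatever inputs the
configuration provides are analysed, failures are recorded and dependent
stages skipped, and a partial result bundle is still written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import imaging, io, simulate, stats, vision
from .classify import FEATURE_COLUMNS, canonical_discriminant, cross_validate_loo

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    output_dir: str
    seed: int = 0
    spectra_dir: str | None = None
    images_dir: str | None = None
    measurement_table: str | None = None
    thresholds: dict = field(
        default_factory=lambda: dict(imaging.DEFAULT_THRESHOLDS))
    background_reflectance: float = 0.30
    priors: str = "equal"            # or "proportional"
    fdr_q: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "spectra_dir": self.spectra_dir,
            "images_dir": self.images_dir,
            "measurement_table": self.measurement_table,
            "thresholds": dict(self.thresholds),
            "background_reflectance": self.background_reflectance,
            "priors": self.priors,
            "fdr_q": self.fdr_q,
        }


def _provenance(config: RunConfig) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }


def _segment_stage(config, bundle, errors):
    images_dir = Path(config.images_dir)
    records = []
    for img_path in sorted(images_dir.glob("*.png")) + sorted(
            images_dir.glob("*.tif*")):
        name = img_path.stem
        throat_p = images_dir / f"{name}_throat.json"
        standard_p = images_dir / f"{name}_standard.json"
        squares_p = images_dir / f"{name}_squares.csv"
        if not throat_p.exists() or not standard_p.exists():
            continue
        try:
            image = io.read_image(img_path)
            throat = io.read_mask(throat_p)
            standard = io.read_mask(standard_p)
            if squares_p.exists():
                sq = pd.read_csv(squares_p)
                model = imaging.fit_linearization(
                    sq[["R", "G", "B"]].to_numpy(),
                    sq["reflectance"].to_numpy())
                image = imaging.apply_calibration(image, model)
            image = imaging.equalize_to_standard(image, standard)
            seg = imaging.segment_throat(image, throat, config.thresholds)
            records.append({"id": name, **seg.as_dict()})
        except Exception as exc:   # noqa: BLE001 - stage errors are recorded
            errors.append({"stage": "segment", "image": name, "error": str(exc)})
    if records:
        bundle["segmentation"] = records


def _contrast_stage(config, bundle, errors):
    spectra_dir = Path(config.spectra_dir)
    system = vision.lizard_tetrachromat()
    records = []
    for spec_path in sorted(spectra_dir.glob("*.csv")):
        try:
            spectrum = io.read_spectrum_csv(spec_path).on_default_grid()
            res = vision.contrast_vs_background(
                spectrum, system,
                background_reflectance=config.background_reflectance)
            records.append({
                "id": spec_path.stem,
                "chromatic_jnd": res.chromatic_jnd,
                "achromatic_jnd": res.achromatic_jnd,
            })
        except Exception as exc:   # noqa: BLE001
            errors.append({"stage": "contrast", "spectrum": spec_path.stem,
                           "error": str(exc)})
    if records:
        bundle["contrasts"] = records


def _classify_stage(config, feature_table, bundle, errors):
    try:
        fit = canonical_discriminant(feature_table)
        priors = None
        if config.priors == "proportional":
            counts = feature_table["morph"].value_counts()
            priors = {m: counts[m] / counts.sum() for m in fit.groups}
        loo = cross_validate_loo(feature_table, priors=priors)
        bundle["dfa"] = {
            "groups": list(fit.groups),
            "eigenvalues": fit.eigenvalues.tolist(),
            "percent_variance": fit.percent_variance.tolist(),
            "wilks_lambda": fit.wilks_lambda,
            "F": fit.f_statistic,
            "df1": fit.df1,
            "df2": fit.df2,
            "confusion_matrix": loo.confusion.tolist(),
            "per_class_rates": loo.per_class_rate,
            "overall_rate": loo.overall_rate,
        }
        scores = fit.transform(
            feature_table.loc[:, list(FEATURE_COLUMNS)].to_numpy())
        bundle["canonical_scores"] = pd.DataFrame(
            scores, columns=[f"can{i + 1}" for i in range(scores.shape[1])]
        ).assign(id=feature_table["id"].values,
                 morph=feature_table["morph"].values)
    except Exception as exc:   # noqa: BLE001
        errors.append({"stage": "classify", "error": str(exc)})


def _hormone_stage(hormone_panel, bundle, errors):
    try:
        res = stats.anova_time(hormone_panel)
        pairs = stats.pairwise_adjusted(hormone_panel)
        bundle["hormone_anova"] = {
            "F": res.f_statistic, "df": [res.df_num, res.df_den],
            "p": res.p_value,
            "lsmeans": {t: {"mean": m, "se": s}
                        for t, (m, s) in res.lsmeans.items()},
            "n_records": res.n_records, "n_females": res.n_females,
            "pairwise": [
                {"pair": list(p.pair), "t": p.t_statistic, "df": p.df,
                 "p_adjusted": p.p_adjusted} for p in pairs],
        }
    except Exception as exc:   # noqa: BLE001
        errors.append({"stage": "hormone", "error": str(exc)})


def _timecourse_stage(config, timecourse, bundle, errors):
    variables = (sorted(timecourse["variable"].unique())
                 if "variable" in timecourse.columns else [None])
    results = {}
    for var in variables:
        sub = (timecourse if var is None
               else timecourse[timecourse["variable"] == var])
        label = var or "value"
        try:
            fit = stats.fit_timecourse(sub)
            entry = {
                "fixed_effects": fit.fixed_effects.reset_index()
                .to_dict("records"),
                "intercept_variance": fit.intercept_variance,
                "residual_variance": fit.residual_variance,
            }
            inter = fit.fixed_effects.loc["morph:time^2"]
            if inter["p_value"] < config.fdr_q:
                entry["per_morph"] = {}
                for morph in sorted(sub["morph"].unique()):
                    m = stats.per_morph_trend(sub, morph)
                    entry["per_morph"][morph] = (
                        m.fixed_effects.reset_index().to_dict("records"))
            results[label] = entry
        except Exception as exc:   # noqa: BLE001
            errors.append({"stage": "timecourse", "variable": label,
                           "error": str(exc)})
    if results:
        bundle["timecourse"] = results


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the configuration provides inputs for.

    Writes ``results.json`` (plus ``canonical_scores.csv`` and the echoed
    config) to the output directory and returns the result bundle. Stage
    errors are recorded under ``errors``; dependent stages are skipped.
    """
    t0 = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"provenance": _provenance(config)}
    errors: list = []

    if config.images_dir and Path(config.images_dir).exists():
        _segment_stage(config, bundle, errors)
    if config.spectra_dir and Path(config.spectra_dir).exists():
        _contrast_stage(config, bundle, errors)

    feature_table = hormone_panel = timecourse = None
    if config.measurement_table and Path(config.measurement_table).exists():
        try:
            feature_table, hormone_panel, timecourse = (
                io.read_measurement_table(config.measurement_table))
        except Exception as exc:   # noqa: BLE001
            errors.append({"stage": "read_table", "error": str(exc)})

    if feature_table is not None and len(feature_table):
        _classify_stage(config, feature_table, bundle, errors)
    if hormone_panel is not None and len(hormone_panel):
        _hormone_stage(hormone_panel, bundle, errors)
    if timecourse is not None and len(timecourse):
        _timecourse_stage(config, timecourse, bundle, errors)

    bundle["errors"] = errors
    bundle["elapsed_s"] = round(time.time() - t0, 3)

    scores = bundle.pop("canonical_scores", None)
    if scores is not None:
        scores.to_csv(out_dir / "canonical_scores.csv", index=False)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    (out_dir / "results.json").write_text(
        json.dumps(bundle, indent=2, default=float))
    logger.info("pipeline finished in %.2fs with %d stage errors",
                bundle["elapsed_s"], len(errors))
    return bundle
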