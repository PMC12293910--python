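"""End-to-end experiment orchestration.

``run_experiment`` chains the stages — simulate, featurize, label,
cross-validate, correlate, embed — and writes every artifact (manifest,
features, CV report, correlation report, UMAP coordinates) stamped with the
configuration digest and seeds, so any output is regenerable from config
plus seed alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .association import correlation_report
from .classifier import CvConfig, prepare_features, run_cv, umap_embed
from .errors import StageError, VibrouroflowError
from .features import (MfccConfig, compute_rms_envelope,
                       extract_vibration_features)
from .flow_metrics import PatternRuleConfig, classify_pattern, flow_parameters
from .io import write_manifest
from .synthetic import generate_cohort
from .types import CohortSpec, config_digest

__all__ = ["ExperimentConfig", "run_experiment", "featurize_cohort"]

logger = logging.getLogger(__name__)

REPORT_FORMAT_VERSION = "1.0"


@dataclass
class ExperimentConfig:
    """Full configuration of one reproducible experiment."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    mfcc: MfccConfig = field(default_factory=MfccConfig)
    rules: PatternRuleConfig = field(default_factory=PatternRuleConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    output_dir: str = "experiment_out"
    log_level: str = "INFO"
    umap_seed: int = 0
    run_classifier: bool = True
    run_umap: bool = True

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "noise_snr_db" in c and c["noise_snr_db"] in ("inf", None):
                c["noise_snr_db"] = np.inf
            kwargs["cohort"] = CohortSpec(**c)
        if "mfcc" in raw:
            kwargs["mfcc"] = MfccConfig(**raw["mfcc"])
        if "rules" in raw:
            kwargs["rules"] = PatternRuleConfig(**raw["rules"])
        if "cv" in raw:
            c = dict(raw["cv"])
            if "oversample_labels" in c:
                c["oversample_labels"] = frozenset(c["oversample_labels"])
            kwargs["cv"] = CvConfig(**c)
        for key in ("output_dir", "log_level", "umap_seed",
                    "run_classifier", "run_umap"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def digest(self) -> str:
        return config_digest({"cohort": self.cohort, "mfcc": self.mfcc,
                              "rules": self.rules, "cv": self.cv})


def featurize_cohort(cohort, mfcc_cfg: MfccConfig = MfccConfig(),
                     rules: PatternRuleConfig = PatternRuleConfig(),
                     onset_frac: float = 0.05) -> pd.DataFrame:
    """Per-session scalar features: uroflow parameters (when ground-truth
    flow is present) and vibration-side RMS features."""
    rows = []
    for s in cohort:
        row = {"session_id": s.session_id,
               "label": int(s.label) if s.label is not None else -1}
        if s.flow is not None:
            fp = flow_parameters(s.flow, zero_flow_cutoff=rules.zero_flow_cutoff)
            row.update(qmax=fp.qmax, voided_volume=fp.voided_volume,
                       voiding_time=fp.voiding_time,
                       time_to_qmax=fp.time_to_qmax,
                       rule_label=int(classify_pattern(s.flow, rules)))
        env = compute_rms_envelope(s.vibration)
        vf = extract_vibration_features(env, onset_frac=onset_frac)
        row.update(rms_magnitude=vf.rms_magnitude, mmax=vf.mmax,
                   signal_time=vf.signal_time, time_to_mmax=vf.time_to_mmax)
        rows.append(row)
    return pd.DataFrame(rows)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except VibrouroflowError as e:
                raise StageError(name, str(e)) from e
        return wrapped
    return deco


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Returns a dict with the in-memory reports; files written under
    ``cfg.output_dir``: ``manifest.csv``, ``features.csv``,
    ``cv_report.json``, ``correlations.json``, ``umap.csv`` and
    ``config_echo.json``.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20),
                        format="%(name)s: %(message)s")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = cfg.digest()

    cohort = _stage("simulate")(generate_cohort)(cfg.cohort, cfg.rules)
    write_manifest(out, cohort)

    features = _stage("featurize")(featurize_cohort)(
        cohort, cfg.mfcc, cfg.rules)
    features.to_csv(out / "features.csv", index=False)

    # sanity: the generator guarantees rule-consistent labels
    mismatches = int((features["label"] != features["rule_label"]).sum())
    if mismatches:
        raise StageError("label", f"{mismatches} sessions disagree with the "
                                  "rule labeler")

    fp_cols = ["voided_volume", "qmax", "voiding_time", "time_to_qmax"]
    corr = _stage("correlate")(_correlate_df)(features)
    corr_doc = {"format_version": REPORT_FORMAT_VERSION,
                "config_digest": digest, **corr.to_dict()}
    (out / "correlations.json").write_text(json.dumps(corr_doc, indent=1))

    result = {"manifest": features[["session_id", "label"] + fp_cols],
              "features": features, "correlations": corr,
              "config_digest": digest}

    if cfg.run_classifier:
        X, y = _stage("featurize")(prepare_features)(
            cohort, cfg.mfcc, cfg.cv.time_pool)
        report = _stage("train")(run_cv)((X, y), cfg.cv, cfg.mfcc)
        doc = {"format_version": REPORT_FORMAT_VERSION,
               "cohort_seed": cfg.cohort.seed, **report.to_dict(),
               "cv_config_digest": report.config_digest,
               "config_digest": digest}
        (out / "cv_report.json").write_text(json.dumps(doc, indent=1))
        result["cv_report"] = report

        if cfg.run_umap:
            emb = _stage("embed")(umap_embed)(
                X.reshape(X.shape[0], -1), cfg.umap_seed, labels=y)
            pd.DataFrame({"session_id": [s.session_id for s in cohort],
                          "x": emb.coords[:, 0], "y": emb.coords[:, 1],
                          "label": emb.labels}).to_csv(
                out / "umap.csv", index=False)
            result["embedding"] = emb

    (out / "config_echo.json").write_text(json.dumps(
        {"format_version": REPORT_FORMAT_VERSION, "config_digest": digest,
         "cohort_seed": cfg.cohort.seed,
         "shuffle_seed": cfg.cv.shuffle_seed,
         "model_seed": cfg.cv.model_seed, "umap_seed": cfg.umap_seed},
        indent=1))
    logger.info("experiment complete; artifacts in %s", out)
    return result


def _correlate_df(features: pd.DataFrame):
    from .types import FlowParameters, VibrationFeatures
    fps, vfs = [], []
    for _, r in features.iterrows():
        if pd.isna(r.get("qmax", np.nan)):
            fps.append(None)
        else:
            fps.append(FlowParameters(
                qmax=r["qmax"], voided_volume=r["voided_volume"],
                voiding_time=r["voiding_time"],
                time_to_qmax=min(r["time_to_qmax"], r["voiding_time"])))
        vfs.append(VibrationFeatures(
            rms_magnitude=r["rms_magnitude"], mmax=r["mmax"],
            signal_time=r["signal_time"],
            time_to_mmax=min(r["time_to_mmax"], r["signal_time"])))
    return correlation_report(fps, vfs)
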