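"""End-to-end orchestration: simulate -> quantify -> grade -> respond ->
validate, with a reproducible output bundle and run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grading import grade_ff_agreement
from .muscles import all_muscle_columns
from .responsiveness import (responsiveness_table, per_muscle_responsiveness,
                             stratified_responsiveness)
from .roi import calf_summary, load_nifti_pair, quantify_image
from .synthetic import CohortConfig, simulate_cohort
from .validity import (baseline_predicts_progression, bridging_correlation,
                       cmtes_cutoff_classification,
                       pooled_ff_clinical_correlation)

logger = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode='synthetic'`` simulates a cohort from ``cohort`` (a
    :class:`~cmtcalf.synthetic.CohortConfig` block); ``mode='real'``
    reads an existing cohort CSV (and optionally NIfTI images) instead.
    """

    mode: str = "synthetic"
    out_dir: str = "cmtcalf_run"
    seed: int | None = None
    cohort_csv: str | None = None      # real mode input
    image_dir: str | None = None       # real mode input (optional)
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    analyses: tuple = ("responsiveness", "stratified", "per_muscle",
                       "agreement", "pooled", "bridging", "cutoff",
                       "baseline_progression")
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("synthetic mode requires a seed")
        if self.mode == "real":
            if not self.cohort_csv:
                raise ValueError("real mode requires cohort_csv")
            if not Path(self.cohort_csv).exists():
                raise FileNotFoundError(self.cohort_csv)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def quantify_image_dir(image_dir, pattern_ff="*_ff.nii*",
                       pixel_area_mm2=None) -> pd.DataFrame:
    """Quantify every FF/label NIfTI pair in a directory.

    Pairs are matched by filename: ``<stem>_ff.nii[.gz]`` with
    ``<stem>_label.nii[.gz]``; ``<stem>`` is expected to encode subject
    and visit as ``<subject>_v<visit>``.  Returns one row per
    subject-visit-muscle.
    """
    image_dir = Path(image_dir)
    rows = []
    for ff_path in sorted(image_dir.glob(pattern_ff)):
        stem = ff_path.name.split("_ff.nii")[0]
        label_path = None
        for suffix in (".nii.gz", ".nii"):
            cand = image_dir / f"{stem}_label{suffix}"
            if cand.exists():
                label_path = cand
                break
        if label_path is None:
            raise FileNotFoundError(f"no label map for {ff_path.name}")
        ff, lab, _, px_area = load_nifti_pair(ff_path, label_path)
        if pixel_area_mm2 is not None:
            px_area = pixel_area_mm2
        subject, _, visit = stem.rpartition("_v")
        measures = quantify_image(ff, lab, px_area)
        summary = calf_summary(measures)
        for m in measures:
            rows.append({"subject_id": subject or stem,
                         "visit": int(visit) if visit.isdigit() else 1,
                         "muscle": m.muscle, "side": m.side,
                         "ff_mean": m.ff_mean, "csa": m.csa, "rma": m.rma,
                         "n_pixels": m.n_pixels,
                         "artifact_excluded": m.artifact_excluded,
                         "calf_ff": summary.ff_weighted,
                         "calf_csa": summary.csa_total,
                         "calf_rma": summary.rma_total})
    return pd.DataFrame(rows)


def _result_json(results: dict) -> dict:
    """Make nested analysis results JSON-serialisable."""
    def conv(x):
        if hasattr(x, "to_dict") and not isinstance(x, pd.DataFrame):
            return conv(x.to_dict())
        if isinstance(x, pd.DataFrame):
            return x.to_dict(orient="records")
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        if isinstance(x, (np.floating, float)):
            return None if not np.isfinite(x) else float(x)
        if isinstance(x, (np.integer,)):
            return int(x)
        return x
    return conv(results)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the output bundle.

    Writes under ``config.out_dir``: cohort and ground-truth CSVs
    (synthetic mode), responsiveness tables (whole-calf and per-muscle),
    stratified responsiveness, a validity JSON and a run manifest with
    config, seed, version and SHA-256 of every output file.  Identical
    config and seed produce a byte-identical bundle.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
        written.append(path)

    if config.mode == "synthetic":
        cc = CohortConfig(seed=config.seed, **config.cohort)
        cohort, truth = simulate_cohort(cc)
        write_csv(cohort, "cohort.csv")
        write_csv(truth, "ground_truth.csv")
        config_echo = {"run": asdict(config), "cohort_config": cc.to_dict()}
    else:
        cohort = pd.read_csv(config.cohort_csv)
        truth = None
        config_echo = {"run": asdict(config)}
        if config.image_dir:
            measures = quantify_image_dir(config.image_dir)
            write_csv(measures, "muscle_measures.csv")

    ff_cols = all_muscle_columns("ff")
    results: dict = {}
    an = set(config.analyses)
    if "responsiveness" in an:
        write_csv(responsiveness_table(
            cohort, ["calf_ff", "calf_csa", "calf_rma", "cmtes", "cmtes_ll"]),
            "responsiveness_summary.csv")
    if "per_muscle" in an:
        write_csv(per_muscle_responsiveness(cohort, ff_cols),
                  "responsiveness_per_muscle.csv")
    if "stratified" in an:
        strat = {v: {k: r.to_dict() for k, r in
                     stratified_responsiveness(cohort, visit=v).items()}
                 for v in (2, 3, 4)}
        results["stratified"] = strat
    if "agreement" in an and "mercuri_R_TA" in cohort.columns:
        base = cohort[(cohort["visit"] == 1) & (cohort["group"] == "patient")]
        mean_grade = base[all_muscle_columns("mercuri")].mean(axis=1)
        results["mercuri_ff_agreement"] = grade_ff_agreement(
            mean_grade, base["calf_ff"])
    if "pooled" in an:
        results["pooled_ff_cmtes"] = pooled_ff_clinical_correlation(cohort)
        results["pooled_ff_cmtes_ll"] = pooled_ff_clinical_correlation(
            cohort, score="cmtes_ll")
    if "bridging" in an:
        try:
            results["bridging"] = bridging_correlation(cohort)
        except ValueError as err:
            results["bridging"] = {"error": str(err)}
    if "cutoff" in an:
        cut = cmtes_cutoff_classification(cohort)
        roc = cut.pop("roc")
        cut["auc"] = roc.auc
        cut["roc_points"] = roc.points
        results["cmtes_cutoff"] = cut
    if "baseline_progression" in an:
        results["baseline_progression"] = baseline_predicts_progression(cohort)

    validity_path = out / "validity.json"
    validity_path.write_text(
        json.dumps(_result_json(results), indent=2, sort_keys=True) + "\n")
    written.append(validity_path)

    manifest = {
        "package": "cmtcalf", "version": __version__,
        "seed": config.seed, "config": config_echo,
        "outputs": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in written},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                             + "\n")
    logger.info("wrote %d files to %s", len(written) + 1, out)
    return {"out_dir": str(out), "results": results, "cohort": cohort,
            "truth": truth, "manifest": manifest}
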