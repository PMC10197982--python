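"""End-to-end orchestration: simulate -> preprocess -> features -> train -> evaluate.

One validated YAML config drives a fully reproducible run. Records are
streamed (generated, preprocessed and reduced to features one at a time)
rather than materialised, so a 1024-record cohort needs only the feature
table in memory. The simulate stage persists the label table, a
generator-truth manifest and a few sample records in the WFDB-style
dialect; downstream stages regenerate signals deterministically from the
config seed, so a resumed run reproduces a fresh one bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from . import classifiers as clf
from . import evaluation as ev
from . import synthetic as syn
from .ecg_io import write_labels, write_record
from .errors import ConfigurationError
from .features import extract_feature_vector
from .preprocess import PreprocessConfig, preprocess_record

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "RunManifest"]

log = logging.getLogger("ecgkalemia")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    n_records: int = 1024
    k_mean: float = 4.83
    k_sd: float = Field(1.01, gt=0)
    k_bounds: tuple[float, float] = (2.5, 8.0)
    duration_s: float = Field(30.0, gt=0)
    fs: float = Field(360.0, gt=0)
    amp_jitter_sd: float = Field(0.15, ge=0)
    t_jitter_sd: float = Field(0.30, ge=0)
    width_jitter_sd: float = Field(0.14, ge=0)
    qrs_width_jitter_sd: float = Field(0.08, ge=0)
    heart_rate_range_bpm: tuple[float, float] = (55.0, 90.0)
    n_sample_records: int = Field(3, ge=0)  # written in the WFDB-style dialect


class EffectSection(_Strict):
    k_ref: float = 4.0
    t_amp_gain: float = Field(0.25, ge=0)
    t_width_shrink: float = Field(0.12, ge=0)
    saturation_mmol: float = Field(1.2, gt=0)
    k_activate: float = 5.5
    p_amp_loss: float = Field(0.25, ge=0)
    pr_prolong_s: float = Field(0.020, ge=0)
    qrs_widen_s: float = Field(0.004, ge=0)


class NoiseSection(_Strict):
    baseline_wander_amp_mv: float = Field(0.20, ge=0)
    baseline_wander_hz: float = Field(0.30, ge=0)
    powerline_hz: float = Field(50.0, ge=0)
    powerline_amp_mv: float = Field(0.08, ge=0)
    white_noise_sigma_mv: float = Field(0.02, ge=0)


class PreprocessSection(_Strict):
    poly_order_pass1: int = Field(5, ge=0)
    poly_order_pass2: int = Field(3, ge=0)
    window_s: float = Field(10.0, gt=0)
    window_stride_s: float = Field(0.5, gt=0)
    reference_lead: str = "V2"
    wavelet_name: str = "db6"
    wavelet_level: int = Field(6, ge=1)
    band_low_hz: float = Field(0.5, gt=0)
    band_high_hz: float = Field(40.0, gt=0)
    filter_order: int = Field(6, ge=1)


class TrainSection(_Strict):
    test_fraction: float = Field(0.2, gt=0, lt=1)
    stratify: bool = True
    families: tuple[str, ...] = clf.MODEL_FAMILIES
    grids: dict[str, dict[str, list]] = Field(default_factory=dict)
    cv_folds: int = Field(5, ge=2)


class PipelineConfig(_Strict):
    """Validated, fully defaulted configuration of one pipeline run."""

    def __init__(self, **data):
        try:
            super().__init__(**data)
        except PydanticValidationError as exc:
            issues = "; ".join(
                f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}".lstrip(": ")
                for e in exc.errors()
            )
            raise ConfigurationError(f"invalid pipeline config: {issues}") from None

    seed: int
    outdir: str = "results/run"
    thresholds: tuple[float, ...] = clf.DEFAULT_THRESHOLDS
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    effect: EffectSection = Field(default_factory=EffectSection)
    noise: NoiseSection = Field(default_factory=NoiseSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    train: TrainSection = Field(default_factory=TrainSection)

    def model_post_init(self, _ctx) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise ConfigurationError("thresholds must be sorted ascending")
        if not self.thresholds:
            raise ConfigurationError("thresholds list must be non-empty")
        if not self.train.families:
            raise ConfigurationError("model family list must be non-empty")
        unknown = [f for f in self.train.families if f not in clf.MODEL_FAMILIES]
        if unknown:
            raise ConfigurationError(f"unknown model families {unknown}")
        for t in self.thresholds:
            if not 1.0 <= t <= 10.0:
                import warnings
                warnings.warn(
                    f"threshold {t} mmol/L is outside the plausible potassium range",
                    stacklevel=2,
                )

    # -- bridges to module-level dataclasses --------------------------------
    def dataset_config(self) -> syn.SyntheticDatasetConfig:
        s = self.simulate
        return syn.SyntheticDatasetConfig(
            n_records=s.n_records, k_mean=s.k_mean, k_sd=s.k_sd,
            k_bounds=tuple(s.k_bounds), duration_s=s.duration_s, fs=s.fs,
            seed=self.seed, amp_jitter_sd=s.amp_jitter_sd,
            t_jitter_sd=s.t_jitter_sd, width_jitter_sd=s.width_jitter_sd,
            qrs_width_jitter_sd=s.qrs_width_jitter_sd,
            heart_rate_range_bpm=tuple(s.heart_rate_range_bpm),
        )

    def effect_model(self) -> syn.KEffectModel:
        return syn.KEffectModel(**self.effect.model_dump())

    def noise_model(self) -> syn.NoiseModel:
        return syn.NoiseModel(**self.noise.model_dump())

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(**self.preprocess.model_dump())

    def model_specs(self) -> dict[str, clf.ModelSpec]:
        specs = clf.default_model_specs()
        out = {}
        for fam in self.train.families:
            grid = self.train.grids.get(fam)
            spec = specs[fam]
            if grid:
                spec = clf.ModelSpec(fam, grid, cv_folds=self.train.cv_folds)
            elif self.train.cv_folds != spec.cv_folds:
                spec = clf.ModelSpec(fam, spec.hyperparameter_grid,
                                     cv_folds=self.train.cv_folds)
            out[fam] = spec
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(path_or_mapping) -> PipelineConfig:
    """Load and validate a YAML config file (or a mapping), defaults filled.

    Unknown keys are rejected and every schema violation is reported, not
    just the first.
    """
    if isinstance(path_or_mapping, (str, Path)):
        raw = yaml.safe_load(Path(path_or_mapping).read_text()) or {}
    else:
        raw = dict(path_or_mapping)
    return PipelineConfig(**raw)


class RunManifest(dict):
    """Per-stage checksums, sizes and timings of one pipeline run."""

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self, indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> Path:
    """Write labels.csv, truth manifest and a few sample WFDB-style records."""
    ds = config.dataset_config()
    effect, noise = config.effect_model(), config.noise_model()
    labels, truth_rows = [], []
    sample_dir = outdir / "sample_records"
    n_samples = config.simulate.n_sample_records
    if n_samples:
        sample_dir.mkdir(parents=True, exist_ok=True)
    for i, (rec, lab, truth) in enumerate(syn.iter_dataset(ds, None, effect, noise)):
        labels.append(lab)
        truth_rows.append({
            "record_id": truth.record_id,
            "k_mmol_per_l": truth.k_mmol_per_l,
            "seed": truth.seed,
            "true_t_amp_mv": truth.effective_template.waves["T"].amp_mv,
            "true_t_width_s": truth.effective_template.waves["T"].width_s,
            "heart_rate_bpm": truth.template.heart_rate_bpm,
        })
        if i < n_samples:
            write_record(rec, sample_dir / f"{rec.record_id}.hea",
                         sample_dir / f"{rec.record_id}.dat")
    labels_path = outdir / "labels.csv"
    write_labels(labels, labels_path)
    pd.DataFrame(truth_rows).to_csv(outdir / "generator_truth.csv", index=False)
    log.info("simulate: %d records -> %s", len(labels), labels_path)
    return labels_path


def stage_extract_features(config: PipelineConfig, outdir: Path) -> Path:
    """Regenerate records from the seed, preprocess, extract 48 features each."""
    ds = config.dataset_config()
    effect, noise = config.effect_model(), config.noise_model()
    pre = config.preprocess_config()
    rows, skipped = [], 0
    for rec, lab, _ in syn.iter_dataset(ds, None, effect, noise):
        try:
            cleaned = preprocess_record(rec, pre)
            fv = extract_feature_vector(cleaned, pre.reference_lead)
        except Exception as exc:  # skip-and-account, never abort the cohort
            skipped += 1
            log.warning("record %s skipped: %s", rec.record_id, exc)
            continue
        row = {"record_id": rec.record_id, "k_mmol_per_l": lab.k_mmol_per_l}
        row.update(fv.as_dict())
        rows.append(row)
    features = pd.DataFrame(rows)
    path = outdir / "features.csv"
    features.to_csv(path, index=False)
    log.info("extract-features: %d records in, %d feature rows out (%d skipped)",
             ds.n_records, len(features), skipped)
    return path


def stage_train(config: PipelineConfig, features_path: Path, outdir: Path) -> Path:
    """Split, tune and train every family at every threshold; write scores."""
    df = pd.read_csv(features_path)
    dataset = clf.LabeledDataset.from_frame(df)
    specs = config.model_specs()
    scores_dir = outdir / "scores"
    scores_dir.mkdir(parents=True, exist_ok=True)
    chosen: dict[str, dict] = {}
    for thr in config.thresholds:
        y = clf.binarize_labels(dataset.k, thr)
        split = clf.split_dataset(
            dataset.n, config.train.test_fraction, seed=config.seed,
            stratify_labels=y if config.train.stratify else None,
        )
        tr, te = split.train_indices, split.test_indices
        for fam, spec in specs.items():
            t0 = time.monotonic()
            model = clf.tune_and_train(
                spec, dataset.features[tr], y[tr], seed=config.seed,
            )
            s = clf.predict_scores(model, dataset.features[te])
            out = pd.DataFrame({
                "record_id": np.asarray(dataset.record_ids)[te],
                "y_true": y[te],
                "score": s,
            })
            out.to_csv(scores_dir / f"{fam}_thr{thr:g}.csv", index=False)
            chosen.setdefault(fam, {})[f"{thr:g}"] = model.chosen_hyperparameters
            log.info("train: %s @ %.1f mmol/L in %.1f s (params %s)",
                     fam, thr, time.monotonic() - t0,
                     model.chosen_hyperparameters)
    (outdir / "chosen_hyperparameters.json").write_text(
        json.dumps(chosen, indent=2, default=str) + "\n")
    return scores_dir


def stage_evaluate(config: PipelineConfig, scores_dir: Path, outdir: Path) -> Path:
    """Assemble the metric grid and the pairwise DeLong matrix."""
    tables: dict[float, dict[str, pd.DataFrame]] = {}
    for thr in config.thresholds:
        fams = {}
        for fam in config.train.families:
            path = scores_dir / f"{fam}_thr{thr:g}.csv"
            if path.exists():
                fams[fam] = pd.read_csv(path)
        if fams:
            tables[thr] = fams
    report = ev.build_report(tables)
    report_path = outdir / "report.csv"
    report.metrics.to_csv(report_path, index=False, float_format="%.4f")
    report.delong.to_csv(outdir / "delong_tests.csv", index=False,
                         float_format="%.6g")
    roc_dir = outdir / "roc_points"
    roc_dir.mkdir(exist_ok=True)
    for (fam, thr), pts in report.roc_points.items():
        pts.to_csv(roc_dir / f"{fam}_thr{thr:g}.csv", index=False,
                   float_format="%.5f")
    log.info("evaluate: report with %d rows -> %s", len(report.metrics),
             report_path)
    return report_path


def run_pipeline(config: PipelineConfig, resume: bool = False) -> RunManifest:
    """Execute all stages in order; with ``resume``, completed stages whose
    outputs exist under a matching config hash are skipped."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), stages={})
    hash_file = outdir / "config_hash.txt"
    stale = not (resume and hash_file.exists()
                 and hash_file.read_text().strip() == config.config_hash())
    hash_file.write_text(config.config_hash() + "\n")
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(json.loads(json.dumps(config.model_dump(), default=list))))

    def _run(name: str, fn, output: Path, *args):
        t0 = time.monotonic()
        if not stale and output.exists():
            log.info("%s: resumed from %s", name, output)
        else:
            try:
                fn(*args)
            except Exception:
                log.error("stage %s failed; partial outputs kept in %s",
                          name, outdir)
                raise
        entry = {"output": str(output), "seconds": round(time.monotonic() - t0, 2)}
        if output.is_file():
            entry["sha256"] = _sha256(output)
        manifest["stages"][name] = entry
        return output

    labels = _run("simulate", stage_simulate, outdir / "labels.csv",
                  config, outdir)
    features = _run("extract_features", stage_extract_features,
                    outdir / "features.csv", config, outdir)
    scores = _run("train", stage_train, outdir / "scores", config,
                  features, outdir)
    _run("evaluate", stage_evaluate, outdir / "report.csv", config,
         scores, outdir)
    manifest["labels"] = str(labels)
    manifest.save(outdir / "manifest.json")
    return manifest
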