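"""End-to-end orchestration: simulate -> calibrate -> segment -> extract ->
preprocess -> select bands -> train -> evaluate.

The classification tasks mirror the drop-test study design:

``detect``
    binary bruised vs unbruised over all samples;
``si`` / ``sii``
    60 cm (resp. 100 cm) drops vs unbruised;
``siii``
    60 cm vs 100 cm drops;
``combined``
    the three-class severity model.

Leakage control: the preprocessing reference (MSC), the NWHFC endmember
count and the PCA band set are all fit on the training partition only and
then applied to the full table.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import band_selection as bs
from . import classification as clf
from . import preprocessing as pp
from .calibration import calibrate
from .core import ConfigurationError, make_camera_profile
from .segmentation import roi_mean_spectrum, segment_cube
from .spectra import SpectrumTable
from .synthetic import SEVERITY_CLASSES, iter_dataset

__all__ = [
    "TASKS",
    "PipelineConfig",
    "TaskResult",
    "PipelineError",
    "extract_spectrum_table",
    "run_task",
    "run_pipeline",
    "compare_preprocess",
    "run_all",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and samples."""


#: task name -> (kept original labels, label mapping, class order)
TASKS: dict[str, tuple[tuple[str, ...], dict[str, str], tuple[str, ...]]] = {
    "detect": (
        SEVERITY_CLASSES,
        {"no_drop": "no_bruise", "drop_60": "bruised", "drop_100": "bruised"},
        clf.DETECTION_ORDER,
    ),
    "si": (
        ("no_drop", "drop_60"),
        {"no_drop": "no_bruise", "drop_60": "bruised"},
        clf.DETECTION_ORDER,
    ),
    "sii": (
        ("no_drop", "drop_100"),
        {"no_drop": "no_bruise", "drop_100": "bruised"},
        clf.DETECTION_ORDER,
    ),
    "siii": (
        ("drop_60", "drop_100"),
        {"drop_60": "drop_60", "drop_100": "drop_100"},
        ("drop_60", "drop_100"),
    ),
    "combined": (
        SEVERITY_CLASSES,
        {c: c for c in SEVERITY_CLASSES},
        clf.SEVERITY_ORDER,
    ),
}


@dataclass
class PipelineConfig:
    """Fully resolved parameters of one pipeline run (YAML round-trippable)."""

    profile: str = "swir"
    n_per_class: int = 30
    seed: int = 1
    scene_height: int = 128
    scene_width: int = 128
    noise_sd: float = 0.02
    severity_shifts: dict = field(
        default_factory=lambda: {"no_drop": 0.0, "drop_60": 0.06, "drop_100": 0.10}
    )
    mixing_fraction: float = 0.85
    rho_ref: float = 0.5
    denominator_floor: float = 1.0
    clip_max: float = 1.2
    roi: str = "segmented"  # segmented | fruit_truth | bruise_truth
    preprocess: str = "snv"
    preprocess_params: dict = field(default_factory=dict)
    pf: float = 1e-3
    max_bands: int = 10
    hidden_width: int = 10
    max_epochs: int = 1000
    patience: int = 6
    learning_rate: float = 0.05
    tasks: tuple[str, ...] = ("detect", "si", "sii", "siii", "combined")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["tasks"] = list(self.tasks)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        return cls(**d)


@dataclass
class TaskResult:
    """Outcome of one classification task."""

    task: str
    report: clf.ConfusionReport
    split: clf.SplitSpec
    band_set: bs.BandSet
    endmember_estimate: bs.EndmemberEstimate
    model: clf.AnnModel
    train_report: clf.ConfusionReport
    validation_report: clf.ConfusionReport

    @property
    def test_accuracy(self) -> float:
        return self.report.accuracy


def extract_spectrum_table(config: PipelineConfig) -> SpectrumTable:
    """Simulate, calibrate and segment scenes into an ROI spectrum table.

    Scenes are generated and processed one at a time (streaming), so memory
    stays bounded for full-size datasets.  ``config.roi`` selects the region
    averaged per sample: the PCA/Otsu-segmented fruit face (default), the
    ground-truth fruit mask, or the ground-truth bruise patch.
    """
    profile = make_camera_profile(config.profile)
    rows, labels, ids = [], [], []
    failures: list[tuple[str, str]] = []
    for sample in iter_dataset(
        config.n_per_class,
        profile,
        config.seed,
        severity_shifts=config.severity_shifts,
        noise_sd=config.noise_sd,
        height=config.scene_height,
        width=config.scene_width,
        mixing_fraction=config.mixing_fraction,
    ):
        try:
            cube = calibrate(
                sample.frames.raw,
                sample.frames.white,
                sample.frames.dark,
                sample.frames.rho_ref,
                denominator_floor=config.denominator_floor,
                clip_max=config.clip_max,
            )
            if config.roi == "segmented":
                mask = segment_cube(cube)
            elif config.roi == "fruit_truth":
                mask = sample.fruit_mask
            elif config.roi == "bruise_truth":
                mask = sample.bruise_mask if sample.bruise_mask.any() else sample.fruit_mask
            else:
                raise ConfigurationError(f"unknown roi mode {config.roi!r}")
            rows.append(roi_mean_spectrum(cube, mask))
            labels.append(sample.label)
            ids.append(sample.sample_id)
        except ConfigurationError:
            raise
        except Exception as exc:  # segmentation/calibration failures are per-sample
            failures.append((sample.sample_id, str(exc)))
    if failures and not rows:
        raise PipelineError(f"extract stage failed for all samples: {failures[:3]}...")
    table = SpectrumTable(
        np.vstack(rows), profile.wavelengths, labels, ids, history=["roi_mean"]
    )
    table.failures = failures  # type: ignore[attr-defined]
    return table


def _preprocess_split_safe(
    table: SpectrumTable, spec: pp.PreprocessSpec, train_idx: np.ndarray
) -> SpectrumTable:
    """Apply preprocessing without test leakage (MSC reference from train rows)."""
    if spec.method == "msc" and "reference" not in spec.params:
        ref = table.X[train_idx].mean(axis=0)
        spec = pp.PreprocessSpec("msc", {**spec.params, "reference": ref})
    out = pp.apply(spec, table)
    excluded = getattr(out, "excluded", [])
    if excluded:
        raise PipelineError(
            f"preprocess stage ({spec.method}) flagged samples: {excluded}"
        )
    return out


def run_task(
    table: SpectrumTable,
    task: str = "combined",
    seed: int = 1,
    *,
    preprocess: str = "snv",
    preprocess_params: dict | None = None,
    pf: float = 1e-3,
    max_bands: int = 10,
    hidden_width: int = 10,
    max_epochs: int = 1000,
    patience: int = 6,
    learning_rate: float = 0.05,
) -> TaskResult:
    """Run one classification task on an extracted spectrum table.

    Splits first, then fits all data-dependent steps (MSC reference, NWHFC
    endmember count, PCA band set) on the training partition only.
    """
    if task not in TASKS:
        raise ConfigurationError(f"unknown task {task!r}; choose from {sorted(TASKS)}")
    keep_classes, mapping, class_order = TASKS[task]
    keep_idx = [i for i, lab in enumerate(table.labels) if lab in keep_classes]
    if not keep_idx:
        raise PipelineError(f"task {task}: no samples with classes {keep_classes}")
    sub = table.take_rows(keep_idx, step=f"task[{task}]")
    mapped = [mapping[lab] for lab in sub.labels]

    split_spec = clf.split(sub.n_samples, seed=seed, labels=mapped, stratify=True)

    spec = pp.PreprocessSpec(preprocess, dict(preprocess_params or {}))
    proc = _preprocess_split_safe(sub, spec, split_spec.train)

    train_table = proc.take_rows(split_spec.train)
    estimate = bs.estimate_endmembers_nwhfc(train_table, pf=pf)
    k = int(np.clip(estimate.k, 1, min(max_bands, proc.n_bands)))
    band_set = bs.select_bands(train_table, k, pf=pf)
    reduced = bs.reduce_table(proc, band_set)

    targets = clf.one_hot(mapped, class_order)
    model = clf.train_ann(
        reduced.X,
        targets,
        split_spec,
        hidden_width=hidden_width,
        max_epochs=max_epochs,
        patience=patience,
        learning_rate=learning_rate,
        seed=seed,
    )

    def _report(idx: np.ndarray) -> clf.ConfusionReport:
        pred, _ = clf.predict(model, reduced.X[idx])
        truth = [mapped[i] for i in idx]
        return clf.evaluate(truth, pred, class_order)

    return TaskResult(
        task=task,
        report=_report(split_spec.test),
        split=split_spec,
        band_set=band_set,
        endmember_estimate=estimate,
        model=model,
        train_report=_report(split_spec.train),
        validation_report=_report(split_spec.validation),
    )


def run_pipeline(config: PipelineConfig | None = None, task: str = "combined", **overrides) -> TaskResult:
    """Simulate a dataset and run one task end to end with one master seed."""
    config = config or PipelineConfig()
    if overrides:
        config = PipelineConfig(**{**asdict(config), **overrides})
    table = extract_spectrum_table(config)
    return run_task(
        table,
        task,
        seed=config.seed,
        preprocess=config.preprocess,
        preprocess_params=config.preprocess_params,
        pf=config.pf,
        max_bands=config.max_bands,
        hidden_width=config.hidden_width,
        max_epochs=config.max_epochs,
        patience=config.patience,
        learning_rate=config.learning_rate,
    )


def compare_preprocess(
    table: SpectrumTable,
    task: str = "combined",
    seeds: tuple[int, ...] = (1, 2, 3),
    **task_kwargs,
) -> dict:
    """Rank all preprocessing variants by mean test accuracy on one table."""
    ranking = []
    for method in pp.METHODS:
        accs = []
        for seed in seeds:
            res = run_task(table, task, seed=seed, preprocess=method, **task_kwargs)
            accs.append(res.test_accuracy)
        ranking.append(
            {"method": method, "mean_test_accuracy_pct": float(np.mean(accs)),
             "per_seed": [float(a) for a in accs]}
        )
    ranking.sort(key=lambda d: -d["mean_test_accuracy_pct"])
    return {"task": task, "seeds": list(seeds), "ranking": ranking}


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Full run: extract once, run every configured task, write artifacts.

    Writes the resolved config, the spectrum table CSV, per-task band-set /
    model / confusion-report JSON files, and a structured log with stage
    timings.  Reruns with identical configs produce identical artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def timed(stage: str, fn):
        t0 = time.perf_counter()
        result = fn()
        log.append({"stage": stage, "seconds": round(time.perf_counter() - t0, 3)})
        return result

    config.to_yaml(out / "config.yaml")
    table = timed("extract", lambda: extract_spectrum_table(config))
    table.to_csv(out / "spectra.csv")
    manifest = [
        {"sample_id": sid, "label": lab}
        for sid, lab in zip(table.sample_ids, table.labels)
    ]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    summary = {}
    for task in config.tasks:
        res = timed(f"task:{task}", lambda t=task: run_task(
            table,
            t,
            seed=config.seed,
            preprocess=config.preprocess,
            preprocess_params=config.preprocess_params,
            pf=config.pf,
            max_bands=config.max_bands,
            hidden_width=config.hidden_width,
            max_epochs=config.max_epochs,
            patience=config.patience,
            learning_rate=config.learning_rate,
        ))
        (out / f"bands_{task}.json").write_text(json.dumps(res.band_set.to_dict(), indent=1))
        (out / f"model_{task}.json").write_text(json.dumps(res.model.to_dict()))
        (out / f"report_{task}.json").write_text(
            json.dumps(res.report.to_dict(), indent=1)
        )
        summary[task] = {
            "test_accuracy_pct": res.test_accuracy,
            "class_error_pct": res.report.class_error,
            "n_bands": len(res.band_set.indices),
            "nwhfc_k": res.endmember_estimate.k,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    (out / "log.json").write_text(json.dumps({"seed": config.seed, "stages": log}, indent=1))
    return out
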