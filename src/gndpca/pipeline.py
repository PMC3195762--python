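"""End-to-end pipeline: simulate/load -> shape-normalize -> fit -> classify.

The pipeline reproduces the study design the method was built for: train a
multilinear texture model on shape-normalized normal volumes, take each
sample's core tensor as its feature, and separate normal from abnormal test
volumes with the largest-distance-of-training (LDT) rule.  All randomness
flows from the single seed in the configuration, so a given configuration
yields a byte-identical report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classify as _classify
from . import model as _model
from .registration import RegistrationConfig, normalize_to
from .synthetic import CohortSpec, LesionSpec, make_template, sample_volume

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage (and file)."""


@dataclass
class PipelineConfig:
    """Validated pipeline settings.

    n_train normal samples are used for model and classifier training;
    n_test_normal extra normals and n_test_abnormal lesioned volumes form
    the test set.  ``ranks`` are the core-tensor dimensions, ``grid_dims``
    the control-interval counts of the normalization lattice.
    """

    seed: int = 0
    n_train: int = 15
    n_test_normal: int = 4
    n_test_abnormal: int = 4
    ranks: tuple[int, int, int] = (25, 25, 16)
    grid_dims: tuple[int, int, int] = (7, 7, 3)
    shape_normalize: bool = True
    max_iter: int = 50
    tol: float = 1e-6
    cohort: CohortSpec = field(default_factory=CohortSpec)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)

    def __post_init__(self) -> None:
        if self.n_train < 1:
            raise ValueError("n_train must be >= 1")
        if self.n_test_normal < 0 or self.n_test_abnormal < 0:
            raise ValueError("test counts must be >= 0")
        self.ranks = tuple(int(r) for r in self.ranks)
        self.grid_dims = tuple(int(g) for g in self.grid_dims)


_COHORT_KEYS = {
    "n_normal", "n_abnormal", "shape", "spacing", "n_texture_modes",
    "texture_sd", "shape_deform_sd", "shape_grid", "lesion", "noise_sd", "seed",
}
_TOP_KEYS = {
    "seed", "n_train", "n_test_normal", "n_test_abnormal", "ranks",
    "grid_dims", "shape_normalize", "max_iter", "tol", "cohort", "registration",
}


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Unknown keys are rejected up front so typos fail before any compute.
    The cohort seed is always slaved to the top-level seed.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cohort_raw = raw.pop("cohort", {})
    unknown = set(cohort_raw) - _COHORT_KEYS
    if unknown:
        raise ValueError(f"unknown cohort keys: {sorted(unknown)}")
    lesion_raw = cohort_raw.pop("lesion", None)
    if lesion_raw is not None:
        cohort_raw["lesion"] = LesionSpec(**{
            k: tuple(v) if k == "radius" else v for k, v in lesion_raw.items()
        })
    for key in ("shape", "spacing", "shape_grid"):
        if key in cohort_raw:
            cohort_raw[key] = tuple(cohort_raw[key])
    reg_raw = raw.pop("registration", {})
    config = PipelineConfig(cohort=CohortSpec(**cohort_raw),
                            registration=RegistrationConfig(**reg_raw), **raw)
    config.cohort.seed = config.seed
    return config


def _stage(name: str, fn, *args, file: str | None = None, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        where = f"stage '{name}'" + (f" (file {file})" if file else "")
        raise PipelineError(f"{where} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full pipeline and return (and optionally write) a report.

    Returns a dict with per-test-sample rows (name, true/predicted label,
    ED, LDT, ED-LDT), the training distances, the per-sweep fit cost, and
    summary accuracies.  With ``out_dir`` set, also writes ``model.npz``,
    ``classifier.json`` and ``report.json`` there.
    """
    spec = config.cohort
    need_norm = config.n_train + config.n_test_normal
    if spec.n_normal < need_norm or spec.n_abnormal < config.n_test_abnormal:
        raise PipelineError(
            f"stage 'simulate' failed: cohort holds {spec.n_normal} normal / "
            f"{spec.n_abnormal} abnormal samples but the split needs "
            f"{need_norm} / {config.n_test_abnormal}"
        )

    names, volumes, labels = [], [], []
    for i in range(need_norm):
        names.append(f"normal_{i:03d}")
        volumes.append(_stage("simulate", sample_volume, spec, i, False, file=names[-1]))
        labels.append("normal")
    for j in range(config.n_test_abnormal):
        idx = spec.n_normal + j
        names.append(f"abnormal_{idx:03d}")
        volumes.append(_stage("simulate", sample_volume, spec, idx, True, file=names[-1]))
        labels.append("abnormal")

    reference = make_template(spec.shape, spec.spacing)
    if config.shape_normalize:
        normalized = [
            _stage("normalize", lambda v: normalize_to(
                v, reference, config.grid_dims, config.registration)[0],
                v, file=n).data
            for n, v in zip(names, volumes)
        ]
    else:
        normalized = [v.data for v in volumes]

    train = normalized[: config.n_train]
    fit_cfg = _model.FitConfig(ranks=config.ranks, max_iter=config.max_iter, tol=config.tol)
    model = _stage("fit", _model.fit, train, fit_cfg)
    train_feats = [_stage("project", _model.project, model, t) for t in train]
    clf = _stage("classify", _classify.build_classifier, train_feats)

    rows = []
    n_correct = 0
    for name, label, data in zip(names[config.n_train:], labels[config.n_train:],
                                 normalized[config.n_train:]):
        feat = _stage("project", _model.project, model, data, file=name)
        pred = _classify.predict(clf, feat)
        correct = pred.label == label
        n_correct += int(correct)
        rows.append(
            {
                "name": name,
                "true_label": label,
                "predicted_label": pred.label,
                "ed": pred.ed,
                "ldt": pred.ldt,
                "ed_minus_ldt": pred.ed_minus_ldt,
                "correct": correct,
            }
        )

    n_test = len(rows)
    report = {
        "config": {
            "seed": config.seed,
            "ranks": list(config.ranks),
            "grid_dims": list(config.grid_dims),
            "shape_normalize": config.shape_normalize,
            "n_train": config.n_train,
            "cohort": {**asdict(spec), "shape": list(spec.shape),
                       "spacing": list(spec.spacing)},
        },
        "fit_history": model.fit_history,
        "converged": model.converged,
        "ldt": clf.ldt,
        "training_distances": clf.training_distances,
        "test": rows,
        "n_test": n_test,
        "n_correct": n_correct,
        "accuracy": (n_correct / n_test) if n_test else None,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _model.save_model(model, out / "model.npz")
        with open(out / "classifier.json", "w") as fh:
            json.dump(
                {
                    "center": clf.center.ravel(order="F").tolist(),
                    "shape": list(clf.center.shape),
                    "ldt": clf.ldt,
                    "training_distances": clf.training_distances,
                },
                fh,
            )
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
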