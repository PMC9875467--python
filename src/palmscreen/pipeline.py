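"""End-to-end experiment: generate -> segment -> features -> augment ->
split -> train the five models -> evaluate.

Everything is driven by one ExperimentConfig (optionally loaded from
YAML) and one master seed; two runs with the same config produce
identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import models as md
from .augment import AugmentSpec, expand_dataset
from .cohort import ANEMIC, CohortSpec, make_cohort
from .errors import StageError
from .features import PixelFilter, compute_features
from .segmentation import crop_roi, segment_palm

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ExperimentConfig:
    """Full configuration of one experiment run."""

    cohort: CohortSpec = dataclasses.field(default_factory=CohortSpec)
    augment: AugmentSpec = dataclasses.field(default_factory=AugmentSpec)
    classifier: md.ClassifierConfig = dataclasses.field(default_factory=md.ClassifierConfig)
    pixel_filter: PixelFilter = dataclasses.field(default_factory=PixelFilter)
    split_mode: str = "pooled"  # pooled | grouped
    models: tuple = md.MODEL_KINDS
    do_cv: bool = True
    cv_folds: int = 10
    cv_include_cnn: bool = False  # convnet CV is 10x the training cost
    seed: int = 0

    def reseeded(self, seed: int) -> "ExperimentConfig":
        """Derive a config whose every random stage keys off ``seed``."""
        return dataclasses.replace(
            self,
            seed=seed,
            cohort=dataclasses.replace(self.cohort, seed=seed),
            classifier=dataclasses.replace(self.classifier, seed=(seed + 2) % (2**31)),
        )


def load_config(path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file.

    Recognized blocks: ``cohort:``, ``augment:``, ``classifier:``,
    ``pixel_filter:`` and top-level keys split_mode / models / do_cv /
    cv_folds / seed. Unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = ExperimentConfig()
    blocks = {
        "cohort": (CohortSpec, "cohort"),
        "augment": (AugmentSpec, "augment"),
        "classifier": (md.ClassifierConfig, "classifier"),
        "pixel_filter": (PixelFilter, "pixel_filter"),
    }
    updates = {}
    for key, value in raw.items():
        if key in blocks:
            cls, attr = blocks[key]
            if "transforms" in (value or {}):
                value["transforms"] = tuple(value["transforms"])
            updates[attr] = dataclasses.replace(getattr(cfg, attr), **(value or {}))
        elif key in ("split_mode", "do_cv", "cv_folds", "cv_include_cnn", "seed"):
            updates[key] = value
        elif key == "models":
            updates["models"] = tuple(value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    cfg = dataclasses.replace(cfg, **updates)
    if "seed" in raw:
        cfg = cfg.reseeded(int(raw["seed"]))
    return cfg


def _extract(images, pixel_filter, want_thumbs: bool):
    """Segment + crop + featurize a list of images."""
    feats, thumbs, labels_by_pid = [], [], {}
    for img in images:
        try:
            crop = crop_roi(img, segment_palm(img))
            feats.append(compute_features(crop, pixel_filter))
            if want_thumbs:
                thumbs.append(md.make_thumbnail(crop))
        except Exception as exc:  # noqa: BLE001
            raise StageError("features", img.image_id, exc) from exc
    return feats, thumbs


def run_experiment(config: ExperimentConfig = ExperimentConfig(), out_dir=None) -> dict:
    """Execute the full pipeline and return (optionally write) the report.

    The report carries dataset accounting, per-model metric tables for the
    validation and test partitions (percentages, two decimals), tenfold CV
    summaries on the training partition, and cumulative-gains / lift
    points on the test partition.
    """
    records, originals = make_cohort(config.cohort)
    label_of = {r.patient_id: r.label for r in records}

    pool = expand_dataset(originals, config.augment)
    want_cnn = "cnn" in config.models
    feats, thumbs = _extract(pool, config.pixel_filter, want_cnn)
    x = np.asarray([f.as_array(config.classifier.include_std_a) for f in feats])
    thumbs = np.asarray(thumbs) if want_cnn else None
    groups = np.asarray([img.patient_id for img in pool])
    y = md.encode_labels([label_of[pid] for pid in groups])

    plan = ev.make_split(groups, ev.SplitPlan(mode=config.split_mode, seed=(config.seed + 1) % 2**31))
    idx = {p: plan.indices(p) for p in ev.PARTITIONS}

    report = {
        "config": _config_dict(config),
        "counts": {
            "originals": len(originals),
            "originals_anemic": sum(r.label == ANEMIC for r in records),
            "pool": len(pool),
            "pool_anemic": int(y.sum()),
            "train": len(idx["train"]),
            "val": len(idx["val"]),
            "test": len(idx["test"]),
            "prevalence_pct": round(100.0 * sum(r.label == ANEMIC for r in records) / len(records), 2),
        },
        "models": {},
    }

    for kind in config.models:
        try:
            inputs = thumbs if kind == "cnn" else x
            model = md.train(kind, inputs[idx["train"]], y[idx["train"]], config.classifier)
            entry = {"converged": model.converged}
            for part in ("val", "test"):
                pred, score = model.predict(inputs[idx[part]])
                rep = ev.metrics(
                    ev.confusion(y[idx[part]], pred), scores=score, labels=y[idx[part]]
                )
                entry[part] = rep.as_percent_dict()
                if part == "test":
                    f, g = ev.cumulative_gains(score, y[idx[part]])
                    fl, lift = ev.lift_curve(score, y[idx[part]])
                    entry["gains"] = {"fraction": f.tolist(), "gain": g.tolist()}
                    entry["lift"] = {"fraction": fl.tolist(), "lift": lift.tolist()}
            if config.do_cv and (kind != "cnn" or config.cv_include_cnn):
                trainer = lambda xt, yt, _k=kind: md.train(_k, xt, yt, config.classifier)
                folds = ev.kfold_cv(
                    inputs[idx["train"]], y[idx["train"]], trainer,
                    k=config.cv_folds, seed=config.seed,
                )
                entry["cv"] = ev.summarize_reports(folds)
            report["models"][kind] = entry
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("train", kind, exc) from exc

    if out_dir is not None:
        _write_report(report, out_dir)
    return report


#: Overlap-heavy cohort used to demonstrate augment-before-split leakage:
#: class means only 8 a* units apart with a between-subject sd of 6, so the
#: image-level feature distributions overlap substantially and generalizing
#: to unseen subjects is genuinely hard.
OVERLAP_COHORT = CohortSpec(
    n_anemic=40,
    n_non_anemic=30,
    anemic_a_mean=147.0,
    non_anemic_a_mean=155.0,
    subject_sd=6.0,
    height=48,
    width=48,
)


def compare_split_modes(
    cohort: CohortSpec = OVERLAP_COHORT,
    model_kind: str = "knn",
    n_seeds: int = 20,
    base_seed: int = 0,
    classifier: md.ClassifierConfig | None = None,
) -> dict:
    """Test accuracy of pooled vs grouped splits over seeded replicates.

    Pooled splitting (augment before split) lets augmented views of one
    subject land in both train and test; since rotations and flips leave
    the color features bit-identical, the test set then contains exact
    copies of training items and accuracy is inflated. Grouped splitting
    holds out whole subjects and measures true generalization. Returns
    per-seed accuracies and their means.
    """
    pooled_acc, grouped_acc = [], []
    for s in range(n_seeds):
        seed = (base_seed + s) % 2**31
        spec = dataclasses.replace(cohort, seed=seed)
        records, originals = make_cohort(spec)
        label_of = {r.patient_id: r.label for r in records}
        pool = expand_dataset(originals)
        feats, _ = _extract(pool, PixelFilter(), False)
        x = np.asarray([f.as_array() for f in feats])
        groups = np.asarray([img.patient_id for img in pool])
        y = md.encode_labels([label_of[pid] for pid in groups])
        cfg = classifier or md.ClassifierConfig(seed=seed)
        for mode, out in (("pooled", pooled_acc), ("grouped", grouped_acc)):
            plan = ev.make_split(groups, ev.SplitPlan(mode=mode, seed=(seed + 1) % 2**31))
            tr, te = plan.indices("train"), plan.indices("test")
            model = md.train(model_kind, x[tr], y[tr], cfg)
            pred, _ = model.predict(x[te])
            out.append(float(np.mean(md.encode_labels(pred) == y[te])))
    return {
        "pooled": pooled_acc,
        "grouped": grouped_acc,
        "pooled_mean": float(np.mean(pooled_acc)),
        "grouped_mean": float(np.mean(grouped_acc)),
    }


def _config_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["augment"]["transforms"] = list(d["augment"]["transforms"])
    d["models"] = list(d["models"])
    return d


def _write_report(report: dict, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    rows = []
    for kind, entry in report["models"].items():
        row = {"model": kind}
        row.update({f"test_{k}": v for k, v in entry["test"].items()})
        row.update({f"val_{k}": v for k, v in entry["val"].items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)
    logger.info("report written to %s", out_dir)
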