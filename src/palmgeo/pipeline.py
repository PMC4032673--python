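"""End-to-end experiment driver plus CSV/JSON readers and writers.

Ties the stages together: obtain a feature table (from a CSV, a directory
of images, or the synthetic generator), split it randomly into train/test,
standardize on the training split, train the PSSVM, and report test
accuracy with a confusion matrix.  Reports are deterministic functions of
(config, seed) and serialize to JSON byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError
from .geometry import DEFAULT_MIN_AREA, extract
from .pssvm import (
    LabeledDataset,
    PssvmHyperparams,
    PssvmModel,
    SolverConfig,
    fit_classifier,
    predict,
    split_train_test,
)
from .synthetic import PopulationSpec, sample_feature_table, sample_population

__all__ = [
    "PipelineConfig",
    "FEATURE_COLUMNS",
    "read_features",
    "write_features",
    "features_to_dataset",
    "dataset_to_frame",
    "extract_directory",
    "obtain_dataset",
    "save_model",
    "load_model",
    "evaluate",
    "run_experiment",
    "write_report",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ("length_px", "width_px", "aspect_ratio")
_META_COLUMNS = ("image_id", "subject_id", "hand", "label")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run depends on; JSON round-trip stable."""

    # input: exactly one of these three sources
    features_path: str | None = None
    images_dir: str | None = None
    simulate: str | None = None  # "images" or "features"
    population: PopulationSpec = field(default_factory=PopulationSpec)
    # segmentation
    min_area: int = DEFAULT_MIN_AREA
    # classifier
    nu: float = 100.0
    k: float = 10.0
    tol: float = 1e-8
    max_iter: int = 100
    standardize: bool = True
    # protocol
    train_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        sources = [self.features_path, self.images_dir, self.simulate]
        if sum(s is not None for s in sources) != 1:
            raise InvalidInputError(
                "exactly one of features_path, images_dir, simulate must be set"
            )
        if self.simulate is not None and self.simulate not in ("images", "features"):
            raise InvalidInputError("simulate must be 'images' or 'features'")
        if not (0.0 < self.train_fraction < 1.0):
            raise InvalidInputError("train_fraction must be in (0, 1)")
        if self.min_area < 0 or self.max_iter < 1 or self.tol <= 0:
            raise InvalidInputError("min_area, max_iter, tol out of range")
        PssvmHyperparams(nu=self.nu, k=self.k)  # validates nu, k

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["population"] = dataclasses.asdict(self.population)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        pop = d.pop("population", None)
        return cls(
            population=PopulationSpec(**pop) if pop else PopulationSpec(), **d
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def read_features(path) -> pd.DataFrame:
    """Read a feature CSV, validating columns and finiteness.

    Required columns: length_px, width_px, aspect_ratio, label.  Labels may
    be +1/-1, the 0/1 display coding (0 = female, 1 = male; mapped to
    -1/+1 with a logged notice), or NA for classify-only rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in (*FEATURE_COLUMNS, "label") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in FEATURE_COLUMNS:
        bad = ~np.isfinite(df[col].to_numpy(dtype=np.float64, na_value=np.nan))
        if bad.any():
            raise FormatError(
                f"{path}: non-finite {col} at row(s) {np.flatnonzero(bad).tolist()}"
            )
    labels = df["label"]
    known = labels.dropna().unique()
    if len(known) and set(known) <= {0, 1} and not set(known) <= {1}:
        logger.info("label column uses 0/1 coding; mapping 0 -> -1 (female), 1 -> +1 (male)")
        df = df.copy()
        df["label"] = labels.map({0: -1, 1: 1})
    elif not set(known) <= {-1, 1}:
        raise FormatError(f"{path}: labels must be -1/+1 (or 0/1), got {sorted(known)}")
    return df


def write_features(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def features_to_dataset(df: pd.DataFrame) -> LabeledDataset:
    """Labeled rows of a feature frame as a dataset (NA labels dropped)."""
    sub = df.dropna(subset=["label"])
    if sub.empty:
        raise InvalidInputError("no labeled rows in feature table")
    return LabeledDataset(
        X=sub[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64),
        y=sub["label"].to_numpy(dtype=np.int64),
        feature_names=FEATURE_COLUMNS,
        groups=sub["subject_id"].to_numpy() if "subject_id" in sub else None,
    )


def dataset_to_frame(data: LabeledDataset) -> pd.DataFrame:
    df = pd.DataFrame(data.X, columns=list(data.feature_names or FEATURE_COLUMNS))
    df.insert(0, "label", data.y)
    if data.groups is not None:
        df.insert(0, "subject_id", data.groups)
    return df


def extract_directory(path, min_area: int = DEFAULT_MIN_AREA) -> pd.DataFrame:
    """Run feature extraction over every PNG/TIFF image under ``path``.

    Labels are read from a ``manifest.csv`` (image_id, label) if present,
    else left NA.
    """
    from .preprocess import read_image

    path = Path(path)
    files = sorted(
        p for p in path.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    ) if path.is_dir() else [path]
    if not files:
        raise InvalidInputError(f"no images found under {path}")
    manifest = {}
    mpath = path / "manifest.csv" if path.is_dir() else None
    if mpath and mpath.exists():
        mdf = pd.read_csv(mpath)
        manifest = dict(zip(mdf["image_id"].astype(str), mdf["label"]))
    rows = []
    for f in files:
        feats = extract(read_image(f), min_area=min_area)
        rows.append({
            "image_id": f.stem,
            "label": manifest.get(f.stem, np.nan),
            "length_px": feats.length_px,
            "width_px": feats.width_px,
            "aspect_ratio": feats.aspect_ratio,
        })
    return pd.DataFrame(rows)


def save_model(model: PssvmModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True))


def load_model(path) -> PssvmModel:
    return PssvmModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# evaluation and the end-to-end experiment
# ---------------------------------------------------------------------------

def evaluate(model: PssvmModel, test: LabeledDataset) -> dict:
    """Accuracy, per-class accuracy, and confusion matrix on a test set.

    Accuracy is correct/total on the given set; +1 (male) is the positive
    class in the confusion matrix.
    """
    pred = predict(model, test.X)
    correct = pred == test.y
    male = test.y == 1
    female = ~male
    cm = {
        "tp": int(np.sum(pred[male] == 1)),
        "fn": int(np.sum(pred[male] == -1)),
        "fp": int(np.sum(pred[female] == 1)),
        "tn": int(np.sum(pred[female] == -1)),
    }
    return {
        "n_test": int(test.m),
        "accuracy": float(correct.mean()),
        "accuracy_male": float(correct[male].mean()) if male.any() else None,
        "accuracy_female": float(correct[female].mean()) if female.any() else None,
        "confusion_matrix": cm,
    }


def obtain_dataset(config: PipelineConfig) -> LabeledDataset:
    """Materialize the config's dataset source as a LabeledDataset."""
    if config.features_path is not None:
        return features_to_dataset(read_features(config.features_path))
    if config.images_dir is not None:
        return features_to_dataset(extract_directory(
            config.images_dir, min_area=config.min_area))
    pop = dataclasses.replace(config.population, seed=config.seed)
    if config.simulate == "features":
        return sample_feature_table(pop)
    rows, labels, groups = [], [], []
    for entry in sample_population(pop):
        feats = extract(entry.image, min_area=config.min_area)
        rows.append(feats.as_array())
        labels.append(entry.label)
        groups.append(entry.subject_id)
    return LabeledDataset(
        X=np.asarray(rows), y=np.asarray(labels),
        feature_names=FEATURE_COLUMNS, groups=np.asarray(groups),
    )


def run_experiment(config: PipelineConfig) -> dict:
    """Run dataset -> split -> standardize -> train -> evaluate; return report.

    The report echoes the resolved config and seed, so identical inputs
    reproduce it byte-for-byte when serialized with sorted keys.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    data = obtain_dataset(config)
    timings["dataset"] = time.perf_counter() - t0
    logger.info("dataset: %d samples, %d male", data.m, int(np.sum(data.y == 1)))

    t0 = time.perf_counter()
    train_set, test_set = split_train_test(data, config.train_fraction, config.seed)
    hp = PssvmHyperparams(nu=config.nu, k=config.k)
    solver = SolverConfig(tol=config.tol, max_iter=config.max_iter)
    model = fit_classifier(train_set, hp, solver, standardize=config.standardize)
    timings["train"] = time.perf_counter() - t0
    logger.info("trained on %d samples (%d iterations, ||grad||=%.2e)",
                train_set.m, model.n_iter, model.final_gradient_norm)

    report = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_train": int(train_set.m),
        "model": model.to_dict(),
        **evaluate(model, test_set),
    }
    logger.info("test accuracy %.4f on %d samples (%.2fs dataset, %.2fs train)",
                report["accuracy"], report["n_test"],
                timings["dataset"], timings["train"])
    return report


def write_report(report: dict, json_path=None, text_path=None) -> str:
    """Serialize a report as canonical JSON and a human-readable summary."""
    payload = json.dumps(report, indent=2, sort_keys=True)
    if json_path is not None:
        Path(json_path).write_text(payload)
    cm = report["confusion_matrix"]
    lines = [
        f"samples: {report['n_train']} train / {report['n_test']} test "
        f"(seed {report['seed']})",
        f"test accuracy: {100 * report['accuracy']:.2f}%",
        f"  male   (+1): {_pct(report['accuracy_male'])}",
        f"  female (-1): {_pct(report['accuracy_female'])}",
        "confusion matrix (rows = truth, cols = prediction):",
        f"            pred +1   pred -1",
        f"  male      {cm['tp']:7d}   {cm['fn']:7d}",
        f"  female    {cm['fp']:7d}   {cm['tn']:7d}",
    ]
    text = "\n".join(lines)
    if text_path is not None:
        Path(text_path).write_text(text + "\n")
    return text


def _pct(x) -> str:
    return "n/a" if x is None else f"{100 * x:.2f}%"
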