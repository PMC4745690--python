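"""100-model random-forest classification systems, majority voting, and SPI.

A *classification system* is a fixed feature set plus one random-forest
model per random training/validation split (100 splits in the reference
design).  A new sample is classified by all models; it is called tumor when
strictly more than half the models vote tumor.

The system performance index (SPI) summarizes how consistently a system
classifies a labeled sample set.  For sample i, the confidence
``s_i = n_it / n`` is the fraction of models voting tumor; the precision
index ``r_i`` equals ``s_i`` for a true tumor sample and ``1 - s_i`` for a
true normal sample; SPI is the mean of ``r_i`` over the samples.  SPI = 1
means every model classifies every sample correctly; SPI near 0.5 means the
system is no better than coin flipping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier

from .io import ExpressionMatrix, CountMatrix, SampleMetadata
from .selection import (
    RF_N_ESTIMATORS,
    FeatureSet,
    ReplicateSplit,
    derive_seeds,
    make_random_assignment,
)


@dataclass
class ClassificationModel:
    """One trained forest with its split and validation accuracy."""

    replicate_id: int
    estimator: RandomForestClassifier
    feature_ids: tuple[str, ...]
    split: ReplicateSplit
    validation_accuracy: float


@dataclass
class ClassificationSystem:
    feature_set: FeatureSet
    models: list[ClassificationModel]

    @property
    def n(self) -> int:
        return len(self.models)

    @property
    def validation_accuracies(self) -> np.ndarray:
        return np.array([m.validation_accuracy for m in self.models])


def _profile_matrix(data: ExpressionMatrix | CountMatrix, feature_ids, sample_ids) -> np.ndarray:
    values = data.data
    missing = [f for f in feature_ids if f not in values.index]
    if missing:
        raise ValueError(f"features missing from the data matrix: {missing[:5]}")
    return values.loc[list(feature_ids), list(sample_ids)].to_numpy(dtype=float).T


def build_system(
    feature_set: FeatureSet,
    data: ExpressionMatrix | CountMatrix,
    metadata: SampleMetadata,
    n_models: int = 100,
    seed: int = 0,
    stratify: bool = False,
    n_estimators: int = RF_N_ESTIMATORS,
) -> ClassificationSystem:
    """Train one random forest per random assignment, all sharing the feature set.

    Each of the ``n_models`` replicates draws a fresh patient-level split
    (seeded deterministically from ``seed``), trains a forest on the
    training samples restricted to the feature set, and records accuracy on
    that replicate's validation samples.
    """
    if not feature_set.feature_ids:
        raise ValueError("cannot build a system from an empty feature set")
    split_seeds = derive_seeds(seed, n_models, "splits")
    rf_seeds = derive_seeds(seed, n_models, "forests")
    models = []
    for i in range(n_models):
        split = make_random_assignment(metadata, split_seeds[i], stratify=stratify, replicate_id=i)
        train_s = metadata.samples_of_patients(split.training_patient_ids)
        valid_s = metadata.samples_of_patients(split.validation_patient_ids)
        X_train = _profile_matrix(data, feature_set.feature_ids, train_s)
        X_valid = _profile_matrix(data, feature_set.feature_ids, valid_s)
        y_train = metadata.tissue_of(train_s).to_numpy()
        y_valid = metadata.tissue_of(valid_s).to_numpy()
        clf = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt",
            random_state=rf_seeds[i], n_jobs=1,
        )
        clf.fit(X_train, y_train)
        acc = float((clf.predict(X_valid) == y_valid).mean())
        models.append(
            ClassificationModel(
                replicate_id=i, estimator=clf,
                feature_ids=feature_set.feature_ids, split=split,
                validation_accuracy=acc,
            )
        )
    return ClassificationSystem(feature_set=feature_set, models=models)


def vote_matrix(system: ClassificationSystem, data: ExpressionMatrix | CountMatrix) -> pd.DataFrame:
    """Boolean tumor votes, models x samples."""
    X = _profile_matrix(data, system.feature_set.feature_ids, data.sample_ids)
    votes = np.stack([m.estimator.predict(X) == "tumor" for m in system.models])
    return pd.DataFrame(votes, index=range(system.n), columns=data.sample_ids)


def classify_sample(
    system: ClassificationSystem, sample_profile: Mapping[str, float] | pd.Series
) -> tuple[str, float, int]:
    """Majority-vote one sample: returns (label, s_i, n_it).

    Tumor requires strictly more than half the models voting tumor, so a
    50/100 tie is called normal.  A missing feature value is an error — no
    imputation is attempted.
    """
    profile = pd.Series(dict(sample_profile)) if not isinstance(sample_profile, pd.Series) else sample_profile
    missing = [f for f in system.feature_set.feature_ids if f not in profile.index or pd.isna(profile[f])]
    if missing:
        raise ValueError(f"sample profile missing features: {missing[:5]}")
    x = profile.loc[list(system.feature_set.feature_ids)].to_numpy(dtype=float).reshape(1, -1)
    n_it = int(sum(m.estimator.predict(x)[0] == "tumor" for m in system.models))
    s_i = n_it / system.n
    label = "tumor" if n_it > system.n / 2 else "normal"
    return label, s_i, n_it


@dataclass
class SpiReport:
    """Per-sample votes/confidence and the system performance index."""

    per_sample: pd.DataFrame  # index sample_id; columns n_it, s_i, predicted, true_label, r_i
    spi: float
    n_models: int

    @property
    def n_samples(self) -> int:
        return len(self.per_sample)

    def write_tsv(self, path: str | Path) -> None:
        self.per_sample.to_csv(path, sep="\t", index_label="sample_id")


def spi_from_votes(
    votes: pd.DataFrame | np.ndarray,
    true_labels: Sequence[str] | pd.Series,
) -> SpiReport:
    """SPI from a models-x-samples boolean tumor-vote matrix and true labels.

    ``s_i`` is the column mean of the vote matrix; ``r_i = s_i`` for tumor
    samples and ``1 - s_i`` for normal samples; SPI is the mean ``r_i``.
    """
    if isinstance(votes, pd.DataFrame):
        sample_ids = list(votes.columns)
        mat = votes.to_numpy(dtype=bool)
    else:
        mat = np.asarray(votes, dtype=bool)
        sample_ids = [f"sample_{i}" for i in range(mat.shape[1])]
    if mat.size == 0:
        raise ValueError("empty vote matrix")
    labels = np.asarray(
        true_labels.loc[sample_ids] if isinstance(true_labels, pd.Series) else list(true_labels)
    )
    if len(labels) != mat.shape[1]:
        raise ValueError("one true label per sample is required")
    bad = set(labels) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"true labels must be tumor/normal; found {sorted(bad)}")

    n = mat.shape[0]
    n_it = mat.sum(axis=0)
    s = n_it / n
    predicted = np.where(n_it > n / 2, "tumor", "normal")
    r = np.where(labels == "tumor", s, 1.0 - s)
    per_sample = pd.DataFrame(
        {"n_it": n_it, "s_i": s, "predicted": predicted, "true_label": labels, "r_i": r},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SpiReport(per_sample=per_sample, spi=float(r.mean()), n_models=n)


def compute_spi(
    system: ClassificationSystem,
    data: ExpressionMatrix | CountMatrix,
    metadata: SampleMetadata,
) -> SpiReport:
    """Vote every sample in ``data`` through the system and compute SPI."""
    if not data.sample_ids:
        raise ValueError("no samples to score")
    votes = vote_matrix(system, data)
    labels = metadata.tissue_of(data.sample_ids)
    return spi_from_votes(votes, labels)


def save_system(system: ClassificationSystem, directory: str | Path) -> None:
    """Persist the trained models (joblib) plus a YAML manifest."""
    import joblib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(system.models, directory / "models.joblib")
    manifest = {
        "level": system.feature_set.level,
        "p_cutoff": system.feature_set.p_cutoff,
        "top_fraction": system.feature_set.top_fraction,
        "feature_ids": list(system.feature_set.feature_ids),
        "n_models": system.n,
        "validation_accuracies": [float(a) for a in system.validation_accuracies],
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def load_system(directory: str | Path) -> ClassificationSystem:
    import joblib

    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    feature_set = FeatureSet(
        level=manifest["level"], p_cutoff=manifest["p_cutoff"],
        top_fraction=manifest["top_fraction"],
        feature_ids=tuple(manifest["feature_ids"]),
    )
    models = joblib.load(directory / "models.joblib")
    return ClassificationSystem(feature_set=feature_set, models=models)
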