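"""Replicate splits, five-replicate feature discovery, and feature-set selection.

Discovery mimics repeated random subsampling: patients (each contributing a
tumor and a normal sample) are split into training and validation halves;
the NB test is run on the training half only, and only features significant
in *all* replicates (by default five) survive.  Surviving candidates are
then ranked by single-feature classification accuracy averaged over the same
replicate splits, and a feature set keeps the top 10%, 5% or 1% of the
ranking — which, crossed with the three Bonferroni cutoffs, yields the nine
selection criteria.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .diffexpr import significant_features, test_level
from .io import CountMatrix, ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

#: random-forest defaults used throughout: 500 trees, sqrt(p) features per
#: split, unlimited depth.
RF_N_ESTIMATORS = 500


def _seed_from(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31))


def derive_seeds(master_seed: int, n: int, label: str = "") -> list[int]:
    """Fan a master seed out into ``n`` reproducible child seeds (< 2**31)."""
    root = np.random.SeedSequence([master_seed, zlib.crc32(label.encode()) % (2**31)])
    return [_seed_from(c) for c in root.spawn(n)]


@dataclass(frozen=True)
class ReplicateSplit:
    """One random assignment of paired patients into training/validation halves."""

    replicate_id: int
    seed: int
    training_patient_ids: tuple[str, ...]
    validation_patient_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.training_patient_ids) & set(self.validation_patient_ids)
        if overlap:
            raise ValueError(f"patients on both sides of the split: {sorted(overlap)[:5]}")
        if abs(len(self.training_patient_ids) - len(self.validation_patient_ids)) > 1:
            raise ValueError("split sizes differ by more than 1")


def make_random_assignment(
    metadata: SampleMetadata,
    seed: int,
    stratify: bool = False,
    replicate_id: int = 0,
) -> ReplicateSplit:
    """Split paired patients into training (the larger half) and validation.

    Both tissues of a patient always fall on the same side.  With
    ``stratify``, patients are grouped by the joint value of their available
    covariates (gender, smoking status, tumor stage) and each stratum is
    split in half, the odd patient of each stratum going to whichever side
    is currently smaller, so strata proportions differ by at most one
    patient between subsets.
    """
    patients = metadata.paired_patients()
    if len(patients) < 4:
        raise ValueError(f"need at least 4 paired patients; found {len(patients)}")
    rng = np.random.default_rng(seed)

    if not stratify:
        order = list(np.array(patients)[rng.permutation(len(patients))])
        n_train = math.ceil(len(order) / 2)
        train, valid = order[:n_train], order[n_train:]
    else:
        pat_table = metadata.table.drop_duplicates("patient_id").set_index("patient_id")
        covars = [c for c in ("gender", "smoking_status", "tumor_stage") if c in pat_table.columns]
        strata: dict[tuple, list[str]] = {}
        for p in patients:
            key = tuple(str(pat_table.at[p, c]) for c in covars)
            strata.setdefault(key, []).append(p)
        train, valid = [], []
        for key in sorted(strata):
            members = strata[key]
            if len(members) == 1:
                logger.warning("stratum %s has a single patient; assigned randomly", key)
            members = list(np.array(members)[rng.permutation(len(members))])
            half = len(members) // 2
            a, b = members[:half], members[half : 2 * half]
            extra = members[2 * half :]
            train.extend(a)
            valid.extend(b)
            for p in extra:  # odd patient: balance overall sizes
                if len(train) <= len(valid):
                    train.append(p)
                else:
                    valid.append(p)
        if len(train) < len(valid):  # training holds the larger half by convention
            train, valid = valid, train

    return ReplicateSplit(
        replicate_id=replicate_id,
        seed=seed,
        training_patient_ids=tuple(train),
        validation_patient_ids=tuple(valid),
    )


@dataclass
class DiscoveryResult:
    """Intersection of significant features over the replicate experiments."""

    level: str
    p_cutoff: float
    features: set[str]
    mean_p: pd.Series                  # mean raw p over replicates, intersection features
    per_replicate_counts: list[int]    # significant features per replicate
    splits: list[ReplicateSplit]


def discover_all_cutoffs(
    counts: CountMatrix,
    metadata: SampleMetadata,
    seeds: Sequence[int],
    level: str,
    p_cutoffs: Sequence[float] = (0.05, 0.01, 0.001),
    stratify: bool = False,
) -> dict[float, DiscoveryResult]:
    """One replicate experiment, intersected at several Bonferroni cutoffs.

    The NB test runs once per replicate training half; the cutoffs are then
    applied to the same per-replicate results, mirroring a design in which
    the three significance thresholds share the five random assignments.
    """
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("replicate seeds must be distinct")
    splits, rep_results, p_frames = [], [], []
    for i, seed in enumerate(seeds):
        split = make_random_assignment(metadata, seed, stratify=stratify, replicate_id=i)
        splits.append(split)
        train_samples = metadata.samples_of_patients(split.training_patient_ids)
        sub = counts.subset_samples(train_samples)
        results = test_level(sub, metadata.subset(train_samples), level)
        rep_results.append(results)
        p_frames.append(pd.Series({r.feature_id: r.p_value for r in results}, name=i))
    mean_p_all = pd.concat(p_frames, axis=1).mean(axis=1)

    out: dict[float, DiscoveryResult] = {}
    for cutoff in p_cutoffs:
        sig_sets = [significant_features(res, cutoff) for res in rep_results]
        shared = set.intersection(*sig_sets) if sig_sets else set()
        if not shared:
            logger.warning(
                "no feature significant in all %d replicates at cutoff %g (level %s)",
                len(seeds), cutoff, level,
            )
        out[cutoff] = DiscoveryResult(
            level=level, p_cutoff=cutoff, features=shared,
            mean_p=mean_p_all.loc[[f for f in mean_p_all.index if f in shared]],
            per_replicate_counts=[len(s) for s in sig_sets],
            splits=splits,
        )
    return out


def five_replicate_discovery(
    counts: CountMatrix,
    metadata: SampleMetadata,
    seeds: Sequence[int],
    level: str,
    p_cutoff: float,
    stratify: bool = False,
) -> DiscoveryResult:
    """Run the NB test on each replicate's training half; intersect the hits.

    ``seeds`` must be distinct (one per replicate; five in the reference
    design).  An empty intersection is returned with a warning rather than
    an error — a cutoff can legitimately yield no shared features.
    """
    return discover_all_cutoffs(
        counts, metadata, seeds, level, p_cutoffs=(p_cutoff,), stratify=stratify
    )[p_cutoff]


def _single_feature_rf(seed: int, n_estimators: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_estimators, max_features=None, random_state=seed, n_jobs=1
    )


def rank_single_feature_accuracy(
    candidates: Sequence[str],
    data: ExpressionMatrix | CountMatrix,
    metadata: SampleMetadata,
    splits: Sequence[ReplicateSplit],
    mean_p: Mapping[str, float] | pd.Series | None = None,
    n_estimators: int = RF_N_ESTIMATORS,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Rank candidates by mean single-feature validation accuracy over the splits.

    For each candidate and split, a one-feature random forest is trained on
    the training samples and scored on the validation samples; accuracies
    are averaged over splits.  A feature that is constant in a training
    subset contributes chance accuracy (0.5) for that split.  Ties are
    broken by smaller mean discovery p-value, then lexicographic id.
    """
    if not candidates:
        raise ValueError("no candidate features to rank")
    values = data.data
    missing = [c for c in candidates if c not in values.index]
    if missing:
        raise ValueError(f"candidates missing from the data matrix: {missing[:5]}")
    rf_seeds = derive_seeds(seed, len(candidates) * len(splits), "rank")

    accs: dict[str, list[float]] = {c: [] for c in candidates}
    k = 0
    for split in splits:
        train_s = metadata.samples_of_patients(split.training_patient_ids)
        valid_s = metadata.samples_of_patients(split.validation_patient_ids)
        y_train = metadata.tissue_of(train_s).to_numpy()
        y_valid = metadata.tissue_of(valid_s).to_numpy()
        for c in candidates:
            x_train = values.loc[c, train_s].to_numpy().reshape(-1, 1)
            x_valid = values.loc[c, valid_s].to_numpy().reshape(-1, 1)
            if np.all(x_train == x_train[0]):
                logger.warning(
                    "feature %s constant in training subset of replicate %d; accuracy 0.5",
                    c, split.replicate_id,
                )
                accs[c].append(0.5)
                k += 1
                continue
            clf = _single_feature_rf(rf_seeds[k], n_estimators)
            k += 1
            clf.fit(x_train, y_train)
            accs[c].append(float((clf.predict(x_valid) == y_valid).mean()))

    mp = pd.Series(dict(mean_p)) if mean_p is not None else pd.Series(dtype=float)
    ranked = sorted(
        ((c, float(np.mean(accs[c]))) for c in candidates),
        key=lambda item: (-item[1], float(mp.get(item[0], 1.0)), item[0]),
    )
    return ranked


@dataclass
class FeatureSet:
    """Features surviving one of the nine (p-cutoff x top-fraction) criteria."""

    level: str
    p_cutoff: float
    top_fraction: float
    feature_ids: tuple[str, ...]  # ordered by rank
    empty_flagged: bool = False

    def __len__(self) -> int:
        return len(self.feature_ids)


def select_feature_set(
    ranked: Sequence[tuple[str, float]],
    level: str,
    p_cutoff: float,
    top_fraction: float,
) -> FeatureSet:
    """Keep the top ``ceil(top_fraction * len(ranked))`` features, rank order preserved."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if not ranked:
        logger.warning("empty ranking at cutoff %g; empty feature set", p_cutoff)
        return FeatureSet(level, p_cutoff, top_fraction, (), empty_flagged=True)
    n_keep = math.ceil(top_fraction * len(ranked))
    return FeatureSet(
        level=level, p_cutoff=p_cutoff, top_fraction=top_fraction,
        feature_ids=tuple(f for f, _ in ranked[:n_keep]),
    )
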