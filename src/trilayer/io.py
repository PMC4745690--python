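"""Typed containers and TSV readers/writers for matrices, metadata and DE tables.

Matrices are features x samples; the underlying storage is a pandas
DataFrame (feature ids as index, sample ids as columns).  Count matrices are
non-negative integers.  Expression (FPKM) matrices are non-negative reals and
may contain missing values (the literal ``NA`` in files), which encode
transcripts reported as *absent* by upstream quantification — a different
state from an observed zero.

All files are tab-separated, UTF-8, ``.`` decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LEVELS = ("gene", "transcript", "exonic_region")

CUTOFFS = (0.05, 0.01, 0.001)


def _check_level(level: str) -> str:
    if level not in LEVELS:
        raise ValueError(f"unknown feature level {level!r}; expected one of {LEVELS}")
    return level


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, tagged with a feature level."""

    level: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_level(self.level)
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("count matrix contains non-numeric values")
        if np.isnan(vals.astype(float)).any():
            raise ValueError("count matrix contains missing values")
        if (vals < 0).any():
            raise ValueError("count matrix contains negative values")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("count matrix contains non-integer values")
        self.data = self.data.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.level, self.data.loc[:, list(sample_ids)])

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.level, self.data.loc[list(feature_ids)])


@dataclass
class ExpressionMatrix:
    """Non-negative real expression values (FPKM); NaN encodes 'absent'."""

    level: str
    data: pd.DataFrame
    allow_duplicate_features: bool = False

    def __post_init__(self) -> None:
        _check_level(self.level)
        if not self.allow_duplicate_features and self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.data.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("expression matrix contains negative values")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.level, self.data.loc[:, list(sample_ids)])

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.level, self.data.loc[list(feature_ids)])


METADATA_FIELDS = ("patient_id", "tissue", "gender", "smoking_status", "tumor_stage")


@dataclass
class SampleMetadata:
    """Per-sample patient id, tissue label (tumor/normal) and strata covariates."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        if "patient_id" not in self.table.columns or "tissue" not in self.table.columns:
            raise ValueError("metadata requires patient_id and tissue columns")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        bad = set(self.table["tissue"]) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"tissue labels must be 'tumor' or 'normal'; found {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def tissue_of(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        t = self.table["tissue"]
        return t if sample_ids is None else t.loc[list(sample_ids)]

    def paired_patients(self) -> list[str]:
        """Patients with exactly one tumor and one normal sample."""
        counts = self.table.groupby("patient_id")["tissue"].value_counts().unstack(fill_value=0)
        for col in ("tumor", "normal"):
            if col not in counts:
                counts[col] = 0
        ok = (counts["tumor"] == 1) & (counts["normal"] == 1) & (counts.sum(axis=1) == 2)
        return sorted(counts.index[ok])

    def unpaired_patients(self) -> list[str]:
        """Patients violating the one-tumor-one-normal pairing (flagged, not dropped)."""
        paired = set(self.paired_patients())
        return sorted(set(self.table["patient_id"]) - paired)

    def samples_of_patients(self, patient_ids: Iterable[str]) -> list[str]:
        pats = set(patient_ids)
        return [s for s in self.table.index if self.table.at[s, "patient_id"] in pats]

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())


@dataclass
class DEResult:
    """Outcome of one feature's tumor-vs-normal negative-binomial test."""

    feature_id: str
    level: str
    base_mean_normal: float
    base_mean_tumor: float
    log2_fold_change: float
    p_value: float
    p_bonferroni: float
    is_significant: dict[float, bool] = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        _check_level(self.level)
        if not self.is_significant:
            self.is_significant = {c: self.p_bonferroni <= c for c in CUTOFFS}


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    return df


def _to_numeric(df: pd.DataFrame, path: Path, allow_na: bool) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        raw = df[col]
        vals = pd.to_numeric(raw.where(raw != "NA") if allow_na else raw, errors="coerce")
        bad = vals.isna()
        if allow_na:
            bad = bad & (raw != "NA")
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        out[col] = vals
    return pd.DataFrame(out, index=df.index)


def read_counts(path: str | Path, level: str) -> CountMatrix:
    """Read an integer count matrix; first column feature ids, header sample ids."""
    path = Path(path)
    df = _to_numeric(_read_tsv(path), path, allow_na=False)
    try:
        return CountMatrix(level, df)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def read_expression(path: str | Path, level: str, allow_duplicate_features: bool = False) -> ExpressionMatrix:
    """Read an FPKM matrix; the literal NA marks absent (not zero) values."""
    path = Path(path)
    df = _to_numeric(_read_tsv(path), path, allow_na=True)
    try:
        return ExpressionMatrix(level, df, allow_duplicate_features=allow_duplicate_features)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def read_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    df = _read_tsv(path)
    df = df.replace("NA", np.nan)
    try:
        return SampleMetadata(df)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def write_counts(m: CountMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="feature_id")


def write_expression(m: ExpressionMatrix, path: str | Path, na_rep: str = "NA") -> None:
    m.data.to_csv(path, sep="\t", index_label="feature_id", na_rep=na_rep)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_totals(path: str | Path) -> pd.Series:
    """Read the sidecar sample_id -> total mapped reads table."""
    path = Path(path)
    df = _to_numeric(_read_tsv(path), path, allow_na=False)
    s = df.iloc[:, 0].astype(float)
    if (s <= 0).any():
        raise ValueError(f"{path}: total mapped reads must be positive")
    return s


def write_totals(totals: Mapping[str, float] | pd.Series, path: str | Path) -> None:
    pd.Series(dict(totals), name="total_mapped_reads").to_csv(
        path, sep="\t", index_label="sample_id"
    )


DE_TABLE_COLUMNS = (
    "feature_id", "base_mean_normal", "base_mean_tumor",
    "log2_fold_change", "p_value", "p_bonferroni",
)


def write_de_table(results: Sequence[DEResult], path: str | Path) -> None:
    """Write DE results (one shared level) as TSV, sorted by ascending p-value.

    Floats are written with 12 significant digits so that a read-back
    round-trips losslessly at that precision.
    """
    levels = {r.level for r in results}
    if len(levels) > 1:
        raise ValueError(f"DE results mix levels: {sorted(levels)}")
    rows = sorted(results, key=lambda r: (r.p_value, r.feature_id))
    with open(Path(path), "w") as fh:
        fh.write("\t".join(DE_TABLE_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.feature_id}\t{r.base_mean_normal:.12g}\t{r.base_mean_tumor:.12g}\t"
                f"{r.log2_fold_change:.12g}\t{r.p_value:.12g}\t{r.p_bonferroni:.12g}\n"
            )


def read_de_table(path: str | Path, level: str) -> list[DEResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        DEResult(
            feature_id=str(row.feature_id), level=level,
            base_mean_normal=float(row.base_mean_normal),
            base_mean_tumor=float(row.base_mean_tumor),
            log2_fold_change=float(row.log2_fold_change),
            p_value=float(row.p_value), p_bonferroni=float(row.p_bonferroni),
        )
        for row in df.itertuples()
    ]
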