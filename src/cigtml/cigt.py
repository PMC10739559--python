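"""Reading, validating, writing and splitting CIGT cohort tables.

A CIGT (Clinically Integrated Genomics and Transcriptomics) table is a
delimited text file with one row per patient and columns for a patient
identifier, a binary diagnosis label (0 = control, 1 = case), optional
demographic attributes (numeric or categorical) and per-gene expression
values. Rows are always patients and columns always features; no
orientation heuristics are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

#: feature-kind tags
EXPRESSION = "expression"
DEMOGRAPHIC_NUMERIC = "demographic_numeric"
DEMOGRAPHIC_CATEGORICAL = "demographic_categorical_encoded"

DEFAULT_ID_COLUMN = "ID"
DEFAULT_LABEL_COLUMN = "Type"


class CIGTFormatError(ValueError):
    """The file does not conform to the CIGT layout (missing columns, ...)."""


class CIGTValidationError(ValueError):
    """The file parses but violates a CIGT invariant (duplicate IDs, ...)."""


@dataclass
class ValidationReport:
    """Outcome of validating a cohort table.

    ``passed`` is true exactly when ``errors`` is empty; warnings never
    fail validation.
    """

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.errors


@dataclass(frozen=True)
class CIGTDataset:
    """Validated patient x feature cohort with binary diagnosis labels.

    Attributes
    ----------
    sample_ids : list of str
        Unique patient identifiers, one per row of ``values``.
    labels : ndarray of shape (n_samples,)
        Binary diagnosis, 0 = control and 1 = case.
    feature_names : list of str
        Unique column names, in the order of the source file.
    values : ndarray of shape (n_samples, n_features)
        Numeric feature matrix with no missing values.
    feature_kinds : list of str
        Per-feature tag, one of ``expression``, ``demographic_numeric`` or
        ``demographic_categorical_encoded``.
    category_maps : dict
        For each categorically encoded column, the mapping from original
        string category to its deterministic (lexicographic) integer code.
    """

    sample_ids: list[str]
    labels: np.ndarray
    feature_names: list[str]
    values: np.ndarray
    feature_kinds: list[str]
    category_maps: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        report = validate(self)
        if not report.passed:
            msgs = "; ".join(f"[{c}] {m} ({loc})" for c, m, loc in report.errors)
            raise CIGTValidationError(msgs)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def feature(self, name: str) -> np.ndarray:
        """Return one feature column by name."""
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature: {name!r}") from None
        return self.values[:, j]

    def matrix(self, features: Sequence[str] | None = None) -> np.ndarray:
        """Return the value matrix restricted to ``features`` (in that order)."""
        if features is None:
            return self.values
        idx = []
        for name in features:
            if name not in self.feature_names:
                raise KeyError(f"unknown feature: {name!r}")
            idx.append(self.feature_names.index(name))
        return self.values[:, idx]

    def subset_samples(self, rows: Sequence[int]) -> "CIGTDataset":
        """Return a dataset containing only the given row positions."""
        rows = list(rows)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in rows],
            labels=self.labels[rows],
            values=self.values[rows, :],
        )

    def to_frame(
        self,
        id_column: str = DEFAULT_ID_COLUMN,
        label_column: str = DEFAULT_LABEL_COLUMN,
    ) -> pd.DataFrame:
        """Materialize the cohort as a DataFrame in CIGT column layout."""
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, label_column, self.labels)
        df.insert(0, id_column, self.sample_ids)
        return df


def validate(ds: CIGTDataset) -> ValidationReport:
    """Check all CIGT invariants; returns a report instead of raising."""
    rep = ValidationReport()
    n = len(ds.sample_ids)
    counts = pd.Series(ds.sample_ids).value_counts()
    dupes = sorted(counts[counts > 1].index.tolist())
    if dupes:
        rep.errors.append(("duplicate_id", f"duplicate sample IDs: {dupes}", "sample_ids"))
    if len(ds.labels) != n:
        rep.errors.append(("shape", f"{len(ds.labels)} labels for {n} samples", "labels"))
    bad_labels = sorted(set(np.unique(ds.labels)) - {0, 1})
    if bad_labels:
        rep.errors.append(
            ("non_binary_label", f"labels must be 0/1; found {bad_labels}", "labels")
        )
    if ds.values.shape != (n, len(ds.feature_names)):
        rep.errors.append(
            ("shape", f"value matrix {ds.values.shape} != ({n}, {len(ds.feature_names)})", "values")
        )
    else:
        nan_cols = [
            ds.feature_names[j]
            for j in range(ds.values.shape[1])
            if np.isnan(ds.values[:, j]).any()
        ]
        if nan_cols:
            rep.errors.append(
                ("missing_values", f"missing values in columns: {nan_cols}", "values")
            )
    fcounts = pd.Series(ds.feature_names).value_counts()
    fdupes = sorted(fcounts[fcounts > 1].index.tolist())
    if fdupes:
        rep.errors.append(("duplicate_feature", f"duplicate feature names: {fdupes}", "feature_names"))
    if len(ds.feature_kinds) != len(ds.feature_names):
        rep.errors.append(("shape", "one feature_kind required per feature", "feature_kinds"))
    else:
        bad_kinds = sorted(
            set(ds.feature_kinds) - {EXPRESSION, DEMOGRAPHIC_NUMERIC, DEMOGRAPHIC_CATEGORICAL}
        )
        if bad_kinds:
            rep.errors.append(("feature_kind", f"unknown feature kinds: {bad_kinds}", "feature_kinds"))
    if set(np.unique(ds.labels)) == {0, 1}:
        n_case = int((ds.labels == 1).sum())
        n_ctrl = int((ds.labels == 0).sum())
        if min(n_case, n_ctrl) < 2:
            rep.warnings.append(
                ("small_class", f"class counts case={n_case} control={n_ctrl}; "
                 "downstream fits require >=2 per class", "labels")
            )
    return rep


def read_cigt(
    path: str | Path,
    id_column: str = DEFAULT_ID_COLUMN,
    label_column: str = DEFAULT_LABEL_COLUMN,
    demographic_columns: Sequence[str] = (),
    allow_missing: bool = False,
) -> CIGTDataset:
    """Read a CIGT CSV into a validated :class:`CIGTDataset`.

    Non-numeric columns are treated as categorical demographics and
    deterministically integer-encoded in lexicographic category order so
    that each input column remains a single feature for downstream
    importance reporting (never one-hot). Numeric columns listed in
    ``demographic_columns`` are tagged ``demographic_numeric``; all other
    numeric columns are tagged ``expression``.

    Missing values are rejected unless ``allow_missing`` is set, in which
    case NaNs survive into the frame returned by the lower-level reader
    and must be imputed explicitly (see :func:`impute_median`).
    """
    path = Path(path)
    if not path.exists():
        raise CIGTFormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col in (id_column, label_column):
        if col not in df.columns:
            raise CIGTFormatError(
                f"required column {col!r} not found in {path.name}; "
                f"columns present: {list(df.columns)}"
            )
    return dataset_from_frame(
        df,
        id_column=id_column,
        label_column=label_column,
        demographic_columns=demographic_columns,
        allow_missing=allow_missing,
    )


def dataset_from_frame(
    df: pd.DataFrame,
    id_column: str = DEFAULT_ID_COLUMN,
    label_column: str = DEFAULT_LABEL_COLUMN,
    demographic_columns: Sequence[str] = (),
    allow_missing: bool = False,
) -> CIGTDataset:
    """Build a validated dataset from an in-memory CIGT-layout frame."""
    labels_raw = df[label_column]
    bad = sorted(set(labels_raw.unique()) - {0, 1, "0", "1"})
    if bad:
        raise CIGTValidationError(
            f"label column {label_column!r} must be binary 0/1; found values {bad}"
        )
    feature_cols = [c for c in df.columns if c not in (id_column, label_column)]
    kinds: list[str] = []
    category_maps: dict[str, dict[str, int]] = {}
    columns: list[np.ndarray] = []
    for col in feature_cols:
        series = df[col]
        if pd.api.types.is_numeric_dtype(series):
            kinds.append(DEMOGRAPHIC_NUMERIC if col in demographic_columns else EXPRESSION)
            columns.append(series.to_numpy(dtype=float))
        else:
            cats = sorted(series.dropna().astype(str).unique())
            mapping = {c: i for i, c in enumerate(cats)}
            category_maps[col] = mapping
            encoded = series.astype(str).map(mapping).to_numpy(dtype=float)
            encoded[series.isna().to_numpy()] = np.nan
            kinds.append(DEMOGRAPHIC_CATEGORICAL)
            columns.append(encoded)
    values = np.column_stack(columns) if columns else np.empty((len(df), 0))
    if not allow_missing and values.size and np.isnan(values).any():
        bad_cols = [feature_cols[j] for j in range(values.shape[1]) if np.isnan(values[:, j]).any()]
        raise CIGTValidationError(
            f"missing values in columns {bad_cols}; re-read with allow_missing=True "
            "and impute explicitly, or clean the input"
        )
    if allow_missing and values.size and np.isnan(values).any():
        values = impute_median(values)
        logger.warning("missing values imputed with per-feature medians")
    return CIGTDataset(
        sample_ids=df[id_column].astype(str).tolist(),
        labels=labels_raw.astype(int).to_numpy(),
        feature_names=feature_cols,
        values=values,
        feature_kinds=kinds,
        category_maps=category_maps,
    )


def impute_median(values: np.ndarray, medians: np.ndarray | None = None) -> np.ndarray:
    """Fill NaNs per column with ``medians`` (or the column medians).

    Pass medians computed on training rows to avoid evaluation leakage.
    """
    out = values.copy()
    if medians is None:
        medians = np.nanmedian(out, axis=0)
    for j in range(out.shape[1]):
        mask = np.isnan(out[:, j])
        out[mask, j] = medians[j]
    return out


def write_cigt(
    ds: CIGTDataset,
    path: str | Path,
    id_column: str = DEFAULT_ID_COLUMN,
    label_column: str = DEFAULT_LABEL_COLUMN,
) -> Path:
    """Write the cohort back to CIGT CSV.

    Categorically encoded columns with a known category map are decoded
    back to their original strings, so reading the written file
    reproduces codes and feature kinds exactly; maps are lexicographic on
    both sides. Encoded columns without a map (e.g. simulated ones whose
    categories were never strings) stay as integer codes.
    """
    path = Path(path)
    df = ds.to_frame(id_column=id_column, label_column=label_column)
    for col in df.columns[2:]:
        if ds.feature_kinds[df.columns.get_loc(col) - 2] != DEMOGRAPHIC_CATEGORICAL:
            continue
        codes = df[col].to_numpy().astype(int)
        mapping = ds.category_maps.get(col)
        if mapping:
            decode = {v: k for k, v in mapping.items()}
            df[col] = [decode[c] for c in codes]
        else:
            df[col] = codes
    df.to_csv(path, index=False)
    return path


def split_dataset(
    ds: CIGTDataset, test_fraction: float, seed: int
) -> tuple[CIGTDataset, CIGTDataset]:
    """Stratified train/test split of a cohort.

    Class proportions in each part are within one sample of the overall
    proportion; the split is a partition (train and test are disjoint and
    jointly exhaustive) and is a deterministic function of ``seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1); got {test_fraction}")
    n_case = int((ds.labels == 1).sum())
    n_ctrl = int((ds.labels == 0).sum())
    if min(n_case, n_ctrl) < 2:
        raise CIGTValidationError(
            f"both classes need >=2 samples to split; got case={n_case} control={n_ctrl}"
        )
    idx = np.arange(ds.n_samples)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=ds.labels
    )
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    for name, part in (("training", train_idx), ("test", test_idx)):
        part_labels = ds.labels[part]
        if len(np.unique(part_labels)) < 2:
            raise CIGTValidationError(f"{name} partition would contain a single class")
    return ds.subset_samples(train_idx), ds.subset_samples(test_idx)
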