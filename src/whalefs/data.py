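"""Dataset container, CSV I/O, stratified splitting, and a synthetic
generator with known informative features.

The synthetic generator emulates clinical tabular benchmarks (a few hundred
to ~1300 instances, ~10–80 features, binary or severity-coded labels):
labels are Bernoulli(class balance); each informative feature is a
class-conditional Gaussian with means ±separation/2 in units of the unit
within-class standard deviation; noise features are standard Gaussians
independent of the label.  Because the generator knows which columns carry
signal, it doubles as the ground-truth oracle for feature-selection tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binary_fs import FeatureMask
from .exceptions import DatasetParseError, SplitError
from .metrics import ConfusionMatrix

__all__ = [
    "Dataset",
    "SplitSpec",
    "SyntheticSpec",
    "read_csv_dataset",
    "write_csv_dataset",
    "train_test_split",
    "synthesize",
    "reference_confusion_matrices",
]

#: Confusion matrices (TP, FP, FN, TN) reported for the WOA+NB pipeline on
#: four public clinical/benchmark datasets; packaged for arithmetic
#: consistency checks and worked examples.  Sizes exceed the source tables'
#: instance counts (pooled repeated evaluations); the counts are used as
#: printed, with no repeat factor assumed.
_REFERENCE_CONFUSION = {
    "Diabetes": (4730, 410, 1140, 1400),
    "Heart disease uci": (1120, 260, 180, 1470),
    "Heart attack prediction": (1660, 250, 130, 900),
    "Sonar": (980, 130, 100, 870),
}


@dataclass
class Dataset:
    """A tabular classification dataset.

    ``X`` is n × C_total (float64 when all columns are numeric, object
    otherwise); ``y`` holds integer codes 0..K−1 with ``label_mapping``
    giving the original labels in code order.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    feature_kinds: list[str]
    name: str = "dataset"
    label_mapping: list = field(default_factory=list)
    row_indices: np.ndarray | None = None  # provenance of a split part

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of instances")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match X columns")
        if len(self.feature_kinds) != len(self.feature_names):
            raise ValueError("feature_kinds length must match feature_names")
        if not self.label_mapping:
            self.label_mapping = sorted(set(self.y.tolist()))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(set(self.y.tolist()))

    def select_features(self, mask) -> "Dataset":
        """Restrict to the columns of a FeatureMask (or index array)."""
        idx = np.flatnonzero(np.asarray(getattr(mask, "bits", mask)))
        return Dataset(
            X=self.X[:, idx],
            y=self.y,
            feature_names=[self.feature_names[i] for i in idx],
            feature_kinds=[self.feature_kinds[i] for i in idx],
            name=self.name,
            label_mapping=list(self.label_mapping),
            row_indices=self.row_indices,
        )

    def take(self, rows: np.ndarray) -> "Dataset":
        return Dataset(
            X=self.X[rows],
            y=self.y[rows],
            feature_names=list(self.feature_names),
            feature_kinds=list(self.feature_kinds),
            name=self.name,
            label_mapping=list(self.label_mapping),
            row_indices=np.asarray(rows),
        )


@dataclass
class SplitSpec:
    """Train/test split parameters: 70/30 stratified by default."""

    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic generator.

    ``class_separation`` is the distance between the two class means along
    each informative axis, in units of the (unit) within-class standard
    deviation; ``class_balance`` is P(label = 1).
    """

    n: int = 600
    k_informative: int = 5
    k_noise: int = 15
    class_separation: float = 1.0
    class_balance: float = 0.5
    seed: int = 0
    categorical: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.k_informative < 1:
            raise ValueError("k_informative must be at least 1")
        if self.k_noise < 0:
            raise ValueError("k_noise must be non-negative")
        if self.class_separation < 0:
            raise ValueError("class_separation must be non-negative")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")


def _infer_kind(col: pd.Series, max_distinct: int) -> str:
    if not pd.api.types.is_numeric_dtype(col):
        return "categorical"
    return "categorical" if col.nunique() <= max_distinct else "continuous"


def read_csv_dataset(
    path: str | Path,
    target_column: str,
    kind_overrides: Mapping[str, str] | None = None,
    categorical_max_distinct: int = 10,
    missing: str = "error",
) -> Dataset:
    """Load an RFC-4180-style CSV (header required) into a Dataset.

    Feature kinds are inferred — non-numeric columns and numeric columns
    with at most ``categorical_max_distinct`` distinct values are
    categorical — and can be overridden per column.  ``missing`` is
    ``"error"`` (default) or ``"drop"`` (drop incomplete rows).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise DatasetParseError(f"{path}: {exc}") from exc
    if df.shape[0] == 0:
        raise DatasetParseError(f"{path}: no data rows")
    if target_column not in df.columns:
        raise DatasetParseError(
            f"{path}: target column {target_column!r} not found "
            f"(columns: {list(df.columns)})"
        )
    if df.isna().any().any():
        if missing == "drop":
            df = df.dropna(axis=0).reset_index(drop=True)
            if df.shape[0] == 0:
                raise DatasetParseError(f"{path}: all rows have missing values")
        else:
            bad = df.columns[df.isna().any()].tolist()
            raise DatasetParseError(
                f"{path}: missing values in columns {bad}; pass missing='drop' "
                "to drop incomplete rows"
            )

    y_raw = df[target_column]
    feats = df.drop(columns=[target_column])
    overrides = dict(kind_overrides or {})
    for name in overrides:
        if name not in feats.columns:
            raise DatasetParseError(f"kind override for unknown column {name!r}")
    kinds = [
        overrides.get(c, _infer_kind(feats[c], categorical_max_distinct))
        for c in feats.columns
    ]
    labels = sorted(y_raw.unique().tolist())
    code = {v: i for i, v in enumerate(labels)}
    y = y_raw.map(code).to_numpy(dtype=int)
    all_numeric = all(pd.api.types.is_numeric_dtype(feats[c]) for c in feats.columns)
    X = feats.to_numpy(dtype=float if all_numeric else object)
    return Dataset(
        X=X,
        y=y,
        feature_names=list(feats.columns),
        feature_kinds=kinds,
        name=path.stem,
        label_mapping=labels,
    )


def write_csv_dataset(dataset: Dataset, path: str | Path, target_column: str = "label") -> None:
    """Write a Dataset back to CSV with original labels in ``target_column``."""
    df = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    df[target_column] = [dataset.label_mapping[c] for c in dataset.y]
    df.to_csv(path, index=False)


def train_test_split(dataset: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Disjoint, exhaustive train/test split.

    Stratified (default): each class is permuted and cut so its train
    fraction is within one instance of ``spec.train_fraction``; a singleton
    class is an error.  Seeded deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    n = dataset.n
    if spec.stratified:
        train_idx: list[np.ndarray] = []
        test_idx: list[np.ndarray] = []
        for label in sorted(set(dataset.y.tolist())):
            members = np.flatnonzero(dataset.y == label)
            if len(members) < 2:
                raise SplitError(
                    f"class {label!r} has a single instance; cannot stratify"
                )
            perm = rng.permutation(members)
            n_train = int(round(len(members) * spec.train_fraction))
            n_train = min(max(n_train, 1), len(members) - 1)
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        tr = np.sort(np.concatenate(train_idx))
        te = np.sort(np.concatenate(test_idx))
    else:
        perm = rng.permutation(n)
        n_train = min(max(int(round(n * spec.train_fraction)), 1), n - 1)
        tr = np.sort(perm[:n_train])
        te = np.sort(perm[n_train:])
    return dataset.take(tr), dataset.take(te)


def synthesize(spec: SyntheticSpec) -> tuple[Dataset, FeatureMask]:
    """Generate a dataset with a known informative-feature mask.

    Returns the dataset (columns shuffled) and the ground-truth mask whose
    1-bits sit at the informative columns' final positions.  Setting
    ``spec.categorical`` discretizes the informative columns into quartile
    codes to exercise the categorical likelihood path.
    """
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n) < spec.class_balance).astype(int)
    half = spec.class_separation / 2.0
    k_total = spec.k_informative + spec.k_noise
    X = rng.standard_normal((spec.n, k_total))
    signs = np.where(y == 1, half, -half)
    X[:, : spec.k_informative] += signs[:, None]
    order = rng.permutation(k_total)
    X = X[:, order]
    bits = np.zeros(k_total, dtype=int)
    bits[np.flatnonzero(order < spec.k_informative)] = 1
    kinds = ["continuous"] * k_total
    if spec.categorical:
        for j in np.flatnonzero(bits):
            q = np.quantile(X[:, j], [0.25, 0.5, 0.75])
            X[:, j] = np.searchsorted(q, X[:, j]).astype(float)
            kinds[j] = "categorical"
    names = [f"f{j}" for j in range(k_total)]
    ds = Dataset(
        X=X,
        y=y,
        feature_names=names,
        feature_kinds=kinds,
        name=f"synthetic(n={spec.n},inf={spec.k_informative},noise={spec.k_noise})",
        label_mapping=[0, 1],
    )
    return ds, FeatureMask(bits)


def reference_confusion_matrices() -> dict[str, ConfusionMatrix]:
    """The packaged reference confusion matrices, as (TP, FP, FN, TN)."""
    return {
        name: ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        for name, (tp, fp, fn, tn) in _REFERENCE_CONFUSION.items()
    }
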