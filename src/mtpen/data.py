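"""Grouped (multi-platform) datasets and their delimited-text I/O.

A :class:`GroupedDataset` holds an ``n x p`` feature matrix whose columns are
partitioned into contiguous platform blocks (e.g. gene expression features
followed by DNA methylation features), a binary outcome, and identifiers.
The block structure is what the multi-tuning-parameter penalty acts on:
penalty factors are constant within a block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GroupedDataset", "load_dataset", "save_dataset"]


@dataclass
class GroupedDataset:
    """Feature matrix with a binary outcome and a platform partition.

    Parameters
    ----------
    features
        ``(n, p)`` real matrix, no missing values.
    outcome
        Length-``n`` vector with entries in ``{0, 1}``.
    group_sizes
        Ordered platform block sizes ``(p1, p2, ...)`` summing to ``p``.
    feature_ids, sample_ids
        Optional identifiers; generated (``f1..fp`` / ``s1..sn``) if omitted.
    """

    features: np.ndarray
    outcome: np.ndarray
    group_sizes: tuple[int, ...]
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.ascontiguousarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.outcome = np.asarray(self.outcome, dtype=np.float64).ravel()
        n, p = self.features.shape
        if self.outcome.shape[0] != n:
            raise ValueError(f"outcome length {self.outcome.shape[0]} != n = {n}")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        uniq = np.unique(self.outcome)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("outcome entries must be 0 or 1")
        self.group_sizes = tuple(int(g) for g in self.group_sizes)
        if any(g <= 0 for g in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if sum(self.group_sizes) != p:
            raise ValueError(
                f"group sizes {self.group_sizes} do not sum to p = {p}"
            )
        if self.feature_ids is None:
            self.feature_ids = [f"f{j + 1}" for j in range(p)]
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        if len(self.feature_ids) != p or len(self.sample_ids) != n:
            raise ValueError("identifier lengths do not match the matrix shape")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def group_labels(self) -> np.ndarray:
        """Integer platform label (0-based) per feature column."""
        return np.repeat(np.arange(self.n_groups), self.group_sizes)

    def has_both_classes(self) -> bool:
        return bool(self.outcome.min() == 0.0 and self.outcome.max() == 1.0)

    def require_both_classes(self) -> None:
        if not self.has_both_classes():
            raise ValueError("outcome must contain both classes for fitting")

    def subset(self, idx: np.ndarray) -> "GroupedDataset":
        """Row subset (samples) keeping the feature partition."""
        idx = np.asarray(idx)
        return GroupedDataset(
            self.features[idx],
            self.outcome[idx],
            self.group_sizes,
            feature_ids=self.feature_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
        )


def load_dataset(
    features_csv: str | Path,
    outcome_csv: str | Path,
    platform_csv: str | Path,
    sep: str = ",",
) -> GroupedDataset:
    """Assemble a :class:`GroupedDataset` from three delimited text files.

    ``features_csv`` is samples x features with a header row of feature IDs
    and the sample ID in the first column.  ``outcome_csv`` has two columns
    (sample ID, 0/1).  ``platform_csv`` has two columns (feature ID,
    platform label); the order in which platform labels first appear defines
    the group order, and features are reordered into contiguous blocks
    accordingly.
    """
    feat = pd.read_csv(features_csv, sep=sep, index_col=0)
    out = pd.read_csv(outcome_csv, sep=sep, index_col=0)
    plat = pd.read_csv(platform_csv, sep=sep)
    if plat.shape[1] != 2:
        raise ValueError("platform annotation must have exactly two columns")
    if out.shape[1] != 1:
        raise ValueError("outcome file must have exactly two columns")

    feat.index = feat.index.astype(str)
    out.index = out.index.astype(str)
    missing = set(feat.index) ^ set(out.index)
    if missing:
        raise ValueError(
            f"sample IDs differ between features and outcome files: {sorted(missing)[:5]}"
        )
    out = out.loc[feat.index]
    y = out.iloc[:, 0].to_numpy()
    if not np.all(np.isin(np.unique(y), [0, 1])):
        raise ValueError("outcome column must be binary 0/1")

    fid_col, lab_col = plat.columns[0], plat.columns[1]
    plat[fid_col] = plat[fid_col].astype(str)
    feat.columns = feat.columns.astype(str)
    unknown = set(feat.columns) ^ set(plat[fid_col])
    if unknown:
        raise ValueError(
            f"feature IDs differ between features and platform files: {sorted(unknown)[:5]}"
        )
    # platform order = first label encountered in the annotation file
    labels_in_order = list(dict.fromkeys(plat[lab_col]))
    by_label = {lab: plat.loc[plat[lab_col] == lab, fid_col].tolist() for lab in labels_in_order}
    ordered_ids = [fid for lab in labels_in_order for fid in by_label[lab]]
    group_sizes = tuple(len(by_label[lab]) for lab in labels_in_order)
    feat = feat[ordered_ids]
    if feat.isna().any().any():
        bad = feat.columns[feat.isna().any()][:5].tolist()
        raise ValueError(f"missing values in feature columns: {bad}")

    return GroupedDataset(
        feat.to_numpy(dtype=np.float64),
        y.astype(np.float64),
        group_sizes,
        feature_ids=ordered_ids,
        sample_ids=feat.index.tolist(),
    )


def save_dataset(
    data: GroupedDataset,
    out_dir: str | Path,
    prefix: str = "dataset",
    platform_names: list[str] | None = None,
) -> dict[str, Path]:
    """Write the three-file CSV layout read back by :func:`load_dataset`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if platform_names is None:
        platform_names = [f"platform{g + 1}" for g in range(data.n_groups)]
    if len(platform_names) != data.n_groups:
        raise ValueError("one platform name per group required")

    paths = {
        "features": out_dir / f"{prefix}_features.csv",
        "outcome": out_dir / f"{prefix}_outcome.csv",
        "platforms": out_dir / f"{prefix}_platforms.csv",
    }
    pd.DataFrame(
        data.features, index=pd.Index(data.sample_ids, name="sample_id"),
        columns=data.feature_ids,
    ).to_csv(paths["features"])
    pd.DataFrame(
        {"outcome": data.outcome.astype(int)},
        index=pd.Index(data.sample_ids, name="sample_id"),
    ).to_csv(paths["outcome"])
    pd.DataFrame(
        {
            "feature_id": data.feature_ids,
            "platform": np.repeat(platform_names, data.group_sizes),
        }
    ).to_csv(paths["platforms"], index=False)
    return paths
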