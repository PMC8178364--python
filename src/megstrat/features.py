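"""Subjects x features container shared by the power and connectivity stages.

A :class:`FeatureMatrix` is a thin wrapper around a pandas DataFrame
(rows = subjects, columns = named features) carrying the group label per
subject and per-feature metadata (feature type, band, region or region
pair). Feature names follow fixed conventions:

* regional power:  ``pow_<band>_<roi>``
* connectivity:    ``aec_<band>_<i>_<j>`` with ``i < j``
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    values: pd.DataFrame          # index: subject_id, columns: feature names
    labels: pd.Series             # index: subject_id, group label
    meta: pd.DataFrame            # index: feature names; columns type, band, ...

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("values and labels must share the subject index")
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("meta must describe exactly the feature columns")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_subjects(self, ids) -> "FeatureMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise KeyError(f"unknown subject ids: {sorted(missing)}")
        return FeatureMatrix(self.values.loc[ids].copy(),
                             self.labels.loc[ids].copy(), self.meta.copy())

    def subset_features(self, names) -> "FeatureMatrix":
        names = list(names)
        missing = set(names) - set(self.values.columns)
        if missing:
            raise KeyError(f"unknown features: {sorted(missing)}")
        return FeatureMatrix(self.values[names].copy(), self.labels.copy(),
                             self.meta.loc[names].copy())

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        """Concatenate feature sets over the same subjects."""
        if not self.values.index.equals(other.values.index):
            raise ValueError("subject indices differ")
        overlap = set(self.values.columns) & set(other.values.columns)
        if overlap:
            raise ValueError(f"duplicate features: {sorted(overlap)[:5]}")
        return FeatureMatrix(pd.concat([self.values, other.values], axis=1),
                             self.labels.copy(),
                             pd.concat([self.meta, other.meta], axis=0))

    # -- persistence ------------------------------------------------------

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.labels)
        out.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, meta: pd.DataFrame | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="subject_id")
        labels = df.pop("group")
        if meta is None:
            meta = meta_from_names(df.columns)
        return cls(df, labels, meta)


def meta_from_names(names) -> pd.DataFrame:
    """Reconstruct feature metadata from conventional feature names."""
    rows = []
    for name in names:
        parts = name.split("_")
        kind = parts[0]
        if kind == "pow":
            rows.append({"type": "power", "band": "_".join(parts[1:-1]),
                         "roi": int(parts[-1]), "i": -1, "j": -1})
        elif kind == "aec":
            rows.append({"type": "aec", "band": "_".join(parts[1:-2]),
                         "roi": -1, "i": int(parts[-2]), "j": int(parts[-1])})
        else:
            rows.append({"type": "other", "band": "", "roi": -1, "i": -1, "j": -1})
    return pd.DataFrame(rows, index=list(names))
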