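"""Per-modality omics data container.

An :class:`OmicsView` holds one modality's samples × features matrix together
with aligned sample and feature identifiers.  Missing entries are represented
by NaN in memory and by empty fields on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["OmicsView"]


@dataclass
class OmicsView:
    """One omics modality: an (n_samples, n_features) real-valued matrix.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Measurement matrix; NaN marks a missing entry.
    sample_ids : list of str
        Unique, ordered sample identifiers (row labels).
    feature_ids : list of str
        Unique, ordered feature identifiers (column labels).
    modality : str
        Name of the modality (e.g. ``"mrna"``, ``"meth"``, ``"mirna"``).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    modality: str = "omics"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, f = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids for {n} rows in {self.modality!r}"
            )
        if len(self.feature_ids) != f:
            raise ValueError(
                f"{len(self.feature_ids)} feature_ids for {f} columns in {self.modality!r}"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.feature_ids)) != f:
            raise ValueError("feature_ids must be unique")

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def with_values(self, values: np.ndarray, feature_ids: list[str] | None = None) -> "OmicsView":
        """Return a copy with new values (and optionally new feature ids)."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            feature_ids=list(feature_ids) if feature_ids is not None else list(self.feature_ids),
        )

    # -- disk round trip ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def to_tsv(self, path) -> None:
        """Write as TSV: first column sample ID, header row feature IDs."""
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path, modality: str = "omics") -> "OmicsView":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=[str(s) for s in df.index],
            feature_ids=[str(f) for f in df.columns],
            modality=modality,
        )
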