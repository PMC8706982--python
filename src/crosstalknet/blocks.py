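"""Omics block container shared by every pipeline stage.

An :class:`OmicsBlock` is one sample-by-feature matrix tagged with the omics
layer it came from (``genus`` counts, ``fecal`` or ``plasma`` metabolite
concentrations) plus an ordered log of the transforms already applied to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BLOCK_LABELS = ("genus", "fecal", "plasma")


class DataError(ValueError):
    """Raised when input data violate a structural requirement."""


class ConfigurationError(ValueError):
    """Raised when a parameter is outside its documented domain."""


@dataclass
class OmicsBlock:
    """One sample x feature matrix with block identity and provenance.

    Parameters
    ----------
    data:
        Samples as rows, features as columns. Missing cells are NaN.
    block_label:
        One of ``genus``, ``fecal``, ``plasma``.
    transform_log:
        Names of transforms applied so far, in application order.
    """

    data: pd.DataFrame
    block_label: str
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.block_label not in BLOCK_LABELS:
            raise ConfigurationError(
                f"block_label must be one of {BLOCK_LABELS}, got {self.block_label!r}"
            )
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise DataError(f"duplicate feature names in {self.block_label} block: {dupes}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise DataError(f"duplicate sample ids in {self.block_label} block: {dupes}")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing cells."""
        return self.data.isna().mean(axis=0)

    def has_transform(self, name: str) -> bool:
        return name in self.transform_log

    def with_data(self, data: pd.DataFrame, log_entry: str | None = None) -> "OmicsBlock":
        """Return a copy holding ``data``, optionally appending to the log."""
        log = list(self.transform_log)
        if log_entry is not None:
            log.append(log_entry)
        return replace(self, data=data, transform_log=log)

    def copy(self) -> "OmicsBlock":
        return replace(self, data=self.data.copy(), transform_log=list(self.transform_log))


def check_shared_samples(blocks: dict[str, OmicsBlock]) -> list[str]:
    """Verify all blocks share one sample index; return it in order.

    Raises :class:`DataError` listing the offending sample ids otherwise.
    """
    labels = list(blocks)
    ref = blocks[labels[0]].sample_ids
    ref_set = set(ref)
    for label in labels[1:]:
        ids = set(blocks[label].sample_ids)
        if ids != ref_set:
            missing = sorted(ref_set - ids)
            extra = sorted(ids - ref_set)
            raise DataError(
                f"sample mismatch between {labels[0]} and {label} blocks: "
                f"missing={missing[:10]} extra={extra[:10]}"
            )
    return ref
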