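"""The features × samples count container shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

LEVELS = ("isomir", "mirna")


@dataclass
class CountMatrix:
    """Non-negative counts, features on rows and sample libraries on columns.

    ``normalized`` distinguishes raw integer read counts from the RPM view
    (reads per million; each retained library column sums to 1e6 when no
    feature has been filtered out).
    """

    data: pd.DataFrame
    level: str = "isomir"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise InputError(f"level must be one of {LEVELS}, got {self.level!r}")
        values = self.data.to_numpy()
        if values.size and np.nanmin(values) < 0:
            raise InputError("count matrix contains negative values")
        if not self.normalized:
            if values.size and not np.allclose(values, np.round(values)):
                raise InputError("raw counts must be integers")
            self.data = self.data.astype("int64")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def library_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def drop_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        keep = [s for s in self.data.columns if s not in set(sample_ids)]
        return replace(self, data=self.data[keep])

    def select_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        return replace(self, data=self.data.loc[list(feature_ids)])
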