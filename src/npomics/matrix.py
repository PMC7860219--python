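"""Expression matrix container shared by every pipeline stage.

An :class:`ExpressionMatrix` is a features x samples table of signal values
plus the metadata the rest of the pipeline needs: which omics layer it came
from (``protein`` or ``mrna``), whether the values are on the linear or the
log2 scale, and which condition (``IVD`` = normal disc, ``IDD`` = degenerated
disc) each sample belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError

LAYERS = ("protein", "mrna")
SCALES = ("linear", "log2")
CONDITIONS = ("IVD", "IDD")


@dataclass
class ExpressionMatrix:
    """Features x samples expression table with layer/scale/group metadata.

    Parameters
    ----------
    data
        DataFrame with feature ids as the index and sample ids as columns.
    layer
        ``"protein"`` or ``"mrna"``.
    scale
        ``"linear"`` or ``"log2"``.
    groups
        Mapping from sample id to condition label. Conditions are expected
        to be ``"IVD"`` (normal) and ``"IDD"`` (degenerated).
    """

    data: pd.DataFrame
    layer: str
    scale: str
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without a group assignment: {missing}")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def condition_samples(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in column order."""
        return [s for s in self.data.columns if self.groups[s] == condition]

    def restrict_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Sub-matrix over the given samples (metadata preserved)."""
        return replace(self, data=self.data[list(sample_ids)])

    def restrict_features(self, feature_ids) -> "ExpressionMatrix":
        """Sub-matrix over the given features (order as requested)."""
        return replace(self, data=self.data.loc[list(feature_ids)])

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return replace(self, data=data, scale=scale or self.scale)

    def check_finite(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                "non-finite value at feature "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
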