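"""Expression-matrix container shared across the pipeline.

An :class:`ExpressionMatrix` is an entities x samples table of abundances
plus per-sample metadata (time point, condition, replicate). Conditions are
``injured`` vs ``sham``; time points are free-form labels ("0h", "24h",
"7d", ...). Values are on a positive, linear-like scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CONDITIONS = ("injured", "sham")

META_COLUMNS = ("time_point", "condition", "replicate")


@dataclass
class ExpressionMatrix:
    """Entities x samples abundance table with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by entity id, one column per sample id.
    sample_meta
        DataFrame indexed by sample id with columns ``time_point``,
        ``condition`` and ``replicate``, aligned 1:1 with ``values`` columns.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate entity ids: {list(dups)[:5]}")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValueError(
                "sample_meta index must equal values columns "
                f"({len(self.values.columns)} columns vs "
                f"{len(self.sample_meta)} metadata rows)"
            )
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta missing columns: {missing}")
        bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(
        self,
        condition: str | None = None,
        time_point: str | None = None,
    ) -> "ExpressionMatrix":
        """Return a new matrix restricted to matching sample columns."""
        mask = pd.Series(True, index=self.sample_meta.index)
        if condition is not None:
            mask &= self.sample_meta["condition"] == condition
        if time_point is not None:
            mask &= self.sample_meta["time_point"].astype(str) == str(time_point)
        cols = self.sample_meta.index[mask]
        return ExpressionMatrix(self.values[cols], self.sample_meta.loc[cols])

    def row(self, entity_id: str):
        """1-D numpy vector of one entity's values across samples."""
        return self.values.loc[entity_id].to_numpy(dtype=float)

    # -- TSV round trip -----------------------------------------------------

    def to_tsv(self, values_path: str | Path, meta_path: str | Path) -> None:
        # %.17g round-trips float64 exactly through text
        self.values.to_csv(
            values_path, sep="\t", index_label="entity_id", float_format="%.17g"
        )
        self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, values_path: str | Path, meta_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(
            values_path, sep="\t", index_col="entity_id",
            float_precision="round_trip",
        )
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        values.columns = values.columns.astype(str)
        meta.index = meta.index.astype(str)
        return cls(values, meta)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and self.sample_meta.equals(
            other.sample_meta
        )
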