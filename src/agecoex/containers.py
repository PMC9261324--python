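"""Core in-memory containers: expression matrices and sample trait tables.

Both are thin validated wrappers around :class:`pandas.DataFrame` so that
every pipeline stage shares one substrate and IDs travel with the values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Recognised measurement scales for an expression matrix.
SCALE_TAGS = ("raw_counts", "fpkm", "log2", "normalized_intensity")

#: Scales on which values are linear (non-negative) rather than logged.
LINEAR_SCALES = ("raw_counts", "fpkm")


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression with IDs.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene ID, columns by sample ID.  All entries must be
        finite; on linear scales they must also be non-negative.
    scale_tag : str
        One of ``raw_counts``, ``fpkm``, ``log2``, ``normalized_intensity``.
    """

    data: pd.DataFrame
    scale_tag: str = "normalized_intensity"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        dup_g = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_g:
            raise ValueError(f"duplicate gene IDs: {dup_g}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample IDs: {dup_s}")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if self.scale_tag in LINEAR_SCALES and vals.size and (vals < 0).any():
            raise ValueError(f"negative values on linear scale {self.scale_tag!r}")

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Row-subset preserving order of `genes`."""
        return ExpressionMatrix(self.data.loc[list(genes)], self.scale_tag)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], self.scale_tag)


@dataclass
class TraitTable:
    """Per-sample traits: age in years, sex, ethnicity, optional group.

    ``data`` is indexed by sample ID; an ``age`` column is required and must
    lie in [0, 120].  ``sex`` values, when present, must be ``F`` or ``M``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        dup = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate sample IDs in trait table: {dup}")
        if "age" not in self.data.columns:
            raise ValueError("trait table requires an 'age' column")
        age = self.data["age"].to_numpy(dtype=float)
        if ((age < 0) | (age > 120)).any():
            raise ValueError("ages must lie within [0, 120] years")
        if "sex" in self.data.columns:
            bad = set(self.data["sex"]) - {"F", "M"}
            if bad:
                raise ValueError(f"sex labels must be F/M, got {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def age(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    def subset(self, samples) -> "TraitTable":
        return TraitTable(self.data.loc[list(samples)])


def align_samples(m: ExpressionMatrix, traits: TraitTable) -> TraitTable:
    """Reorder `traits` to the matrix's samples; error on any mismatch.

    Sample subsetting of expression propagates to traits only through this
    explicit step so silent misalignment cannot occur.
    """
    missing = [s for s in m.sample_ids if s not in set(traits.sample_ids)]
    if missing:
        raise ValueError(f"samples missing from trait table: {missing}")
    return traits.subset(m.sample_ids)
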