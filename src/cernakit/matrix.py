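"""Feature-by-sample expression container shared by every pipeline stage.

The matrix holds raw counts (integers) or transformed values (floats),
plus per-feature metadata (biotype, optional genomic coordinates) and
per-sample metadata (tumor/normal condition, pairing, optional subclass
and survival columns). All downstream stages — filtering, differential
expression, classification, correlation — consume this one object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: recognised feature biotypes
BIOTYPES = ("mRNA", "lncRNA", "circRNA", "miRNA")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Expression values with aligned feature and sample metadata.

    Parameters
    ----------
    values
        DataFrame of shape (n_features, n_samples). Raw counts must be
        non-negative; transformed matrices may hold arbitrary floats
        (set ``transformed=True``).
    feature_meta
        DataFrame indexed by feature id. Expected column ``biotype``;
        optional ``chrom``, ``start``, ``end``, ``strand``.
    sample_meta
        DataFrame indexed by sample id. Expected column ``condition``
        with values ``tumor``/``normal``; optional ``pair_id``,
        ``subclass``, ``time``, ``event``.
    transformed
        False for raw integer counts, True after log transformation.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame = None
    sample_meta: pd.DataFrame = None
    transformed: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dups[:5]}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=v.index)
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=v.columns)
        missing = v.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValidationError(
                f"samples missing from metadata: {missing.tolist()[:5]}"
            )
        missing_f = v.index.difference(self.feature_meta.index)
        if len(missing_f):
            raise ValidationError(
                f"features missing from metadata: {missing_f.tolist()[:5]}"
            )
        # keep metadata aligned to the matrix
        self.feature_meta = self.feature_meta.loc[v.index]
        self.sample_meta = self.sample_meta.loc[v.columns]
        if not self.transformed:
            arr = v.to_numpy()
            if not np.issubdtype(arr.dtype, np.number):
                raise ValidationError("count matrix contains non-numeric cells")
            if (arr < 0).any():
                i, j = np.argwhere(arr < 0)[0]
                raise ValidationError(
                    f"negative count at feature {v.index[i]!r}, "
                    f"sample {v.columns[j]!r}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def biotype(self, biotype: str) -> "ExpressionMatrix":
        """Subset to features of one biotype."""
        keep = self.feature_meta.index[self.feature_meta["biotype"] == biotype]
        return self.subset_features(keep)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[feature_ids],
            self.feature_meta.loc[feature_ids],
            self.sample_meta,
            transformed=self.transformed,
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)],
            self.feature_meta,
            self.sample_meta.loc[list(sample_ids)],
            transformed=self.transformed,
        )

    def condition_groups(self) -> dict:
        """Map condition label -> list of sample ids."""
        return {
            str(c): list(idx)
            for c, idx in self.sample_meta.groupby("condition").groups.items()
        }
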