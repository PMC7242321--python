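"""Core data containers: expression, count and GEBV matrices, attribute tables.

All containers are thin validating wrappers around :class:`pandas.DataFrame`
with a shared TSV dialect: tab-delimited, UTF-8, ``.`` decimal separator,
first column holding feature ids (or sample ids for GEBV tables) and the
header row holding sample ids (or trait ids).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CountMatrix",
    "GEBVMatrix",
    "AttributeTable",
    "read_matrix_tsv",
]

VALID_ROLES = ("gene", "mirna")
VALID_ATTRIBUTE_KINDS = ("DEG", "TF", "cis_eqtl", "trans_eqtl")
VALID_DIRECTIONS = ("up", "down", "none")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


class ExpressionMatrix:
    """Normalized expression values, features x samples, with a role per feature.

    Parameters
    ----------
    data : pandas.DataFrame
        Features on rows, samples on columns. No missing values allowed.
    feature_role : str or pandas.Series
        Either a single role applied to all features or a per-feature Series
        aligned to ``data.index``. Roles are ``"gene"`` or ``"mirna"``.
    """

    _dtype_check = staticmethod(lambda v: None)

    def __init__(self, data: pd.DataFrame, feature_role: str | pd.Series = "gene"):
        if data.size == 0:
            # empty matrices are legal (e.g. a pipeline run without miRNAs)
            data = data.astype(float) if data.shape[1] else data
        _check_unique(data.index, "feature ids")
        _check_unique(data.columns, "sample ids")
        values = data.to_numpy()
        if values.size and not np.isfinite(values.astype(float)).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        self._dtype_check(values)
        self.data = data
        if isinstance(feature_role, str):
            if feature_role not in VALID_ROLES:
                raise ValueError(f"invalid feature role {feature_role!r}")
            self.feature_role = pd.Series(feature_role, index=data.index, dtype=object)
        else:
            role = feature_role.reindex(data.index)
            if role.isna().any():
                missing = role.index[role.isna()].tolist()
                raise ValueError(f"feature role missing for {missing[:5]}")
            bad = set(role.unique()) - set(VALID_ROLES)
            if bad:
                raise ValueError(f"invalid feature roles {sorted(bad)}")
            self.feature_role = role.astype(object)

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, ids) -> "ExpressionMatrix":
        ids = [i for i in self.data.index if i in set(ids)]
        return type(self)(self.data.loc[ids], self.feature_role.loc[ids])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path, feature_role: str | pd.Series = "gene") -> "ExpressionMatrix":
        return cls(read_matrix_tsv(path), feature_role)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        roles = self.feature_role.value_counts().to_dict()
        return f"<{type(self).__name__} {self.n_features}x{self.n_samples} roles={roles}>"


def _check_counts(values: np.ndarray) -> None:
    if values.size == 0:
        return
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("count matrix has negative entries")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("count matrix has non-integral entries")


class CountMatrix(ExpressionMatrix):
    """Raw read counts, features x samples; entries non-negative integers."""

    _dtype_check = staticmethod(_check_counts)


class GEBVMatrix:
    """Genomic estimated breeding values, samples x traits."""

    def __init__(self, data: pd.DataFrame):
        _check_unique(data.index, "sample ids")
        _check_unique(data.columns, "trait ids")
        values = data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("GEBV matrix contains missing/non-finite values")
        self.data = data.astype(float)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def trait_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_traits(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "GEBVMatrix":
        return cls(read_matrix_tsv(path))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<GEBVMatrix {self.n_samples} samples x {self.n_traits} traits>"


class AttributeTable:
    """Feature annotations used as network attribute layers.

    Rows carry (feature_id, kind, trait_id, direction) where kind is one of
    DEG / TF / cis_eqtl / trans_eqtl. trait_id and direction are meaningful
    for DEG rows (the trait the gene is differential for, and whether it is
    more expressed in the high or the low group); TF/eQTL rows leave them
    blank.
    """

    COLUMNS = ("feature_id", "kind", "trait_id", "direction")

    def __init__(self, data: pd.DataFrame | None = None):
        if data is None:
            data = pd.DataFrame(columns=list(self.COLUMNS))
        data = data.copy()
        for col in self.COLUMNS:
            if col not in data.columns:
                data[col] = ""
        data = data[list(self.COLUMNS)].fillna("")
        data["direction"] = data["direction"].replace("", "none")
        bad_kind = set(data["kind"].unique()) - set(VALID_ATTRIBUTE_KINDS)
        if bad_kind:
            raise ValueError(f"invalid attribute kinds {sorted(bad_kind)}")
        bad_dir = set(data["direction"].unique()) - set(VALID_DIRECTIONS)
        if bad_dir:
            raise ValueError(f"invalid directions {sorted(bad_dir)}")
        key = data[["feature_id", "kind", "trait_id"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].head(5).to_dict("records")
            raise ValueError(f"duplicate attribute rows: {dupes}")
        self.data = data.reset_index(drop=True)

    def rows_of_kind(self, kind: str) -> pd.DataFrame:
        return self.data[self.data["kind"] == kind]

    def deg_ids(self, trait_id: str) -> list:
        degs = self.rows_of_kind("DEG")
        return degs.loc[degs["trait_id"] == trait_id, "feature_id"].tolist()

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AttributeTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls(df)

    def __len__(self) -> int:
        return len(self.data)


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a TSV matrix with ids in the first column and a header row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
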