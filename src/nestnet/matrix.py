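"""Expression-matrix and sample-metadata containers.

The canonical in-memory layout is a pandas DataFrame with genes as rows and
samples as columns, wrapped in :class:`ExpressionMatrix` together with a
scale tag (``counts``, ``tpm`` or ``log2tpm``) so that downstream operations
can refuse inputs on the wrong scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

SCALE_TAGS = ("counts", "tpm", "log2tpm")

SEXES = ("M", "F")
TREATMENTS = ("E", "NM", "NP")

#: metadata columns every analysis expects
METADATA_COLUMNS = ("sample_id", "bird_id", "sex", "region", "treatment", "trial")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table with an explicit scale tag.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with sample ids as columns.
    scale:
        One of ``counts``, ``tpm`` (both nonnegative) or ``log2tpm``.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALE_TAGS:
            raise FormatError(f"unknown scale tag {self.scale!r}; expected one of {SCALE_TAGS}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated gene ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicated sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise FormatError(
                f"missing/non-numeric value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if self.scale in ("counts", "tpm") and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value on {self.scale} scale at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    # -- light accessors -------------------------------------------------
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

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.scale)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], self.scale)

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(data, scale or self.scale)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class Stratum:
    """A (region, sex) stratum and the sample ids that belong to it."""

    region: str
    sex: str
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def read_expression(path: str | Path, scale: str = "tpm") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Raises :class:`FormatError` with row/column context for duplicate ids,
    non-numeric cells, ragged rows or an empty file.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty expression file") from None
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise FormatError(f"{path}: malformed TSV: {exc}") from None
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: expression table has no data rows or columns")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value (ragged row?) at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), scale)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV.

    Required columns: sample_id, bird_id, sex, region, treatment, trial.
    Extra columns (behavior frequencies etc.) pass through untouched.
    """
    path = Path(path)
    try:
        meta = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty metadata file") from None
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata is missing required column(s): {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicated sample ids in metadata: {dups}")
    bad_sex = sorted(set(meta["sex"]) - set(SEXES))
    if bad_sex:
        raise FormatError(f"unknown sex label(s): {bad_sex}; expected {SEXES}")
    bad_trt = sorted(set(meta["treatment"]) - set(TREATMENTS))
    if bad_trt:
        raise FormatError(f"unknown treatment label(s): {bad_trt}; expected {TREATMENTS}")
    return meta.reset_index(drop=True)


def strata(meta: pd.DataFrame) -> list[Stratum]:
    """Split metadata into (region, sex) strata, the unit of every analysis."""
    out = []
    for (region, sex), grp in meta.groupby(["region", "sex"], sort=True):
        out.append(Stratum(region=region, sex=sex, sample_ids=grp["sample_id"].tolist()))
    return out


def align_samples(m: ExpressionMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Return metadata reordered to the matrix's sample order; error on mismatch."""
    missing = [s for s in m.sample_ids if s not in set(meta["sample_id"])]
    if missing:
        raise FormatError(f"samples present in matrix but absent from metadata: {missing[:5]}")
    return meta.set_index("sample_id").loc[m.sample_ids].reset_index()
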