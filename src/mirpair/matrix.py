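"""Expression matrix container and its TSV dialect.

A matrix is features x samples of log2 intensities, with per-sample
metadata (patient pairing, tumor/normal group) and optional per-cell
detection flags (semicolon-joined label strings, e.g.
``"IsGeneDetected;WellAboveNeg"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("tumor", "normal")


class MatrixError(ValueError):
    """Malformed expression matrix or metadata."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values with sample metadata.

    Parameters
    ----------
    values : DataFrame
        Features (rows) x samples (columns), numeric.
    metadata : DataFrame
        Indexed by sample id, with columns ``patient_id`` and ``group``
        (``tumor`` or ``normal``).
    flags : DataFrame, optional
        Same shape as ``values``; each cell a semicolon-joined string of
        detection-flag labels.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise MatrixError(f"duplicate feature id: {dup[0]!r}")
        dup = self.values.columns[self.values.columns.duplicated()]
        if len(dup):
            raise MatrixError(f"duplicate sample id: {dup[0]!r}")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise MatrixError(f"sample {missing[0]!r} has no metadata")
        for col in ("patient_id", "group"):
            if col not in self.metadata.columns:
                raise MatrixError(f"metadata lacks column {col!r}")
        bad = set(self.metadata.loc[list(self.values.columns), "group"]) - set(GROUPS)
        if bad:
            raise MatrixError(f"unknown group label {sorted(bad)[0]!r}")
        if self.flags is not None:
            if not self.flags.index.equals(self.values.index) or not self.flags.columns.equals(
                self.values.columns
            ):
                raise MatrixError("flags grid does not match value grid")

    # -- accessors ----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_samples(self, group: str) -> list[str]:
        meta = self.metadata.loc[list(self.values.columns)]
        return list(meta.index[meta["group"] == group])

    def complete_patients(self) -> list[str]:
        """Patients that contribute both a tumor and a normal sample."""
        meta = self.metadata.loc[list(self.values.columns)]
        counts = meta.groupby("patient_id")["group"].agg(lambda g: set(g))
        return sorted(p for p, gs in counts.items() if gs == set(GROUPS))

    def paired_diffs(self) -> pd.DataFrame:
        """Per-feature tumor - normal log2 differences, one column per patient.

        Raises
        ------
        MatrixError
            If no patient has a complete tumor/normal pair.
        """
        meta = self.metadata.loc[list(self.values.columns)]
        patients = self.complete_patients()
        if not patients:
            raise MatrixError("no complete tumor/normal patient pairs")
        cols = {}
        for p in patients:
            sub = meta[meta["patient_id"] == p]
            t = sub.index[sub["group"] == "tumor"][0]
            n = sub.index[sub["group"] == "normal"][0]
            cols[p] = self.values[t] - self.values[n]
        return pd.DataFrame(cols, index=self.values.index)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        keep = [f for f in self.values.index if f in set(feature_ids)]
        return ExpressionMatrix(
            values=self.values.loc[keep].copy(),
            metadata=self.metadata.copy(),
            flags=None if self.flags is None else self.flags.loc[keep].copy(),
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """New matrix sharing metadata/flags, different value grid."""
        flags = self.flags
        if flags is not None and not values.index.equals(flags.index):
            flags = None
        return ExpressionMatrix(values=values, metadata=self.metadata.copy(),
                                flags=None if flags is None else flags.copy())


# -- I/O ---------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "group"}
    if not required <= set(meta.columns):
        raise MatrixError(f"metadata file {path} lacks columns {sorted(required - set(meta.columns))}")
    return meta.set_index("sample_id")


def read_matrix(path, metadata_path, flags_path=None) -> ExpressionMatrix:
    """Read a TSV matrix (first column feature_id) plus metadata TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if values.isna().any().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise MatrixError(
            f"missing value at feature {values.index[r]!r}, sample {values.columns[c]!r}"
        )
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise MatrixError(f"non-numeric value in {path}: {exc}") from exc
    metadata = read_metadata(metadata_path)
    flags = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0, dtype=str).fillna("")
    return ExpressionMatrix(values=values, metadata=metadata, flags=flags)


def write_matrix(matrix: ExpressionMatrix, path, metadata_path=None, flags_path=None) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")
    if metadata_path is not None:
        meta = matrix.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")
    if flags_path is not None and matrix.flags is not None:
        fl = matrix.flags.copy()
        fl.index.name = "feature_id"
        fl.to_csv(flags_path, sep="\t")
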