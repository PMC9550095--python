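"""Dataset and result-table readers/writers.

CSV datasets follow the common tabular convention: header row, one sample
per row, the class label in the last column. ARFF files are read through
scipy. Non-numeric columns are label-encoded; missing values are
mean-imputed per column with a logged warning (the label column may not
be missing).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

from .errors import DataError, InvalidArgument, InvalidDataset
from .feature_selection import Dataset

__all__ = ["read_dataset", "write_results", "read_results", "write_dataset"]

log = logging.getLogger("coffo")

SCHEMA_COMMENT = "# coffo-results schema=1"


def _encode_column(col: pd.Series) -> pd.Series:
    """Numeric columns pass through; others are label-encoded (NaN kept)."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().sum() >= col.notna().sum():
        return numeric
    codes, _ = pd.factorize(col, use_na_sentinel=True)
    return pd.Series(codes, index=col.index, dtype=float).mask(codes == -1)


def _frame_to_dataset(frame: pd.DataFrame, source: str) -> Dataset:
    if frame.shape[1] < 2:
        raise DataError(f"{source}: need at least one feature column plus a label")
    if frame.shape[0] == 0:
        raise DataError(f"{source}: file contains no samples")
    features = frame.iloc[:, :-1].apply(_encode_column)
    labels = frame.iloc[:, -1]
    if labels.isna().any():
        raise DataError(f"{source}: label column contains missing values")
    if not pd.api.types.is_numeric_dtype(labels):
        labels, _ = pd.factorize(labels)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise InvalidDataset(f"{source}: label column has a single class")
    missing = features.isna().sum()
    if missing.any():
        log.warning("%s: mean-imputing %d missing values in columns %s", source,
                    int(missing.sum()), list(missing.index[missing > 0]))
        features = features.fillna(features.mean())
    return Dataset(features=features.to_numpy(dtype=float), labels=labels,
                   feature_names=[str(c) for c in features.columns])


def read_dataset(path, fmt: Optional[str] = None) -> Dataset:
    """Load a CSV or ARFF classification dataset (label = last column)."""
    path = Path(path)
    if fmt is None:
        fmt = "arff" if path.suffix.lower() == ".arff" else "csv"
    if fmt not in ("csv", "arff"):
        raise InvalidArgument(f"unknown dataset format {fmt!r}")
    if fmt == "csv":
        try:
            frame = pd.read_csv(path, comment="#")
        except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
            raise DataError(f"{path}: unparseable CSV ({exc})") from exc
    else:
        try:
            records, _meta = scipy_arff.loadarff(path)
        except Exception as exc:
            raise DataError(f"{path}: unparseable ARFF ({exc})") from exc
        frame = pd.DataFrame(records)
        for col in frame.columns:  # scipy returns nominal fields as bytes
            if frame[col].dtype == object:
                frame[col] = frame[col].str.decode("utf-8")
    return _frame_to_dataset(frame, str(path))


def write_dataset(data: Dataset, path) -> None:
    """Write a dataset as CSV (header, label in the last column)."""
    names = data.feature_names or [f"f{j}" for j in range(data.n_features)]
    frame = pd.DataFrame(data.features, columns=names)
    frame["label"] = data.labels
    frame.to_csv(path, index=False)


def write_results(rows, path, columns: Optional[list] = None) -> None:
    """Write result rows as CSV with a schema-version comment header.

    ``rows`` is a list of dicts (or a DataFrame); column order is the
    insertion order of the first row unless ``columns`` is given.
    """
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows, columns=columns)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        frame.to_csv(fh, index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")
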