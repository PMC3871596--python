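"""Data model and I/O for single-voxel MRS spectra on a ppm axis.

Spectra are stored as a ``d x n`` matrix (``d`` frequency points, ``n``
cases), following the orientation in which the factorization consumes the
data.  File readers accept either orientation.  The default axis is the 195
clinically relevant frequency points in the [4.24, 0.50] ppm window, listed
from high to low ppm as spectra are conventionally plotted.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_PPM_HIGH = 4.24
DEFAULT_PPM_LOW = 0.50
DEFAULT_N_POINTS = 195

__all__ = [
    "PpmAxis",
    "SpectrumDataset",
    "read_dataset",
    "write_dataset",
    "ul2_normalize",
    "class_mean_spectrum",
    "split_dataset",
]


@dataclass(frozen=True)
class PpmAxis:
    """Chemical-shift axis, strictly monotone, conventionally descending."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("ppm axis needs at least 2 points")
        diffs = np.diff(vals)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        object.__setattr__(self, "values", vals)

    @classmethod
    def default(cls) -> "PpmAxis":
        """The 195-point [4.24, 0.50] ppm window, descending."""
        return cls(np.linspace(DEFAULT_PPM_HIGH, DEFAULT_PPM_LOW, DEFAULT_N_POINTS))

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PpmAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values
        )


def ul2_normalize(x: np.ndarray) -> np.ndarray:
    """Scale a spectrum (or each column of a matrix) to unit Euclidean norm."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        nrm = np.linalg.norm(x)
        if nrm == 0 or not np.isfinite(nrm):
            raise ValueError("cannot UL2-normalize a zero or non-finite vector")
        return x / nrm
    nrm = np.linalg.norm(x, axis=0)
    if np.any(nrm == 0) or not np.all(np.isfinite(nrm)):
        raise ValueError("cannot UL2-normalize a zero or non-finite column")
    return x / nrm


@dataclass
class SpectrumDataset:
    """A set of spectra sharing one ppm axis.

    Parameters
    ----------
    X : ndarray of shape (d, n)
        Intensities, frequency points as rows and cases as columns.
    axis : PpmAxis
        Shared chemical-shift axis of length ``d``.
    labels : sequence of str or None
        Per-case class names; ``None`` for a fully unlabeled set.
    te_mode : {"STE", "LTE"}
        Echo-time acquisition mode tag.
    case_ids : sequence of str, optional
        Per-case identifiers; generated as ``case0001`` ... when absent.
    """

    X: np.ndarray
    axis: PpmAxis
    labels: np.ndarray | None = None
    te_mode: str = "STE"
    case_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix (frequencies x cases)")
        if self.X.shape[0] != len(self.axis):
            raise ValueError(
                f"X has {self.X.shape[0]} rows but the axis has {len(self.axis)} points"
            )
        if self.te_mode not in ("STE", "LTE"):
            raise ValueError("te_mode must be 'STE' or 'LTE'")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.size != self.X.shape[1]:
                raise ValueError("label count must equal case count")
        if self.case_ids is None:
            self.case_ids = np.array(
                [f"case{i + 1:04d}" for i in range(self.X.shape[1])], dtype=object
            )
        else:
            self.case_ids = np.asarray(self.case_ids, dtype=object)
            if self.case_ids.size != self.X.shape[1]:
                raise ValueError("case_id count must equal case count")

    @property
    def n_cases(self) -> int:
        return self.X.shape[1]

    @property
    def n_points(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> list[str]:
        """Sorted set of class names (empty list when unlabeled)."""
        if self.labels is None:
            return []
        return sorted(set(self.labels))

    def class_counts(self) -> dict[str, int]:
        if self.labels is None:
            return {}
        vals, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def normalized(self) -> "SpectrumDataset":
        """Return a copy with every case UL2-normalized."""
        return SpectrumDataset(
            ul2_normalize(self.X),
            self.axis,
            None if self.labels is None else self.labels.copy(),
            self.te_mode,
            self.case_ids.copy(),
        )

    def subset(self, idx: Sequence[int] | np.ndarray) -> "SpectrumDataset":
        idx = np.asarray(idx, dtype=int)
        return SpectrumDataset(
            self.X[:, idx],
            self.axis,
            None if self.labels is None else self.labels[idx],
            self.te_mode,
            self.case_ids[idx],
        )

    def with_labels(self, labels: Iterable[str]) -> "SpectrumDataset":
        return SpectrumDataset(
            self.X.copy(), self.axis, np.asarray(list(labels), dtype=object),
            self.te_mode, self.case_ids.copy(),
        )


def read_dataset(
    path: str | Path | io.IOBase,
    orientation: str = "cases-rows",
    te_mode: str = "STE",
    sep: str | None = None,
) -> SpectrumDataset:
    """Read a delimited table of spectra into a :class:`SpectrumDataset`.

    The table's header row carries the ppm values of the axis.  With the
    default ``cases-rows`` orientation each data row is one case (the common
    spreadsheet export); with ``cases-cols`` each column is one case.  An
    optional ``label`` column (or row) attaches class names, and a
    ``case_id`` column names the cases.

    Raises
    ------
    ValueError
        On ragged rows or non-numeric intensity cells (the offending
        location is reported).
    """
    if orientation not in ("cases-rows", "cases-cols"):
        raise ValueError("orientation must be 'cases-rows' or 'cases-cols'")
    if sep is None:
        sep = "\t"
    try:
        with warnings.catch_warnings():
            # over-long rows only warn under index_col=False; treat as errors
            warnings.simplefilter("error", pd.errors.ParserWarning)
            df = pd.read_csv(path, sep=sep, header=0, dtype=str, index_col=False)
    except (pd.errors.ParserError, pd.errors.ParserWarning) as exc:
        raise ValueError(f"malformed table: {exc}") from None
    if df.isna().any().any():
        bad = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0])
        raise ValueError(f"ragged or incomplete row at line {bad + 2}")

    if orientation == "cases-cols":
        # first column holds ppm values / the 'label' marker row
        df = df.set_index(df.columns[0]).T.reset_index()
        df = df.rename(columns={"index": "case_id"})

    labels = None
    case_ids = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=object)
    if "case_id" in df.columns:
        case_ids = df.pop("case_id").to_numpy(dtype=object)

    try:
        ppm = np.array([float(c) for c in df.columns])
    except ValueError:
        raise ValueError(
            "header must contain numeric ppm values (plus optional "
            "'label'/'case_id' columns)"
        ) from None

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col].to_numpy()):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric intensity at row {i + 2}, column {j + 1}: {cell!r}"
                ) from None

    return SpectrumDataset(values.T, PpmAxis(ppm), labels, te_mode, case_ids)


def write_dataset(
    dataset: SpectrumDataset,
    path: str | Path | io.IOBase,
    orientation: str = "cases-rows",
    sep: str = "\t",
) -> None:
    """Write a dataset back to a delimited table (inverse of ``read_dataset``)."""
    cols = [f"{v:.6f}" for v in dataset.axis.values]
    df = pd.DataFrame(dataset.X.T, columns=cols)
    df.insert(0, "case_id", dataset.case_ids)
    if dataset.labels is not None:
        df.insert(1, "label", dataset.labels)
    if orientation == "cases-cols":
        df = df.set_index("case_id").T.reset_index(names=[""])
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def class_mean_spectrum(dataset: SpectrumDataset, class_name: str) -> np.ndarray:
    """Arithmetic mean spectrum over all cases of one class."""
    if dataset.labels is None:
        raise ValueError("dataset is unlabeled")
    mask = dataset.labels.astype(str) == str(class_name)
    if not mask.any():
        raise KeyError(f"class {class_name!r} not present in dataset")
    return dataset.X[:, mask].mean(axis=1)


def split_dataset(
    dataset: SpectrumDataset,
    fraction: float = 2.0 / 3.0,
    seed: int | None = None,
) -> tuple[SpectrumDataset, SpectrumDataset]:
    """Stratified random split into (train, holdout).

    Per class, ``round(fraction * class size)`` cases go to train and the
    remainder to holdout; the split is disjoint, exhaustive, and
    reproducible under ``seed``.  A class with fewer than 2 members cannot
    be stratified and is kept entirely in train (with a warning).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if dataset.n_cases < 3:
        raise ValueError("need at least 3 cases to split")
    if dataset.labels is None:
        raise ValueError("stratified split requires labels")
    rng = np.random.default_rng(seed)
    labels = dataset.labels.astype(str)
    train_idx: list[int] = []
    hold_idx: list[int] = []
    for cls in sorted(set(labels)):
        members = np.flatnonzero(labels == cls)
        if members.size < 2:
            warnings.warn(
                f"class {cls!r} has fewer than 2 members; kept entirely in train",
                stacklevel=2,
            )
            train_idx.extend(members.tolist())
            continue
        perm = rng.permutation(members)
        n_train = int(round(fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(perm[:n_train].tolist())
        hold_idx.extend(perm[n_train:].tolist())
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(hold_idx))
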