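"""Rectangular dataset container with an explicit missingness mask.

A :class:`Dataset` holds an ``N x K`` value matrix, a boolean mask
(``True`` = observed), and a per-column type tag (``"binary"`` or
``"continuous"``). Masked cells are stored as ``NaN`` in the exposed
``values`` array so that no imputation routine can accidentally consult
the deleted truth; when a mask is applied to previously complete data the
original values are retained privately and are reachable only through
:meth:`Dataset.hidden_truth`, which exists for validation and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset", "read_csv", "write_csv"]

#: token written to CSV for an unobserved cell
NA_TOKEN = "NA"

_COLUMN_TYPES = ("binary", "continuous")


@dataclass
class Dataset:
    """Values, mask and typing for one rectangular dataset.

    Parameters
    ----------
    values
        ``N x K`` float matrix. Cells where ``mask`` is ``False`` must be
        ``NaN`` (the constructor enforces this).
    mask
        ``N x K`` boolean, ``True`` where the cell is observed.
    column_types
        Tag per column, each ``"binary"`` or ``"continuous"``. Binary
        columns are coded 0/1 where observed.
    column_names
        Identifier per column.
    """

    values: np.ndarray
    mask: np.ndarray
    column_types: tuple[str, ...]
    column_names: tuple[str, ...]
    _hidden: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=float)
        self.mask = np.array(self.mask, dtype=bool)
        self.column_types = tuple(self.column_types)
        self.column_names = tuple(self.column_names)
        n, k = self.values.shape
        if n < 1 or k < 2:
            raise ValueError(f"need N >= 1 and K >= 2, got shape {(n, k)}")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if len(self.column_types) != k or len(self.column_names) != k:
            raise ValueError("column metadata length must equal K")
        for t in self.column_types:
            if t not in _COLUMN_TYPES:
                raise ValueError(f"unknown column type {t!r}")
        # enforce the access barrier: unobserved cells carry no information
        self.values = self.values.copy()
        self.values[~self.mask] = np.nan
        if np.isnan(self.values[self.mask]).any():
            raise ValueError("observed cells must not be NaN")
        for j, t in enumerate(self.column_types):
            if t == "binary":
                obs = self.values[self.mask[:, j], j]
                if not np.isin(obs, (0.0, 1.0)).all():
                    raise ValueError(
                        f"binary column {self.column_names[j]!r} has values outside {{0,1}}"
                    )

    # ------------------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def column_index(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise KeyError(f"no column named {name!r}") from None

    @property
    def complete_rows(self) -> np.ndarray:
        """Boolean selector of rows with every cell observed."""
        return self.mask.all(axis=1)

    @property
    def incomplete_columns(self) -> tuple[str, ...]:
        """Names of columns with at least one unobserved cell."""
        return tuple(
            name
            for j, name in enumerate(self.column_names)
            if not self.mask[:, j].all()
        )

    def is_complete(self) -> bool:
        return bool(self.mask.all())

    # ------------------------------------------------------------------
    def completed(self, filled_values: np.ndarray) -> "Dataset":
        """Return a fully observed copy with missing cells replaced.

        ``filled_values`` must agree with the observed cells; only masked
        cells are taken from it.
        """
        filled = np.asarray(filled_values, dtype=float)
        if filled.shape != self.values.shape:
            raise ValueError("filled_values shape must match")
        out = self.values.copy()
        out[~self.mask] = filled[~self.mask]
        if np.isnan(out).any():
            raise ValueError("completion left NaN cells")
        return Dataset(
            out,
            np.ones_like(self.mask),
            self.column_types,
            self.column_names,
        )

    def hidden_truth(self) -> np.ndarray:
        """Pre-masking values (validation/testing only; never used by samplers)."""
        if self._hidden is None:
            raise ValueError("this dataset was not produced by masking complete data")
        return self._hidden.copy()

    def copy(self) -> "Dataset":
        return Dataset(
            self.values.copy(),
            self.mask.copy(),
            self.column_types,
            self.column_names,
            _hidden=None if self._hidden is None else self._hidden.copy(),
        )

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.column_names))


def write_csv(data: Dataset, path) -> None:
    """Write one row per subject, header of column names, ``NA`` for missing."""
    data.to_frame().to_csv(path, index=False, na_rep=NA_TOKEN)


def read_csv(path, binary_columns: tuple[str, ...] | None = None) -> Dataset:
    """Read a dataset written by :func:`write_csv`.

    Missing cells may be the literal token ``NA`` or an empty field. Columns
    listed in ``binary_columns`` are tagged binary; if omitted, a column is
    tagged binary when all its observed values lie in ``{0, 1}``.
    """
    frame = pd.read_csv(path, na_values=[NA_TOKEN, ""], keep_default_na=False)
    values = frame.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    names = tuple(str(c) for c in frame.columns)
    if binary_columns is None:
        types = tuple(
            "binary"
            if mask[:, j].any() and np.isin(values[mask[:, j], j], (0.0, 1.0)).all()
            else "continuous"
            for j in range(values.shape[1])
        )
    else:
        types = tuple(
            "binary" if name in binary_columns else "continuous" for name in names
        )
    return Dataset(values, mask, types, names)
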