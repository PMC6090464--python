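"""Plain-text I/O for connectivity matrices and sweep-result tables.

Connectivity matrices are dense square numeric text files (whitespace- or
comma-delimited, optionally with a single header row of region labels), one
subject per file — the distribution format of public functional-connectome
repositories.  Entries are correlation coefficients in [-1, 1] with a zero
diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: tolerance absorbing text round-off in range/symmetry checks
VALIDATION_TOL = 1e-9


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's weighted brain network.

    Attributes
    ----------
    subject_id:
        Free-form label, usually derived from the file name.
    weights:
        Symmetric ``(N, N)`` array of signed correlation weights
        ``w_ij`` in ``[-1, 1]`` with an exactly-zero diagonal.
    """

    subject_id: str
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] < 2:
            raise ValidationError("a connectivity matrix needs at least 2 regions")
        if not np.isfinite(w).all():
            raise ValidationError("weights contain non-finite entries")
        if np.abs(w).max() > 1.0 + VALIDATION_TOL:
            bad = float(np.abs(w).max())
            raise ValidationError(f"|w| entries must be <= 1, max is {bad}")
        asym = float(np.abs(w - w.T).max())
        if asym > VALIDATION_TOL:
            raise ValidationError(f"matrix asymmetry {asym} exceeds tolerance {VALIDATION_TOL}")
        if np.any(np.diag(w) != 0.0):
            # self-correlation carries no information here; tools disagree on storing 1.0
            logger.warning(
                "subject %s: nonzero diagonal zeroed (max |diag| = %g)",
                self.subject_id,
                float(np.abs(np.diag(w)).max()),
            )
            w = w.copy()
            np.fill_diagonal(w, 0.0)
        # exact symmetrization + clip of sub-tolerance excursions so invariants hold exactly
        w = (w + w.T) / 2.0
        np.clip(w, -1.0, 1.0, out=w)
        object.__setattr__(self, "weights", w)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def offdiag_abs(self) -> np.ndarray:
        """Upper-triangle off-diagonal ``|w_ij|`` values (each pair once)."""
        iu = np.triu_indices(self.n_regions, k=1)
        return np.abs(self.weights[iu])


def _detect_delimiter(first_line: str, hint: str | None) -> str | None:
    """Return the numpy delimiter (None = any whitespace)."""
    if hint is not None:
        return None if hint in ("whitespace", "space", "\t", " ") else hint
    return "," if "," in first_line else None


def _looks_numeric(line: str, delimiter: str | None) -> bool:
    tokens = line.split(delimiter) if delimiter else line.split()
    if not tokens:
        return False
    try:
        [float(t) for t in tokens if t != ""]
    except ValueError:
        return False
    return True


def read_connectivity_matrix(
    path: str | Path, delimiter_hint: str | None = None
) -> ConnectivityMatrix:
    """Read and validate a dense square connectivity matrix from text.

    The delimiter (comma vs whitespace) is auto-detected from the first
    line unless ``delimiter_hint`` is given; a non-numeric first line is
    treated as a header of region labels and skipped.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = _detect_delimiter(first, delimiter_hint)
    skiprows = 0 if _looks_numeric(first, delimiter) else 1
    try:
        w = np.loadtxt(path, delimiter=delimiter, skiprows=skiprows, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse as a numeric matrix: {exc}") from exc
    if w.shape[0] != w.shape[1]:
        raise FormatError(
            f"{path}: matrix is not square ({w.shape[0]} rows x {w.shape[1]} columns)"
        )
    return ConnectivityMatrix(subject_id=path.stem, weights=w)


def write_connectivity_matrix(matrix: ConnectivityMatrix, path: str | Path) -> Path:
    """Write a matrix as whitespace-delimited text at full double precision."""
    path = Path(path)
    np.savetxt(path, matrix.weights, fmt="%.17g")
    return path


#: fixed column order of sweep tables; ks_* columns appended per fitted model
SWEEP_COLUMNS = [
    "subject_id",
    "n",
    "w_t",
    "p",
    "m",
    "lcc_fraction",
    "clustering",
    "delta_clustering",
]


def write_sweep_table(
    rows: Iterable[Mapping[str, object]] | pd.DataFrame, path: str | Path
) -> Path:
    """Serialize sweep records as CSV with a fixed, documented header.

    Required fields are ``SWEEP_COLUMNS``; any ``ks_<model>`` fields are
    appended after them in sorted order.  Column order is stable across
    runs so repeated sweeps with the same seed are byte-identical.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        records = list(rows)
        if records:
            keys = set(records[0].keys())
            for r in records[1:]:
                if set(r.keys()) != keys:
                    raise SchemaError(
                        f"heterogeneous record fields: {sorted(keys)} vs {sorted(r.keys())}"
                    )
        df = pd.DataFrame.from_records(records)
    for col in SWEEP_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    extra = sorted(c for c in df.columns if c not in SWEEP_COLUMNS)
    df = df[SWEEP_COLUMNS + extra]
    df.to_csv(path, index=False, float_format="%.17g")
    return path
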