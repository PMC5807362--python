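"""Experiment container and CSV serialisation.

File dialect: a counts CSV with header columns
``experiment_id, z_log10M, n0, count`` (one row per well; replicate wells
repeat the dose) and a background CSV with a single ``noise`` column holding
the compound-free measurements used to identify the assay noise mean/variance.
Concentrations are exchanged as log10 molar throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Experiment", "read_experiment", "write_experiment"]

COUNTS_COLUMNS = ["experiment_id", "z_log10M", "n0", "count"]
BACKGROUND_COLUMN = "noise"


@dataclass
class Experiment:
    """One compound x cell-line chemo-sensitivity dataset.

    ``z`` (log10 M), ``n0`` (known initial counts) and ``x`` (measured
    follow-up counts) are aligned per-well arrays; ``background`` holds the
    q compound-free noise measurements.
    """

    experiment_id: str
    z: np.ndarray
    n0: np.ndarray
    x: np.ndarray
    background: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.n0 = np.asarray(self.n0, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not (self.z.shape == self.n0.shape == self.x.shape):
            raise ValueError("z, n0 and x must be aligned per-well arrays")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("doses must be finite log10 M values")
        if np.any(self.n0 <= 0):
            raise ValueError("all initial counts n0 must be positive")
        if self.n_doses < 2:
            raise ValueError("an experiment needs at least 2 distinct doses")
        if self.background.size < 2:
            raise ValueError(
                "at least 2 background measurements are required to identify "
                "the noise mean theta and variance sigma2"
            )

    @property
    def doses(self) -> np.ndarray:
        """Sorted distinct doses (log10 M)."""
        return np.unique(self.z)

    @property
    def n_doses(self) -> int:
        return len(np.unique(self.z))

    @property
    def n_wells(self) -> int:
        return self.z.size

    def dose_index(self) -> np.ndarray:
        """Index of each well's dose into :meth:`doses`."""
        return np.searchsorted(self.doses, self.z)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna()]
    if len(bad):
        # +2: header line and 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise ValueError(
            f"{path}: non-numeric or missing value in column '{col}' at line(s) {lines}"
        )
    return vals.to_numpy(dtype=float)


def read_experiment(counts_path, background_path, experiment_id: str | None = None) -> Experiment:
    """Read and validate one experiment from a counts CSV and a background CSV.

    If the counts file holds several experiment_ids, ``experiment_id``
    selects one; otherwise the single id present is used.
    """
    counts_path, background_path = Path(counts_path), Path(background_path)
    df = pd.read_csv(counts_path, float_precision="round_trip")
    _require_columns(df, COUNTS_COLUMNS, counts_path)
    if experiment_id is not None:
        df = df[df["experiment_id"].astype(str) == str(experiment_id)]
        if df.empty:
            raise ValueError(f"{counts_path}: no rows for experiment_id {experiment_id!r}")
    ids = df["experiment_id"].astype(str).unique()
    if len(ids) != 1:
        raise ValueError(
            f"{counts_path}: expected one experiment_id, found {list(ids)}; "
            "pass experiment_id= to select one"
        )
    z = _numeric(df, "z_log10M", counts_path)
    n0 = _numeric(df, "n0", counts_path)
    x = _numeric(df, "count", counts_path)
    bg_df = pd.read_csv(background_path, float_precision="round_trip")
    _require_columns(bg_df, [BACKGROUND_COLUMN], background_path)
    e = _numeric(bg_df, BACKGROUND_COLUMN, background_path)
    if e.size < 2:
        raise ValueError(
            f"{background_path}: need >= 2 background rows to identify "
            "theta and sigma2"
        )
    return Experiment(ids[0], z, n0, x, e)


def write_experiment(exp: Experiment, counts_path, background_path) -> None:
    """Write an experiment back to the CSV dialect (full-precision floats)."""
    df = pd.DataFrame(
        {
            "experiment_id": exp.experiment_id,
            "z_log10M": exp.z,
            "n0": exp.n0,
            "count": exp.x,
        }
    )
    df.to_csv(counts_path, index=False, float_format="%.17g")
    pd.DataFrame({BACKGROUND_COLUMN: exp.background}).to_csv(
        background_path, index=False, float_format="%.17g"
    )
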