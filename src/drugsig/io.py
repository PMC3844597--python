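"""Expression matrix I/O and the normalization chain.

The preprocessing pipeline applied to raw intensity data is:
quantile normalization across arrays, log2 transform, then per-batch
z-score standardization of each probe to remove hybridization-batch
shifts and scale distortions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ["drug", "time_h", "replicate", "batch", "is_vehicle"]


@dataclass
class ExpressionMatrix:
    """Probes × samples expression values plus the per-sample design sheet.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample id, float
        log2 intensities (or raw intensities before :func:`log2_transform`).
    samples
        DataFrame indexed by sample id with columns ``drug``, ``time_h``,
        ``replicate``, ``batch`` and ``is_vehicle``, one row per column
        of ``values``, in the same order.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate probe ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups[:5])}")
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        unmatched = self.values.columns.difference(self.samples.index)
        if len(unmatched):
            raise ValueError(
                f"samples without a sample-sheet row: {list(unmatched[:5])}"
            )
        self.samples = self.samples.loc[self.values.columns]
        if self.values.isna().any().any():
            bad = np.argwhere(self.values.isna().to_numpy())[0]
            raise ValueError(
                "missing value at probe "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        if (pd.to_numeric(self.samples["time_h"]) <= 0).any():
            raise ValueError("time_h must be positive")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, samples=self.samples.copy())


def load_expression(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    """Read a probes × samples TSV and its sample sheet into a typed matrix.

    Probe and sample order is preserved from the files.  Every matrix
    column must have a sample-sheet row; unparseable numeric cells are
    reported with their probe/sample coordinates.
    """
    matrix_path, sample_sheet_path = Path(matrix_path), Path(sample_sheet_path)
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    try:
        values = raw.astype(float)
    except ValueError:
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy() & raw.notna().to_numpy())
        if len(bad):
            i, j = bad[0]
            raise ValueError(
                f"unparseable value {raw.iat[i, j]!r} at probe {raw.index[i]!r},"
                f" sample {raw.columns[j]!r} in {matrix_path}"
            ) from None
        values = numeric
    sheet = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
    if "is_vehicle" in sheet.columns:
        sheet["is_vehicle"] = sheet["is_vehicle"].astype(bool)
    return ExpressionMatrix(values=values, samples=sheet)


def write_expression(em: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    """Write the matrix and sample sheet as UTF-8 tab-delimited files."""
    vals = em.values.copy()
    vals.index.name = "probe_id"
    vals.to_csv(matrix_path, sep="\t", encoding="utf-8")
    sheet = em.samples.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(sample_sheet_path, sep="\t", encoding="utf-8")


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common row-rank-mean distribution.

    The reference distribution is the mean across samples of the
    column-sorted values; ties within a column receive the average of
    the reference values at the tied ranks.  Idempotent.
    """
    if values.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input")
        return values.copy()
    x = values.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    # average ranks (1-based, fractional at ties); interpolate the reference
    from scipy.stats import rankdata

    out = np.empty_like(x)
    grid = np.arange(1, x.shape[0] + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log2_transform(values: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """log2 of linear-scale intensities, flooring values at ``floor`` first."""
    return np.log2(values.clip(lower=floor))


def standardize_batches(values: pd.DataFrame, batch_labels: pd.Series) -> pd.DataFrame:
    """Per-probe z-score within each hybridization batch.

    Uses the population (divide by n) standard deviation.  Probes that
    are constant within a batch are mapped to 0 with a warning.  Any
    per-batch affine distortion ``a*x + b`` (a > 0) is removed exactly.
    """
    batch_labels = pd.Series(batch_labels)
    unmatched = values.columns.difference(batch_labels.index)
    if len(unmatched):
        raise ValueError(f"samples without batch label: {list(unmatched[:5])}")
    out = values.copy().astype(float)
    n_constant = 0
    for batch, cols in values.columns.to_series().groupby(batch_labels.loc[values.columns].to_numpy()):
        if len(cols) < 2:
            raise ValueError(f"batch {batch!r} has a single sample; cannot z-score")
        block = values[cols.to_numpy()].to_numpy(dtype=float)
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=0, keepdims=True)
        zero = sd[:, 0] == 0
        n_constant += int(zero.sum())
        sd[zero] = 1.0
        z = (block - mu) / sd
        z[zero, :] = 0.0
        out[cols.to_numpy()] = z
    if n_constant:
        warnings.warn(
            f"{n_constant} probe/batch blocks were constant; z-scores set to 0"
        )
    return out


def normalize(
    em: ExpressionMatrix,
    quantile: bool = True,
    log2: bool = False,
    batch_standardize: bool = True,
    background_hook=None,
) -> ExpressionMatrix:
    """Run the full normalization chain in the canonical order.

    ``background_hook`` is a pass-through slot for a background
    subtraction callable (raw bead-level background handling is out of
    scope for this package; synthetic data has none).
    """
    vals = em.values
    if background_hook is not None:
        vals = background_hook(vals)
    if quantile:
        vals = quantile_normalize(vals)
    if log2:
        vals = log2_transform(vals)
    if batch_standardize:
        vals = standardize_batches(vals, em.samples["batch"])
    return em.copy_with(vals)
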