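"""Expression-matrix container, preprocessing, and TSV input/output.

The universal input of the pipeline is a genes x samples matrix of log2
intensities together with a sample sheet assigning each sample a lighting
condition (LD: light/dark cycle, DD: constant dark, LL: constant light) and a
circadian time (CT, hours after lights-on). Within a condition, samples are
kept sorted by CT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CONDITIONS = ("LD", "DD", "LL")

SAMPLE_SHEET_COLUMNS = ("sample_id", "condition", "ct")


@dataclass
class TimeSeriesMatrix:
    """Genes x samples log2 expression with per-sample condition and CT.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id, log2 scale.
    samples : pandas.DataFrame
        Indexed by sample id with columns ``condition`` and ``ct``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing[:5]}")
        self.samples = self.samples.loc[list(self.values.columns)]
        ct = pd.to_numeric(self.samples["ct"], errors="coerce")
        if not np.isfinite(ct.to_numpy(dtype=float)).all():
            raise ValueError("every sample needs a finite circadian time")
        bad = set(self.samples["condition"]) - set(VALID_CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        # canonical order: condition blocks, CT ascending inside each block
        order = self.samples.sort_values(["condition", "ct"], kind="stable").index
        order = [s for s in order if s in self.values.columns]
        self.values = self.values[order]
        self.samples = self.samples.loc[order]
        for cond, grp in self.samples.groupby("condition"):
            if grp["ct"].duplicated().any():
                raise ValueError(f"duplicate CT within condition {cond}")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def condition(self, cond: str) -> "TimeSeriesMatrix":
        """Sub-matrix restricted to one lighting condition (CT-sorted)."""
        keep = self.samples.index[self.samples["condition"] == cond]
        if len(keep) == 0:
            raise KeyError(f"no samples in condition {cond!r}")
        return TimeSeriesMatrix(self.values[keep], self.samples.loc[keep])

    def timepoints(self, cond: str | None = None) -> np.ndarray:
        sheet = self.samples if cond is None else self.samples[self.samples["condition"] == cond]
        return sheet["ct"].to_numpy(dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        conds = ",".join(sorted(set(self.samples["condition"])))
        return f"TimeSeriesMatrix({self.values.shape[0]} genes x {self.values.shape[1]} samples; {conds})"


# -- preprocessing -------------------------------------------------------------


def quantile_normalize(matrix: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Force every sample (column) onto the common rank-mean distribution.

    The reference distribution is the across-column mean of the column-sorted
    values; each value is replaced by the reference value at its within-column
    rank. Ties within a column receive the mean of the tied ranks' reference
    values, so the transform is idempotent.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = vals.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if np.isnan(vals).any():
        raise ValueError("missing values not supported")
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_samples):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # average reference values across tied runs of the sorted column
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [n_genes]))
        for s, e in zip(starts, stops):
            if e - s > 1:
                assigned[order[s:e]] = reference[s:e].mean()
        out[:, j] = assigned
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return TimeSeriesMatrix(values, matrix.samples.copy())


def filter_detected(
    matrix: TimeSeriesMatrix,
    detect_flags: pd.DataFrame | None,
    min_fraction: float = 0.75,
) -> TimeSeriesMatrix:
    """Keep genes flagged as detected in at least ``min_fraction`` of samples.

    ``detect_flags`` is a boolean frame aligned with the matrix; ``None`` means
    no detection calls are available and every gene is kept (the synthetic data
    carry no detection calls). The boundary is inclusive: detected in exactly
    75% of samples passes the default threshold.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if detect_flags is None:
        return matrix
    flags = detect_flags.reindex(index=matrix.values.index, columns=matrix.values.columns)
    if flags.isna().any().any():
        raise ValueError("detect_flags must cover every gene and sample of the matrix")
    frac = flags.astype(bool).mean(axis=1)
    keep = frac[frac >= min_fraction].index
    return TimeSeriesMatrix(matrix.values.loc[keep], matrix.samples.copy())


def zscore_per_gene(matrix: TimeSeriesMatrix) -> tuple[TimeSeriesMatrix, pd.Series]:
    """Standardize each gene row to mean 0, sd 1 (population sd).

    Constant rows cannot be standardized; they come back as all-zero and are
    flagged in the returned boolean series rather than raising.
    """
    vals = matrix.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    degenerate = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (vals - mean) / safe_sd
    out[degenerate, :] = 0.0
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    flags = pd.Series(degenerate, index=matrix.values.index, name="degenerate")
    return TimeSeriesMatrix(values, matrix.samples.copy()), flags


# -- TSV input/output ----------------------------------------------------------


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes-in-rows TSV matrix (gzip-transparent, '.' decimal)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    sheet["ct"] = pd.to_numeric(sheet["ct"])
    return sheet.set_index("sample_id")


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.reset_index(names="sample_id").to_csv(path, sep="\t", index=False)


def load_timeseries(matrix_path, sample_sheet_path) -> TimeSeriesMatrix:
    """Load an expression TSV plus its sample sheet into a TimeSeriesMatrix."""
    return TimeSeriesMatrix(read_expression_tsv(matrix_path), read_sample_sheet(sample_sheet_path))


def save_timeseries(matrix: TimeSeriesMatrix, matrix_path, sample_sheet_path) -> None:
    write_expression_tsv(matrix.values, matrix_path)
    write_sample_sheet(matrix.samples, sample_sheet_path)
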