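"""Count matrices, sample metadata, normalization and QC.

Fragment counts per element x sample are normalized by median-of-ratios
size factors and variance-stabilized as ``log2(count / factor +
pseudocount)`` — a simple monotone transform that serves the same role
as a model-based VST for clustering and PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from regland.errors import ParameterError, ValidationError

SAMPLE_FACTORS = ["cell_type", "sag_nM", "day", "replicate"]


class SampleTable:
    """Sample metadata: cell type, SAG dose (nM), day, replicate."""

    def __init__(self, df: pd.DataFrame) -> None:
        df = df.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        missing = [c for c in SAMPLE_FACTORS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing column(s) {missing}")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample_id in sample table")
        df["sag_nM"] = df["sag_nM"].astype(int)
        df["day"] = df["day"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        self.df = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    def condition_of(self) -> pd.Series:
        """Condition label ``cell_type.dN.sagnM`` per sample."""
        d = self.df
        return pd.Series(
            [f"{c}.d{day}.sag{s}" for c, day, s in
             zip(d["cell_type"], d["day"], d["sag_nM"])],
            index=d.index, name="condition",
        )

    def __len__(self) -> int:
        return len(self.df)


class CountMatrix:
    """Integer fragment counts per element x sample."""

    def __init__(self, values: pd.DataFrame,
                 library_total: pd.Series | None = None) -> None:
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            values = values.round().astype(np.int64)
        if (values.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if values.index.duplicated().any():
            raise ValidationError("duplicate element ids in count matrix")
        if values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in count matrix")
        self.values = values
        if library_total is not None:
            library_total = library_total.reindex(values.columns)
            if library_total.isna().any():
                raise ValidationError("library_total missing for some samples")
        self.library_total = library_total

    @property
    def element_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.values.equals(other.values)


@dataclass
class NormalizedMatrix:
    """Normalized (optionally variance-stabilized) element x sample matrix."""

    values: pd.DataFrame
    size_factors: pd.Series
    transform: str = "none"

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValidationError("size factors must be positive")


def read_counts(path: str | Path, library_total_row: str = "__library_total__",
                ) -> CountMatrix:
    """Read a TSV count table (first column element id, then samples).

    Leading ``chrom``/``start``/``end`` annotation columns are dropped if
    present. A row named `library_total_row` is split off as per-sample
    library totals.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("chrom", "start", "end"):
        if col in df.columns:
            df = df.drop(columns=col)
    library_total = None
    if library_total_row in df.index:
        library_total = df.loc[library_total_row].astype(np.int64)
        df = df.drop(index=library_total_row)
    bad = df.columns[~df.apply(lambda c: np.allclose(c, np.round(c)))]
    if len(bad):
        raise ValidationError(f"non-integer counts in column(s) {list(bad)}")
    return CountMatrix(df.round().astype(np.int64), library_total=library_total)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    out = counts.values.copy()
    if counts.library_total is not None:
        out.loc["__library_total__"] = counts.library_total
    out.to_csv(path, sep="\t", index_label="element_id")


def read_samples(path: str | Path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t"))


def write_samples(samples: SampleTable, path: str | Path) -> None:
    samples.df.to_csv(path, sep="\t", index_label="sample_id")


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The per-element reference is the geometric mean across samples,
    computed over elements with all counts > 0 only; factor_j is the
    median over those elements of count_ij / reference_i.
    """
    x = counts.values.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no element with nonzero counts in every sample; consider a "
            "pseudo-reference fallback"
        )
    logx = np.log(x[all_pos])
    ref = logx.mean(axis=1)
    factors = np.exp(np.median(logx - ref[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def vst(counts: CountMatrix, factors: pd.Series,
        pseudocount: float = 1.0) -> NormalizedMatrix:
    """log2(count / size_factor + pseudocount) variance-stabilization."""
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be > 0")
    factors = factors.reindex(counts.sample_ids)
    norm = counts.values.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    vals = pd.DataFrame(np.log2(norm + pseudocount),
                        index=counts.element_ids, columns=counts.sample_ids)
    return NormalizedMatrix(vals, size_factors=factors, transform="vst")


def normalized_counts(counts: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Counts divided by per-sample size factors (no log transform)."""
    factors = factors.reindex(counts.sample_ids)
    return counts.values / factors


def frip(counts: CountMatrix) -> pd.Series:
    """Fraction of reads in peaks (column sum / library total) per sample."""
    if counts.library_total is None:
        raise ValidationError("frip requires library_total")
    colsum = counts.values.sum(axis=0)
    total = counts.library_total
    if (total == 0).any():
        zero = total.index[total == 0][0]
        raise ValidationError(f"sample {zero!r} has zero library total")
    if (colsum > total).any():
        over = colsum.index[colsum > total][0]
        raise ValidationError(
            f"sample {over!r}: in-peak count exceeds library total"
        )
    return (colsum / total).rename("frip")


def sample_correlation(norm: NormalizedMatrix,
                       element_mask: pd.Series | None = None) -> pd.DataFrame:
    """Sample x sample squared Pearson correlation (R^2).

    `element_mask` optionally restricts to a subset of elements (e.g. the
    promoter or distal fraction from :func:`regland.peaks.annotate_tss`).
    Zero-variance columns yield NaN entries with a warning rather than a
    silent 0.
    """
    vals = norm.values
    if element_mask is not None:
        vals = vals.loc[element_mask.reindex(vals.index).fillna(False).astype(bool)]
    if len(vals) < 2:
        raise ValidationError("need at least 2 elements for sample correlation")
    std = vals.std(axis=0)
    if (std == 0).any():
        warnings.warn(
            f"zero-variance sample(s) {list(std.index[std == 0])}: "
            "correlation undefined (NaN)", stacklevel=2,
        )
    r = vals.corr(method="pearson")
    r.values[np.arange(len(r)), np.arange(len(r))] = 1.0
    return r ** 2
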