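"""Genomic peak intervals: BED I/O, consensus filtering, TSS annotation.

Coordinates are BED-convention 0-based half-open throughout; a TSS window
``[pos - w, pos + w)`` is likewise half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from regland.errors import ValidationError

_PEAK_COLUMNS = ["chrom", "start", "end", "id"]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"interval {self.id!r}: start {self.start} < 0")
        if self.start >= self.end:
            raise ValidationError(
                f"interval {self.id!r}: start {self.start} >= end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


class PeakSet:
    """An ordered set of genomic elements with optional per-sample q-values.

    Parameters
    ----------
    df
        DataFrame with columns ``chrom, start, end, id``.
    qval
        Optional interval x sample matrix of MACS q-values, indexed by
        interval id (as produced by per-sample peak calling).
    sort
        If True, sort by (chrom, start) instead of requiring sorted input.
    """

    def __init__(self, df: pd.DataFrame, qval: pd.DataFrame | None = None,
                 sort: bool = False) -> None:
        df = df.loc[:, _PEAK_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        df["id"] = df["id"].astype(str)
        if sort:
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
            df = df.reset_index(drop=True)
        bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
        if len(bad):
            raise ValidationError(
                f"invalid interval(s) at row(s) {list(bad[:5])}: need 0 <= start < end"
            )
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValidationError(f"duplicate interval id {dup!r}")
        if not self._is_sorted(df):
            raise ValidationError(
                "intervals are not sorted by (chrom, start); pass sort=True to fix"
            )
        self.df = df
        if qval is not None:
            qval = qval.reindex(df["id"].to_numpy())
            if qval.isna().all(axis=1).any():
                missing = qval.index[qval.isna().all(axis=1)][0]
                raise ValidationError(f"q-value matrix missing interval {missing!r}")
        self.qval = qval

    @staticmethod
    def _is_sorted(df: pd.DataFrame) -> bool:
        key = list(zip(df["chrom"], df["start"]))
        return all(key[i] <= key[i + 1] for i in range(len(key) - 1))

    @classmethod
    def from_intervals(cls, intervals: list[GenomicInterval],
                       qval: pd.DataFrame | None = None,
                       sort: bool = False) -> "PeakSet":
        df = pd.DataFrame(
            [(iv.chrom, iv.start, iv.end, iv.id) for iv in intervals],
            columns=_PEAK_COLUMNS,
        )
        return cls(df, qval=qval, sort=sort)

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.df["id"])

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(*row) for row in self.df.itertuples(index=False)]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.df.equals(other.df)

    def subset(self, ids) -> "PeakSet":
        """Return the sub-PeakSet containing exactly `ids`, original order."""
        keep = self.df["id"].isin(set(ids))
        qv = self.qval.loc[self.df.loc[keep, "id"]] if self.qval is not None else None
        return PeakSet(self.df.loc[keep], qval=qv)


def read_peaks(path: str | Path, qval_column: int | None = None,
               sort: bool = False) -> PeakSet:
    """Read a BED3+/BED6+/narrowPeak file into a :class:`PeakSet`.

    Missing names (column 4) get generated ids ``peak_<n>``. Extra columns
    are ignored, except `qval_column` (0-based index) which, if given, is
    read as a -log10 MACS q-value and exposed as a single-sample q-value
    matrix.
    """
    path = Path(path)
    rows: list[tuple] = []
    qvals: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path.name}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValidationError(
                    f"{path.name}:{lineno}: non-integer coordinate"
                ) from exc
            if start < 0 or start >= end:
                raise ValidationError(
                    f"{path.name}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") \
                else f"peak_{len(rows) + 1}"
            rows.append((fields[0], start, end, name))
            if qval_column is not None:
                if len(fields) <= qval_column:
                    raise ValidationError(
                        f"{path.name}:{lineno}: no column {qval_column}"
                    )
                qvals.append(10.0 ** -float(fields[qval_column]))
    df = pd.DataFrame(rows, columns=_PEAK_COLUMNS)
    qv = None
    if qval_column is not None:
        qv = pd.DataFrame({"sample_1": qvals}, index=df["id"].to_numpy())
    return PeakSet(df, qval=qv, sort=sort)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    """Write intervals as BED4 (tab-separated chrom/start/end/id)."""
    peaks.df.to_csv(path, sep="\t", header=False, index=False)


def filter_consensus(peaks: PeakSet, q_max: float = 1e-5) -> PeakSet:
    """Keep elements called significant in at least one sample.

    An element is retained iff its minimum q-value across samples is
    strictly below `q_max` (default 1e-5), matching the consensus-peak
    filter applied after per-sample MACS peak calling.
    """
    if peaks.qval is None:
        raise ValidationError("filter_consensus requires a per-sample q-value matrix")
    if len(peaks) == 0:
        return peaks
    keep = peaks.qval.min(axis=1) < q_max
    return peaks.subset(peaks.qval.index[keep])


def annotate_tss(peaks: PeakSet,
                 tss: list[tuple[str, int, str]],
                 window_bp: int = 500) -> pd.Series:
    """Label each element ``promoter`` or ``distal``.

    An element is a promoter iff it overlaps ``[pos - window_bp,
    pos + window_bp)`` for any TSS on the same chromosome (half-open
    overlap arithmetic). The TSS window size is not a measured quantity;
    the 500 bp default is a documented package choice.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be >= 0")
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos, _strand in tss:
        by_chrom.setdefault(str(chrom), []).append(int(pos))
    labels = []
    for chrom, start, end, _id in peaks.df.itertuples(index=False):
        promoter = False
        for pos in by_chrom.get(chrom, ()):
            w_start, w_end = pos - window_bp, pos + window_bp
            if w_start == w_end:  # window 0: the single TSS base
                w_end = w_start + 1
            if start < w_end and w_start < end:
                promoter = True
                break
        labels.append("promoter" if promoter else "distal")
    return pd.Series(labels, index=peaks.ids, name="tss_annotation")
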