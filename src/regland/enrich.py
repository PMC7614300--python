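"""Interval overlap and per-cluster ChIP enrichment statistics.

Overlap is >= 1 bp under half-open arithmetic, computed by a sweep over
merged reference intervals. Per-cluster enrichment against a ChIP peak
set is a hypergeometric upper-tail test on element counts with BH
adjustment across clusters — a statistical companion to coverage
heatmaps, reported as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from regland.cluster import ClusterModel
from regland.errors import ParameterError, ValidationError
from regland.peaks import PeakSet


@dataclass
class OverlapResult:
    """Per-query overlap flags and the summary fraction."""

    flags: pd.Series  # bool per query id
    n_query: int
    n_overlapping: int

    @property
    def fraction(self) -> float:
        return self.n_overlapping / self.n_query if self.n_query else 0.0


def _ensure_sorted(peaks: PeakSet, name: str) -> PeakSet:
    if PeakSet._is_sorted(peaks.df):
        return peaks
    warnings.warn(f"{name} intervals unsorted; sorting", stacklevel=3)
    return PeakSet(peaks.df, sort=True)


def _merged_by_chrom(ref: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in ref.df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        m_starts, m_ends = [], []
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_e:  # touching intervals ([0,5),[5,9)) stay separate
                cur_e = max(cur_e, e)
            else:
                m_starts.append(cur_s)
                m_ends.append(cur_e)
                cur_s, cur_e = s, e
        m_starts.append(cur_s)
        m_ends.append(cur_e)
        out[chrom] = (np.asarray(m_starts), np.asarray(m_ends))
    return out


def overlaps(query: PeakSet, reference: PeakSet) -> OverlapResult:
    """Flag each query interval sharing >= 1 base with any reference interval."""
    query = _ensure_sorted(query, "query")
    reference = _ensure_sorted(reference, "reference")
    merged = _merged_by_chrom(reference) if len(reference) else {}
    flags = np.zeros(len(query), dtype=bool)
    for chrom, sub in query.df.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        m_starts, m_ends = merged[chrom]
        q_start = sub["start"].to_numpy()
        q_end = sub["end"].to_numpy()
        # candidate merged interval: last with start < q_end
        idx = np.searchsorted(m_starts, q_end, side="left") - 1
        hit = (idx >= 0) & (m_ends[np.clip(idx, 0, None)] > q_start)
        flags[query.df.index.get_indexer(sub.index)] = hit
    ser = pd.Series(flags, index=query.ids, name="overlapped")
    return OverlapResult(flags=ser, n_query=len(query),
                         n_overlapping=int(flags.sum()))


def cluster_overlap_fraction(model: ClusterModel, peaks: PeakSet,
                             reference: PeakSet, cluster_id: int) -> float:
    """Fraction of a cluster's elements overlapping the reference peaks."""
    in_cluster = model.merged.index[model.merged == cluster_id]
    if len(in_cluster) == 0:
        raise ParameterError(f"cluster {cluster_id} is empty or unknown")
    sub = peaks.subset(in_cluster)
    if len(sub) != len(in_cluster):
        raise ValidationError("some clustered elements missing from PeakSet")
    return overlaps(sub, reference).fraction


def cluster_enrichment(model: ClusterModel, peaks: PeakSet,
                       chip: PeakSet) -> pd.DataFrame:
    """Hypergeometric overlap enrichment per cluster vs all clustered elements.

    Universe = all clustered elements (size N, K of which overlap the
    ChIP set); each cluster of size n with k overlaps gets fold =
    (k/n)/(K/N) and upper-tail p = P[X >= k], X ~ Hypergeom(N, K, n);
    q-values are BH across clusters.
    """
    universe = model.merged.index
    sub = peaks.subset(universe)
    if len(sub) != len(universe):
        raise ValidationError("some clustered elements missing from PeakSet")
    ov = overlaps(sub, chip).flags
    n_universe = len(universe)
    k_universe = int(ov.sum())
    rows = []
    for m in model.centroids.index:
        members = model.merged.index[model.merged == m]
        n = len(members)
        k = int(ov.loc[members].sum())
        fold = ((k / n) / (k_universe / n_universe)
                if n and k_universe else np.nan)
        p = float(stats.hypergeom.sf(k - 1, n_universe, k_universe, n))
        rows.append((m, k, n, n_universe, k_universe, fold, p))
    out = pd.DataFrame(rows, columns=["cluster", "k", "n", "N", "K",
                                      "fold", "pvalue"]).set_index("cluster")
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def mean_signal_matrix(values: pd.DataFrame, model: ClusterModel,
                       ) -> pd.DataFrame:
    """Mean signal per (cluster, sample); NaNs propagate with a count.

    `values` rows must align to clustered elements (e.g. mean coverage
    per element per sample precomputed elsewhere).
    """
    missing = model.merged.index.difference(values.index)
    if len(missing):
        raise ValidationError(f"signal missing for element(s) {list(missing[:5])}")
    sub = values.loc[model.merged.index]
    n_nan = int(sub.isna().to_numpy().sum())
    if n_nan:
        warnings.warn(f"{n_nan} missing signal value(s) propagated",
                      stacklevel=2)
    clusters = sorted(model.merged.unique())
    arr = sub.to_numpy(dtype=float)
    codes = model.merged.to_numpy()
    rows = [arr[codes == m].mean(axis=0) for m in clusters]  # NaN propagates
    grouped = pd.DataFrame(rows, index=pd.Index(clusters, name="cluster"),
                           columns=sub.columns)
    return grouped
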