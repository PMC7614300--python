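"""Element clustering and regulatory-regime classification.

Differentially accessible elements are summarized as per-condition mean
accessibility profiles (z-scored per element so clusters capture shape,
not amplitude), clustered in two stages — k-means with a deliberately
high number of centers (default 30), then hierarchical merging of the
centroids under correlation distance down to a target number of final
clusters (default 9) — labeled by simple rules on their z-scored
centroids, and used to classify each cell type's regulatory strategy as
differential accessibility (it owns cell-type-specific open elements)
or differential binding (it does not).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from regland.counts import NormalizedMatrix, SampleTable
from regland.errors import ParameterError, ValidationError


@dataclass
class ProfileMatrix:
    """Per-condition accessibility profiles of selected elements.

    `values` holds per-row z-scored condition means; `raw_means` the
    unscaled condition means (used for ordering by average
    accessibility). Columns are a (cell_type, day, sag_nM) MultiIndex in
    order of first appearance in the sample table.
    """

    values: pd.DataFrame
    raw_means: pd.DataFrame
    dropped: pd.Index = field(default_factory=lambda: pd.Index([]))


@dataclass
class ClusterModel:
    """Two-stage clustering result."""

    stage1: pd.Series            # element -> 1..k1
    merged: pd.Series            # element -> 1..k_final
    stage1_to_merged: pd.Series  # stage-1 id -> merged id
    centroids: pd.DataFrame      # merged id x condition (z space)
    seed: int
    labels: dict[int, str] = field(default_factory=dict)


@dataclass
class RegimeReport:
    """Per-cell-type regulatory-strategy call with supporting counts."""

    table: pd.DataFrame  # index cell_type; columns n_specific, n_accessible,
    #                      specificity_fraction, regime
    tau: float


def build_profiles(norm: NormalizedMatrix, samples: SampleTable,
                   elements) -> ProfileMatrix:
    """Condition means across replicates, then per-row z-score.

    Zero-variance rows are dropped (reported in ``dropped``) since they
    carry no dynamics.
    """
    elements = pd.Index(elements)
    if len(elements) == 0:
        raise ValidationError("empty element selection")
    missing = elements.difference(norm.values.index)
    if len(missing):
        raise ValidationError(f"unknown element(s) {list(missing[:5])}")
    cond = samples.condition_of()
    meta = samples.df
    order: list[tuple] = []
    seen = set()
    for sid in meta.index:
        key = (meta.at[sid, "cell_type"], int(meta.at[sid, "day"]),
               int(meta.at[sid, "sag_nM"]))
        if key not in seen:
            seen.add(key)
            order.append(key)
    cols = pd.MultiIndex.from_tuples(order, names=["cell_type", "day", "sag_nM"])
    vals = norm.values.loc[elements]
    means = pd.DataFrame(index=elements, columns=cols, dtype=float)
    for key in order:
        in_cond = [s for s in meta.index
                   if (meta.at[s, "cell_type"], int(meta.at[s, "day"]),
                       int(meta.at[s, "sag_nM"])) == key]
        if not in_cond:
            raise ValidationError(f"condition {key} has no samples")
        means[key] = vals.loc[:, in_cond].mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    keep = sd > 0
    dropped = means.index[~keep]
    if len(dropped):
        warnings.warn(f"dropped {len(dropped)} zero-variance element(s)",
                      stacklevel=2)
    means = means.loc[keep]
    z = means.sub(means.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return ProfileMatrix(values=z, raw_means=means, dropped=dropped)


def two_stage_cluster(profiles: ProfileMatrix, k1: int = 30,
                      k_final: int = 9, seed: int = 0,
                      metric: str = "correlation",
                      linkage: str = "average",
                      n_init: int = 10) -> ClusterModel:
    """k-means with many centers, then hierarchical merging of centroids.

    Stage 1: k-means (k1 centers, k-means++ init, `n_init` restarts,
    fixed seed). Stage 2: average-linkage hierarchical clustering of the
    stage-1 centroids under correlation distance (1 - Pearson), tree cut
    to `k_final` groups; merged assignment is the composition. Fully
    deterministic given the seed.
    """
    x = profiles.values.to_numpy(dtype=float)
    n = x.shape[0]
    if k_final > k1:
        raise ParameterError(f"k_final ({k_final}) > k1 ({k1})")
    if k1 > n:
        raise ParameterError(f"k1 ({k1}) > number of elements ({n})")
    km = KMeans(n_clusters=k1, n_init=n_init, init="k-means++",
                random_state=int(seed))
    stage1 = km.fit_predict(x) + 1
    centroids1 = km.cluster_centers_
    if k_final == k1:
        s1m = np.arange(1, k1 + 1)
    else:
        # correlation distance is undefined for a constant centroid; give
        # such centroids a tiny deterministic ripple instead of NaNs
        c = centroids1.copy()
        flat = c.std(axis=1) == 0
        if flat.any():
            c[flat] += 1e-9 * np.arange(c.shape[1])
        dist = pdist(c, metric=metric)
        tree = hierarchy.linkage(dist, method=linkage)
        s1m = hierarchy.fcluster(tree, t=k_final, criterion="maxclust")
    merged = s1m[stage1 - 1]
    idx = profiles.values.index
    merged_ser = pd.Series(merged, index=idx, name="merged")
    cent = pd.DataFrame(
        [x[merged == m].mean(axis=0) for m in sorted(set(merged))],
        index=sorted(set(merged)), columns=profiles.values.columns,
    )
    return ClusterModel(
        stage1=pd.Series(stage1, index=idx, name="stage1"),
        merged=merged_ser,
        stage1_to_merged=pd.Series(s1m, index=np.arange(1, k1 + 1)),
        centroids=cent,
        seed=int(seed),
    )


def order_elements(model: ClusterModel, profiles: ProfileMatrix) -> pd.Index:
    """Heatmap ordering: clusters by id, elements by mean accessibility.

    Within each merged cluster, elements are sorted by descending mean of
    the unscaled condition means; ties broken by element id.
    """
    raw_mean = profiles.raw_means.mean(axis=1)
    ordered: list = []
    for m in model.centroids.index:
        in_m = model.merged.index[model.merged == m]
        sub = pd.DataFrame({"mean": raw_mean.loc[in_m]}, index=in_m)
        sub = sub.sort_index().sort_values("mean", ascending=False,
                                           kind="mergesort")
        ordered.extend(sub.index)
    return pd.Index(ordered)


def pca(norm: NormalizedMatrix, top_n: int = 30000,
        n_components: int | None = None):
    """PCA of samples over the most variable elements.

    Elements are ranked by variance across samples; the matrix is
    centered per element and decomposed by SVD. Returns (coordinates
    sample x PC, variance-explained fractions).
    """
    vals = norm.values
    if vals.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 samples")
    var = vals.var(axis=1, ddof=1)
    if top_n < len(vals):
        top = var.sort_values(ascending=False, kind="mergesort").index[:top_n]
        vals = vals.loc[top]
    elif top_n > len(vals):
        warnings.warn(
            f"top_n ({top_n}) exceeds element count ({len(vals)}); using all",
            stacklevel=2,
        )
    x = vals.to_numpy(dtype=float).T              # samples x elements
    xc = x - x.mean(axis=0, keepdims=True)        # center per element
    u, s, _vt = np.linalg.svd(xc, full_matrices=False)
    k = n_components or min(xc.shape)
    coords = u[:, :k] * s[:k]
    total = (xc ** 2).sum()
    var_explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    coords_df = pd.DataFrame(coords, index=norm.values.columns,
                             columns=[f"PC{i + 1}" for i in range(k)])
    return coords_df, var_explained


def _condition_groups(columns: pd.MultiIndex):
    cts = list(dict.fromkeys(columns.get_level_values("cell_type")))
    days = sorted(set(columns.get_level_values("day")))
    min_day = days[0]
    origin_cts = {ct for ct, day, _ in columns if day == min_day}
    # origin = cell types only ever seen at the earliest days, i.e. whose
    # latest day is below the global maximum (the NMP-like source state)
    origin = {ct for ct in origin_cts
              if max(d for c, d, _ in columns if c == ct) < days[-1]}
    neural = [ct for ct in cts if ct not in origin]
    return origin, neural


def label_clusters(model: ClusterModel, profiles: ProfileMatrix,
                   samples: SampleTable, high_z: float = 0.5,
                   low_z: float = -0.5) -> dict[int, str]:
    """Semantic labels for merged clusters from their z-scored centroids.

    Rules, applied in order per cluster (H = conditions with z >= high_z):
    ``NMP`` if H is non-empty and lies entirely in the origin cell
    type's conditions; ``pan-neural`` if every origin condition is low
    (<= low_z) and every non-origin condition is non-negative;
    ``<ct>-specific`` if H lies in exactly one non-origin cell type's
    conditions and every other condition is low; ``<ct>-enriched`` if
    the outside maximum is merely moderate (< high_z); else ``other``.
    """
    cols = model.centroids.columns
    origin, neural = _condition_groups(cols)
    labels: dict[int, str] = {}
    for m in model.centroids.index:
        z = model.centroids.loc[m]
        high = z[z >= high_z]
        label = "other"
        h_cts = set(high.index.get_level_values("cell_type"))
        if len(high) and h_cts <= origin:
            label = "NMP"
        elif (len(origin) > 0
              and all(z[c] <= low_z for c in cols
                      if c[0] in origin)
              and all(z[c] >= 0 for c in cols if c[0] not in origin)):
            label = "pan-neural"
        elif len(high) and len(h_cts) == 1 and not (h_cts & origin):
            ct = next(iter(h_cts))
            outside = z[[c for c in cols if c[0] != ct]]
            if len(outside) == 0 or outside.max() <= low_z:
                label = f"{ct}-specific"
            elif outside.max() < high_z:
                label = f"{ct}-enriched"
        labels[int(m)] = label
    model.labels = labels
    return labels


def cluster_stability(profiles: ProfileMatrix, k1: int = 30,
                      k_final: int = 9, seeds: list[int] = (0, 1, 2, 3, 4),
                      ) -> float:
    """Mean pairwise adjusted Rand index of merged assignments across seeds."""
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ParameterError("need >= 2 seeds")
    assignments = [two_stage_cluster(profiles, k1=k1, k_final=k_final,
                                     seed=s).merged.to_numpy()
                   for s in seeds]
    aris = [adjusted_rand_score(a, b)
            for i, a in enumerate(assignments)
            for b in assignments[i + 1:]]
    return float(np.mean(aris))


def classify_regime(model: ClusterModel, profiles: ProfileMatrix,
                    samples: SampleTable, cell_types: list[str] | None = None,
                    tau: float = 0.15, high_z: float = 0.5) -> RegimeReport:
    """Classify each cell type's regulatory strategy.

    An element counts as accessible in a cell type if its mean z-profile
    over that cell type's conditions exceeds `high_z`. The specificity
    fraction is the share of those elements sitting in clusters labeled
    ``<ct>-specific`` or ``<ct>-enriched``; cell types above `tau`
    (default 0.15, a simulator-calibrated package default) are called
    ``differential_accessibility``, the rest ``differential_binding``.
    """
    if not model.labels:
        raise ValidationError("run label_clusters first")
    cols = profiles.values.columns
    origin, neural = _condition_groups(cols)
    if cell_types is None:
        cell_types = neural
    rows = []
    for ct in cell_types:
        ct_cols = [c for c in cols if c[0] == ct]
        if not ct_cols:
            raise ParameterError(f"cell type {ct!r} absent from conditions")
        mean_z = profiles.values[ct_cols].mean(axis=1)
        accessible = profiles.values.index[mean_z > high_z]
        tagged = {m for m, lab in model.labels.items()
                  if lab in (f"{ct}-specific", f"{ct}-enriched")}
        in_tagged = model.merged.loc[accessible].isin(tagged)
        n_acc = len(accessible)
        n_spec = int(in_tagged.sum())
        if n_acc == 0:
            warnings.warn(f"{ct}: no accessible differential elements",
                          stacklevel=2)
            frac = 0.0
        else:
            frac = n_spec / n_acc
        regime = ("differential_accessibility" if frac > tau
                  else "differential_binding")
        rows.append((ct, n_spec, n_acc, frac, regime))
    table = pd.DataFrame(
        rows, columns=["cell_type", "n_specific", "n_accessible",
                       "specificity_fraction", "regime"],
    ).set_index("cell_type")
    return RegimeReport(table=table, tau=tau)
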