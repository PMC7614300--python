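"""Lineage-tracing quantification from multi-channel section images.

Nuclei are segmented on the DAPI channel (Gaussian smooth, global Otsu,
8-connected components, size filter); per-nucleus mean intensities are
measured for the marker channels; thresholds (Otsu on per-nucleus means
by default, quantile as fallback) split positive from negative cells;
SOX2+/NKX2.2+ cells are classified p3 and NKX2.2-only cells V3; a
positional QC excludes NKX2.2+ cells far from the p3 domain (antibody
background); tdTomato-positive p3 and V3 cells are counted per section.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters, measure

from regland.errors import ParameterError, ValidationError

CHANNELS = ("DAPI", "SOX2", "NKX2.2", "tdTomato")


@dataclass
class ImageStack:
    """Named 2-D channels of one section."""

    channels: dict[str, np.ndarray]
    section_id: str = ""
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValidationError(f"channel shapes differ: {shapes}")
        for ch, a in self.channels.items():
            if (np.asarray(a) < 0).any():
                raise ValidationError(f"channel {ch!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class SectionSummary:
    """Per-section lineage-tracing counts."""

    section_id: str
    n_p3_tdtom: int
    n_v3_tdtom: int
    n_p3: int
    n_v3: int
    n_other: int


def segment_nuclei(dapi: np.ndarray, smooth_sigma: float = 1.0,
                   min_area: int = 20, max_area: int = 10_000,
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment nuclei on the DAPI channel.

    Gaussian smooth -> global Otsu threshold -> 8-connected components
    -> [min_area, max_area] size filter. Returns the filtered label
    image and a record table (label, centroid, area).
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.size == 0:
        raise ParameterError("empty image")
    empty = pd.DataFrame(columns=["label", "centroid_row", "centroid_col",
                                  "area_px"])
    if dapi.max() == dapi.min():
        warnings.warn("constant DAPI image: no foreground", stacklevel=2)
        return np.zeros(dapi.shape, dtype=np.int32), empty
    smooth = filters.gaussian(dapi, sigma=smooth_sigma, preserve_range=True)
    thr = filters.threshold_otsu(smooth, nbins=256)
    labels = measure.label(smooth > thr, connectivity=2)
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    nxt = 1
    for prop in measure.regionprops(labels):
        if min_area <= prop.area <= max_area:
            keep[prop.label] = nxt
            rows.append((nxt, prop.centroid[0], prop.centroid[1],
                         int(prop.area)))
            nxt += 1
    records = pd.DataFrame(rows, columns=["label", "centroid_row",
                                          "centroid_col", "area_px"])
    return keep[labels], records


def measure_intensities(labels: np.ndarray, stack: ImageStack,
                        records: pd.DataFrame) -> pd.DataFrame:
    """Mean intensity per nucleus per channel, appended to the records."""
    if labels.shape != stack.shape:
        raise ValidationError("label image shape does not match channels")
    out = records.copy()
    flat = labels.ravel()
    n_labels = int(labels.max())
    counts = np.bincount(flat, minlength=n_labels + 1)
    for ch, img in stack.channels.items():
        sums = np.bincount(flat, weights=np.asarray(img, dtype=float).ravel(),
                           minlength=n_labels + 1)
        with np.errstate(invalid="ignore"):
            means = sums / counts
        out[f"mean_{ch}"] = means[out["label"].to_numpy()]
    return out


def find_threshold(values, method: str = "otsu", q: float = 0.5) -> float:
    """Threshold per-nucleus intensities.

    ``otsu``: between-class-variance maximizer over a 256-bin histogram
    of the values. ``quantile``: the q-th empirical quantile.
    """
    values = np.asarray(values, dtype=float)
    if method == "quantile":
        return float(np.quantile(values, q))
    if method == "otsu":
        if len(np.unique(values)) < 2:
            raise ParameterError(
                "Otsu undefined for < 2 distinct values; use method='quantile'"
            )
        return float(filters.threshold_otsu(values, nbins=256))
    raise ParameterError(f"unknown threshold method {method!r}")


def classify_cells(records: pd.DataFrame,
                   thresholds: dict[str, float]) -> pd.DataFrame:
    """Classify cells as p3 / V3 / other and flag tdTomato positivity.

    p3: SOX2 > t and NKX2.2 > t. V3: NKX2.2 > t only. Everything else
    (including SOX2-only) is ``other``.
    """
    for ch in ("SOX2", "NKX2.2", "tdTomato"):
        if ch not in thresholds:
            raise ValidationError(f"missing threshold for channel {ch!r}")
        if f"mean_{ch}" not in records.columns:
            raise ValidationError(f"missing intensity column mean_{ch}")
    out = records.copy()
    sox = out["mean_SOX2"] > thresholds["SOX2"]
    nkx = out["mean_NKX2.2"] > thresholds["NKX2.2"]
    out["cell_class"] = np.where(sox & nkx, "p3",
                                 np.where(nkx & ~sox, "V3", "other"))
    out["tdtomato_positive"] = out["mean_tdTomato"] > thresholds["tdTomato"]
    return out


def position_qc(cells: pd.DataFrame, max_distance_px: float,
                center: tuple[float, float] | None = None) -> pd.DataFrame:
    """Exclude NKX2.2+ cells far from the p3 domain.

    The domain center defaults to the coordinate-wise median position of
    NKX2.2+ (p3 or V3) cells — a robust location that the far
    background-binding cells this step is meant to remove cannot drag
    towards themselves. NKX2.2+ cells farther than `max_distance_px`
    fail QC; NKX2.2-negative cells always pass.
    """
    out = cells.copy()
    nkx_pos = out["cell_class"].isin(["p3", "V3"])
    if center is None:
        if not nkx_pos.any():
            warnings.warn("no NKX2.2+ cells: all pass positional QC",
                          stacklevel=2)
            out["passed_position_qc"] = True
            return out
        center = (
            float(out.loc[nkx_pos, "centroid_row"].median()),
            float(out.loc[nkx_pos, "centroid_col"].median()),
        )
    dist = np.hypot(out["centroid_row"] - center[0],
                    out["centroid_col"] - center[1])
    out["passed_position_qc"] = ~nkx_pos | (dist <= max_distance_px)
    return out


def count_per_section(cells: pd.DataFrame, section_id: str = "",
                      ) -> SectionSummary:
    """Count tdTomato+ p3 and V3 cells among QC-passing cells."""
    if "cell_class" not in cells.columns:
        raise ValidationError("run classify_cells first")
    if "passed_position_qc" in cells.columns:
        cells = cells[cells["passed_position_qc"]]
    cls = cells["cell_class"]
    tdt = cells["tdtomato_positive"]
    return SectionSummary(
        section_id=section_id,
        n_p3_tdtom=int(((cls == "p3") & tdt).sum()),
        n_v3_tdtom=int(((cls == "V3") & tdt).sum()),
        n_p3=int((cls == "p3").sum()),
        n_v3=int((cls == "V3").sum()),
        n_other=int((cls == "other").sum()),
    )


def quantify_sections(stacks: list[ImageStack], smooth_sigma: float = 1.0,
                      min_area: int = 20, max_area: int = 10_000,
                      max_distance_px: float | None = None,
                      threshold_method: str = "otsu",
                      ) -> tuple[list[SectionSummary], pd.DataFrame]:
    """Full per-section pipeline with thresholds pooled across sections.

    Pooling the per-nucleus intensities before thresholding keeps the
    Otsu split meaningful when a single section happens to contain only
    positives or only negatives for a channel.
    """
    per_section = []
    for stack in stacks:
        labels, records = segment_nuclei(stack.channels["DAPI"],
                                         smooth_sigma=smooth_sigma,
                                         min_area=min_area,
                                         max_area=max_area)
        meas = measure_intensities(labels, stack, records)
        meas.insert(0, "section_id", stack.section_id)
        per_section.append(meas)
    all_cells = pd.concat(per_section, ignore_index=True)
    thresholds = {ch: find_threshold(all_cells[f"mean_{ch}"],
                                     method=threshold_method)
                  for ch in ("SOX2", "NKX2.2", "tdTomato")}
    summaries = []
    classified = []
    for stack, meas in zip(stacks, per_section):
        cells = classify_cells(meas, thresholds)
        if max_distance_px is not None:
            cells = position_qc(cells, max_distance_px=max_distance_px)
        classified.append(cells)
        summaries.append(count_per_section(cells, section_id=stack.section_id))
    return summaries, pd.concat(classified, ignore_index=True)
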