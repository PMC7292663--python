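"""Fixed-timepoint surface-staining quantification.

Pipeline for multi-channel fields of immunostained, non-permeabilized cells:
segment nuclei, dilate them into cell proxies (nearest-nucleus assignment of
contested pixels), exclude permeabilized/dead cells by their summed
surface-calnexin signal, sum the surface channel-of-interest ("apol1") per
cell, derive the positivity threshold from untransfected control fields (the
maximum per-cell sum observed there), and aggregate per-condition metrics
normalized to a no-trigger reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import expand_labels, watershed

__all__ = [
    "ImageField",
    "segment_nuclei",
    "approximate_cells",
    "measure_cells",
    "filter_permeabilized",
    "sum_apol1_intensity",
    "surface_positive_threshold",
    "analyze_field",
    "quantify_condition",
]


@dataclass
class ImageField:
    """One registered multi-channel 2-D field with condition metadata.

    Channels are keyed by canonical names ("nuclei", "calnexin", "apol1").
    ``ground_truth`` optionally carries the per-cell simulation truth
    (positions and positivity flags) for round-trip validation.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.65
    condition: str = ""
    transfected: bool = True
    metadata: dict = field(default_factory=dict)
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a field needs at least one channel")
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"all channels must share one shape, got {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D (project stacks upstream)")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (z, y, x) stack to 2-D."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3-D (z, y, x) stack")
    return stack.max(axis=0)


def segment_nuclei(
    fld: ImageField,
    sigma: float = 2.0,
    min_size_px: int = 30,
    min_distance_px: int = 7,
) -> np.ndarray:
    """Label image of nuclei from the nuclear-stain channel.

    Gaussian smoothing, Otsu global threshold, hole filling, small-object
    removal, then a distance-transform watershed to split touching nuclei.
    A blank channel yields zero labels with a warning rather than an error.
    """
    if "nuclei" not in fld.channels:
        raise KeyError("field has no 'nuclei' channel")
    img = fld.channels["nuclei"].astype(float)
    if np.ptp(img) == 0:
        warnings.warn("blank nuclei channel: returning zero labels", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)
    smooth = gaussian(img, sigma=sigma, preserve_range=True)
    mask = smooth > threshold_otsu(smooth)
    mask = ndi.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=min_size_px)
    if not mask.any():
        warnings.warn("no nuclei above threshold: returning zero labels", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_distance_px, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
    labels = watershed(-distance, markers, mask=mask)
    return labels.astype(np.int32)


def approximate_cells(nuclei_labels: np.ndarray, dilation_radius_px: float = 15.0) -> np.ndarray:
    """Dilate nucleus labels into cell proxies.

    Each label grows by ``dilation_radius_px``; contested pixels go to the
    nearest nucleus, so the label count is always preserved and every nucleus
    mask is contained in its cell mask.
    """
    if dilation_radius_px <= 0:
        raise ValueError("dilation radius must be positive")
    return expand_labels(nuclei_labels, distance=dilation_radius_px)


def sum_apol1_intensity(
    fld: ImageField,
    cell_labels: np.ndarray,
    channel: str = "apol1",
    background_mode: str | None = None,
) -> pd.Series:
    """Per-cell summed intensity of a channel over the dilated cell masks.

    ``background_mode="median"`` subtracts the median intensity of pixels
    outside every cell mask from each in-mask pixel (clipped at zero for the
    cell) before summing; None sums raw intensities.
    """
    if channel not in fld.channels:
        raise KeyError(f"field has no {channel!r} channel")
    img = fld.channels[channel].astype(float)
    ids = np.arange(1, int(cell_labels.max()) + 1)
    if ids.size == 0:
        return pd.Series(dtype=float, name=f"sum_{channel}")
    sums = ndi.sum_labels(img, labels=cell_labels, index=ids)
    if background_mode == "median":
        outside = img[cell_labels == 0]
        bg = float(np.median(outside)) if outside.size else 0.0
        areas = ndi.sum_labels(np.ones_like(img), labels=cell_labels, index=ids)
        sums = np.clip(sums - bg * areas, 0.0, None)
    elif background_mode is not None:
        raise ValueError(f"unknown background_mode {background_mode!r}")
    return pd.Series(sums, index=ids, name=f"sum_{channel}")


def measure_cells(
    fld: ImageField,
    cell_labels: np.ndarray,
    nuclei_labels: np.ndarray | None = None,
    background_mode: str | None = None,
) -> pd.DataFrame:
    """Per-cell region table: centroid, area and summed intensity per channel."""
    ids = np.arange(1, int(cell_labels.max()) + 1)
    if ids.size == 0:
        cols = ["label", "row", "col", "area_px"] + [f"sum_{c}" for c in fld.channels]
        return pd.DataFrame(columns=cols)
    centroids = ndi.center_of_mass(
        np.ones(cell_labels.shape), labels=cell_labels, index=ids
    )
    table = pd.DataFrame(
        {
            "label": ids,
            "row": [c[0] for c in centroids],
            "col": [c[1] for c in centroids],
            "area_px": ndi.sum_labels(np.ones(cell_labels.shape), cell_labels, ids),
        }
    )
    for name in fld.channels:
        mode = background_mode if name == "apol1" else None
        table[f"sum_{name}"] = sum_apol1_intensity(fld, cell_labels, name, mode).to_numpy()
    return table


def filter_permeabilized(
    cells: pd.DataFrame,
    threshold: float | str = "auto",
    calnexin_column: str = "sum_calnexin",
) -> tuple[pd.DataFrame, int]:
    """Flag and drop permeabilized/dead cells by surface-calnexin signal.

    The ER marker is inaccessible to surface staining in intact cells, so a
    large in-mask calnexin sum marks a permeabilized cell.  ``threshold``
    "auto" uses twice the population median (robust when most cells are
    intact); a float is an absolute cutoff.  Returns the retained table and
    the exclusion count; the input gains a ``permeabilized`` flag column.
    """
    if calnexin_column not in cells.columns:
        raise KeyError(f"cell table has no column {calnexin_column!r}")
    vals = cells[calnexin_column].to_numpy(dtype=float)
    if threshold == "auto":
        cutoff = 2.0 * float(np.median(vals)) if len(vals) else np.inf
    else:
        cutoff = float(threshold)
        if cutoff < 0:
            raise ValueError("threshold must be >= 0")
    flag = vals > cutoff
    cells = cells.copy()
    cells["permeabilized"] = flag
    return cells.loc[~flag].reset_index(drop=True), int(flag.sum())


def surface_positive_threshold(
    untransfected_tables: list[pd.DataFrame],
    column: str = "sum_apol1",
) -> float:
    """Positivity cutoff: maximum per-cell sum across untransfected controls.

    A cell in an experimental field counts as surface-positive only if its
    summed stain intensity exceeds every retained cell of every untransfected
    control field.
    """
    sums = [t[column].to_numpy(dtype=float) for t in untransfected_tables if len(t)]
    if not sums:
        raise ValueError("no retained cells in untransfected control fields")
    return float(np.max(np.concatenate(sums)))


def analyze_field(
    fld: ImageField,
    dilation_radius_px: float = 15.0,
    permeabilization_threshold: float | str = "auto",
    background_mode: str | None = None,
    sigma: float = 2.0,
    min_distance_px: int = 7,
) -> pd.DataFrame:
    """Run the whole per-field pipeline; returns the retained-cell table.

    The result carries the field's condition metadata so tables from many
    fields can be concatenated and fed to :func:`quantify_condition`.
    """
    nuclei = segment_nuclei(fld, sigma=sigma, min_distance_px=min_distance_px)
    cell_labels = approximate_cells(nuclei, dilation_radius_px)
    table = measure_cells(fld, cell_labels, nuclei, background_mode=background_mode)
    if "sum_calnexin" in table.columns and len(table):
        table, _ = filter_permeabilized(table, permeabilization_threshold)
    table = table.copy()
    table["condition"] = fld.condition
    table["transfected_field"] = fld.transfected
    return table


def quantify_condition(
    cells: pd.DataFrame,
    threshold: float,
    reference_condition: str,
    intensity_column: str = "sum_apol1",
) -> pd.DataFrame:
    """Per-condition surface-staining metrics, normalized to a reference.

    For each condition: retained cell count, mean summed intensity, percent
    of cells above the positivity threshold, and both metrics divided by the
    matched no-trigger reference condition.
    """
    if reference_condition not in set(cells["condition"]):
        raise ValueError(f"reference condition {reference_condition!r} not present")
    rows = []
    for cond, grp in cells.groupby("condition", sort=True):
        sums = grp[intensity_column].to_numpy(dtype=float)
        rows.append(
            {
                "condition": cond,
                "n_cells": int(len(sums)),
                "mean_intensity": float(np.mean(sums)) if len(sums) else np.nan,
                "pct_positive": 100.0 * float(np.mean(sums > threshold)) if len(sums) else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    ref = out.loc[out["condition"] == reference_condition].iloc[0]
    if ref["n_cells"] == 0:
        raise ValueError("reference condition has zero retained cells")
    out["norm_mean_intensity"] = out["mean_intensity"] / ref["mean_intensity"]
    out["norm_pct_positive"] = (
        out["pct_positive"] / ref["pct_positive"] if ref["pct_positive"] > 0 else np.nan
    )
    return out
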