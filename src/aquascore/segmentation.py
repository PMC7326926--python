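"""Cell segmentation and per-compartment quantification.

Cells are identified on the DAPI channel: threshold (Otsu by default),
split touching nuclei by a distance-transform watershed, and filter by an
equivalent-radius window. Subcellular compartments are then derived
geometrically — cytoplasm as a ring of fixed width around the nucleus and
membrane as a further ring outside it — with contested pixels assigned to
the nearest nucleus (ties to the lower cell label). Finally, marker
intensities are summed per cell, marker and compartment on a per-pixel
basis; these sums and pixel areas are the terms of the AQUA score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .types import (
    BACKGROUND,
    COMPARTMENT_CODES,
    COMPARTMENTS,
    CYTOPLASM,
    ChannelStack,
    CompartmentMask,
    ConfigurationError,
    MEMBRANE,
    NUCLEUS,
)


def normalize_stack(
    stack: ChannelStack, channel_max: dict[str, float] | None = None
) -> ChannelStack:
    """Scale each channel into [0, 1].

    By default each channel is divided by its own maximum. When several
    cores are analysed together, pass ``channel_max`` (e.g. from
    :func:`batch_channel_max`) so all cores share one denominator per
    channel — dividing per-core would erase the between-core intensity
    differences the AQUA score is meant to capture. All-zero channels pass
    through unchanged.
    """
    out = stack.pixels.copy()
    for i, name in enumerate(stack.channel_names):
        m = channel_max[name] if channel_max is not None else float(out[i].max())
        if m > 0:
            out[i] = out[i] / m
    return ChannelStack(np.clip(out, 0.0, 1.0), stack.channel_names, stack.pixel_size_um)


def batch_channel_max(stacks: list[ChannelStack]) -> dict[str, float]:
    """Per-channel maximum over a batch of cores (the shared denominator)."""
    maxima: dict[str, float] = {}
    for stack in stacks:
        for i, name in enumerate(stack.channel_names):
            m = float(stack.pixels[i].max())
            maxima[name] = max(maxima.get(name, 0.0), m)
    return maxima


def detect_cells(
    stack: ChannelStack,
    min_radius_px: float = 3.0,
    max_radius_px: float = 12.0,
    threshold: float | None = None,
) -> np.ndarray:
    """Label nuclei on the DAPI channel.

    Pixels above ``threshold`` (Otsu on the DAPI channel when ``None``)
    form candidate nuclear regions; merged nuclei are split by watershed
    on the Euclidean distance transform, seeded at distance peaks at least
    ``min_radius_px`` apart. Regions whose equivalent-circle radius falls
    outside ``[min_radius_px, max_radius_px]`` are discarded. Labels are
    renumbered densely from 1.
    """
    dapi = stack.channel("DAPI")
    if threshold is None:
        if dapi.max() <= dapi.min():
            return np.zeros(dapi.shape, dtype=np.int32)
        threshold = float(threshold_otsu(dapi))
    binary = dapi > threshold
    if not binary.any():
        return np.zeros(dapi.shape, dtype=np.int32)

    distance = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance,
        min_distance=max(1, int(round(min_radius_px))),
        labels=binary,
        exclude_border=False,
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-distance, markers, mask=binary)

    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for region in regionprops(labels):
        radius = np.sqrt(region.area / np.pi)
        if min_radius_px <= radius <= max_radius_px:
            out[labels == region.label] = next_label
            next_label += 1
    return out


def _nearest_nucleus(nuclear_labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign every pixel to its nearest nucleus; ties go to the lower label.

    Returns (assigned label map, distance-to-nucleus map). Implemented
    with two EDT passes, the second over a label-reversed map: where the
    two passes disagree the pixel is equidistant from both candidates, and
    the lower label wins.
    """
    background = nuclear_labels == 0
    dist, (ir, ic) = ndimage.distance_transform_edt(background, return_indices=True)
    assigned = nuclear_labels[ir, ic]

    labels = np.unique(nuclear_labels)
    labels = labels[labels > 0]
    if labels.size > 1:
        # Reverse the label order and redo the EDT: a differing assignment
        # at equal distance exposes a tie.
        remap = np.zeros(int(labels.max()) + 1, dtype=nuclear_labels.dtype)
        remap[labels] = labels[::-1]
        reversed_labels = remap[nuclear_labels]
        _, (jr, jc) = ndimage.distance_transform_edt(
            reversed_labels == 0, return_indices=True
        )
        assigned_rev = remap[reversed_labels[jr, jc]]  # back to original labels
        assigned = np.minimum(assigned, assigned_rev)
    return assigned, dist


def derive_compartments(
    nuclear_labels: np.ndarray,
    cytoplasm_width_px: float,
    membrane_width_px: float,
) -> CompartmentMask:
    """Build nucleus/cytoplasm/membrane masks from a nuclear label map.

    The cytoplasm is the ring of ``cytoplasm_width_px`` around each
    nucleus and the membrane the next ring of ``membrane_width_px``
    outside it; rings are truncated where neighbouring cells' territories
    meet (each pixel belongs only to its nearest nucleus). Nucleus,
    cytoplasm and membrane pixels of a cell are disjoint by construction.
    """
    if cytoplasm_width_px <= 0 or membrane_width_px <= 0:
        raise ConfigurationError("compartment ring widths must be > 0")
    nuclear_labels = np.asarray(nuclear_labels)

    assigned, dist = _nearest_nucleus(nuclear_labels)
    compartments = np.full(nuclear_labels.shape, BACKGROUND, dtype=np.uint8)
    compartments[nuclear_labels > 0] = NUCLEUS
    outside = nuclear_labels == 0
    compartments[outside & (dist <= cytoplasm_width_px)] = CYTOPLASM
    compartments[
        outside
        & (dist > cytoplasm_width_px)
        & (dist <= cytoplasm_width_px + membrane_width_px)
    ] = MEMBRANE

    cell_labels = np.where(compartments != BACKGROUND, assigned, 0).astype(np.int32)
    cell_labels[nuclear_labels > 0] = nuclear_labels[nuclear_labels > 0]
    return CompartmentMask(cell_labels, compartments)


def quantify_cells(stack: ChannelStack, mask: CompartmentMask) -> pd.DataFrame:
    """Per-cell, per-marker, per-compartment pixel sums, areas and means.

    ``stack`` should already be normalized to [0, 1]. Returns a tidy
    frame with one row per (cell_id, marker, compartment): columns
    ``intensity_sum`` (sum of per-pixel intensity), ``pixel_area`` (pixel
    count) and ``mean_intensity``, plus the cell centroid. Compartments
    with zero pixels for a cell are omitted.
    """
    if mask.cell_labels.shape != stack.shape:
        raise ConfigurationError(
            f"mask shape {mask.cell_labels.shape} != image shape {stack.shape}"
        )
    labels = mask.labels
    if labels.size == 0:
        return pd.DataFrame(
            columns=[
                "cell_id", "marker", "compartment",
                "intensity_sum", "pixel_area", "mean_intensity",
                "centroid_row", "centroid_col",
            ]
        )
    n_max = int(labels.max())

    # Composite bin: cell label x compartment code, flattened for bincount.
    comp = mask.compartment_of_pixel.astype(np.int64)
    lab = mask.cell_labels.astype(np.int64)
    inside = lab > 0
    composite = (lab[inside] - 1) * 4 + comp[inside]
    n_bins = n_max * 4

    areas = np.bincount(composite, minlength=n_bins)

    # Centroids over the full cell footprint.
    rr, cc = np.nonzero(inside)
    foot = lab[inside] - 1
    foot_counts = np.bincount(foot, minlength=n_max)
    cen_r = np.bincount(foot, weights=rr, minlength=n_max) / np.maximum(foot_counts, 1)
    cen_c = np.bincount(foot, weights=cc, minlength=n_max) / np.maximum(foot_counts, 1)

    records: list[dict] = []
    for ci, marker in enumerate(stack.channel_names):
        sums = np.bincount(
            composite, weights=stack.pixels[ci][inside], minlength=n_bins
        )
        for cell in labels:
            base = (int(cell) - 1) * 4
            for comp_name in COMPARTMENTS:
                code = COMPARTMENT_CODES[comp_name]
                area = int(areas[base + code])
                if area == 0:
                    continue
                s = float(sums[base + code])
                records.append({
                    "cell_id": int(cell),
                    "marker": marker,
                    "compartment": comp_name,
                    "intensity_sum": s,
                    "pixel_area": area,
                    "mean_intensity": s / area,
                    "centroid_row": cen_r[int(cell) - 1],
                    "centroid_col": cen_c[int(cell) - 1],
                })
    return pd.DataFrame.from_records(records)


def cell_means_wide(quant: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy quantification into one row per cell.

    Columns are named ``mean_<MARKER>_<compartment>``; centroids are
    carried along. Missing (cell, marker, compartment) cells become NaN.
    """
    if quant.empty:
        return pd.DataFrame(columns=["cell_id"])
    wide = quant.pivot_table(
        index="cell_id",
        columns=["marker", "compartment"],
        values="mean_intensity",
        aggfunc="first",
    )
    wide.columns = [f"mean_{m}_{c}" for m, c in wide.columns]
    centroids = quant.groupby("cell_id")[["centroid_row", "centroid_col"]].first()
    return wide.join(centroids).reset_index()
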