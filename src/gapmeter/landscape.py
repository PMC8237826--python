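"""Per-cell landscape metrics from binary habitat, road and urban rasters.

Six metrics are produced for every grid cell:

* ``prop_habitat`` — fraction of habitat within a square moving window;
* ``fragment_size`` — log10 area (ha) of the habitat fragment the cell
  belongs to (8-connectivity); NaN for non-habitat cells;
* ``connectivity`` — log10(area_ha * 100) of the functionally connected
  cluster: patches whose gap does not exceed ``gap_m`` are merged, and
  non-habitat cells within ``gap_m`` of a patch inherit its value;
* ``homogeneity`` — similarity of a continuous vegetation index between
  adjacent cells, in [0, 1];
* ``dist_urban`` / ``dist_road`` — exact Euclidean distance (m) between cell
  centers and the nearest mask cell center.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from gapmeter.raster import Raster

__all__ = [
    "proportion_habitat",
    "fragment_sizes",
    "functional_connectivity",
    "homogeneity",
    "distance_to",
    "compute_metrics",
]

# Diagonal adjacency joins fragments (8-connectivity).
_STRUCT8 = np.ones((3, 3), dtype=bool)


def _binary(raster: Raster) -> np.ndarray:
    data = np.nan_to_num(raster.data, nan=0.0)
    return data > 0.5


def _cell_area_ha(raster: Raster) -> float:
    return raster.cell_size**2 / 10_000.0


def proportion_habitat(habitat: Raster, window_m: float = 1000.0) -> Raster:
    """Moving-window habitat fraction; edge cells use the truncated window."""
    n = int(round(window_m / habitat.cell_size))
    if n < 1:
        raise ValueError("window smaller than one cell")
    if n % 2 == 0:
        n += 1
    mask = _binary(habitat).astype(float)
    kernel_sum = ndimage.uniform_filter(mask, size=n, mode="constant", cval=0.0) * n * n
    counts = ndimage.uniform_filter(np.ones_like(mask), size=n, mode="constant", cval=0.0) * n * n
    return habitat.like(kernel_sum / counts)


def fragment_sizes(habitat: Raster) -> tuple[Raster, np.ndarray]:
    """Label habitat fragments and return per-cell log10(area in ha) + labels."""
    mask = _binary(habitat)
    labels, n_frag = ndimage.label(mask, structure=_STRUCT8)
    counts = np.bincount(labels.ravel(), minlength=n_frag + 1).astype(float)
    area_ha = counts * _cell_area_ha(habitat)
    out = np.full(habitat.shape, np.nan)
    if n_frag:
        out[mask] = np.log10(area_ha[labels[mask]])
    return habitat.like(out), labels


def _dilation_footprint(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    if r < 1:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_cells**2


def functional_connectivity(habitat: Raster, gap_m: float = 180.0) -> Raster:
    """Area of functionally connected habitat, log10(ha * 100), per cell.

    Patches are merged when separated by at most ``gap_m`` (cell-center to
    cell-center between boundary cells), implemented by labeling the union of
    per-patch dilations by ``gap_m / 2``.  Cluster area is the sum of the
    *original* patch areas.  Non-habitat cells within ``gap_m`` of a patch
    take the value of the nearest patch, mirroring the rule that sites just
    outside a fragment edge score as if inside it.
    """
    if gap_m < 0:
        raise ValueError("gap_m must be non-negative")
    mask = _binary(habitat)
    frag_labels, n_frag = ndimage.label(mask, structure=_STRUCT8)
    if n_frag == 0:
        return habitat.like(np.full(habitat.shape, np.nan))

    radius_cells = (gap_m / 2.0) / habitat.cell_size
    dilated = ndimage.binary_dilation(mask, structure=_dilation_footprint(radius_cells))
    cluster_labels, _ = ndimage.label(dilated, structure=_STRUCT8)

    # Sum original habitat areas within each dilation cluster.
    cell_ha = _cell_area_ha(habitat)
    cluster_of_cell = cluster_labels[mask]
    cluster_area = np.bincount(cluster_of_cell, weights=np.full(cluster_of_cell.shape, cell_ha))

    value = np.full(habitat.shape, np.nan)
    value[mask] = np.log10(cluster_area[cluster_labels[mask]] * 100.0)

    # Inheritance: non-habitat cells within gap_m of a patch edge.
    dist, (inear, jnear) = ndimage.distance_transform_edt(
        ~mask, sampling=habitat.cell_size, return_indices=True
    )
    inherit = (~mask) & (dist <= gap_m)
    value[inherit] = value[inear[inherit], jnear[inherit]]
    return habitat.like(value)


def homogeneity(veg_index: Raster) -> Raster:
    """1 - (mean |difference to 8 neighbors| / global range); constant field -> 1."""
    data = veg_index.data
    rng = np.nanmax(data) - np.nanmin(data)
    if not np.isfinite(rng) or rng == 0:
        return veg_index.like(np.ones_like(data))
    def shift(arr: np.ndarray, di: int, dj: int) -> np.ndarray:
        out = np.full_like(arr, np.nan)
        h, w = arr.shape
        src_i = slice(max(di, 0), h + min(di, 0))
        src_j = slice(max(dj, 0), w + min(dj, 0))
        dst_i = slice(max(-di, 0), h + min(-di, 0))
        dst_j = slice(max(-dj, 0), w + min(-dj, 0))
        out[dst_i, dst_j] = arr[src_i, src_j]
        return out

    total = np.zeros_like(data)
    count = np.zeros_like(data)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            shifted = shift(data, di, dj)
            valid = ~np.isnan(shifted)
            total[valid] += np.abs(data - shifted)[valid]
            count[valid] += 1
    mean_diff = np.divide(total, count, out=np.zeros_like(total), where=count > 0)
    return veg_index.like(np.clip(1.0 - mean_diff / rng, 0.0, 1.0))


def distance_to(mask: Raster) -> Raster:
    """Exact Euclidean distance (m) from each cell center to the nearest mask cell."""
    m = _binary(mask)
    if not m.any():
        raise ValueError("distance_to: mask is empty")
    dist = ndimage.distance_transform_edt(~m, sampling=mask.cell_size)
    return mask.like(dist)


def compute_metrics(
    habitat: Raster,
    roads: Raster,
    urban: Raster,
    veg_index: Raster,
    window_m: float = 1000.0,
    gap_m: float = 180.0,
) -> dict[str, Raster]:
    """All six per-cell metrics, keyed by name."""
    frag, _ = fragment_sizes(habitat)
    return {
        "prop_habitat": proportion_habitat(habitat, window_m=window_m),
        "fragment_size": frag,
        "connectivity": functional_connectivity(habitat, gap_m=gap_m),
        "homogeneity": homogeneity(veg_index),
        "dist_urban": distance_to(urban),
        "dist_road": distance_to(roads),
    }
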