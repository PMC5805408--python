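"""Spatial mapping of per-cell metrics against a pole landmark.

The pole landmark (the centroid of the polar-cell pair) anchors all
gradient analyses: any per-cell metric can be binned by the Euclidean
distance of the cell centroid to the pole, and an exponential decay
``metric(d) = baseline + A * exp(-d / lambda)`` can be fitted to the bin
means to estimate the gradient amplitude and length scale.  Also here:
AP line-profile quantification (wide-band relative intensity along a
freehand path), cell counting along the AP chord, cell volume from mean
surface x mean height, and per-cell metric heat maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import matplotlib
from matplotlib import colors
from scipy.optimize import curve_fit
from skimage.draw import line as draw_line

from .errors import InputError

__all__ = [
    "GradientProfile",
    "metric_vs_distance",
    "relative_apical_surface",
    "line_profile",
    "count_cells_on_ap_line",
    "cell_volume",
    "heatmap_export",
]


@dataclass
class GradientProfile:
    """Binned metric-vs-distance profile with an optional exponential fit.

    ``bins`` columns: ``bin_center_um, metric_mean, metric_sd, n_cells``.
    ``fit`` is None or a dict with ``amplitude_at_pole, baseline,
    decay_length_um`` from least squares on the bin means.
    """

    bins: pd.DataFrame
    fit: dict | None


def _exp_decay(d, baseline, amplitude, lam):
    return baseline + amplitude * np.exp(-d / lam)


def metric_vs_distance(
    metric,
    centroids_um,
    pole_um,
    bin_width_um: float = 10.0,
    fit: bool = True,
    min_bin_n: int = 3,
) -> GradientProfile:
    """Bin a per-cell metric by distance from the pole landmark.

    Distances are Euclidean in the projection plane.  Bins are
    fixed-width from 0; a trailing partial bin is kept only with at least
    ``min_bin_n`` cells.  With ``fit``, ``baseline + A*exp(-d/lambda)``
    is fitted to the bin means by least squares (skipped, with a warning,
    when fewer than 3 bins are populated).
    """
    metric = np.asarray(metric, dtype=float)
    centroids = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    if len(metric) == 0:
        raise InputError("no cells supplied")
    if centroids.shape[0] != len(metric) or centroids.shape[1] != 2:
        raise InputError("centroids must be (n, 2) matching metric length")
    pole = np.asarray(pole_um, dtype=float)
    dist = np.hypot(centroids[:, 0] - pole[0], centroids[:, 1] - pole[1])

    n_bins = int(np.ceil(dist.max() / bin_width_um)) or 1
    idx = np.minimum((dist / bin_width_um).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = metric[idx == b]
        if len(sel) == 0:
            continue
        is_last = b == n_bins - 1
        if is_last and len(sel) < min_bin_n and n_bins > 1:
            continue
        rows.append(
            {
                "bin_center_um": (b + 0.5) * bin_width_um,
                "metric_mean": float(sel.mean()),
                "metric_sd": float(sel.std(ddof=1)) if len(sel) > 1 else 0.0,
                "n_cells": int(len(sel)),
            }
        )
    bins = pd.DataFrame(rows)

    fit_result = None
    if fit:
        if len(bins) < 3:
            warnings.warn(
                "fewer than 3 populated bins; exponential fit skipped",
                stacklevel=2,
            )
        else:
            d = bins.bin_center_um.to_numpy()
            y = bins.metric_mean.to_numpy()
            span = max(y.max() - y.min(), 1e-12)
            p0 = (y.min(), span, max(d.max() / 3.0, bin_width_um))
            # weight bin means by their standard errors (pooled sd floor
            # guards against lucky zero-variance bins)
            sd = bins.metric_sd.to_numpy().astype(float)
            sd = np.maximum(sd, np.median(sd[sd > 0]) if (sd > 0).any() else 1.0)
            sem = sd / np.sqrt(bins.n_cells.to_numpy())
            try:
                popt, _ = curve_fit(
                    _exp_decay,
                    d,
                    y,
                    p0=p0,
                    sigma=sem,
                    absolute_sigma=False,
                    bounds=(
                        [-np.inf, 0.0, bin_width_um / 10.0],
                        [np.inf, np.inf, 100.0 * d.max()],
                    ),
                    maxfev=10000,
                )
                fit_result = {
                    "baseline": float(popt[0]),
                    "amplitude_at_pole": float(popt[1]),
                    "decay_length_um": float(popt[2]),
                }
            except RuntimeError:
                warnings.warn("exponential fit did not converge", stacklevel=2)
    return GradientProfile(bins=bins, fit=fit_result)


def relative_apical_surface(
    areas_um2, centroids_um, pole_um, bin_width_um: float = 10.0, **kwargs
) -> GradientProfile:
    """Profile of apical surface relative to the smallest cell (= 1)."""
    areas = np.asarray(areas_um2, dtype=float)
    if len(areas) == 0:
        raise InputError("no cells supplied")
    if np.any(areas <= 0):
        raise InputError("areas must be > 0")
    rel = areas / areas.min()
    return metric_vs_distance(rel, centroids_um, pole_um, bin_width_um, **kwargs)


def line_profile(
    image: np.ndarray, path_points, width_px: int = 15
) -> np.ndarray:
    """Relative intensity profile along a wide freehand line.

    The path (sequence of (x, y) pixel points) is resampled to ~1 px
    steps; at each station the intensity is averaged over ``width_px``
    nearest-pixel samples along the local perpendicular, and the profile
    is divided by its own mean, so the result has mean 1.  Stations whose
    band leaves the image are clipped to the image with a warning.
    """
    image = np.asarray(image, dtype=float)
    pts = np.atleast_2d(np.asarray(path_points, dtype=float))
    if pts.shape[0] < 2 or pts.shape[1] != 2:
        raise InputError("path needs >= 2 (x, y) points")
    if width_px < 1:
        raise InputError("width_px must be >= 1")
    # resample to unit arc length
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.r_[0.0, np.cumsum(seglen)]
    if s[-1] == 0:
        raise InputError("path has zero length")
    stations = np.arange(0.0, s[-1] + 0.5, 1.0)
    px = np.interp(stations, s, pts[:, 0])
    py = np.interp(stations, s, pts[:, 1])
    tx = np.gradient(px)
    ty = np.gradient(py)
    norm = np.hypot(tx, ty)
    nx, ny = -ty / norm, tx / norm
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    sx = px[:, None] + nx[:, None] * offsets[None, :]
    sy = py[:, None] + ny[:, None] * offsets[None, :]
    ix = np.round(sx).astype(int)
    iy = np.round(sy).astype(int)
    h, w = image.shape
    if (ix < 0).any() or (ix >= w).any() or (iy < 0).any() or (iy >= h).any():
        warnings.warn("line band leaves the image; clipped", stacklevel=2)
        ix = np.clip(ix, 0, w - 1)
        iy = np.clip(iy, 0, h - 1)
    prof = image[iy, ix].mean(axis=1)
    return prof / prof.mean()


def count_cells_on_ap_line(
    labels: np.ndarray, pole_a, pole_b, exclude_labels=()
) -> int:
    """Number of distinct cells crossed by the discrete AP chord.

    ``pole_a``/``pole_b`` are (x, y) pixel coordinates; labels in
    ``exclude_labels`` (e.g. the polar cells themselves) and background
    (0) are not counted.  Returns 0 with a warning when the segment only
    touches background.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    for p in (pole_a, pole_b):
        if not (0 <= p[0] < w and 0 <= p[1] < h):
            raise InputError(f"pole {p} outside image bounds {w}x{h}")
    rr, cc = draw_line(
        int(round(pole_a[1])), int(round(pole_a[0])),
        int(round(pole_b[1])), int(round(pole_b[0])),
    )
    hit = np.unique(labels[rr, cc])
    hit = hit[(hit > 0) & ~np.isin(hit, list(exclude_labels))]
    if hit.size == 0:
        warnings.warn("AP segment crosses only background", stacklevel=2)
    return int(hit.size)


def cell_volume(mean_apical_surface_um2: float, mean_height_um: float) -> float:
    """Cell volume as mean apical surface times mean height (µm³)."""
    if mean_apical_surface_um2 <= 0 or mean_height_um <= 0:
        raise InputError("surface and height must be > 0")
    return float(mean_apical_surface_um2 * mean_height_um)


def heatmap_export(
    labels: np.ndarray,
    metric_by_label: dict,
    colormap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
    missing_color=(0.5, 0.5, 0.5),
) -> tuple[np.ndarray, dict]:
    """Paint each cell by its metric value; background black.

    Returns an (H, W, 3) float RGB image and a colour-scale metadata dict
    (colormap name, vmin, vmax).  Labels without a metric get a neutral
    grey and a warning.
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    missing = [int(v) for v in present if v not in metric_by_label]
    if missing:
        warnings.warn(
            f"{len(missing)} labels lack a metric value; painted neutral",
            stacklevel=2,
        )
    vals = np.array(
        [metric_by_label[k] for k in present if k in metric_by_label], float
    )
    if vals.size == 0:
        raise InputError("no metric values for any label")
    lo = vals.min() if vmin is None else vmin
    hi = vals.max() if vmax is None else vmax
    norm = colors.Normalize(vmin=lo, vmax=hi if hi > lo else lo + 1.0)
    mapper = matplotlib.colormaps[colormap]
    out = np.zeros(labels.shape + (3,), dtype=float)
    for lab in present:
        if int(lab) in missing:
            out[labels == lab] = missing_color
        else:
            out[labels == lab] = mapper(norm(metric_by_label[lab]))[:3]
    meta = {"colormap": colormap, "vmin": float(lo), "vmax": float(hi)}
    return out, meta
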