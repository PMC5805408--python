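"""Cell segmentation, tracking and bond extraction on membrane channels.

Segmentation is marker-controlled watershed: the junctional (membrane)
channel is Gaussian-blurred, regional minima deeper than ``h_minima_depth``
seed one marker per cell interior, and the watershed of the blurred image
recovers cell outlines.  Tracking is greedy maximal-overlap (IoU)
assignment between consecutive frames — adequate when sampling is fast
enough that displacements are small against the cell diameter.

Areas and lengths are always reported calibrated (µm, µm²); pixel
coordinates are 0-based; the AP axis is the image x axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology, segmentation

from .errors import InputError, LookupError_, SegmentationError
from .io import ImageStack

__all__ = [
    "SegmentationParams",
    "CellTrack",
    "max_project",
    "segment_frame",
    "segment_stack",
    "track_cells",
    "measure_cell",
    "measure_frame",
    "measure_tracks",
    "tracks_to_table",
    "table_to_tracks",
    "extract_bonds",
    "match_labels",
]


def max_project(zstack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (Z, H, W) stack along z."""
    zstack = np.asarray(zstack)
    if zstack.ndim == 2:
        return zstack.copy()
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise InputError(f"need a (Z, H, W) stack with >= 1 plane, got {zstack.shape}")
    return zstack.max(axis=0)


@dataclass(frozen=True)
class SegmentationParams:
    """Watershed segmentation parameters.

    blur_sigma : Gaussian pre-blur, pixels.
    h_minima_depth : depth threshold for seed minima (image intensity units).
    min_area_um2, max_area_um2 : size gate on accepted regions.
    clear_border : drop cells touching the image border.
    """

    blur_sigma: float = 1.5
    h_minima_depth: float = 0.1
    min_area_um2: float = 4.0
    max_area_um2: float = 400.0
    clear_border: bool = True


def segment_frame(
    image: np.ndarray,
    pixel_size_um: float,
    params: SegmentationParams = SegmentationParams(),
    allow_empty: bool = False,
) -> np.ndarray:
    """Segment one membrane-channel frame into a label mask.

    Returns an integer mask with 0 on watershed lines/background and
    sequential labels 1..n.  Raises :class:`SegmentationError` when no
    seeds are found (unless ``allow_empty``).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InputError(f"expected a 2-D image, got shape {image.shape}")
    blurred = ndimage.gaussian_filter(image, params.blur_sigma)
    seeds = morphology.h_minima(blurred, params.h_minima_depth)
    markers, n_seeds = ndimage.label(seeds)
    if n_seeds == 0:
        if allow_empty:
            return np.zeros(image.shape, dtype=np.int32)
        raise SegmentationError(
            "no watershed seeds found "
            f"(blur_sigma={params.blur_sigma}, h={params.h_minima_depth}, "
            f"image range [{image.min():.3g}, {image.max():.3g}])"
        )
    labels = segmentation.watershed(blurred, markers, watershed_line=True)
    labels[labels < 0] = 0
    if params.clear_border:
        labels = segmentation.clear_border(labels)
    # size gate in calibrated units
    areas = np.bincount(labels.ravel())
    px2 = pixel_size_um**2
    bad = np.flatnonzero(
        (areas * px2 < params.min_area_um2) | (areas * px2 > params.max_area_um2)
    )
    labels[np.isin(labels, bad[bad > 0])] = 0
    out, _, _ = segmentation.relabel_sequential(labels)
    return out.astype(np.int32)


def segment_stack(
    stack: ImageStack,
    channel: str = "membrane",
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Segment every frame of a stack's membrane channel; (T, H, W) labels."""
    frames = stack.channel(channel)
    return np.stack(
        [
            segment_frame(f, stack.pixel_size_um, params, allow_empty=True)
            for f in frames
        ]
    )


# --------------------------------------------------------------------------
# tracking
# --------------------------------------------------------------------------

def _overlap_table(a: np.ndarray, b: np.ndarray) -> pd.DataFrame:
    """Pairwise pixel overlaps between two label masks (excluding 0-0)."""
    mask = (a > 0) | (b > 0)
    pairs = a[mask].astype(np.int64) * (b.max() + 1) + b[mask]
    uniq, counts = np.unique(pairs, return_counts=True)
    la, lb = np.divmod(uniq, b.max() + 1)
    return pd.DataFrame({"a": la, "b": lb, "inter": counts})


def track_cells(
    masks: Sequence[np.ndarray] | np.ndarray, min_iou: float = 0.3
) -> np.ndarray:
    """Link label masks across frames by greedy maximal-overlap assignment.

    Each frame's labels are matched to the previous frame's tracked
    labels in decreasing order of IoU; a track ends when its best match
    falls below ``min_iou``, and unmatched regions start new tracks.
    Returns a (T, H, W) stack relabelled with stable cell ids.
    """
    masks = np.asarray(masks)
    if masks.ndim != 3 or masks.shape[0] < 2:
        raise InputError("need >= 2 frames of 2-D label masks")
    out = np.zeros_like(masks, dtype=np.int32)
    first, _, _ = segmentation.relabel_sequential(masks[0])
    out[0] = first
    next_id = int(out[0].max()) + 1
    for t in range(1, len(masks)):
        prev, cur = out[t - 1], masks[t]
        areas_prev = np.bincount(prev.ravel())
        areas_cur = np.bincount(cur.ravel())
        ov = _overlap_table(prev, cur)
        ov = ov[(ov.a > 0) & (ov.b > 0)]
        ov = ov.assign(
            iou=ov.inter
            / (areas_prev[ov.a] + areas_cur[ov.b] - ov.inter)
        ).sort_values("iou", ascending=False)
        mapping: dict[int, int] = {}
        used_prev: set[int] = set()
        for row in ov.itertuples():
            if row.iou < min_iou:
                break
            if row.b in mapping or row.a in used_prev:
                continue
            mapping[row.b] = row.a
            used_prev.add(row.a)
        frame = np.zeros_like(cur, dtype=np.int32)
        for lab in np.unique(cur):
            if lab == 0:
                continue
            if lab in mapping:
                frame[cur == lab] = mapping[lab]
            else:
                frame[cur == lab] = next_id
                next_id += 1
        out[t] = frame
    return out


# --------------------------------------------------------------------------
# measurement
# --------------------------------------------------------------------------

@dataclass
class CellTrack:
    """One cell's per-frame apical measurements over a contiguous frame range."""

    cell_id: int
    frames: np.ndarray
    area_um2: np.ndarray
    centroid_x_um: np.ndarray
    centroid_y_um: np.ndarray
    bbox_ap_um: np.ndarray
    bbox_ml_um: np.ndarray
    sigma_ap_um: np.ndarray | None = None
    sigma_ml_um: np.ndarray | None = None
    intensity: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def measure_frame(
    labels: np.ndarray,
    channels: Mapping[str, np.ndarray],
    pixel_size_um: float,
) -> pd.DataFrame:
    """Measure every labelled region of one frame.

    Returns a table with ``cell_id, area_um2, centroid_x_um, centroid_y_um,
    bbox_ap_um, bbox_ml_um`` and one ``mean_<channel>`` column per channel.
    AP extent is along x (columns), ML along y (rows).
    """
    names = list(channels)
    intensity = (
        np.stack([np.asarray(channels[n], dtype=float) for n in names], axis=-1)
        if names
        else None
    )
    props = measure.regionprops_table(
        labels,
        intensity_image=intensity,
        properties=("label", "area", "centroid", "bbox", "moments_central")
        + (("intensity_mean",) if names else ()),
    )
    df = pd.DataFrame(props)
    ps = pixel_size_um
    mu00 = df["moments_central-0-0"]
    out = pd.DataFrame(
        {
            "cell_id": df["label"].astype(int),
            "area_um2": df["area"] * ps**2,
            "centroid_x_um": df["centroid-1"] * ps,
            "centroid_y_um": df["centroid-0"] * ps,
            "bbox_ap_um": (df["bbox-3"] - df["bbox-1"]) * ps,
            "bbox_ml_um": (df["bbox-2"] - df["bbox-0"]) * ps,
            # RMS extents from second central moments (rows = ML, cols = AP);
            # smoother than bounding boxes, which are corner-dominated
            "sigma_ap_um": np.sqrt(df["moments_central-0-2"] / mu00) * ps,
            "sigma_ml_um": np.sqrt(df["moments_central-2-0"] / mu00) * ps,
        }
    )
    for i, n in enumerate(names):
        key = f"intensity_mean-{i}"
        if key not in df:
            key = "intensity_mean"
        out[f"mean_{n}"] = df[key]
    return out


def measure_cell(
    labels: np.ndarray,
    channels: Mapping[str, np.ndarray],
    cell_id: int,
    pixel_size_um: float,
) -> pd.Series:
    """Measurements for a single cell id; raises on a missing label."""
    df = measure_frame(labels, channels, pixel_size_um)
    row = df[df.cell_id == cell_id]
    if row.empty:
        raise LookupError_(f"cell_id {cell_id} not present in mask")
    return row.iloc[0]


def measure_tracks(tracked: np.ndarray, stack: ImageStack) -> pd.DataFrame:
    """Per-frame measurements of a tracked label stack against all channels.

    Long-format table: one row per (cell_id, frame).
    """
    frames = []
    for t in range(tracked.shape[0]):
        channels = {
            n: stack.data[t, i] for i, n in enumerate(stack.channel_names)
        }
        df = measure_frame(tracked[t], channels, stack.pixel_size_um)
        df.insert(1, "frame", t)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def tracks_to_table(tracks: Sequence[CellTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        d = {
            "cell_id": tr.cell_id,
            "frame": tr.frames,
            "area_um2": tr.area_um2,
            "centroid_x_um": tr.centroid_x_um,
            "centroid_y_um": tr.centroid_y_um,
            "bbox_ap_um": tr.bbox_ap_um,
            "bbox_ml_um": tr.bbox_ml_um,
        }
        if tr.sigma_ap_um is not None:
            d["sigma_ap_um"] = tr.sigma_ap_um
            d["sigma_ml_um"] = tr.sigma_ml_um
        for name, vals in tr.intensity.items():
            d[f"mean_{name}"] = vals
        rows.append(pd.DataFrame(d))
    return pd.concat(rows, ignore_index=True)


def table_to_tracks(
    table: pd.DataFrame, full_length_only: bool = False
) -> list[CellTrack]:
    """Build :class:`CellTrack` objects from a long-format track table.

    With ``full_length_only`` only tracks spanning every frame of the
    table are returned (the pulse-metric eligibility rule).
    """
    n_frames = table.frame.nunique()
    tracks = []
    for cid, grp in table.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        if full_length_only and len(grp) < n_frames:
            continue
        intensity = {
            c[len("mean_"):]: grp[c].to_numpy()
            for c in grp.columns
            if c.startswith("mean_")
        }
        tracks.append(
            CellTrack(
                cell_id=int(cid),
                frames=grp.frame.to_numpy(),
                area_um2=grp.area_um2.to_numpy(),
                centroid_x_um=grp.centroid_x_um.to_numpy(),
                centroid_y_um=grp.centroid_y_um.to_numpy(),
                bbox_ap_um=grp.bbox_ap_um.to_numpy(),
                bbox_ml_um=grp.bbox_ml_um.to_numpy(),
                sigma_ap_um=(
                    grp.sigma_ap_um.to_numpy() if "sigma_ap_um" in grp else None
                ),
                sigma_ml_um=(
                    grp.sigma_ml_um.to_numpy() if "sigma_ml_um" in grp else None
                ),
                intensity=intensity,
            )
        )
    return tracks


# --------------------------------------------------------------------------
# bonds
# --------------------------------------------------------------------------

_SHIFTS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_stack(labels: np.ndarray) -> np.ndarray:
    """(8, H, W) array of 8-neighbour labels, -1 outside the image."""
    h, w = labels.shape
    out = np.full((8, h, w), -1, dtype=np.int64)
    for k, (dy, dx) in enumerate(_SHIFTS8):
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        yd = slice(max(-dy, 0), h + min(-dy, 0))
        xd = slice(max(-dx, 0), w + min(-dx, 0))
        out[k][yd, xd] = labels[ys, xs]
    return out


def extract_bonds(
    labels: np.ndarray,
    channels: Mapping[str, np.ndarray],
    pixel_size_um: float,
    min_bond_px: int = 3,
    dilate_px: int = 0,
    end_trim_frac: float = 0.25,
) -> pd.DataFrame:
    """Extract cell-cell bonds (junction segments) from a label mask.

    Handles both watershed-line masks (0-valued ridges between cells) and
    touching-label masks.  A bond's pixels are the boundary pixels shared
    by exactly two cells; pixels where three or more cells meet
    (tricellular vertices) are excluded.  The bond angle is the axial
    orientation of the principal direction of its pixels relative to the
    AP (x) axis, folded into [0, 90] degrees.  Intensity is the mean over
    the bond pixels themselves (the intensity ridge), after trimming
    ``end_trim_frac`` of the bond length from each end (when enough
    pixels remain) so that intensity mixing around tricellular vertices
    does not contaminate the bond value; ``dilate_px`` widens the
    sampling band, which is more tolerant of a misregistered segmentation
    but dilutes junctional signal with cytoplasm.

    Returns a table ``cell_a, cell_b, angle_deg, length_um, n_px`` plus
    one ``mean_<channel>`` column per supplied channel; empty for masks
    with fewer than two cells.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    cols = ["cell_a", "cell_b", "angle_deg", "length_um", "n_px"] + [
        f"mean_{n}" for n in channels
    ]
    if len(ids) < 2:
        return pd.DataFrame(columns=cols)

    nb = _neighbor_stack(labels)
    h, w = labels.shape
    bond_of: dict[tuple[int, int], list] = {}

    ridge_mode = bool(
        (labels == 0).any()
        and not _any_touching(labels)
    )
    if ridge_mode:
        cand = np.argwhere(labels == 0)
        vals = nb[:, labels == 0].T  # (n0, 8)
    else:
        cand = np.argwhere(labels > 0)
        vals = nb[:, labels > 0].T

    own = labels[cand[:, 0], cand[:, 1]]
    for (y, x), v, me in zip(cand, vals, own):
        partners = np.unique(v[(v > 0) & (v != me)])
        if ridge_mode:
            if len(partners) == 2:
                key = (int(partners[0]), int(partners[1]))
                bond_of.setdefault(key, []).append((y, x))
        else:
            if len(partners) == 1:
                key = (int(min(me, partners[0])), int(max(me, partners[0])))
                bond_of.setdefault(key, []).append((y, x))

    rows = []
    chan_arrays = {n: np.asarray(a, dtype=float) for n, a in channels.items()}
    for (a, b), px in bond_of.items():
        if len(px) < min_bond_px:
            continue
        px = np.asarray(px)
        ys, xs = px[:, 0], px[:, 1]
        angle = _axial_angle_deg(xs, ys)
        # length: extent of projections onto the principal axis
        th = np.radians(angle)
        proj = xs * np.cos(th) + ys * np.sin(th)
        length = (proj.max() - proj.min() + 1.0) * pixel_size_um
        # central portion for intensity sampling (vertex exclusion)
        s_ys, s_xs = ys, xs
        if end_trim_frac > 0 and len(px) >= 6:
            lo_q = proj.min() + end_trim_frac * (proj.max() - proj.min())
            hi_q = proj.max() - end_trim_frac * (proj.max() - proj.min())
            core = (proj >= lo_q) & (proj <= hi_q)
            if core.sum() >= min_bond_px:
                s_ys, s_xs = ys[core], xs[core]
        row = {
            "cell_a": a,
            "cell_b": b,
            "angle_deg": angle,
            "length_um": length,
            "n_px": len(px),
        }
        if chan_arrays:
            if dilate_px > 0:
                band = np.zeros(labels.shape, dtype=bool)
                band[s_ys, s_xs] = True
                band = ndimage.binary_dilation(band, iterations=dilate_px)
                for n, arr in chan_arrays.items():
                    row[f"mean_{n}"] = float(arr[band].mean())
            else:
                for n, arr in chan_arrays.items():
                    row[f"mean_{n}"] = float(arr[s_ys, s_xs].mean())
        rows.append(row)
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["cell_a", "cell_b"], ignore_index=True
    )


def _any_touching(labels: np.ndarray) -> bool:
    for a, b in (
        (labels[:-1, :], labels[1:, :]),
        (labels[:, :-1], labels[:, 1:]),
    ):
        if np.any((a > 0) & (b > 0) & (a != b)):
            return True
    return False


def _axial_angle_deg(xs: np.ndarray, ys: np.ndarray) -> float:
    """Axial angle of a pixel set's principal axis vs x, in [0, 90] deg.

    Note image y increases downward; the fold to [0, 90] makes the
    convention immaterial for axial (undirected) angles.
    """
    x = xs - xs.mean()
    y = ys - ys.mean()
    mxx, myy, mxy = (x * x).mean(), (y * y).mean(), (x * y).mean()
    theta = 0.5 * np.arctan2(2 * mxy, mxx - myy)
    deg = np.degrees(theta) % 180.0
    return float(min(deg, 180.0 - deg))


# --------------------------------------------------------------------------
# evaluation helpers
# --------------------------------------------------------------------------

def match_labels(pred: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Match predicted labels to ground-truth labels by maximal overlap.

    For every true label, reports its best-overlapping predicted label
    and the IoU of the pair (pred 0 means unmatched).  Used to validate
    segmentation against synthetic ground truth.
    """
    ov = _overlap_table(pred, truth)
    ov = ov[(ov.a > 0) & (ov.b > 0)]
    areas_p = np.bincount(pred.ravel())
    areas_t = np.bincount(truth.ravel())
    ov = ov.assign(iou=ov.inter / (areas_p[ov.a] + areas_t[ov.b] - ov.inter))
    best = (
        ov.sort_values("iou", ascending=False)
        .drop_duplicates("b")
        .rename(columns={"b": "true_label", "a": "pred_label"})
    )
    all_true = pd.DataFrame({"true_label": np.unique(truth[truth > 0])})
    out = all_true.merge(
        best[["true_label", "pred_label", "iou"]], on="true_label", how="left"
    )
    out["pred_label"] = out.pred_label.fillna(0).astype(int)
    out["iou"] = out.iou.fillna(0.0)
    return out
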