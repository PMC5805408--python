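"""Planar-polarity quantification on cell-cell bonds and cell shapes.

Bonds (junction segments) are undirected, so all angle statistics here
are *axial*: angles are folded into [0°, 90°] relative to the AP axis for
intensity profiles, into [0°, 180°) for rose diagrams, and doubled before
any circular test or mean.  Planar polarization of a junctional protein
shows up as bond intensity depending on bond angle; its absence — the
relevant negative control for isotropically pulsing tissues — as a flat
relative-intensity profile.

The cell elongation tensor uses the log-nematic convention: per cell,
magnitude = ½·ln(major/minor axis) and orientation the major-axis axial
angle; the tissue tensor is the component-wise mean of
(m·cos 2θ, m·sin 2θ), so opposite orientations cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from skimage import measure

from .errors import InputError, InsufficientDataError

__all__ = [
    "AngleProfile",
    "ElongationTensor",
    "bond_angle_profile",
    "rose_histogram",
    "rose_plot",
    "division_orientation_test",
    "cell_elongation_tensor",
]


@dataclass
class AngleProfile:
    """Relative bond intensity by axial angle bin.

    ``bins`` columns: ``angle_lo, angle_hi, relative_intensity, n_bonds``;
    relative intensity is the bin mean divided by the global mean bond
    intensity, so the n-weighted mean over bins is 1.
    """

    bins: pd.DataFrame
    channel: str
    global_mean: float


def bond_angle_profile(
    bonds: pd.DataFrame, channel: str, bin_width_deg: float = 10.0
) -> AngleProfile:
    """Bin bond intensities by axial angle to the AP axis.

    ``bonds`` is a table from :func:`follipulse.segtrack.extract_bonds`
    (needs ``angle_deg`` and ``mean_<channel>``).  Bins partition
    [0°, 90°]; empty bins are reported with NaN intensity.
    """
    col = f"mean_{channel}"
    if col not in bonds.columns:
        raise InputError(f"bond table has no column {col!r}")
    if len(bonds) == 0:
        raise InputError("no bonds supplied")
    angles = bonds.angle_deg.to_numpy(float)
    vals = bonds[col].to_numpy(float)
    if np.any(~np.isfinite(vals)):
        raise InputError(f"non-finite intensities in {col}")
    gmean = vals.mean()
    n_bins = int(np.ceil(90.0 / bin_width_deg))
    idx = np.minimum((angles / bin_width_deg).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = vals[idx == b]
        rows.append(
            {
                "angle_lo": b * bin_width_deg,
                "angle_hi": min((b + 1) * bin_width_deg, 90.0),
                "relative_intensity": (
                    float(sel.mean() / gmean) if len(sel) else np.nan
                ),
                "n_bonds": int(len(sel)),
            }
        )
    return AngleProfile(
        bins=pd.DataFrame(rows), channel=channel, global_mean=float(gmean)
    )


def rose_histogram(
    angles_deg, bin_width_deg: float = 10.0, axial: bool = True
) -> pd.DataFrame:
    """Histogram of angles for a rose diagram.

    With ``axial`` (undirected lines: bonds, division axes) angles are
    folded into [0°, 180°); otherwise they are taken mod 360°.  Returns
    ``angle_lo, angle_hi, count`` with counts summing to the input size.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if np.any(~np.isfinite(angles)):
        raise InputError("angles must be finite")
    period = 180.0 if axial else 360.0
    folded = np.mod(angles, period)
    n_bins = int(np.ceil(period / bin_width_deg))
    idx = np.minimum((folded / bin_width_deg).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame(
        {
            "angle_lo": np.arange(n_bins) * bin_width_deg,
            "angle_hi": np.minimum((np.arange(n_bins) + 1) * bin_width_deg, period),
            "count": counts,
        }
    )


def rose_plot(hist: pd.DataFrame, ax=None, **bar_kwargs):
    """Polar bar plot of a rose histogram (bin size ∝ count)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.radians((hist.angle_lo + hist.angle_hi) / 2.0)
    widths = np.radians(hist.angle_hi - hist.angle_lo)
    ax.bar(centers, hist["count"], width=widths, bottom=0.0, **bar_kwargs)
    return ax


def division_orientation_test(angles_deg) -> tuple[pd.DataFrame, float]:
    """Rose bins plus a Rayleigh uniformity test on axial angles.

    Angles are doubled before the Rayleigh test (axial statistics);
    p > alpha means no detectable orientation bias of the division axes.
    Requires n >= 5.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if len(angles) < 5:
        raise InsufficientDataError(f"need >= 5 angles, got {len(angles)}")
    hist = rose_histogram(angles, axial=True)
    _, pval = pg.circ_rayleigh(np.radians(2.0 * np.mod(angles, 180.0)))
    return hist, float(pval)


@dataclass
class ElongationTensor:
    """Per-cell and tissue-level nematic elongation."""

    per_cell: pd.DataFrame  # cell_id, magnitude, orientation_deg
    magnitude: float  # tissue mean magnitude (nematic norm)
    orientation_deg: float  # tissue mean orientation, axial [0, 180)
    n_cells: int


def cell_elongation_tensor(labels: np.ndarray) -> ElongationTensor:
    """Elongation tensor of a segmented cell sheet.

    Per cell: principal axes from second central moments, magnitude
    ``0.5*ln(major/minor)`` and axial major-axis orientation (degrees
    from the x axis, in [0, 180)).  Tissue values come from averaging the
    nematic components (m·cos 2θ, m·sin 2θ) over cells, so randomly
    oriented or orthogonally paired cells cancel to magnitude ≈ 0.
    Single-pixel or degenerate cells are skipped with a warning.
    """
    labels = np.asarray(labels)
    props = measure.regionprops(labels)
    if not props:
        raise InputError("no cells in mask")
    rows = []
    skipped = 0
    for p in props:
        if p.area < 2 or p.axis_minor_length == 0:
            skipped += 1
            continue
        mag = 0.5 * np.log(p.axis_major_length / p.axis_minor_length)
        # skimage orientation is vs the row axis; convert to vs-x axial
        theta = np.mod(90.0 - np.degrees(p.orientation), 180.0)
        rows.append(
            {"cell_id": int(p.label), "magnitude": float(mag),
             "orientation_deg": float(theta)}
        )
    if skipped:
        warnings.warn(f"{skipped} degenerate cells skipped", stacklevel=2)
    if not rows:
        raise InputError("all cells degenerate")
    df = pd.DataFrame(rows)
    two_theta = np.radians(2.0 * df.orientation_deg.to_numpy())
    qx = float((df.magnitude * np.cos(two_theta)).mean())
    qy = float((df.magnitude * np.sin(two_theta)).mean())
    mag = float(np.hypot(qx, qy))
    orient = float(np.mod(np.degrees(np.arctan2(qy, qx)) / 2.0, 180.0))
    return ElongationTensor(
        per_cell=df, magnitude=mag, orientation_deg=orient, n_cells=len(df)
    )
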