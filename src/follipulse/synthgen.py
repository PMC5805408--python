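"""Synthetic follicle cohorts and pulsing-epithelium movies with ground truth.

The generator emulates the statistical structure of live imaging of the
early *Drosophila* follicular epithelium: a roughly regular apical cell
mosaic in which each cell's apical surface undergoes asynchronous
contraction-relaxation pulses (raised-cosine episodes of ~3 min separated
by exponentially distributed pauses), with a pulse-amplitude gradient
decaying exponentially with distance from a pole landmark, a myosin
channel whose per-cell signal anticipates the area contraction by a fixed
number of frames, optional mediolateral/anteroposterior pulse anisotropy,
and optional angular enrichment of junctional ("bond") intensity.

Geometry is kinematic, not mechanical: cells are cells of an anisotropic
power diagram (weighted Voronoi tessellation) whose per-frame weights are
iterated so each cell's rendered pixel area tracks its prescribed target
area.  The tessellation partitions the field every frame, so cell
identities persist and the true label stack is exact ground truth for
segmentation and tracking.

Axis convention: the image x axis is the anteroposterior (AP) axis and y
is mediolateral (ML); the pole sits at a stated pixel (default: centre of
the left edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GeometryError, SpecValidationError
from .io import ImageStack

__all__ = [
    "CohortSpec",
    "NoiseModel",
    "TissueSpec",
    "GroundTruth",
    "gen_follicle_cohort",
    "gen_pulsing_tissue",
    "gen_ellipse_mask",
]


# --------------------------------------------------------------------------
# follicle cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic follicle cohort.

    The cohort follows the linear elongation model: within a genotype the
    follicle long axis grows as ``slope * short_axis + intercept`` with
    additive Gaussian noise, so the slope of the long-on-short regression
    (the elongation coefficient) is the genotype's ground truth.

    Attributes
    ----------
    n_follicles : int
        Number of follicles, >= 2.
    short_axis_range : (float, float)
        Min/max short axis in micrometres; min > 0.
    slope : float
        True elongation coefficient (1 = no elongation).
    intercept : float
        Regression intercept, micrometres.
    noise_sd : float
        SD of additive Gaussian noise on the long axis, micrometres.
    genotype_label : str
        Cohort label carried into the output table.
    seed : int
        RNG seed; identical specs give identical cohorts.
    spacing : {"even", "random"}
        Whether short axes are evenly spaced across the range or drawn
        uniformly at random.
    """

    n_follicles: int
    short_axis_range: tuple[float, float] = (20.0, 80.0)
    slope: float = 1.6
    intercept: float = 0.0
    noise_sd: float = 0.0
    genotype_label: str = "wt"
    seed: int = 0
    spacing: str = "even"

    def __post_init__(self):
        if self.n_follicles < 2:
            raise SpecValidationError("n_follicles", "must be >= 2")
        lo, hi = self.short_axis_range
        if not (0 < lo <= hi):
            raise SpecValidationError(
                "short_axis_range", f"need 0 < min <= max, got ({lo}, {hi})"
            )
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd", "must be >= 0")
        if self.spacing not in ("even", "random"):
            raise SpecValidationError("spacing", "must be 'even' or 'random'")


def gen_follicle_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a table of follicle axis measurements.

    Returns a DataFrame with columns ``follicle_id, genotype, stage,
    short_axis_um, long_axis_um, source``.  Long axes are clipped so that
    ``long >= short`` always holds (an aspect ratio below 1 only relabels
    the axes).  Stages are assigned ordinally from the short axis (synthetic
    convention: the range maps linearly onto stages 2-7) so stage filters
    have something to act on; they carry no independent information.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.short_axis_range
    if spec.spacing == "even":
        short = np.linspace(lo, hi, spec.n_follicles)
    else:
        short = rng.uniform(lo, hi, spec.n_follicles)
    long = spec.slope * short + spec.intercept
    if spec.noise_sd > 0:
        long = long + rng.normal(0.0, spec.noise_sd, spec.n_follicles)
    long = np.maximum(long, short)
    # ordinal stage from size: early previtellogenic stages span the range
    frac = (short - lo) / (hi - lo) if hi > lo else np.zeros_like(short)
    stage = 2 + np.floor(frac * 5.999).astype(int)  # stages 2..7
    return pd.DataFrame(
        {
            "follicle_id": [
                f"{spec.genotype_label}_{i:03d}" for i in range(spec.n_follicles)
            ],
            "genotype": spec.genotype_label,
            "stage": stage,
            "short_axis_um": short,
            "long_axis_um": long,
            "source": "synthetic",
        }
    )


# --------------------------------------------------------------------------
# pulsing tissue
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Imaging noise: Gaussian read noise plus Poisson-like photon noise.

    ``photon_scale`` is the number of photons corresponding to intensity
    1.0; larger means less shot noise.  Set both to 0 for a noise-free
    render.
    """

    gaussian_sd: float = 0.03
    photon_scale: float = 200.0

    def __post_init__(self):
        if self.gaussian_sd < 0:
            raise SpecValidationError("gaussian_sd", "must be >= 0")
        if self.photon_scale < 0:
            raise SpecValidationError("photon_scale", "must be >= 0")


@dataclass(frozen=True)
class TissueSpec:
    """Parameters of a synthetic pulsing epithelium movie.

    Defaults mirror the acquisition the analysis is built for: 40 frames
    at 15 s intervals (10 min), pulses of ~180 s, and a pulse-amplitude
    gradient ``A(d) = baseline + (amplitude_at_pole - baseline) *
    exp(-d / decay_length)`` with distance ``d`` from the pole landmark
    in micrometres.

    Attributes
    ----------
    n_cells : int
        Number of cells tessellating the field.
    field_size : int or (int, int)
        Field edge length in pixels (rows, cols if a pair).
    pixel_size : float
        Micrometres per pixel.
    n_frames, frame_interval_s : int, float
        Movie length and temporal sampling.
    pulse_period_s : float
        Duration of one contraction-relaxation episode (raised cosine).
    mean_pause_s : float
        Mean of the exponential pause between episodes.
    amplitude_at_pole, baseline_amplitude : float
        Fractional area amplitude at the pole and far from it.
    decay_length : float
        Gradient length scale, micrometres.
    myosin_lag_frames : int
        Frames by which the myosin signal precedes the area response.
    myosin_gain : float
        Intensity per unit contraction drive in the myosin channel.
    anisotropy_ratio : float
        ML/AP pulse amplitude ratio (1 = isotropic pulses).
    bond_enrichment : float
        Intensity factor applied to membrane bonds whose axial angle to
        the AP axis falls in ``bond_enrichment_band`` (1 = unpolarized).
    bond_enrichment_band : (float, float)
        Angle band in degrees within [0, 90].
    pole_xy : (float, float) or None
        Pole pixel (x, y); default centre of the left (anterior) edge.
    noise_model : NoiseModel or None
        None renders noise-free images.
    seed : int
        RNG seed for geometry, phases and noise.
    """

    n_cells: int = 100
    field_size: int | tuple[int, int] = 256
    pixel_size: float = 0.2
    n_frames: int = 40
    frame_interval_s: float = 15.0
    pulse_period_s: float = 180.0
    mean_pause_s: float = 60.0
    amplitude_at_pole: float = 0.4
    baseline_amplitude: float = 0.1
    decay_length: float = 30.0
    myosin_lag_frames: int = 2
    myosin_gain: float = 1.0
    anisotropy_ratio: float = 1.0
    bond_enrichment: float = 1.0
    bond_enrichment_band: tuple[float, float] = (70.0, 90.0)
    pole_xy: tuple[float, float] | None = None
    noise_model: NoiseModel | None = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise SpecValidationError("n_cells", "must be >= 1")
        if self.n_frames < 2:
            raise SpecValidationError("n_frames", "must be >= 2")
        if self.pixel_size <= 0:
            raise SpecValidationError("pixel_size", "must be > 0")
        if not (self.amplitude_at_pole >= self.baseline_amplitude >= 0):
            raise SpecValidationError(
                "amplitude_at_pole",
                "need amplitude_at_pole >= baseline_amplitude >= 0",
            )
        if self.amplitude_at_pole >= 1:
            raise SpecValidationError(
                "amplitude_at_pole", "fractional amplitude must be < 1"
            )
        if self.decay_length <= 0:
            raise SpecValidationError("decay_length", "must be > 0")
        if self.anisotropy_ratio <= 0:
            raise SpecValidationError("anisotropy_ratio", "must be > 0")
        if self.bond_enrichment <= 0:
            raise SpecValidationError("bond_enrichment", "must be > 0")
        if self.myosin_lag_frames < 0:
            raise SpecValidationError("myosin_lag_frames", "must be >= 0")
        if self.pulse_period_s <= 0:
            raise SpecValidationError("pulse_period_s", "must be > 0")
        lo, hi = self.bond_enrichment_band
        if not (0 <= lo < hi <= 90):
            raise SpecValidationError(
                "bond_enrichment_band", "need 0 <= lo < hi <= 90"
            )

    @property
    def shape(self) -> tuple[int, int]:
        fs = self.field_size
        return (fs, fs) if np.isscalar(fs) else (int(fs[0]), int(fs[1]))

    @property
    def pole(self) -> tuple[float, float]:
        if self.pole_xy is not None:
            return tuple(float(v) for v in self.pole_xy)
        h, _ = self.shape
        return (0.0, h / 2.0)


@dataclass
class GroundTruth:
    """Truth tables for a synthetic movie.

    Attributes
    ----------
    label_stack : ndarray, shape (T, H, W)
        True cell labels per frame (1..n_cells; the tessellation
        partitions the field, so there is no background).
    per_cell : DataFrame
        One row per cell: ``cell_id, seed_x_um, seed_y_um,
        dist_to_pole_um, true_amplitude, true_mean_area_um2``.
    drive : ndarray, shape (T, n_cells)
        Contraction drive in [0, 1] governing each cell's area.
    myosin : ndarray, shape (T, n_cells)
        True per-cell myosin intensity (drive advanced by the lag).
    target_area_um2 : ndarray, shape (T, n_cells)
        Prescribed area series the tessellation tracks.
    shape_scale_ap, shape_scale_ml : ndarray, shape (T, n_cells)
        True per-frame linear scale factors along AP and ML.
    global_params : dict
        ``myosin_lag_frames, decay_length, anisotropy_ratio,
        bond_enrichment`` and the pole coordinate.
    """

    label_stack: np.ndarray
    per_cell: pd.DataFrame
    drive: np.ndarray
    myosin: np.ndarray
    target_area_um2: np.ndarray
    shape_scale_ap: np.ndarray
    shape_scale_ml: np.ndarray
    global_params: dict


def _lloyd_points(rng: np.random.Generator, n: int, shape: tuple[int, int],
                  iters: int = 4) -> np.ndarray:
    """Uniform random seeds regularized by Lloyd relaxation on a coarse grid."""
    h, w = shape
    pts = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    # coarse sample grid (every 2nd pixel) keeps this cheap
    ys, xs = np.mgrid[0.5:h:2.0, 0.5:w:2.0]
    grid = np.column_stack([xs.ravel(), ys.ravel()])
    for _ in range(iters):
        owner = cKDTree(pts).query(grid, k=1)[1]
        for i in range(n):
            sel = grid[owner == i]
            if len(sel):
                pts[i] = sel.mean(axis=0)
    return pts


def _pulse_drive(rng: np.random.Generator, n_cells: int, n_samples: int,
                 dt: float, period_s: float, mean_pause_s: float) -> np.ndarray:
    """Raised-cosine contraction episodes with exponential pauses.

    Returns drive in [0, 1], shape (n_samples, n_cells).  The process is
    started at a random point of its cycle so phases are asynchronous.
    """
    t_end = n_samples * dt
    times = np.arange(n_samples) * dt
    drive = np.zeros((n_samples, n_cells))
    for i in range(n_cells):
        t0 = -rng.uniform(0, period_s + mean_pause_s)
        while t0 < t_end:
            inside = (times >= t0) & (times < t0 + period_s)
            drive[inside, i] = 0.5 * (
                1 - np.cos(2 * np.pi * (times[inside] - t0) / period_s)
            )
            t0 += period_s + rng.exponential(mean_pause_s)
    return drive


def _assign_labels(d2, cand, weights, rows):
    """Power-diagram assignment over candidate seeds.

    d2 : (n_px, k) squared (possibly warped) distances to candidate seeds
    cand : (n_px, k) candidate seed indices
    rows : arange(n_px), preallocated
    returns flat owner index per pixel

    The distance part is constant while the weights are servoed, so the
    per-iteration cost is one gather, one subtraction and an argmin.
    """
    cost = d2 - weights[cand]
    return cand[rows, np.argmin(cost, axis=1)]


def gen_pulsing_tissue(spec: TissueSpec) -> tuple[ImageStack, GroundTruth]:
    """Generate a two-channel pulsing-epithelium movie plus ground truth.

    The membrane channel renders cell boundaries (bright junctional
    signal over a dim cytoplasmic background, Gaussian-blurred); the
    myosin channel fills each cell with its myosin intensity.  Per-frame
    cell geometry comes from an anisotropic power diagram whose weights
    are iterated until every cell's pixel area is within ~1% of its
    prescribed target, so the true label stack and true area series are
    mutually consistent.
    """
    h, w = spec.shape
    ps = spec.pixel_size
    mean_area_px = h * w / spec.n_cells
    if 2 * np.sqrt(mean_area_px / np.pi) < 3:
        raise GeometryError(
            f"field {h}x{w} px too small for {spec.n_cells} cells "
            "(mean cell diameter < 3 px)"
        )
    rng = np.random.default_rng(spec.seed)

    seeds = _lloyd_points(rng, spec.n_cells, (h, w))
    pole = np.asarray(spec.pole)
    dist_um = np.hypot(*(seeds - pole).T) * ps
    amp = spec.baseline_amplitude + (
        spec.amplitude_at_pole - spec.baseline_amplitude
    ) * np.exp(-dist_um / spec.decay_length)

    # base (relaxed) areas: mild lognormal size variation, sum = field area
    base = rng.lognormal(0.0, 0.12, spec.n_cells)
    base *= h * w / base.sum()

    lag = spec.myosin_lag_frames
    n_samp = spec.n_frames + lag
    drive = _pulse_drive(
        rng, spec.n_cells, n_samp, spec.frame_interval_s,
        spec.pulse_period_s, spec.mean_pause_s,
    )
    area_frac = 1.0 - amp[None, :] * drive[: spec.n_frames]  # (T, n)
    # anisotropy: split the area change between AP (x) and ML (y) so that
    # ln(ml scale)/ln(ap scale) = anisotropy_ratio
    rho = spec.anisotropy_ratio
    log_a = np.log(area_frac)
    scale_ap = np.exp(log_a / (1.0 + rho))
    scale_ml = np.exp(log_a * rho / (1.0 + rho))

    # candidate seeds per pixel (k nearest; anisotropy and weights are
    # perturbations of the Euclidean diagram, so candidates are stable)
    k = min(12, spec.n_cells)
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5]).astype(np.float32)
    _, cand = cKDTree(seeds).query(pix, k=k)
    cand = np.atleast_2d(cand)
    if cand.shape[0] == 1 and len(pix) > 1:
        cand = cand.T
    dx = (pix[:, 0:1] - seeds[cand, 0]).astype(np.float32)
    dy = (pix[:, 1:2] - seeds[cand, 1]).astype(np.float32)
    d2 = dx * dx + dy * dy
    rows = np.arange(len(pix))

    labels = np.empty((spec.n_frames, h, w), dtype=np.uint16)
    areas_px = np.empty((spec.n_frames, spec.n_cells))
    weights = np.zeros(spec.n_cells, dtype=np.float32)
    # weight update: moving a cell's boundary outward by dr needs a weight
    # increase of ~2R*dr; with dA = perimeter*dr = 2*pi*R*dr this gives
    # dw = dA/pi, damped for stability against simultaneous neighbours
    lr = 0.7 / np.pi
    px_x = pix[:, 0]
    px_y = pix[:, 1]
    n = spec.n_cells

    def _measure(owner):
        """Per-cell pixel count and RMS extents along x and y."""
        got = np.bincount(owner, minlength=n)
        denom = np.maximum(got, 1)
        out = []
        for coord in (px_x, px_y):
            s1 = np.bincount(owner, weights=coord, minlength=n)
            s2 = np.bincount(owner, weights=coord * coord, minlength=n)
            var = s2 / denom - (s1 / denom) ** 2
            out.append(np.sqrt(np.maximum(var, 1e-3)))
        return got, out[0], out[1]

    # area-servo convergence: relative tolerance with an absolute floor —
    # discrete pixel flips make sub-3-px accuracy unattainable for small
    # cells and would burn the full iteration budget every frame
    def _area_ok(err, target, rel):
        return (np.abs(err) <= np.maximum(3.0, rel * target)).all()

    # rest tessellation: converge weights at base areas, record per-cell
    # resting extents and which cells touch the field border
    for _ in range(120):
        owner = _assign_labels(d2, cand, weights, rows)
        got = np.bincount(owner, minlength=n)
        err = base - got
        if _area_ok(err, base, 0.003):
            break
        weights += (lr * err).astype(np.float32)
    owner = _assign_labels(d2, cand, weights, rows)
    _, rest_bx, rest_by = _measure(owner)
    lab0 = (owner + 1).reshape(h, w)
    border_ids = np.zeros(n, dtype=bool)
    border_ids[
        np.unique(np.r_[lab0[0], lab0[-1], lab0[:, 0], lab0[:, -1]]) - 1
    ] = True

    # Pass 1: isotropic tessellation.  Per frame, servo the power-diagram
    # weights until every cell's pixel area is within ~0.5% of target.
    isotropic = rho == 1.0
    weights_t = np.empty((spec.n_frames, n), dtype=np.float32)
    for t in range(spec.n_frames):
        target = base * area_frac[t]
        target *= h * w / target.sum()
        n_iter = 150 if t == 0 else 60
        for _ in range(n_iter):
            owner = _assign_labels(d2, cand, weights, rows)
            aerr = target - np.bincount(owner, minlength=n)
            if _area_ok(aerr, target, 0.005):
                break
            weights += (lr * aerr).astype(np.float32)
        weights_t[t] = weights
        if isotropic:
            owner = _assign_labels(d2, cand, weights, rows)
            labels[t] = (owner + 1).reshape(h, w).astype(np.uint16)
            areas_px[t] = np.bincount(owner, minlength=n)

    if not isotropic:
        # Pass 2: anisotropy via a smooth deviatoric displacement field.
        # In a power diagram, per-cell metric shear is under-expressed
        # because a boundary splits the difference between neighbouring
        # metrics (shear demands of adjacent cells are zero-sum), whereas
        # junctions in a real epithelium move *with* the contracting cell.
        # Each cell therefore contributes a pure-shear kernel
        # u_i(x) = g * s_i(t) * K_i(x) * (x - c_ix, -(y - c_iy)), with
        # s_i(t) = ln(area_frac) * (1 - rho) / (2 (1 + rho)) the prescribed
        # deviatoric log-strain, and the diagram is evaluated at x - u(x).
        # The scalar gain g is calibrated in whole-movie passes so the
        # realized population log-shear per unit prescribed equals 1
        # (kernel overlap and candidate truncation make the open-loop
        # transfer < 1); a scalar monotone feedback, hence stable.
        sigma_k = (1.3 * np.sqrt(base / np.pi)).astype(np.float32)
        kv = np.exp(
            -(dx * dx + dy * dy) / (2.0 * sigma_k[cand] ** 2)
        ).astype(np.float32)
        kv_dx = kv * dx
        kv_dy = kv * dy
        s_an = (
            np.log(area_frac) * (1.0 - rho) / (2.0 * (1.0 + rho))
        ).astype(np.float32)  # (T, n)
        ctrl = ~border_ids

        def _warped_d2(s):
            ux = (s[cand] * kv_dx).sum(axis=1)
            uy = -(s[cand] * kv_dy).sum(axis=1)
            dxs = dx - ux[:, None]
            dys = dy - uy[:, None]
            return dxs * dxs + dys * dys

        # Transfer is judged by the same statistic downstream estimators
        # use — the ratio of pooled cov(ln sigma, ln area) over interior
        # cells — and it is measured on the fully rendered configuration
        # (warp plus area re-servo, since the shear field is only
        # area-preserving to first order).  The last calibration pass is
        # the final render.
        target_dev = (rho - 1.0) / (rho + 1.0)
        g = 1.0
        warp_w = weights_t.copy()
        targets = base * area_frac
        targets *= (h * w) / targets.sum(axis=1, keepdims=True)
        SX = np.empty((spec.n_frames, n))
        SY = np.empty((spec.n_frames, n))
        for _cal in range(4):
            for t in range(spec.n_frames):
                wts = warp_w[t]
                d2w = _warped_d2(g * s_an[t])
                for _ in range(30):
                    owner = _assign_labels(d2w, cand, wts, rows)
                    aerr = targets[t] - np.bincount(owner, minlength=n)
                    if _area_ok(aerr, targets[t], 0.005):
                        break
                    wts += (lr * aerr).astype(np.float32)
                owner = _assign_labels(d2w, cand, wts, rows)
                labels[t] = (owner + 1).reshape(h, w).astype(np.uint16)
                areas_px[t], SX[t], SY[t] = _measure(owner)
            ok = ctrl & (areas_px > 0).all(axis=0)
            la = np.log(areas_px[:, ok])
            lx = np.log(SX[:, ok])
            ly = np.log(SY[:, ok])
            la -= la.mean(axis=0)
            lx -= lx.mean(axis=0)
            ly -= ly.mean(axis=0)
            rho_real = float((ly * la).sum() / (lx * la).sum())
            m = ((rho_real - 1.0) / (rho_real + 1.0)) / target_dev
            if abs(m - 1.0) < 0.03 or m <= 0.05:
                break
            g = min(g / max(m, 0.05), 6.0)

    if (areas_px.min(axis=0) <= 0).any():
        missing = np.where(areas_px.min(axis=0) <= 0)[0] + 1
        raise GeometryError(f"cells {missing.tolist()} vanished during rendering")

    myosin_series = 0.1 + spec.myosin_gain * drive[lag : lag + spec.n_frames]

    # Membrane render: analytic sub-pixel junction profile.  For every
    # pixel the signed distance to the nearest cell-cell bisector follows
    # from the best and second-best assignment costs (cost difference
    # over twice the seed separation); the junctional signal is a
    # Gaussian ridge in that distance.  This keeps ridge height
    # independent of bond orientation — a stair-stepped binary boundary
    # plus blur renders diagonal bonds dimmer than axis-aligned ones.
    bg = 0.1
    ridge_sigma = 0.9  # px
    band_lo, band_hi = spec.bond_enrichment_band
    rows_idx = np.arange(dx.shape[0])
    membrane = np.empty((spec.n_frames, h, w), dtype=np.float32)
    myosin_img = np.empty_like(membrane)
    for t in range(spec.n_frames):
        if isotropic:
            cost = d2 - weights_t[t][cand]
        else:
            cost = _warped_d2(g * s_an[t]) - warp_w[t][cand]
        top2 = np.argpartition(cost, 1, axis=1)[:, :2]
        c_a = cost[rows_idx, top2[:, 0]]
        c_b = cost[rows_idx, top2[:, 1]]
        swap = c_b < c_a
        first = np.where(swap, top2[:, 1], top2[:, 0])
        second = np.where(swap, top2[:, 0], top2[:, 1])
        j1 = cand[rows_idx, first]
        j2 = cand[rows_idx, second]
        margin = np.abs(c_b - c_a)
        sep = np.hypot(
            seeds[j1, 0] - seeds[j2, 0], seeds[j1, 1] - seeds[j2, 1]
        )
        d_bisector = margin / (2.0 * sep + 1e-9)
        amp_px = np.ones(len(j1), dtype=np.float32)
        if spec.bond_enrichment != 1.0:
            # boundary direction is perpendicular to the seed-seed vector
            normal_deg = np.degrees(
                np.arctan2(seeds[j2, 1] - seeds[j1, 1],
                           seeds[j2, 0] - seeds[j1, 0])
            )
            bond_deg = np.mod(normal_deg + 90.0, 180.0)
            bond_deg = np.minimum(bond_deg, 180.0 - bond_deg)
            in_band = (bond_deg >= band_lo) & (bond_deg <= band_hi)
            amp_px[in_band] = spec.bond_enrichment
        # Gaussian ridge plus a weak Lorentzian tail: junctional signal
        # bleeds into the cytoplasm in real imaging, and the tail keeps
        # interiors strictly decreasing away from junctions (an exactly
        # flat interior makes watershed flooding degenerate)
        profile = np.exp(-(d_bisector**2) / (2.0 * ridge_sigma**2)) + 0.08 / (
            1.0 + (d_bisector / (2.0 * ridge_sigma)) ** 2
        )
        membrane[t] = (bg + amp_px * profile).reshape(h, w)
        myosin_img[t] = myosin_series[t][labels[t] - 1]
    myosin_img = ndimage.gaussian_filter(myosin_img, (0, 1.0, 1.0))

    data = np.stack([membrane, myosin_img], axis=1)
    nm = spec.noise_model
    if nm is not None and (nm.photon_scale > 0 or nm.gaussian_sd > 0):
        if nm.photon_scale > 0:
            data = rng.poisson(data * nm.photon_scale) / nm.photon_scale
        if nm.gaussian_sd > 0:
            data = data + rng.normal(0.0, nm.gaussian_sd, data.shape)
        data = np.clip(data, 0.0, None)

    stack = ImageStack(
        data=data.astype(np.float32),
        channel_names=["membrane", "myosin"],
        pixel_size_um=ps,
        frame_interval_s=spec.frame_interval_s,
        meta={"generator": "gen_pulsing_tissue", "spec": _spec_dict(spec)},
    )
    per_cell = pd.DataFrame(
        {
            "cell_id": np.arange(1, spec.n_cells + 1),
            "seed_x_um": seeds[:, 0] * ps,
            "seed_y_um": seeds[:, 1] * ps,
            "dist_to_pole_um": dist_um,
            "true_amplitude": amp,
            "true_mean_area_um2": areas_px.mean(axis=0) * ps**2,
        }
    )
    truth = GroundTruth(
        label_stack=labels,
        per_cell=per_cell,
        drive=drive[: spec.n_frames],
        myosin=myosin_series,
        target_area_um2=(base * area_frac) * ps**2,
        shape_scale_ap=scale_ap,
        shape_scale_ml=scale_ml,
        global_params={
            "myosin_lag_frames": lag,
            "decay_length": spec.decay_length,
            "anisotropy_ratio": rho,
            "bond_enrichment": spec.bond_enrichment,
            "bond_enrichment_band": spec.bond_enrichment_band,
            "pole_xy_px": spec.pole,
            "pixel_size_um": ps,
            "frame_interval_s": spec.frame_interval_s,
        },
    )
    return stack, truth


def _spec_dict(spec) -> dict:
    out = {}
    for fname in spec.__dataclass_fields__:
        val = getattr(spec, fname)
        if isinstance(val, NoiseModel):
            val = {"gaussian_sd": val.gaussian_sd, "photon_scale": val.photon_scale}
        out[fname] = val
    return out


# --------------------------------------------------------------------------
# ellipse fixtures
# --------------------------------------------------------------------------

def gen_ellipse_mask(
    semi_major: float,
    semi_minor: float,
    orientation: float = 0.0,
    pixel_size: float = 1.0,
    margin_px: int = 3,
) -> tuple[np.ndarray, float]:
    """Rasterize a filled ellipse and return it with its true aspect ratio.

    Parameters are in micrometres (``pixel_size`` converts to pixels);
    ``orientation`` is the major-axis angle in degrees from the x axis.
    Raises :class:`GeometryError` if the minor semi-axis is below 5 px.
    """
    if not (semi_major >= semi_minor > 0):
        raise SpecValidationError(
            "semi_minor", "need semi_major >= semi_minor > 0"
        )
    b_px = semi_minor / pixel_size
    if b_px < 5:
        raise GeometryError(
            f"semi-minor axis is {b_px:.1f} px; need >= 5 px for a faithful mask"
        )
    a, b = semi_major / pixel_size, b_px
    th = np.radians(orientation)
    ex = np.sqrt((a * np.cos(th)) ** 2 + (b * np.sin(th)) ** 2)
    ey = np.sqrt((a * np.sin(th)) ** 2 + (b * np.cos(th)) ** 2)
    nx = int(np.ceil(2 * ex)) + 2 * margin_px
    ny = int(np.ceil(2 * ey)) + 2 * margin_px
    ys, xs = np.mgrid[0:ny, 0:nx]
    x = xs - (nx - 1) / 2.0
    y = ys - (ny - 1) / 2.0
    u = (x * np.cos(th) + y * np.sin(th)) / a
    v = (-x * np.sin(th) + y * np.cos(th)) / b
    mask = (u * u + v * v) <= 1.0
    return mask, semi_major / semi_minor
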