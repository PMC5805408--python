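"""Follicle-level shape statistics.

A follicle cohort is a table of long/short axis measurements (one row per
follicle, µm).  Elongation is quantified by the *elongation coefficient*:
the slope of the ordinary least-squares regression of the long axis on
the short axis across a cohort of previtellogenic follicles (stage < 8 by
default).  A slope of 1 means no elongation — spheres grow with
long == short — which makes the statistic robust to staging ambiguity in
round-follicle mutants.  Cohorts are compared by ANCOVA (separate-slopes
model ``long ~ short × genotype``) with Bonferroni-adjusted pairwise
slope contrasts.

Per-pole shape asymmetry is quantified by the extrapolated aspect ratio
(eAR): the follicle width is measured at 25% of its AP length from the
pole tip; for an ellipse that chord is exactly √3/2 of the full width, so
dividing the chord by √3/2 extrapolates a pole-specific width, and
length / extrapolated width is a pole-specific aspect ratio.  Anterior
and posterior eAR are compared by a two-way repeated-measures ANOVA
(within factor: pole; between factor: genotype) with two Bonferroni
pairwise pole contrasts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import ndimage
from skimage import measure

from .errors import GeometryError, InputError, InsufficientDataError

__all__ = [
    "ElongationFit",
    "AncovaResult",
    "PoleEAR",
    "PoleComparison",
    "validate_follicle_table",
    "fit_follicle_axes",
    "aspect_ratio",
    "elongation_coefficient",
    "compare_elongation",
    "extrapolated_AR",
    "compare_poles",
]

# exact chord factor: an ellipse's width at 25% of its length is
# sqrt(3)/2 of its full width
CHORD_FACTOR_25 = np.sqrt(3.0) / 2.0


REQUIRED_COLUMNS = ("long_axis_um", "short_axis_um")


def validate_follicle_table(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a follicle table (long/short axes in µm, long >= short > 0)."""
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise InputError(f"follicle table lacks required column {col!r}")
    bad = records[
        ~(
            (records.short_axis_um > 0)
            & (records.long_axis_um >= records.short_axis_um)
        )
    ]
    if len(bad):
        raise InputError(
            f"{len(bad)} records violate long >= short > 0 "
            f"(first offender: {bad.iloc[0].to_dict()})"
        )
    return records


# --------------------------------------------------------------------------
# axes and aspect ratio
# --------------------------------------------------------------------------

def fit_follicle_axes(
    mask: np.ndarray, pixel_size_um: float = 1.0
) -> tuple[float, float, float]:
    """Long axis, short axis (µm) and major-axis orientation of a mask.

    Axes are the equivalent-ellipse axis lengths from second central
    moments (length = 4·sqrt(eigenvalue of the normalized covariance));
    orientation is degrees of the major axis from the image x axis,
    counter-clockwise in image coordinates, in (-90, 90].
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 100:
        raise GeometryError(f"mask has {mask.sum()} px; need >= 100")
    lab, n = ndimage.label(mask)
    if n != 1:
        raise GeometryError(f"mask has {n} connected components; need exactly 1")
    props = measure.regionprops(lab)[0]
    long_ax = props.axis_major_length * pixel_size_um
    short_ax = props.axis_minor_length * pixel_size_um
    # skimage orientation: radians between major axis and the *row* axis;
    # convert to angle from x (columns), sign per standard math convention
    orient = 90.0 - np.degrees(props.orientation)
    if orient > 90.0:
        orient -= 180.0
    return float(long_ax), float(short_ax), float(orient)


def aspect_ratio(record: pd.Series | dict) -> float:
    """Follicle aspect ratio long/short; validates long >= short > 0."""
    long_ax = float(record["long_axis_um"])
    short_ax = float(record["short_axis_um"])
    if not (long_ax >= short_ax > 0):
        raise InputError(
            f"invalid record: long={long_ax}, short={short_ax} "
            "(need long >= short > 0)"
        )
    return long_ax / short_ax


# --------------------------------------------------------------------------
# elongation coefficient and ANCOVA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElongationFit:
    """OLS fit of long axis on short axis for one cohort."""

    genotype: str
    slope: float
    intercept: float
    n: int
    slope_ci: tuple[float, float]
    residual_sd: float

    @property
    def elongation_coefficient(self) -> float:
        return self.slope


def _stage_filter(records: pd.DataFrame, max_stage: int | None) -> pd.DataFrame:
    if max_stage is None or "stage" not in records.columns:
        return records
    stages = pd.to_numeric(records["stage"], errors="coerce")
    return records[stages.isna() | (stages < max_stage)]


def elongation_coefficient(
    records: pd.DataFrame,
    max_stage: int | None = 8,
    through_origin: bool = False,
) -> ElongationFit:
    """Elongation coefficient of one cohort: OLS slope of long on short.

    Records with stage >= ``max_stage`` are excluded (previtellogenic
    scoping; pass None to keep all).  ``through_origin`` drops the
    intercept.  Requires >= 3 records after filtering.
    """
    records = validate_follicle_table(records)
    records = _stage_filter(records, max_stage)
    if len(records) < 3:
        raise InsufficientDataError(
            f"{len(records)} records after stage filter; need >= 3"
        )
    y = records.long_axis_um.to_numpy(float)
    x = records.short_axis_um.to_numpy(float)
    X = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope_idx = 0 if through_origin else 1
    ci = fit.conf_int(alpha=0.05)[slope_idx]
    genotype = (
        str(records.genotype.iloc[0]) if "genotype" in records.columns else ""
    )
    return ElongationFit(
        genotype=genotype,
        slope=float(fit.params[slope_idx]),
        intercept=0.0 if through_origin else float(fit.params[0]),
        n=len(records),
        slope_ci=(float(ci[0]), float(ci[1])),
        residual_sd=float(np.sqrt(fit.scale)),
    )


@dataclass
class AncovaResult:
    """Separate-slopes ANCOVA across genotypes.

    ``slopes`` maps genotype -> fitted slope; ``interaction_p`` tests
    whether any slopes differ; ``pairwise`` has one row per genotype pair
    with the slope difference and Bonferroni-adjusted p-value.
    """

    slopes: dict[str, float]
    interaction_F: float
    interaction_p: float
    pairwise: pd.DataFrame
    n: int


def compare_elongation(
    records: pd.DataFrame,
    max_stage: int | None = 8,
    adjust: str = "bonferroni",
) -> AncovaResult:
    """Compare elongation coefficients of >= 2 genotypes by ANCOVA.

    Fits ``long ~ short * C(genotype)`` and reports per-genotype slopes,
    the slope-homogeneity (interaction) F test, and all pairwise
    slope-difference contrasts with Bonferroni (or no) adjustment.
    """
    records = validate_follicle_table(records)
    if "genotype" not in records.columns:
        raise InputError("records need a 'genotype' column")
    records = _stage_filter(records, max_stage)
    groups = sorted(records.genotype.unique())
    if len(groups) < 2:
        raise InputError(f"need >= 2 genotypes, got {groups}")
    for g in groups:
        if (records.genotype == g).sum() < 3:
            raise InsufficientDataError(f"genotype {g!r} has < 3 records")
    df = records.rename(
        columns={"long_axis_um": "long", "short_axis_um": "short"}
    )[["long", "short", "genotype"]].copy()
    full = smf.ols("long ~ short * C(genotype)", data=df).fit()
    reduced = smf.ols("long ~ short + C(genotype)", data=df).fit()
    comp = sm.stats.anova_lm(reduced, full)
    inter_F = float(comp["F"].iloc[1])
    inter_p = float(comp["Pr(>F)"].iloc[1])

    ref = groups[0]
    slopes: dict[str, float] = {}
    for g in groups:
        s = full.params["short"]
        if g != ref:
            s = s + full.params.get(f"short:C(genotype)[T.{g}]", 0.0)
        slopes[g] = float(s)

    names = list(full.params.index)

    def slope_vec(g: str) -> np.ndarray:
        v = np.zeros(len(names))
        v[names.index("short")] = 1.0
        if g != ref:
            v[names.index(f"short:C(genotype)[T.{g}]")] = 1.0
        return v

    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for a, b in pairs:
        tt = full.t_test(slope_vec(a) - slope_vec(b))
        p = float(np.squeeze(tt.pvalue))
        p_adj = min(1.0, p * len(pairs)) if adjust == "bonferroni" else p
        rows.append(
            {
                "genotype_a": a,
                "genotype_b": b,
                "slope_diff": slopes[a] - slopes[b],
                "t": float(np.squeeze(tt.tvalue)),
                "p_raw": p,
                "p_adj": p_adj,
            }
        )
    return AncovaResult(
        slopes=slopes,
        interaction_F=inter_F,
        interaction_p=inter_p,
        pairwise=pd.DataFrame(rows),
        n=len(df),
    )


# --------------------------------------------------------------------------
# extrapolated aspect ratio (eAR)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PoleEAR:
    """Per-pole extrapolated aspect ratio of one follicle."""

    pole: str  # "anterior" | "posterior"
    length_um: float
    width_at_25: float
    extrapolated_width: float
    eAR: float


def extrapolated_AR(
    mask: np.ndarray,
    pole: str,
    pixel_size_um: float = 1.0,
    orientation_deg: float | None = None,
) -> PoleEAR:
    """Extrapolated aspect ratio at one pole of a follicle mask.

    The mask is rotated so its major axis lies along x (anterior = -x);
    the width (ML extent) is measured one quarter of the AP length from
    the given pole's tip and divided by the ellipse chord factor √3/2 to
    extrapolate a full width for that pole; eAR = length / extrapolated
    width.  ``orientation_deg`` overrides the moment-based major-axis
    angle (degrees from x) when the AP axis is known externally.
    """
    if pole not in ("anterior", "posterior"):
        raise InputError(f"pole must be 'anterior' or 'posterior', not {pole!r}")
    mask = np.asarray(mask).astype(bool)
    if orientation_deg is None:
        _, _, orientation_deg = fit_follicle_axes(mask, pixel_size_um)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise GeometryError("empty mask")
    # rotate pixel-centre coordinates so the AP axis is x (no image
    # resampling, hence no interpolation artifacts)
    th = np.radians(orientation_deg)
    xr = xs * np.cos(th) + ys * np.sin(th)
    yr = -xs * np.sin(th) + ys * np.cos(th)
    # coverage length, corrected for the average grid dilation (~0.4 px
    # over random sub-pixel phases; exact alignment gives 0)
    x_min, x_max = xr.min(), xr.max()
    length_px = (x_max - x_min) + 1.0 - 0.4
    x_tip_a = x_min - 0.3
    x_tip_p = x_max + 0.3
    xq = (
        x_tip_a + 0.25 * length_px
        if pole == "anterior"
        else x_tip_p - 0.25 * length_px
    )
    # chord estimate: coverage area of a band around the 25% station over
    # the band width (pixels are unit squares, weighted by their overlap
    # with the band), then corrected for the ellipse profile curvature
    # across the band so a wide, low-noise band stays unbiased
    half_band = 2.5
    overlap = np.clip(
        np.minimum(xr + 0.5, xq + half_band)
        - np.maximum(xr - 0.5, xq - half_band),
        0.0,
        1.0,
    )
    w_band = overlap.sum() / (2.0 * half_band)
    if w_band <= 0:
        raise GeometryError(f"zero width at 25% length from {pole} pole")
    semi = length_px / 2.0
    x_c = 0.5 * (x_tip_a + x_tip_p)
    u = np.linspace(xq - half_band, xq + half_band, 41) - x_c
    profile = np.sqrt(np.clip(1.0 - (u / semi) ** 2, 0.0, None))
    station = np.sqrt(max(1.0 - ((xq - x_c) / semi) ** 2, 1e-9))
    w25_px = w_band * station / profile.mean()
    length = length_px * pixel_size_um
    w25 = w25_px * pixel_size_um
    extrap = w25 / CHORD_FACTOR_25
    return PoleEAR(
        pole=pole,
        length_um=float(length),
        width_at_25=float(w25),
        extrapolated_width=float(extrap),
        eAR=float(length / extrap),
    )


# --------------------------------------------------------------------------
# pole comparison
# --------------------------------------------------------------------------

@dataclass
class PoleComparison:
    """Two-way repeated-measures ANOVA of eAR over poles and genotypes."""

    anova: pd.DataFrame  # pingouin mixed_anova table
    pairwise: pd.DataFrame  # per-genotype pole contrasts, Bonferroni-adjusted
    n_follicles: int
    excluded: list


def compare_poles(ear_table: pd.DataFrame) -> PoleComparison:
    """Compare anterior vs posterior eAR across genotypes.

    ``ear_table`` columns: ``follicle_id, genotype, pole, eAR`` with pole
    in {anterior, posterior}.  Follicles missing either pole are excluded
    with a warning.  The omnibus test is a mixed ANOVA (within: pole,
    between: genotype); the post-hoc is one paired t-test per genotype
    (anterior vs posterior), Bonferroni-adjusted across genotypes.
    """
    required = {"follicle_id", "genotype", "pole", "eAR"}
    if not required.issubset(ear_table.columns):
        raise InputError(f"ear_table needs columns {sorted(required)}")
    counts = ear_table.groupby("follicle_id")["pole"].nunique()
    excluded = sorted(counts[counts < 2].index.tolist())
    if excluded:
        warnings.warn(
            f"{len(excluded)} follicles lack one pole and were excluded",
            stacklevel=2,
        )
    data = ear_table[~ear_table.follicle_id.isin(excluded)].copy()
    if data.follicle_id.nunique() < 3:
        raise InsufficientDataError("need >= 3 complete follicles")
    genotypes = sorted(data.genotype.unique())
    if len(genotypes) < 2:
        raise InputError("need >= 2 genotypes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=data,
            dv="eAR",
            within="pole",
            subject="follicle_id",
            between="genotype",
        )
    rows = []
    for g in genotypes:
        sub = data[data.genotype == g].pivot(
            index="follicle_id", columns="pole", values="eAR"
        )
        res = pg.ttest(sub["anterior"], sub["posterior"], paired=True)
        pcol = "p_val" if "p_val" in res.columns else "p-val"
        p = float(res[pcol].iloc[0])
        rows.append(
            {
                "genotype": g,
                "mean_anterior": float(sub["anterior"].mean()),
                "mean_posterior": float(sub["posterior"].mean()),
                "t": float(res["T"].iloc[0]),
                "p_raw": p,
                "p_adj": min(1.0, p * len(genotypes)),
                "n": len(sub),
            }
        )
    return PoleComparison(
        anova=aov,
        pairwise=pd.DataFrame(rows),
        n_follicles=data.follicle_id.nunique(),
        excluded=excluded,
    )
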