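"""Eye-specific segregation curves for two-channel dorsal-LGN images.

The dorsal lateral geniculate nucleus receives retinal input from both eyes;
during development the ipsilateral- and contralateral-eye axon territories
segregate into non-overlapping zones.  Segregation is quantified on a
two-channel image (ipsilateral and contralateral labels) by sweeping a
threshold over the contralateral channel: at each level t the fraction of the
(fixed, thresholded) ipsilateral region NOT overlapping the contralateral
mask is reported, giving the "fraction of segregated ipsilateral inputs"
curve.  Because the contralateral masks are nested in t, the curve is
non-decreasing.

A quality-control check uses the ventral LGN, which receives no contralateral
retinal input: images whose ventral fluorescence exceeds background are
rejected before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.restoration import rolling_ball

__all__ = [
    "FluoImage2D",
    "DLGNRoi",
    "SegregationParams",
    "SegregationCurve",
    "QCResult",
    "subtract_background",
    "qc_ventral_background",
    "ipsi_mask",
    "segregation_curve",
    "compare_curves",
    "analyze_scene",
]


@dataclass(frozen=True)
class FluoImage2D:
    """A two-channel fluorescence image on the 8-bit scale.

    ``ipsi`` and ``contra`` are 2D arrays of identical shape with intensities
    in [0, 255]; ``pixel_size`` (um) is carried as metadata only — segregation
    depends on pixel sets, not physical scale.
    """

    ipsi: np.ndarray
    contra: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self):
        ipsi = np.asarray(self.ipsi, dtype=float)
        contra = np.asarray(self.contra, dtype=float)
        object.__setattr__(self, "ipsi", ipsi)
        object.__setattr__(self, "contra", contra)
        if ipsi.shape != contra.shape or ipsi.ndim != 2:
            raise ValueError("channels must be 2D arrays of identical shape")
        for name, ch in (("ipsi", ipsi), ("contra", contra)):
            if ch.min() < 0 or ch.max() > 255:
                raise ValueError(f"{name} intensities must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ipsi.shape


@dataclass(frozen=True)
class DLGNRoi:
    """Dorsal-LGN outline and ventral QC region, as simple polygons.

    Vertices are (row, col) pixel coordinates, 0-based; masks are produced by
    even-odd rasterization of the polygon.  The boundary polygon is drawn to
    exclude the ventral LGN and the optic tract.
    """

    boundary: np.ndarray
    ventral_roi: np.ndarray

    def __post_init__(self):
        for name in ("boundary", "ventral_roi"):
            poly = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, poly)
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
                raise ValueError(f"{name} must be an (n>=3, 2) vertex array")

    def boundary_mask(self, shape) -> np.ndarray:
        return polygon2mask(shape, self.boundary)

    def ventral_mask(self, shape) -> np.ndarray:
        return polygon2mask(shape, self.ventral_roi)


@dataclass(frozen=True)
class SegregationParams:
    """Tunable parameters of the segregation pipeline.

    ``background_ball_radius`` is the rolling-ball radius in pixels (the
    classical protocol states a 200-pixel diameter); ``contra_thresholds``
    is the inclusive (start, stop, step) sweep of 8-bit levels; the single
    ipsilateral threshold must lie in the admissible 35-45 band.
    """

    background_ball_radius: int = 100
    contra_thresholds: tuple[int, int, int] = (0, 150, 5)
    ipsi_threshold: int = 40
    qc_tolerance: float = 1.5

    def __post_init__(self):
        start, stop, step = self.contra_thresholds
        if step <= 0 or stop < start:
            raise ValueError("contra threshold sweep must have step > 0, stop >= start")
        if not 35 <= self.ipsi_threshold <= 45:
            raise ValueError("ipsi_threshold must lie in the admissible band 35-45")
        if self.background_ball_radius < 1:
            raise ValueError("background_ball_radius must be >= 1")
        if self.qc_tolerance <= 0:
            raise ValueError("qc_tolerance must be positive")

    def threshold_grid(self) -> np.ndarray:
        start, stop, step = self.contra_thresholds
        return np.arange(start, stop + 1, step)


@dataclass(frozen=True)
class SegregationCurve:
    """Fraction of segregated ipsilateral inputs per contralateral threshold."""

    thresholds: np.ndarray
    fraction_segregated: np.ndarray
    ipsi_area: int

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        f = np.asarray(self.fraction_segregated, dtype=float)
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "fraction_segregated", f)
        if len(t) != len(f):
            raise ValueError("thresholds and fractions must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if f.min() < 0 or f.max() > 1:
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(np.diff(f) < -1e-12):
            raise ValueError("fraction_segregated must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fraction_segregated": self.fraction_segregated}
        )


@dataclass(frozen=True)
class QCResult:
    passed: bool
    ratio: float
    tolerance: float


def subtract_background(img: FluoImage2D, radius: int | None = None) -> FluoImage2D:
    """Rolling-ball background subtraction, per channel, clipped at zero.

    A flat image maps to all zeros; isolated features narrower than the ball
    are preserved.  ``radius`` defaults to 100 px (200-pixel ball diameter).
    """
    r = 100 if radius is None else int(radius)
    if r < 1:
        raise ValueError("radius must be >= 1")
    if r >= min(img.shape):
        raise ValueError(f"ball radius {r} does not fit in image of shape {img.shape}")
    out = []
    for ch in (img.ipsi, img.contra):
        bg = rolling_ball(ch, radius=r)
        out.append(np.clip(ch - bg, 0, None))
    return FluoImage2D(out[0], out[1], pixel_size=img.pixel_size)


def qc_ventral_background(
    img: FluoImage2D, roi: DLGNRoi, params: SegregationParams | None = None
) -> QCResult:
    """Check that ventral-LGN contralateral fluorescence is background-like.

    Returns the ratio of the mean contralateral intensity inside the ventral
    ROI to the mean intensity outside the whole LGN outline; images whose
    ratio exceeds the tolerance should be omitted from analysis.
    """
    params = params or SegregationParams()
    ventral = roi.ventral_mask(img.shape)
    if not ventral.any():
        raise ValueError("ventral ROI rasterizes to an empty mask")
    outside = ~roi.boundary_mask(img.shape) & ~ventral
    if not outside.any():
        raise ValueError("no background pixels outside the LGN outline")
    bg_mean = float(img.contra[outside].mean())
    ventral_mean = float(img.contra[ventral].mean())
    if bg_mean <= 0:
        # all-dark background: any ventral signal at all is suspicious
        ratio = np.inf if ventral_mean > 0 else 1.0
    else:
        ratio = ventral_mean / bg_mean
    return QCResult(passed=bool(ratio <= params.qc_tolerance), ratio=ratio,
                    tolerance=params.qc_tolerance)


def ipsi_mask(
    img: FluoImage2D, roi: DLGNRoi, params: SegregationParams | None = None
) -> np.ndarray:
    """Threshold the ipsilateral channel inside the dorsal-LGN outline."""
    params = params or SegregationParams()
    mask = (img.ipsi >= params.ipsi_threshold) & roi.boundary_mask(img.shape)
    if not mask.any():
        warnings.warn("ipsilateral mask is empty; segregation fractions undefined",
                      stacklevel=2)
    return mask


def segregation_curve(
    img: FluoImage2D, roi: DLGNRoi, params: SegregationParams | None = None
) -> SegregationCurve:
    """Sweep the contralateral threshold and measure segregated fractions.

    For each level t in the sweep, the contralateral mask is
    {contra >= t, contra > 0} within the LGN outline, and

        fraction(t) = 1 - |ipsi_mask & contra_mask(t)| / |ipsi_mask|.

    Zero-valued pixels are never part of a contralateral mask, so on a
    background-subtracted image the t = 0 point measures overlap with the
    labeled contralateral region rather than with the whole outline.
    """
    params = params or SegregationParams()
    boundary = roi.boundary_mask(img.shape)
    imask = (img.ipsi >= params.ipsi_threshold) & boundary
    area = int(imask.sum())
    if area == 0:
        raise ValueError("ipsilateral mask is empty: segregation is undefined")
    contra_in_roi = np.where(boundary, img.contra, -1.0)
    ipsi_contra_vals = contra_in_roi[imask]
    thresholds = params.threshold_grid()
    overlap = np.array(
        [((ipsi_contra_vals >= t) & (ipsi_contra_vals > 0)).sum() for t in thresholds]
    )
    fractions = 1.0 - overlap / area
    return SegregationCurve(thresholds=thresholds.astype(float),
                            fraction_segregated=fractions, ipsi_area=area)


def analyze_scene(
    img: FluoImage2D,
    roi: DLGNRoi,
    params: SegregationParams | None = None,
    subtract: bool = False,
) -> tuple[SegregationCurve, QCResult]:
    """QC then curve; raises if the image fails ventral-background QC."""
    params = params or SegregationParams()
    work = subtract_background(img, params.background_ball_radius) if subtract else img
    qc = qc_ventral_background(work, roi, params)
    if not qc.passed:
        raise ValueError(
            f"image failed ventral-background QC (ratio {qc.ratio:.2f} > "
            f"{qc.tolerance}); omit from analysis"
        )
    return segregation_curve(work, roi, params), qc


def compare_curves(
    group_a: list[SegregationCurve],
    group_b: list[SegregationCurve],
    labels: tuple[str, str] = ("A", "B"),
) -> dict:
    """Group mean +/- s.e.m. curves and a two-factor test on animal curves.

    Animals (one curve each) are the replication unit.  Returns per-threshold
    summaries for both groups and the group-effect row of a two-way
    (group x threshold) ANOVA fitted on the long-format animal-level
    fractions.
    """
    for name, grp in zip(labels, (group_a, group_b)):
        if len(grp) < 2:
            raise ValueError(f"group {name!r} needs at least 2 curves")
    grid = group_a[0].thresholds
    for c in list(group_a) + list(group_b):
        if len(c.thresholds) != len(grid) or np.any(c.thresholds != grid):
            raise ValueError("all curves must share a common threshold grid")

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = []
    summaries = {}
    for name, grp in zip(labels, (group_a, group_b)):
        stack = np.vstack([c.fraction_segregated for c in grp])
        summaries[name] = pd.DataFrame(
            {
                "threshold": grid,
                "mean": stack.mean(axis=0),
                "sem": stack.std(axis=0, ddof=1) / np.sqrt(len(grp)),
                "n": len(grp),
            }
        )
        for ai, c in enumerate(grp):
            for t, f in zip(grid, c.fraction_segregated):
                rows.append((name, f"{name}{ai}", float(t), float(f)))
    long = pd.DataFrame(rows, columns=["group", "animal", "threshold", "fraction"])
    model = smf.ols("fraction ~ C(group) + C(threshold)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    grp_row = table.loc["C(group)"]
    return {
        "summaries": summaries,
        "anova": table,
        "group_F": float(grp_row["F"]),
        "group_p": float(grp_row["PR(>F)"]),
        "group_df": (int(grp_row["df"]), int(table.loc["Residual", "df"])),
    }
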