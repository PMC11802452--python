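"""Synthetic two-channel dorsal-LGN scenes with a controllable overlap.

Each scene renders an ipsilateral and a contralateral retinal-input territory
(elliptical regions) into a two-channel 8-bit image, with a known fraction of
the ipsilateral territory lying inside the contralateral one.  The overlap is
controlled by bisecting the horizontal separation of the territories against
the rasterized masks, so the emitted ground truth is exact at pixel level.
A ventral strip of the image is reserved as background only, supporting the
ventral-fluorescence quality-control check of the analysis module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LGNSceneSpec", "LGNScene", "generate_lgn_pair", "random_lgn_spec"]


@dataclass(frozen=True)
class LGNSceneSpec:
    """Parameters of a synthetic labeled-LGN scene.

    ``signal_levels`` is (ipsi, contra) mean intensity on the 8-bit scale;
    ellipse radii are (row, col) semi-axes in pixels.  The contralateral
    territory sits at ``contra_center``; the ipsilateral territory is placed
    on the same row, displaced horizontally to achieve ``overlap_fraction``.
    """

    image_shape: tuple[int, int] = (192, 256)
    contra_center: tuple[float, float] = (80.0, 110.0)
    contra_radii: tuple[float, float] = (48.0, 60.0)
    ipsi_radii: tuple[float, float] = (22.0, 28.0)
    overlap_fraction: float = 0.5
    signal_levels: tuple[float, float] = (180.0, 120.0)
    background_level: float = 3.0
    noise_sd: float = 2.0
    ventral_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if min(self.signal_levels) <= self.background_level:
            raise ValueError("signal levels must exceed the background level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.ventral_fraction < 0.5:
            raise ValueError("ventral_fraction must be in (0, 0.5)")
        if self.ipsi_radii >= self.contra_radii:
            raise ValueError(
                "ipsi territory must be smaller than contra (full containment "
                "at overlap_fraction=1 must be possible)"
            )


@dataclass(frozen=True)
class LGNScene:
    """Rendered scene plus ground truth.

    ``image`` is (2, h, w) uint8 with channel 0 = ipsilateral and channel 1 =
    contralateral.  ``roi_boundary`` and ``ventral_roi`` are polygons in
    (row, col) pixel coordinates suitable for the analysis module.
    """

    image: np.ndarray
    ipsi_mask: np.ndarray
    contra_mask: np.ndarray
    achieved_overlap: float
    roi_boundary: np.ndarray
    ventral_roi: np.ndarray
    spec: LGNSceneSpec


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _overlap_ratio(shape, contra_mask, ipsi_center, ipsi_radii):
    ipsi = _ellipse_mask(shape, ipsi_center, ipsi_radii)
    area = int(ipsi.sum())
    return int((ipsi & contra_mask).sum()) / area, ipsi


def generate_lgn_pair(spec: LGNSceneSpec) -> LGNScene:
    """Render a two-channel LGN scene with ground-truth territory masks.

    The rendered image is territory signal plus background plus Gaussian
    noise, clipped to [0, 255].  The achieved overlap fraction (rasterized
    overlap area over ipsi area) is reported in the ground truth; bisection
    on the territory separation brings it within pixel-level discretization
    of the requested value.
    """
    h, w = spec.image_shape
    cy, cx = spec.contra_center
    dorsal_bottom = int(round(h * (1.0 - spec.ventral_fraction))) - 4

    contra = _ellipse_mask(spec.image_shape, spec.contra_center, spec.contra_radii)
    _check_in_bounds("contra", spec.contra_center, spec.contra_radii, w, dorsal_bottom)

    # solve for the horizontal displacement achieving the requested overlap
    if spec.overlap_fraction >= 1.0:
        d = 0.0
    elif spec.overlap_fraction <= 0.0:
        d = spec.contra_radii[1] + spec.ipsi_radii[1] + 3.0
    else:
        lo, hi = 0.0, spec.contra_radii[1] + spec.ipsi_radii[1] + 2.0
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            ratio, _ = _overlap_ratio(spec.image_shape, contra, (cy, cx + mid), spec.ipsi_radii)
            if ratio > spec.overlap_fraction:
                lo = mid
            else:
                hi = mid
        d = 0.5 * (lo + hi)

    ipsi_center = (cy, cx + d)
    _check_in_bounds("ipsi", ipsi_center, spec.ipsi_radii, w, dorsal_bottom)
    achieved, ipsi = _overlap_ratio(spec.image_shape, contra, ipsi_center, spec.ipsi_radii)

    rng = np.random.default_rng(spec.seed)
    img = np.full((2, h, w), spec.background_level, dtype=float)
    img[0][ipsi] = spec.signal_levels[0]
    img[1][contra] = spec.signal_levels[1]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    ventral_top = int(round(h * (1.0 - spec.ventral_fraction))) + 2
    roi_boundary = np.array(
        [[2, 2], [2, w - 3], [dorsal_bottom, w - 3], [dorsal_bottom, 2]], dtype=float
    )
    ventral_roi = np.array(
        [[ventral_top, 2], [ventral_top, w - 3], [h - 3, w - 3], [h - 3, 2]], dtype=float
    )
    return LGNScene(
        image=img,
        ipsi_mask=ipsi,
        contra_mask=contra,
        achieved_overlap=achieved,
        roi_boundary=roi_boundary,
        ventral_roi=ventral_roi,
        spec=spec,
    )


def _check_in_bounds(name, center, radii, width, dorsal_bottom):
    if (
        center[0] - radii[0] < 1
        or center[0] + radii[0] > dorsal_bottom - 1
        or center[1] - radii[1] < 1
        or center[1] + radii[1] > width - 2
    ):
        raise ValueError(
            f"{name} territory (center {center}, radii {radii}) exceeds the "
            f"dorsal image region (rows < {dorsal_bottom}, cols < {width})"
        )


def random_lgn_spec(seed: int, noise_sd: float = 2.0) -> LGNSceneSpec:
    """Draw a random valid scene spec (overlap, radii and seed vary)."""
    rng = np.random.default_rng(seed)
    overlap = float(rng.uniform(0.0, 1.0))
    contra_radii = (float(rng.uniform(42, 52)), float(rng.uniform(52, 64)))
    ipsi_radii = (float(rng.uniform(18, 26)), float(rng.uniform(22, 30)))
    return LGNSceneSpec(
        contra_radii=contra_radii,
        ipsi_radii=ipsi_radii,
        overlap_fraction=overlap,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
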