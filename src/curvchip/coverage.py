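"""Colony coverage kinetics on chip wells.

Cells seeded as a central droplet expand radially outward; coverage is
tracked as the area (mm^2) of the colony mask at each imaging day, the
coverage *rate* is the area gained per day between two time points
(conventionally day 3 to day 6, the main expansion window), and the
*fold change* compares a condition's rate with the flat-control rate.
Areas are bounded by the well disc (pi * a^2 ~ 50.27 mm^2 for a 4 mm
well); flat-control rates can sit near zero, so fold changes use a
configurable positive floor on the reference rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .imaging import otsu_mask

__all__ = [
    "WELL_RADIUS_MM",
    "CoverageSeries",
    "coverage_area",
    "coverage_rate",
    "fold_change",
    "mask_from_nuclei",
    "coverage_contour",
]

#: Default well radius of the chip, mm.
WELL_RADIUS_MM = 4.0

#: Default positive floor (mm^2/day) guarding fold changes against
#: division by near-zero reference rates.
DEFAULT_RATE_FLOOR = 0.1


def coverage_area(
    mask: np.ndarray,
    pixel_size_um: float,
    well_radius_mm: float | None = WELL_RADIUS_MM,
    well_center_px: tuple[float, float] | None = None,
) -> float:
    """Colony area in mm^2 from a binary mask: pixel count x pixel area.

    If ``well_radius_mm`` is given the mask is clipped to the well disc
    (centred at ``well_center_px``, default the image centre) so that
    spurious signal outside the well never inflates the area.
    """
    if not pixel_size_um or pixel_size_um <= 0:
        raise ValueError("pixel_size_um is required and must be positive")
    m = np.asarray(mask).astype(bool)
    if well_radius_mm is not None:
        h, w = m.shape
        cy, cx = well_center_px if well_center_px is not None else ((h - 1) / 2, (w - 1) / 2)
        yy, xx = np.ogrid[:h, :w]
        r_px = well_radius_mm * 1e3 / pixel_size_um
        m = m & ((yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2)
    return float(m.sum()) * (pixel_size_um * 1e-3) ** 2


@dataclass(frozen=True)
class CoverageSeries:
    """Coverage areas of one condition over imaging days."""

    days: tuple[float, ...]
    areas_mm2: tuple[float, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.days) != len(self.areas_mm2):
            raise ValueError("days and areas must have equal length")
        if any(a < 0 for a in self.areas_mm2):
            raise ValueError("coverage areas must be nonnegative")

    def area_at(self, day: float) -> float:
        try:
            return self.areas_mm2[self.days.index(day)]
        except ValueError:
            raise KeyError(f"day {day} not in series (have {self.days})") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.days, "area_mm2": self.areas_mm2, "condition": self.condition}
        )


def coverage_rate(series: CoverageSeries, t_start: float = 3.0, t_end: float = 6.0) -> float:
    """Coverage rate (mm^2/day) between two imaging days.

    ``(A(t_end) - A(t_start)) / (t_end - t_start)``; negative rates
    (colony shrinkage) are returned but flagged with a warning.
    """
    if t_end == t_start:
        raise ValueError("t_start and t_end must differ")
    rate = (series.area_at(t_end) - series.area_at(t_start)) / (t_end - t_start)
    if rate < 0:
        warnings.warn(
            f"negative coverage rate {rate:.3g} mm^2/day for {series.condition!r}",
            stacklevel=2,
        )
    return rate


def fold_change(
    rate: float, reference_rate: float, floor: float = DEFAULT_RATE_FLOOR
) -> float:
    """Rate relative to a (flat-control) reference rate.

    Reference rates below ``floor`` (mm^2/day) are raised to the floor —
    flat-control colonies can be nearly static, and an unguarded ratio
    would be dominated by measurement noise.  A non-positive floor is
    rejected.
    """
    if floor <= 0:
        raise ValueError("fold-change floor must be positive")
    if reference_rate <= 0 and reference_rate < floor:
        warnings.warn(
            f"reference rate {reference_rate:.3g} below floor {floor}; using floor",
            stacklevel=2,
        )
    return rate / max(reference_rate, floor)


def mask_from_nuclei(
    nuclei_image: np.ndarray,
    pixel_size_um: float,
    dilation_um: float = 30.0,
    largest_component_only: bool = True,
) -> np.ndarray:
    """Colony mask from a nuclei image.

    Nuclei are Otsu-thresholded, dilated by ``dilation_um`` (about one
    cell-body radius, so neighbouring cells merge into one colony
    footprint), optionally reduced to the largest connected component
    (discarding stray satellite debris), and enclosed holes are filled —
    a colony footprint is simply connected, while the dilated union of
    randomly placed nuclei always leaves small interior gaps.
    """
    if not pixel_size_um or pixel_size_um <= 0:
        raise ValueError("pixel_size_um is required and must be positive")
    mask = otsu_mask(np.asarray(nuclei_image, dtype=float))
    if not mask.any():
        return mask
    radius_px = max(1, int(round(dilation_um / pixel_size_um)))
    mask = ndimage.binary_dilation(
        mask, structure=_disk_structure(radius_px), iterations=1
    )
    if largest_component_only:
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def _disk_structure(radius_px: int) -> np.ndarray:
    yy, xx = np.ogrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    return (yy**2 + xx**2) <= radius_px**2


def coverage_contour(mask: np.ndarray, pixel_size_um: float) -> list[np.ndarray]:
    """Colony boundary polylines in mm (list of (N, 2) arrays, row/col order)."""
    if not pixel_size_um or pixel_size_um <= 0:
        raise ValueError("pixel_size_um is required and must be positive")
    contours = measure.find_contours(np.asarray(mask, dtype=float), 0.5)
    return [c * pixel_size_um * 1e-3 for c in contours]
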