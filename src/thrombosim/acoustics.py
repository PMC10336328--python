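"""Focal pressure field of the histotripsy source.

The therapy transducer is a 1.5-MHz focused source whose measured focal
zone has -6 dB (half-maximum) widths of 4.3 mm along the propagation axis
and 0.7 mm laterally. Only those widths are available, so the in-plane
peak-negative-pressure map is modelled as a separable elliptical Gaussian
whose half-maximum contour matches them; a measured map on the same grid
can be substituted wherever a :class:`PressureField` is accepted.

Axial is the grid row direction (propagation top to bottom); the focus
defaults to the thrombus centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .histology import HistologySection

__all__ = ["SourceSpec", "PressureField", "elliptical_gaussian_field", "read_pressure_field"]

_LN2 = float(np.log(2.0))


@dataclass
class SourceSpec:
    """Focused-source parameters (pressures in MPa, lengths in mm)."""

    peak_negative_pressure_mpa: float
    frequency_mhz: float = 1.5
    axial_width_6db_mm: float = 4.3
    lateral_width_6db_mm: float = 0.7
    focus_mm: tuple[float, float] | None = None  # (y, x); None -> thrombus centroid

    def __post_init__(self) -> None:
        if self.axial_width_6db_mm <= 0 or self.lateral_width_6db_mm <= 0:
            raise ValueError("focal widths must be positive")
        if self.peak_negative_pressure_mpa < 0:
            raise ValueError("peak negative pressure must be non-negative")


@dataclass
class PressureField:
    """Per-pixel peak negative pressure (MPa) co-registered to a section."""

    p_neg_mpa: np.ndarray
    pixel_size_um: float
    focus_px: tuple[float, float]

    def __post_init__(self) -> None:
        if (self.p_neg_mpa < 0).any():
            raise ValueError("peak negative pressure must be non-negative")


def elliptical_gaussian_field(spec: SourceSpec, section: HistologySection) -> PressureField:
    """Separable Gaussian focal field on the section's grid.

    The value equals the peak at the focus and falls to half-maximum at
    +/- half the -6 dB width along each principal axis.
    """
    ny, nx = section.shape
    px_mm = section.pixel_size_um * 1e-3
    if spec.focus_mm is None:
        # snap to the nearest pixel centre so the peak is attained on-grid
        cy, cx = section.centroid_px()
        fy, fx = float(round(cy)), float(round(cx))
    else:
        fy = spec.focus_mm[0] / px_mm
        fx = spec.focus_mm[1] / px_mm
        if not (0 <= fy < ny and 0 <= fx < nx):
            raise ValueError("focus lies outside the section grid")

    y_mm = (np.arange(ny) - fy) * px_mm
    x_mm = (np.arange(nx) - fx) * px_mm
    ax = np.exp(-_LN2 * (y_mm / (spec.axial_width_6db_mm / 2.0)) ** 2)
    lat = np.exp(-_LN2 * (x_mm / (spec.lateral_width_6db_mm / 2.0)) ** 2)
    p = spec.peak_negative_pressure_mpa * np.outer(ax, lat)
    return PressureField(p_neg_mpa=p, pixel_size_um=section.pixel_size_um, focus_px=(fy, fx))


def read_pressure_field(path: str | Path, pixel_size_um: float,
                        focus_px: tuple[float, float] | None = None) -> PressureField:
    """Import a measured peak-negative-pressure map (MPa) from delimited text."""
    arr = np.loadtxt(Path(path), ndmin=2)
    if focus_px is None:
        focus_px = tuple(float(i) for i in np.unravel_index(np.argmax(arr), arr.shape))
    return PressureField(p_neg_mpa=arr, pixel_size_um=pixel_size_um, focus_px=focus_px)
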