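"""Analytic maximum bubble radius in viscoelastic thrombus.

Histotripsy pulses nucleate nanometre-scale nuclei that expand explosively
during the rarefactional phase. For short (single-cycle) intrinsic-threshold
pulses the maximum radius admits a closed form in a Kelvin-Voigt medium:
the bubble wall accelerates under the dimensionless driving tension

    xi = xi_HA(p_neg) - 6 G / P0,

where ``xi_HA`` is the Holland-Apfel rarefactional tension (implemented as
``(p_neg - P0)/P0`` and swappable) and the elastic modulus G both reduces
the net tension and stiffens the confining "Blake brake" pressure

    p_EFF = P0 (1 + 4 G / (3 P0)).

The maximum radius reached during/after a tension window of duration tau is

    R_MAX = R0 + sqrt(2 P0 xi / (9 rho)) * tau * (xi P0 / (3 p_EFF) + 1)^(1/3)

with no growth (R_MAX = R0) when xi <= 0. Agreement with full numerical
Kelvin-Voigt Rayleigh-Plesset integrations is at the tens-of-percent level
over 28-40 MPa and G up to ~1 MPa, adequate for the 2D ablation-footprint
model built on top of it.

In heterogeneous thrombus, G at a nucleation site is the arithmetic mean
of per-pixel moduli (fibrin 14 MPa, RBC 4 kPa, liquefied 0) over a 500-um
radius neighbourhood; outcomes are insensitive to that radius over
100-1000 um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .histology import HistologySection, Label

__all__ = [
    "MaterialParameters",
    "xi_holland_apfel",
    "effective_pressure",
    "xi",
    "max_radius",
    "modulus_map",
    "local_shear_modulus",
]


def xi_holland_apfel(p_neg_pa: np.ndarray | float, p0_pa: float) -> np.ndarray | float:
    """Dimensionless rarefactional driving tension, (p_neg - P0)/P0."""
    return (np.asarray(p_neg_pa, dtype=float) - p0_pa) / p0_pa


@dataclass
class MaterialParameters:
    """Physical constants of the bubble-growth model (SI units).

    Defaults: ambient pressure 0.1 MPa, density 1000 kg/m3, nucleus radius
    2.5 nm, fibrin modulus 14 MPa, RBC modulus 4 kPa, liquefied modulus 0,
    tension duration tau = one rarefactional half-period at 1.5 MHz,
    modulus-averaging radius 500 um.
    """

    p0_pa: float = 1.0e5
    rho_kg_m3: float = 1000.0
    r0_m: float = 2.5e-9
    g_fibrin_pa: float = 14.0e6
    g_rbc_pa: float = 4.0e3
    g_ablated_pa: float = 0.0
    tau_s: float = 1.0 / (2 * 1.5e6)
    averaging_radius_um: float = 500.0
    xi_ha: Callable[[np.ndarray | float, float], np.ndarray | float] = field(
        default=xi_holland_apfel, repr=False
    )

    def __post_init__(self) -> None:
        if min(self.g_fibrin_pa, self.g_rbc_pa, self.g_ablated_pa) < 0:
            raise ValueError("elastic moduli must be non-negative")
        if self.tau_s <= 0 or self.r0_m <= 0 or self.averaging_radius_um <= 0:
            raise ValueError("tau, R0 and averaging radius must be positive")


def effective_pressure(g_pa: np.ndarray | float, m: MaterialParameters | None = None
                       ) -> np.ndarray | float:
    """Blake-brake confining pressure p_EFF = P0 (1 + 4G/(3 P0)), in Pa."""
    m = m or MaterialParameters()
    g = np.asarray(g_pa, dtype=float)
    if (g < 0).any():
        raise ValueError("elastic modulus must be non-negative")
    out = m.p0_pa * (1.0 + 4.0 * g / (3.0 * m.p0_pa))
    return float(out) if np.isscalar(g_pa) else out


def xi(p_neg_pa: np.ndarray | float, g_pa: np.ndarray | float,
       m: MaterialParameters | None = None) -> np.ndarray | float:
    """Net dimensionless tension xi = xi_HA(p_neg) - 6G/P0 (may be negative)."""
    m = m or MaterialParameters()
    out = np.asarray(m.xi_ha(p_neg_pa, m.p0_pa)) - 6.0 * np.asarray(g_pa, dtype=float) / m.p0_pa
    scalar = np.isscalar(p_neg_pa) and np.isscalar(g_pa)
    return float(out) if scalar else out


def max_radius(p_neg_pa: np.ndarray | float, g_pa: np.ndarray | float,
               m: MaterialParameters | None = None) -> np.ndarray | float:
    """Maximum bubble radius (m); R0 wherever the net tension is <= 0."""
    m = m or MaterialParameters()
    x = np.asarray(xi(p_neg_pa, g_pa, m), dtype=float)
    p_eff = np.asarray(effective_pressure(g_pa, m), dtype=float)
    xp = np.clip(x, 0.0, None)
    r = m.r0_m + (
        np.sqrt(2.0 * m.p0_pa * xp / (9.0 * m.rho_kg_m3))
        * m.tau_s
        * np.cbrt(xp * m.p0_pa / (3.0 * p_eff) + 1.0)
    )
    r = np.where(x <= 0.0, m.r0_m, r)
    scalar = np.isscalar(p_neg_pa) and np.isscalar(g_pa)
    return float(r) if scalar else r


def modulus_map(labels: np.ndarray, ablated_mask: np.ndarray | None,
                m: MaterialParameters) -> np.ndarray:
    """Per-pixel elastic modulus (Pa); NaN on background pixels.

    Ablated (liquefied) pixels carry ``g_ablated_pa`` so that progressive
    lesion growth softens the neighbourhood average.
    """
    g = np.full(labels.shape, np.nan)
    g[labels == Label.FIBRIN] = m.g_fibrin_pa
    g[(labels == Label.RBC) | (labels == Label.ABLATED)] = m.g_rbc_pa
    g[labels == Label.ABLATED] = m.g_ablated_pa
    if ablated_mask is not None:
        g[ablated_mask] = m.g_ablated_pa
    return g


def local_shear_modulus(section: HistologySection, ablated_mask: np.ndarray | None,
                        location_px: tuple[int, int],
                        m: MaterialParameters | None = None) -> float:
    """Mean elastic modulus (Pa) over pixels within the averaging radius.

    Background pixels are excluded from the average; a neighbourhood with
    no thrombus pixels at all is degenerate and raises.
    """
    m = m or MaterialParameters()
    iy, ix = location_px
    ny, nx = section.shape
    if not (0 <= iy < ny and 0 <= ix < nx):
        raise ValueError("location outside the grid")
    r_px = m.averaging_radius_um / section.pixel_size_um
    ri = int(np.ceil(r_px))
    y0, y1 = max(0, iy - ri), min(ny, iy + ri + 1)
    x0, x1 = max(0, ix - ri), min(nx, ix + ri + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disk = (yy - iy) ** 2 + (xx - ix) ** 2 <= r_px**2
    g = modulus_map(section.labels[y0:y1, x0:x1],
                    None if ablated_mask is None else ablated_mask[y0:y1, x0:x1], m)
    vals = g[disk]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no thrombus pixels within the averaging radius")
    return float(vals.mean())
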