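"""Synthetic thrombus histology sections.

Venous thrombus is modelled as a 2D labelled pixel grid with three classes:
fibrin mesh, red blood cells (RBC), and background (non-thrombus). Real
sections of this kind come from H&E-stained specimens segmented into
fibrin/RBC maps; here they are generated synthetically as spatially
clustered composition fields so that cohorts with controlled fibrin
fraction can be studied.

Compositional subgroups follow the clinical convention: fibrin-dominant
(>75% fibrin, chronic-like), RBC-dominant (>75% RBC, acute-like) and
"half-half" (everything in between, subacute-like). The 75%/25% boundaries
are strict, so a section at exactly 75% fibrin is half-half.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "Label",
    "Subgroup",
    "HistologySection",
    "CompositionSummary",
    "generate_section",
    "composition",
    "classify_subgroup",
    "read_label_mask",
    "write_label_mask",
]


class Label(enum.IntEnum):
    """Pixel classes of a labelled section (integer codes used on disk)."""

    BACKGROUND = 0
    RBC = 1
    FIBRIN = 2
    ABLATED = 3  # liquefied RBC; appears only in treatment output masks


class Subgroup(str, enum.Enum):
    FIBRIN_DOMINANT = "fibrin_dominant"
    RBC_DOMINANT = "rbc_dominant"
    HALF_HALF = "half_half"


@dataclass
class HistologySection:
    """A labelled composition grid with physical scale.

    Parameters
    ----------
    labels
        2D uint8 array of :class:`Label` codes, shape (ny, nx); row index is
        the axial (ultrasound propagation) direction.
    pixel_size_um
        Edge length of one square pixel in micrometres (> 0).
    origin_mm
        Physical coordinate (y, x) in mm of the grid corner at index (0, 0).
    """

    labels: np.ndarray
    pixel_size_um: float
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        codes = np.unique(self.labels)
        valid = {int(l) for l in Label}
        if not set(codes.tolist()) <= valid:
            raise ValueError(f"unknown label codes: {sorted(set(codes.tolist()) - valid)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def thrombus_mask(self) -> np.ndarray:
        """Boolean mask of thrombus pixels (fibrin, RBC or ablated)."""
        return self.labels != Label.BACKGROUND

    @property
    def rbc_mask(self) -> np.ndarray:
        return self.labels == Label.RBC

    @property
    def fibrin_mask(self) -> np.ndarray:
        return self.labels == Label.FIBRIN

    def centroid_px(self) -> tuple[float, float]:
        """(row, col) centroid of the thrombus region, in pixel units."""
        mask = self.thrombus_mask
        if not mask.any():
            raise ValueError("section has no thrombus pixels")
        ys, xs = np.nonzero(mask)
        return float(ys.mean()), float(xs.mean())

    def pixel_area_mm2(self) -> float:
        return (self.pixel_size_um * 1e-3) ** 2


@dataclass
class CompositionSummary:
    fibrin_fraction: float
    rbc_fraction: float
    subgroup: Subgroup
    thrombus_area_mm2: float


def classify_subgroup(fibrin_fraction: float) -> Subgroup:
    """Assign a compositional subgroup from the fibrin fraction.

    Thresholds are strict: >0.75 fibrin is fibrin-dominant, <0.25 fibrin
    (i.e. >75% RBC) is RBC-dominant, exactly 0.75 or 0.25 falls in half-half.
    """
    if not 0.0 <= fibrin_fraction <= 1.0:
        raise ValueError(f"fibrin_fraction must lie in [0, 1], got {fibrin_fraction}")
    if fibrin_fraction > 0.75:
        return Subgroup.FIBRIN_DOMINANT
    if fibrin_fraction < 0.25:
        return Subgroup.RBC_DOMINANT
    return Subgroup.HALF_HALF


def composition(section: HistologySection) -> CompositionSummary:
    """Fibrin/RBC fractions over thrombus pixels and total thrombus area.

    Ablated pixels count toward thrombus area and toward the RBC fraction
    (they were RBC before liquefaction).
    """
    labels = section.labels
    n_fibrin = int(np.count_nonzero(labels == Label.FIBRIN))
    n_rbc = int(np.count_nonzero((labels == Label.RBC) | (labels == Label.ABLATED)))
    n_thrombus = n_fibrin + n_rbc
    if n_thrombus == 0:
        raise ValueError("section contains no thrombus pixels")
    f = n_fibrin / n_thrombus
    return CompositionSummary(
        fibrin_fraction=f,
        rbc_fraction=n_rbc / n_thrombus,
        subgroup=classify_subgroup(f),
        thrombus_area_mm2=n_thrombus * section.pixel_area_mm2(),
    )


def generate_section(
    target_fibrin_fraction: float,
    clustering_scale_mm: float = 0.5,
    extent_mm: float = 10.0,
    pixel_size_um: float = 7.4,
    seed: int = 0,
    ellipse_fill: tuple[float, float] = (0.74, 0.66),
) -> HistologySection:
    """Generate a synthetic thrombus section with clustered composition.

    The thrombus outline is an axis-aligned ellipse centred in the grid with
    axes ``ellipse_fill`` times the extent. Inside it, fibrin/RBC territories
    are produced by thresholding an isotropically smoothed Gaussian random
    field at the quantile matching ``target_fibrin_fraction``, which yields
    contiguous patches and a realised fibrin fraction exact to pixel
    quantisation.

    ``clustering_scale_mm`` is the territory correlation length at balanced
    (50/50) composition. The effective patch scale shrinks linearly with the
    minority-component fraction, mirroring thrombus histology: mixed and
    acute regions organise into large (~0.1-1 mm) component territories,
    whereas the minority component of a strongly dominated section (e.g.
    residual red blood cells in organised, fibrin-rich clot) is finely
    dispersed rather than pooled into lakes.

    Identical (parameters, seed) reproduce a bit-identical section.
    """
    if not 0.0 <= target_fibrin_fraction <= 1.0:
        raise ValueError("target_fibrin_fraction must lie in [0, 1]")
    if extent_mm <= 0 or pixel_size_um <= 0 or clustering_scale_mm <= 0:
        raise ValueError("extent, pixel size and clustering scale must be positive")

    n = int(round(extent_mm * 1000.0 / pixel_size_um))
    if n < 8:
        raise ValueError("grid too small; increase extent or decrease pixel size")

    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    a = ellipse_fill[0] * n / 2.0  # semi-axis, rows
    b = ellipse_fill[1] * n / 2.0  # semi-axis, cols
    inside = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, n))
    minority = 2.0 * min(target_fibrin_fraction, 1.0 - target_fibrin_fraction)
    sigma_px = max(clustering_scale_mm * minority * 1000.0 / pixel_size_um, 2.0)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")

    labels = np.zeros((n, n), dtype=np.uint8)
    vals = smooth[inside]
    if target_fibrin_fraction <= 0.0:
        fibrin_sel = np.zeros(vals.shape, dtype=bool)
    elif target_fibrin_fraction >= 1.0:
        fibrin_sel = np.ones(vals.shape, dtype=bool)
    else:
        # fibrin = pixels above the (1 - f) quantile of the smoothed field
        thr = np.quantile(vals, 1.0 - target_fibrin_fraction)
        fibrin_sel = vals > thr
    region = np.where(fibrin_sel, np.uint8(Label.FIBRIN), np.uint8(Label.RBC))
    labels[inside] = region
    return HistologySection(labels=labels, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# label-mask I/O: 8-bit grayscale PNG/TIFF or delimited text, with a plain
# key-value sidecar carrying the physical metadata
# ---------------------------------------------------------------------------

_TEXT_SUFFIXES = {".txt", ".tsv", ".csv"}


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta")


def write_label_mask(section: HistologySection, path: str | Path) -> None:
    """Write a section as an image (PNG/TIFF) or delimited-text matrix.

    A sidecar ``<name>.meta`` records ``pixel_size_um`` and ``origin_mm``.
    """
    path = Path(path)
    arr = section.labels.astype(np.uint8)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        np.savetxt(path, arr, fmt="%d", delimiter="\t")
    else:
        Image.fromarray(arr, mode="L").save(path)
    oy, ox = section.origin_mm
    _sidecar_path(path).write_text(
        f"pixel_size_um: {section.pixel_size_um!r}\n"
        f"origin_y_mm: {oy!r}\norigin_x_mm: {ox!r}\n"
    )


def read_label_mask(path: str | Path) -> HistologySection:
    """Read a section written by :func:`write_label_mask`.

    Raises
    ------
    ValueError
        If the matrix contains unknown label codes or metadata is missing.
    """
    path = Path(path)
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise ValueError(f"missing metadata sidecar {meta_path}")
    meta: dict[str, float] = {}
    for line in meta_path.read_text().splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            meta[k.strip()] = float(v)
    if "pixel_size_um" not in meta:
        raise ValueError("metadata sidecar lacks pixel_size_um")

    if path.suffix.lower() in _TEXT_SUFFIXES:
        arr = np.loadtxt(path, dtype=np.uint8, ndmin=2)
    else:
        arr = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
    return HistologySection(
        labels=arr,
        pixel_size_um=meta["pixel_size_um"],
        origin_mm=(meta.get("origin_y_mm", 0.0), meta.get("origin_x_mm", 0.0)),
    )
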