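"""2D mid-plane activity imaging from list-mode coincidences.

Beam-OFF events are back-projected onto the mid-horizontal plane of the
scanner: for parallel flat panels the line of response crosses the
mid-plane at the coordinate-wise mean of the two hit positions, which is
an unbiased position estimator for sources on that plane.  Images are
binned at 2 x 2 mm^2 pixels and corrected pixel-wise for scanner
sensitivity (solid-angle acceptance) and photon attenuation in the
phantom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import PhantomSpec, ScannerSpec, detect_pairs

__all__ = [
    "ImageGeometry",
    "ActivityImage",
    "CorrectionMaps",
    "reconstruct_midplane",
    "build_correction_maps",
    "correct_image",
    "rect_solid_angle",
    "write_image",
    "read_image",
]


@dataclass(frozen=True)
class ImageGeometry:
    """Pixel grid on the mid-plane: depth (beam) x lateral (width) axes.

    Extents are mm relative to the phantom entrance face (depth) and the
    beam axis (lateral); pixels are half-open ``[left, right)`` bins of
    ``pixel_size`` mm on both axes.
    """

    pixel_size: float = 2.0
    depth_extent: tuple[float, float] = (-1.0, 227.0)
    lateral_extent: tuple[float, float] = (-111.0, 111.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for lo, hi in (self.depth_extent, self.lateral_extent):
            if hi <= lo:
                raise ValueError("extent must be increasing")

    @property
    def depth_edges(self) -> np.ndarray:
        n = int(round((self.depth_extent[1] - self.depth_extent[0]) / self.pixel_size))
        return self.depth_extent[0] + self.pixel_size * np.arange(n + 1)

    @property
    def lateral_edges(self) -> np.ndarray:
        n = int(round((self.lateral_extent[1] - self.lateral_extent[0]) / self.pixel_size))
        return self.lateral_extent[0] + self.pixel_size * np.arange(n + 1)

    @property
    def depth_centers(self) -> np.ndarray:
        e = self.depth_edges
        return (e[:-1] + e[1:]) / 2

    @property
    def lateral_centers(self) -> np.ndarray:
        e = self.lateral_edges
        return (e[:-1] + e[1:]) / 2

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.depth_edges) - 1, len(self.lateral_edges) - 1)

    @classmethod
    def for_scanner(cls, scanner: ScannerSpec, pixel_size: float = 2.0) -> "ImageGeometry":
        """Geometry covering the scanner field of view.

        The grid is shifted by half a pixel so pixel centres coincide
        with the lattice of LOR mid-points of the quantized crystal
        grid (crystal-centre midpoints fall on multiples of half the
        crystal pitch); without this offset those mid-points sit exactly
        on pixel edges and the image picks up a half-pixel bias.
        """
        u0, u1 = scanner.panel_depth_interval
        w0, w1 = scanner.panel_width_interval
        h = pixel_size / 2
        return cls(
            pixel_size=pixel_size,
            depth_extent=(u0 - h, u1 + h),
            lateral_extent=(w0 - h, w1 + h),
        )


@dataclass
class ActivityImage:
    """Counts grid (depth x lateral) with geometry and bookkeeping."""

    counts: np.ndarray
    geometry: ImageGeometry
    corrected: bool = False
    n_events: int = 0
    n_dropped: int = 0
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.geometry.shape:
            raise ValueError(
                f"counts shape {self.counts.shape} != geometry {self.geometry.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class CorrectionMaps:
    """Per-pixel sensitivity (unit mean over FoV) and attenuation survival."""

    sensitivity: np.ndarray
    attenuation_survival: np.ndarray
    geometry: ImageGeometry
    valid: np.ndarray = field(default=None)  # pixels usable for correction

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = (self.sensitivity > 0) & (self.attenuation_survival > 0)


def reconstruct_midplane(
    events: pd.DataFrame,
    geometry: ImageGeometry,
    allow_beam_on: bool = False,
) -> ActivityImage:
    """Back-project list-mode events onto the mid-plane pixel grid.

    Events must already be restricted to beam-OFF times (only those are
    analysed); the presence of beam-ON events raises unless
    ``allow_beam_on``.  LOR mid-points falling outside the image extent
    are dropped and counted in ``n_dropped``.
    """
    if not allow_beam_on and bool(events["beam_on"].any()):
        raise ValueError(
            "events contain beam-ON entries; filter them out or pass allow_beam_on=True"
        )
    u = (events["top_depth_mm"].to_numpy() + events["bottom_depth_mm"].to_numpy()) / 2
    w = (events["top_width_mm"].to_numpy() + events["bottom_width_mm"].to_numpy()) / 2
    counts, _, _ = np.histogram2d(
        u, w, bins=[geometry.depth_edges, geometry.lateral_edges]
    )
    retained = int(counts.sum())
    return ActivityImage(
        counts=counts,
        geometry=geometry,
        corrected=False,
        n_events=retained,
        n_dropped=len(events) - retained,
    )


def rect_solid_angle(
    x0: float, x1: float, y0: float, y1: float, d: float
) -> float:
    """Solid angle of the rectangle [x0,x1] x [y0,y1] at height d above
    a point at the lateral origin (standard four-corner arctan sum)."""
    if x1 <= x0 or y1 <= y0:
        return 0.0

    def corner(x: float, y: float) -> float:
        return np.arctan2(x * y, d * np.sqrt(x * x + y * y + d * d))

    return float(corner(x1, y1) - corner(x0, y1) - corner(x1, y0) + corner(x0, y0))


def _point_acceptance(u: float, w: float, scanner: ScannerSpec) -> float:
    """Exact pair-detection solid-angle fraction for a mid-plane point.

    For a point on the mid-plane the bottom hit is the point reflection
    of the top hit, so both photons land on their panels iff the top hit
    falls in the intersection of the panel rectangle with its own point
    reflection about the source — a rectangle whose solid angle gives
    the acceptance as 2*Omega / 4*pi (either photon may go up).
    """
    u0, u1 = scanner.panel_depth_interval
    w0, w1 = scanner.panel_width_interval
    d = scanner.panel_separation / 2
    a0, a1 = max(u0, 2 * u - u1), min(u1, 2 * u - u0)
    b0, b1 = max(w0, 2 * w - w1), min(w1, 2 * w - w0)
    if a1 <= a0 or b1 <= b0:
        return 0.0
    omega = rect_solid_angle(a0 - u, a1 - u, b0 - w, b1 - w, d)
    return omega / (2 * np.pi)


def build_correction_maps(
    phantom: PhantomSpec,
    scanner: ScannerSpec,
    geometry: ImageGeometry,
    mode: str = "analytic",
    scan_step: int = 5,
    scan_pairs: int = 4000,
    rng: np.random.Generator | None = None,
) -> CorrectionMaps:
    """Sensitivity and attenuation correction maps for the image grid.

    ``analytic`` mode evaluates the pair-acceptance solid angle at every
    pixel centre in closed form; ``from_scan`` emulates a point-source
    mapping measurement by simulating ``scan_pairs`` annihilations at
    every ``scan_step``-th pixel and interpolating bilinearly in between.
    Sensitivity is normalized to unit mean over pixels with non-zero
    acceptance.  Attenuation survival uses the vertical chord through
    the phantom at each pixel (exp(-mu * chord); 1 outside the phantom).
    """
    uc = geometry.depth_centers
    wc = geometry.lateral_centers
    if mode == "analytic":
        sens = np.array([[_point_acceptance(u, w, scanner) for w in wc] for u in uc])
    elif mode == "from_scan":
        rng = rng or np.random.default_rng(0)
        iu = np.unique(np.r_[np.arange(0, len(uc), scan_step), len(uc) - 1])
        iw = np.unique(np.r_[np.arange(0, len(wc), scan_step), len(wc) - 1])
        coarse = np.zeros((len(iu), len(iw)))
        for a, i in enumerate(iu):
            for b, j in enumerate(iw):
                pos = np.tile([uc[i], 0.0, wc[j]], (scan_pairs, 1))
                ok, _, _ = detect_pairs(
                    pos, scanner, rng, phantom, attenuation=False, quantize=False
                )
                coarse[a, b] = ok.mean()
        # separable bilinear interpolation onto the full grid
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (uc[iu], wc[iw]), coarse, bounds_error=False, fill_value=None
        )
        uu, ww = np.meshgrid(uc, wc, indexing="ij")
        sens = interp(np.column_stack([uu.ravel(), ww.ravel()])).reshape(uu.shape)
        sens = np.clip(sens, 0.0, None)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    pos_mask = sens > 0
    if pos_mask.any():
        sens = sens / sens[pos_mask].mean()

    d0, d1 = phantom.depth_interval
    half_w = phantom.size[2] / 2
    chord = np.where(
        (uc[:, None] >= d0) & (uc[:, None] <= d1) & (np.abs(wc[None, :]) <= half_w),
        phantom.size[1],
        0.0,
    )
    att = np.exp(-phantom.mu_511 * chord)
    return CorrectionMaps(sensitivity=sens, attenuation_survival=att, geometry=geometry)


def correct_image(image: ActivityImage, maps: CorrectionMaps) -> ActivityImage:
    """Divide counts by sensitivity and attenuation survival, pixel-wise.

    Per-pixel variance is propagated as Poisson variance (``max(counts,
    1)`` so empty pixels keep a one-count error scale) times the squared
    correction factor.  Pixels flagged invalid in the maps are zeroed.
    Correcting an already-corrected image raises.
    """
    if image.corrected:
        raise ValueError("image is already corrected")
    if maps.geometry.shape != image.geometry.shape:
        raise ValueError("correction maps do not match image geometry")
    factor = np.zeros_like(image.counts)
    valid = maps.valid
    factor[valid] = 1.0 / (maps.sensitivity[valid] * maps.attenuation_survival[valid])
    counts = image.counts * factor
    variance = np.maximum(image.counts, 1.0) * factor**2
    return ActivityImage(
        counts=counts,
        geometry=image.geometry,
        corrected=True,
        n_events=image.n_events,
        n_dropped=image.n_dropped,
        variance=variance,
    )


def write_image(image: ActivityImage, path: str | Path) -> Path:
    """Write the counts matrix as TSV plus a JSON sidecar with metadata."""
    path = Path(path)
    np.savetxt(path, image.counts, delimiter="\t")
    meta = {
        "geometry": asdict(image.geometry),
        "corrected": image.corrected,
        "n_events": image.n_events,
        "n_dropped": image.n_dropped,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_image(path: str | Path) -> ActivityImage:
    """Read an image written by :func:`write_image`."""
    path = Path(path)
    counts = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    geo = meta["geometry"]
    geometry = ImageGeometry(
        pixel_size=geo["pixel_size"],
        depth_extent=tuple(geo["depth_extent"]),
        lateral_extent=tuple(geo["lateral_extent"]),
    )
    return ActivityImage(
        counts=counts,
        geometry=geometry,
        corrected=meta["corrected"],
        n_events=meta["n_events"],
        n_dropped=meta["n_dropped"],
    )
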