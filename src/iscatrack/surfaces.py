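"""Surface models: spatial binding affinity plus static scattering background.

A :class:`SurfaceModel` couples two per-pixel maps on the same grid:

* ``affinity`` — relative (unnormalised) probability that a molecule
  arriving from solution lands on a given pixel.  Uniform on pristine
  hBN; enhanced inside an ion-beam-milled defect square; concentrated in
  narrow ridges just inside the trenches of an etched lane pattern.
* ``background_template`` — the static scattering intensity the camera
  sees with no analyte, including the bright lane/flake edges that
  dominate raw iSCAT images.

Lane geometry (edge positions along the cross-lane axis and the lane
direction) rides along so that lane-relative statistics can be computed
on both simulated and measured localizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "SurfaceModel",
    "uniform_surface",
    "defect_square_surface",
    "lane_surface",
]

#: Default static scattering level in camera counts.
DEFAULT_BASE_INTENSITY = 1000.0


@dataclass
class SurfaceModel:
    """Per-pixel affinity + background template with optional lane geometry.

    ``lane_edges_x`` are edge positions (nm) along the cross-lane axis,
    strictly increasing; consecutive pairs (0, 1), (2, 3), ... bound the
    etched trenches.  ``lane_axis`` is the unit direction of the lanes in
    (x, y) image coordinates.
    """

    affinity: np.ndarray
    background_template: np.ndarray
    lane_edges_x: np.ndarray | None = None
    lane_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))

    def __post_init__(self) -> None:
        self.affinity = np.asarray(self.affinity, dtype=np.float64)
        self.background_template = np.asarray(
            self.background_template, dtype=np.float64
        )
        if self.affinity.ndim != 2:
            raise ConfigurationError("affinity must be a 2-D (H, W) map")
        if self.background_template.shape != self.affinity.shape:
            raise ConfigurationError(
                "background_template and affinity shapes differ: "
                f"{self.background_template.shape} vs {self.affinity.shape}"
            )
        if np.any(self.affinity < 0) or not np.all(np.isfinite(self.affinity)):
            raise ConfigurationError("affinity must be finite and >= 0 everywhere")
        if np.any(self.background_template < 0):
            raise ConfigurationError("background_template must be >= 0")
        if self.lane_edges_x is not None:
            self.lane_edges_x = np.asarray(self.lane_edges_x, dtype=np.float64)
            if self.lane_edges_x.ndim != 1 or np.any(np.diff(self.lane_edges_x) <= 0):
                raise ConfigurationError("lane_edges_x must be strictly increasing")
        self.lane_axis = np.asarray(self.lane_axis, dtype=np.float64)
        norm = np.hypot(*self.lane_axis)
        if norm == 0:
            raise ConfigurationError("lane_axis must be a nonzero vector")
        self.lane_axis = self.lane_axis / norm

    @property
    def shape(self) -> tuple[int, int]:
        return self.affinity.shape


def _grid_nm(n_px: int, pixel_nm: float) -> np.ndarray:
    """Pixel-center coordinates (nm) of a row of ``n_px`` pixels."""
    return (np.arange(n_px) + 0.5) * pixel_nm


def uniform_surface(
    shape: tuple[int, int],
    base_intensity: float = DEFAULT_BASE_INTENSITY,
    interior_margin_px: int = 0,
) -> SurfaceModel:
    """Pristine flake: flat affinity, flat scattering background.

    ``interior_margin_px`` zeroes the affinity in a border band, so all
    binding lands in the interior — the configuration for validation
    runs where blobs should stay clear of the field-of-view edge.
    """
    H, W = shape
    affinity = np.ones((H, W))
    m = interior_margin_px
    if m > 0:
        if 2 * m >= min(H, W):
            raise ConfigurationError("interior margin leaves no landing area")
        affinity[:m, :] = affinity[-m:, :] = 0.0
        affinity[:, :m] = affinity[:, -m:] = 0.0
    return SurfaceModel(
        affinity=affinity,
        background_template=np.full((H, W), float(base_intensity)),
    )


def defect_square_surface(
    shape: tuple[int, int],
    pixel_nm: float,
    square_origin_nm: tuple[float, float],
    square_size_nm: float,
    enhancement: float = 3.0,
    base_intensity: float = DEFAULT_BASE_INTENSITY,
) -> SurfaceModel:
    """Milled defect square: affinity raised by ``enhancement`` inside it.

    ``square_origin_nm`` is the (x, y) of the square's lower corner.
    """
    H, W = shape
    if enhancement < 0:
        raise ConfigurationError("enhancement must be >= 0")
    x = _grid_nm(W, pixel_nm)[None, :]
    y = _grid_nm(H, pixel_nm)[:, None]
    x0, y0 = square_origin_nm
    inside = (
        (x >= x0)
        & (x < x0 + square_size_nm)
        & (y >= y0)
        & (y < y0 + square_size_nm)
    )
    affinity = np.ones((H, W))
    affinity[np.broadcast_to(inside, (H, W))] = 1.0 + enhancement
    return SurfaceModel(
        affinity=affinity,
        background_template=np.full((H, W), float(base_intensity)),
    )


def lane_surface(
    shape: tuple[int, int],
    pixel_nm: float,
    lane_edges_x_nm: np.ndarray | list[float],
    *,
    edge_brightness: float = 0.3,
    edge_sigma_nm: float = 60.0,
    affinity_peak_offset_nm: float = 300.0,
    affinity_peak_sigma_nm: float = 80.0,
    affinity_peak_enhancement: float = 8.0,
    affinity_floor: float = 1.0,
    base_intensity: float = DEFAULT_BASE_INTENSITY,
) -> SurfaceModel:
    """Etched lane pattern with edge-enhanced binding affinity.

    The background template carries a bright Gaussian ridge (relative
    amplitude ``edge_brightness``, width ``edge_sigma_nm``) at every lane
    edge, mimicking edge scattering.  The affinity map is a uniform floor
    plus Gaussian ridges of relative height ``affinity_peak_enhancement``
    centred ``affinity_peak_offset_nm`` *inside* each trench from each of
    its two edges — the enhanced-binding geometry this model family is
    built to recover (peak offsets of a few hundred nm are the empirical
    scale).  Lanes run along +y; the cross-lane axis is x.
    """
    H, W = shape
    edges = np.asarray(lane_edges_x_nm, dtype=np.float64)
    x = _grid_nm(W, pixel_nm)
    bg_profile = np.ones(W)
    for e in edges:
        bg_profile += edge_brightness * np.exp(-0.5 * ((x - e) / edge_sigma_nm) ** 2)
    aff_profile = np.full(W, float(affinity_floor))
    # trenches are bounded by consecutive edge pairs
    for i in range(0, len(edges) - 1, 2):
        left, right = edges[i], edges[i + 1]
        for centre in (left + affinity_peak_offset_nm, right - affinity_peak_offset_nm):
            aff_profile += affinity_peak_enhancement * np.exp(
                -0.5 * ((x - centre) / affinity_peak_sigma_nm) ** 2
            )
    return SurfaceModel(
        affinity=np.tile(aff_profile, (H, 1)),
        background_template=float(base_intensity) * np.tile(bg_profile, (H, 1)),
        lane_edges_x=edges,
        lane_axis=np.array([0.0, 1.0]),
    )
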