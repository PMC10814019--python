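"""Rasterize a vessel tree onto a pixel grid with an axial-velocity field.

Pixel convention: 0-based row-major indices, row 0 at the shallowest depth,
pixel centers at (i + 0.5) * pitch. Occupancy is the union of stadium-shaped
dilations of the centerlines by diameter/2; the axial velocity at a lumen
pixel is the segment flow speed times the axial (depth) direction cosine of
the locally nearest centerline tangent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import VesselTree

__all__ = ["RasterMap", "rasterize"]


@dataclass
class RasterMap:
    occupancy: np.ndarray        # (H, W) bool
    axial_velocity: np.ndarray   # (H, W) float, mm/s; zero outside occupancy
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.axial_velocity = np.asarray(self.axial_velocity, dtype=float)
        if self.occupancy.shape != self.axial_velocity.shape:
            raise ValueError("occupancy and axial_velocity shapes differ")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if np.any((self.axial_velocity != 0) & ~self.occupancy):
            raise ValueError("axial velocity must be zero outside occupancy")

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape

    @property
    def field_of_view_mm(self) -> tuple[float, float]:
        pitch_mm = self.pixel_pitch_um * 1e-3
        return (self.shape[0] * pitch_mm, self.shape[1] * pitch_mm)


def _densify(points: np.ndarray, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ~step_mm spacing; return points and unit tangents."""
    deltas = np.diff(points, axis=0)
    seg_len = np.linalg.norm(deltas, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total == 0:
        t = deltas[0] if len(deltas) else np.array([1.0, 0.0])
        return points[:1], np.array([t / (np.linalg.norm(t) + 1e-12)])
    n = max(2, int(np.ceil(total / step_mm)) + 1)
    s = np.linspace(0.0, total, n)
    z = np.interp(s, cum, points[:, 0])
    x = np.interp(s, cum, points[:, 1])
    dense = np.column_stack([z, x])
    tang = np.gradient(dense, s, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True) + 1e-12
    return dense, tang


def rasterize(
    tree: VesselTree,
    pixel_pitch_um: float,
    grid_shape: tuple[int, int],
) -> RasterMap:
    """Render a tree to an occupancy grid and axial-velocity map.

    Raises ``ValueError`` if the tree (including its lumen radius) does not fit
    inside the grid.
    """
    if pixel_pitch_um <= 0:
        raise ValueError("pixel pitch must be positive")
    H, W = int(grid_shape[0]), int(grid_shape[1])
    pitch_mm = pixel_pitch_um * 1e-3

    occupancy = np.zeros((H, W), dtype=bool)
    velocity = np.zeros((H, W), dtype=float)
    if not tree.segments:
        return RasterMap(occupancy, velocity, pixel_pitch_um)

    lo, hi = tree.bounding_box_mm()
    max_r_mm = max(s.diameter_um for s in tree.segments) / 2.0 * 1e-3
    if (lo - max_r_mm < -pitch_mm).any() or (
        hi[0] + max_r_mm > H * pitch_mm + pitch_mm or hi[1] + max_r_mm > W * pitch_mm + pitch_mm
    ):
        raise ValueError("vessel tree (with lumen) extends outside the raster grid")

    # distance-to-nearest-centerline-sample, tracked to assign per-pixel velocity
    best_d2 = np.full((H, W), np.inf)

    for seg in tree.segments:
        r_mm = seg.diameter_um / 2.0 * 1e-3
        pts, tang = _densify(seg.centerline_mm, step_mm=pitch_mm / 4.0)
        v_axial = seg.flow_mm_s * tang[:, 0]  # depth component of the tangent

        pad = r_mm + pitch_mm
        i0 = max(0, int((pts[:, 0].min() - pad) / pitch_mm))
        i1 = min(H, int(np.ceil((pts[:, 0].max() + pad) / pitch_mm)) + 1)
        j0 = max(0, int((pts[:, 1].min() - pad) / pitch_mm))
        j1 = min(W, int(np.ceil((pts[:, 1].max() + pad) / pitch_mm)) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        zi = (np.arange(i0, i1) + 0.5) * pitch_mm
        xj = (np.arange(j0, j1) + 0.5) * pitch_mm
        # (win_h, win_w, n_samples) squared distances, chunked over samples
        win_best = np.full((i1 - i0, j1 - j0), np.inf)
        win_vel = np.zeros((i1 - i0, j1 - j0))
        chunk = 256
        for k0 in range(0, len(pts), chunk):
            p = pts[k0 : k0 + chunk]
            d2 = (zi[:, None, None] - p[None, None, :, 0]) ** 2 + (
                xj[None, :, None] - p[None, None, :, 1]
            ) ** 2
            kmin = np.argmin(d2, axis=2)
            dmin = np.take_along_axis(d2, kmin[:, :, None], axis=2)[:, :, 0]
            upd = dmin < win_best
            win_best[upd] = dmin[upd]
            win_vel[upd] = v_axial[k0 : k0 + chunk][kmin[upd]]
        inside = win_best <= r_mm**2
        view_occ = occupancy[i0:i1, j0:j1]
        view_vel = velocity[i0:i1, j0:j1]
        view_d2 = best_d2[i0:i1, j0:j1]
        view_occ |= inside
        closer = inside & (win_best < view_d2)
        view_vel[closer] = win_vel[closer]
        view_d2[closer] = win_best[closer]

    velocity[~occupancy] = 0.0
    return RasterMap(occupancy, velocity, pixel_pitch_um)
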