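"""Geometric phantoms with closed-form thickness, for validation.

Both phantoms place the bone-cartilage interface on the flat low-z face.
For the slab, nearest-surface thickness at interior positions equals
column height exactly; for the hemispherical cap of radius R over a flat
base, the nearest point on the cap surface from a base position at
in-plane radius r lies along the radial ray, so the analytic
nearest-surface thickness is R - r.
"""

from __future__ import annotations

import numpy as np

from .morphometry import SegmentationMask


def make_slab_mask(n_cols: tuple[int, int], n_vox: int,
                   spacing: tuple[float, float, float],
                   plate: str = "MT", laterality: str = "right",
                   pad: int = 2) -> SegmentationMask:
    """Axis-aligned slab: every column carries ``n_vox`` cartilage voxels."""
    if n_vox < 1:
        raise ValueError("n_vox must be >= 1")
    nx, ny = n_cols
    occ = np.zeros((nx + 2 * pad, ny + 2 * pad, n_vox + 2 * pad), dtype=bool)
    occ[pad:pad + nx, pad:pad + ny, pad:pad + n_vox] = True
    return SegmentationMask({plate: occ}, {plate: "low"}, tuple(spacing),
                            laterality).validate()


def slab_interior(mask: SegmentationMask, plate: str, margin: int = 1
                  ) -> np.ndarray:
    """2-D boolean of footprint positions at least ``margin`` px from the rim."""
    fp = mask.footprint(plate)
    interior = fp.copy()
    for _ in range(margin):
        nb = interior.copy()
        nb[1:, :] &= interior[:-1, :]
        nb[:-1, :] &= interior[1:, :]
        nb[:, 1:] &= interior[:, :-1]
        nb[:, :-1] &= interior[:, 1:]
        interior = nb
    return interior


def make_hemisphere_mask(radius_mm: float,
                         spacing: tuple[float, float, float],
                         plate: str = "MT", laterality: str = "right",
                         ) -> tuple[SegmentationMask, tuple[float, float]]:
    """Hemispherical cap of radius R on a flat base at the low-z face.

    A voxel is cartilage iff its center lies inside the hemisphere.
    Returns the mask and the in-plane center (mm) of the base disk.
    """
    dx, dy, dz = spacing
    nx = int(np.ceil(2 * radius_mm / dx)) + 4
    ny = int(np.ceil(2 * radius_mm / dy)) + 4
    nz = int(np.ceil(radius_mm / dz)) + 2
    cx = nx * dx / 2.0
    cy = ny * dy / 2.0
    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    x = (i + 0.5) * dx - cx
    y = (j + 0.5) * dy - cy
    z = (k + 0.5) * dz
    occ = x**2 + y**2 + z**2 <= radius_mm**2
    mask = SegmentationMask({plate: occ}, {plate: "low"}, tuple(spacing),
                            laterality).validate()
    return mask, (cx, cy)
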