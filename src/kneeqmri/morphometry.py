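"""Cartilage thickness morphometry and the 16-subregion atlas.

Thickness is defined as the nearest distance (3-D, in mm) from each
position on the bone-cartilage interface to the articular surface, with
both surfaces represented by exposed voxel-face centers of the
segmentation mask.  The articular surface is the exposed face set
opposite the interface along the depth axis; the lateral cartilage
margin is not articular surface.  On axis-aligned slab geometry the
measure reduces exactly to column height (voxel count x slice spacing),
which is the oracle the synthetic plates are built around.

Subregion scheme: each tibial plate splits into a central ellipse
(matching the bounding-box aspect ratio, 20 % of plate area by pixel
count) plus four ring sectors (anterior/posterior/interior/exterior) cut
by the bounding-box diagonals; each central femoral plate splits into
three equal-width mediolateral bands.  "Interior" always faces the
intercondylar notch, resolved from knee laterality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .regions import (PLATES, SUBREGIONS_OF_PLATE, TIBIAL_PLATES,
                      interior_sign)

log = logging.getLogger(__name__)

PLATE_CODES = {"MT": 1, "cMF": 2, "LT": 3, "cLF": 4}
CODE_TO_PLATE = {v: k for k, v in PLATE_CODES.items()}

#: Fraction of tibial plate area assigned to the central ellipse.
CENTRAL_AREA_FRACTION = 0.20


class EmptyPlateError(ValueError):
    """A plate mask has no voxels."""


@dataclass
class SegmentationMask:
    """Per-plate boolean occupancy on a shared voxel grid.

    Axis convention: axis 0 = mediolateral, axis 1 = anteroposterior,
    axis 2 = depth (slice normal).  ``interface_side[plate]`` states on
    which axis-2 side of the cartilage the bone-cartilage interface lies
    ('low' for tibial plates, 'high' for femoral plates in the synthetic
    geometry).
    """

    plate_masks: dict[str, np.ndarray]
    interface_side: dict[str, str]
    spacing: tuple[float, float, float]
    laterality: str

    def validate(self) -> "SegmentationMask":
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0")
        for plate, occ in self.plate_masks.items():
            if plate not in PLATES:
                raise ValueError(f"unknown plate {plate!r}")
            if occ.ndim != 3:
                raise ValueError(f"plate {plate!r} mask must be 3-D")
            if not occ.any():
                raise EmptyPlateError(f"plate {plate!r} is empty")
            if self.interface_side.get(plate) not in ("low", "high"):
                raise ValueError(f"interface_side[{plate!r}] must be 'low' or 'high'")
        # plates must be pairwise disjoint
        total = None
        for occ in self.plate_masks.values():
            if total is None:
                total = occ.astype(np.int8).copy()
            else:
                total += occ
        if total is not None and (total > 1).any():
            raise ValueError("plate masks overlap")
        return self

    @classmethod
    def from_label_volume(cls, labels: np.ndarray, spacing, laterality,
                          interface_side: dict[str, str]) -> "SegmentationMask":
        masks = {p: labels == c for p, c in PLATE_CODES.items() if (labels == c).any()}
        return cls(masks, dict(interface_side), tuple(spacing), laterality).validate()

    def footprint(self, plate: str) -> np.ndarray:
        """2-D support of a plate (projection along axis 2)."""
        return self.plate_masks[plate].any(axis=2)


def _exposed(occ: np.ndarray, axis: int, side: str) -> np.ndarray:
    """Voxels whose face on (axis, side) borders background."""
    nb = np.zeros_like(occ)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if side == "low":
        dst[axis], src[axis] = slice(1, None), slice(0, -1)
    else:
        dst[axis], src[axis] = slice(0, -1), slice(1, None)
    nb[tuple(dst)] = occ[tuple(src)]
    return occ & ~nb


def _face_centers(vox_idx: tuple[np.ndarray, ...], axis: int, side: str,
                  spacing) -> np.ndarray:
    pts = np.stack([(vox_idx[a] + 0.5) * spacing[a] for a in range(3)], axis=1)
    pts[:, axis] = (vox_idx[axis] + (0.0 if side == "low" else 1.0)) * spacing[axis]
    return pts


@dataclass
class ThicknessMap:
    """Per interface position: thickness (mm) over each plate.

    ``ij`` are the in-plane voxel indices of the interface positions
    (used to look subregion labels up in the atlas); ``xyz`` the positions
    in mm; NaN thickness marks positions with no opposing surface.
    """

    plates: dict[str, dict[str, np.ndarray]]
    spacing: tuple[float, float, float]
    n_missing: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for plate, d in self.plates.items():
            rows.append(pd.DataFrame({
                "plate": plate,
                "i": d["ij"][:, 0], "j": d["ij"][:, 1],
                "thickness_mm": d["thickness"],
            }))
        return pd.concat(rows, ignore_index=True)


def compute_thickness_map(mask: SegmentationMask) -> ThicknessMap:
    """Nearest-surface thickness at every bone-interface position."""
    mask.validate()
    plates: dict[str, dict[str, np.ndarray]] = {}
    n_missing: dict[str, int] = {}
    for plate, occ in mask.plate_masks.items():
        iface_side = mask.interface_side[plate]
        iface_vox = np.nonzero(_exposed(occ, 2, iface_side))
        iface_pts = _face_centers(iface_vox, 2, iface_side, mask.spacing)

        # articular surface: exposed faces opposite the interface along the
        # depth axis (the lateral cartilage margin is not articular surface)
        surf_side = "high" if iface_side == "low" else "low"
        surf_pts = []
        vox = np.nonzero(_exposed(occ, 2, surf_side))
        if vox[0].size:
            surf_pts.append(_face_centers(vox, 2, surf_side, mask.spacing))
        thick = np.full(iface_pts.shape[0], np.nan)
        if surf_pts:
            tree = cKDTree(np.concatenate(surf_pts))
            thick, _ = tree.query(iface_pts, workers=-1)
        miss = int(np.isnan(thick).sum())
        if miss or not surf_pts:
            miss = miss if surf_pts else len(thick)
            log.warning("plate %s: %d interface positions without opposing surface",
                        plate, miss)
        n_missing[plate] = miss
        plates[plate] = {
            "ij": np.stack([iface_vox[0], iface_vox[1]], axis=1),
            "xyz": iface_pts,
            "thickness": thick if surf_pts else np.full(len(iface_pts), np.nan),
        }
    return ThicknessMap(plates=plates, spacing=mask.spacing, n_missing=n_missing)


# ---------------------------------------------------------------------------
# subregion atlas
# ---------------------------------------------------------------------------

@dataclass
class SubregionAtlas:
    """Subregion label per in-plane position, per plate."""

    labels2d: dict[str, np.ndarray]   # object dtype; '' outside support
    spacing: tuple[float, float, float]
    laterality: str

    def area_mm2(self, label: str) -> float:
        plate = _plate_of_label(label)
        px = float(self.spacing[0] * self.spacing[1])
        return float((self.labels2d[plate] == label).sum()) * px

    def plate_area_mm2(self, plate: str) -> float:
        px = float(self.spacing[0] * self.spacing[1])
        return float((self.labels2d[plate] != "").sum()) * px

    def areas(self) -> dict[str, float]:
        return {lab: self.area_mm2(lab)
                for plate in self.labels2d
                for lab in SUBREGIONS_OF_PLATE[plate]}


def _plate_of_label(label: str) -> str:
    for plate, subs in SUBREGIONS_OF_PLATE.items():
        if label in subs:
            return plate
    raise KeyError(label)


def partition_plate(support: np.ndarray, spacing2d, plate: str,
                    laterality: str,
                    central_area_fraction: float = CENTRAL_AREA_FRACTION,
                    ) -> np.ndarray:
    """Assign each supported in-plane position to a subregion label.

    Returns an object-dtype array, '' outside the support.
    """
    if plate not in PLATES:
        raise ValueError(f"unknown plate {plate!r}")
    ii, jj = np.nonzero(support)
    if ii.size < 9:
        raise EmptyPlateError(f"plate {plate!r} support degenerate ({ii.size} px)")
    dx, dy = spacing2d
    labels = np.full(support.shape, "", dtype=object)
    subs = SUBREGIONS_OF_PLATE[plate]

    if plate in TIBIAL_PLATES:
        x = (ii + 0.5) * dx
        y = (jj + 0.5) * dy
        cx, cy = x.mean(), y.mean()        # area centroid
        w = (ii.max() - ii.min() + 1) * dx  # bounding-box extents
        h = (jj.max() - jj.min() + 1) * dy
        u = (x - cx) / (w / 2.0)
        v = (y - cy) / (h / 2.0)
        # central ellipse with the bbox aspect ratio: the configured
        # fraction of pixels with smallest scaled radius
        r = np.hypot(u, v)
        k = max(1, int(round(central_area_fraction * ii.size)))
        thr = np.partition(r, k - 1)[k - 1]
        central = r <= thr
        c_lab, e_lab, i_lab, a_lab, p_lab = subs
        sign = interior_sign(plate, laterality)
        out = np.where(central, c_lab,
                       np.where(np.abs(v) > np.abs(u),
                                np.where(v > 0, a_lab, p_lab),
                                np.where(np.sign(u) * sign > 0, i_lab, e_lab)))
        labels[ii, jj] = out
    else:  # femoral plates: three equal-width mediolateral bands
        i0, i1 = ii.min(), ii.max()
        w = i1 - i0 + 1
        e1 = i0 + int(round(w / 3.0))
        e2 = i0 + int(round(2.0 * w / 3.0))
        c_lab, e_lab, i_lab = subs
        band = np.where(ii < e1, 0, np.where(ii < e2, 1, 2))
        sign = interior_sign(plate, laterality)
        # band index 2 is at the high-i end; interior band sits at the
        # notch-facing end
        hi_lab, lo_lab = (i_lab, e_lab) if sign > 0 else (e_lab, i_lab)
        out = np.where(band == 1, c_lab, np.where(band == 2, hi_lab, lo_lab))
        labels[ii, jj] = out
    return labels


def build_subregion_atlas(mask: SegmentationMask, plate: str | None = None,
                          central_area_fraction: float = CENTRAL_AREA_FRACTION,
                          ) -> SubregionAtlas:
    """Partition one plate (or all plates) into subregions."""
    plates = [plate] if plate is not None else list(mask.plate_masks)
    labels2d = {}
    for p in plates:
        labels2d[p] = partition_plate(mask.footprint(p), mask.spacing[:2], p,
                                      mask.laterality, central_area_fraction)
    return SubregionAtlas(labels2d=labels2d, spacing=mask.spacing,
                          laterality=mask.laterality)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class RegionalThickness:
    """Mean thickness (mm) per subregion, region, compartment and joint."""

    values: dict[str, float]
    n_positions: dict[str, int]

    def __getitem__(self, loc: str) -> float:
        return self.values[loc]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name="mean_thickness_mm")


def summarize_thickness(tmap: ThicknessMap, atlas: SubregionAtlas
                        ) -> RegionalThickness:
    """Area-weighted subregional/regional means and compartment sums.

    Interface positions are on a uniform in-plane grid, so the area-weighted
    mean is the plain mean over positions.  MFTC = MT + cMF, LFTC = LT + cLF,
    FTJ = (MFTC + LFTC) / 2.  NaN-thickness positions (no opposing surface)
    are excluded.
    """
    values: dict[str, float] = {}
    counts: dict[str, int] = {}
    for plate, d in tmap.plates.items():
        if plate not in atlas.labels2d:
            raise ValueError(f"atlas lacks plate {plate!r}")
        lab2d = atlas.labels2d[plate]
        ij = d["ij"]
        labs = lab2d[ij[:, 0], ij[:, 1]]
        thick = d["thickness"]
        ok = np.isfinite(thick) & (labs != "")
        if (labs == "").any():
            raise ValueError(f"thickness map and atlas supports differ on {plate!r}")
        values[plate] = float(np.mean(thick[ok]))
        counts[plate] = int(ok.sum())
        for sub in SUBREGIONS_OF_PLATE[plate]:
            sel = ok & (labs == sub)
            values[sub] = float(np.mean(thick[sel])) if sel.any() else float("nan")
            counts[sub] = int(sel.sum())
    if all(p in values for p in ("MT", "cMF")):
        values["MFTC"] = values["MT"] + values["cMF"]
        counts["MFTC"] = counts["MT"] + counts["cMF"]
    if all(p in values for p in ("LT", "cLF")):
        values["LFTC"] = values["LT"] + values["cLF"]
        counts["LFTC"] = counts["LT"] + counts["cLF"]
    if all(c in values for c in ("MFTC", "LFTC")):
        values["FTJ"] = 0.5 * (values["MFTC"] + values["LFTC"])
        counts["FTJ"] = counts["MFTC"] + counts["LFTC"]
    return RegionalThickness(values=values, n_positions=counts)
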