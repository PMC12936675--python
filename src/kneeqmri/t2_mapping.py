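"""Voxel-wise T2 estimation from the two qDESS echoes and laminar summaries.

The core estimator is the ideal-spoiling two-echo exponential-ratio
inversion: with echo signals s1 and s2 acquired TR apart at echo time TE,

    T2 = -2 (TR - TE) / ln(s2 / s1),        valid when 0 < s2 < s1.

A full steady-state analytic correction (flip-angle and T1 dependent) can
be plugged in through ``correction``; the default is the identity, and the
synthetic forward model is built to match the core estimator exactly.

Laminar analysis splits every cartilage voxel stack at 50 % of local
thickness: a voxel is *deep* iff its center depth fraction (0 at the bone
interface, 1 at the articular surface) is below 0.5, *superficial*
otherwise.  Voxels with invalid T2 are excluded from means and reported
as a QC fraction, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .regions import LATERAL_PLATES, MEDIAL_PLATES, PLATES

log = logging.getLogger(__name__)

# reason codes for invalid voxels
VALID, BAD_S1, RATIO_GE_ONE, BAD_S2 = 0, 1, 2, 3


def estimate_t2_voxel(s1, s2, tr_ms: float, te_ms: float):
    """T2 (ms) from a pair of qDESS echo signals; NaN where invalid.

    Accepts scalars or arrays.  Returns ``(t2, reason)`` where ``reason``
    is 0 for valid voxels, 1 for s1 <= 0, 2 for s2 >= s1 (non-decaying
    ratio, T2 unbounded), 3 for s2 <= 0.
    """
    if not te_ms < tr_ms:
        raise ValueError("te_ms must be smaller than tr_ms")
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    reason = np.zeros(np.broadcast(s1, s2).shape, dtype=np.int8)
    reason[np.broadcast_to(s1 <= 0, reason.shape)] = BAD_S1
    reason[(reason == 0) & np.broadcast_to(s2 <= 0, reason.shape)] = BAD_S2
    reason[(reason == 0) & np.broadcast_to(s2 >= s1, reason.shape)] = RATIO_GE_ONE
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(reason == 0, s2 / np.where(s1 > 0, s1, np.nan), np.nan)
        t2 = -2.0 * (tr_ms - te_ms) / np.log(ratio)
    t2 = np.where(reason == 0, t2, np.nan)
    if t2.ndim == 0:
        return float(t2), int(reason)
    return t2, reason


def stack_depth_fractions(n: int) -> np.ndarray:
    """Center depth fractions of an n-voxel stack, interface to surface."""
    return (np.arange(n) + 0.5) / n


def assign_laminae(stack_depths_mm, local_thickness_mm: float) -> np.ndarray:
    """Layer labels for a depth-ordered voxel stack.

    ``stack_depths_mm`` are voxel-center distances from the bone interface;
    a voxel is 'deep' iff its center depth fraction is < 0.5, else
    'superficial' (centers exactly at 50 % count as superficial).
    """
    depths = np.asarray(stack_depths_mm, dtype=float)
    if depths.size == 0:
        raise ValueError("empty voxel stack")
    if local_thickness_mm <= 0:
        raise ValueError("local_thickness_mm must be > 0")
    frac = depths / local_thickness_mm
    return np.where(frac < 0.5, "deep", "superficial")


@dataclass
class T2Map:
    """Voxel-wise T2 (ms) and depth fractions over the cartilage plates."""

    t2: np.ndarray          # float volume; NaN outside cartilage or invalid
    depth_frac: np.ndarray  # float volume; NaN outside cartilage
    plate_labels: np.ndarray  # object volume; '' outside cartilage
    reason: np.ndarray      # int8 volume of validity reason codes
    spacing: tuple[float, float, float]

    def valid_fraction(self, plate: str) -> float:
        sel = self.plate_labels == plate
        if not sel.any():
            return float("nan")
        return float(np.isfinite(self.t2[sel]).mean())


def estimate_t2_map(echo1: np.ndarray, echo2: np.ndarray, mask,
                    tr_ms: float, te_ms: float,
                    correction: Callable[[np.ndarray], np.ndarray] | None = None,
                    ) -> T2Map:
    """Voxel-wise T2 over a :class:`~kneeqmri.morphometry.SegmentationMask`.

    Depth fractions use the same interface-to-surface correspondence as
    thickness: voxel stacks run along axis 2 from the plate's bone
    interface to the articular surface.
    """
    t2 = np.full(echo1.shape, np.nan)
    depth = np.full(echo1.shape, np.nan)
    reason = np.zeros(echo1.shape, dtype=np.int8)
    plate_labels = np.full(echo1.shape, "", dtype=object)
    for plate, occ in mask.plate_masks.items():
        vox = occ.nonzero()
        est, rs = estimate_t2_voxel(echo1[vox], echo2[vox], tr_ms, te_ms)
        if correction is not None:
            est = correction(est)
        t2[vox] = est
        reason[vox] = rs
        plate_labels[vox] = plate
        frac = _column_depth_fractions(occ, mask.interface_side[plate])
        depth[vox] = frac[vox]
        n_bad = int((rs != VALID).sum())
        if n_bad:
            log.info("plate %s: %d/%d voxels with invalid T2", plate, n_bad, len(rs))
    return T2Map(t2=t2, depth_frac=depth, plate_labels=plate_labels,
                 reason=reason, spacing=tuple(mask.spacing))


def _column_depth_fractions(occ: np.ndarray, interface_side: str) -> np.ndarray:
    """Per-voxel center depth fraction within each axis-2 column."""
    frac = np.full(occ.shape, np.nan)
    n_col = occ.sum(axis=2)
    # rank of each occupied voxel within its column, counted from the
    # interface side
    order = np.cumsum(occ, axis=2) - 1          # 0-based from low end
    if interface_side == "high":
        order = n_col[:, :, None] - 1 - order
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (order + 0.5) / n_col[:, :, None]
    frac[occ] = f[occ]
    return frac


@dataclass
class LaminarT2Summary:
    """Mean T2 (ms) per location x layer with valid-voxel counts."""

    table: pd.DataFrame  # columns: location, layer, mean_t2_ms, n_valid

    def get(self, location: str, layer: str = "total") -> float:
        sel = self.table[(self.table.location == location)
                         & (self.table.layer == layer)]
        if sel.empty:
            raise KeyError((location, layer))
        return float(sel.mean_t2_ms.iloc[0])

    def n_valid(self, location: str, layer: str = "total") -> int:
        sel = self.table[(self.table.location == location)
                         & (self.table.layer == layer)]
        return int(sel.n_valid.iloc[0])


def summarize_t2(t2map: T2Map, atlas=None) -> LaminarT2Summary:
    """Region x layer means plus compartment/joint aggregation.

    Region means pool valid voxels; compartment and joint values are the
    unweighted means of their member *region* values (MFTC = mean(MT, cMF),
    LFTC = mean(LT, cLF), FTJ = mean of all four regions), never re-pooled
    voxels.  Regions with zero valid voxels yield NaN and a log entry.
    """
    if atlas is not None:
        for plate in atlas.labels2d:
            if not (t2map.plate_labels == plate).any():
                raise ValueError(f"T2 map lacks plate {plate!r} present in atlas")
    rows = []
    region_vals: dict[tuple[str, str], float] = {}
    region_ns: dict[tuple[str, str], int] = {}
    present = [p for p in PLATES if (t2map.plate_labels == p).any()]
    for plate in present:
        sel = t2map.plate_labels == plate
        vals = t2map.t2[sel]
        fracs = t2map.depth_frac[sel]
        ok = np.isfinite(vals)
        layers = {
            "total": ok,
            "deep": ok & (fracs < 0.5),
            "superficial": ok & (fracs >= 0.5),
        }
        for layer, lsel in layers.items():
            n = int(lsel.sum())
            mean = float(vals[lsel].mean()) if n else float("nan")
            if n == 0:
                log.warning("region %s layer %s: no valid voxels", plate, layer)
            region_vals[(plate, layer)] = mean
            region_ns[(plate, layer)] = n
            rows.append({"location": plate, "layer": layer,
                         "mean_t2_ms": mean, "n_valid": n})
    compartments = {"MFTC": MEDIAL_PLATES, "LFTC": LATERAL_PLATES, "FTJ": PLATES}
    for comp, members in compartments.items():
        if not all(m in present for m in members):
            continue
        for layer in ("total", "deep", "superficial"):
            vals = [region_vals[(m, layer)] for m in members]
            rows.append({
                "location": comp, "layer": layer,
                "mean_t2_ms": float(np.mean(vals)),
                "n_valid": int(sum(region_ns[(m, layer)] for m in members)),
            })
    return LaminarT2Summary(table=pd.DataFrame(rows))
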